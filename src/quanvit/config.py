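"""Flat dotted-key run configuration: parsing, validation, defaults, fixtures.

A run config is a flat mapping (YAML file or dict) with dotted keys, e.g.::

    task: binary
    mode: qnn
    scale: 0.125
    train.max_epochs: 10

Unknown keys are rejected with the nearest valid key named; missing required
keys are reported by name; defaults are filled in and echoed so any run is
reconstructible from its echoed config plus seed.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

__all__ = ["KNOWN_KEYS", "REQUIRED_KEYS", "RunConfig", "validate_config",
           "make_fixtures"]

#: key -> (default, type)
KNOWN_KEYS: dict[str, tuple[Any, type]] = {
    "task": (None, str),                  # binary | multi
    "mode": (None, str),                  # qnn | cnn
    "scale": (0.125, float),
    "seed": (0, int),
    "k": (5, int),
    "out_dir": ("runs", str),
    "input_size": (32, int),
    "head": ("softmax", str),             # softmax | sigmoid (binary only)
    "data.manifest": ("", str),           # external manifest; empty = phantoms
    "data.n_per_class": (25, int),
    "data.image_size": (32, int),
    "data.stage1_target": (0, int),       # 0 = auto (current max class count)
    "data.stage2_target": (0, int),       # 0 = skip stage 2
    "data.holdout_per_class": (5, int),
    "train.lr": (1e-3, float),
    "train.batch_size": (32, int),
    "train.max_epochs": (20, int),
    "train.patience": (5, int),
    "vit.depth": (12, int),
    "vit.dim": (768, int),
    "vit.heads": (12, int),
    "vit.upsample_tokens": (False, bool),
    "quanv.seed": (-1, int),              # -1 = reuse the run seed
    "quanv.trainable": (False, bool),
}

REQUIRED_KEYS = ("task", "mode")

_CHOICES = {
    "task": ("binary", "multi"),
    "mode": ("qnn", "cnn"),
    "head": ("softmax", "sigmoid"),
}


@dataclass(frozen=True)
class RunConfig:
    """Validated flat configuration with all defaults filled."""

    values: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.values[key]

    def echo(self) -> dict[str, Any]:
        """The full key -> value mapping (for logging into run outputs)."""
        return dict(self.values)


def _coerce(key: str, value: Any, typ: type) -> Any:
    if typ is bool:
        if isinstance(value, bool):
            return value
        if str(value).lower() in ("true", "1", "yes"):
            return True
        if str(value).lower() in ("false", "0", "no"):
            return False
        raise ValueError(f"config key {key!r}: cannot parse {value!r} as bool")
    try:
        return typ(value)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"config key {key!r}: {exc}") from exc


def validate_config(raw: Mapping[str, Any] | str | Path) -> RunConfig:
    """Validate a raw flat mapping (or YAML file path) into a RunConfig."""
    if isinstance(raw, (str, Path)):
        import yaml

        text = Path(raw).read_text()
        raw = yaml.safe_load(text) or {}
    raw = dict(raw)
    unknown = [k for k in raw if k not in KNOWN_KEYS]
    if unknown:
        hints = []
        for k in unknown:
            close = difflib.get_close_matches(k, KNOWN_KEYS, n=1)
            hints.append(f"{k!r}" + (f" (did you mean {close[0]!r}?)" if close else ""))
        raise ValueError(
            f"unknown config keys: {', '.join(hints)}; "
            f"known keys: {sorted(KNOWN_KEYS)}"
        )
    missing = [k for k in REQUIRED_KEYS if k not in raw or raw[k] in (None, "")]
    if missing:
        raise ValueError(f"missing required config keys: {missing}")
    values: dict[str, Any] = {}
    for key, (default, typ) in KNOWN_KEYS.items():
        values[key] = _coerce(key, raw[key], typ) if key in raw else default
    for key, choices in _CHOICES.items():
        if values[key] is not None and values[key] not in choices:
            raise ValueError(f"config key {key!r} must be one of {choices}")
    if not (0 < values["scale"] <= 1):
        raise ValueError("scale must lie in (0, 1]")
    if values["k"] < 2:
        raise ValueError("k must be >= 2")
    return RunConfig(values)


def make_fixtures(seed: int = 0, image_size: int = 32):
    """Tiny deterministic datasets + desk-scale configs for both modes.

    Returns a dict with a binary dataset (15 + 15 frames), a multi-class
    dataset (8 per class), and scale-1/8 run configs for the qnn and cnn
    modes — small enough that a full train run completes in well under two
    minutes on one CPU.
    """
    from .phantom import generate_dataset, make_splits

    binary = generate_dataset(
        {"normal": 15, "polyp": 15}, image_size=image_size, seed=seed
    )
    binary = make_splits(binary, {"normal": 3, "polyp": 3}, ratio=0.75, seed=seed)
    multi = generate_dataset(
        {"normal": 8, "hyperplastic": 8, "adenomatous": 8, "serrated": 8},
        image_size=image_size, seed=seed + 1,
    )
    multi = make_splits(
        multi, {c: 2 for c in ("normal", "hyperplastic", "adenomatous", "serrated")},
        ratio=0.75, seed=seed,
    )
    configs = {
        mode: validate_config(
            {
                "task": task,
                "mode": mode,
                "scale": 0.125,
                "seed": seed,
                "input_size": image_size,
                "data.image_size": image_size,
                "train.max_epochs": 5,
            }
        )
        for mode, task in (("qnn", "binary"), ("cnn", "binary"))
    }
    return {"binary": binary, "multi": multi, "configs": configs}
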