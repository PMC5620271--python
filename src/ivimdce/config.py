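"""Pipeline configuration: defaults, validation, (de)serialization.

An empty config file yields the full default protocol (13-b-value IVIM
scheme, 65-dynamic DCE scheme with injection at the 8th dynamic, the
published 29/46 two-group cohort parameters).  Unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cohort import CohortSpec
from .errors import ValidationError
from .schemes import DceScheme, DwiScheme


@dataclass(frozen=True)
class FitOptions:
    """Knobs of the voxel-wise fitting stages."""

    b_threshold: float = 200.0
    snr_k: float = 5.0
    refine_D: bool = False
    cutoff_criterion: str = "youden"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.b_threshold < 0:
            raise ValidationError("b_threshold: must be >= 0")
        if self.snr_k < 0:
            raise ValidationError("snr_k: must be >= 0")
        if self.cutoff_criterion not in ("youden", "accuracy"):
            raise ValidationError("cutoff_criterion: 'youden' or 'accuracy'")
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha: must lie in (0, 1)")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end run needs, round-trippable to YAML/JSON."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    dwi_scheme: DwiScheme = field(default_factory=DwiScheme)
    dce_scheme: DceScheme = field(default_factory=DceScheme)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    fit: FitOptions = field(default_factory=FitOptions)

    def save(self, path: str | Path) -> None:
        d = _listify(asdict(self))
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(d, sort_keys=False))
        else:
            path.write_text(json.dumps(d, indent=2))


def _listify(obj):
    """Tuples -> lists recursively (YAML/JSON friendliness)."""
    if isinstance(obj, dict):
        return {k: _listify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_listify(v) for v in obj]
    return obj


_SECTIONS = {
    "dwi_scheme": DwiScheme,
    "dce_scheme": DceScheme,
    "cohort": CohortSpec,
    "fit": FitOptions,
}


def _build_section(cls, data: dict):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValidationError(
            f"{cls.__name__}: unknown keys {sorted(unknown)}")
    kw = dict(data)
    for key in ("b_values", "shape"):
        if key in kw and isinstance(kw[key], list):
            kw[key] = tuple(kw[key])
    if cls is CohortSpec and "group_params" in kw:
        kw["group_params"] = {
            grp: {k: tuple(v) for k, v in params.items()}
            for grp, params in kw["group_params"].items()
        }
    return cls(**kw)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML or JSON config (empty file = defaults)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"config: file not found: {path}")
    text = path.read_text()
    if path.suffix in (".yml", ".yaml"):
        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text) if text.strip() else {}
    raw = raw or {}
    if not isinstance(raw, dict):
        raise ValidationError("config: top level must be a mapping")

    top_allowed = {"out_dir", "seed", *_SECTIONS}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ValidationError(f"config: unknown keys {sorted(unknown)}")
    kw: dict = {}
    for key in ("out_dir", "seed"):
        if key in raw:
            kw[key] = raw[key]
    for key, cls in _SECTIONS.items():
        if key in raw:
            kw[key] = _build_section(cls, raw[key] or {})
    return PipelineConfig(**kw)
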