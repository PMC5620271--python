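"""Acquisition schemes for the diffusion and dynamic contrast-enhanced series.

Defaults reproduce a 3-T head-and-neck protocol: a 13-b-value IVIM
diffusion acquisition (b from 0 to 1000 s/mm², three orthogonal
directions averaged) and a 65-dynamic spoiled-gradient-echo DCE
acquisition with a 5° pre-contrast scan, 15° dynamics, TR 4.8 ms and
contrast arrival at the 8th dynamic.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError

#: 13-b-value IVIM protocol (s/mm²).
DEFAULT_B_VALUES: tuple[float, ...] = (
    0, 10, 20, 30, 40, 60, 100, 120, 160, 200, 300, 500, 1000,
)


@dataclass(frozen=True)
class DwiScheme:
    """Diffusion-weighted acquisition: b-values and signal averaging.

    Parameters
    ----------
    b_values : strictly increasing diffusion weightings, s/mm²; must
        start at 0 (the unweighted reference).
    n_averages : number of signal averages folded into the stored
        (direction-averaged) series; reduces effective noise by √n.
    """

    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    n_averages: int = 3

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b.ndim != 1 or b.size < 2:
            raise ValidationError("b_values: need at least two b-values")
        if b[0] != 0:
            raise ValidationError("b_values: first b-value must be 0")
        if np.any(np.diff(b) <= 0):
            raise ValidationError("b_values: must be strictly increasing")
        if self.n_averages < 1:
            raise ValidationError("n_averages: must be >= 1")
        object.__setattr__(self, "b_values", tuple(float(x) for x in b))

    @property
    def n_b(self) -> int:
        return len(self.b_values)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DwiScheme":
        d = json.loads(Path(path).read_text())
        d["b_values"] = tuple(d["b_values"])
        return cls(**d)


@dataclass(frozen=True)
class DceScheme:
    """Dynamic contrast-enhanced SPGR acquisition.

    Parameters
    ----------
    n_dynamics : number of dynamic volumes.
    dt : inter-dynamic interval, s (default 9.2 s ≈ 10 min / 65).
    injection_index : 1-based dynamic at which contrast arrives.
    TR : repetition time, ms.
    flip_pre, flip_dyn : flip angles of the pre-contrast and dynamic
        scans, degrees; the two-point T1 fit needs them distinct.
    r1 : contrast-agent longitudinal relaxivity, 1/(mM·s)
        (Gd-DOTA at 3 T ≈ 3.5).
    dose : injected dose, mmol/kg body weight.
    """

    n_dynamics: int = 65
    dt: float = 9.2
    injection_index: int = 8
    TR: float = 4.8
    flip_pre: float = 5.0
    flip_dyn: float = 15.0
    r1: float = 3.5
    dose: float = 0.1

    def __post_init__(self) -> None:
        if self.n_dynamics < 2:
            raise ValidationError("n_dynamics: must be >= 2")
        if self.dt <= 0:
            raise ValidationError("dt: must be > 0")
        if not (1 <= self.injection_index <= self.n_dynamics):
            raise ValidationError(
                f"injection_index: {self.injection_index} outside "
                f"[1, {self.n_dynamics}]"
            )
        if self.TR <= 0:
            raise ValidationError("TR: must be > 0")
        for name in ("flip_pre", "flip_dyn"):
            a = getattr(self, name)
            if not (0 < a < 90):
                raise ValidationError(f"{name}: must lie in (0, 90) degrees")
        if self.flip_pre == self.flip_dyn:
            raise ValidationError("flip_pre: must differ from flip_dyn")
        if self.r1 <= 0:
            raise ValidationError("r1: must be > 0")
        if self.dose <= 0:
            raise ValidationError("dose: must be > 0")

    @property
    def times(self) -> np.ndarray:
        """Acquisition times of the dynamics, s from series start."""
        return np.arange(self.n_dynamics) * self.dt

    @property
    def injection_time(self) -> float:
        """Contrast arrival time, s (time of the injection dynamic)."""
        return (self.injection_index - 1) * self.dt

    @property
    def n_baseline(self) -> int:
        """Number of pre-injection (baseline) dynamics."""
        return self.injection_index - 1

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "DceScheme":
        return cls(**json.loads(Path(path).read_text()))
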