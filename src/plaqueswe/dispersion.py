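"""Analytic dispersion laws used as synthetic ground truth.

A dispersion law maps temporal frequency f (Hz) to shear-wave phase
velocity c_p(f) (m/s). Three kinds are supported:

``constant``
    Non-dispersive medium: c_p(f) = c0. Group and phase velocity
    coincide, which ties the time-domain and Fourier-domain analysis
    stages together in tests.
``power_law``
    c_p(f) = c_ref * (f / f_ref) ** exponent.
``plate_A0``
    Low-frequency asymptote of the lowest antisymmetric (flexural)
    guided mode of an incompressible elastic plate of thickness h and
    bulk shear speed c_T:

        c_p(f) = sqrt(2 * pi * f * h * c_T / sqrt(3))

    i.e. phase speed grows as sqrt(f). This is the standard thin-plate
    model for guided shear waves in layered soft tissue and has a closed
    form, which makes it a verifiable dispersive ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

_KINDS = ("constant", "power_law", "plate_A0")


@dataclass(frozen=True)
class DispersionLaw:
    """Named analytic phase-velocity law c_p(f)."""

    kind: str
    parameters: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown dispersion law kind {self.kind!r}; expected one of {_KINDS}")
        required = {
            "constant": {"c0"},
            "power_law": {"c_ref", "f_ref", "exponent"},
            "plate_A0": {"h", "c_T"},
        }[self.kind]
        missing = required - set(self.parameters)
        if missing:
            raise ValueError(f"{self.kind} law missing parameters: {sorted(missing)}")

    def __call__(self, f):
        return evaluate_dispersion(self, f)

    @classmethod
    def constant(cls, c0: float) -> "DispersionLaw":
        return cls("constant", {"c0": float(c0)})

    @classmethod
    def power_law(cls, c_ref: float, f_ref: float, exponent: float) -> "DispersionLaw":
        return cls("power_law", {"c_ref": float(c_ref), "f_ref": float(f_ref), "exponent": float(exponent)})

    @classmethod
    def plate_a0(cls, h: float, c_T: float) -> "DispersionLaw":
        return cls("plate_A0", {"h": float(h), "c_T": float(c_T)})


def evaluate_dispersion(law: DispersionLaw, f):
    """Phase velocity (m/s) of *law* at frequency *f* (Hz).

    *f* may be a scalar or array; every entry must be strictly positive.
    """
    f_arr = np.asarray(f, dtype=float)
    if np.any(f_arr <= 0):
        raise ValueError("frequency must be strictly positive")
    p = law.parameters
    if law.kind == "constant":
        c = np.broadcast_to(float(p["c0"]), f_arr.shape).copy()
    elif law.kind == "power_law":
        c = p["c_ref"] * (f_arr / p["f_ref"]) ** p["exponent"]
    elif law.kind == "plate_A0":
        c = np.sqrt(2.0 * np.pi * f_arr * p["h"] * p["c_T"] / np.sqrt(3.0))
    else:  # pragma: no cover - guarded in the constructor
        raise ValueError(f"unknown dispersion law kind {law.kind!r}")
    if not np.all(np.isfinite(c)) or np.any(c <= 0):
        raise ValueError("dispersion law produced non-finite or non-positive speed")
    return float(c) if np.isscalar(f) or f_arr.ndim == 0 else c
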