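"""Beer–Lambert transmission arithmetic and nanorod fluorescence blocking.

Photothermal heating of a PCR reaction — directly by water absorption or
indirectly through gold nanorods — obeys Beer's law: the fraction of laser
power transmitted through a path of length L with decadic attenuation ε at
absorber concentration c is T = 10^(−ε·c·L).  Nanorods additionally attenuate
the instrument's fluorescence channels; the blocking metric here averages the
sample/control fluorescence ratio across an LED gain-response curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AbsorberSpec",
    "OpticalPath",
    "GainCurve",
    "BlockingResult",
    "absorbance",
    "transmittance",
    "scale_transmittance",
    "blocking_fraction",
    "decadic_to_natural",
    "natural_to_decadic",
    "calibrate_attenuation",
]

_LN10 = math.log(10.0)


@dataclass(frozen=True)
class AbsorberSpec:
    """An absorbing species: decadic attenuation per (concentration × mm)."""

    decadic_attenuation: float
    concentration: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.decadic_attenuation < 0:
            raise ValueError("decadic_attenuation must be >= 0")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass(frozen=True)
class OpticalPath:
    """A straight optical path through the reaction volume, in mm."""

    length_mm: float
    label: str = "custom"  # "narrowest" | "thickest" | "custom"

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("path length must be positive")


def absorbance(absorber: AbsorberSpec, path: OpticalPath) -> float:
    """Decadic absorbance A = ε·c·L."""
    return absorber.decadic_attenuation * absorber.concentration * path.length_mm


def transmittance(absorber: AbsorberSpec, path: OpticalPath) -> float:
    """Transmitted fraction T = 10^(−ε·c·L)."""
    return 10.0 ** (-absorbance(absorber, path))


def scale_transmittance(t_ref: float, c_ref: float, c_new: float) -> float:
    """Rescale a measured transmittance to a new absorber concentration.

    Along the same path, absorbance is proportional to concentration, so
    ``T_new = t_ref ** (c_new / c_ref)``.
    """
    if not 0.0 < t_ref <= 1.0:
        raise ValueError(f"t_ref must be in (0, 1], got {t_ref}")
    if c_ref <= 0:
        raise ValueError(f"c_ref must be positive, got {c_ref}")
    if c_new < 0:
        raise ValueError(f"c_new must be >= 0, got {c_new}")
    return t_ref ** (c_new / c_ref)


def decadic_to_natural(eps: float) -> float:
    """Convert a decadic (base-10) attenuation coefficient to natural (base-e)."""
    return eps * _LN10


def natural_to_decadic(alpha: float) -> float:
    """Convert a natural (base-e) attenuation coefficient to decadic (base-10)."""
    return alpha / _LN10


def calibrate_attenuation(t_target: float, concentration: float, length_mm: float) -> float:
    """Decadic attenuation that reproduces a target transmittance.

    Vendor extinction coefficients are often proprietary; this solves
    ε = −log10(T)/(c·L) so a printed transmission fraction can anchor the
    optical model.
    """
    if not 0.0 < t_target <= 1.0:
        raise ValueError("t_target must be in (0, 1]")
    if concentration <= 0 or length_mm <= 0:
        raise ValueError("concentration and length must be positive")
    return -math.log10(t_target) / (concentration * length_mm)


@dataclass(frozen=True)
class GainCurve:
    """Fluorescence measured while stepping up the excitation LED power."""

    power: tuple[float, ...]
    fluorescence: tuple[float, ...]
    channel: str = "green"  # green | yellow | orange | red

    def __post_init__(self) -> None:
        if self.channel not in ("green", "yellow", "orange", "red"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if len(self.power) != len(self.fluorescence):
            raise ValueError("power and fluorescence must have equal length")
        if len(self.power) < 1:
            raise ValueError("gain curve needs at least one point")
        p = np.asarray(self.power, dtype=float)
        if not np.all(np.diff(p) > 0):
            raise ValueError("power settings must be strictly increasing")

    @classmethod
    def from_arrays(cls, power, fluorescence, channel="green") -> "GainCurve":
        return cls(tuple(float(x) for x in power), tuple(float(x) for x in fluorescence), channel)


@dataclass(frozen=True)
class BlockingResult:
    """Mean fraction of fluorescence remaining relative to a control sample."""

    fraction: float
    n_used: int
    n_excluded: int  # gain settings skipped because the control read zero


def blocking_fraction(sample: GainCurve, control: GainCurve) -> BlockingResult:
    """Average sample/control fluorescence ratio over the gain response curve.

    1.0 means no blocking; 0.5 means half the light is lost.  The two curves
    must share identical power settings; settings where the control reads zero
    are excluded and counted in ``n_excluded``.
    """
    if sample.power != control.power:
        raise ValueError("sample and control gain curves must share identical power settings")
    s = np.asarray(sample.fluorescence, dtype=float)
    c = np.asarray(control.fluorescence, dtype=float)
    ok = c != 0.0
    n_excluded = int(np.sum(~ok))
    if not np.any(ok):
        raise ValueError("control fluorescence is zero at every gain setting")
    ratios = s[ok] / c[ok]
    return BlockingResult(
        fraction=float(np.mean(ratios)), n_used=int(np.sum(ok)), n_excluded=n_excluded
    )
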