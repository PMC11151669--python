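"""Conditioning of the correlation volume before inversion.

The Legendre inversion assumes quadrature that is uniform in cos ψ, while
the correlation is computed on a uniform θ grid; the |sin θ| weight is
the Jacobian between the two samplings and its application is recorded so
the inversion stage can refuse (or account for) unweighted volumes.  Two
further elementwise clean-ups are provided: a band-pass on both q axes
(spurious static signals are often confined to low q) and a mask around
θ = 0, where uncorrelated per-pixel noise piles up a q = q′ variance
ridge.  All three operations are elementwise and commute.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .correlate import CorrelationVolume


@dataclass(frozen=True)
class ConditioningRecord:
    """What has been applied to a correlation volume, and with what values."""

    sintheta_exponent: float | None = None
    q_low: float | None = None
    q_high: float | None = None
    taper_width: float | None = None
    theta_zero_halfwidth_deg: float | None = None

    def to_dict(self) -> dict:
        return {
            "sintheta_exponent": self.sintheta_exponent,
            "q_low": self.q_low,
            "q_high": self.q_high,
            "taper_width": self.taper_width,
            "theta_zero_halfwidth_deg": self.theta_zero_halfwidth_deg,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ConditioningRecord":
        return cls(**{k: d.get(k) for k in cls.__dataclass_fields__})


def _record(C: CorrelationVolume) -> ConditioningRecord:
    return C.conditioning if C.conditioning is not None else ConditioningRecord()


def apply_sintheta_weight(
    C: CorrelationVolume, exponent: float = 1.0
) -> CorrelationVolume:
    """Multiply the volume by |sin θ|^exponent along the angular axis.

    The default exponent 1 is the Jacobian from uniform-θ to
    uniform-cos θ quadrature; 0.5 and 2 are accepted alternatives and the
    exponent is recorded either way.
    """
    w = np.abs(np.sin(C.theta_grid)) ** exponent
    rec = replace(_record(C), sintheta_exponent=float(exponent))
    return C.copy_with(C.values * w[None, None, :], conditioning=rec)


def q_bandpass(
    C: CorrelationVolume,
    q_low: float = 0.0,
    q_high: float | None = None,
    taper_width: float = 0.0,
) -> CorrelationVolume:
    """Zero entries whose q or q′ falls outside [q_low, q_high].

    The cut is hard by default; ``taper_width`` > 0 replaces it with a
    cosine roll-off of that width (nm^-1) centred on each cut, so the
    value exactly at the cut is half the interior value.
    """
    if q_high is None or q_high == 0.0:
        q_high = C.qmax
    if not (0.0 <= q_low < q_high <= C.qmax * (1 + 1e-12)):
        raise ValueError(
            f"require 0 <= q_low < q_high <= qmax, got ({q_low}, {q_high})"
        )
    q = C.q_grid

    def edge(qv: np.ndarray, cut: float, rising: bool) -> np.ndarray:
        if taper_width <= 0:
            return (qv >= cut) if rising else (qv <= cut)
        x = (qv - cut) / taper_width if rising else (cut - qv) / taper_width
        return np.clip(0.5 * (1.0 + np.sin(np.pi * np.clip(x, -0.5, 0.5))), 0.0, 1.0)

    w1 = np.ones_like(q) if q_low == 0.0 else np.asarray(edge(q, q_low, True), float)
    w2 = (
        np.ones_like(q)
        if q_high >= C.qmax
        else np.asarray(edge(q, q_high, False), float)
    )
    w = w1 * w2
    rec = replace(
        _record(C),
        q_low=float(q_low),
        q_high=float(q_high),
        taper_width=float(taper_width) if taper_width else None,
    )
    return C.copy_with(
        C.values * w[:, None, None] * w[None, :, None], conditioning=rec
    )


def theta_zero_mask(C: CorrelationVolume, halfwidth_deg: float) -> CorrelationVolume:
    """Zero the angular band within ``halfwidth_deg`` of θ = 0 (mod 2π).

    Both the region near 0 and its mirror near 2π are removed: the
    correlation's exchange symmetry makes them equally contaminated by
    per-pixel noise variance.
    """
    if halfwidth_deg < 0:
        raise ValueError("halfwidth must be non-negative")
    th = np.degrees(C.theta_grid)
    dist = np.minimum(th, 360.0 - th)
    keep = dist > halfwidth_deg + 1e-12
    rec = replace(_record(C), theta_zero_halfwidth_deg=float(halfwidth_deg))
    return C.copy_with(C.values * keep[None, None, :], conditioning=rec)
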