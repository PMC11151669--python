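"""Angular intensity cross-correlation of serial diffraction data.

For a dataset of polar-resampled exposures I_i(q, θ), the correlation
volume is

    C(q, q′, Δ) = (1/N) Σ_i (1/nθ) Σ_j I_i(q, θ_j) I_i(q′, θ_j + Δ)

computed ring pair by ring pair with the 1D FFT and the convolution
theorem.  Three modes are supported: ``standard`` (each exposure with
itself), ``background`` (each exposure with a randomly paired partner,
which estimates the static-signal background for uniformly oriented
data), and ``difference`` (the self-correlation of ΔI_i = I_i − I_j(i)).
With a shared pairing the difference mode satisfies
C_DIFF = 2 (C − C_BG) elementwise.

Normalization: each ring correlation is divided by nθ (so C is
independent of the angular sampling rate) and the dataset average by N.
The background term is symmetrized over each pair, ½[corr(I_i, I_j) +
corr(I_j, I_i)], which preserves the exchange symmetry
C(q, q′, Δ) = C(q′, q, −Δ) and makes the difference identity exact for
any derangement.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .geometry import PolarIntensity
from .volio import Volume3D


@dataclass
class CorrelationVolume:
    """C(q, q′, θ) on an nq×nq×nθ grid with provenance metadata."""

    values: np.ndarray
    qmax: float
    mode: str = "standard"
    n_patterns: int = 0
    split: str = "all"  # "all" | "a" (odd-index frames) | "b" (even-index)
    mask_corrected: bool = False
    conditioning: Any = None  # ConditioningRecord once conditioned

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("correlation volume must have shape (nq, nq, ntheta)")

    @property
    def nq(self) -> int:
        return self.values.shape[0]

    @property
    def ntheta(self) -> int:
        return self.values.shape[2]

    @property
    def q_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.qmax, self.nq)

    @property
    def theta_grid(self) -> np.ndarray:
        """θ samples in radians, uniform on [0, 2π)."""
        return np.arange(self.ntheta) * 2.0 * np.pi / self.ntheta

    def copy_with(self, values: np.ndarray, **meta: Any) -> "CorrelationVolume":
        kwargs = dict(
            qmax=self.qmax,
            mode=self.mode,
            n_patterns=self.n_patterns,
            split=self.split,
            mask_corrected=self.mask_corrected,
            conditioning=self.conditioning,
        )
        kwargs.update(meta)
        return CorrelationVolume(values=values, **kwargs)

    # -- persistence ---------------------------------------------------------

    def to_volume3d(self) -> Volume3D:
        meta = {
            "kind": "correlation",
            "mode": self.mode,
            "n_patterns": self.n_patterns,
            "split": self.split,
            "mask_corrected": self.mask_corrected,
            "conditioning": None
            if self.conditioning is None
            else self.conditioning.to_dict(),
        }
        return Volume3D(
            values=self.values,
            axis_names=("q", "q", "theta"),
            axis_max=(self.qmax, self.qmax, 360.0),
            meta=meta,
        )

    @classmethod
    def from_volume3d(cls, vol: Volume3D) -> "CorrelationVolume":
        from .condition import ConditioningRecord

        meta = vol.meta or {}
        cond = meta.get("conditioning")
        return cls(
            values=vol.values,
            qmax=vol.axis_max[0],
            mode=meta.get("mode", "standard"),
            n_patterns=int(meta.get("n_patterns", 0)),
            split=meta.get("split", "all"),
            mask_corrected=bool(meta.get("mask_corrected", False)),
            conditioning=None if cond is None else ConditioningRecord.from_dict(cond),
        )


def ring_correlation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Circular cross-correlation c(Δ) = Σ_j a(θ_j) b(θ_j + Δ) via the FFT."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ring profiles must be 1D and of equal length")
    return np.fft.irfft(np.conj(np.fft.rfft(a)) * np.fft.rfft(b), n=len(a))


def random_derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    """A uniformly sampled permutation with no fixed point (rejection method)."""
    if n < 2:
        raise ValueError("a derangement needs at least two elements")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


def split_odd_even(patterns: Sequence[PolarIntensity]):
    """('a', 'b') sub-datasets from even- and odd-positioned frames (0-based)."""
    return list(patterns[0::2]), list(patterns[1::2])


def _check_patterns(patterns: Sequence[PolarIntensity]) -> tuple[int, int, float]:
    if len(patterns) < 1:
        raise ValueError("need at least one pattern")
    nq, nth, qmax = patterns[0].nq, patterns[0].ntheta, patterns[0].qmax
    for p in patterns:
        if p.nq != nq or p.ntheta != nth or p.qmax != qmax:
            raise ValueError("all polar patterns must share the same grids")
    return nq, nth, qmax


def dataset_correlation(
    patterns: Sequence[PolarIntensity],
    mode: str = "standard",
    pairing: np.ndarray | None = None,
    seed: int = 0,
    split: str = "all",
) -> CorrelationVolume:
    """Correlation volume of a dataset in one of the three modes.

    ``pairing`` is the partner permutation j(i) used by the background
    and difference modes; pass the same array to both to make
    C_DIFF = 2 (C − C_BG) hold exactly.  If omitted, a random
    derangement seeded by ``seed`` is drawn (falling back to the cyclic
    shift i → i+1 for very small datasets where rejection sampling is
    wasteful).
    """
    nq, nth, qmax = _check_patterns(patterns)
    n = len(patterns)
    if mode not in ("standard", "background", "difference"):
        raise ValueError(f"unknown correlation mode {mode!r}")
    if mode != "standard":
        if n < 2:
            raise ValueError(f"mode {mode!r} requires at least two patterns")
        if pairing is None:
            if n < 4:
                pairing = np.roll(np.arange(n), -1)
            else:
                pairing = random_derangement(n, np.random.default_rng(seed))
        pairing = np.asarray(pairing)
        if np.any(pairing == np.arange(n)):
            raise ValueError("pairing must have no fixed points (j(i) != i)")

    acc = np.zeros((nq, nq, nth // 2 + 1), dtype=np.complex128)
    ffts = None
    if mode in ("standard", "background"):
        for i, p in enumerate(patterns):
            F = np.fft.rfft(p.values, axis=1)
            if mode == "standard":
                acc += np.conj(F)[:, None, :] * F[None, :, :]
            else:
                if ffts is None:
                    ffts = [np.fft.rfft(pp.values, axis=1) for pp in patterns]
                G = ffts[pairing[i]]
                cross = np.conj(F)[:, None, :] * G[None, :, :]
                acc += 0.5 * (cross + np.conj(np.swapaxes(cross, 0, 1)))
    else:  # difference
        for i, p in enumerate(patterns):
            diff = p.values - patterns[pairing[i]].values
            F = np.fft.rfft(diff, axis=1)
            acc += np.conj(F)[:, None, :] * F[None, :, :]

    values = np.fft.irfft(acc, n=nth, axis=2) / (nth * n)
    return CorrelationVolume(
        values=values,
        qmax=qmax,
        mode=mode,
        n_patterns=n,
        split=split,
    )


def dataset_correlation_ab(
    patterns: Sequence[PolarIntensity],
    mode: str = "standard",
    seed: int = 0,
) -> tuple[CorrelationVolume, CorrelationVolume, CorrelationVolume]:
    """(full, a, b) correlation volumes; a/b are the odd/even-frame splits."""
    pa, pb = split_odd_even(patterns)
    full = dataset_correlation(patterns, mode=mode, seed=seed)
    va = dataset_correlation(pa, mode=mode, seed=seed + 1, split="a")
    vb = dataset_correlation(pb, mode=mode, seed=seed + 2, split="b")
    return full, va, vb


def mask_correlation(polar_mask: PolarIntensity) -> CorrelationVolume:
    """Self-correlation of a binary detector mask in its polar representation."""
    vol = dataset_correlation([polar_mask], mode="standard")
    vol.mode = "mask"
    return vol


def mask_correction(
    C: CorrelationVolume,
    C_mask: CorrelationVolume,
    tol_rel: float = 1e-10,
) -> CorrelationVolume:
    """Divide out the mask correlation: C / C_mask where C_mask > tolerance.

    Entries where the mask correlation is at or below
    ``tol_rel × max(C_mask)`` are set to zero.  With an all-ones mask the
    correction is the identity.
    """
    if C.values.shape != C_mask.values.shape or C.qmax != C_mask.qmax:
        raise ValueError("correlation and mask-correlation grids do not match")
    thresh = tol_rel * float(C_mask.values.max(initial=0.0))
    good = C_mask.values > thresh
    out = np.zeros_like(C.values)
    np.divide(C.values, C_mask.values, out=out, where=good)
    return C.copy_with(out, mask_corrected=True)
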