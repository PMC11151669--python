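"""Inversion of the correlation volume to the pair angle distribution.

The chain has three linear stages:

1. **Harmonic extraction.**  On the Ewald sphere the correlation of two
   rings q and q′ at azimuthal separation θ is a finite even-order
   Legendre series,

       C(q, q′, θ) = Σ_{even l ≤ l_max} B_l(q, q′) P_l(cos ψ),
       cos ψ = cos θ_q cos θ_q′ + sin θ_q sin θ_q′ cos θ,

   where cos θ_q = qλ/2 is the out-of-plane tilt of the measured q
   vector (half the scattering angle); in the flat-Ewald limit λ → 0,
   cos ψ → cos θ.  For each (q, q′) the series is inverted by a
   pseudo-inverse of the design matrix over all θ samples.  Rows carry
   the √|sin θ| quadrature weight (the square-root split of the
   Legendre-orthogonality Jacobian) and columns are normalized, which
   makes the design matrix near-orthonormal; singular values below
   ``regularization`` × the largest (default 0.5) are discarded, which
   removes only directions that the detector geometry genuinely cannot
   distinguish.  The matrices depend on geometry, not data, and are
   cached across (q, q′) pairs.  Only even orders are used: with
   elastic kinematic scattering and no absorption the intensity has
   Friedel symmetry and odd-order terms vanish.

2. **Radial transform.**  Each B_l(q, q′) is mapped to real space by a
   discrete spherical Bessel transform on each axis.  The discrete form
   samples order l at the scaled zeros q_ln of j_l; B_0 lands on the
   j_0 zeros (which are uniform, nπ) and matrices with l > 0 are
   interpolated onto their own zero grids before transforming.  With q
   in cycles per nm the kernels are j_l(2π q r).

3. **Reassembly.**  Θ̃(r, r′, θ) = Σ_l w_l B_l(r, r′) P_l(cos θ) on
   θ ∈ [0°, 180°] with completeness weights w_l = (2l+1)/4π, then the
   scaling to a pair-count-like density: multiply by r² r′² (a pair
   shell at distance r arrives from the double transform carrying
   1/r²) and by |sin θ| (the density-per-angle Jacobian).  Values
   within ±(360°/l_max)/2 of θ = 0 are flagged unreliable: the sin θ
   factor is inconsistent with a finite angular basis there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.optimize import brentq
from scipy.special import eval_legendre, spherical_jn

from .correlate import CorrelationVolume
from .volio import Volume3D


# ---------------------------------------------------------------------------
# geometry of the inversion
# ---------------------------------------------------------------------------


def legendre_argument(q, qp, theta, wavelength: float):
    """cos ψ between two Ewald-sphere q vectors at azimuthal separation θ.

    ``q``/``qp`` in nm^-1, ``theta`` in radians, ``wavelength`` in nm.
    Requires qλ/2 ≤ 1 (beyond that there is no elastic scattering
    geometry).  Broadcasts over array inputs.
    """
    q = np.asarray(q, dtype=float)
    qp = np.asarray(qp, dtype=float)
    ctq = q * wavelength / 2.0
    ctqp = qp * wavelength / 2.0
    if np.any(ctq > 1.0) or np.any(ctqp > 1.0):
        raise ValueError("qλ/2 exceeds 1: beyond the back-scattering limit")
    stq = np.sqrt(1.0 - ctq**2)
    stqp = np.sqrt(1.0 - ctqp**2)
    return np.clip(ctq * ctqp + stq * stqp * np.cos(theta), -1.0, 1.0)


@lru_cache(maxsize=128)
def jl_zeros(l: int, n: int) -> np.ndarray:
    """First ``n`` positive zeros of the spherical Bessel function j_l."""
    zeros: list[float] = []
    f = lambda x: spherical_jn(l, x)
    x = l + 0.5
    prev = f(x)
    step = 0.5
    while len(zeros) < n:
        x2 = x + step
        cur = f(x2)
        if prev == 0.0:
            zeros.append(x)
        elif prev * cur < 0:
            zeros.append(brentq(f, x, x2, xtol=1e-13))
        x, prev = x2, cur
    return np.asarray(zeros[:n])


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class BlMatrixSetQ:
    """Even-order harmonic matrices B_l(q, q′).

    ``sampling='uniform'`` shares one uniform q grid across orders;
    ``sampling='bessel'`` samples order l on its own scaled j_l zeros
    (``q_grids[i]``), which is what the discrete radial transform needs.
    """

    data: np.ndarray  # (nl, n, n)
    ls: np.ndarray  # even orders
    wavelength: float
    sampling: str = "uniform"
    q_grid: np.ndarray | None = None  # uniform sampling
    q_grids: list[np.ndarray] | None = None  # per-order Bessel sampling
    rmax: float | None = None

    def __post_init__(self) -> None:
        self.ls = np.asarray(self.ls)
        if np.any(self.ls % 2):
            raise ValueError("only even orders are allowed")

    @property
    def lmax(self) -> int:
        return int(self.ls.max())


@dataclass
class BlMatrixSetR:
    """Real-space matrices B_l(r, r′) on a common increasing r grid (nm)."""

    data: np.ndarray  # (nl, nr, nr)
    ls: np.ndarray
    r_grid: np.ndarray
    rmax: float

    def __post_init__(self) -> None:
        if np.any(np.diff(self.r_grid) <= 0):
            raise ValueError("r grid must be strictly increasing")
        if self.r_grid.max() > self.rmax * (1 + 1e-12):
            raise ValueError("r grid exceeds rmax")


@dataclass
class PADFVolume:
    """Θ(r, r′, θ) with its scaling provenance.

    ``scaling`` records which θ and radial weights were applied and, in
    absolute mode, the constants used.  ``unreliable_theta_deg`` is the
    half-width of the angular band around θ = 0 whose heights cannot be
    read quantitatively at the chosen l_max.
    """

    values: np.ndarray  # (nr, nr, ntheta)
    r_grid: np.ndarray
    rmax: float
    lmax: int
    scaling: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("PADF volume must have shape (nr, nr, ntheta)")

    @property
    def ntheta(self) -> int:
        return self.values.shape[2]

    @property
    def theta_deg(self) -> np.ndarray:
        return np.linspace(0.0, 180.0, self.ntheta)

    @property
    def unreliable_theta_deg(self) -> float:
        return (360.0 / self.lmax) / 2.0

    def diagonal(self) -> np.ndarray:
        """The r = r′ plane, shape (nr, ntheta)."""
        n = len(self.r_grid)
        return self.values[np.arange(n), np.arange(n), :]

    def to_volume3d(self) -> Volume3D:
        meta = {
            "kind": "padf",
            "lmax": self.lmax,
            "scaling": self.scaling,
            "r_grid": self.r_grid.tolist(),
        }
        return Volume3D(
            values=self.values,
            axis_names=("r", "r", "theta"),
            axis_max=(self.rmax, self.rmax, 180.0),
            meta=meta,
        )

    @classmethod
    def from_volume3d(cls, vol: Volume3D) -> "PADFVolume":
        meta = vol.meta or {}
        r_grid = np.asarray(meta.get("r_grid", []))
        if r_grid.size == 0:
            n = vol.values.shape[0]
            r_grid = np.arange(1, n + 1) * vol.axis_max[0] / n
        return cls(
            values=vol.values,
            r_grid=r_grid,
            rmax=vol.axis_max[0],
            lmax=int(meta.get("lmax", 0) or (vol.values.shape[2] - 1) * 2),
            scaling=meta.get("scaling", {}),
        )


# ---------------------------------------------------------------------------
# stage 1: harmonic extraction
# ---------------------------------------------------------------------------


def extract_bl(
    C: CorrelationVolume,
    l_max: int,
    wavelength: float,
    regularization: float = 0.5,
    allow_unconditioned: bool = False,
) -> BlMatrixSetQ:
    """Invert the Legendre series of a conditioned correlation volume.

    The volume must carry the |sin θ| conditioning record (see
    :mod:`padfkit.condition`) unless ``allow_unconditioned`` is set; the
    recorded exponent is divided out internally so the least-squares
    weighting is always the Legendre-orthogonality weight |sin θ|,
    regardless of the exponent chosen at the conditioning stage.  A θ=0
    noise mask in the record removes those rows from the fit.  Where the
    cutoff discards every singular value the B_l row is set to zero.
    """
    if l_max % 2 or l_max < 0:
        raise ValueError("l_max must be even and non-negative")
    rec = C.conditioning
    if (rec is None or rec.sintheta_exponent is None) and not allow_unconditioned:
        raise ValueError(
            "correlation volume lacks the |sin θ| conditioning weight; apply "
            "condition.apply_sintheta_weight first or pass allow_unconditioned=True"
        )
    w_exp = 0.0 if rec is None or rec.sintheta_exponent is None else rec.sintheta_exponent

    theta = C.theta_grid
    sth = np.abs(np.sin(theta))
    row_w = np.sqrt(sth)
    if rec is not None and rec.theta_zero_halfwidth_deg is not None:
        thd = np.degrees(theta)
        dist = np.minimum(thd, 360.0 - thd)
        row_w = row_w * (dist > rec.theta_zero_halfwidth_deg + 1e-12)

    # bring the stored volume to the √|sinθ|-weighted right-hand side:
    # stored = |sinθ|^w · C_raw  →  rhs = |sinθ|^{1/2-w} · stored
    with np.errstate(divide="ignore", invalid="ignore"):
        to_rhs = np.where(sth > 0, sth ** (0.5 - w_exp), 0.0)

    ls = np.arange(0, l_max + 2, 2)
    nl = len(ls)
    nq = C.nq
    qs = C.q_grid
    ctq = qs * wavelength / 2.0
    if np.any(ctq > 1.0):
        raise ValueError("q grid extends beyond the back-scattering limit for this wavelength")
    stq = np.sqrt(1.0 - ctq**2)
    cos_t = np.cos(theta)

    B = np.zeros((nl, nq, nq))
    rhs_all = C.values * to_rhs[None, None, :]
    for a in range(nq):
        for b in range(a, nq):
            cospsi = np.clip(ctq[a] * ctq[b] + stq[a] * stq[b] * cos_t, -1.0, 1.0)
            A = row_w[:, None] * eval_legendre(ls[None, :], cospsi[:, None])
            norms = np.linalg.norm(A, axis=0)
            ok = norms > 0
            if not np.any(ok):
                continue
            pinv = np.linalg.pinv(A[:, ok] / norms[ok], rcond=regularization)
            B[ok, a, b] = (pinv @ rhs_all[a, b]) / norms[ok]
            if b != a:
                B[ok, b, a] = (pinv @ rhs_all[b, a]) / norms[ok]
    return BlMatrixSetQ(
        data=B, ls=ls, wavelength=wavelength, sampling="uniform", q_grid=qs
    )


def synthesize_correlation(
    bl: BlMatrixSetQ,
    ntheta: int,
    conditioned: bool = True,
) -> CorrelationVolume:
    """Forward-evaluate the Legendre series of a uniform-grid B_l set.

    Returns Σ_l B_l(q, q′) P_l(cos ψ(q, q′, θ)) on an nθ grid, optionally
    multiplied by the |sin θ| conditioning weight so it compares directly
    with a conditioned measured volume.  This is the forward model whose
    inverse is :func:`extract_bl`.
    """
    if bl.sampling != "uniform":
        raise ValueError("forward synthesis expects a uniform-grid B_l set")
    qs = bl.q_grid
    nq = len(qs)
    theta = np.arange(ntheta) * 2.0 * np.pi / ntheta
    ctq = qs * bl.wavelength / 2.0
    stq = np.sqrt(1.0 - ctq**2)
    cos_t = np.cos(theta)
    out = np.empty((nq, nq, ntheta))
    for a in range(nq):
        cospsi = np.clip(
            ctq[a] * ctq[:, None] + stq[a] * stq[:, None] * cos_t[None, :], -1.0, 1.0
        )
        P = eval_legendre(bl.ls[None, None, :], cospsi[..., None])
        out[a] = np.einsum("btl,lb->bt", P, bl.data[:, a, :])
    from .condition import ConditioningRecord

    vol = CorrelationVolume(values=out, qmax=float(qs[-1]), mode="synthetic")
    if conditioned:
        vol.values *= np.abs(np.sin(theta))[None, None, :]
        vol.conditioning = ConditioningRecord(sintheta_exponent=1.0)
    return vol


# ---------------------------------------------------------------------------
# stage 2: radial transforms
# ---------------------------------------------------------------------------


def resample_bl(
    bl: BlMatrixSetQ,
    nr: int | None = None,
    rmax: float | None = None,
    method: str = "cubic",
) -> BlMatrixSetQ:
    """Remap uniform-grid B_l matrices onto per-order Bessel-zero grids.

    Order l is sampled at q_ln / (2πR) for the first ``nr`` zeros q_ln of
    j_l, with R = ``rmax`` (default nr / (2 q_max), which matches the
    real-space extent to the measured q range).  The j_0 zeros are nπ, so
    the l = 0 grid is uniform and coincides with the measurement grid
    when nr = nq − 1; orders l > 0 are interpolated (cubic by default,
    ``method='linear'`` for bilinear) and values beyond the measured
    range are set to zero.
    """
    if bl.sampling != "uniform":
        raise ValueError("input must be on the uniform measurement grid")
    qs = bl.q_grid
    qmax = float(qs[-1])
    if nr is None:
        nr = len(qs) - 1
    if rmax is None:
        rmax = nr / (2.0 * qmax)
    if rmax <= 0:
        raise ValueError("rmax must be positive")

    out = np.zeros((len(bl.ls), nr, nr))
    grids: list[np.ndarray] = []
    for i, l in enumerate(bl.ls):
        zl = jl_zeros(int(l), nr)
        qtarget = zl / (2.0 * np.pi * rmax)
        grids.append(qtarget)
        inside = qtarget <= qmax * (1 + 1e-12)
        k = int(inside.sum())
        if k <= len(qs) - 1 and np.allclose(
            qtarget[inside], qs[1 : 1 + k], rtol=0, atol=1e-12 * qmax
        ):
            # target grid coincides with the source grid: copy bit-exactly
            out[i, :k, :k] = bl.data[i, 1 : 1 + k, 1 : 1 + k]
            continue
        interp = RegularGridInterpolator(
            (qs, qs), bl.data[i], method=method, bounds_error=False, fill_value=0.0
        )
        qa, qb = np.meshgrid(qtarget[inside], qtarget[inside], indexing="ij")
        vals = interp(np.stack([qa.ravel(), qb.ravel()], axis=-1))
        sub = np.zeros((nr, nr))
        sub[np.ix_(inside, inside)] = vals.reshape(inside.sum(), inside.sum())
        out[i] = sub
    return BlMatrixSetQ(
        data=out,
        ls=bl.ls,
        wavelength=bl.wavelength,
        sampling="bessel",
        q_grids=grids,
        rmax=float(rmax),
    )


def sbt_matrix(l: int, nzeros: int, rmax: float, r_out: np.ndarray) -> np.ndarray:
    """Discrete spherical Bessel synthesis matrix for order ``l``.

    Maps samples f̂(q_ln / 2πR) on the zero grid to real space,

        f(r_k) = Σ_n [√(2π) / (R³ j_{l+1}²(q_ln))] f̂_n j_l(q_ln r_k / R),

    evaluated at arbitrary output radii ``r_out`` ≤ R.
    """
    zl = jl_zeros(int(l), nzeros)
    w = np.sqrt(2.0 * np.pi) / (rmax**3 * spherical_jn(l + 1, zl) ** 2)
    return spherical_jn(l, np.outer(r_out, zl) / rmax) * w[None, :]


def sbt_forward_matrix(l: int, nzeros: int, rmax: float) -> np.ndarray:
    """Forward discrete transform (real space → zero grid) for order ``l``.

    Samples f at r_n = q_ln R / q_l,N+1 (the mirror of the synthesis
    sampling) and returns f̂ on the q_ln / 2πR grid; together with
    :func:`sbt_matrix` it is self-inverse on band-limited input.
    """
    zl = jl_zeros(int(l), nzeros + 1)
    zn, zN = zl[:nzeros], zl[nzeros]
    K = zN / rmax
    w = np.sqrt(2.0 * np.pi) / (K**3 * spherical_jn(l + 1, zn) ** 2)
    return spherical_jn(l, np.outer(zn, zn) / zN) * w[None, :]


def sbt_bl(bl: BlMatrixSetQ, r_grid: np.ndarray | None = None) -> BlMatrixSetR:
    """Transform Bessel-sampled B_l(q, q′) to B_l(r, r′).

    The per-order synthesis matrix is applied along the q axis and then
    along the q′ axis.  The default real-space grid is
    r_k = k R / nr, k = 1..nr.
    """
    if bl.sampling != "bessel":
        raise ValueError("radial transform expects Bessel-zero sampling; run resample_bl")
    nr = bl.data.shape[1]
    rmax = float(bl.rmax)
    if r_grid is None:
        r_grid = np.arange(1, nr + 1) * rmax / nr
    out = np.empty((len(bl.ls), len(r_grid), len(r_grid)))
    for i, l in enumerate(bl.ls):
        T = sbt_matrix(int(l), nr, rmax, r_grid)
        out[i] = T @ bl.data[i] @ T.T
    return BlMatrixSetR(data=out, ls=bl.ls, r_grid=np.asarray(r_grid), rmax=rmax)


# ---------------------------------------------------------------------------
# stage 3: reassembly
# ---------------------------------------------------------------------------


def assemble_padf(
    blr: BlMatrixSetR,
    ntheta: int = 181,
    sintheta_exponent: float = 1.0,
    radial_weight: bool = True,
    l_weights: np.ndarray | None = None,
    absolute: tuple[float, float] | None = None,
) -> PADFVolume:
    """Sum the real-space harmonics into Θ(r, r′, θ) on [0°, 180°].

    ``l_weights`` overrides the default completeness weights
    (2l+1)/(4π).  ``radial_weight`` multiplies by r² r′² and
    ``sintheta_exponent`` by |sin θ|^exp (both recorded); together they
    scale shell deltas to pair-count-like peak heights.  ``absolute``
    supplies (ρ₀ in nm⁻³, N_I quanta) and divides by ρ₀² N_I²; without
    it the output is proportional to the pair angle distribution.
    """
    expected = np.arange(0, blr.ls.max() + 2, 2)
    if len(blr.ls) != len(expected) or np.any(np.sort(blr.ls) != expected):
        raise ValueError("B_l set must contain every even order up to l_max")
    theta = np.linspace(0.0, np.pi, ntheta)
    wl = (
        (2.0 * blr.ls + 1.0) / (4.0 * np.pi)
        if l_weights is None
        else np.asarray(l_weights, dtype=float)
    )
    P = eval_legendre(blr.ls[None, :], np.cos(theta)[:, None])  # (ntheta, nl)
    values = np.einsum("lab,tl->abt", blr.data, P * wl[None, :])
    scaling: dict = {
        "l_weights": "(2l+1)/4pi" if l_weights is None else "custom",
        "sintheta_exponent": float(sintheta_exponent),
        "radial_weight": bool(radial_weight),
        "absolute": None,
    }
    if sintheta_exponent:
        values = values * np.abs(np.sin(theta))[None, None, :] ** sintheta_exponent
    if radial_weight:
        r2 = blr.r_grid**2
        values = values * r2[:, None, None] * r2[None, :, None]
    if absolute is not None:
        rho0, ni = absolute
        if rho0 <= 0 or ni <= 0:
            raise ValueError("absolute scaling needs positive (rho0, N_I)")
        values = values / (rho0**2 * ni**2)
        scaling["absolute"] = {"rho0": float(rho0), "n_incident": float(ni)}
    return PADFVolume(
        values=values,
        r_grid=blr.r_grid,
        rmax=blr.rmax,
        lmax=int(blr.ls.max()),
        scaling=scaling,
    )


def correlation_to_padf(
    C: CorrelationVolume,
    wavelength: float,
    l_max: int = 32,
    nr: int | None = None,
    rmax: float | None = None,
    regularization: float = 0.5,
    ntheta_out: int = 181,
    resample_method: str = "cubic",
) -> tuple[PADFVolume, BlMatrixSetQ, BlMatrixSetR]:
    """Convenience chain: extract, resample, transform and assemble."""
    blq = extract_bl(C, l_max, wavelength, regularization=regularization)
    blqz = resample_bl(blq, nr=nr, rmax=rmax, method=resample_method)
    blr = sbt_bl(blqz)
    padf = assemble_padf(blr, ntheta=ntheta_out)
    return padf, blq, blr
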