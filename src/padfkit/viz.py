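"""Slicing, smoothing, plotting and peak quantification of 3D volumes.

Works on both correlation volumes (q, q′, θ on [0°, 360°)) and PADF
volumes (r, r′, θ on [0°, 180°]).  Slices are nearest-grid-plane
extractions; smoothing is a separable normalized Gaussian; peaks are
grid-point maxima inside user windows, with pairwise height ratios for
quantitative comparison against ideal models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .correlate import CorrelationVolume
from .padf import PADFVolume

_HWHM_TO_SIGMA = 1.0 / np.sqrt(2.0 * np.log(2.0))


def _axes_of(vol) -> tuple[np.ndarray, np.ndarray, str]:
    """(radial-axis grid, angular grid in degrees, radial-axis name)."""
    if isinstance(vol, PADFVolume):
        return vol.r_grid, vol.theta_deg, "r"
    if isinstance(vol, CorrelationVolume):
        return vol.q_grid, np.degrees(vol.theta_grid), "q"
    raise TypeError(f"unsupported volume type {type(vol).__name__}")


def _nearest(grid: np.ndarray, value: float, name: str) -> int:
    if value < grid.min() - 1e-9 or value > grid.max() + 1e-9:
        raise ValueError(
            f"{name}={value} outside the grid range [{grid.min():.6g}, {grid.max():.6g}]"
        )
    return int(np.argmin(np.abs(grid - value)))


def slice_volume(vol, kind: str, at: float = 0.0, at2: float | None = None) -> np.ndarray:
    """Extract a 1D/2D section of a volume.

    kinds: ``req`` — the r = r′ (or q = q′) diagonal plane, shape
    (n, nθ); ``theta`` — constant-angle plane at ``at`` degrees;
    ``r`` — constant-radius plane at ``at``; ``line-r`` — radial line at
    r′ = ``at``, θ = ``at2`` degrees; ``line-theta`` — angular line at
    r = ``at``, r′ = ``at2`` (defaults to r).
    """
    rad, ang, rname = _axes_of(vol)
    v = vol.values
    if kind == "req":
        n = v.shape[0]
        return v[np.arange(n), np.arange(n), :]
    if kind == "theta":
        return v[:, :, _nearest(ang, at, "theta")]
    if kind == "r":
        return v[_nearest(rad, at, rname), :, :]
    if kind == "line-r":
        j = _nearest(rad, at, rname)
        k = _nearest(ang, 0.0 if at2 is None else at2, "theta")
        return v[:, j, k]
    if kind == "line-theta":
        i = _nearest(rad, at, rname)
        j = i if at2 is None else _nearest(rad, at2, rname)
        return v[i, j, :]
    raise ValueError(f"unknown slice kind {kind!r}")


def gaussian_smooth(
    vol,
    radial_halfwidth: float,
    angular_halfwidth: float,
    interpretation: str = "sigma",
):
    """Separable Gaussian smoothing of a volume (returns a new volume).

    Half-widths are in the volume's own units (nm or nm^-1 radially,
    degrees angularly) and are interpreted as the Gaussian σ by default
    (``interpretation='hwhm'`` converts half-width-at-half-maximum to σ).
    Kernels are normalized and truncated at 3 half-widths; boundaries are
    reflective, which at θ = 0°/180° matches the angular mirror symmetry.
    """
    if radial_halfwidth < 0 or angular_halfwidth < 0:
        raise ValueError("half-widths must be non-negative")
    rad, ang, _ = _axes_of(vol)
    dr = rad[1] - rad[0]
    dth = ang[1] - ang[0]
    s_r, s_t = radial_halfwidth / dr, angular_halfwidth / dth
    if interpretation == "hwhm":
        s_r, s_t = s_r * _HWHM_TO_SIGMA, s_t * _HWHM_TO_SIGMA
    elif interpretation != "sigma":
        raise ValueError("interpretation must be 'sigma' or 'hwhm'")
    smoothed = gaussian_filter(
        vol.values, sigma=(s_r, s_r, s_t), mode="reflect", truncate=3.0
    )
    if isinstance(vol, PADFVolume):
        return PADFVolume(
            values=smoothed, r_grid=vol.r_grid, rmax=vol.rmax, lmax=vol.lmax,
            scaling={**vol.scaling,
                     "smoothed": [radial_halfwidth, angular_halfwidth, interpretation]},
        )
    return vol.copy_with(smoothed)


@dataclass
class PeakRow:
    label: str
    r: float
    rprime: float
    theta_deg: float
    height: float


@dataclass
class PeakTable:
    """Windowed grid-point maxima of a volume, with height ratios."""

    rows: list[PeakRow]

    def __getitem__(self, label: str) -> PeakRow:
        for row in self.rows:
            if row.label == label:
                return row
        raise KeyError(label)

    def ratio(self, num: str, den: str) -> float:
        return self[num].height / self[den].height


def peak_table(vol, windows: dict[str, tuple[float, float, float, float, float, float]]) -> PeakTable:
    """Locate the maximum of a volume inside each (r, r′, θ) window.

    ``windows`` maps a label to ``(r_lo, r_hi, r'_lo, r'_hi, θ_lo, θ_hi)``
    in the volume's units (θ in degrees).  The reported position is the
    grid point of the maximum; heights are read from the volume as given
    (smooth first if desired).  An empty window is an error.
    """
    rad, ang, _ = _axes_of(vol)
    rows = []
    for label, (rlo, rhi, plo, phi, tlo, thi) in windows.items():
        mi = (rad >= rlo) & (rad <= rhi)
        mj = (rad >= plo) & (rad <= phi)
        mk = (ang >= tlo) & (ang <= thi)
        if not (mi.any() and mj.any() and mk.any()):
            raise ValueError(f"window {label!r} contains no grid points")
        sub = vol.values[np.ix_(mi, mj, mk)]
        i, j, k = np.unravel_index(np.argmax(sub), sub.shape)
        rows.append(
            PeakRow(
                label=label,
                r=float(rad[mi][i]),
                rprime=float(rad[mj][j]),
                theta_deg=float(ang[mk][k]),
                height=float(sub[i, j, k]),
            )
        )
    return PeakTable(rows)


def diagonal_peaks(
    values_rt: np.ndarray,
    r_grid: np.ndarray,
    theta_deg: np.ndarray,
    r_window: tuple[float, float],
    theta_window: tuple[float, float],
) -> tuple[float, float, float]:
    """Maximum of an (r, θ) diagonal slice inside a window → (r, θ, height)."""
    mi = (r_grid >= r_window[0]) & (r_grid <= r_window[1])
    mk = (theta_deg >= theta_window[0]) & (theta_deg <= theta_window[1])
    if not (mi.any() and mk.any()):
        raise ValueError("empty diagonal window")
    sub = values_rt[np.ix_(mi, mk)]
    i, k = np.unravel_index(np.argmax(sub), sub.shape)
    return float(r_grid[mi][i]), float(theta_deg[mk][k]), float(sub[i, k])


def plot_slice(
    vol,
    kind: str,
    at: float = 0.0,
    at2: float | None = None,
    png: str | None = None,
    title: str | None = None,
):
    """Render a slice with matplotlib; optionally save a PNG.

    Returns the figure.  2D slices are drawn as images with labelled
    physical axes, 1D lines as curves.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rad, ang, rname = _axes_of(vol)
    data = slice_volume(vol, kind, at, at2)
    fig, ax = plt.subplots(figsize=(6, 4.5), constrained_layout=True)
    unit = "nm" if rname == "r" else "nm$^{-1}$"
    if data.ndim == 2:
        if kind == "req":
            extent = [ang[0], ang[-1], rad[0], rad[-1]]
            ax.imshow(data, origin="lower", aspect="auto", extent=extent)
            ax.set_xlabel(r"$\theta$ (deg)")
            ax.set_ylabel(f"{rname} = {rname}$'$ ({unit})")
        elif kind == "theta":
            extent = [rad[0], rad[-1], rad[0], rad[-1]]
            ax.imshow(data, origin="lower", aspect="auto", extent=extent)
            ax.set_xlabel(f"{rname}$'$ ({unit})")
            ax.set_ylabel(f"{rname} ({unit})")
        else:
            extent = [ang[0], ang[-1], rad[0], rad[-1]]
            ax.imshow(data, origin="lower", aspect="auto", extent=extent)
            ax.set_xlabel(r"$\theta$ (deg)")
            ax.set_ylabel(f"{rname}$'$ ({unit})")
    else:
        x = rad if kind == "line-r" else ang
        ax.plot(x, data)
        ax.set_xlabel(f"{rname} ({unit})" if kind == "line-r" else r"$\theta$ (deg)")
        ax.set_ylabel("value")
    if title:
        ax.set_title(title)
    if png:
        fig.savefig(png, dpi=150)
        plt.close(fig)
    return fig
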