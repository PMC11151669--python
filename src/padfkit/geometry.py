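"""Detector geometry and polar resampling.

The pixel → q map follows the elastic-scattering (Ewald sphere) geometry
with the electron-convention momentum transfer q = (2/λ) sin(θ_s/2) in
cycles per nm (the crystallographic convention carries an extra 2π).  A
pixel at radial distance r from the beam centre scatters through
θ_s = arctan(r/z); its 3D scattering vector is q⃗ = (ŝ − ẑ)/λ with ŝ the
unit vector from the sample to the pixel centre.  Because of Ewald
curvature, uniform pixel radii sample q non-uniformly; :meth:`to_polar`
interpolates each exposure onto exactly uniform (q, θ) grids.

Conventions: pixel (0, 0) spans [0, 1)² so pixel centres sit at
half-integer coordinates; the beam centre is in fractional pixel units;
θ is measured counter-clockwise from the +x detector axis on [0, 2π).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class DetectorGeometry:
    """Flat-detector geometry for a monochromatic beam.

    Parameters
    ----------
    wavelength : float
        Beam wavelength in nm.
    distance : float
        Sample-to-detector distance z in m.
    pixel_width : float
        Side length of a (square) pixel in m.
    shape : tuple of int
        Detector size (nx, ny) in pixels.
    beam_centre : tuple of float, optional
        Beam centre in fractional pixel units; defaults to the image
        centre (nx/2, ny/2).
    """

    wavelength: float
    distance: float
    pixel_width: float
    shape: tuple[int, int]
    beam_centre: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.distance <= 0:
            raise ValueError("sample-to-detector distance must be positive")
        if self.pixel_width <= 0:
            raise ValueError("pixel width must be positive")
        if self.beam_centre is None:
            object.__setattr__(
                self, "beam_centre", (self.shape[0] / 2.0, self.shape[1] / 2.0)
            )

    # -- scalar pixel <-> q maps -------------------------------------------------

    def scattering_angle(self, r):
        """Scattering angle θ_s = arctan(r/z) of a pixel at radius r (m)."""
        return np.arctan(np.asarray(r, dtype=float) / self.distance)

    def q_of_radius(self, r):
        """|q| (nm^-1) of a pixel at radial distance r (m) from the centre."""
        return (2.0 / self.wavelength) * np.sin(self.scattering_angle(r) / 2.0)

    def radius_of_q(self, q):
        """Inverse of :meth:`q_of_radius`: detector radius (m) of a given q."""
        half = np.arcsin(np.clip(np.asarray(q, dtype=float) * self.wavelength / 2.0, -1.0, 1.0))
        return self.distance * np.tan(2.0 * half)

    @property
    def edge_q(self) -> float:
        """q at the nearest detector edge from the beam centre (nm^-1)."""
        cx, cy = self.beam_centre
        nx, ny = self.shape
        margins = [cx, nx - cx, cy, ny - cy]
        return float(self.q_of_radius(min(margins) * self.pixel_width))

    @classmethod
    def for_edge_q(
        cls,
        npix: int,
        edge_q: float,
        wavelength: float = 0.1,
        pixel_width: float = 1e-4,
    ) -> "DetectorGeometry":
        """Build a square geometry whose half-width edge sits at ``edge_q``.

        The distance z is solved from the stated wavelength and pixel
        width so that q at a half-width radius equals ``edge_q``.
        """
        if edge_q <= 0:
            raise ValueError("edge_q must be positive")
        half_angle = 2.0 * np.arcsin(edge_q * wavelength / 2.0)
        z = (npix // 2) * pixel_width / np.tan(half_angle)
        return cls(wavelength=wavelength, distance=z, pixel_width=pixel_width,
                   shape=(npix, npix))

    # -- vector maps ---------------------------------------------------------------

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical (x, y) of all pixel centres relative to the beam centre (m)."""
        cx, cy = self.beam_centre
        x = (np.arange(self.shape[0]) + 0.5 - cx) * self.pixel_width
        y = (np.arange(self.shape[1]) + 0.5 - cy) * self.pixel_width
        return np.meshgrid(x, y, indexing="ij")

    def ewald_qvectors(self) -> np.ndarray:
        """3D scattering vectors q⃗ = (ŝ − ẑ)/λ of every pixel, shape (nx, ny, 3).

        The z component (cos θ_s − 1)/λ is ≤ 0 everywhere: the Ewald
        sphere bends behind the detector-plane origin.
        """
        X, Y = self.pixel_coords()
        R = np.hypot(X, Y)
        L = np.sqrt(R * R + self.distance**2)
        sx, sy, sz = X / L, Y / L, self.distance / L
        q = np.empty(self.shape + (3,))
        q[..., 0] = sx / self.wavelength
        q[..., 1] = sy / self.wavelength
        q[..., 2] = (sz - 1.0) / self.wavelength
        return q

    def ewald_qvector(self, px: float, py: float) -> np.ndarray:
        """q⃗ of a single (fractional) pixel position."""
        cx, cy = self.beam_centre
        x = (px + 0.5 - cx) * self.pixel_width
        y = (py + 0.5 - cy) * self.pixel_width
        L = np.sqrt(x * x + y * y + self.distance**2)
        s = np.array([x, y, self.distance]) / L
        s[2] -= 1.0
        return s / self.wavelength


def pixel_q(r, geometry: DetectorGeometry):
    """Scattering angle and |q| for pixels at radial distance ``r`` (m).

    Returns ``(theta_s, q)`` with θ_s = arctan(r/z) in radians and
    q = (2/λ) sin(θ_s/2) in nm^-1.
    """
    theta = geometry.scattering_angle(r)
    return theta, (2.0 / geometry.wavelength) * np.sin(theta / 2.0)


@dataclass
class PolarIntensity:
    """One exposure resampled onto uniform (q, θ) grids.

    ``values[k, j]`` holds I(q_k, θ_j) with q_k uniform on [0, qmax] and
    θ_j uniform on [0, 2π) (exclusive of 2π).
    """

    values: np.ndarray
    qmax: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("polar intensity must be 2D (nq, ntheta)")

    @property
    def nq(self) -> int:
        return self.values.shape[0]

    @property
    def ntheta(self) -> int:
        return self.values.shape[1]

    @property
    def q_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.qmax, self.nq)

    @property
    def theta_grid(self) -> np.ndarray:
        return np.arange(self.ntheta) * 2.0 * np.pi / self.ntheta


def polar_sample_coordinates(
    geometry: DetectorGeometry, nq: int, ntheta: int, qmax: float
) -> np.ndarray:
    """Fractional pixel coordinates of the uniform polar grid, shape (2, nq, nθ)."""
    qs = np.linspace(0.0, qmax, nq)
    ths = np.arange(ntheta) * 2.0 * np.pi / ntheta
    rad = geometry.radius_of_q(qs) / geometry.pixel_width
    cx, cy = geometry.beam_centre
    px = rad[:, None] * np.cos(ths)[None, :] + cx - 0.5
    py = rad[:, None] * np.sin(ths)[None, :] + cy - 0.5
    return np.stack([px, py])


def to_polar(
    image: np.ndarray,
    geometry: DetectorGeometry,
    nq: int,
    ntheta: int,
    qmax: float | None = None,
    order: int = 3,
    _coords: np.ndarray | None = None,
) -> PolarIntensity:
    """Resample a detector image onto a uniform (q, θ) grid.

    Interpolation uses separable spline interpolation at the non-integer
    pixel coordinates of each (q_k, θ_j) sample (default cubic,
    ``order=1`` for linear); samples mapping outside the detector are 0.
    ``_coords`` optionally reuses precomputed sample coordinates from
    :func:`polar_sample_coordinates` across many exposures.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.shape != tuple(geometry.shape):
        raise ValueError(
            f"image shape {image.shape} does not match geometry {geometry.shape}"
        )
    if nq < 2 or ntheta < 2:
        raise ValueError("nq and ntheta must both be at least 2")
    if qmax is None:
        qmax = geometry.edge_q
    if qmax > geometry.edge_q * (1 + 1e-9):
        raise ValueError(
            f"qmax={qmax} exceeds detector coverage; maximum allowed is "
            f"{geometry.edge_q:.6g} nm^-1"
        )
    coords = _coords if _coords is not None else polar_sample_coordinates(
        geometry, nq, ntheta, qmax
    )
    vals = ndimage.map_coordinates(
        image, coords, order=order, mode="constant", cval=0.0
    )
    return PolarIntensity(values=vals, qmax=float(qmax))


# -- raw-image pre-processing ----------------------------------------------------


def centre_crop(image: np.ndarray, centre: tuple[float, float], size: int) -> np.ndarray:
    """Crop a square of ``size`` pixels about (the pixel containing) ``centre``."""
    image = np.asarray(image)
    ci, cj = int(round(centre[0])), int(round(centre[1]))
    half = size // 2
    i0, j0 = ci - half, cj - half
    if i0 < 0 or j0 < 0 or i0 + size > image.shape[0] or j0 + size > image.shape[1]:
        raise ValueError("crop window extends beyond the image")
    return image[i0 : i0 + size, j0 : j0 + size]


def rebin(image: np.ndarray, factor: int) -> np.ndarray:
    """Mean-rebin by an integer factor (image size must divide evenly)."""
    image = np.asarray(image, dtype=np.float64)
    if factor == 1:
        return image
    nx, ny = image.shape
    if nx % factor or ny % factor:
        raise ValueError(f"image shape {image.shape} not divisible by rebin factor {factor}")
    return image.reshape(nx // factor, factor, ny // factor, factor).mean(axis=(1, 3))
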