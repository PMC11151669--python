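"""Forward kinematic diffraction simulation and an ideal-model oracle.

The simulator produces serial-diffraction test data: a rigid set of
scatterers is given one uniformly random 3D orientation per exposure and
the detector records the kinematic (single-scattering) elastic intensity

    I(q⃗) = |Σ_j f_j(|q⃗|) exp(2πi q⃗ · R r_j)|²

on the Ewald sphere, with no absorption and (by default) no detector
noise.  An optional cos³θ_s factor models the reduced solid angle of
edge pixels, and optional Poisson sampling models finite photon counts.

:func:`model_padf_oracle` gives the ideal pair-angle distribution of a
model by direct enumeration of every ordered pair of ordered atom pairs;
it is used to compute ideal peak positions and height ratios,
independently of the scattering pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import DetectorGeometry


@dataclass
class StructureModel:
    """Rigid atomic model: positions (nm) and Gaussian scattering factors.

    Atom j scatters with amplitude f_j(q) = f0_j · exp(−b_j q²); b = 0
    gives an ideal point scatterer.
    """

    positions: np.ndarray  # (natom, 3) nm
    f0: np.ndarray  # (natom,)
    b: np.ndarray  # (natom,) nm^2

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        self.f0 = np.atleast_1d(np.asarray(self.f0, dtype=np.float64))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=np.float64))
        n = len(self.positions)
        if n < 1:
            raise ValueError("a structure model needs at least one atom")
        if self.positions.shape != (n, 3):
            raise ValueError("positions must have shape (natom, 3)")
        if len(self.f0) != n or len(self.b) != n:
            raise ValueError("f0 and b must have one entry per atom")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def natoms(self) -> int:
        return len(self.positions)

    def form_factors(self, q: np.ndarray) -> np.ndarray:
        """f_j(q) for each atom at each |q|; shape q.shape + (natom,)."""
        q = np.asarray(q, dtype=np.float64)
        return self.f0 * np.exp(-np.multiply.outer(q**2, self.b))


def make_hexagon(d: float = 15.0) -> StructureModel:
    """Six unit point scatterers on a regular hexagon of side ``d`` (nm).

    The vertices lie in the z = 0 plane with centroid at the origin; the
    circumradius of a regular hexagon equals its side, so every atom sits
    at distance ``d`` from the centre.  Pair distances are d (12 ordered
    pairs), √3·d (12) and 2d (6).
    """
    if d <= 0:
        raise ValueError("nearest-neighbour distance must be positive")
    ang = np.arange(6) * np.pi / 3.0
    pos = np.stack([d * np.cos(ang), d * np.sin(ang), np.zeros(6)], axis=1)
    return StructureModel(positions=pos, f0=np.ones(6), b=np.zeros(6))


def load_model(path: str | Path) -> StructureModel:
    """Read a whitespace model file with one ``x y z f0 b`` row per atom (nm)."""
    arr = np.atleast_2d(np.loadtxt(path))
    if arr.shape[1] == 3:
        return StructureModel(arr, np.ones(len(arr)), np.zeros(len(arr)))
    if arr.shape[1] == 5:
        return StructureModel(arr[:, :3], arr[:, 3], arr[:, 4])
    raise ValueError("model file must have 3 (x y z) or 5 (x y z f0 b) columns")


def random_rotations(n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` rotation matrices drawn uniformly from SO(3), shape (n, 3, 3).

    Uses the uniform unit-quaternion construction: four i.i.d. standard
    normals normalized to a unit quaternion are uniform on S³, which maps
    to Haar-uniform rotations.
    """
    quat = rng.standard_normal((n, 4))
    quat /= np.linalg.norm(quat, axis=1, keepdims=True)
    w, x, y, z = quat.T
    R = np.empty((n, 3, 3))
    R[:, 0, 0] = 1 - 2 * (y * y + z * z)
    R[:, 0, 1] = 2 * (x * y - w * z)
    R[:, 0, 2] = 2 * (x * z + w * y)
    R[:, 1, 0] = 2 * (x * y + w * z)
    R[:, 1, 1] = 1 - 2 * (x * x + z * z)
    R[:, 1, 2] = 2 * (y * z - w * x)
    R[:, 2, 0] = 2 * (x * z - w * y)
    R[:, 2, 1] = 2 * (y * z + w * x)
    R[:, 2, 2] = 1 - 2 * (x * x + y * y)
    return R


def simulate_pattern(
    model: StructureModel,
    rotation: np.ndarray,
    geometry: DetectorGeometry,
    solid_angle: bool = False,
    photons: float | None = None,
    rng: np.random.Generator | None = None,
    _qvec: np.ndarray | None = None,
) -> np.ndarray:
    """Kinematic diffraction pattern of the rotated model on the detector.

    ``_qvec`` optionally reuses ``geometry.ewald_qvectors()`` across many
    exposures.  With ``photons`` set, the pattern is scaled to that total
    count and Poisson sampled.
    """
    if photons is not None and photons < 0:
        raise ValueError("photon count must be non-negative")
    qvec = geometry.ewald_qvectors() if _qvec is None else _qvec
    rpos = np.asarray(model.positions) @ np.asarray(rotation).T  # R r_j
    phase = np.exp(
        2j * np.pi * np.tensordot(qvec, rpos.T, axes=([2], [0]))
    )  # (nx, ny, natom)
    if np.any(model.b != 0) or np.any(model.f0 != 1):
        qmag = np.linalg.norm(qvec, axis=-1)
        amp = (model.form_factors(qmag) * phase).sum(axis=-1)
    else:
        amp = phase.sum(axis=-1)
    intensity = np.abs(amp) ** 2
    if solid_angle:
        X, Y = geometry.pixel_coords()
        costh = geometry.distance / np.sqrt(X * X + Y * Y + geometry.distance**2)
        intensity = intensity * costh**3
    if photons:
        total = intensity.sum()
        if total > 0:
            scaled = intensity * (photons / total)
            if rng is None:
                rng = np.random.default_rng()
            intensity = rng.poisson(scaled).astype(np.float64)
    return intensity


@dataclass
class ExposureSet:
    """A simulated serial-diffraction dataset."""

    patterns: list[np.ndarray]
    rotations: np.ndarray  # (n, 3, 3)
    geometry: DetectorGeometry
    seed: int
    model: StructureModel | None = None
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.patterns) != len(self.rotations):
            raise ValueError("one rotation per pattern is required")

    def __len__(self) -> int:
        return len(self.patterns)

    def write(self, folder: str | Path, tag: str = "diff") -> list[Path]:
        """Write one NPY per exposure plus a JSON manifest; returns the paths."""
        folder = Path(folder)
        folder.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, pat in enumerate(self.patterns):
            p = folder / f"{tag}_{i}.npy"
            np.save(p, pat)
            paths.append(p)
        manifest = {
            "tag": tag,
            "n_patterns": len(self),
            "seed": self.seed,
            "geometry": {
                "wavelength_nm": self.geometry.wavelength,
                "distance_m": self.geometry.distance,
                "pixel_width_m": self.geometry.pixel_width,
                "shape": list(self.geometry.shape),
                "beam_centre": list(self.geometry.beam_centre),
            },
            "model_positions_nm": None
            if self.model is None
            else self.model.positions.tolist(),
            "options": self.options,
        }
        (folder / f"{tag}_manifest.json").write_text(json.dumps(manifest, indent=1))
        return paths


def simulate_dataset(
    model: StructureModel,
    geometry: DetectorGeometry,
    n: int,
    seed: int = 0,
    solid_angle: bool = False,
    photons: float | None = None,
) -> ExposureSet:
    """Simulate ``n`` exposures at independent uniformly random orientations."""
    if n < 1:
        raise ValueError("need at least one pattern")
    rng = np.random.default_rng(seed)
    rots = random_rotations(n, rng)
    qvec = geometry.ewald_qvectors()
    patterns = [
        simulate_pattern(
            model, rots[i], geometry,
            solid_angle=solid_angle, photons=photons, rng=rng, _qvec=qvec,
        )
        for i in range(n)
    ]
    return ExposureSet(
        patterns=patterns,
        rotations=rots,
        geometry=geometry,
        seed=seed,
        model=model,
        options={"solid_angle": solid_angle, "photons": photons},
    )


def model_padf_oracle(
    model: StructureModel,
    r_edges: np.ndarray,
    theta_edges_deg: np.ndarray,
) -> np.ndarray:
    """Ideal pair-angle histogram of a model by direct enumeration.

    For every ordered pair of ordered atom pairs ((i, j), (k, l)) with
    i ≠ j and k ≠ l, a weight f0_i f0_j f0_k f0_l is accumulated at
    (|r_ij|, |r_kl|, ∠(r_ij, r_kl)).  The result is a histogram on the
    given bin edges (r in nm, θ in degrees), with no kernel smoothing.
    Used to read off ideal peak positions and peak-height ratios.
    """
    pos = model.positions
    n = len(pos)
    if n < 2:
        raise ValueError("oracle needs at least two atoms")
    vecs, weights = [], []
    for i in range(n):
        for j in range(n):
            if i != j:
                vecs.append(pos[j] - pos[i])
                weights.append(model.f0[i] * model.f0[j])
    vecs = np.asarray(vecs)
    weights = np.asarray(weights)
    dists = np.linalg.norm(vecs, axis=1)
    units = vecs / dists[:, None]

    cosang = np.clip(units @ units.T, -1.0, 1.0)
    ang = np.degrees(np.arccos(cosang))
    r1 = np.broadcast_to(dists[:, None], cosang.shape)
    r2 = np.broadcast_to(dists[None, :], cosang.shape)
    w = np.outer(weights, weights)  # f0_i f0_j f0_k f0_l

    hist, _ = np.histogramdd(
        np.stack([r1.ravel(), r2.ravel(), ang.ravel()], axis=1),
        bins=(r_edges, r_edges, theta_edges_deg),
        weights=w.ravel(),
    )
    return hist
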