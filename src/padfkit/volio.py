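"""Array and volume I/O.

Three-dimensional volumes (correlation functions, PADFs) are stored either
as NPY files or as raw little-endian float64 binaries; both carry a JSON
sidecar recording shape, axis names, axis maxima and arbitrary stage
metadata, so a write→read round trip is bit-exact in the values and exact
in the metadata.  2D images load from NPY, grayscale TIFF or a named HDF5
dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class VolumeIOError(IOError):
    pass


@dataclass
class Volume3D:
    """A 3D real volume with named axes and their maxima.

    ``axis_names`` are drawn from {"q", "r", "theta"}; ``axis_max`` holds
    the maximum coordinate of each axis (nm^-1, nm or degrees).  ``meta``
    is free-form JSON-serializable stage metadata.
    """

    values: np.ndarray
    axis_names: tuple[str, str, str]
    axis_max: tuple[float, float, float]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("Volume3D requires a 3D array")
        self.axis_names = tuple(self.axis_names)  # type: ignore[assignment]
        self.axis_max = tuple(float(x) for x in self.axis_max)  # type: ignore[assignment]


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def save_volume(vol: Volume3D, path: str | Path, fmt: str = "npy") -> Path:
    """Write a volume plus its JSON sidecar; returns the data path.

    ``fmt='npy'`` stores a NumPy v1.0 array file; ``fmt='raw'`` stores raw
    little-endian float64 with the last (theta) axis fastest-varying.
    """
    path = Path(path)
    if fmt == "npy":
        if path.suffix != ".npy":
            path = path.with_suffix(".npy")
        np.save(path, vol.values.astype("<f8"))
    elif fmt == "raw":
        if path.suffix != ".bin":
            path = path.with_suffix(".bin")
        vol.values.astype("<f8").tofile(path)
    else:
        raise VolumeIOError(f"unknown volume format {fmt!r} (use 'npy' or 'raw')")
    sidecar = {
        "shape": list(vol.values.shape),
        "dtype": "<f8",
        "axis_names": list(vol.axis_names),
        "axis_max": list(vol.axis_max),
        "meta": vol.meta,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def load_volume(path: str | Path) -> Volume3D:
    """Read a volume written by :func:`save_volume`."""
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"volume file not found: {path}")
    side = _sidecar_path(path)
    if path.suffix == ".npy":
        values = np.load(path)
        if side.exists():
            sc = json.loads(side.read_text())
        else:  # bare NPY: values only, unit axes
            sc = {
                "axis_names": ["q", "q", "theta"],
                "axis_max": [1.0, 1.0, 360.0],
                "meta": {},
            }
    elif path.suffix == ".bin":
        if not side.exists():
            raise VolumeIOError(
                f"raw volume {path} has no sidecar {side.name}; "
                "shape metadata is required to read raw binaries"
            )
        sc = json.loads(side.read_text())
        values = np.fromfile(path, dtype=np.dtype(sc.get("dtype", "<f8")))
        values = values.reshape(sc["shape"])
    else:
        raise VolumeIOError(f"unrecognized volume suffix {path.suffix!r}")
    return Volume3D(
        values=values,
        axis_names=tuple(sc["axis_names"]),
        axis_max=tuple(sc["axis_max"]),
        meta=sc.get("meta", {}),
    )


def load_image(path: str | Path, h5_dataset: str | None = None) -> np.ndarray:
    """Load a 2D detector image from NPY, TIFF or HDF5.

    For HDF5, ``h5_dataset`` names the dataset; if omitted the first 2D
    dataset found is used.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"image file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".npy":
        arr = np.load(path)
    elif suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    elif suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "r") as fh:
            if h5_dataset is not None:
                arr = fh[h5_dataset][()]
            else:
                arr = None

                def _grab(name, obj):
                    nonlocal arr
                    if arr is None and hasattr(obj, "ndim") and obj.ndim == 2:
                        arr = obj[()]

                fh.visititems(_grab)
                if arr is None:
                    raise VolumeIOError(f"no 2D dataset found in {path}")
    else:
        raise VolumeIOError(f"unsupported image format {suffix!r}")
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim != 2:
        raise VolumeIOError(f"expected a 2D image in {path}, got shape {arr.shape}")
    return arr


def save_image(arr: np.ndarray, path: str | Path) -> Path:
    """Write a 2D image as NPY or TIFF depending on the suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".npy":
        np.save(path, np.asarray(arr, dtype=np.float64))
    elif suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, np.asarray(arr, dtype=np.float32))
    else:
        raise VolumeIOError(f"unsupported image format {suffix!r}")
    return path
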