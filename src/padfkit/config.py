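"""Parameter handling shared by all pipeline stages.

Each stage (``diffract``, ``difftocorr``, ``maskcorr``, ``corrtopadf``,
``plotfxs3d``) owns a flat namespace of typed parameters.  Values come from
three sources with a strict precedence: built-in defaults are read first,
then an INI configuration file (section named after the stage), and finally
command-line flags, which override everything else.  Every resolved value
remembers where it came from.
"""

from __future__ import annotations

import configparser
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence


class ConfigError(ValueError):
    """Raised for malformed, missing or unknown parameters."""


_REQUIRED = object()


@dataclass(frozen=True)
class ParamSpec:
    """Declaration of a single stage parameter."""

    name: str
    type: str  # "int" | "float" | "str" | "bool" | "path"
    default: Any = _REQUIRED
    help: str = ""

    @property
    def required(self) -> bool:
        return self.default is _REQUIRED

    def coerce(self, raw: Any) -> Any:
        if isinstance(raw, str):
            raw = raw.strip()
        try:
            if self.type == "int":
                if isinstance(raw, bool):
                    raise ValueError
                if isinstance(raw, float) and raw != int(raw):
                    raise ValueError
                return int(raw)
            if self.type == "float":
                if isinstance(raw, bool):
                    raise ValueError
                return float(raw)
            if self.type == "bool":
                if isinstance(raw, bool):
                    return raw
                low = str(raw).lower()
                if low in ("true", "1", "yes", "on"):
                    return True
                if low in ("false", "0", "no", "off"):
                    return False
                raise ValueError
            if self.type == "path":
                return Path(raw)
            if self.type == "str":
                return str(raw)
        except (TypeError, ValueError):
            raise ConfigError(
                f"parameter '{self.name}' expects {self.type}, got {raw!r}"
            ) from None
        raise ConfigError(f"unknown parameter type {self.type!r} for '{self.name}'")


@dataclass
class ParamSet:
    """Resolved parameters for one stage, with per-entry provenance.

    Provenance is one of ``default``, ``config-file`` or ``command-line``;
    each entry carries exactly one tag.
    """

    stage: str
    entries: dict[str, Any] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.entries[key]

    def get(self, key: str, fallback: Any = None) -> Any:
        return self.entries.get(key, fallback)

    def set(self, key: str, value: Any, provenance: str) -> None:
        self.entries[key] = value
        self.provenance[key] = provenance


def _geometry_specs() -> list[ParamSpec]:
    return [
        ParamSpec("wavelength", "float", help="beam wavelength (nm)"),
        ParamSpec("detector_z", "float", help="sample-to-detector distance (m)"),
        ParamSpec("pixel_width", "float", help="detector pixel width (m)"),
        ParamSpec("beam_centre_x", "float", -1.0, "beam centre x (fractional pixels; <0 = image centre)"),
        ParamSpec("beam_centre_y", "float", -1.0, "beam centre y (fractional pixels; <0 = image centre)"),
    ]


#: Parameter declarations per pipeline stage.
STAGES: dict[str, dict[str, ParamSpec]] = {}


def _register(stage: str, specs: Sequence[ParamSpec]) -> None:
    STAGES[stage] = {s.name: s for s in specs}


_register(
    "diffract",
    [
        ParamSpec("outpath", "path", help="output folder for simulated patterns"),
        ParamSpec("npatterns", "int", 100, "number of exposures to simulate"),
        ParamSpec("npix", "int", 256, "detector side length in pixels"),
        ParamSpec("wavelength", "float", 0.1, "beam wavelength (nm)"),
        ParamSpec("pixel_width", "float", 1e-4, "detector pixel width (m)"),
        ParamSpec("edge_q", "float", 1.28, "q at the detector half-width edge (nm^-1)"),
        ParamSpec("hexagon_side", "float", 15.0, "nearest-neighbour distance of the built-in hexagon model (nm)"),
        ParamSpec("model_file", "str", "", "optional atom model file (x y z f0 b per line, nm units)"),
        ParamSpec("solid_angle", "bool", False, "apply the cos^3(theta) solid-angle factor"),
        ParamSpec("photons", "float", 0.0, "Poisson-sample to this photon count per pattern (0 = noise free)"),
        ParamSpec("seed", "int", 0, "random seed for orientations"),
        ParamSpec("tag", "str", "diff", "filename prefix for output patterns"),
    ],
)

_register(
    "difftocorr",
    [
        ParamSpec("folder", "path", help="folder containing one diffraction image per file"),
        ParamSpec("name_format", "str", help="filename format with '#' marking the frame index, e.g. diff_#.npy"),
        ParamSpec("npatterns", "int", 0, "maximum number of patterns to use (0 = all)"),
        *_geometry_specs(),
        ParamSpec("nq", "int", 0, "radial samples (0 = half the image width)"),
        ParamSpec("ntheta", "int", 360, "azimuthal samples on [0, 2pi)"),
        ParamSpec("qmax", "float", 0.0, "maximum q of the polar grid (nm^-1; 0 = detector edge)"),
        ParamSpec("mode", "str", "standard", "correlation mode: standard | background | difference"),
        ParamSpec("mask_file", "str", "", "optional binary detector mask image"),
        ParamSpec("interpolation_order", "int", 3, "polar resampling spline order (1 or 3)"),
        ParamSpec("crop", "int", 0, "crop images to this square size about the beam centre (0 = off)"),
        ParamSpec("rebin", "int", 1, "mean-rebin factor applied after cropping"),
        ParamSpec("pairing_seed", "int", 0, "seed of the random derangement used for background/difference modes"),
        ParamSpec("outpath", "path", help="output folder"),
        ParamSpec("tag", "str", "corr", "output filename prefix"),
        ParamSpec("output_format", "str", "npy", "volume format: npy | raw"),
    ],
)

_register(
    "maskcorr",
    [
        ParamSpec("input", "path", help="correlation volume to condition"),
        ParamSpec("output", "path", help="conditioned output volume"),
        ParamSpec("sintheta", "bool", True, "apply the |sin(theta)| sampling weight"),
        ParamSpec("sintheta_exponent", "float", 1.0, "exponent of the |sin(theta)| weight"),
        ParamSpec("qlow", "float", 0.0, "low-pass cut (nm^-1)"),
        ParamSpec("qhigh", "float", 0.0, "high-pass cut (nm^-1; 0 = qmax)"),
        ParamSpec("taper", "float", 0.0, "cosine taper width of the band-pass (nm^-1; 0 = hard cut)"),
        ParamSpec("thzero_halfwidth", "float", 0.0, "half-width of the theta=0 noise mask (degrees)"),
        ParamSpec("output_format", "str", "npy", "volume format: npy | raw"),
    ],
)

_register(
    "corrtopadf",
    [
        ParamSpec("input", "path", help="conditioned correlation volume"),
        ParamSpec("outpath", "path", help="output folder"),
        ParamSpec("tag", "str", "padf", "output filename prefix"),
        ParamSpec("wavelength", "float", help="beam wavelength (nm)"),
        ParamSpec("lmax", "int", 32, "highest (even) spherical-harmonic order"),
        ParamSpec("nr", "int", 0, "radial output samples (0 = nq - 1)"),
        ParamSpec("rmax", "float", 0.0, "maximum real-space distance (nm; 0 = nr / (2 qmax))"),
        ParamSpec("regularization", "float", 0.5, "relative SVD cutoff of the inversion"),
        ParamSpec("ntheta_out", "int", 181, "angular output samples on [0, 180] degrees"),
        ParamSpec("save_blqq", "bool", False, "also save the Bl(q,q') matrices"),
        ParamSpec("save_blrr", "bool", False, "also save the Bl(r,r') matrices"),
        ParamSpec("absolute", "bool", False, "divide by the absolute-scale constants"),
        ParamSpec("rho0", "float", 0.0, "mean density (nm^-3) for absolute scaling"),
        ParamSpec("ni", "float", 0.0, "incident quanta per exposure for absolute scaling"),
        ParamSpec("output_format", "str", "npy", "volume format: npy | raw"),
    ],
)

_register(
    "plotfxs3d",
    [
        ParamSpec("input", "path", help="correlation or PADF volume"),
        ParamSpec("slice", "str", "req", "slice kind: req | theta | r | line-r | line-theta"),
        ParamSpec("at", "float", 0.0, "coordinate of the slice (degrees or nm)"),
        ParamSpec("at2", "float", 0.0, "second coordinate for 1D lines (nm)"),
        ParamSpec("smooth_r", "float", 0.0, "radial Gaussian half-width (nm)"),
        ParamSpec("smooth_th", "float", 0.0, "angular Gaussian half-width (degrees)"),
        ParamSpec("png", "str", "", "output PNG path (empty = no plot file)"),
        ParamSpec("csv", "str", "", "optional CSV dump of the slice"),
    ],
)


def _parse_cli(tokens: Sequence[str]) -> dict[str, str]:
    """Parse ``--name value`` pairs into a dict; reject malformed input."""
    out: dict[str, str] = {}
    toks = list(tokens)
    i = 0
    while i < len(toks):
        tok = toks[i]
        if not tok.startswith("--"):
            raise ConfigError(f"expected a --flag, got {tok!r}")
        name = tok[2:]
        if "=" in name:
            name, value = name.split("=", 1)
        else:
            if i + 1 >= len(toks):
                raise ConfigError(f"flag --{name} is missing a value")
            value = toks[i + 1]
            i += 1
        out[name] = value
        i += 1
    return out


def load_params(
    stage: str,
    config_path: str | Path | None = None,
    cli_args: Sequence[str] = (),
) -> ParamSet:
    """Merge defaults, a config file and CLI flags for one stage.

    Precedence is command-line > config-file > built-in default.  Unknown
    keys from either source are fatal, as is a missing required parameter.
    """
    if stage not in STAGES:
        raise ConfigError(f"unknown stage {stage!r}; valid stages: {sorted(STAGES)}")
    schema = STAGES[stage]
    ps = ParamSet(stage=stage)

    for spec in schema.values():
        if not spec.required:
            ps.set(spec.name, spec.coerce(spec.default), "default")

    if config_path is not None:
        config_path = Path(config_path)
        if not config_path.exists():
            raise ConfigError(f"config file not found: {config_path}")
        parser = configparser.ConfigParser()
        try:
            parser.read(config_path)
        except configparser.Error as exc:
            raise ConfigError(f"cannot parse {config_path}: {exc}") from exc
        if parser.has_section(stage):
            for key, raw in parser.items(stage):
                if key not in schema:
                    raise ConfigError(
                        f"unknown parameter '{key}' in [{stage}] of {config_path}; "
                        f"valid: {sorted(schema)}"
                    )
                ps.set(key, schema[key].coerce(raw), "config-file")

    cli = _parse_cli(cli_args)
    for key, raw in cli.items():
        if key == "config":
            continue
        if key not in schema:
            raise ConfigError(
                f"unknown flag --{key} for stage '{stage}'; "
                f"valid flags: " + ", ".join("--" + k for k in sorted(schema))
            )
        ps.set(key, schema[key].coerce(raw), "command-line")

    missing = [s.name for s in schema.values() if s.name not in ps.entries]
    if missing:
        raise ConfigError(
            f"missing required parameter(s) for stage '{stage}': {', '.join(missing)}"
        )
    return ps


def build_file_list(
    folder: str | Path, name_format: str, n_max: int = 0
) -> list[Path]:
    """List dataset files matching ``name_format`` in ascending frame order.

    The format contains a single ``#`` token standing for a run of digits
    (the frame index).  Files sort by that integer, ties broken
    lexicographically, so the result is independent of filesystem
    enumeration order.  ``n_max`` > 0 truncates to the first ``n_max``.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise ConfigError(f"diffraction folder not found: {folder}")
    if name_format.count("#") != 1:
        raise ConfigError(
            f"name format must contain exactly one '#' token, got {name_format!r}"
        )
    pattern = re.compile(
        "^" + re.escape(name_format).replace(r"\#", r"(\d+)") + "$"
    )
    matches: list[tuple[int, str, Path]] = []
    for p in folder.iterdir():
        m = pattern.match(p.name)
        if m:
            matches.append((int(m.group(1)), p.name, p))
    if not matches:
        raise ConfigError(
            f"no diffraction files found in {folder} matching {name_format!r}"
        )
    matches.sort(key=lambda t: (t[0], t[1]))
    paths = [t[2] for t in matches]
    if n_max and n_max > 0:
        paths = paths[:n_max]
    return paths
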