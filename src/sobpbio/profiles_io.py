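"""Depth grids, dose profiles, mixed-field spectra and their CSV formats.

The geometry convention is a 1D stack of scoring slices along the beam axis
of a water phantom: slice ``i`` covers the half-open interval
``[origin + i*dz, origin + (i+1)*dz)`` and is reported at its center
``origin + (i + 0.5)*dz``.  All depths are millimetres; doses are Gy (or Gy
per primary particle), with an explicit ``unit_tag`` once a profile has been
normalized.

A mixed-field spectrum decomposes the dose in each slice by particle species
and kinetic energy per nucleon — the per-component doses that feed the
dose-averaged linear-quadratic mixing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GridError, ValidationError

logger = logging.getLogger(__name__)

#: Canonical particle-species vocabulary. Anything else folds into "other".
SPECIES_TOKENS = ("p", "He", "Li", "Be", "B", "C", "other")

#: Alias map applied when reading spectra from arbitrary MC exports.
SPECIES_ALIASES = {
    "H": "p", "H1": "p", "proton": "p", "protons": "p",
    "He3": "He", "He4": "He", "alpha": "He", "helium": "He",
    "Li6": "Li", "Li7": "Li", "lithium": "Li",
    "Be7": "Be", "Be9": "Be", "Be10": "Be", "beryllium": "Be",
    "B10": "B", "B11": "B", "boron": "B",
    "C11": "C", "C12": "C", "C13": "C", "carbon": "C",
}

_DEPTH_TOL_MM = 1e-6


def normalize_species(token: str) -> str:
    """Map an arbitrary species label onto the canonical vocabulary.

    Unknown labels fold into ``"other"`` with a logged warning so that the
    per-slice dose sum (the denominator of the mixing formula) always covers
    the full physical dose.
    """
    token = token.strip()
    if token in SPECIES_TOKENS:
        return token
    if token in SPECIES_ALIASES:
        return SPECIES_ALIASES[token]
    logger.warning("unknown species token %r folded into 'other'", token)
    return "other"


@dataclass(frozen=True)
class DepthGrid:
    """Uniform 1D scoring grid along the beam axis.

    Parameters
    ----------
    n_slices
        Number of scoring slices (> 0).
    slice_thickness_mm
        Slice thickness in mm (> 0); the scoring resolution.
    origin_mm
        Depth of the phantom entrance (defaults to 0).
    """

    n_slices: int
    slice_thickness_mm: float = 1.0
    origin_mm: float = 0.0

    def __post_init__(self):
        if self.n_slices <= 0:
            raise ValidationError("n_slices must be positive")
        if self.slice_thickness_mm <= 0:
            raise ValidationError("slice_thickness_mm must be positive")

    def centers(self) -> np.ndarray:
        """Slice-center depths in mm (strictly increasing)."""
        return self.origin_mm + (np.arange(self.n_slices) + 0.5) * self.slice_thickness_mm

    def edges(self) -> np.ndarray:
        """Slice edges in mm, length ``n_slices + 1``."""
        return self.origin_mm + np.arange(self.n_slices + 1) * self.slice_thickness_mm

    @property
    def extent_mm(self) -> float:
        return self.n_slices * self.slice_thickness_mm


def grid_from_depths(depths_mm: np.ndarray) -> DepthGrid:
    """Reconstruct a uniform :class:`DepthGrid` from slice-center depths.

    Raises :class:`GridError` when the depths are not consistent with a
    uniform grid to within 1e-6 mm.
    """
    depths = np.asarray(depths_mm, dtype=float)
    if depths.ndim != 1 or depths.size < 1:
        raise GridError("need a 1D, non-empty depth sequence")
    if depths.size == 1:
        thickness = 1.0
    else:
        steps = np.diff(depths)
        thickness = float(depths[-1] - depths[0]) / (depths.size - 1)
        if thickness <= 0 or not np.all(np.abs(steps - thickness) <= _DEPTH_TOL_MM):
            raise GridError("depths are not uniformly spaced")
    # snap away sub-nm float residue so reconstruction is idempotent
    thickness = round(thickness, 9)
    origin = round(float(depths[0] - 0.5 * thickness), 9)
    grid = DepthGrid(depths.size, thickness, origin)
    if not np.all(np.abs(grid.centers() - depths) <= _DEPTH_TOL_MM):
        raise GridError("depths are not slice centers of a uniform grid")
    return grid


@dataclass
class DoseProfile:
    """Per-slice scalar quantity (dose, survival, ...) with 1-sigma uncertainty."""

    grid: DepthGrid
    values: np.ndarray
    sigma: np.ndarray | None = None
    unit_tag: str = "absolute_Gy"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.sigma is None:
            self.sigma = np.zeros_like(self.values)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = self.grid.n_slices
        if self.values.shape != (n,) or self.sigma.shape != (n,):
            raise ValidationError(
                f"values/sigma must have shape ({n},), got {self.values.shape}/{self.sigma.shape}"
            )
        if np.any(self.values < 0) or np.any(self.sigma < 0):
            raise ValidationError("values and sigma must be non-negative")
        if self.unit_tag not in ("absolute_Gy", "normalized"):
            raise ValidationError(f"unknown unit_tag {self.unit_tag!r}")

    def depths_mm(self) -> np.ndarray:
        return self.grid.centers()


@dataclass(frozen=True)
class MixedFieldRecord:
    """Dose contribution of one (species, energy) component in one slice."""

    slice_index: int
    species: str
    energy_MeV_per_u: float
    dose_Gy_per_primary: float

    def __post_init__(self):
        if self.species not in SPECIES_TOKENS:
            raise ValidationError(f"species {self.species!r} not in canonical vocabulary")
        if self.energy_MeV_per_u <= 0:
            raise ValidationError("energy must be positive")
        if self.dose_Gy_per_primary < 0:
            raise ValidationError("dose must be non-negative")


@dataclass
class MixedFieldSpectrum:
    """Per-depth decomposition of dose by particle species and energy."""

    grid: DepthGrid
    records: list[MixedFieldRecord] = field(default_factory=list)

    def __post_init__(self):
        for r in self.records:
            if not (0 <= r.slice_index < self.grid.n_slices):
                raise ValidationError(
                    f"slice_index {r.slice_index} out of range [0, {self.grid.n_slices})"
                )

    def records_by_slice(self) -> list[list[MixedFieldRecord]]:
        out: list[list[MixedFieldRecord]] = [[] for _ in range(self.grid.n_slices)]
        for r in self.records:
            out[r.slice_index].append(r)
        return out


@dataclass
class RunSet:
    """Independent statistical runs of one scoring setup (n >= 2)."""

    runs: list
    n_primaries_per_run: int = 2_000_000

    def __post_init__(self):
        if len(self.runs) < 2:
            raise ValidationError("RunSet requires at least 2 runs")
        grids = [r.grid for r in self.runs]
        g0 = grids[0]
        for g in grids[1:]:
            if (g.n_slices, g.slice_thickness_mm, g.origin_mm) != (
                g0.n_slices, g0.slice_thickness_mm, g0.origin_mm,
            ):
                raise ValidationError("all runs must share one depth grid")
        if self.n_primaries_per_run <= 0:
            raise ValidationError("n_primaries_per_run must be positive")

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def grid(self) -> DepthGrid:
        return self.runs[0].grid


# ---------------------------------------------------------------------------
# CSV I/O
#
# Dialect: comma-separated, "." decimal, UTF-8; "#"-prefixed `key=value`
# metadata lines before the header; floats written with %.17g so that
# write -> read round-trips are bit exact.
# ---------------------------------------------------------------------------

def _read_metadata(path: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def write_profile_csv(profile: DoseProfile, path: str, extra_metadata: dict | None = None) -> None:
    """Write a profile as ``depth_mm,value,sigma`` with ``# key=value`` metadata."""
    meta = {"unit": profile.unit_tag}
    if extra_metadata:
        meta.update(extra_metadata)
    df = pd.DataFrame(
        {"depth_mm": profile.depths_mm(), "value": profile.values, "sigma": profile.sigma}
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_profile_csv(path: str) -> DoseProfile:
    """Read a ``depth_mm,value,sigma`` file, reconstructing the uniform grid."""
    meta = _read_metadata(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    expected = ["depth_mm", "value", "sigma"]
    if list(df.columns[:3]) != expected:
        raise ValidationError(f"profile CSV must have columns {expected}, got {list(df.columns)}")
    grid = grid_from_depths(df["depth_mm"].to_numpy())
    unit = meta.get("unit", "absolute_Gy")
    return DoseProfile(grid, df["value"].to_numpy(), df["sigma"].to_numpy(), unit_tag=unit)


def write_spectrum_csv(spectrum: MixedFieldSpectrum, path: str,
                       extra_metadata: dict | None = None) -> None:
    """Write ``slice_index,species,energy_MeV_per_u,dose_Gy_per_primary`` records."""
    meta = {
        "n_slices": spectrum.grid.n_slices,
        "slice_thickness_mm": repr(spectrum.grid.slice_thickness_mm),
        "origin_mm": repr(spectrum.grid.origin_mm),
    }
    if extra_metadata:
        meta.update(extra_metadata)
    df = pd.DataFrame(
        {
            "slice_index": [r.slice_index for r in spectrum.records],
            "species": [r.species for r in spectrum.records],
            "energy_MeV_per_u": [r.energy_MeV_per_u for r in spectrum.records],
            "dose_Gy_per_primary": [r.dose_Gy_per_primary for r in spectrum.records],
        }
    )
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_spectrum_csv(path: str, grid: DepthGrid | None = None) -> MixedFieldSpectrum:
    """Read spectrum records, validating slice indices against ``grid``.

    When ``grid`` is omitted it is reconstructed from the file's metadata
    lines.  Species labels outside the canonical vocabulary are folded into
    ``"other"`` (with a logged warning).
    """
    meta = _read_metadata(path)
    if grid is None:
        try:
            grid = DepthGrid(
                int(meta["n_slices"]),
                float(meta["slice_thickness_mm"]),
                float(meta.get("origin_mm", 0.0)),
            )
        except KeyError as exc:
            raise ValidationError("spectrum CSV lacks grid metadata; pass grid=") from exc
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    expected = ["slice_index", "species", "energy_MeV_per_u", "dose_Gy_per_primary"]
    if list(df.columns[:4]) != expected:
        raise ValidationError(f"spectrum CSV must have columns {expected}")
    records = [
        MixedFieldRecord(int(i), normalize_species(str(s)), float(e), float(d))
        for i, s, e, d in zip(
            df["slice_index"], df["species"], df["energy_MeV_per_u"], df["dose_Gy_per_primary"]
        )
    ]
    return MixedFieldSpectrum(grid, records)


def total_dose_profile(spectrum: MixedFieldSpectrum) -> DoseProfile:
    """Sum the record doses slice by slice (the mixing denominator)."""
    totals = np.zeros(spectrum.grid.n_slices)
    for r in spectrum.records:
        totals[r.slice_index] += r.dose_Gy_per_primary
    return DoseProfile(spectrum.grid, totals)
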