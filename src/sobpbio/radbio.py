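"""Mixed-field linear-quadratic radiobiology: dose-averaged coefficients,
survival, RBE and photon-equivalent (Gy-Eq) dose.

Cells along a therapeutic ion beam sit in a mixed radiation field: each
scoring slice receives dose from several particle species at several
energies, each with its own linear-quadratic radiosensitivity (alpha, beta).
Following the Zaider-Rossi formalism, the mixed-field coefficients in a
slice are the dose-weighted averages

    alpha = sum_i alpha_i D_i / sum_i D_i
    beta  = ( sum_i sqrt(beta_i) D_i / sum_i D_i )^2

i.e. alpha averages linearly while sqrt(beta) averages linearly (so the
mixed beta is the square of the dose-averaged sqrt(beta), not the plain
dose average of beta).  Survival at the slice's total dose D is then
S = exp(-alpha*D - beta*D^2), and the RBE at iso-survival is the photon
dose producing the same effect divided by D; that photon dose is the Gy-Eq
dose of the slice.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .profiles_io import DepthGrid, DoseProfile, MixedFieldSpectrum, total_dose_profile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CellLine:
    """Photon radiosensitivity of a cell line: alpha_x (1/Gy), beta_x (1/Gy^2)."""

    name: str
    alpha_x: float
    beta_x: float

    def __post_init__(self):
        if self.alpha_x <= 0 or self.beta_x <= 0:
            raise ValidationError("alpha_x and beta_x must be positive")


#: Human squamous cell carcinoma — radiosensitive, high alpha/beta.
SCC = CellLine("SCC", alpha_x=0.379, beta_x=0.0299)
#: Human chordoma — radioresistant, low alpha/beta.
CHORDOMA = CellLine("chordoma", alpha_x=0.1567, beta_x=0.0661)

CELL_LINES = {c.name: c for c in (SCC, CHORDOMA)}


def alpha_beta_ratio(cell: CellLine) -> float:
    """alpha_x / beta_x in Gy — the standard radiosensitivity descriptor."""
    return cell.alpha_x / cell.beta_x


@dataclass
class RadiosensitivityTable:
    """Per-species, energy-indexed LQ coefficients for one cell line.

    ``entries`` maps a species token to ``(energy_MeV_per_u, alpha, beta)``
    arrays with a strictly increasing energy grid.  Species without an entry
    (including ``"other"``) fall back to the photon coefficients, which keeps
    the mixing denominator equal to the full physical dose.
    """

    cell_line: CellLine
    entries: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        for sp, (e, a, b) in self.entries.items():
            e = np.asarray(e, float)
            a = np.asarray(a, float)
            b = np.asarray(b, float)
            if not (e.shape == a.shape == b.shape) or e.ndim != 1:
                raise ValidationError(f"ragged table entry for {sp!r}")
            if np.any(np.diff(e) <= 0):
                raise ValidationError(f"energy grid for {sp!r} must be strictly increasing")
            if np.any(a < 0) or np.any(b < 0):
                raise ValidationError("alpha and beta must be non-negative")
            self.entries[sp] = (e, a, b)


def lookup_alpha_beta(
    table: RadiosensitivityTable, species: str, energy_MeV_per_u: float
) -> tuple[float, float]:
    """Interpolated (alpha, beta) for one field component.

    alpha and sqrt(beta) are interpolated linearly in log(energy), so that
    interpolation commutes with the mixing rule on flat tables.  Queries
    outside the tabulated energy range clamp to the nearest endpoint (with a
    logged warning); species without a table entry use the photon fallback.
    """
    if energy_MeV_per_u <= 0:
        raise DomainError("energy must be positive")
    if species not in table.entries:
        return table.cell_line.alpha_x, table.cell_line.beta_x
    e, a, b = table.entries[species]
    loge = math.log(energy_MeV_per_u)
    le = np.log(e)
    if loge < le[0] or loge > le[-1]:
        logger.warning(
            "energy %.4g MeV/u outside table range [%.4g, %.4g] for %s; clamping",
            energy_MeV_per_u, e[0], e[-1], species,
        )
    alpha = float(np.interp(loge, le, a))
    sqrt_beta = float(np.interp(loge, le, np.sqrt(b)))
    return alpha, sqrt_beta**2


@dataclass(frozen=True)
class LQCoefficients:
    """Mixed-field LQ coefficients of one slice, with uncertainties."""

    alpha: float
    beta: float
    sigma_alpha: float = 0.0
    sigma_beta: float = 0.0
    defined: bool = True

    def __post_init__(self):
        if self.defined and (self.alpha < 0 or self.beta < 0):
            raise ValidationError("alpha and beta must be non-negative")
        if self.sigma_alpha < 0 or self.sigma_beta < 0:
            raise ValidationError("sigmas must be non-negative")


UNDEFINED_LQ = LQCoefficients(float("nan"), float("nan"), 0.0, 0.0, defined=False)


def mix_coefficients(doses, alphas, betas) -> LQCoefficients:
    """Dose-averaged LQ coefficients of a mixed field (Zaider-Rossi).

    ``alpha`` is the dose-weighted mean of the component alphas;
    ``beta`` is the square of the dose-weighted mean of sqrt(beta_i).
    Raises :class:`DomainError` when the total dose is zero (the caller
    decides how to flag such slices).
    """
    D = np.asarray(doses, float)
    a = np.asarray(alphas, float)
    b = np.asarray(betas, float)
    if not (D.shape == a.shape == b.shape) or D.ndim != 1 or D.size < 1:
        raise ValidationError("doses, alphas, betas must be equal-length 1D sequences")
    if np.any(D < 0):
        raise ValidationError("doses must be non-negative")
    total = D.sum()
    if total <= 0:
        raise DomainError("total dose is zero: mixed coefficients undefined")
    if D.size == 1:  # a single component reproduces its own coefficients exactly
        return LQCoefficients(float(a[0]), float(b[0]))
    alpha = float((a * D).sum() / total)
    beta = float(((np.sqrt(b) * D).sum() / total) ** 2)
    return LQCoefficients(alpha, beta)


def mix_spectrum(
    spectrum: MixedFieldSpectrum, table: RadiosensitivityTable
) -> list[LQCoefficients]:
    """Per-slice mixed coefficients; zero-dose slices are flagged undefined."""
    out: list[LQCoefficients] = []
    for slice_records in spectrum.records_by_slice():
        doses = [r.dose_Gy_per_primary for r in slice_records]
        if not slice_records or sum(doses) <= 0:
            out.append(UNDEFINED_LQ)
            continue
        ab = [lookup_alpha_beta(table, r.species, r.energy_MeV_per_u) for r in slice_records]
        out.append(mix_coefficients(doses, [x[0] for x in ab], [x[1] for x in ab]))
    return out


def survival(alpha: float, beta: float, dose_Gy: float):
    """Linear-quadratic survival S = exp(-alpha*D - beta*D^2)."""
    dose = np.asarray(dose_Gy, float)
    if np.any(dose < 0):
        raise DomainError("dose must be non-negative")
    out = np.exp(-(np.asarray(alpha, float) * dose + np.asarray(beta, float) * dose**2))
    return float(out) if out.ndim == 0 else out


def rbe_and_gyeq(
    alpha: float, beta: float, dose_Gy: float, cell: CellLine
) -> tuple[float, float]:
    """Iso-survival RBE and photon-equivalent dose (Gy-Eq).

    Solves ``alpha_x Dx + beta_x Dx^2 = alpha D + beta D^2`` for the photon
    dose ``Dx`` producing the same survival; RBE = Dx / D and Gy-Eq = Dx.
    Zero dose yields an undefined RBE (NaN) with Gy-Eq 0.
    """
    if dose_Gy < 0:
        raise DomainError("dose must be non-negative")
    if dose_Gy == 0:
        return float("nan"), 0.0
    effect = alpha * dose_Gy + beta * dose_Gy**2
    ax, bx = cell.alpha_x, cell.beta_x
    dx = (-ax + math.sqrt(ax * ax + 4.0 * bx * effect)) / (2.0 * bx)
    return dx / dose_Gy, dx


@dataclass
class BioProfile:
    """Depth-resolved biological endpoint bundle for one spectrum and cell line."""

    grid: DepthGrid
    dose: DoseProfile
    coefficients: list[LQCoefficients]
    survival: np.ndarray
    sigma_survival: np.ndarray
    rbe: np.ndarray  # NaN where undefined (zero-dose slices)
    gyeq: np.ndarray
    cell_line: CellLine | None = None

    def defined_mask(self) -> np.ndarray:
        return np.array([c.defined for c in self.coefficients])

    def survival_profile(self) -> DoseProfile:
        return DoseProfile(self.grid, self.survival, self.sigma_survival,
                           unit_tag="normalized")


def bio_profile(
    spectrum: MixedFieldSpectrum,
    table: RadiosensitivityTable,
    cell: CellLine | None = None,
) -> BioProfile:
    """Full per-slice biological pipeline: dose, mixed LQ, survival, RBE, Gy-Eq.

    Zero-dose slices carry survival 1, RBE NaN and Gy-Eq 0 and are flagged
    undefined so downstream comparisons can exclude them.
    """
    if cell is None:
        cell = table.cell_line
    dose = total_dose_profile(spectrum)
    coeffs = mix_spectrum(spectrum, table)
    n = spectrum.grid.n_slices
    S = np.ones(n)
    rbe = np.full(n, np.nan)
    gyeq = np.zeros(n)
    for i, (c, D) in enumerate(zip(coeffs, dose.values)):
        if not c.defined:
            continue
        S[i] = survival(c.alpha, c.beta, D)
        rbe[i], gyeq[i] = rbe_and_gyeq(c.alpha, c.beta, D, cell)
    return BioProfile(spectrum.grid, dose, coeffs, S, np.zeros(n), rbe, gyeq, cell)


# -- radiosensitivity table I/O ---------------------------------------------

def write_radiosensitivity_csv(table: RadiosensitivityTable, path: str) -> None:
    cell = table.cell_line
    rows = []
    for sp, (e, a, b) in table.entries.items():
        for ei, ai, bi in zip(e, a, b):
            rows.append((sp, ei, ai, bi))
    df = pd.DataFrame(rows, columns=["species", "energy_MeV_per_u", "alpha_Gy-1", "beta_Gy-2"])
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# cell_line={cell.name}\n")
        fh.write(f"# alpha_x={cell.alpha_x!r}\n")
        fh.write(f"# beta_x={cell.beta_x!r}\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_radiosensitivity_csv(path: str) -> RadiosensitivityTable:
    from .profiles_io import _read_metadata, normalize_species

    meta = _read_metadata(path)
    try:
        cell = CellLine(meta.get("cell_line", "unknown"),
                        float(meta["alpha_x"]), float(meta["beta_x"]))
    except KeyError as exc:
        raise ValidationError(f"table CSV missing metadata: {exc}") from exc
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    entries = {}
    for sp, sub in df.groupby("species"):
        sub = sub.sort_values("energy_MeV_per_u")
        entries[normalize_species(str(sp))] = (
            sub["energy_MeV_per_u"].to_numpy(),
            sub["alpha_Gy-1"].to_numpy(),
            sub["beta_Gy-2"].to_numpy(),
        )
    return RadiosensitivityTable(cell, entries)
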