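"""Synthetic stand-in for the two Monte Carlo transport engines.

Real inputs to the biophysical interface are per-depth mixed-field dose
spectra scored by a transport code, plus a database of per-species,
per-energy LQ radiosensitivity coefficients produced by a biophysical
model.  Neither is publicly deposited, so this module emulates both:

* a parametric radiosensitivity table whose alpha(LET) rises linearly at
  low LET and rolls over exponentially (the classic effectiveness rise
  followed by overkill decline), anchored so that alpha -> alpha_x and
  beta -> beta_x in the low-LET (photon-like) limit;
* the decomposition of a designed SOBP into per-slice (species, energy)
  records, using the inverse range-energy relation for the local primary
  energy and labelling dose beyond the primary range as "other";
* paired "code A vs code B" multi-run outputs with controllable
  discrepancies: a depth shift of the code-B profiles (sub-mm to mm),
  a multiplier on the fragment-tail dose, and per-slice relative Gaussian
  noise, independent across runs and codes.

All randomness flows from explicit integer seeds; fixed seeds give
bit-identical run sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bragg import PristineKernel, SOBPPlan, range_to_energy
from .errors import ValidationError
from .profiles_io import MixedFieldRecord, MixedFieldSpectrum, RunSet
from .radbio import CellLine, RadiosensitivityTable

_Z_BY_SPECIES = {"p": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6}

#: LET(species, E) = LET_COEFF * Z^2 / (E/u)^0.8, scaled so protons at
#: 10 MeV/u have ~4.5 keV/um.
_LET_EXP = 0.8
_LET_COEFF = 4.5 * 10.0**_LET_EXP


def let_keV_um(species: str, energy_MeV_per_u) -> np.ndarray:
    """Parametric monotone LET model per species (keV/um)."""
    z = _Z_BY_SPECIES.get(species)
    if z is None:
        raise ValidationError(f"no LET model for species {species!r}")
    e = np.asarray(energy_MeV_per_u, float)
    out = _LET_COEFF * z**2 / e**_LET_EXP
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SyntheticRadbioParams:
    """Shape parameters of the synthetic alpha(LET), beta(LET) curves."""

    cell_line: CellLine
    let_scale_keV_um: float = 80.0
    alpha_gain: float = 3.0

    def __post_init__(self):
        if self.let_scale_keV_um <= 0 or self.alpha_gain <= 0:
            raise ValidationError("let_scale and alpha_gain must be positive")


def synth_alpha_beta_table(
    params: SyntheticRadbioParams,
    species_list=("p", "He", "Li", "Be", "B", "C"),
    energy_grid=None,
) -> RadiosensitivityTable:
    """Generate a radiosensitivity table with LQ-vs-LET shape.

    alpha(E) = alpha_x (1 + g L/L0) exp(-L/L0) rises with LET, peaks at
    L0 (g-1)/g and declines (overkill); sqrt(beta) decays as exp(-L/(2 L0)).
    Both tend to the photon coefficients as LET -> 0.
    """
    if energy_grid is None:
        energy_grid = np.logspace(np.log10(0.05), np.log10(2000.0), 60)
    energy_grid = np.asarray(energy_grid, float)
    if np.any(np.diff(energy_grid) <= 0):
        raise ValidationError("energy grid must be strictly increasing")
    cell = params.cell_line
    L0, g = params.let_scale_keV_um, params.alpha_gain
    entries = {}
    for sp in species_list:
        L = let_keV_um(sp, energy_grid)
        alpha = cell.alpha_x * (1.0 + g * L / L0) * np.exp(-L / L0)
        sqrt_beta = np.sqrt(cell.beta_x) * np.exp(-L / (2.0 * L0))
        entries[sp] = (energy_grid.copy(), alpha, sqrt_beta**2)
    return RadiosensitivityTable(cell, entries)


def _beam_spectrum_records(
    plan: SOBPPlan,
    kernels: list[PristineKernel],
    range_shift_mm: float = 0.0,
    tail_scale: float = 1.0,
    slice_factors: np.ndarray | None = None,
) -> list[MixedFieldRecord]:
    """Records for one (possibly perturbed) realization of the plan.

    The primary (stopping) and tail (fragment) components of each beam are
    shifted in depth by linear resampling; the tail is scaled; per-slice
    multiplicative ``slice_factors`` model statistical noise.  Primary dose
    in slices beyond the (shifted) range — the straggling spill-over — and
    all tail dose are labelled "other".
    """
    kern = sorted(kernels, key=lambda k: k.energy_MeV_per_u)
    grid = kern[0].depth_dose.grid
    centers = grid.centers()
    if slice_factors is None:
        slice_factors = np.ones(grid.n_slices)
    records: list[MixedFieldRecord] = []
    for (energy, weight), kernel in zip(plan.beams, kern):
        if weight <= 0:
            continue
        primary = np.interp(centers - range_shift_mm, centers, kernel.primary,
                            left=kernel.primary[0], right=0.0)
        tail = tail_scale * np.interp(centers - range_shift_mm, centers, kernel.tail,
                                      left=0.0, right=0.0)
        R_mm = 10.0 * kernel.range_cm + range_shift_mm
        resid_cm = (R_mm - centers) / 10.0
        for i in range(grid.n_slices):
            f = weight * slice_factors[i]
            d_primary = f * primary[i]
            d_tail = f * tail[i]
            if d_primary > 0:
                # below ~1 um of residual range the primary is effectively
                # stopped; its dose joins the "other" pool
                if resid_cm[i] > 1e-4:
                    e_local = float(range_to_energy(plan.ion, resid_cm[i]))
                    records.append(MixedFieldRecord(i, plan.ion.token, e_local, d_primary))
                else:
                    records.append(MixedFieldRecord(i, "other", energy, d_primary))
            if d_tail > 0:
                records.append(MixedFieldRecord(i, "other", energy, d_tail))
    return records


def synth_mixed_field_spectrum(
    plan: SOBPPlan, kernels: list[PristineKernel]
) -> MixedFieldSpectrum:
    """Decompose a composed SOBP into per-slice (species, energy) records.

    The local primary energy in each slice follows from the inverse
    range-energy relation E(z) = ((R - z) / (a A/Z^2))^(1/p); fragment-tail
    dose and straggling dose beyond the range are labelled "other".  The
    per-slice record sum reproduces the composed SOBP dose exactly.
    """
    if len(kernels) != len(plan.beams):
        raise ValidationError("kernel list does not match plan beams")
    grid = kernels[0].depth_dose.grid
    return MixedFieldSpectrum(grid, _beam_spectrum_records(plan, kernels))


@dataclass(frozen=True)
class PerturbationParams:
    """Controllable code-B discrepancies and per-run statistical noise."""

    range_shift_mm: float = 0.5
    tail_scale: float = 1.1
    noise_rel: float = 0.01
    n_runs: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.n_runs < 2:
            raise ValidationError("need n_runs >= 2")
        if self.noise_rel < 0 or self.tail_scale <= 0:
            raise ValidationError("noise_rel must be >= 0 and tail_scale > 0")


def generate_code_pair(
    plan: SOBPPlan,
    kernels: list[PristineKernel],
    perturbation: PerturbationParams,
    n_primaries_per_run: int = 2_000_000,
) -> tuple[RunSet, RunSet]:
    """Paired multi-run outputs of two emulated transport codes.

    Code A is the unperturbed decomposition of the plan; code B carries the
    configured depth shift and fragment-tail scaling.  Each run of either
    code adds independent per-slice relative Gaussian noise (factors clipped
    at zero to keep doses non-negative).  Deterministic for a fixed seed.
    """
    grid = sorted(kernels, key=lambda k: k.energy_MeV_per_u)[0].depth_dose.grid
    rng = np.random.default_rng(perturbation.seed)

    def runs(shift: float, tail_scale: float) -> list[MixedFieldSpectrum]:
        out = []
        for _ in range(perturbation.n_runs):
            factors = np.clip(
                1.0 + perturbation.noise_rel * rng.standard_normal(grid.n_slices), 0.0, None
            )
            out.append(MixedFieldSpectrum(
                grid, _beam_spectrum_records(plan, kernels, shift, tail_scale, factors)
            ))
        return out

    set_a = RunSet(runs(0.0, 1.0), n_primaries_per_run)
    set_b = RunSet(runs(perturbation.range_shift_mm, perturbation.tail_scale),
                   n_primaries_per_run)
    return set_a, set_b
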