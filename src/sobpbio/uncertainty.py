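"""Run-to-run statistics and survival error propagation.

Monte Carlo scoring is repeated as n independent runs; depth-dependent
quantities (dose, mixed alpha, mixed beta) are averaged across runs and
their standard error of the mean is

    sem = sqrt( sum_i (x_i - <x>)^2 / (n (n - 1)) ).

The survival uncertainty follows from first-order (delta-method) error
propagation through S = exp(-alpha D - beta D^2):

    sigma_S = S * sqrt( D^2 sigma_alpha^2 + D^4 sigma_beta^2
                        + (alpha + 2 beta D)^2 sigma_D^2 ),

treating the alpha and beta estimates as uncorrelated (no covariance term).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AggregationError, DomainError, ValidationError
from .profiles_io import DoseProfile, MixedFieldSpectrum, RunSet, total_dose_profile


@dataclass
class AggregatedQuantity:
    """Per-slice mean and standard error over a run set."""

    mean: np.ndarray
    sem: np.ndarray
    n_runs: int

    def __post_init__(self):
        self.mean = np.asarray(self.mean, float)
        self.sem = np.asarray(self.sem, float)
        if self.mean.shape != self.sem.shape:
            raise ValidationError("mean and sem shapes differ")
        if np.any(self.sem < 0):
            raise ValidationError("sem must be non-negative")
        if self.n_runs < 2:
            raise AggregationError("need n_runs >= 2")


def mean_and_sem(samples: np.ndarray, axis: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Mean and standard error of the mean along ``axis`` (n >= 2)."""
    samples = np.asarray(samples, float)
    n = samples.shape[axis]
    if n < 2:
        raise AggregationError("need at least 2 runs for run statistics")
    mean = samples.mean(axis=axis)
    ss = ((samples - np.expand_dims(mean, axis)) ** 2).sum(axis=axis)
    sem = np.sqrt(ss / (n * (n - 1)))
    return mean, sem


def aggregate_runs(runs: RunSet, quantity: str = "dose", table=None) -> AggregatedQuantity:
    """Per-slice mean and SEM of dose, mixed alpha, or mixed beta over runs.

    Runs may be :class:`DoseProfile` (quantity ``"dose"`` only) or
    :class:`MixedFieldSpectrum` objects; alpha/beta require a
    radiosensitivity ``table``.  Slices where a run's coefficients are
    undefined (zero dose) contribute NaN, which propagates to the aggregate
    so downstream consumers can exclude them.
    """
    if quantity not in ("dose", "alpha", "beta"):
        raise ValidationError(f"unknown quantity {quantity!r}")
    rows = []
    for run in runs.runs:
        if quantity == "dose":
            prof = run if isinstance(run, DoseProfile) else total_dose_profile(run)
            rows.append(prof.values)
        else:
            if not isinstance(run, MixedFieldSpectrum):
                raise ValidationError("alpha/beta aggregation requires spectra runs")
            if table is None:
                raise ValidationError("alpha/beta aggregation requires a radiosensitivity table")
            from .radbio import mix_spectrum

            coeffs = mix_spectrum(run, table)
            rows.append(np.array([getattr(c, quantity) for c in coeffs]))
    mean, sem = mean_and_sem(np.stack(rows), axis=0)
    return AggregatedQuantity(mean, sem, runs.n_runs)


def propagate_survival_sigma(alpha, beta, dose, sigma_alpha, sigma_beta, sigma_dose, survival):
    """First-order uncertainty of LQ survival from (alpha, beta, D) sigmas.

    Vectorized; exact zero when all input sigmas are zero.
    """
    alpha, beta, dose = (np.asarray(x, float) for x in (alpha, beta, dose))
    sa, sb, sd = (np.asarray(x, float) for x in (sigma_alpha, sigma_beta, sigma_dose))
    S = np.asarray(survival, float)
    if np.any(sa < 0) or np.any(sb < 0) or np.any(sd < 0):
        raise DomainError("sigmas must be non-negative")
    if np.any(dose < 0):
        raise DomainError("dose must be non-negative")
    var = dose**2 * sa**2 + dose**4 * sb**2 + (alpha + 2.0 * beta * dose) ** 2 * sd**2
    out = S * np.sqrt(var)
    return float(out) if out.ndim == 0 else out
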