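"""Statistical comparison of fitted MSD exponents across conditions.

Regression confidence intervals are converted to standard errors by the
large-sample convention se = (95% CI half-width)/1.96, and exponent pairs
are compared with a two-sample z-test.  The CI-overlap verdict (the
informal criterion often used alongside) is reported as well.  The
polymer-in-viscoelastic-medium prediction that a chromosomal locus moves
with half the exponent of a free cytoplasmic tracer is tested as
H0: alpha_locus − alpha_particle/2 = 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .msd import PowerLawFit

__all__ = ["ExponentComparison", "diff_exponents", "rouse_ratio_test"]

_Z95 = 1.96  # large-sample 95% normal quantile used to recover se from CIs


@dataclass
class ExponentComparison:
    """Two-sample z-test result for a pair of fitted exponents."""

    alpha_1: float
    alpha_2: float
    se_1: float
    se_2: float
    z_stat: float
    p_value: float
    level: float
    significant: bool
    ci_overlap: bool | None = None
    ratio: float | None = None  # alpha_1/alpha_2 where meaningful
    null: str = "alpha_1 - alpha_2 = 0"


def _se_from_fit(fit: PowerLawFit) -> float:
    return fit.alpha_ci / _Z95


def diff_exponents(
    fit1: PowerLawFit, fit2: PowerLawFit, level: float = 0.95
) -> ExponentComparison:
    """Two-sample z-test for a difference between two fitted exponents.

    ``significant`` is True iff |z| exceeds the two-sided normal quantile
    at ``level``.  A zero-width CI on both fits with equal exponents makes
    z undefined; that case is reported as not significant with a warning.
    """
    se1, se2 = _se_from_fit(fit1), _se_from_fit(fit2)
    diff = fit1.alpha - fit2.alpha
    denom = np.hypot(se1, se2)
    if denom == 0:
        warnings.warn(
            "both fits have zero-width CIs; z undefined, reporting not "
            "significant",
            stacklevel=2,
        )
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
        significant = bool(diff != 0)
        p = np.nan
    else:
        z = diff / denom
        p = 2.0 * stats.norm.sf(abs(z))
        significant = bool(abs(z) > stats.norm.ppf(0.5 + level / 2.0))
    overlap = abs(diff) <= (fit1.alpha_ci + fit2.alpha_ci)
    return ExponentComparison(
        alpha_1=fit1.alpha,
        alpha_2=fit2.alpha,
        se_1=se1,
        se_2=se2,
        z_stat=float(z),
        p_value=float(p),
        level=level,
        significant=significant,
        ci_overlap=bool(overlap),
        ratio=fit1.alpha / fit2.alpha if fit2.alpha != 0 else None,
    )


def rouse_ratio_test(
    particle_fit: PowerLawFit, locus_fit: PowerLawFit, level: float = 0.95
) -> ExponentComparison:
    """Test the half-exponent prediction alpha_locus = alpha_particle/2.

    H0: alpha_locus − alpha_particle/2 = 0 with
    se = sqrt(se_locus² + se_particle²/4).  The ratio
    alpha_particle/alpha_locus (2 under H0) is reported alongside.
    """
    se_p, se_l = _se_from_fit(particle_fit), _se_from_fit(locus_fit)
    diff = locus_fit.alpha - particle_fit.alpha / 2.0
    denom = np.sqrt(se_l**2 + se_p**2 / 4.0)
    if denom == 0:
        warnings.warn(
            "both fits have zero-width CIs; z undefined, reporting not "
            "significant",
            stacklevel=2,
        )
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
        significant = bool(diff != 0)
        p = np.nan
    else:
        z = diff / denom
        p = 2.0 * stats.norm.sf(abs(z))
        significant = bool(abs(z) > stats.norm.ppf(0.5 + level / 2.0))
    return ExponentComparison(
        alpha_1=particle_fit.alpha,
        alpha_2=locus_fit.alpha,
        se_1=se_p,
        se_2=se_l,
        z_stat=float(z),
        p_value=float(p),
        level=level,
        significant=significant,
        ratio=(
            particle_fit.alpha / locus_fit.alpha
            if locus_fit.alpha != 0
            else None
        ),
        null="alpha_locus - alpha_particle/2 = 0",
    )
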