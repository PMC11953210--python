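"""Gaussian prevalence modelling on the T-score scale.

Under the Gaussian population model, the fraction of a population falling
at or below a T-score cutpoint ``c`` is

    P(T <= c) = Phi((c - mean_t) / sd_t)

with Phi the standard normal CDF.  The inverse — the cutpoint at which a
target fraction of the population lies below — is the quantile map
``mean_t + sd_t * Phi^{-1}(p)``.  This is the machinery behind deriving
sex-specific diagnostic thresholds by prevalence matching: choose the male
cutpoint so that the male prevalence equals a stated multiple (e.g. 1x or
0.5x) of the female prevalence at the female cutpoint.

Threshold comparisons are closed (``T <= c``) throughout the package.
"""

from __future__ import annotations

from scipy.stats import norm

from .errors import DomainError, InputError
from .reference_model import PopulationModel


def prevalence_below(cutpoint: float, pop: PopulationModel) -> float:
    """Fraction of the population with T-score <= ``cutpoint``.

    Full-precision value in [0, 1]; rendering as a percentage happens only
    at report boundaries.
    """
    mean_t, sd_t = pop.require_t()
    return float(norm.cdf((cutpoint - mean_t) / sd_t))


def cutpoint_for_prevalence(p: float, pop: PopulationModel) -> float:
    """T-score cutpoint below which a fraction ``p`` of the population lies.

    Inverse of :func:`prevalence_below`: the round trip holds to 1e-9.
    """
    if not (0.0 < p < 1.0):
        raise InputError(f"prevalence must lie in the open interval (0, 1), got {p}")
    mean_t, sd_t = pop.require_t()
    return float(mean_t + sd_t * norm.ppf(p))


def prevalence_matched_cutpoint(
    ref_cut: float,
    ref_pop: PopulationModel,
    target_pop: PopulationModel,
    ratio: float = 1.0,
) -> float:
    """Cutpoint in ``target_pop`` whose prevalence is ``ratio`` times the
    prevalence of ``ref_cut`` in ``ref_pop``.

    ``ratio=1`` matches prevalences exactly; ``ratio=0.5`` encodes e.g. a
    2:1 female:male fracture-incidence ratio.
    """
    if not (ratio > 0):
        raise InputError(f"ratio must be > 0, got {ratio}")
    p = ratio * prevalence_below(ref_cut, ref_pop)
    if not (0.0 < p < 1.0):
        raise DomainError(
            f"scaled prevalence {p} outside (0, 1): ref_cut={ref_cut}, ratio={ratio}"
        )
    return cutpoint_for_prevalence(p, target_pop)
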