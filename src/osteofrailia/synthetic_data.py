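"""Synthetic populations, cohorts, and marginal-constrained fixtures.

The simulator operationalizes the two ingredients behind the observation
that men fracture at higher T-scores than women:

1. **Gaussian populations** — each sex's baseline T-scores are drawn from
   Normal(mean_t, sd_t), with male population means sitting above female
   ones;
2. **a gradient of risk** — fracture probability over the follow-up window
   is a decreasing function of baseline T.  The risk form is a
   complementary-log-log (hazard-style) curve

       risk(T) = 1 − exp(−h · e^{−β·T}),    h = −ln(1 − baseline_risk)

   chosen because under it the T-score distribution *among cases* has a
   closed-form rare-event limit: as the baseline hazard becomes small,
   cases are the population Gaussian exponentially tilted by β, i.e.
   shifted to mean_t − β·sd_t² with unchanged SD.  Two sexes sharing β and
   sd_t therefore show case-mean differences equal to their population-mean
   differences — the parallelism the analyses turn on — and
   :func:`expected_case_mean_shift` provides the exact (numerically
   integrated) case mean as an analytic oracle for the simulator.

All randomness flows through explicit integer seeds; identical spec + seed
reproduces identical output.  The fixture builder is fully deterministic
(quantile placement, no sampling), so fixtures are stable across versions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize
from scipy.stats import norm

from .cohort_analysis import CohortTable
from .errors import DomainError, InputError


@dataclass(frozen=True)
class RiskModel:
    """Log-linear fracture-risk-per-SD specification.

    Parameters
    ----------
    beta : float
        Log relative hazard per one-unit *decrease* in T-score (≥ 0);
        ``exp(beta)`` is the gradient of risk per SD on the reference scale.
    baseline_risk : float
        Probability of fracture over the follow-up window for a subject at
        T-score 0, in (0, 1).
    """

    beta: float
    baseline_risk: float

    def __post_init__(self) -> None:
        if not (self.beta >= 0):
            raise InputError(f"beta must be >= 0, got {self.beta}")
        if not (0.0 < self.baseline_risk < 1.0):
            raise InputError(f"baseline_risk must be in (0, 1), got {self.baseline_risk}")

    @property
    def baseline_hazard(self) -> float:
        return -math.log1p(-self.baseline_risk)

    def risk(self, t):
        """Fracture probability at baseline T-score ``t`` (vectorized).

        Strictly decreasing in ``t`` when beta > 0; approaches 1 as
        ``t → −∞`` and 0 as ``t → +∞``.
        """
        t = np.asarray(t, dtype=float)
        with np.errstate(over="ignore"):
            lam = self.baseline_hazard * np.exp(-self.beta * t)
        out = -np.expm1(-lam)  # lam = inf maps cleanly to risk 1
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class ArmSpec:
    """One sex's population and risk model within a simulation."""

    label: str
    sex: str
    mean_t: float
    sd_t: float
    n: int
    risk_model: RiskModel

    def __post_init__(self) -> None:
        if self.sex not in {"F", "M"}:
            raise InputError(f"sex must be 'F' or 'M', got {self.sex!r}")
        if not (self.n >= 1):
            raise InputError(f"n must be >= 1, got {self.n}")
        if not (self.sd_t > 0):
            raise InputError(f"sd_t must be > 0, got {self.sd_t}")
        if not math.isfinite(self.mean_t):
            raise InputError(f"mean_t must be finite, got {self.mean_t}")


@dataclass(frozen=True)
class SimulationSpec:
    """A reproducible multi-arm cohort simulation: arms + one integer seed."""

    arms: tuple[ArmSpec, ...]
    seed: int

    def __post_init__(self) -> None:
        if not self.arms:
            raise InputError("spec needs at least one arm")
        if not isinstance(self.seed, (int, np.integer)):
            raise InputError(f"seed must be an integer, got {type(self.seed).__name__}")


def simulate_population(arm: ArmSpec, seed: int) -> np.ndarray:
    """``arm.n`` baseline T-scores drawn from Normal(mean_t, sd_t)."""
    rng = np.random.default_rng(seed)
    return rng.normal(arm.mean_t, arm.sd_t, size=arm.n)


def simulate_cohort(spec: SimulationSpec) -> CohortTable:
    """Simulate a follow-up cohort: draw each arm's baseline T-scores, then
    each subject's fracture indicator independently with probability
    ``risk_model.risk(T)``."""
    rng = np.random.default_rng(spec.seed)
    frames = []
    for arm in spec.arms:
        t = rng.normal(arm.mean_t, arm.sd_t, size=arm.n)
        fx = rng.random(arm.n) < arm.risk_model.risk(t)
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"{arm.label}-{i:06d}" for i in range(arm.n)],
                    "sex": arm.sex,
                    "baseline_t": t,
                    "fracture": fx,
                }
            )
        )
    return CohortTable(pd.concat(frames, ignore_index=True))


def simulate_paired_tscores(
    n: int,
    correlation: float,
    mean_x: float = -1.5,
    sd_x: float = 1.0,
    mean_y: float = -1.2,
    sd_y: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """``n`` draws from a bivariate Gaussian with the given marginals and
    Pearson correlation — e.g. paired femoral-neck / total-hip T-scores.

    The population regression line of y on x has slope
    ``correlation * sd_y / sd_x``.
    """
    if not (-1.0 < correlation < 1.0):
        raise InputError(f"correlation must be in (-1, 1), got {correlation}")
    if n < 2:
        raise InputError(f"need n >= 2 pairs, got {n}")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    x = mean_x + sd_x * z1
    y = mean_y + sd_y * (correlation * z1 + math.sqrt(1.0 - correlation**2) * z2)
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# analytic oracle


def expected_incidence(mean_t: float, sd_t: float, model: RiskModel) -> float:
    """Population fracture incidence E[risk(T)], T ~ Normal(mean_t, sd_t)."""
    lo, hi = mean_t - 15.0 * sd_t, mean_t + 15.0 * sd_t
    val, err = integrate.quad(
        lambda t: model.risk(t) * norm.pdf(t, mean_t, sd_t), lo, hi, limit=200
    )
    if not np.isfinite(val) or err > max(1e-6 * val, 1e-9):
        raise DomainError(
            f"incidence integral did not converge (value={val}, abserr={err})"
        )
    return float(val)


def expected_case_mean_shift(mean_t: float, sd_t: float, model: RiskModel) -> float:
    """Mean baseline T-score among fracture cases, E[T·risk(T)] / E[risk(T)].

    Computed by adaptive quadrature over the Gaussian density.  In the
    rare-event limit (small hazard over the bulk of the case distribution)
    this approaches the exponential-tilting value ``mean_t − beta·sd_t²``;
    for baseline risk ≤ 0.01 and the low-T population regimes used in these
    analyses the agreement is within 1% of the case mean.
    """
    if not (sd_t > 0):
        raise InputError(f"sd_t must be > 0, got {sd_t}")
    lo, hi = mean_t - 15.0 * sd_t, mean_t + 15.0 * sd_t
    den = expected_incidence(mean_t, sd_t, model)
    if den <= 0:
        raise DomainError("population incidence is zero; case mean undefined")
    num, err = integrate.quad(
        lambda t: t * model.risk(t) * norm.pdf(t, mean_t, sd_t), lo, hi, limit=200
    )
    if not np.isfinite(num) or err > max(1e-6 * abs(num), 1e-9):
        raise DomainError(
            f"case-mean integral did not converge (value={num}, abserr={err})"
        )
    return float(num / den)


def calibrate_baseline_risk(
    mean_t: float, sd_t: float, beta: float, target_incidence: float
) -> float:
    """Baseline risk at T = 0 such that the population incidence
    E[risk(T)] equals ``target_incidence`` (to 1e-6), by monotone
    root-finding: incidence is strictly increasing in baseline risk."""
    if not (0.0 < target_incidence < 1.0):
        raise InputError(f"target_incidence must be in (0, 1), got {target_incidence}")

    def gap(p0: float) -> float:
        return expected_incidence(mean_t, sd_t, RiskModel(beta, p0)) - target_incidence

    lo, hi = 1e-12, 1.0 - 1e-12
    if gap(lo) > 0 or gap(hi) < 0:
        raise DomainError(
            f"no baseline risk in (0,1) yields incidence {target_incidence} "
            f"for beta={beta}, population N({mean_t}, {sd_t}²)"
        )
    p0 = optimize.brentq(gap, lo, hi, xtol=1e-14, rtol=8.9e-16)
    return float(p0)


# ---------------------------------------------------------------------------
# marginal-constrained fixtures


def _fit_probit_params(
    thresholds: Sequence[float], counts: Sequence[int], total: int
) -> tuple[float, float]:
    """Normal (mu, sigma) matching the empirical fractions below each
    threshold on the probit scale; used when no moment targets are given."""
    ts, zs = [], []
    for t, c in zip(thresholds, counts):
        p = c / total
        if 0.0 < p < 1.0:
            ts.append(t)
            zs.append(norm.ppf(p))
    if len(ts) >= 2:
        z = np.asarray(zs)
        t = np.asarray(ts)
        var = float(np.var(z))
        if var > 0:
            sigma = float(np.cov(z, t, bias=True)[0, 1] / var)
            if sigma > 0:
                return float(np.mean(t) - sigma * np.mean(z)), sigma
    if len(ts) >= 1:
        return float(ts[0] - zs[0]), 1.0
    return 0.0, 1.0


def _place_in_bins(
    edges: Sequence[float], bin_counts: Sequence[int], mu: float, sigma: float
) -> np.ndarray:
    """Deterministic quantile placement: for each bin (open-ended at the
    extremes), place its count at equally spaced quantiles of
    Normal(mu, sigma) truncated to the bin.  Values are strictly interior
    to their bin, so '≤ threshold' counts are exact by construction."""
    bounds = [-np.inf, *edges, np.inf]
    values: list[np.ndarray] = []
    for i, c in enumerate(bin_counts):
        if c == 0:
            continue
        lo, hi = bounds[i], bounds[i + 1]
        p_lo, p_hi = norm.cdf(lo, mu, sigma), norm.cdf(hi, mu, sigma)
        if p_hi - p_lo > 1e-12:
            levels = p_lo + (np.arange(c) + 0.5) / c * (p_hi - p_lo)
            v = norm.ppf(levels, mu, sigma)
        else:
            # bin carries essentially no mass under the placement normal:
            # fall back to an even spread just inside the bin
            left = lo if np.isfinite(lo) else hi - 1.0
            right = hi if np.isfinite(hi) else lo + 1.0
            width = right - left
            v = left + (np.arange(c) + 0.5) / c * width
        values.append(np.asarray(v))
    return np.concatenate(values) if values else np.empty(0)


def _place_group(
    edges: list[float],
    counts_below: Mapping[float, int],
    total: int,
    mean: float | None,
    sd: float | None,
    what: str,
) -> np.ndarray:
    """Values for one stratum honouring its below-threshold counts exactly
    and, when given, its mean/SD targets (0.02 / 0.05 tolerance)."""
    cum = [counts_below[e] for e in edges]
    bin_counts = np.diff([0, *cum, total]).tolist()
    if any(c < 0 for c in bin_counts):
        raise InputError(f"{what}: counts below thresholds must be non-decreasing")

    if mean is None and sd is None:
        mu, sigma = _fit_probit_params(edges, cum, total)
        return _place_in_bins(edges, bin_counts, mu, sigma)

    if mean is None or sd is None:
        raise InputError(f"{what}: mean and sd targets must be given together")
    if total < 2:
        raise InputError(f"{what}: moment targets need at least 2 subjects")

    def resid(params: np.ndarray) -> np.ndarray:
        mu, log_sigma = params
        v = _place_in_bins(edges, bin_counts, mu, math.exp(log_sigma))
        return np.array([v.mean() - mean, v.std(ddof=1) - sd])

    sol = optimize.least_squares(
        resid, x0=np.array([mean, math.log(max(sd, 1e-3))]), xtol=1e-14, ftol=1e-14
    )
    v = _place_in_bins(edges, bin_counts, sol.x[0], math.exp(sol.x[1]))
    err_mean = abs(v.mean() - mean)
    err_sd = abs(v.std(ddof=1) - sd)
    if err_mean > 0.02 or err_sd > 0.05:
        raise DomainError(
            f"{what}: moment targets unreachable under the count constraints "
            f"(|Δmean|={err_mean:.4f} > 0.02 or |Δsd|={err_sd:.4f} > 0.05)"
        )
    return v


def fixture_cohort_from_marginals(
    n: int,
    cases: int,
    case_counts_below: Mapping[float, int],
    population_counts_below: Mapping[float, int] | None = None,
    case_mean: float | None = None,
    case_sd: float | None = None,
    noncase_mean: float | None = None,
    noncase_sd: float | None = None,
    sex: str = "M",
    id_prefix: str | None = None,
) -> CohortTable:
    """Deterministic cohort exactly reproducing printed count marginals.

    Parameters
    ----------
    n, cases : int
        Cohort size and number of fracture cases.
    case_counts_below : mapping threshold → count
        Exact number of *cases* with baseline T ≤ threshold.
    population_counts_below : mapping threshold → count, optional
        Exact number of *all subjects* with baseline T ≤ threshold; every
        threshold here must also appear in ``case_counts_below`` so the
        non-case count can be derived.
    case_mean, case_sd, noncase_mean, noncase_sd : float, optional
        Moment targets per stratum, matched by constrained quantile
        placement to within 0.02 (mean) / 0.05 (SD).

    The construction is deterministic — identical marginals give an
    identical table — and every supplied count is reproduced exactly
    (ties are impossible: values are placed strictly inside their bins).
    """
    if not (0 <= cases <= n):
        raise InputError(f"need 0 <= cases <= n, got cases={cases}, n={n}")
    if cases == 0:
        raise InputError("fixture needs at least one fracture case")

    case_edges = sorted(case_counts_below)
    for t in case_edges:
        c = case_counts_below[t]
        if not (0 <= c <= cases):
            raise InputError(
                f"case count below {t} is {c}, outside [0, cases={cases}]"
            )
    case_cum = [case_counts_below[t] for t in case_edges]
    if any(b < a for a, b in zip(case_cum, case_cum[1:])):
        raise InputError("case counts below thresholds must be non-decreasing")

    noncase_counts: dict[float, int] = {}
    if population_counts_below:
        for t in sorted(population_counts_below):
            if t not in case_counts_below:
                raise InputError(
                    f"population count at threshold {t} has no matching case count; "
                    "cannot split it into case / non-case strata"
                )
            pc = population_counts_below[t]
            cc = case_counts_below[t]
            if pc < cc:
                raise InputError(
                    f"population count below {t} ({pc}) is smaller than the case "
                    f"count below it ({cc})"
                )
            if pc > n:
                raise InputError(f"population count below {t} ({pc}) exceeds n={n}")
            noncase_counts[t] = pc - cc
    nc_cum = [noncase_counts[t] for t in sorted(noncase_counts)]
    if any(b < a for a, b in zip(nc_cum, nc_cum[1:])):
        raise InputError(
            "implied non-case counts below thresholds are decreasing; "
            "population and case marginals are mutually inconsistent"
        )

    case_t = _place_group(case_edges, case_counts_below, cases,
                          case_mean, case_sd, "cases")
    nc_edges = sorted(noncase_counts)
    noncase_t = _place_group(nc_edges, noncase_counts, n - cases,
                             noncase_mean, noncase_sd, "non-cases")

    prefix = id_prefix if id_prefix is not None else sex
    df = pd.DataFrame(
        {
            "subject_id": [f"{prefix}-case-{i:05d}" for i in range(cases)]
            + [f"{prefix}-ctrl-{i:05d}" for i in range(n - cases)],
            "sex": sex,
            "baseline_t": np.concatenate([np.sort(case_t), np.sort(noncase_t)]),
            "fracture": [True] * cases + [False] * (n - cases),
        }
    )
    cohort = CohortTable(df)

    # construction sanity: every supplied count must be reproduced exactly
    for t, c in case_counts_below.items():
        got = int((df.loc[df["fracture"], "baseline_t"] <= t).sum())
        if got != c:
            raise AssertionError(f"internal error: case count at {t}: {got} != {c}")
    for t, pc in (population_counts_below or {}).items():
        got = int((df["baseline_t"] <= t).sum())
        if got != pc:
            raise AssertionError(f"internal error: population count at {t}: {got} != {pc}")
    return cohort


# ---------------------------------------------------------------------------
# shipped fixture cohorts (MrOS / MsOS Hong Kong printed marginals)

#: printed marginals of the two Hong Kong prospective cohorts: 2000 subjects
#: per sex; 63 male / 69 female hip fractures over follow-up; case counts at
#: the revised Chinese osteoporosis (−2.7) and male osteofrailia (−2.1)
#: thresholds; whole-cohort counts at the same thresholds; and the fracture
#: groups' baseline T-score moments.
HK_COHORT_MARGINALS: dict[str, dict] = {
    "M": dict(
        n=2000,
        cases=63,
        case_counts_below={-2.7: 10, -2.1: 29},
        population_counts_below={-2.7: 67, -2.1: 310},
        case_mean=-1.97,
        case_sd=0.72,
        sex="M",
    ),
    "F": dict(
        n=2000,
        cases=69,
        case_counts_below={-2.7: 31},
        population_counts_below={-2.7: 338},
        case_mean=-2.59,
        case_sd=1.00,
        sex="F",
    ),
}


def hk_fixture_cohorts() -> dict[str, CohortTable]:
    """The two marginal-constrained Hong Kong cohort fixtures (men, women).

    Count marginals are reproduced exactly; the fracture groups' moments to
    the placement tolerance.  Subject-level values are synthetic — the
    underlying studies published only the marginals encoded in
    :data:`HK_COHORT_MARGINALS`.
    """
    return {sex: fixture_cohort_from_marginals(**kw)
            for sex, kw in HK_COHORT_MARGINALS.items()}
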