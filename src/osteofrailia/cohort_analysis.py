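"""Subject-level threshold analysis of fracture cohorts.

Given a cohort of subjects with baseline femoral-neck T-scores and a
fracture indicator over follow-up, a candidate diagnostic threshold ``c``
partitions the cohort into a 2×2 table (fracture × baseline T ≤ c).  From
it come the two fractions the screening argument turns on:

* **sensitivity** — the fraction of fracture cases captured, i.e. cases
  with baseline T ≤ c (ties at the threshold count as captured);
* **cohort prevalence** — the fraction of *all* subjects with baseline
  T ≤ c, the size of the flagged group.

Crude fractions only: no time-to-event modelling, no age adjustment.
Percentages are displayed to one decimal (half away from zero); the
underlying fractions are kept at full precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConflictError, EmptySelectionError, InputError, ParseError
from .reference_model import Registry, round_half_away, tscore


@dataclass(frozen=True)
class CohortTable:
    """Subject-level cohort: one row per subject.

    ``data`` columns: ``subject_id`` (unique), ``sex`` ("F"/"M"),
    ``baseline_t`` (T-score, no missing values), ``fracture`` (bool),
    and optional ``followup_years``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        required = {"subject_id", "sex", "baseline_t", "fracture"}
        missing = required - set(df.columns)
        if missing:
            raise InputError(f"cohort missing columns {sorted(missing)}")
        if df["subject_id"].duplicated().any():
            dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()[:5]
            raise ConflictError(f"duplicate subject_id values (first few: {dupes})")
        if df["baseline_t"].isna().any():
            n_bad = int(df["baseline_t"].isna().sum())
            raise InputError(
                f"{n_bad} subjects have missing baseline_t; subjects without a "
                "baseline measurement must be excluded upstream, not silently dropped"
            )
        bad_sex = set(df["sex"].unique()) - {"F", "M"}
        if bad_sex:
            raise InputError(f"sex must be 'F' or 'M', found {sorted(bad_sex)}")
        if df["fracture"].dtype != bool:
            vals = set(df["fracture"].unique())
            if not vals <= {0, 1, True, False}:
                raise InputError(f"fracture must be boolean/0-1, found {sorted(vals)}")
            object.__setattr__(self, "data", df.assign(fracture=df["fracture"].astype(bool)))

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_cases(self) -> int:
        return int(self.data["fracture"].sum())


def load_cohort(path: str | Path, registry: Registry | None = None) -> CohortTable:
    """Read a delimited cohort table, converting BMD-based tables to T-scores.

    Header columns: ``subject_id``, ``sex``, and exactly one of
    ``baseline_t`` or (``baseline_bmd`` + ``reference``); plus ``fracture``
    and optional ``followup_years``.  A BMD-based table names, per row, a
    reference id that must exist in ``registry``; conversion happens at load
    so that all downstream analysis is on the T-score scale.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from exc

    has_t = "baseline_t" in df.columns
    has_bmd = "baseline_bmd" in df.columns
    if has_t and has_bmd:
        raise ParseError(
            f"{path}: carries both baseline_t and baseline_bmd; a table must use "
            "exactly one parameterization"
        )
    if not has_t and not has_bmd:
        raise ParseError(f"{path}: needs baseline_t or baseline_bmd + reference")

    if has_bmd:
        if "reference" not in df.columns:
            raise ParseError(f"{path}: BMD-based table requires a 'reference' column")
        if registry is None:
            raise InputError("BMD-based cohort requires a registry for conversion")
        t = np.empty(len(df))
        for i, (bmd, ref_id) in enumerate(zip(df["baseline_bmd"], df["reference"])):
            t[i] = tscore(float(bmd), registry.reference(str(ref_id)))
        df = df.drop(columns=["baseline_bmd", "reference"]).assign(baseline_t=t)

    try:
        return CohortTable(df)
    except (InputError, ConflictError) as exc:
        raise type(exc)(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# threshold statistics


@dataclass(frozen=True)
class ThresholdFraction:
    """A captured/total count pair with its full-precision fraction."""

    numerator: int
    denominator: int

    @property
    def fraction(self) -> float:
        return self.numerator / self.denominator

    @property
    def percent(self) -> float:
        """Display percentage, one decimal, half away from zero."""
        return round_half_away(100.0 * self.fraction, 1)

    def __str__(self) -> str:
        return f"{self.percent}% ({self.numerator}/{self.denominator})"


def sensitivity_at_threshold(cohort: CohortTable, threshold: float) -> ThresholdFraction:
    """Fraction of fracture cases with baseline T ≤ threshold."""
    cases = cohort.data.loc[cohort.data["fracture"], "baseline_t"]
    if len(cases) == 0:
        raise EmptySelectionError("cohort has no fracture cases")
    captured = int((cases <= threshold).sum())
    return ThresholdFraction(captured, len(cases))


def cohort_prevalence(cohort: CohortTable, threshold: float) -> ThresholdFraction:
    """Fraction of all subjects with baseline T ≤ threshold."""
    if len(cohort) == 0:
        raise EmptySelectionError("cohort is empty")
    below = int((cohort.data["baseline_t"] <= threshold).sum())
    return ThresholdFraction(below, len(cohort))


@dataclass(frozen=True)
class ClassificationTable:
    """2×2 counts: fracture status × (baseline T ≤ threshold)."""

    case_below: int
    case_above: int
    noncase_below: int
    noncase_above: int

    @property
    def total(self) -> int:
        return self.case_below + self.case_above + self.noncase_below + self.noncase_above

    @property
    def cases(self) -> int:
        return self.case_below + self.case_above

    @property
    def below(self) -> int:
        return self.case_below + self.noncase_below

    def sensitivity(self) -> ThresholdFraction:
        return ThresholdFraction(self.case_below, self.cases)

    def prevalence(self) -> ThresholdFraction:
        return ThresholdFraction(self.below, self.total)


def classification_table(cohort: CohortTable, threshold: float) -> ClassificationTable:
    """Partition the cohort into the 2×2 fracture × below-threshold table.

    Margins reconcile exactly with :func:`sensitivity_at_threshold` and
    :func:`cohort_prevalence`.
    """
    if len(cohort) == 0:
        raise EmptySelectionError("cohort is empty")
    frac = cohort.data["fracture"].to_numpy()
    below = (cohort.data["baseline_t"] <= threshold).to_numpy()
    return ClassificationTable(
        case_below=int((frac & below).sum()),
        case_above=int((frac & ~below).sum()),
        noncase_below=int((~frac & below).sum()),
        noncase_above=int((~frac & ~below).sum()),
    )


def group_baseline_stats(cohort: CohortTable, by: tuple[str, ...] | str = ("sex", "fracture")) -> pd.DataFrame:
    """Per-group mean, sample SD (n−1), and n of baseline T-score.

    ``by`` names one or more of ``sex`` / ``fracture``.  Single-subject
    groups get ``sd = NaN`` (undefined, flagged not erroneous); an empty
    requested grouping raises.
    """
    if isinstance(by, str):
        by = tuple(k.strip() for k in by.split(","))
    bad = set(by) - {"sex", "fracture"}
    if bad:
        raise InputError(f"can only group by sex/fracture, got {sorted(bad)}")
    if len(cohort) == 0:
        raise EmptySelectionError("cohort is empty")
    grouped = cohort.data.groupby(list(by), observed=True)["baseline_t"]
    out = grouped.agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count").reset_index()
    return out
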