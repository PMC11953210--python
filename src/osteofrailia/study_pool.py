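"""Pooling of study-level fracture T-score / BMD summaries and sex offsets.

Published hip-fracture series report the mean femoral-neck (FN) or total-hip
(TH) T-score of their cases; the pooled mean across studies, with every
study given equal weight (no sample-size weighting), summarizes where
fracture cases sit on the T-score scale, and the male-minus-female pooled
difference is the *sex offset* used to translate a female diagnostic
cutpoint into a risk-equivalent male one.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import EmptySelectionError, InputError, ParseError
from .reference_model import ReferenceDatabase

VALID_REGIONS = frozenset({"EA", "EU", "other"})
VALID_SEX_GROUPS = frozenset({"F", "M", "mixed"})


@dataclass(frozen=True)
class StudyRecord:
    """One published study group's summary statistics.

    At least one of ``mean_t`` (T-score units) / ``mean_bmd`` (g/cm²) must
    be present; ``sd_t`` and ``n`` are optional but must be positive when
    given.  ``region`` is EA (East Asia), EU (Europe), or ``other``;
    ``sex_group`` is F, M, or ``mixed`` for series that pooled the sexes.
    """

    study_id: str
    region: str
    sex_group: str
    site: str
    mean_t: float | None = None
    sd_t: float | None = None
    mean_bmd: float | None = None
    n: int | None = None
    age_mean: float | None = None

    def __post_init__(self) -> None:
        if self.region not in VALID_REGIONS:
            raise InputError(
                f"study {self.study_id!r}: region must be one of "
                f"{sorted(VALID_REGIONS)}, got {self.region!r}"
            )
        if self.sex_group not in VALID_SEX_GROUPS:
            raise InputError(
                f"study {self.study_id!r}: sex_group must be one of "
                f"{sorted(VALID_SEX_GROUPS)}, got {self.sex_group!r}"
            )
        if self.site not in {"FN", "TH", "LS"}:
            raise InputError(
                f"study {self.study_id!r}: site must be FN, TH or LS, got {self.site!r}"
            )
        if self.mean_t is None and self.mean_bmd is None:
            raise InputError(
                f"study {self.study_id!r}: at least one of mean_t / mean_bmd required"
            )
        if self.sd_t is not None and not (self.sd_t > 0):
            raise InputError(f"study {self.study_id!r}: sd_t must be > 0, got {self.sd_t}")
        if self.n is not None and not (self.n > 0):
            raise InputError(f"study {self.study_id!r}: n must be > 0, got {self.n}")


def load_study_table(path: str | Path) -> list[StudyRecord]:
    """Read a comma-delimited study table (UTF-8, header row) into records.

    Recognized columns: study_id, region, sex_group, site, mean_t, sd_t,
    mean_bmd, n, age_mean.  Unknown columns are preserved in the file but
    ignored here; missing values are empty fields.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    required = {"study_id", "region", "sex_group", "site"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing required columns {sorted(missing)}")

    records: list[StudyRecord] = []
    for i, row in df.iterrows():
        def opt(col: str, cast=float):
            if col not in df.columns or pd.isna(row[col]):
                return None
            return cast(row[col])

        try:
            records.append(
                StudyRecord(
                    study_id=str(row["study_id"]),
                    region=str(row["region"]),
                    sex_group=str(row["sex_group"]),
                    site=str(row["site"]),
                    mean_t=opt("mean_t"),
                    sd_t=opt("sd_t"),
                    mean_bmd=opt("mean_bmd"),
                    n=opt("n", int),
                    age_mean=opt("age_mean"),
                )
            )
        except InputError as exc:
            raise ParseError(f"{path}: row {i + 2}: {exc}") from exc
    return records


def _filter(
    records: Iterable[StudyRecord],
    site: str | None,
    sex_group: str | None,
    region: str | None,
) -> list[StudyRecord]:
    out = [
        r
        for r in records
        if (site is None or r.site == site)
        and (sex_group is None or r.sex_group == sex_group)
        and (region is None or r.region == region)
    ]
    return out


def pooled_mean(
    records: Sequence[StudyRecord],
    site: str | None = None,
    sex_group: str | None = None,
    region: str | None = None,
    weighting: str = "equal",
    value: str = "t",
) -> float:
    """Pooled mean of the filtered studies' group means.

    ``weighting="equal"`` gives each study equal weight (the convention for
    these cross-study comparisons: sample sizes are *not* weighted);
    ``"by_n"`` weights by sample size and requires ``n`` on every surviving
    record.  ``value`` selects the pooled quantity: ``"t"`` (T-score) or
    ``"bmd"`` (g/cm²); every surviving record must carry it.
    """
    if weighting not in {"equal", "by_n"}:
        raise InputError(f"weighting must be 'equal' or 'by_n', got {weighting!r}")
    if value not in {"t", "bmd"}:
        raise InputError(f"value must be 't' or 'bmd', got {value!r}")
    sel = _filter(records, site, sex_group, region)
    if not sel:
        raise EmptySelectionError(
            f"no studies match site={site!r}, sex_group={sex_group!r}, region={region!r}"
        )
    attr = "mean_t" if value == "t" else "mean_bmd"
    means = [getattr(r, attr) for r in sel]
    if any(m is None for m in means):
        bad = [r.study_id for r, m in zip(sel, means) if m is None]
        raise InputError(f"studies {bad} lack {attr}, cannot pool on that scale")
    if weighting == "equal":
        return float(sum(means) / len(means))
    if any(r.n is None for r in sel):
        bad = [r.study_id for r in sel if r.n is None]
        raise InputError(f"by_n weighting requires n on every study; missing for {bad}")
    total = sum(r.n for r in sel)
    return float(sum(m * r.n for m, r in zip(means, sel)) / total)


def sex_offset(
    records: Sequence[StudyRecord],
    site: str | None = None,
    region: str | None = None,
    weighting: str = "equal",
    value: str = "t",
) -> float:
    """Male-minus-female difference of pooled means (positive when men
    fracture at higher T-scores).  Mixed-sex records are excluded — their
    sex composition is unknown."""
    m = pooled_mean(records, site=site, sex_group="M", region=region,
                    weighting=weighting, value=value)
    f = pooled_mean(records, site=site, sex_group="F", region=region,
                    weighting=weighting, value=value)
    return m - f


def bmd_delta_to_tscore_delta(delta_bmd: float, ref: ReferenceDatabase) -> float:
    """Convert a BMD difference (g/cm²) to T-score units under a reference
    (e.g. a 0.1 g/cm² FN difference is 0.1/0.137 ≈ 0.73 T-score units under
    the NHANES III male reference)."""
    if not isinstance(ref, ReferenceDatabase):
        raise InputError(f"ref must be a ReferenceDatabase, got {type(ref).__name__}")
    return delta_bmd / ref.young_sd_bmd
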