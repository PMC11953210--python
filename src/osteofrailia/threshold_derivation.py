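"""Derivation of proposed diagnostic thresholds.

Three routes are implemented:

* **risk-equivalent cutpoint** — shift a reference (female) cutpoint by the
  observed male-minus-female fracture T-score offset, so that a man at the
  shifted cutpoint has approximately the fracture risk of a woman at the
  reference cutpoint;
* **site mapping** — a linear FN→TH (or other paired-site) map, either
  supplied as slope/intercept or fitted by ordinary least squares to paired
  T-scores, used to translate a femoral-neck threshold to another site;
* **the composite report** — per ethnicity, the female osteoporosis
  cutpoint, the male risk-equivalent cutpoint (raw and display-rounded),
  the adopted male threshold, and the Gaussian prevalence of each under the
  configured older-population models, with the male/female prevalence-ratio
  check.

Proposed thresholds are rounded to one decimal, half away from zero, only
at the reporting layer; raw values are always carried and emitted as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml
from scipy import stats

from .errors import ConfigurationError, DegenerateDataError, InputError, ParseError
from .population_prevalence import prevalence_below
from .reference_model import Registry, round_half_away


def risk_equivalent_cutpoint(
    ref_cut: float, offset: float, decimals: int | None = None
) -> float:
    """Reference cutpoint shifted by a sex offset, optionally display-rounded.

    ``decimals=None`` returns the raw value; an integer rounds half away
    from zero to that many decimals (e.g. −2.5 + 0.59 = −1.91 → −1.9).
    """
    if not math.isfinite(ref_cut):
        raise InputError(f"ref_cut must be finite, got {ref_cut}")
    if not math.isfinite(offset):
        raise InputError(f"offset must be finite, got {offset}")
    value = ref_cut + offset
    if decimals is None:
        return value
    return round_half_away(value, decimals)


@dataclass(frozen=True)
class SiteMapping:
    """Linear map between two sites' T-scores: target = intercept + slope·source."""

    slope: float
    intercept: float
    correlation: float | None = None
    slope_se: float | None = None
    intercept_se: float | None = None

    def __post_init__(self) -> None:
        if not (self.slope > 0):
            raise InputError(f"slope must be > 0, got {self.slope}")

    def inverse(self) -> "SiteMapping":
        return SiteMapping(slope=1.0 / self.slope, intercept=-self.intercept / self.slope,
                           correlation=self.correlation)


def site_map_threshold(fn_cut: float, mapping: SiteMapping) -> float:
    """Translate a femoral-neck threshold through a linear site mapping."""
    return mapping.intercept + mapping.slope * fn_cut


def fit_site_mapping(pairs: Sequence[tuple[float, float]]) -> SiteMapping:
    """Ordinary least-squares line of the second site on the first, with the
    Pearson correlation and parameter standard errors.

    Requires at least 3 pairs and non-degenerate variance in the predictor.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise InputError(f"pairs must be a sequence of (source_t, target_t), got shape {arr.shape}")
    if arr.shape[0] < 3:
        raise InputError(f"need at least 3 pairs, got {arr.shape[0]}")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("paired T-scores carry no variance; cannot fit a line")
    res = stats.linregress(x, y)
    return SiteMapping(
        slope=float(res.slope),
        intercept=float(res.intercept),
        correlation=float(res.rvalue),
        slope_se=float(res.stderr),
        intercept_se=float(res.intercept_stderr),
    )


# ---------------------------------------------------------------------------
# composite report


@dataclass(frozen=True)
class ThresholdRow:
    """One sex-pair's derived thresholds and model prevalences."""

    ethnicity: str
    site: str
    female_cutpoint: float
    female_prevalence: float
    male_raw_cutpoint: float
    male_rounded_cutpoint: float
    male_adopted_cutpoint: float
    male_prevalence: float
    prevalence_ratio: float  # male / female at the adopted cutpoints
    sex_offset: float


@dataclass(frozen=True)
class SiteThreshold:
    """A configured single-site threshold constant with a status flag."""

    site: str
    cutpoint: float
    status: str  # "adopted" | "tentative" | "working"
    note: str = ""


@dataclass(frozen=True)
class OsteofrailiaReport:
    rows: tuple[ThresholdRow, ...]
    site_thresholds: tuple[SiteThreshold, ...]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame([vars(r) for r in self.rows])


def load_threshold_config(path: str | Path) -> dict:
    """Load the threshold-derivation config (YAML mapping)."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict) or "groups" not in raw:
        raise ParseError(f"{path}: expected a mapping with a 'groups' list")
    return raw


def derive_osteofrailia_report(config: dict, registry: Registry) -> OsteofrailiaReport:
    """Derive, per configured ethnicity group, the female cutpoint, the male
    risk-equivalent cutpoint (raw, rounded, adopted) and the Gaussian
    prevalence of each under the registry's population models.

    Config structure (see the shipped ``osteofrailia_config.yaml``)::

        groups:
          - ethnicity: US-Caucasian
            site: FN
            female_population: us_older_f
            male_population: us_older_m
            female_cutpoint: -2.5
            sex_offset: 0.59
            adopted_male_cutpoint: -2.0   # optional; default: rounded raw
        site_thresholds:
          - {site: TH, cutpoint: -1.7, status: adopted, note: ...}

    The adopted male cutpoint may be a configured constant (e.g. thresholds
    taken from a separate reference-population argument rather than from
    offset arithmetic); when omitted it defaults to the one-decimal rounded
    risk-equivalent value.
    """
    groups = config.get("groups") or []
    if not groups:
        raise ConfigurationError("config contains no groups")
    decimals = int(config.get("rounding_decimals", 1))

    rows = []
    for g in groups:
        for key in ("ethnicity", "female_population", "male_population",
                    "female_cutpoint", "sex_offset"):
            if key not in g:
                raise ConfigurationError(f"group {g.get('ethnicity', '?')!r} missing {key!r}")
        f_pop = registry.population(g["female_population"])
        m_pop = registry.population(g["male_population"])
        f_cut = float(g["female_cutpoint"])
        offset = float(g["sex_offset"])
        raw = risk_equivalent_cutpoint(f_cut, offset)
        rounded = round_half_away(raw, decimals)
        adopted = float(g.get("adopted_male_cutpoint", rounded))
        f_prev = prevalence_below(f_cut, f_pop)
        m_prev = prevalence_below(adopted, m_pop)
        rows.append(
            ThresholdRow(
                ethnicity=str(g["ethnicity"]),
                site=str(g.get("site", "FN")),
                female_cutpoint=f_cut,
                female_prevalence=f_prev,
                male_raw_cutpoint=raw,
                male_rounded_cutpoint=rounded,
                male_adopted_cutpoint=adopted,
                male_prevalence=m_prev,
                prevalence_ratio=m_prev / f_prev,
                sex_offset=offset,
            )
        )

    site_rows = tuple(
        SiteThreshold(
            site=str(s["site"]),
            cutpoint=float(s["cutpoint"]),
            status=str(s.get("status", "adopted")),
            note=str(s.get("note", "")),
        )
        for s in (config.get("site_thresholds") or [])
    )
    return OsteofrailiaReport(rows=tuple(rows), site_thresholds=site_rows)


def default_threshold_config() -> dict:
    """The shipped default configuration."""
    from importlib.resources import files

    return load_threshold_config(
        Path(str(files("osteofrailia") / "data" / "osteofrailia_config.yaml"))
    )
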