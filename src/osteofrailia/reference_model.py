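"""Reference databases and T-score / Z-score arithmetic.

A DXA T-score expresses a patient's areal bone mineral density (BMD,
g/cm²) as the number of young-adult standard deviations below the
young-adult mean of a sex- and site-specific reference database:

    T = (BMD_patient − BMD_young_mean) / SD_young

A Z-score is the analogous quantity against the age-matched older
population rather than the young-adult reference.  Because an older
population's BMD spread generally differs from the young-adult spread,
its distribution on the T-score scale is Gaussian with an SD equal to
the ratio of the two BMD SDs — the linear map from BMD to T preserves
shape and rescales spread.

The module houses two value types — :class:`ReferenceDatabase` (the
young-adult normative pair that defines a T-score scale) and
:class:`PopulationModel` (a Gaussian description of an older
population tied to such a reference) — a YAML registry loader, and the
scalar conversions built on them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

from .errors import ConfigurationError, ConflictError, DomainError, InputError, ParseError

VALID_SITES = frozenset({"FN", "TH", "LS"})
VALID_SEXES = frozenset({"F", "M"})

#: tolerance for agreement between a dual (BMD and T) parameterization
DUAL_PARAM_TOL = 1e-9


@dataclass(frozen=True)
class ReferenceDatabase:
    """Young-adult normative parameters defining one T-score scale.

    Parameters
    ----------
    id : str
        Short unique label, e.g. ``"nhanes3_fn_m"``.
    site : {"FN", "TH", "LS"}
        Femoral neck, total hip, or lumbar spine.
    sex : {"F", "M"}
    ethnicity : str
        Free label (e.g. ``"US-Caucasian"``); reference-database choice is
        itself contested in the field, so no enum is imposed.
    device_family : str
        Free label (e.g. ``"Hologic"``); BMD in g/cm² is not comparable
        across manufacturers.
    young_mean_bmd, young_sd_bmd : float
        Young-adult mean and SD of areal BMD, g/cm²; both must be > 0.
    """

    id: str
    site: str
    sex: str
    ethnicity: str
    device_family: str
    young_mean_bmd: float
    young_sd_bmd: float

    def __post_init__(self) -> None:
        if self.site not in VALID_SITES:
            raise InputError(f"site must be one of {sorted(VALID_SITES)}, got {self.site!r}")
        if self.sex not in VALID_SEXES:
            raise InputError(f"sex must be one of {sorted(VALID_SEXES)}, got {self.sex!r}")
        if not (self.young_mean_bmd > 0):
            raise InputError(f"young_mean_bmd must be > 0, got {self.young_mean_bmd}")
        if not (self.young_sd_bmd > 0):
            raise InputError(f"young_sd_bmd must be > 0, got {self.young_sd_bmd}")


@dataclass(frozen=True)
class PopulationModel:
    """Gaussian model of an older population's BMD / T-score distribution.

    The distribution may be given on the BMD scale (``mean_bmd``/``sd_bmd``,
    g/cm²), on the T-score scale (``mean_t``/``sd_t``), or mixed.  When a
    linked :class:`ReferenceDatabase` is present the missing half of each
    pair is completed through the linear map

        mean_t = (mean_bmd − young_mean_bmd) / young_sd_bmd
        sd_t   = sd_bmd / young_sd_bmd

    and, where both parameterizations were supplied, they must agree to
    within ``1e-9`` on the T scale.  Without a reference a complete pair on
    at least one scale is required.
    """

    label: str
    reference: ReferenceDatabase | None = None
    mean_bmd: float | None = None
    sd_bmd: float | None = None
    mean_t: float | None = None
    sd_t: float | None = None
    id: str = field(default="")

    def __post_init__(self) -> None:
        for name in ("sd_bmd", "sd_t"):
            v = getattr(self, name)
            if v is not None and not (v > 0):
                raise InputError(f"{name} must be > 0 when present, got {v}")

        ref = self.reference
        if ref is not None:
            # complete each pair through the reference, checking consistency
            # on the T scale when both halves were given
            if self.mean_bmd is not None:
                implied_t = (self.mean_bmd - ref.young_mean_bmd) / ref.young_sd_bmd
                if self.mean_t is None:
                    object.__setattr__(self, "mean_t", implied_t)
                elif abs(self.mean_t - implied_t) > DUAL_PARAM_TOL:
                    raise ConfigurationError(
                        f"population {self.label!r}: mean_t={self.mean_t} inconsistent "
                        f"with mean_bmd={self.mean_bmd} under reference {ref.id!r} "
                        f"(implied mean_t={implied_t!r})"
                    )
            elif self.mean_t is not None:
                object.__setattr__(
                    self, "mean_bmd", ref.young_mean_bmd + self.mean_t * ref.young_sd_bmd
                )
            if self.sd_bmd is not None:
                implied_sd_t = self.sd_bmd / ref.young_sd_bmd
                if self.sd_t is None:
                    object.__setattr__(self, "sd_t", implied_sd_t)
                elif abs(self.sd_t - implied_sd_t) > DUAL_PARAM_TOL:
                    raise ConfigurationError(
                        f"population {self.label!r}: sd_t={self.sd_t} inconsistent with "
                        f"sd_bmd={self.sd_bmd} under reference {ref.id!r} "
                        f"(implied sd_t={implied_sd_t!r})"
                    )
            elif self.sd_t is not None:
                object.__setattr__(self, "sd_bmd", self.sd_t * ref.young_sd_bmd)

        has_bmd = self.mean_bmd is not None and self.sd_bmd is not None
        has_t = self.mean_t is not None and self.sd_t is not None
        if not (has_bmd or has_t):
            raise ConfigurationError(
                f"population {self.label!r} lacks a complete parameterization "
                "(need mean and SD on the BMD or the T-score scale)"
            )

    # -- convenience accessors raising the documented error class ---------
    def require_t(self) -> tuple[float, float]:
        """Return ``(mean_t, sd_t)`` or raise :class:`ConfigurationError`."""
        if self.mean_t is None or self.sd_t is None:
            raise ConfigurationError(
                f"population {self.label!r} has no T-score parameterization"
            )
        return self.mean_t, self.sd_t

    def require_bmd(self) -> tuple[float, float]:
        """Return ``(mean_bmd, sd_bmd)`` or raise :class:`ConfigurationError`."""
        if self.mean_bmd is None or self.sd_bmd is None:
            raise ConfigurationError(
                f"population {self.label!r} has no BMD parameterization"
            )
        return self.mean_bmd, self.sd_bmd


# ---------------------------------------------------------------------------
# scalar conversions


def tscore(bmd: float, ref: ReferenceDatabase) -> float:
    """T-score of a BMD value under a reference database, full precision."""
    if not isinstance(ref, ReferenceDatabase):
        raise InputError(f"ref must be a ReferenceDatabase, got {type(ref).__name__}")
    if not (bmd > 0):
        raise InputError(f"bmd must be > 0 g/cm², got {bmd}")
    return (bmd - ref.young_mean_bmd) / ref.young_sd_bmd


def bmd_from_tscore(t: float, ref: ReferenceDatabase) -> float:
    """Invert :func:`tscore`: the BMD (g/cm²) at T-score ``t``.

    Raises :class:`DomainError` when the T-score implies a non-physical
    (≤ 0) BMD under the given reference.
    """
    if not isinstance(ref, ReferenceDatabase):
        raise InputError(f"ref must be a ReferenceDatabase, got {type(ref).__name__}")
    if not math.isfinite(t):
        raise InputError(f"t must be finite, got {t}")
    bmd = ref.young_mean_bmd + t * ref.young_sd_bmd
    if bmd <= 0:
        raise DomainError(
            f"T-score {t} implies BMD {bmd:.4f} g/cm² ≤ 0 under reference {ref.id!r}"
        )
    return bmd


def zscore(bmd: float, pop: PopulationModel) -> float:
    """Z-score of a BMD value against an age-matched population model."""
    mean_bmd, sd_bmd = pop.require_bmd()
    if not (bmd > 0):
        raise InputError(f"bmd must be > 0 g/cm², got {bmd}")
    return (bmd - mean_bmd) / sd_bmd


def tscore_sd_of_population(sd_older_bmd: float, sd_young_bmd: float) -> float:
    """Older-population SD on the T-score scale: the BMD-SD ratio older/young.

    The T-score is an affine function of BMD, so a population whose BMD SD
    is ``sd_older_bmd`` has T-score SD ``sd_older_bmd / sd_young_bmd`` under
    a reference with young SD ``sd_young_bmd``.
    """
    if not (sd_older_bmd > 0):
        raise InputError(f"sd_older_bmd must be > 0, got {sd_older_bmd}")
    if not (sd_young_bmd > 0):
        raise InputError(f"sd_young_bmd must be > 0, got {sd_young_bmd}")
    return sd_older_bmd / sd_young_bmd


def quantile_map_threshold(
    t: float, source: PopulationModel, target: PopulationModel
) -> float:
    """Map a T-score threshold between populations at equal Gaussian percentile.

    Standardizes ``t`` in the source population and re-expresses the same
    z-value in the target population; under the Gaussian model the mapped
    threshold cuts off the same fraction of the target population as ``t``
    does of the source.
    """
    src_mean, src_sd = source.require_t()
    tgt_mean, tgt_sd = target.require_t()
    return tgt_mean + tgt_sd * (t - src_mean) / src_sd


# ---------------------------------------------------------------------------
# registry


@dataclass
class Registry:
    """A loaded collection of reference databases and population models."""

    references: dict[str, ReferenceDatabase]
    populations: dict[str, PopulationModel]

    def reference(self, ref_id: str) -> ReferenceDatabase:
        try:
            return self.references[ref_id]
        except KeyError:
            raise ConfigurationError(f"unknown reference id {ref_id!r}") from None

    def population(self, pop_id: str) -> PopulationModel:
        try:
            return self.populations[pop_id]
        except KeyError:
            raise ConfigurationError(f"unknown population id {pop_id!r}") from None


_REF_REQUIRED = ("id", "site", "sex", "ethnicity", "device_family",
                 "young_mean_bmd", "young_sd_bmd")


def load_reference_registry(path: str | Path) -> Registry:
    """Load and validate a YAML registry of references and populations.

    The file carries a ``references`` list (one record per site/sex/
    ethnicity/device combination) and an optional ``populations`` list whose
    records name their reference by id.  Every record must pass the type
    invariants; duplicate ids are rejected.
    """
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ParseError(f"{path}: not valid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: top level must be a mapping")

    references: dict[str, ReferenceDatabase] = {}
    for i, rec in enumerate(raw.get("references", []) or []):
        if not isinstance(rec, dict):
            raise ParseError(f"{path}: references[{i}] is not a mapping")
        missing = [k for k in _REF_REQUIRED if k not in rec]
        if missing:
            raise ParseError(f"{path}: references[{i}] missing fields {missing}")
        try:
            ref = ReferenceDatabase(**{k: rec[k] for k in _REF_REQUIRED})
        except InputError as exc:
            raise ParseError(f"{path}: references[{i}] ({rec.get('id')!r}): {exc}") from exc
        if ref.id in references:
            raise ConflictError(f"{path}: duplicate reference id {ref.id!r}")
        references[ref.id] = ref

    populations: dict[str, PopulationModel] = {}
    for i, rec in enumerate(raw.get("populations", []) or []):
        if not isinstance(rec, dict):
            raise ParseError(f"{path}: populations[{i}] is not a mapping")
        if "id" not in rec:
            raise ParseError(f"{path}: populations[{i}] missing 'id'")
        ref = None
        if rec.get("reference") is not None:
            ref_id = rec["reference"]
            if ref_id not in references:
                raise ParseError(
                    f"{path}: populations[{i}] ({rec['id']!r}) names unknown "
                    f"reference {ref_id!r}"
                )
            ref = references[ref_id]
        try:
            pop = PopulationModel(
                id=rec["id"],
                label=rec.get("label", rec["id"]),
                reference=ref,
                mean_bmd=rec.get("mean_bmd"),
                sd_bmd=rec.get("sd_bmd"),
                mean_t=rec.get("mean_t"),
                sd_t=rec.get("sd_t"),
            )
        except (InputError, ConfigurationError) as exc:
            raise ParseError(f"{path}: populations[{i}] ({rec['id']!r}): {exc}") from exc
        if pop.id in populations:
            raise ConflictError(f"{path}: duplicate population id {pop.id!r}")
        populations[pop.id] = pop

    return Registry(references=references, populations=populations)


def default_registry() -> Registry:
    """The registry shipped with the package (NHANES III and Hong Kong rows)."""
    from importlib.resources import files

    return load_reference_registry(Path(str(files("osteofrailia") / "data" / "registry.yaml")))


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (the display convention for T-scores and
    percentages; Python's built-in ``round`` is half-to-even)."""
    scale = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale
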