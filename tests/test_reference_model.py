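"""T-score / Z-score arithmetic, population models, and the registry."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from osteofrailia import (
    ConfigurationError,
    ConflictError,
    DomainError,
    InputError,
    ParseError,
    PopulationModel,
    ReferenceDatabase,
    bmd_from_tscore,
    load_reference_registry,
    quantile_map_threshold,
    tscore,
    tscore_sd_of_population,
    zscore,
)

REF = ReferenceDatabase(
    id="r", site="FN", sex="F", ethnicity="test", device_family="test",
    young_mean_bmd=0.858, young_sd_bmd=0.120,
)
REF_M = ReferenceDatabase(
    id="rm", site="FN", sex="M", ethnicity="test", device_family="test",
    young_mean_bmd=0.934, young_sd_bmd=0.137,
)


class TestTscoreArithmetic:
    @pytest.mark.parametrize(
        "bmd,expected",
        [
            (REF.young_mean_bmd, 0.0),
            (REF.young_mean_bmd - REF.young_sd_bmd, -1.0),
            (REF.young_mean_bmd + 2 * REF.young_sd_bmd, 2.0),
        ],
    )
    def test_identity_and_sd_cases(self, bmd, expected):
        assert tscore(bmd, REF) == pytest.approx(expected, abs=1e-12)

    def test_tenth_gram_gap_is_073_tscore_units(self):
        """A 0.1 g/cm² BMD gap is ≈0.73 T-score units under the male
        reference with young SD 0.137."""
        t_hi = tscore(0.80, REF_M)
        t_lo = tscore(0.70, REF_M)
        assert t_hi - t_lo == pytest.approx(0.1 / 0.137)
        assert round(t_hi - t_lo, 2) == 0.73

    def test_bmd_from_tscore_example(self):
        assert bmd_from_tscore(-2.5, REF) == pytest.approx(0.558)
        assert bmd_from_tscore(0.0, REF) == REF.young_mean_bmd

    def test_nonpositive_bmd_rejected(self):
        with pytest.raises(InputError):
            tscore(0.0, REF)
        with pytest.raises(InputError):
            tscore(-0.5, REF)

    def test_nonphysical_tscore_rejected(self):
        with pytest.raises(DomainError):
            bmd_from_tscore(-10.0, REF)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=-5.0, max_value=3.0))
    def test_round_trip_is_identity(self, t):
        assert tscore(bmd_from_tscore(t, REF), REF) == pytest.approx(t, abs=1e-12)

    def test_tscore_strictly_increasing_in_bmd(self):
        b = np.linspace(0.3, 1.3, 50)
        t = [(tscore(x, REF)) for x in b]
        assert all(a < c for a, c in zip(t, t[1:]))


class TestZscore:
    POP = PopulationModel(label="older", mean_bmd=0.70, sd_bmd=0.129)

    def test_mean_and_two_sd(self):
        assert zscore(0.70, self.POP) == 0.0
        assert zscore(0.70 + 2 * 0.129, self.POP) == pytest.approx(2.0)

    def test_low_bmd_despite_average_for_age(self):
        """Average-for-age (Z≈0) can still mean low absolute BMD: under a
        population centred at T ≈ −1.7, a Z=0 subject has T ≈ −1.7."""
        pop = PopulationModel(label="older-f", reference=REF, mean_t=-1.7, sd_t=1.0)
        bmd_at_z0 = pop.mean_bmd
        assert zscore(bmd_at_z0, pop) == pytest.approx(0.0, abs=1e-12)
        assert tscore(bmd_at_z0, REF) == pytest.approx(-1.7, abs=1e-12)

    def test_missing_bmd_parameterization_raises(self):
        pop_t_only = PopulationModel(label="t-only", mean_t=-1.2, sd_t=1.0)
        with pytest.raises(ConfigurationError):
            zscore(0.7, pop_t_only)


class TestPopulationSd:
    @pytest.mark.parametrize(
        "older,young,expected",
        [(0.139, 0.137, 0.139 / 0.137), (0.129, 0.120, 1.075), (0.5, 0.5, 1.0)],
    )
    def test_ratio(self, older, young, expected):
        assert tscore_sd_of_population(older, young) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(InputError):
            tscore_sd_of_population(0.0, 0.1)
        with pytest.raises(InputError):
            tscore_sd_of_population(0.1, -0.1)

    def test_matches_monte_carlo_sd_of_transformed_sample(self):
        """The BMD-SD ratio equals the SD of T-scores of a simulated older
        BMD sample, within 3 standard errors."""
        rng = np.random.default_rng(1234)
        n = 200_000
        bmd = rng.normal(0.70, 0.139, n)
        t = (bmd - REF_M.young_mean_bmd) / REF_M.young_sd_bmd
        expected = tscore_sd_of_population(0.139, REF_M.young_sd_bmd)
        se = expected / math.sqrt(2 * (n - 1))
        assert abs(t.std(ddof=1) - expected) < 3 * se


class TestQuantileMap:
    SRC = PopulationModel(label="m", mean_t=-1.241, sd_t=1.0145985401459854)
    TGT = PopulationModel(label="f", mean_t=-1.717, sd_t=1.075)

    def test_identity_cases(self):
        assert quantile_map_threshold(-2.5, self.SRC, self.SRC) == -2.5
        assert quantile_map_threshold(self.SRC.mean_t, self.SRC, self.TGT) == pytest.approx(
            self.TGT.mean_t
        )

    def test_known_mapping(self):
        got = quantile_map_threshold(-2.5, self.SRC, self.TGT)
        assert got == pytest.approx(-3.051, abs=5e-4)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=-5, max_value=3))
    def test_round_trip_and_monotone(self, t):
        back = quantile_map_threshold(
            quantile_map_threshold(t, self.SRC, self.TGT), self.TGT, self.SRC
        )
        assert back == pytest.approx(t, abs=1e-12)
        assert quantile_map_threshold(t + 0.1, self.SRC, self.TGT) > quantile_map_threshold(
            t, self.SRC, self.TGT
        )

    def test_missing_t_parameterization_raises(self):
        bmd_only = PopulationModel(label="b", mean_bmd=0.7, sd_bmd=0.13)
        with pytest.raises(ConfigurationError):
            quantile_map_threshold(-2.5, bmd_only, self.TGT)


class TestRegistry:
    def test_shipped_registry_loads(self, registry):
        assert {"nhanes3_fn_m", "nhanes3_fn_f"} <= set(registry.references)
        assert {"us_older_m", "us_older_f", "hk_older_m", "hk_older_f"} <= set(
            registry.populations
        )
        m = registry.population("us_older_m")
        assert m.sd_t == pytest.approx(0.139 / 0.137)

    def test_dual_parameterization_completed_consistently(self, registry):
        pop = registry.population("us_older_m")
        ref = registry.reference("nhanes3_fn_m")
        assert pop.mean_bmd == pytest.approx(
            ref.young_mean_bmd + pop.mean_t * ref.young_sd_bmd, abs=1e-12
        )

    def test_nonpositive_sd_rejected(self, tmp_path):
        bad = tmp_path / "reg.yaml"
        bad.write_text(
            "references:\n"
            "- {id: x, site: FN, sex: M, ethnicity: e, device_family: d,\n"
            "   young_mean_bmd: 0.9, young_sd_bmd: -0.1}\n"
        )
        with pytest.raises(ParseError):
            load_reference_registry(bad)

    def test_duplicate_id_rejected(self, tmp_path):
        bad = tmp_path / "reg.yaml"
        rec = ("- {id: x, site: FN, sex: M, ethnicity: e, device_family: d,\n"
               "   young_mean_bmd: 0.9, young_sd_bmd: 0.1}\n")
        bad.write_text("references:\n" + rec + rec)
        with pytest.raises(ConflictError):
            load_reference_registry(bad)

    def test_inconsistent_dual_parameterization_rejected(self, tmp_path):
        bad = tmp_path / "reg.yaml"
        bad.write_text(
            "references:\n"
            "- {id: x, site: FN, sex: M, ethnicity: e, device_family: d,\n"
            "   young_mean_bmd: 0.934, young_sd_bmd: 0.137}\n"
            "populations:\n"
            "- {id: p, reference: x, mean_t: -1.241, sd_t: 1.0, mean_bmd: 0.9}\n"
        )
        with pytest.raises(ParseError):
            load_reference_registry(bad)
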