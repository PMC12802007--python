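import numpy as np
import pytest

from pmbod.attribution import (
    SUM_LABEL,
    AttributionResult,
    HealthOutcomeRecord,
    HealthOutcomeTable,
    attributable_burden,
    attributable_by_cause,
    daly_decomposition,
    load_health_table,
    paf_distribution,
    paf_pwc,
)
from pmbod.curves import CurveSpec, RelativeRisk10, make_curve
from pmbod.errors import DataError, ValidationError
from pmbod.exposure import collapse_to_pwc, population_weighted_concentration

from .conftest import make_dist, random_dist

LINEAR_08 = make_curve(CurveSpec(shape="linear", rr10=RelativeRisk10(1.08), cutoff=0.0))


class TestPafDistribution:
    def test_degenerate_at_5(self, degenerate_at_5):
        # 0.04 / 1.04, by hand
        assert paf_distribution(degenerate_at_5, LINEAR_08) == pytest.approx(
            0.038461538461538464, abs=1e-12
        )

    def test_null_curve(self, synthetic_dist):
        curve = make_curve(CurveSpec(shape="linear", rr10=RelativeRisk10(1.08), cutoff=1000.0))
        assert paf_distribution(synthetic_dist, curve) == 0.0

    def test_two_bin_hand_value(self, two_bin_symmetric):
        # RR at midpoints 0.5 and 9.5: 1.004, 1.076 -> mean 1.04; hand value
        # for the spec's stylised {1.0, 1.076} pair: (1.038-1)/1.038
        curve = lambda c: np.where(np.asarray(c) < 1, 1.0, 1.076)
        assert paf_distribution(two_bin_symmetric, curve) == pytest.approx(
            0.0366088631984586, abs=1e-12
        )

    def test_nonpositive_rr_rejected(self, two_bin_symmetric):
        with pytest.raises(ValidationError):
            paf_distribution(two_bin_symmetric, lambda c: np.zeros_like(np.asarray(c, float)))

    def test_brute_force_oracle(self, rng):
        curve = make_curve(CurveSpec(shape="loglog", rr10=RelativeRisk10(1.08), cutoff=2.0))
        for _ in range(20):
            dist = random_dist(rng, n_bins=50)
            s = sum(float(curve(b.midpoint)) * b.fraction for b in dist.bins)
            expected = (s - 1) / s
            assert paf_distribution(dist, curve) == pytest.approx(expected, abs=1e-12)


class TestPafPwc:
    @pytest.mark.parametrize(
        "rr,expected",
        [(1.04, 0.038461538461538464), (1.0, 0.0), (1.24, 0.1935483870967742)],
    )
    def test_hand_values(self, rr, expected):
        assert paf_pwc(rr) == pytest.approx(expected, abs=1e-12)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            paf_pwc(0.0)


class TestEquivalenceAndZeroLaw:
    def test_linear_no_cutoff_equivalence(self, synthetic_dist):
        # linear in C: full-distribution PAF equals the PWC shortcut exactly
        paf_full = paf_distribution(synthetic_dist, LINEAR_08)
        paf_short = paf_pwc(LINEAR_08(population_weighted_concentration(synthetic_dist)))
        assert paf_full == pytest.approx(paf_short, abs=1e-12)

    def test_collapse_matches_pwc_pathway(self, synthetic_dist):
        collapsed = collapse_to_pwc(synthetic_dist)
        assert paf_distribution(collapsed, LINEAR_08) == pytest.approx(
            paf_pwc(LINEAR_08(population_weighted_concentration(synthetic_dist))), abs=1e-12
        )

    def test_pwc_below_cutoff_kills_estimate(self, synthetic_dist):
        # PWC 5 < cut-off 6: the PWC pathway reports zero while the full
        # distribution keeps the mass above 6
        curve = make_curve(CurveSpec(shape="linear", rr10=RelativeRisk10(1.08), cutoff=6.0))
        assert paf_distribution(collapse_to_pwc(synthetic_dist), curve) == 0.0
        assert paf_distribution(synthetic_dist, curve) > 0.0

    def test_jensen_for_loglog(self, rng):
        # log-log is concave above the cut-off, so the distribution PAF
        # cannot exceed the PWC-pathway PAF
        curve = make_curve(CurveSpec(shape="loglog", rr10=RelativeRisk10(1.08), cutoff=0.0))
        for _ in range(20):
            dist = random_dist(rng, n_bins=30)
            paf_full = paf_distribution(dist, curve)
            paf_short = paf_pwc(float(curve(population_weighted_concentration(dist))))
            assert paf_full <= paf_short + 1e-12


class TestHealthRecords:
    def test_ci_ordering(self):
        with pytest.raises(ValidationError):
            HealthOutcomeRecord("IHD", "deaths", 100, lo=120, hi=150)

    def test_unknown_measure(self):
        with pytest.raises(ValidationError):
            HealthOutcomeRecord("IHD", "mortality", 100)

    def test_daly_consistency_enforced(self):
        records = [
            HealthOutcomeRecord("IHD", "YLL", 80),
            HealthOutcomeRecord("IHD", "YLD", 20),
            HealthOutcomeRecord("IHD", "DALY", 150),
        ]
        with pytest.raises(ValidationError, match="DALY"):
            HealthOutcomeTable(records)

    def test_daly_tolerance_for_rounded_inputs(self):
        records = [
            HealthOutcomeRecord("IHD", "YLL", 80.2),
            HealthOutcomeRecord("IHD", "YLD", 20.2),
            HealthOutcomeRecord("IHD", "DALY", 100.0),
        ]
        HealthOutcomeTable(records)  # |100.4 - 100| < 0.5

    def test_registry_record_has_no_interval(self, registry_table):
        rec = registry_table.get("IHD", "deaths")
        assert not rec.has_interval
        with pytest.raises(DataError, match="no interval"):
            rec.endpoint("lo")

    def test_csv_roundtrip(self, tmp_path, health_table):
        path = tmp_path / "health.csv"
        health_table.to_csv(path)
        reloaded = load_health_table(path)
        for rec in health_table.records:
            got = reloaded.get(rec.cause, rec.measure)
            assert got.value == pytest.approx(rec.value)
            assert got.lo == pytest.approx(rec.lo)


class TestAttributableBurden:
    def test_scaling(self):
        rec = HealthOutcomeRecord("all-cause", "deaths", 100)
        assert attributable_burden(0.1, rec).attributable == pytest.approx(10.0)

    def test_reference_magnitude(self, health_table):
        # PAF 0.04/1.04 times the default synthetic all-cause death count
        rec = health_table.get("all-cause", "deaths")
        result = attributable_burden(paf_pwc(1.04), rec)
        assert round(result.attributable) == 1448

    def test_zero_paf(self, health_table):
        rec = health_table.get("all-cause", "deaths")
        assert attributable_burden(0.0, rec).attributable == 0.0

    def test_paf_out_of_range(self, health_table):
        rec = health_table.get("all-cause", "deaths")
        with pytest.raises(ValidationError):
            attributable_burden(1.0, rec)


class TestAttributableByCause:
    CAUSES = ("IHD", "stroke", "COPD", "ALRI", "lung cancer")

    def _shared_curves(self, rr10=1.08, cutoff=0.0):
        return {
            cause: make_curve(CurveSpec(shape="linear", rr10=RelativeRisk10(rr10), cutoff=cutoff))
            for cause in self.CAUSES
        }

    def test_additivity(self, degenerate_at_5):
        table = HealthOutcomeTable(
            [HealthOutcomeRecord(c, "deaths", 100) for c in self.CAUSES]
        )
        curves = {c: lambda conc: np.full_like(np.asarray(conc, float), 51 / 49) for c in self.CAUSES}
        results = attributable_by_cause(degenerate_at_5, curves, table, "deaths")
        per_cause = [r for r in results if r.cause != SUM_LABEL]
        assert all(r.attributable == pytest.approx(100 * (1 - 49 / 51)) for r in per_cause)
        total = next(r for r in results if r.cause == SUM_LABEL)
        assert total.attributable == pytest.approx(sum(r.attributable for r in per_cause))

    def test_single_cause_reduces_to_attributable_burden(self, degenerate_at_5, health_table):
        curves = {"IHD": LINEAR_08}
        results = attributable_by_cause(degenerate_at_5, curves, health_table, "deaths")
        expected = attributable_burden(
            paf_distribution(degenerate_at_5, LINEAR_08), health_table.get("IHD", "deaths")
        )
        assert results[0].attributable == pytest.approx(expected.attributable)

    def test_disease_sum_below_all_cause(self, synthetic_dist, health_table):
        # shared curve + disease deaths summing below all-cause deaths
        results = attributable_by_cause(
            synthetic_dist, self._shared_curves(), health_table, "deaths"
        )
        disease_sum = next(r for r in results if r.cause == SUM_LABEL).attributable
        all_cause = attributable_burden(
            paf_distribution(synthetic_dist, LINEAR_08),
            health_table.get("all-cause", "deaths"),
        ).attributable
        assert disease_sum < all_cause

    def test_missing_cause_is_error(self, synthetic_dist, health_table):
        curves = {"asthma": LINEAR_08}
        with pytest.raises(DataError, match="asthma"):
            attributable_by_cause(synthetic_dist, curves, health_table, "deaths")

    def test_uncovered_causes_skipped_with_notice(self, synthetic_dist, health_table, caplog):
        import logging

        with caplog.at_level(logging.INFO, logger="pmbod.attribution"):
            attributable_by_cause(synthetic_dist, {"IHD": LINEAR_08}, health_table, "deaths")
        assert any("skipped" in rec.message for rec in caplog.records)


class TestDalyDecomposition:
    def test_arithmetic(self):
        yll = AttributionResult("IHD", "YLL", 0.1, 75.0)
        yld = AttributionResult("IHD", "YLD", 0.1, 25.0)
        daly, share = daly_decomposition(yll, yld)
        assert daly.attributable == pytest.approx(100.0)
        assert share == pytest.approx(0.75)

    def test_zero_yld_share_is_one(self):
        yll = AttributionResult("IHD", "YLL", 0.1, 50.0)
        yld = AttributionResult("IHD", "YLD", 0.1, 0.0)
        _, share = daly_decomposition(yll, yld)
        assert share == 1.0

    def test_zero_total_share_missing(self):
        yll = AttributionResult("IHD", "YLL", 0.0, 0.0)
        yld = AttributionResult("IHD", "YLD", 0.0, 0.0)
        _, share = daly_decomposition(yll, yld)
        assert share is None

    def test_cause_mismatch(self):
        yll = AttributionResult("IHD", "YLL", 0.1, 75.0)
        yld = AttributionResult("stroke", "YLD", 0.1, 25.0)
        with pytest.raises(DataError, match="mismatch"):
            daly_decomposition(yll, yld)

    def test_same_paf_equals_direct_product(self, degenerate_at_5, health_table):
        paf = paf_distribution(degenerate_at_5, LINEAR_08)
        yll_rec = health_table.get("IHD", "YLL")
        yld_rec = health_table.get("IHD", "YLD")
        daly, _ = daly_decomposition(
            attributable_burden(paf, yll_rec), attributable_burden(paf, yld_rec)
        )
        assert daly.attributable == pytest.approx(paf * (yll_rec.value + yld_rec.value), abs=1e-9)
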