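"""Period scanning: scores, null calibration, correction, families."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from periscan.features import FeatureSet
from periscan.periodicity import (
    PeriodCandidate,
    correct_pvalue,
    detect_harmonic_families,
    find_common_periods,
    periodicity_score,
    periodobar_table,
    phase_transform,
    pvalue_uniform_null,
    rayleigh_pvalue,
    scan_periods,
    select_significant,
)
from periscan.synthetic import PlantedConfig, generate_periodic_positions

from conftest import ECOLI_G


def brute_force_score(phases, period):
    """Independent oracle: direct complex-sum evaluation of S = N*R^2."""
    z = sum(complex(math.cos(2 * math.pi * p / period), math.sin(2 * math.pi * p / period))
            for p in phases)
    return abs(z) ** 2 / len(phases)


class TestPhaseTransform:
    def test_examples(self):
        assert phase_transform([14_930], 14_830)[0] == pytest.approx(100.0)
        assert phase_transform([0, 14_830, 2 * 14_830], 14_830) == pytest.approx([0, 0, 0])

    def test_invalid_period(self):
        with pytest.raises(ValueError):
            phase_transform([1, 2], 0)

    @given(
        positions=st.lists(st.integers(0, 10**7), min_size=1, max_size=30),
        period=st.floats(1.0, 1e6),
    )
    @settings(derandomize=True, max_examples=60)
    def test_phases_in_range_order_preserved(self, positions, period):
        phases = phase_transform(positions, period)
        assert np.all((phases >= 0) & (phases < period))
        assert len(phases) == len(positions)


class TestPeriodicityScore:
    def test_all_in_phase_gives_n(self):
        assert periodicity_score([7.0] * 20, 100.0) == pytest.approx(20.0)

    def test_antipodal_cancellation(self):
        assert periodicity_score([0.0, 50.0], 100.0) == pytest.approx(0.0, abs=1e-12)

    def test_two_pairs_at_right_angle(self):
        # angles {0, 0, pi/2, pi/2}: R = sqrt(2)/2, S = N*R^2 = 2
        phases = [0.0, 0.0, 25.0, 25.0]
        assert periodicity_score(phases, 100.0) == pytest.approx(2.0)

    def test_fewer_than_two_phases_rejected(self):
        with pytest.raises(ValueError):
            periodicity_score([1.0], 10.0)

    @given(
        data=st.lists(st.floats(0, 1e6, allow_nan=False), min_size=2, max_size=50),
        period=st.floats(10.0, 1e5),
        shift=st.floats(0, 1e6),
    )
    @settings(derandomize=True, max_examples=100)
    def test_matches_brute_force_and_translation_invariance(self, data, period, shift):
        s = periodicity_score(np.asarray(data) % period, period)
        assert s == pytest.approx(brute_force_score(data, period), abs=1e-9)
        assert s <= len(data) + 1e-9
        shifted = periodicity_score((np.asarray(data) + shift) % period, period)
        assert shifted == pytest.approx(s, abs=1e-6)


class TestPValues:
    def test_perfect_alignment_highly_significant(self):
        p = pvalue_uniform_null(
            20.0, 20, period=100_000, genome_length=ECOLI_G, n_mc=10_000, seed=0
        )
        assert p < 1e-3

    def test_zero_score_p_one(self):
        p = pvalue_uniform_null(
            0.0, 10, period=50_000, genome_length=ECOLI_G, n_mc=500, seed=0
        )
        assert p == pytest.approx(1.0)

    def test_analytic_agrees_with_monte_carlo(self):
        p_mc = pvalue_uniform_null(
            5.0, 50, period=100_000, genome_length=ECOLI_G, n_mc=100_000, seed=1
        )
        p_an = pvalue_uniform_null(
            5.0, 50, period=100_000, genome_length=ECOLI_G, method="analytic"
        )
        assert abs(p_mc - p_an) < 0.01

    def test_monte_carlo_converges_to_analytic_within_3se(self):
        # large n_mc: MC estimate should sit within 3 standard errors of the
        # analytic approximation for N >= 30
        n_mc = 100_000
        for n, s in [(30, 3.0), (50, 5.0)]:
            p_an = rayleigh_pvalue(s, n, 100_000, ECOLI_G)
            p_mc = pvalue_uniform_null(
                s, n, period=100_000, genome_length=ECOLI_G, n_mc=n_mc, seed=7
            )
            se = math.sqrt(p_an * (1 - p_an) / n_mc)
            assert abs(p_mc - p_an) < 3 * se + 1 / n_mc

    def test_wrap_bias_null_large_period(self):
        # at P comparable to G the uniform null concentrates phases; the
        # analytic tail must track a simulated null, not plain Rayleigh
        rng = np.random.default_rng(3)
        pos = rng.integers(1, ECOLI_G + 1, size=(40_000, 50)).astype(float)
        ang = 2 * np.pi * pos / 2_000_000.0
        s_null = (np.cos(ang).sum(1) ** 2 + np.sin(ang).sum(1) ** 2) / 50
        s_crit = np.quantile(s_null, 0.99)
        p = rayleigh_pvalue(s_crit, 50, 2_000_000.0, ECOLI_G)
        assert 0.005 < p < 0.02

    def test_classical_tail_matches_independent_implementation(self):
        # pingouin's Rayleigh test is an independent implementation of the
        # finite-N tail; our unbiased form must agree with it
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(11)
        for n in (12, 40):
            angles = rng.uniform(0, 2 * np.pi, n)
            _, p_ref = pingouin.circ_rayleigh(angles)
            phases = angles / (2 * np.pi) * 1000.0
            s = __import__("periscan").periodicity_score(phases, 1000.0)
            assert rayleigh_pvalue(s, n) == pytest.approx(p_ref, rel=1e-6, abs=1e-9)

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            pvalue_uniform_null(1.0, 10, period=10, genome_length=100, method="bogus")


class TestCorrectPValue:
    def test_sidak_example(self):
        # m = floor(4641652 / 93000) = 49
        assert correct_pvalue(0.001, 93_000, 4_641_652) == pytest.approx(0.0478, abs=2e-4)

    def test_single_test_identity(self):
        assert correct_pvalue(0.3, 600, 1000) == pytest.approx(0.3)

    def test_zero_stays_zero_and_monotone(self):
        assert correct_pvalue(0.0, 1000, 100_000) == 0.0
        ps = [correct_pvalue(0.01, P, 100_000) for P in (50_000, 10_000, 1_000)]
        assert ps == sorted(ps)

    def test_period_beyond_genome_rejected(self):
        with pytest.raises(ValueError):
            correct_pvalue(0.5, 2000, 1000)


class TestScanPeriods:
    def test_circ_mode_tests_integer_divisors(self):
        fs = FeatureSet.from_positions([100, 400, 900], 1000)
        res = scan_periods(fs, mode="CIRC", p_min=100, p_max=500)
        expected = [1000 / k for k in range(10, 1, -1)]
        assert np.allclose(res.periods, expected)

    def test_planted_lattice_argmax_exact(self):
        cfg = PlantedConfig(ECOLI_G, 93_000.0, 40, 0.0, 0, seed=5)
        fs, _ = generate_periodic_positions(cfg)
        res = scan_periods(fs, "DOM", p_min=80_000, p_max=110_000, step=3.0)
        best = res.best()
        assert best.period == pytest.approx(93_000.0, abs=3.0)
        assert best.p_corrected < 1e-6

    def test_translation_invariance_of_scores(self):
        # a plain shift leaves S unchanged at every tested period; a shift
        # modulo G does so at the CIRC periods G/k, where G/P is an integer
        rng = np.random.default_rng(0)
        pos = rng.integers(1, 100_001, size=20)
        fs1 = FeatureSet.from_positions(pos, 200_000)
        fs2 = FeatureSet.from_positions(pos + 54_321, 200_000)
        r1 = scan_periods(fs1, "DOM", 10_000, 50_000, step=100)
        r2 = scan_periods(fs2, "DOM", 10_000, 50_000, step=100)
        assert np.allclose([c.score for c in r1.candidates],
                           [c.score for c in r2.candidates], atol=1e-8)
        fs3 = FeatureSet.from_positions((pos + 123_456 - 1) % 200_000 + 1, 200_000)
        c1 = scan_periods(fs1, "CIRC", 10_000, 50_000)
        c3 = scan_periods(fs3, "CIRC", 10_000, 50_000)
        assert np.allclose([c.score for c in c1.candidates],
                           [c.score for c in c3.candidates], atol=1e-8)

    def test_divisor_property_exact_lattice(self):
        # lattice of spacing T is significant at T and at T/2
        cfg = PlantedConfig(ECOLI_G, 200_000.0, 23, 0.0, 0, seed=2)
        fs, _ = generate_periodic_positions(cfg)
        res = scan_periods(fs, "DOM", 80_000, 250_000, step=50)
        sig_periods = [c.period for c in select_significant(res, 0.05)]
        assert any(abs(p - 200_000) / 200_000 < 0.01 for p in sig_periods)
        assert any(abs(p - 100_000) / 100_000 < 0.01 for p in sig_periods)

    def test_proximity_filter_applied_before_scoring(self):
        fs = FeatureSet.from_positions([100, 150, 200, 50_000], 100_000)
        res = scan_periods(fs, "DOM", 10_000, 50_000, step=1000, proximity=500)
        assert res.params["n_used"] == 2

    def test_empty_after_filter_reports_count(self):
        fs = FeatureSet.from_positions([100, 150], 100_000)
        with pytest.raises(ValueError, match="1 feature"):
            scan_periods(fs, "DOM", 10_000, 50_000, proximity=500)


class TestSelection:
    def _result(self):
        fs = FeatureSet.from_positions([100, 400, 900, 2000], 10_000)
        return scan_periods(fs, "DOM", 1000, 5000, step=500)

    def test_alpha_bounds(self):
        res = self._result()
        assert select_significant(res, 1.0) == sorted(
            res.candidates, key=lambda c: (c.p_corrected, c.period)
        )
        assert select_significant(res, 0.0) == []

    def test_threshold_is_strict(self):
        from periscan.periodicity import PeriodScanResult

        res = PeriodScanResult(
            periods=np.array([100.0, 200.0]), scores=np.array([1.0, 1.0]),
            p_raw=np.array([0.02, 0.03]), p_corrected=np.array([0.04, 0.06]),
            mode="DOM", n_features=5, params={},
        )
        hits = select_significant(res, 0.05)
        assert [c.period for c in hits] == [100.0]


class TestHarmonicFamilies:
    def test_doubled_period_grouped(self):
        fams = detect_harmonic_families([93_094, 186_317], rel_tol=0.01)
        assert fams == [[93_094.0, 186_317.0]]

    def test_ratio_outside_tolerance(self):
        assert detect_harmonic_families([100, 307], rel_tol=0.01) == []

    def test_exact_family_of_three(self):
        fams = detect_harmonic_families([1000.0, 2000.0, 4000.0])
        assert fams == [[1000.0, 2000.0, 4000.0]]

    def test_bad_tolerance(self):
        with pytest.raises(ValueError):
            detect_harmonic_families([100.0], rel_tol=0.5)


class TestCommonPeriods:
    def test_table_one_style_pair(self):
        df = find_common_periods({"A": [93_094], "B": [90_216]})
        assert df.common_period.notna().all()
        assert df.rel_diff.max() == pytest.approx(abs(93_094 - 90_216) / 93_094)

    def test_distant_periods_report_none(self):
        df = find_common_periods({"A": [93_094], "B": [750_416]})
        assert df.common_period.isna().all()

    def test_identical_everywhere(self):
        df = find_common_periods({"A": [5.0], "B": [5.0], "C": [5.0]})
        assert (df.rel_diff == 0).all()


class TestPeriodobar:
    def test_neg_log10_and_flags(self):
        fs = FeatureSet.from_positions([100, 400, 900, 2000], 10_000)
        res = scan_periods(fs, "DOM", 1000, 5000, step=500)
        table = periodobar_table(res, alpha=0.05)
        assert len(table) == len(res.candidates)
        row = table.iloc[0]
        assert row.neg_log10_p == pytest.approx(-np.log10(row.p_corrected))
        assert (table.significant == (table.p_corrected < 0.05)).all()
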