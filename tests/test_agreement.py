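"""Error records, Bland-Altman agreement, ICC and Pearson statistics."""

import numpy as np
import pytest

from musclevol import (
    PairedVolumes,
    VolumeEstimate,
    bland_altman,
    compute_errors,
    icc_two_way_mixed,
    pearson_correlation,
    summarize_by_cell,
    summary_to_frame,
)


def _estimate(subject, interval, volume, equation="cylinder"):
    return VolumeEstimate(subject, equation, interval, 0.0, volume, 10)


def _pairs(diffs, ref=1000.0, equation="cylinder", interval=2.0):
    return [
        PairedVolumes(f"s{i}", equation, interval, ref, ref - d)
        for i, d in enumerate(diffs)
    ]


class TestErrorRecords:
    def test_error_arithmetic(self):
        ests = [_estimate("a", 1.0, 1000.0), _estimate("a", 2.0, 990.0)]
        (rec,) = compute_errors(ests)
        assert rec.signed_difference == 10.0
        assert rec.absolute_error == 10.0
        assert rec.relative_error == pytest.approx(1.0)

    def test_identical_volumes_give_zero_error(self):
        ests = [_estimate("a", 1.0, 500.0), _estimate("a", 3.0, 500.0)]
        (rec,) = compute_errors(ests)
        assert (rec.signed_difference, rec.absolute_error, rec.relative_error) == (0, 0, 0)

    def test_overestimation_sign(self):
        ests = [_estimate("a", 1.0, 1000.0), _estimate("a", 2.0, 1010.0)]
        (rec,) = compute_errors(ests)
        assert rec.signed_difference == -10.0
        assert rec.absolute_error == 10.0
        assert rec.relative_error == pytest.approx(1.0)

    def test_missing_reference_names_subject(self):
        ests = [
            _estimate("a", 1.0, 1000.0),
            _estimate("a", 2.0, 990.0),
            _estimate("b", 2.0, 880.0),
        ]
        with pytest.raises(ValueError, match="'b'"):
            compute_errors(ests)


class TestBlandAltman:
    def test_hand_computed_loa(self):
        # d = {+1,-1,+1,-1}: bias 0, sample SD = sqrt(4/3), LOA = +-1.96*1.1547
        s = bland_altman(_pairs([1.0, -1.0, 1.0, -1.0]))
        assert s.mean_bias == pytest.approx(0.0)
        assert s.loa_high == pytest.approx(1.96 * np.sqrt(4 / 3), abs=1e-9)
        assert s.loa_low == pytest.approx(-1.96 * np.sqrt(4 / 3), abs=1e-9)

    def test_zero_variance_collapses_loa(self):
        s = bland_altman(_pairs([5.0, 5.0, 5.0]))
        assert s.mean_bias == 5.0
        assert (s.loa_low, s.loa_high) == (5.0, 5.0)
        assert s.n_within_loa == 3  # boundary counts as within

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            bland_altman(_pairs([1.0, 2.0]))

    def test_gaussian_coverage_of_loa(self, rng):
        """~95 % of Gaussian differences fall within the 1.96 SD limits."""
        d = rng.normal(0.0, 7.0, size=10_000)
        s = bland_altman(_pairs(d, ref=500.0))
        frac = s.n_within_loa / s.n_total
        assert 0.94 <= frac <= 0.96

    def test_bias_antisymmetry_under_swap(self, rng):
        d = rng.normal(3.0, 2.0, size=20)
        fwd = bland_altman(_pairs(d))
        swapped = [
            PairedVolumes(p.subject_id, p.equation, p.interval_cm,
                          p.comparison_volume, p.reference_volume)
            for p in _pairs(d)
        ]
        rev = bland_altman(swapped)
        assert rev.mean_bias == pytest.approx(-fwd.mean_bias)
        assert (rev.loa_high - rev.loa_low) == pytest.approx(fwd.loa_high - fwd.loa_low)


class TestScaling:
    def test_relative_error_scale_invariant_absolute_scales(self):
        base = [_estimate("a", 1.0, 1000.0), _estimate("a", 4.0, 950.0)]
        scaled = [_estimate("a", 1.0, 3000.0), _estimate("a", 4.0, 2850.0)]
        (rb,), (rs,) = compute_errors(base), compute_errors(scaled)
        assert rs.relative_error == pytest.approx(rb.relative_error)
        assert rs.absolute_error == pytest.approx(3 * rb.absolute_error)


class TestICC:
    def test_perfect_agreement(self):
        x = np.arange(8.0).reshape(-1, 1).repeat(2, axis=1)
        icc, lo, hi = icc_two_way_mixed(x)
        assert icc == pytest.approx(1.0)

    def test_consistency_invariant_under_rater_shift(self, rng):
        a = rng.normal(900, 100, 10)
        x = np.column_stack([a, a + rng.normal(0, 5, 10)])
        shifted = x.copy()
        shifted[:, 1] += 250.0  # systematic offset between fixed raters
        icc1, *_ = icc_two_way_mixed(x)
        icc2, *_ = icc_two_way_mixed(shifted)
        assert icc2 == pytest.approx(icc1, rel=1e-12)

    def test_independent_raters_give_near_zero(self, rng):
        a = rng.normal(0, 1, 600)
        x = np.column_stack([a, rng.permutation(a)])
        icc, *_ = icc_two_way_mixed(x)
        assert abs(icc) < 0.12

    def test_high_reliability_regime(self):
        """Between-subject SD >> rater noise: ICC(3,1) >= 0.99 almost always."""
        rng = np.random.default_rng(42)
        hits = 0
        reps = 1000
        for _ in range(reps):
            subj = rng.normal(900.0, 100.0, 8)
            x = subj[:, None] + rng.normal(0.0, 1.0, (8, 2))
            icc, *_ = icc_two_way_mixed(x)
            hits += icc >= 0.99
        assert hits / reps >= 0.95

    def test_matches_pingouin_oracle(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        subj = rng.normal(50, 12, 12)
        x = subj[:, None] + np.array([0.0, 1.5, -0.8]) + rng.normal(0, 4, (12, 3))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": x.ravel(),
            }
        )
        res = pg.intraclass_corr(df, "subject", "rater", "score").set_index("Type")
        icc, lo, hi = icc_two_way_mixed(x, form="consistency")
        assert icc == pytest.approx(res.loc["ICC(C,1)", "ICC"], abs=1e-10)
        # pingouin rounds its CI bounds to two decimals
        np.testing.assert_allclose([lo, hi], res.loc["ICC(C,1)", "CI95"], atol=5.1e-3)
        icc2, lo2, hi2 = icc_two_way_mixed(x, form="agreement")
        assert icc2 == pytest.approx(res.loc["ICC(A,1)", "ICC"], abs=1e-10)
        np.testing.assert_allclose([lo2, hi2], res.loc["ICC(A,1)", "CI95"], atol=5.1e-3)

    def test_negative_estimate_clipped_with_warning(self):
        x = np.array([[0, 1], [1, 0], [0, 1], [1, 0], [0.5, 0.5]])
        with pytest.warns(UserWarning, match="clipped"):
            icc, *_ = icc_two_way_mixed(x)
        assert icc == 0.0

    def test_missing_cells_rejected(self):
        x = np.full((6, 2), 1.0)
        x[2, 1] = np.nan
        with pytest.raises(ValueError, match="missing cells"):
            icc_two_way_mixed(x)


class TestPearson:
    def test_exact_positive_linearity(self):
        x = np.arange(10.0)
        r, r2, p = pearson_correlation(x, 2 * x + 3)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_exact_negative_linearity(self):
        x = np.arange(10.0)
        r, _, _ = pearson_correlation(x, -x)
        assert r == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_correlation(np.ones(5), np.arange(5.0))

    def test_recovers_population_r_squared(self, rng):
        """Bivariate normal with rho = 0.66 at n = 30: mean r^2 ~ 0.44."""
        rho, n, reps = 0.66, 30, 2000
        r2s = np.empty(reps)
        for i in range(reps):
            x = rng.normal(size=n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
            _, r2s[i], _ = pearson_correlation(x, y)
        assert np.mean(r2s) == pytest.approx(0.44, abs=0.05)


class TestSummaries:
    def test_fully_crossed_cells(self):
        ests = []
        for subj in "abc":
            for eq in ("cylinder", "truncated_cone"):
                for iv, v in [(1.0, 1000.0), (2.0, 995.0), (3.0, 985.0), (4.0, 975.0)]:
                    ests.append(_estimate(subj, iv, v + 3 * ord(subj), eq))
        summaries = summarize_by_cell(compute_errors(ests))
        assert len(summaries) == 6
        frame = summary_to_frame(summaries)
        assert set(frame["interval_cm"]) == {2.0, 3.0, 4.0}
        assert (frame["n"] == 3).all()

    def test_single_subject_sd_zero(self):
        ests = [_estimate("a", 1.0, 1000.0), _estimate("a", 2.0, 990.0)]
        (s,) = summarize_by_cell(compute_errors(ests))
        assert s.n_total == 1
        assert s.sd_abs_error == 0.0 and s.sd_rel_error == 0.0
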