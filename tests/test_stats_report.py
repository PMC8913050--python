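"""Peak extraction, waveform correlation, paired tests and the report tables."""

import numpy as np
import pytest
from scipy.stats import t as t_dist

from aclgait.stats_report import (
    build_report,
    correlate_with_center,
    detect_stance_peaks,
    paired_ttest_vs_center,
)
from aclgait.tis_sweep import ForceCurve, SweepResult, TISOffset


def _curve(force, sid="S01", offset=None):
    return ForceCurve(sid, offset or TISOffset("center"), np.asarray(force, float))


def _bump_curve():
    """100 N bump at 12% cycle, 80 N bump at 48%."""
    t = np.linspace(0, 1, 101)
    f = 100.0 * np.exp(-0.5 * ((t - 0.12) / 0.03) ** 2)
    f += 80.0 * np.exp(-0.5 * ((t - 0.48) / 0.03) ** 2)
    return _curve(f)


class TestPeaks:
    def test_two_bump_curve(self):
        pk = detect_stance_peaks(_bump_curve(), stance_fraction=0.60, split=0.30)
        assert pk.valid
        assert pk.first_peak == pytest.approx(100.0, rel=1e-6)
        assert pk.first_peak_time == pytest.approx(0.12)
        assert pk.second_peak == pytest.approx(80.0, rel=1e-6)
        assert pk.second_peak_time == pytest.approx(0.48)
        assert pk.first_peak_time < pk.second_peak_time

    def test_all_slack_curve_invalid(self):
        pk = detect_stance_peaks(_curve(np.zeros(101)))
        assert not pk.valid
        assert np.isnan(pk.first_peak)

    def test_monotone_decreasing_peak_at_cycle_start(self):
        f = np.linspace(50.0, 0.0, 101)
        pk = detect_stance_peaks(_curve(f))
        assert pk.first_peak_time == 0.0
        assert pk.first_peak == pytest.approx(50.0)

    def test_bad_windows_rejected(self):
        with pytest.raises(ValueError):
            detect_stance_peaks(_bump_curve(), stance_fraction=0.25, split=0.30)


class TestCorrelation:
    def test_self_correlation_is_one(self):
        c = _bump_curve()
        res = correlate_with_center(c, c)
        assert res.r == pytest.approx(1.0)
        assert not res.na

    def test_perfect_anticorrelation(self):
        c = _bump_curve()
        neg = _curve(-c.force + 200.0)
        res = correlate_with_center(c, neg)
        assert res.r == pytest.approx(-1.0)

    def test_matches_sigma_formula_oracle(self):
        """Seeded pseudo-random pair vs. the textbook Σ-based formula."""
        rng = np.random.default_rng(0)
        x = rng.uniform(0.0, 100.0, 101)
        y = 0.4 * x + rng.uniform(0.0, 30.0, 101)
        n = 101
        sx, sy, sxy = x.sum(), y.sum(), (x * y).sum()
        sxx, syy = (x * x).sum(), (y * y).sum()
        r_oracle = (n * sxy - sx * sy) / np.sqrt(
            (n * sxx - sx**2) * (n * syy - sy**2)
        )
        t_stat = r_oracle * np.sqrt((n - 2) / (1 - r_oracle**2))
        p_oracle = 2.0 * t_dist.sf(abs(t_stat), n - 2)
        res = correlate_with_center(_curve(x), _curve(y))
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-10)
        assert res.n_points == 101

    def test_constant_curve_is_na(self):
        res = correlate_with_center(_bump_curve(), _curve(np.full(101, 5.0)))
        assert res.na
        res2 = correlate_with_center(_curve(np.zeros(101)), _bump_curve())
        assert res2.na

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correlate_with_center(_bump_curve(), _curve(np.ones(50)))


class TestPairedT:
    def test_identical_samples(self):
        res = paired_ttest_vs_center([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p_value == 1.0

    def test_constant_shift_flagged_zero_variance(self):
        res = paired_ttest_vs_center([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])
        assert res.zero_variance
        assert res.p_value == 0.0

    def test_matches_formula_and_cdf_oracle(self):
        """Fixed 7-pair set vs. the hand formula t = d̄ / (s_d/√n)."""
        center = np.array([71.0, 60.0, 85.0, 92.0, 55.0, 66.0, 78.0])
        offset = np.array([205.0, 190.0, 260.0, 240.0, 150.0, 210.0, 231.0])
        d = offset - center
        n = d.size
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(n))
        p_oracle = 2.0 * t_dist.sf(abs(t_oracle), n - 1)
        res = paired_ttest_vs_center(center, offset)
        assert res.t == pytest.approx(t_oracle, abs=1e-10)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-10)
        assert res.mean_center == pytest.approx(center.mean())
        assert res.sd_offset == pytest.approx(offset.std(ddof=1))

    def test_pairwise_exclusion_and_na_below_two(self):
        res = paired_ttest_vs_center([1.0, np.nan, 3.0], [np.nan, 2.0, 4.0])
        assert res.na
        assert res.n < 2


class TestReport:
    def test_mean_column_recomputes(self, default_sweep):
        table = build_report(default_sweep)
        col = ("anterior", 2.5)
        subject_rows = table.corr_wide[col].dropna()
        assert table.corr_wide[col].mean(skipna=True) == pytest.approx(
            subject_rows.sum() / len(subject_rows), abs=1e-12
        )

    def test_posterior_slack_rendered_na(self, default_sweep, tmp_path):
        table = build_report(default_sweep)
        paths = table.write(tmp_path)
        text2 = paths[0].read_text()
        assert "N/A" in text2
        summary = table.peak_summary.set_index(["direction", "magnitude_mm"])
        for mag in (5.0, 7.5):
            assert summary.loc[("posterior", mag), "first_peak_sig"] == "N/A"
            assert np.isnan(summary.loc[("posterior", mag), "first_peak_mean_N"])

    def test_center_column_r_is_one(self, default_sweep):
        table = build_report(default_sweep)
        assert np.allclose(table.corr_wide[("center", 0.0)].to_numpy(), 1.0)

    def test_single_subject_ttests_na(self, default_sweep):
        one = SweepResult(
            curves=[c for c in default_sweep.curves if c.subject_id == "S01"],
            manifest={},
        )
        table = build_report(one)
        non_center = table.peak_summary[table.peak_summary["direction"] != "center"]
        taut = non_center[non_center["first_peak_mean_N"].notna()]
        assert (taut["first_peak_sig"] == "N/A").all()

    def test_missing_cell_listed(self, default_sweep):
        broken = SweepResult(curves=default_sweep.curves[:-1], manifest={})
        with pytest.raises(ValueError, match="missing cells.*S07"):
            build_report(broken)

    def test_mean_correlation_decays_with_offset_distance(self, default_sweep):
        """Larger displacement distorts the waveform more (as in the study)."""
        table = build_report(default_sweep)
        for direction in ("anterior", "medial", "lateral"):
            means = [
                table.corr_wide[(direction, m)].mean(skipna=True)
                for m in (2.5, 5.0, 7.5)
            ]
            assert means[0] > means[1] > means[2], (direction, means)

    def test_report_markdown_contains_tables_and_notes(self, default_sweep, tmp_path):
        table = build_report(default_sweep)
        _, _, report_md = table.write(tmp_path)
        text = report_md.read_text()
        assert "| " in text and "N/A" in text
        assert "no multiple-testing correction" in text.lower()

    def test_plot_smoke(self, default_sweep, tmp_path):
        from aclgait.stats_report import plot_force_curves

        out = plot_force_curves(default_sweep, tmp_path / "anterior.png")
        assert out.exists() and out.stat().st_size > 0

    def test_significance_stars_reproduce_from_p_values(self, default_sweep, tmp_path):
        """Rendered stars are a pure function of the stored p-values."""
        import pandas as pd

        table = build_report(default_sweep)
        table2_path, _, _ = table.write(tmp_path)
        rendered = pd.read_csv(table2_path, header=[0, 1], index_col=0)
        for _, row in table.correlations.iterrows():
            if row["na"]:
                continue
            cell = str(rendered.loc[row["subject_id"]][
                (row["direction"], str(row["magnitude_mm"]))
            ])
            want = "**" if row["p_value"] < 0.01 else "*" if row["p_value"] < 0.05 else ""
            assert cell.endswith(want) and cell.count("*") == len(want), (row, cell)
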