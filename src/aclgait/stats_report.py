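"""Analysis layer: stance-phase peaks, curve correlations, paired tests, tables.

Two force peaks occur in the stance phase of a taut graft — one at initial
contact, one at terminal stance — so peaks are extracted as maxima over the
early-stance window [0, split] and the late-stance window (split,
stance_fraction], split defaulting to 30% of the cycle.  Each offset
condition's 101-point force curve is compared to the centre condition by
sample Pearson correlation (two-sided p from the t transform with n-2 df),
and stance-phase peaks are compared to the centre with paired t-tests.
Conditions in which the graft never tensions (all-slack) are reported as
N/A, never as zero-valued statistics, and slack pairs are excluded pairwise
from the t-tests.  No multiple-testing correction is applied; raw p-values
are reported against the 0.05 and 0.01 levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .tis_sweep import DIRECTIONS, ForceCurve, SweepResult, TISOffset

__all__ = [
    "PeakResult",
    "CorrelationResult",
    "TTestResult",
    "ComparisonTable",
    "detect_stance_peaks",
    "correlate_with_center",
    "paired_ttest_vs_center",
    "build_report",
    "plot_force_curves",
]


@dataclass(frozen=True)
class PeakResult:
    subject_id: str
    offset: TISOffset
    first_peak: float
    first_peak_time: float
    second_peak: float
    second_peak_time: float
    valid: bool


@dataclass(frozen=True)
class CorrelationResult:
    subject_id: str
    offset: TISOffset
    r: float
    p_value: float
    n_points: int
    na: bool


@dataclass(frozen=True)
class TTestResult:
    t: float
    p_value: float
    n: int
    mean_center: float
    sd_center: float
    mean_offset: float
    sd_offset: float
    na: bool
    zero_variance: bool = False


def detect_stance_peaks(
    curve: ForceCurve, stance_fraction: float = 0.60, split: float = 0.30
) -> PeakResult:
    """First (initial-contact) and second (terminal-stance) force peaks.

    ``first_peak`` is the maximum over cycle fractions [0, split],
    ``second_peak`` over (split, stance_fraction].  All-slack curves return
    ``valid=False`` with NaN peaks.
    """
    if stance_fraction <= split:
        raise ValueError("stance_fraction must exceed the peak-window split")
    if curve.all_slack:
        return PeakResult(
            curve.subject_id, curve.offset, np.nan, np.nan, np.nan, np.nan, valid=False
        )
    t = curve.cycle_time
    w1 = t <= split
    w2 = (t > split) & (t <= stance_fraction)
    i1 = int(np.argmax(curve.force[w1]))
    idx2 = np.flatnonzero(w2)
    i2 = int(idx2[np.argmax(curve.force[idx2])])
    return PeakResult(
        subject_id=curve.subject_id,
        offset=curve.offset,
        first_peak=float(curve.force[w1][i1]),
        first_peak_time=float(t[w1][i1]),
        second_peak=float(curve.force[i2]),
        second_peak_time=float(t[i2]),
        valid=True,
    )


def correlate_with_center(
    center_curve: ForceCurve, offset_curve: ForceCurve
) -> CorrelationResult:
    """Sample Pearson correlation of the two force waveforms over all samples."""
    if center_curve.n_points != offset_curve.n_points:
        raise ValueError("curves must have the same number of samples")
    x, y = center_curve.force, offset_curve.force
    degenerate = (
        center_curve.all_slack
        or offset_curve.all_slack
        or np.ptp(x) == 0
        or np.ptp(y) == 0
    )
    if degenerate:
        return CorrelationResult(
            offset_curve.subject_id, offset_curve.offset, np.nan, np.nan,
            center_curve.n_points, na=True,
        )
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(
        subject_id=offset_curve.subject_id,
        offset=offset_curve.offset,
        r=float(r),
        p_value=float(p),
        n_points=center_curve.n_points,
        na=False,
    )


def paired_ttest_vs_center(peaks_center, peaks_offset) -> TTestResult:
    """Classical paired t-test on per-subject peak forces vs. the centre.

    Pairs with a missing (NaN, i.e. slack) member are excluded pairwise;
    with fewer than 2 remaining pairs the result is N/A.  Zero-variance
    differences with a non-zero mean are reported with p = 0 and flagged.
    """
    x = np.asarray(peaks_center, dtype=float)
    y = np.asarray(peaks_offset, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 2:
        return TTestResult(np.nan, np.nan, n, np.nan, np.nan, np.nan, np.nan, na=True)
    mc, sc = float(np.mean(x)), float(np.std(x, ddof=1))
    mo, so = float(np.mean(y)), float(np.std(y, ddof=1))
    d = y - x
    if np.std(d, ddof=1) == 0.0:
        if np.mean(d) == 0.0:
            return TTestResult(0.0, 1.0, n, mc, sc, mo, so, na=False)
        return TTestResult(
            float(np.inf * np.sign(np.mean(d))), 0.0, n, mc, sc, mo, so,
            na=False, zero_variance=True,
        )
    t, p = sps.ttest_rel(y, x)
    return TTestResult(float(t), float(p), n, mc, sc, mo, so, na=False)


def _md_table(df: pd.DataFrame, index: bool = False) -> str:
    """Minimal GitHub-style markdown rendering of a small table."""
    d = df.reset_index() if index else df
    if isinstance(d.columns, pd.MultiIndex):
        d = d.copy()
        d.columns = [" ".join(str(x) for x in col if str(x) != "") for col in d.columns]
    cells = d.map(lambda v: "" if pd.isna(v) else (f"{v:g}" if isinstance(v, float) else str(v)))
    header = [str(c) for c in cells.columns]
    lines = ["| " + " | ".join(header) + " |",
             "| " + " | ".join("---" for _ in header) + " |"]
    for _, row in cells.iterrows():
        lines.append("| " + " | ".join(row.tolist()) + " |")
    return "\n".join(lines)


def _stars(p: float, alpha: float, alpha_strong: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < alpha_strong:
        return "**"
    if p < alpha:
        return "*"
    return ""


@dataclass
class ComparisonTable:
    """Correlation and peak tables in the layout of a TIS-sweep report."""

    correlations: pd.DataFrame  # tidy: subject, direction, magnitude, r, p, na
    corr_wide: pd.DataFrame  # subjects x (direction, magnitude), r values
    peaks: pd.DataFrame  # tidy per-subject peak table
    peak_summary: pd.DataFrame  # per-offset mean/SD + t-test vs center
    notes: list[str]

    def write(self, out_dir: str | Path, alpha: float = 0.05, alpha_strong: float = 0.01):
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)

        rendered = self.corr_wide.copy().astype(object)
        pmat = self.correlations.pivot_table(
            index="subject_id", columns=["direction", "magnitude_mm"],
            values="p_value", aggfunc="first", dropna=False,
        )
        for col in rendered.columns:
            for idx in rendered.index:
                r = rendered.loc[idx, col]
                if pd.isna(r):
                    rendered.loc[idx, col] = "N/A"
                else:
                    p = pmat.loc[idx, col] if col in pmat.columns else np.nan
                    rendered.loc[idx, col] = f"{r:.3f}{_stars(p, alpha, alpha_strong)}"
        mean_row = self.corr_wide.mean(axis=0, skipna=True)
        rendered.loc["Mean"] = [
            "N/A" if pd.isna(v) else f"{v:.3f}" for v in mean_row
        ]
        table2 = out_dir / "table2_correlations.csv"
        rendered.to_csv(table2)

        table3 = out_dir / "table3_peaks.csv"
        self.peak_summary.to_csv(table3, index=False, float_format="%.9g")

        report = out_dir / "report.md"
        lines = ["# TIS sweep report", ""]
        lines.append("## Correlation of force curves vs. center (Table-2 layout)")
        lines.append("")
        lines.append(_md_table(rendered, index=True))
        lines.append("")
        lines.append("## Stance-phase peak forces (Table-3 layout)")
        lines.append("")
        lines.append(_md_table(self.peak_summary))
        lines.append("")
        for note in self.notes:
            lines.append(f"- {note}")
        report.write_text("\n".join(lines) + "\n")
        return table2, table3, report


def _group_curves(sweep: SweepResult) -> dict[str, dict[str, ForceCurve]]:
    by_subject: dict[str, dict[str, ForceCurve]] = {}
    for c in sweep.curves:
        by_subject.setdefault(c.subject_id, {})[c.offset.label] = c
    return by_subject


def build_report(
    sweep: SweepResult,
    stance_fraction: float = 0.60,
    split: float = 0.30,
    alpha: float = 0.05,
    alpha_strong: float = 0.01,
    ultimate_force_annotation: float = 600.0,
) -> ComparisonTable:
    """Assemble the per-subject correlation table and the peak-force summary.

    Requires a complete sweep: every subject must carry the same set of
    offset conditions, including the centre.  Mean peak forces exceeding the
    literature ultimate-force annotation (default 600 N, the lower end of
    the cadaveric failure range) are flagged in the notes — annotation only,
    no failure is modelled.
    """
    by_subject = _group_curves(sweep)
    if not by_subject:
        raise ValueError("sweep is empty")
    all_labels = sorted({lbl for curves in by_subject.values() for lbl in curves})
    missing = [
        (sid, lbl)
        for sid, curves in by_subject.items()
        for lbl in all_labels
        if lbl not in curves
    ]
    if "center" not in all_labels:
        missing.append(("<all>", "center"))
    if missing:
        raise ValueError(f"incomplete sweep; missing cells: {missing}")

    corr_rows, peak_rows = [], []
    for sid in sorted(by_subject):
        curves = by_subject[sid]
        center = curves["center"]
        for lbl in all_labels:
            c = curves[lbl]
            pk = detect_stance_peaks(c, stance_fraction, split)
            peak_rows.append(
                {
                    "subject_id": sid,
                    "direction": c.offset.direction,
                    "magnitude_mm": c.offset.magnitude_mm,
                    "first_peak_N": pk.first_peak,
                    "first_peak_time": pk.first_peak_time,
                    "second_peak_N": pk.second_peak,
                    "second_peak_time": pk.second_peak_time,
                    "valid": pk.valid,
                }
            )
            cr = correlate_with_center(center, c)
            corr_rows.append(
                {
                    "subject_id": sid,
                    "direction": c.offset.direction,
                    "magnitude_mm": c.offset.magnitude_mm,
                    "r": cr.r,
                    "p_value": cr.p_value,
                    "na": cr.na,
                }
            )
    correlations = pd.DataFrame(corr_rows)
    peaks = pd.DataFrame(peak_rows)

    order = [
        (d, m)
        for d in DIRECTIONS
        for m in sorted(peaks.loc[peaks["direction"] == d, "magnitude_mm"].unique())
    ]
    corr_wide = correlations.pivot_table(
        index="subject_id", columns=["direction", "magnitude_mm"], values="r",
        aggfunc="first", dropna=False,
    )
    corr_wide = corr_wide.reindex(columns=pd.MultiIndex.from_tuples(order))

    center_first = peaks[peaks["direction"] == "center"].set_index("subject_id")
    summary_rows = []
    notes = [
        "N/A: no ACL force generated at this position during gait (slack graft).",
        "Raw p-values; no multiple-testing correction across the offset comparisons.",
        f"Peak significance vs. center: * p < {alpha}, ** p < {alpha_strong} (paired t).",
    ]
    for direction, mag in order:
        sub = peaks[(peaks["direction"] == direction) & (peaks["magnitude_mm"] == mag)]
        sub = sub.set_index("subject_id").reindex(center_first.index)
        row: dict = {"direction": direction, "magnitude_mm": mag}
        for which in ("first", "second"):
            vals = sub[f"{which}_peak_N"]
            if vals.notna().sum() == 0:
                row[f"{which}_peak_mean_N"] = np.nan
                row[f"{which}_peak_sd_N"] = np.nan
                row[f"{which}_peak_sig"] = "N/A"
                continue
            tt = paired_ttest_vs_center(center_first[f"{which}_peak_N"], vals)
            row[f"{which}_peak_mean_N"] = float(vals.mean(skipna=True))
            row[f"{which}_peak_sd_N"] = (
                float(vals.std(ddof=1, skipna=True)) if vals.notna().sum() > 1 else np.nan
            )
            if direction == "center":
                row[f"{which}_peak_sig"] = ""
            elif tt.na:
                row[f"{which}_peak_sig"] = "N/A"
            else:
                row[f"{which}_peak_sig"] = _stars(tt.p_value, alpha, alpha_strong)
                row[f"{which}_peak_p"] = tt.p_value
            if row[f"{which}_peak_mean_N"] > ultimate_force_annotation:
                notes.append(
                    f"{direction} {mag:g} mm mean {which} peak "
                    f"{row[f'{which}_peak_mean_N']:.1f} N exceeds the literature "
                    f"ultimate-force annotation ({ultimate_force_annotation:g} N)."
                )
        summary_rows.append(row)
    peak_summary = pd.DataFrame(summary_rows)

    return ComparisonTable(
        correlations=correlations,
        corr_wide=corr_wide,
        peaks=peaks,
        peak_summary=peak_summary,
        notes=notes,
    )


def plot_force_curves(sweep: SweepResult, out_path: str | Path, direction: str = "anterior"):
    """Mean force vs. cycle % per magnitude, with the centre-condition SD band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = sweep.to_frame()
    fig, ax = plt.subplots(figsize=(7, 4.5))
    center = df[df["direction"] == "center"].groupby("cycle_pct")["force_N"]
    ax.fill_between(
        center.mean().index,
        center.mean() - center.std(),
        center.mean() + center.std(),
        alpha=0.25,
        label="center ± SD",
    )
    ax.plot(center.mean().index, center.mean(), "k-", label="center")
    sub = df[df["direction"] == direction]
    for mag, grp in sub.groupby("magnitude_mm"):
        m = grp.groupby("cycle_pct")["force_N"].mean()
        ax.plot(m.index, m.values, label=f"{direction} {mag:g} mm")
    ax.set_xlabel("gait cycle (%)")
    ax.set_ylabel("ACL force (N)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
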