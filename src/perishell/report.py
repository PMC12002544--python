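"""Result tables, plot-data exports, and the sensitivity summary.

Tables mirror the study's reporting conventions: group-level cells are
``median (min; max)`` of subject means at two decimals, the lesion-level
shell table is ``mean (SD)`` across lesions for lesion, PL, and shells
1-3, and p-value columns carry a ``*`` marker exactly where the BH-FDR
procedure rejects.  Plot rendering is deliberately separated from data
export: the testable surface is the CSV/JSON data files, not pixels.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .extract import group_level_medians
from .volume import BIOMARKERS, BIOMARKER_UNITS

__all__ = [
    "export_plot_data",
    "make_group_tables",
    "make_shell_table",
    "sensitivity_summary",
]

#: Biomarkers whose lesion values sit above (+1) or below (-1) their PL
#: values within every patient; used by the sign-structure diagnostics.
EXPECTED_SIGN = {
    "MWF": -1, "MTsat": -1, "ihMTR": -1, "T1wT2w": -1,
    "qT1": 1, "qT2": 1, "qT2star": 1, "PD": 1, "QSM": 1,
}


def _fmt(x: float, digits: int = 2) -> str:
    return f"{x:.{digits}f}"


def _cell(med: float, lo: float, hi: float) -> str:
    return f"{_fmt(med)} ({_fmt(lo)}; {_fmt(hi)})"


def _row_label(bm: str) -> str:
    unit = BIOMARKER_UNITS[bm]
    return f"{bm} [{unit}]" if unit else bm


def _pcol(battery: pd.DataFrame, contrast: str, bm: str) -> str:
    if battery.empty:
        return "-"
    sel = battery[(battery["contrast"] == contrast) & (battery["biomarker"] == bm)]
    if sel.empty:
        return "-"
    row = sel.iloc[0]
    mark = "*" if bool(row["reject_fdr"]) else ""
    return f"{row['p']:.3f}{mark}"


def make_group_tables(
    cohort: pd.DataFrame, battery: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Formatted group-level tables.

    The first table compares HC and normal-appearing MS tissue (GM and
    WM columns with the group-contrast p-values); the second lists the
    MS tissue types (lesion, PL, NAWM, NAGM) with the five within-MS
    contrast p-values.  Missing cells render as ``-``.
    """
    med = group_level_medians(cohort)

    def cell(group: str, voi: str, bm: str) -> str:
        sel = med[
            (med["group"] == group) & (med["voi"] == voi) & (med["biomarker"] == bm)
        ]
        if sel.empty:
            return "-"
        r = sel.iloc[0]
        return _cell(r["median"], r["min"], r["max"])

    rows_hc = []
    rows_ms = []
    for bm in BIOMARKERS:
        rows_hc.append(
            {
                "biomarker": _row_label(bm),
                "HCGM": cell("HC", "GM", bm),
                "NAGM": cell("MS", "NAGM", bm),
                "p_GM": _pcol(battery, "HCGM_vs_NAGM", bm),
                "HCWM": cell("HC", "WM", bm),
                "NAWM": cell("MS", "NAWM", bm),
                "p_WM": _pcol(battery, "HCWM_vs_NAWM", bm),
            }
        )
        rows_ms.append(
            {
                "biomarker": _row_label(bm),
                "lesion": cell("MS", "avgLesion", bm),
                "PL": cell("MS", "avgPL", bm),
                "NAWM": cell("MS", "NAWM", bm),
                "NAGM": cell("MS", "NAGM", bm),
                "p_lesion_vs_PL": _pcol(battery, "lesion_vs_PL", bm),
                "p_lesion_vs_NAWM": _pcol(battery, "lesion_vs_NAWM", bm),
                "p_lesion_vs_NAGM": _pcol(battery, "lesion_vs_NAGM", bm),
                "p_PL_vs_NAWM": _pcol(battery, "PL_vs_NAWM", bm),
                "p_PL_vs_NAGM": _pcol(battery, "PL_vs_NAGM", bm),
            }
        )
    hc_table = pd.DataFrame(rows_hc)
    ms_table = pd.DataFrame(rows_ms)
    if cohort[cohort["group"] == "MS"].empty:
        ms_table = ms_table.iloc[0:0]
        hc_table = hc_table[["biomarker", "HCGM", "HCWM"]]
    return hc_table, ms_table


def shell_stats(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric mean/SD of per-lesion means per (biomarker, ring class)."""
    les = cohort[cohort["level"] == "lesion"]
    if les.empty:
        return pd.DataFrame(columns=["biomarker", "voi", "mean", "sd", "n_lesions"])
    return (
        les.groupby(["biomarker", "voi"])["value"]
        .agg(mean="mean", sd=lambda v: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
             n_lesions="count")
        .reset_index()
    )


def make_shell_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Lesion-level table: ``mean (SD)`` across lesions per ring class."""
    stats = shell_stats(cohort)
    rows = []
    for bm in BIOMARKERS:
        row = {"biomarker": _row_label(bm)}
        for voi, col in (
            ("lesion", "lesion"), ("pl", "PL"), ("shell1", "shell1"),
            ("shell2", "shell2"), ("shell3", "shell3"),
        ):
            sel = stats[(stats["biomarker"] == bm) & (stats["voi"] == voi)]
            if sel.empty:
                row[col] = "-"
            else:
                r = sel.iloc[0]
                row[col] = f"{_fmt(r['mean'])} ({_fmt(r['sd'])})"
        rows.append(row)
    return pd.DataFrame(rows)


def export_plot_data(cohort: pd.DataFrame, outdir: str | Path) -> dict[str, Path]:
    """Write tidy plot-data files: boxplot, line plot, violin, spider.

    * boxplot: one subject mean per (group, biomarker, VOI),
    * lineplot: per-MS-subject trajectories over avgLesion, avgPL, NAWM,
      NAGM plus the cohort mean trajectory,
    * violin: one per-lesion mean per (biomarker, ring class),
    * spider: cohort medians per biomarker in HCWM, NAWM, avgPL, avgLesion.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    subj = cohort[cohort["level"] == "subject"].copy()
    box = subj[["group", "subject", "biomarker", "voi", "value"]].sort_values(
        ["biomarker", "voi", "group", "subject"]
    )
    paths["boxplot"] = outdir / "boxplot.csv"
    box.to_csv(paths["boxplot"], index=False)

    traj_vois = ["avgLesion", "avgPL", "NAWM", "NAGM"]
    ms = subj[(subj["group"] == "MS") & (subj["voi"].isin(traj_vois))]
    line = ms.pivot_table(index=["biomarker", "subject"], columns="voi", values="value")
    line = line.reindex(columns=traj_vois).reset_index()
    if not line.empty:
        mean_rows = (
            line.groupby("biomarker")[traj_vois].mean().reset_index()
        )
        mean_rows.insert(1, "subject", "cohort_mean")
        line = pd.concat([line, mean_rows], ignore_index=True)
    line = line.sort_values(["biomarker", "subject"])
    paths["lineplot"] = outdir / "lineplot.csv"
    line.to_csv(paths["lineplot"], index=False)

    les = cohort[cohort["level"] == "lesion"]
    violin = les[["subject", "lesion_id", "biomarker", "voi", "value"]].sort_values(
        ["biomarker", "voi", "subject", "lesion_id"]
    )
    paths["violin"] = outdir / "violin.csv"
    violin.to_csv(paths["violin"], index=False)

    med = group_level_medians(cohort)
    spider_cells = [("HC", "WM", "HCWM"), ("MS", "NAWM", "NAWM"),
                    ("MS", "avgPL", "avgPL"), ("MS", "avgLesion", "avgLesion")]
    rows = []
    for bm in sorted(med["biomarker"].unique()):
        row = {"biomarker": bm}
        for group, voi, label in spider_cells:
            sel = med[(med["group"] == group) & (med["voi"] == voi)
                      & (med["biomarker"] == bm)]
            row[label] = float(sel.iloc[0]["median"]) if not sel.empty else np.nan
        rows.append(row)
    paths["spider"] = outdir / "spider.csv"
    pd.DataFrame(rows).to_csv(paths["spider"], index=False)
    return paths


def sensitivity_summary(
    cohort: pd.DataFrame,
    battery: pd.DataFrame,
    heterogeneity_threshold: float = 1.5,
) -> pd.DataFrame:
    """Per-biomarker diagnostic profile.

    For each biomarker: (a) whether the three lesion-ring contrasts
    (lesion vs PL, lesion vs NAWM, PL vs NAWM) are all FDR-significant;
    (b) the signed relative difference of the NAWM vs HCWM group medians
    and its rank by magnitude; (c) a heterogeneity flag set when the
    across-lesion SD in the lesion core exceeds ``heterogeneity_threshold``
    times the SD in shell 3.
    """
    med = group_level_medians(cohort)
    sstats = shell_stats(cohort)
    lesion_contrasts = ("lesion_vs_PL", "lesion_vs_NAWM", "PL_vs_NAWM")
    rows = []
    for bm in BIOMARKERS:
        rec: dict = {"biomarker": bm}
        flags = []
        for contrast in lesion_contrasts:
            sel = battery[
                (battery["contrast"] == contrast) & (battery["biomarker"] == bm)
            ]
            flags.append(bool(sel.iloc[0]["reject_fdr"]) if not sel.empty else False)
        rec["lesion_detection"] = all(flags)

        hc = med[(med["group"] == "HC") & (med["voi"] == "WM") & (med["biomarker"] == bm)]
        msn = med[
            (med["group"] == "MS") & (med["voi"] == "NAWM") & (med["biomarker"] == bm)
        ]
        if hc.empty or msn.empty:
            rec["nawm_abs_diff"] = np.nan
            rec["nawm_rel_diff_pct"] = np.nan
        else:
            h, m = float(hc.iloc[0]["median"]), float(msn.iloc[0]["median"])
            rec["nawm_abs_diff"] = m - h
            rec["nawm_rel_diff_pct"] = 100.0 * (m - h) / h if h != 0 else np.nan

        les_sd = sstats[(sstats["biomarker"] == bm) & (sstats["voi"] == "lesion")]
        s3_sd = sstats[(sstats["biomarker"] == bm) & (sstats["voi"] == "shell3")]
        if not s3_sd.empty:
            # an SD at round-off level relative to the mean is effectively
            # zero (identical lesion means summed over different voxel
            # counts differ in the last ulp)
            r = s3_sd.iloc[0]
            tol = 1e-9 * max(1.0, abs(float(r["mean"])))
            s3_value = float(r["sd"]) if float(r["sd"]) > tol else 0.0
        if les_sd.empty or s3_sd.empty or s3_value == 0:
            rec["lesion_sd_ratio"] = np.nan
            rec["heterogeneous_lesions"] = False
        else:
            ratio = float(les_sd.iloc[0]["sd"]) / s3_value
            rec["lesion_sd_ratio"] = ratio
            rec["heterogeneous_lesions"] = ratio > heterogeneity_threshold
        rows.append(rec)
    out = pd.DataFrame(rows)
    mags = out["nawm_rel_diff_pct"].abs()
    out["nawm_diff_rank"] = mags.rank(ascending=False, method="min").astype("Int64")
    return out


def write_report_bundle(
    cohort: pd.DataFrame,
    battery: pd.DataFrame,
    outdir: str | Path,
    heterogeneity_threshold: float = 1.5,
) -> dict[str, Path]:
    """Write all tables, plot-data files, and the sensitivity summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    hc_table, ms_table = make_group_tables(cohort, battery)
    paths["group_table_hc_vs_ms"] = outdir / "group_table_hc_vs_ms.csv"
    hc_table.to_csv(paths["group_table_hc_vs_ms"], index=False)
    paths["group_table_ms_tissues"] = outdir / "group_table_ms_tissues.csv"
    ms_table.to_csv(paths["group_table_ms_tissues"], index=False)
    paths["shell_table"] = outdir / "shell_table.csv"
    make_shell_table(cohort).to_csv(paths["shell_table"], index=False)
    paths.update(export_plot_data(cohort, outdir / "plots"))
    summary = sensitivity_summary(cohort, battery, heterogeneity_threshold)
    paths["sensitivity"] = outdir / "sensitivity_summary.csv"
    summary.to_csv(paths["sensitivity"], index=False)
    paths["battery"] = outdir / "stats.csv"
    battery.to_csv(paths["battery"], index=False)
    paths["cohort_table"] = outdir / "cohort_table.csv"
    cohort.to_csv(paths["cohort_table"], index=False)
    return paths


def render_figures(plot_dir: str | Path, outdir: str | Path) -> list[Path]:
    """Render PNG figures from previously exported plot-data files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plot_dir, outdir = Path(plot_dir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    box_path = plot_dir / "boxplot.csv"
    if box_path.exists():
        box = pd.read_csv(box_path)
        for bm, grp in box.groupby("biomarker"):
            fig, ax = plt.subplots(figsize=(6, 4))
            keys = sorted(grp.groupby(["group", "voi"]).groups)
            data = [grp[(grp["group"] == g) & (grp["voi"] == v)]["value"] for g, v in keys]
            ax.boxplot(data, tick_labels=[f"{g}:{v}" for g, v in keys])
            ax.set_title(bm)
            ax.set_ylabel(BIOMARKER_UNITS.get(bm, ""))
            path = outdir / f"boxplot_{bm}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
    return written
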