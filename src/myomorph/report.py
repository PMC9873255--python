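"""Figure-style summary reports: group tables (mean ± SD) and overview plots."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ReconciliationError
from .stats import normalize_cohort_to_sham

__all__ = ["ReportBundle", "build_report"]

_GROUP_COLS = ["sex", "genotype", "treatment", "timepoint"]

#: responses summarized when present in the cohort table
_DEFAULT_RESPONSES = [
    "body_mass_g",
    "ss_mass_mg",
    "is_mass_mg",
    "ta_mass_mg",
    "fiber_number",
    "fiber_length_cm",
    "csa_2a_um2",
    "csa_2b_um2",
    "p0_n",
    "specific_tension_n_cm2",
]


@dataclass
class ReportBundle:
    """Named summary tables plus an optional directory of rendered files."""

    tables: dict[str, pd.DataFrame]
    figures: dict[str, "object"] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        index = {}
        for name, table in self.tables.items():
            path = out / f"{name}.csv"
            table.to_csv(path, index=False)
            index[name] = path.name
        for name, fig in self.figures.items():
            path = out / f"{name}.png"
            fig.savefig(path, dpi=120)
            index[name] = path.name
        (out / "report_index.json").write_text(json.dumps(index, indent=2))
        return out


def _group_summary(df: pd.DataFrame, response: str) -> pd.DataFrame:
    grouped = df.groupby(_GROUP_COLS, observed=False)[response]
    summary = grouped.agg(n="count", mean="mean", sd="std").reset_index()
    summary["mean_sd"] = [
        f"{m:.4g} ± {s:.4g}" if np.isfinite(s) else f"{m:.4g} ± n/a"
        for m, s in zip(summary["mean"], summary["sd"])
    ]
    summary.insert(0, "response", response)
    return summary


def build_report(
    cohort: pd.DataFrame,
    metrics: pd.DataFrame | None = None,
    decompositions: pd.DataFrame | None = None,
    stats: dict | None = None,
    responses: list[str] | None = None,
    make_figures: bool = False,
) -> ReportBundle:
    """Assemble per-figure-style summary tables from the analysis outputs.

    All tables report group mean ± standard deviation per design cell.
    Tables sharing ``animal_id`` must agree on the id set; orphan ids
    raise :class:`ReconciliationError`.
    """
    for other in (metrics, decompositions):
        if other is not None and "animal_id" in other.columns:
            cohort_ids = set(cohort["animal_id"])
            other_ids = set(other["animal_id"])
            orphans = other_ids - cohort_ids
            if orphans:
                raise ReconciliationError(orphans)

    responses = responses or [c for c in _DEFAULT_RESPONSES if c in cohort.columns]
    tables: dict[str, pd.DataFrame] = {}
    tables["group_summaries"] = pd.concat(
        [_group_summary(cohort, r) for r in responses], ignore_index=True
    )

    # sham-normalized masses per sex (the study's primary mass panel)
    norm = cohort.copy()
    try:
        norm["ss_mass_norm"] = normalize_cohort_to_sham(cohort, "ss_mass_mg")
        tables["normalized_ss_mass"] = _group_summary(norm, "ss_mass_norm")
    except Exception:  # no sham cells for some groups: leave an explicit gap
        tables["normalized_ss_mass"] = pd.DataFrame(
            columns=["response", *_GROUP_COLS, "n", "mean", "sd", "mean_sd"]
        )

    if decompositions is not None and not decompositions.empty:
        share_cols = [c for c in decompositions.columns if c.startswith("share_")]
        shares = (
            decompositions.groupby(["sex", "timepoint"], observed=False)[
                share_cols + ["predicted_deficit", "measured_deficit"]
            ]
            .agg(["mean", "std"])
            .reset_index()
        )
        shares.columns = ["_".join(c).rstrip("_") for c in shares.columns]
        tables["contribution_shares"] = shares

    if metrics is not None and not metrics.empty:
        tables["section_metrics"] = metrics.copy()

    if stats:
        rows = []
        for name, result in stats.items():
            for term, rec in result.anova_table.iterrows():
                if term == "Residual":
                    continue
                rows.append(
                    {
                        "analysis": name,
                        "term": term,
                        "F": rec.get("F", np.nan),
                        "p": rec.get("PR(>F)", np.nan),
                    }
                )
        tables["anova_effects"] = pd.DataFrame(rows)

    figures = {}
    if make_figures:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if "normalized_ss_mass" in tables and not tables["normalized_ss_mass"].empty:
            fig, ax = plt.subplots(figsize=(6, 4))
            t = tables["normalized_ss_mass"]
            for sex, sub in t.groupby("sex"):
                sub = sub[sub["treatment"] == "TEN"]
                ax.errorbar(
                    sub["timepoint"], sub["mean"], yerr=sub["sd"], label=sex, marker="o"
                )
            ax.axhline(1.0, color="gray", ls=":")
            ax.set_ylabel("SS mass (fraction of sex-matched sham)")
            ax.legend(title="sex")
            figures["normalized_mass"] = fig
        if decompositions is not None and "contribution_shares" in tables:
            fig, ax = plt.subplots(figsize=(6, 4))
            t = tables["contribution_shares"]
            labels = t["sex"] + " " + t["timepoint"]
            bottom = np.zeros(len(t))
            for col, color in (
                ("share_fiber_length_mean", "0.3"),
                ("share_fiber_number_mean", "0.6"),
                ("share_fiber_csa_mean", "0.9"),
            ):
                if col in t.columns:
                    ax.bar(labels, t[col], bottom=bottom, color=color,
                           label=col.replace("share_", "").replace("_mean", ""))
                    bottom += t[col].to_numpy()
            ax.set_ylabel("fraction of predicted mass deficit")
            ax.legend()
            figures["contribution_shares"] = fig

    return ReportBundle(tables=tables, figures=figures)
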