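"""Normalization schemes and factorial statistics.

Outcomes are normalized either to the sham-group mean of the same sex
(and genotype/timepoint where applicable) or, per animal, to a reference
mass such as the intact tibialis anterior or body mass.  Group
comparisons use full-factorial n-way ANOVA (type-II sums of squares, the
standard choice for mildly unbalanced cell counts) with Sidak-corrected
pairwise contrasts for two-way designs and Benjamini–Hochberg FDR for
three-way designs.  Normality is checked with Shapiro–Wilk and reported,
never auto-switched to a nonparametric fallback.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DegenerateInputError, InputError

__all__ = [
    "StatResult",
    "normalize_to_sham",
    "normalize_cohort_to_sham",
    "ratio_normalize",
    "adjust_pvalues",
    "nway_anova",
    "shapiro_wilk",
]


def normalize_to_sham(values, sham_values):
    """Divide ``values`` by the mean of the sham group.

    The sham group itself then has mean exactly 1.
    """
    sham = np.asarray(sham_values, dtype=float)
    if sham.size == 0:
        raise InputError("empty sham group")
    mean = sham.mean()
    if mean == 0:
        raise InputError("sham mean is zero")
    return np.asarray(values, dtype=float) / mean


def normalize_cohort_to_sham(
    df: pd.DataFrame,
    column: str,
    by: tuple[str, ...] = ("sex", "genotype", "timepoint"),
    treatment_col: str = "treatment",
    sham_level: str = "SHM",
) -> pd.Series:
    """Per-cell sham normalization of one cohort column.

    Every value is divided by the sham mean of its own ``by`` cell
    (sex-matched, and genotype/timepoint-matched where those factors are
    present in ``by``).
    """
    sham = df[df[treatment_col] == sham_level]
    if sham.empty:
        raise InputError("cohort contains no sham animals")
    means = sham.groupby(list(by))[column].mean()
    keys = pd.MultiIndex.from_frame(df[list(by)])
    denom = means.reindex(keys).to_numpy()
    if np.any(~np.isfinite(denom)):
        missing = sorted({k for k, d in zip(keys, denom) if not np.isfinite(d)})
        raise InputError(f"no sham animals for cells: {missing}")
    return pd.Series(df[column].to_numpy() / denom, index=df.index, name=f"{column}_norm")


def ratio_normalize(mass, reference_mass):
    """Per-animal ratio normalization, e.g. SS mass / TA mass or / body mass."""
    ref = np.asarray(reference_mass, dtype=float)
    if np.any(ref <= 0):
        raise InputError("reference mass must be positive")
    out = np.asarray(mass, dtype=float) / ref
    return float(out) if np.isscalar(mass) and np.isscalar(reference_mass) else out


def adjust_pvalues(pvalues, method: str) -> np.ndarray:
    """Multiple-testing adjustment: 'sidak' or 'fdr' (Benjamini–Hochberg step-up)."""
    p = np.asarray(pvalues, dtype=float)
    if method == "sidak":
        key = "sidak"
    elif method == "fdr":
        key = "fdr_bh"
    else:
        raise ConfigurationError(f"unknown correction {method!r}")
    return multipletests(p, method=key)[1]


@dataclass
class StatResult:
    """n-way ANOVA output: effect table, corrected pairwise comparisons, normality."""

    anova_table: pd.DataFrame
    comparisons: pd.DataFrame
    correction: str
    normality: dict[str, tuple[float, float]] = field(default_factory=dict)

    def effect_pvalue(self, name: str) -> float:
        return float(self.anova_table.loc[name, "PR(>F)"])


def _check_cells(df: pd.DataFrame, factors: list[str]):
    levels = [sorted(df[f].unique()) for f in factors]
    counts = df.groupby(factors, observed=False).size()
    empty = [
        cell
        for cell in itertools.product(*levels)
        if (cell if len(cell) > 1 else cell[0]) not in counts.index
    ]
    if empty:
        raise InputError(f"empty design cells make the model inestimable: {empty}")
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise InputError(f"cells with fewer than 2 observations: {small}")


def nway_anova(
    table: pd.DataFrame,
    response: str,
    factors: list[str],
    correction: str | None = None,
    pairwise_factor: str | None = None,
) -> StatResult:
    """Full-factorial ANOVA with corrected pairwise contrasts.

    The linear model includes all interactions; sums of squares are
    type II.  Pairwise comparisons contrast levels of
    ``pairwise_factor`` (default: the first factor) within every
    combination of the remaining factors, by Welch t-tests adjusted with
    Sidak (default for <= 2 factors) or FDR (default for 3).
    """
    if not 1 <= len(factors) <= 3:
        raise ConfigurationError("between 1 and 3 crossed factors are supported")
    data = table.dropna(subset=[response, *factors])
    _check_cells(data, list(factors))
    if correction is None:
        correction = "sidak" if len(factors) <= 2 else "fdr"

    terms = " * ".join(f"C(Q('{f}'))" for f in factors)
    model = smf.ols(f"Q('{response}') ~ {terms}", data=data).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    # readable term names: drop the C(Q('...')) wrapper
    anova.index = [
        idx.replace("C(Q('", "").replace("'))", "") for idx in anova.index
    ]

    pairwise_factor = pairwise_factor or factors[0]
    if pairwise_factor not in factors:
        raise ConfigurationError(f"{pairwise_factor!r} is not one of the factors")
    others = [f for f in factors if f != pairwise_factor]
    rows = []
    strata = (
        data.groupby(others, observed=False) if others else [((), data)]
    )
    for stratum_key, sub in strata:
        if not isinstance(stratum_key, tuple):
            stratum_key = (stratum_key,)
        levels = sorted(sub[pairwise_factor].unique())
        for a, b in itertools.combinations(levels, 2):
            xa = sub.loc[sub[pairwise_factor] == a, response].to_numpy()
            xb = sub.loc[sub[pairwise_factor] == b, response].to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                continue
            t, p = sps.ttest_ind(xa, xb, equal_var=False)
            rows.append(
                {
                    "stratum": dict(zip(others, stratum_key)),
                    "pair": (a, b),
                    "t": float(t),
                    "p_raw": float(p),
                }
            )
    comparisons = pd.DataFrame(rows)
    if not comparisons.empty:
        comparisons["p_adj"] = adjust_pvalues(comparisons["p_raw"], correction)
        comparisons["correction"] = correction

    normality = {}
    for key, sub in data.groupby(factors, observed=False):
        vals = sub[response].to_numpy()
        if 3 <= len(vals) <= 5000 and np.ptp(vals) > 0:
            w, p = sps.shapiro(vals)
            normality[key] = (float(w), float(p))
    return StatResult(
        anova_table=anova,
        comparisons=comparisons,
        correction=correction,
        normality=normality,
    )


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk normality test (W, p) for 3 <= n <= 5000."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or not 3 <= x.size <= 5000:
        raise InputError("Shapiro–Wilk requires a 1-D sample with 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise DegenerateInputError("constant sample has no distributional shape")
    w, p = sps.shapiro(x)
    return float(w), float(p)
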