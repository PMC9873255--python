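"""Normalization schemes, factorial ANOVA, multiple-testing corrections,
Shapiro--Wilk, and the report builder."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import myomorph as mm


# ---------------------------------------------------------------- normalization
def test_normalize_to_sham_examples():
    sham = [10.0, 12.0, 14.0]
    assert mm.normalize_to_sham([9.0], sham)[0] == pytest.approx(0.75)
    assert mm.normalize_to_sham([12.0], sham)[0] == pytest.approx(1.0)
    # scale invariance for a constant sham group
    for c in (0.1, 3.0, 1e4):
        assert mm.normalize_to_sham([c], [c, c, c])[0] == pytest.approx(1.0)
    # the sham group itself has mean exactly 1
    assert mm.normalize_to_sham(sham, sham).mean() == pytest.approx(1.0)
    with pytest.raises(mm.InputError):
        mm.normalize_to_sham([1.0], [])


def test_normalize_cohort_to_sham_groups(noise_free_cohort):
    norm = mm.normalize_cohort_to_sham(noise_free_cohort, "ss_mass_mg")
    sham = norm[noise_free_cohort["treatment"] == "SHM"]
    assert np.allclose(sham, 1.0)


def test_ratio_normalize_examples():
    assert mm.ratio_normalize(50.0, 50.0) == pytest.approx(1.0)
    assert mm.ratio_normalize(45.0, 30.0) == pytest.approx(1.5)
    # invariant to a common unit change
    assert mm.ratio_normalize(45.0 * 1e3, 30.0 * 1e3) == pytest.approx(1.5)
    with pytest.raises(mm.InputError):
        mm.ratio_normalize(45.0, 0.0)


# ---------------------------------------------------------------- corrections
def test_sidak_formula_case():
    p = mm.adjust_pvalues([0.01, 0.01, 0.01, 0.01, 0.01], "sidak")
    assert np.allclose(p, 1 - (1 - 0.01) ** 5)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.floats(1e-6, 0.999), min_size=2, max_size=40))
def test_correction_invariants(pvals):
    raw = np.asarray(pvals)
    sidak = mm.adjust_pvalues(raw, "sidak")
    fdr = mm.adjust_pvalues(raw, "fdr")
    assert (sidak >= raw - 1e-12).all()
    assert ((sidak <= 1.0) & (fdr <= 1.0)).all()
    # FDR step-up preserves the raw ordering (monotone)
    order = np.argsort(raw)
    assert (np.diff(fdr[order]) >= -1e-12).all()


# ---------------------------------------------------------------- ANOVA
def _two_group_table(rng, n=8, delta=0.0):
    return pd.DataFrame(
        {
            "g": ["a"] * n + ["b"] * n,
            "y": np.concatenate([rng.normal(0, 1, n), rng.normal(delta, 1, n)]),
        }
    )


def test_one_factor_f_equals_pooled_t_squared():
    rng = np.random.default_rng(3)
    df = _two_group_table(rng, n=9, delta=0.6)
    res = mm.nway_anova(df, "y", ["g"])
    t, _ = sps.ttest_ind(df.y[df.g == "a"], df.y[df.g == "b"], equal_var=True)
    assert res.anova_table.loc["g", "F"] == pytest.approx(t ** 2, rel=1e-10)


def test_anova_invariant_under_affine_response_transform():
    rng = np.random.default_rng(4)
    df = pd.DataFrame(
        {
            "sex": rng.choice(["M", "F"], 40),
            "treatment": rng.choice(["SHM", "TEN"], 40),
            "y": rng.normal(0, 1, 40),
        }
    )
    # guarantee filled cells
    df.loc[:3, ["sex", "treatment"]] = [
        ["M", "SHM"], ["M", "TEN"], ["F", "SHM"], ["F", "TEN"],
    ]
    res1 = mm.nway_anova(df, "y", ["sex", "treatment"])
    df2 = df.assign(y=5.0 * df.y - 11.0)
    res2 = mm.nway_anova(df2, "y", ["sex", "treatment"])
    p1 = res1.anova_table["PR(>F)"].dropna().to_numpy()
    p2 = res2.anova_table["PR(>F)"].dropna().to_numpy()
    assert np.allclose(p1, p2, rtol=1e-8)


def test_empty_cell_raises_listing_cells():
    df = pd.DataFrame(
        {
            "sex": ["M", "M", "M", "M", "F", "F"],
            "treatment": ["SHM", "SHM", "TEN", "TEN", "SHM", "SHM"],
            "y": np.arange(6.0),
        }
    )
    with pytest.raises(mm.InputError, match="F"):
        mm.nway_anova(df, "y", ["sex", "treatment"])


def test_three_factor_defaults_to_fdr_and_two_to_sidak():
    rng = np.random.default_rng(5)
    rows = []
    for s in "MF":
        for g in ("WT", "MKD"):
            for t in ("W1", "W8"):
                for _ in range(3):
                    rows.append({"sex": s, "genotype": g, "timepoint": t,
                                 "y": rng.normal()})
    df = pd.DataFrame(rows)
    res3 = mm.nway_anova(df, "y", ["sex", "genotype", "timepoint"])
    assert res3.correction == "fdr"
    res2 = mm.nway_anova(df, "y", ["sex", "genotype"])
    assert res2.correction == "sidak"
    assert (res2.comparisons["p_adj"] >= res2.comparisons["p_raw"] - 1e-12).all()


def test_anova_power_increases_with_effect_size():
    rng = np.random.default_rng(6)
    rejections = []
    for delta in (0.0, 0.8, 1.6):
        hits = 0
        for _ in range(120):
            df = _two_group_table(rng, n=8, delta=delta)
            res = mm.nway_anova(df, "y", ["g"])
            hits += res.effect_pvalue("g") < 0.05
        rejections.append(hits / 120)
    assert rejections[0] < rejections[1] < rejections[2]


# ---------------------------------------------------------------- Shapiro--Wilk
def test_shapiro_wilk_behaviour():
    rng = np.random.default_rng(7)
    w, p = mm.shapiro_wilk(rng.normal(size=200))
    assert 0.9 < w <= 1.0
    # strongly bimodal: two separated point-mass clusters
    bimodal = np.concatenate([rng.normal(0, 0.05, 25), rng.normal(10, 0.05, 25)])
    _, p_bim = mm.shapiro_wilk(bimodal)
    assert p_bim < 0.05
    with pytest.raises(mm.DegenerateInputError):
        mm.shapiro_wilk(np.ones(20))
    with pytest.raises(mm.InputError):
        mm.shapiro_wilk([1.0, 2.0])


def test_shapiro_pvalues_roughly_uniform_under_normality():
    rng = np.random.default_rng(8)
    ps = [mm.shapiro_wilk(rng.normal(size=40))[1] for _ in range(200)]
    # Kolmogorov-Smirnov against U(0,1); generous alpha for a smoke check
    assert sps.kstest(ps, "uniform").pvalue > 0.01


# ---------------------------------------------------------------- report
def test_report_tables_and_roundtrip(tmp_path, default_effects):
    df = mm.generate_cohort(mm.CohortDesign(seed=9, n_per_group=3), default_effects)
    dec = mm.decompose_cohort(df, default_effects.area_fractions)
    bundle = mm.build_report(df, decompositions=dec)
    summaries = bundle.tables["group_summaries"]
    # one row per (response, design cell)
    cells = df.groupby(["sex", "genotype", "treatment", "timepoint"]).ngroups
    per_response = summaries.groupby("response").size()
    assert (per_response == cells).all()
    assert summaries["mean_sd"].str.contains("±").all()
    out = bundle.write(tmp_path / "report")
    back = pd.read_csv(out / "group_summaries.csv")
    assert len(back) == len(summaries)
    assert np.allclose(back["mean"], summaries["mean"])


def test_report_with_empty_ten_group_has_gaps_not_crashes(default_effects):
    df = mm.generate_cohort(mm.CohortDesign(seed=10, n_per_group=2), default_effects)
    sham_only = df[df.treatment == "SHM"].reset_index(drop=True)
    bundle = mm.build_report(sham_only)
    assert "group_summaries" in bundle.tables


def test_report_orphan_ids_raise(default_effects):
    df = mm.generate_cohort(mm.CohortDesign(seed=9, n_per_group=2), default_effects)
    dec = mm.decompose_cohort(df, default_effects.area_fractions)
    dec.loc[0, "animal_id"] = "GHOST-01"
    with pytest.raises(mm.ReconciliationError, match="GHOST-01"):
        mm.build_report(df, decompositions=dec)
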