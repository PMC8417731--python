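"""Summaries, split-block ANOVA, variance components and heritability.

Tiny-design sums of squares are checked against a brute-force cell-mean
projection oracle written independently here, and the five published
single-environment heritabilities are reproduced from their printed
genotype-by-density mean squares and variance components.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from fourway_qtl import pheno
from fourway_qtl.pheno import (VarianceComponents, anova_split_block,
                               estimate_varcomp, heritability, summarize)


def _tiny_pheno(values, lines=None, dens=("D1",), reps=(1,), env="E1"):
    rows = []
    i = 0
    lines = lines or [f"L{k}" for k in range(len(values))]
    for line in lines:
        for d in dens:
            for r in reps:
                rows.append({"line": line, "env": env, "density": d,
                             "rep": r, "value": values[i]})
                i += 1
    return pd.DataFrame(rows)


# ------------------------------------------------------------------- summarize

def test_constant_group_flags_undefined_moments():
    tab = summarize(_tiny_pheno([5.0, 5.0, 5.0]))
    assert tab.loc[0, "std"] == 0
    assert not tab.loc[0, "moments_defined"]
    assert np.isnan(tab.loc[0, "skew"]) and np.isnan(tab.loc[0, "kurt"])


def test_symmetric_sample_has_zero_skew():
    tab = summarize(_tiny_pheno([1.0, 2, 3, 4, 5]))
    assert tab.loc[0, "skew"] == pytest.approx(0.0, abs=1e-12)


def test_moments_match_hand_coded_oracle():
    """Adjusted Fisher-Pearson skewness and excess kurtosis from raw moments."""
    v = np.array([1.0, 2, 3, 4, 10])
    n = v.size
    m2 = ((v - v.mean()) ** 2).mean()
    m3 = ((v - v.mean()) ** 3).mean()
    m4 = ((v - v.mean()) ** 4).mean()
    skew = np.sqrt(n * (n - 1)) / (n - 2) * m3 / m2 ** 1.5
    kurt = (n - 1) / ((n - 2) * (n - 3)) * ((n + 1) * (m4 / m2 ** 2 - 3) + 6)
    tab = summarize(_tiny_pheno(list(v)))
    assert tab.loc[0, "mean"] == pytest.approx(4.0)
    assert tab.loc[0, "std"] == pytest.approx(np.std(v, ddof=1))
    assert tab.loc[0, "skew"] == pytest.approx(skew)
    assert tab.loc[0, "kurt"] == pytest.approx(kurt)


def test_summarize_averages_replicates_first():
    phe = _tiny_pheno([1.0, 3, 2, 6], lines=["A", "B"], reps=(1, 2))
    tab = summarize(phe)
    assert tab.loc[0, "mean"] == pytest.approx(3.0)  # means of (2, 4)
    assert tab.loc[0, "min"] == pytest.approx(2.0)


# ----------------------------------------------------------------------- ANOVA

def _balanced_pheno(rng, g, d, r, e=1):
    rows = []
    for env in [f"E{k + 1}" for k in range(e)]:
        for line in [f"L{k}" for k in range(g)]:
            for dens in [f"D{k + 1}" for k in range(d)]:
                for rep in range(1, r + 1):
                    rows.append({"line": line, "env": env, "density": dens,
                                 "rep": rep, "value": rng.normal()})
    return pd.DataFrame(rows)


def _oracle_ss_single(phe):
    """Brute-force cell-mean projection oracle for the split-block SS."""
    gm = phe["value"].mean()
    mean = lambda cols: phe.groupby(cols)["value"].transform("mean")  # noqa: E731
    return {
        "block": ((mean(["rep"]) - gm) ** 2).sum(),
        "density": ((mean(["density"]) - gm) ** 2).sum(),
        "block_x_density": ((mean(["rep", "density"]) - mean(["rep"])
                             - mean(["density"]) + gm) ** 2).sum(),
        "genotype": ((mean(["line"]) - gm) ** 2).sum(),
        "genotype_x_density": ((mean(["line", "density"]) - mean(["line"])
                                - mean(["density"]) + gm) ** 2).sum(),
        "residual": ((phe["value"] - mean(["line", "density"]) - mean(["rep", "density"])
                      + mean(["density"])) ** 2).sum(),
    }


def test_constant_phenotype_gives_zero_ss():
    phe = _balanced_pheno(np.random.default_rng(0), 3, 2, 2)
    phe["value"] = 7.0
    tab = anova_split_block(phe, "single")
    assert np.allclose(tab["ss"], 0.0, atol=1e-18)
    assert tab["F"].isna().all()


def test_tiny_design_matches_projection_oracle():
    phe = _balanced_pheno(np.random.default_rng(3), 2, 2, 2)
    tab = anova_split_block(phe, "single").set_index("source")
    oracle = _oracle_ss_single(phe)
    for src, ss in oracle.items():
        assert tab.loc[src, "ss"] == pytest.approx(ss, abs=1e-8)


@pytest.mark.parametrize("scope,g,d,r,e", [("single", 144, 2, 3, 1),
                                           ("joint", 20, 2, 3, 5)])
def test_df_and_ss_additivity(scope, g, d, r, e):
    phe = _balanced_pheno(np.random.default_rng(4), g, d, r, e)
    tab = anova_split_block(phe, scope)
    assert tab["df"].sum() == g * d * r * e - 1
    assert tab["ss"].sum() == pytest.approx(tab.attrs["ss_total"], rel=1e-8)
    if scope == "single":
        by = tab.set_index("source")["df"]
        assert by["genotype"] == 143 and by["genotype_x_density"] == 143


def test_single_replicate_drops_f_tests():
    phe = _balanced_pheno(np.random.default_rng(5), 4, 2, 1)
    tab = anova_split_block(phe, "single").set_index("source")
    assert tab.loc["block", "df"] == 0
    assert np.isnan(tab.loc["density", "F"])  # its error stratum has 0 df


def test_unbalanced_data_falls_back_with_warning():
    phe = _balanced_pheno(np.random.default_rng(6), 4, 2, 2).iloc[:-1]
    with pytest.warns(UserWarning, match="unbalanced"):
        tab = anova_split_block(phe, "single")
    assert set(tab["source"]) >= {"genotype", "genotype_x_density", "residual"}


def test_permuted_genotype_pvalues_are_uniform():
    """Under the null (no genotype effect) genotype F p-values are uniform:
    KS test not rejected at alpha=0.01 over 500 null datasets."""
    rng = np.random.default_rng(8)
    template = _balanced_pheno(rng, 10, 2, 2)
    pvals = []
    for _ in range(500):
        phe = template.copy()
        phe["value"] = rng.normal(size=len(phe))
        tab = anova_split_block(phe, "single").set_index("source")
        pvals.append(tab.loc["genotype", "p"])
    assert stats.kstest(pvals, "uniform").pvalue > 0.01


# --------------------------------------------------------- variance components

def _ms_table(ms_g, ms_gd, ms_res, g=144, d=2, r=3):
    tab = pd.DataFrame({
        "source": ["genotype", "genotype_x_density", "residual"],
        "df": [g - 1, (g - 1) * (d - 1), 1],
        "ss": [0.0] * 3, "ms": [ms_g, ms_gd, ms_res],
        "F": [np.nan] * 3, "p": [np.nan] * 3})
    tab.attrs.update(g=g, d=d, r=r, e=1)
    return tab


def test_equal_ms_gives_zero_interaction_component():
    vc = estimate_varcomp(_ms_table(10.0, 4.0, 4.0))
    assert vc.sigma2_GD == 0.0


def test_published_e5_row_implies_printed_residual():
    """MS_GD=11.92 with residual 2.80 yields the printed sigma2_GD=3.04."""
    vc = estimate_varcomp(_ms_table(35.81, 11.92, 2.80))
    assert vc.sigma2_GD == pytest.approx(3.04, abs=1e-9)
    assert vc.sigma2_res == pytest.approx(2.80)


def test_negative_component_truncated_and_logged():
    vc = estimate_varcomp(_ms_table(10.0, 2.0, 5.0))
    assert vc.sigma2_GD == 0.0
    assert any(name == "sigma2_GD" for name, _ in vc.truncated)


def test_missing_source_raises():
    tab = _ms_table(1, 1, 1)
    with pytest.raises(KeyError):
        estimate_varcomp(tab[tab["source"] != "genotype_x_density"])


def test_varcomp_recovery_within_15pct():
    """Known mixed-model components at 500 lines recovered within 15%."""
    rng = np.random.default_rng(9)
    g, d, r, e = 500, 2, 3, 3
    sig = dict(G=2.0, GD=1.0, GE=1.0, GDE=0.8, res=1.5)
    G = rng.normal(0, np.sqrt(sig["G"]), g)
    GD = rng.normal(0, np.sqrt(sig["GD"]), (g, d))
    GE = rng.normal(0, np.sqrt(sig["GE"]), (e, g))
    GDE = rng.normal(0, np.sqrt(sig["GDE"]), (e, g, d))
    y = (G[None, :, None, None] + GD[None, :, :, None] + GE[:, :, None, None]
         + GDE[..., None] + rng.normal(0, np.sqrt(sig["res"]), (e, g, d, r)))
    idx = pd.MultiIndex.from_product(
        [[f"E{i}" for i in range(e)], [f"L{i}" for i in range(g)],
         ["D1", "D2"], [1, 2, 3]], names=["env", "line", "density", "rep"])
    phe = pd.DataFrame({"value": y.ravel()}, index=idx).reset_index()
    vc = estimate_varcomp(anova_split_block(phe, "joint"))
    for est, true in [(vc.sigma2_G, sig["G"]), (vc.sigma2_GD, sig["GD"]),
                      (vc.sigma2_GE, sig["GE"]), (vc.sigma2_GDE, sig["GDE"]),
                      (vc.sigma2_res, sig["res"])]:
        assert abs(est - true) / true < 0.15


# ---------------------------------------------------------------- heritability

def test_heritability_limits():
    assert heritability(VarianceComponents(4.0, 0.0, 0.0), d=2, r=3).h2 == 1.0
    assert heritability(VarianceComponents(0.0, 1.0, 1.0), d=2, r=3).h2 == 0.0
    assert not heritability(VarianceComponents(0.0, 0.0, 0.0), d=2, r=3).defined


@pytest.mark.parametrize("s_g,s_gd,ms_gd,expected", [
    (0.38, 8.96, 30.00, 0.07),
    (1.47, 2.05, 9.13, 0.49),
    (2.37, 5.04, 18.32, 0.44),
    (2.32, 2.71, 10.89, 0.56),
    (4.16, 3.04, 11.92, 0.68),
])
def test_single_environment_heritabilities_reproduce(s_g, s_gd, ms_gd, expected):
    """Each environment's printed h2 follows from its printed components with
    the EMS residual sigma2 = MS_GD - r*sigma2_GD (d=2, r=3)."""
    vc = VarianceComponents(s_g, s_gd, ms_gd - 3 * s_gd)
    assert round(heritability(vc, d=2, r=3).h2, 2) == expected


def test_joint_formula_excludes_ge_unless_flagged():
    vc = VarianceComponents(2.0, 1.0, 1.2, sigma2_GE=0.9, sigma2_GDE=0.6)
    base = heritability(vc, d=2, r=3, e=5).h2
    with_ge = heritability(vc, d=2, r=3, e=5, include_ge=True).h2
    assert with_ge < base
    denom = 2.0 + 1.0 / 2 + 0.6 / 10 + 1.2 / 30
    assert base == pytest.approx(2.0 / denom)


def test_h2_monotone_in_components():
    base = heritability(VarianceComponents(2.0, 1.0, 1.0), d=2, r=3).h2
    assert heritability(VarianceComponents(3.0, 1.0, 1.0), d=2, r=3).h2 > base
    assert heritability(VarianceComponents(2.0, 2.0, 1.0), d=2, r=3).h2 < base
    assert heritability(VarianceComponents(2.0, 1.0, 2.0), d=2, r=3).h2 < base
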