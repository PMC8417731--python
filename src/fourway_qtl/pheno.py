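"""Descriptive summaries, split-block ANOVA, variance components, heritability.

The field design is a split block: within each replicate block the two
planting densities are main plots and the RIL genotypes are subplots.  The
density F test therefore uses the main-block error stratum (block x density),
while genotype and genotype x density are tested against the subplot
residual.  Variance components come from the expected-mean-square
(method-of-moments) identities of the balanced design, and broad-sense
heritability on a line-mean basis is

    single environment:  h2 = s2_G / (s2_G + s2_GD/d + s2/(d r))
    joint (e envs):      h2 = s2_G / (s2_G + s2_GD/d + s2_GDE/(d e) + s2/(e d r))

with d densities and r replicates.  The joint formula has no s2_GE term; a
GE-inclusive variant is available behind ``include_ge=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceComponents",
    "Heritability",
    "summarize",
    "anova_split_block",
    "estimate_varcomp",
    "heritability",
]


@dataclass
class VarianceComponents:
    sigma2_G: float
    sigma2_GD: float
    sigma2_res: float
    sigma2_GE: float | None = None
    sigma2_GDE: float | None = None
    truncated: list = field(default_factory=list)


@dataclass
class Heritability:
    h2: float
    scope: str  # "single" | "joint"
    d: int
    r: int
    e: int | None = None
    defined: bool = True


def _line_means(pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-line replicate means within each env x density cell."""
    return (pheno.groupby(["env", "density", "line"], sort=False)["value"]
            .mean().reset_index())


def summarize(pheno: pd.DataFrame) -> pd.DataFrame:
    """Per-treatment (env x density) summary of line means.

    Lines are averaged over replicates first; std uses n-1, skewness is the
    adjusted Fisher-Pearson coefficient and kurtosis is the excess form, so
    a Gaussian sample is near 0 on both.  Constant groups get std 0 and
    NaN skew/kurt with ``moments_defined`` False.
    """
    lm = _line_means(pheno)
    rows = []
    for (env, dens), g in lm.groupby(["env", "density"], sort=True):
        v = g["value"].to_numpy(dtype=float)
        if v.size < 2:
            raise ValueError(f"treatment {env}{dens} has <2 observations")
        sd = float(np.std(v, ddof=1))
        defined = sd > 0
        rows.append({
            "treatment": f"{env}{dens}", "env": env, "density": dens,
            "n": v.size, "min": float(v.min()), "max": float(v.max()),
            "mean": float(v.mean()), "std": sd,
            "skew": float(stats.skew(v, bias=False)) if defined else np.nan,
            "kurt": float(stats.kurtosis(v, bias=False, fisher=True)) if defined else np.nan,
            "moments_defined": defined,
        })
    return pd.DataFrame(rows)


def _is_balanced(pheno: pd.DataFrame, cols) -> bool:
    counts = pheno.groupby(cols, sort=False).size()
    full = int(np.prod([pheno[c].nunique() for c in cols]))
    return len(counts) == full and counts.nunique() == 1 and counts.iloc[0] == 1


def _marg(y: np.ndarray, axes: tuple) -> np.ndarray:
    """Mean over ``axes``, broadcast back to the full shape."""
    return y.mean(axis=axes, keepdims=True)


def _anova_rows(names, dfs, sss, error_for):
    """Assemble the table and wire each F test to its error stratum."""
    ms = {n: (ss / df if df > 0 else np.nan) for n, df, ss in zip(names, dfs, sss)}
    rows = []
    for n, df, ss in zip(names, dfs, sss):
        err = error_for.get(n)
        if err is not None and df > 0 and ms.get(err, np.nan) == ms.get(err):
            denom = ms[err]
            df_err = dict(zip(names, dfs))[err]
            if denom > 0 and df_err > 0:
                f = ms[n] / denom
                p = float(stats.f.sf(f, df, df_err))
            else:
                f, p = np.nan, np.nan
        else:
            f, p = np.nan, np.nan
        rows.append({"source": n, "df": int(df), "ss": float(ss),
                     "ms": float(ms[n]) if df > 0 else np.nan, "F": f, "p": p})
    return pd.DataFrame(rows)


def _anova_single(pheno: pd.DataFrame) -> pd.DataFrame:
    lines = pheno["line"].unique()
    dens = pheno["density"].unique()
    reps = np.sort(pheno["rep"].unique())
    g, d, r = len(lines), len(dens), len(reps)
    y = (pheno.set_index(["line", "density", "rep"])["value"]
         .unstack(["density", "rep"])
         .reindex(index=lines)
         .to_numpy().reshape(g, d, r))
    gm = y.mean()
    ss = lambda a: float((np.broadcast_to(a, y.shape) ** 2).sum())  # noqa: E731
    ss_tot = ss(y - gm)
    ss_R = ss(_marg(y, (0, 1)) - gm)
    ss_D = ss(_marg(y, (0, 2)) - gm)
    ss_RD = ss(_marg(y, (0,)) - _marg(y, (0, 1)) - _marg(y, (0, 2)) + gm)
    ss_G = ss(_marg(y, (1, 2)) - gm)
    ss_GD = ss(_marg(y, (2,)) - _marg(y, (1, 2)) - _marg(y, (0, 2)) + gm)
    ss_res = ss_tot - (ss_R + ss_D + ss_RD + ss_G + ss_GD)
    dfs = [r - 1, d - 1, (r - 1) * (d - 1), g - 1, (g - 1) * (d - 1)]
    dfs.append(g * d * r - 1 - sum(dfs))
    names = ["block", "density", "block_x_density", "genotype",
             "genotype_x_density", "residual"]
    error_for = {"block": "block_x_density", "density": "block_x_density",
                 "genotype": "residual", "genotype_x_density": "residual"}
    tab = _anova_rows(names, dfs, [ss_R, ss_D, ss_RD, ss_G, ss_GD, ss_res], error_for)
    tab.attrs.update(g=g, d=d, r=r, e=1, ss_total=ss_tot)
    return tab


def _anova_joint(pheno: pd.DataFrame) -> pd.DataFrame:
    lines = pheno["line"].unique()
    dens = pheno["density"].unique()
    envs = pheno["env"].unique()
    reps = np.sort(pheno["rep"].unique())
    e, g, d, r = len(envs), len(lines), len(dens), len(reps)
    y = (pheno.set_index(["env", "line", "density", "rep"])["value"]
         .unstack(["line", "density", "rep"])
         .reindex(index=envs)
         .to_numpy().reshape(e, g, d, r))
    gm = y.mean()
    m = lambda *ax: _marg(y, tuple(ax))  # noqa: E731
    ss = lambda a: float((np.broadcast_to(a, y.shape) ** 2).sum())  # noqa: E731
    ss_E = ss(m(1, 2, 3) - gm)
    ss_ER = ss(m(1, 2) - m(1, 2, 3))  # blocks nested in environments
    ss_D = ss(m(0, 1, 3) - gm)
    ss_ED = ss(m(1, 3) - m(1, 2, 3) - m(0, 1, 3) + gm)
    ss_ERD = ss(m(1) - m(1, 2) - m(1, 3) + m(1, 2, 3))
    ss_G = ss(m(0, 2, 3) - gm)
    ss_GD = ss(m(0, 3) - m(0, 2, 3) - m(0, 1, 3) + gm)
    ss_GE = ss(m(2, 3) - m(1, 2, 3) - m(0, 2, 3) + gm)
    ss_GDE = ss(m(3) - m(2, 3) - m(1, 3) - m(0, 3)
                + m(1, 2, 3) + m(0, 2, 3) + m(0, 1, 3) - gm)
    ss_tot = ss(y - gm)
    parts = [ss_E, ss_ER, ss_D, ss_ED, ss_ERD, ss_G, ss_GD, ss_GE, ss_GDE]
    ss_res = ss_tot - sum(parts)
    dfs = [e - 1, e * (r - 1), d - 1, (e - 1) * (d - 1), e * (r - 1) * (d - 1),
           g - 1, (g - 1) * (d - 1), (g - 1) * (e - 1), (g - 1) * (d - 1) * (e - 1)]
    dfs.append(e * g * d * r - 1 - sum(dfs))
    names = ["env", "env_block", "density", "env_x_density", "env_block_x_density",
             "genotype", "genotype_x_density", "genotype_x_env",
             "genotype_x_density_x_env", "residual"]
    error_for = {"env": "env_block", "density": "env_block_x_density",
                 "env_x_density": "env_block_x_density",
                 "genotype": "residual", "genotype_x_density": "residual",
                 "genotype_x_env": "residual", "genotype_x_density_x_env": "residual"}
    tab = _anova_rows(names, dfs, parts + [ss_res], error_for)
    tab.attrs.update(g=g, d=d, r=r, e=e, ss_total=ss_tot)
    return tab


def _anova_unbalanced(pheno: pd.DataFrame, scope: str) -> pd.DataFrame:
    # Sequential (type-I) SS in model order; the field design itself is balanced,
    # so this path only serves damaged inputs.
    import statsmodels.api as sm
    from statsmodels.formula.api import ols
    warnings.warn("unbalanced data: falling back to sequential least squares")
    if scope == "single":
        model = ols("value ~ C(rep) + C(density) + C(rep):C(density)"
                    " + C(line) + C(line):C(density)", data=pheno).fit()
        rename = {"C(rep)": "block", "C(density)": "density",
                  "C(rep):C(density)": "block_x_density", "C(line)": "genotype",
                  "C(line):C(density)": "genotype_x_density", "Residual": "residual"}
    else:
        model = ols("value ~ C(env) + C(env):C(rep) + C(density) + C(env):C(density)"
                    " + C(env):C(rep):C(density) + C(line) + C(line):C(density)"
                    " + C(line):C(env) + C(line):C(density):C(env)",
                    data=pheno).fit()
        rename = {"C(env)": "env", "C(env):C(rep)": "env_block",
                  "C(density)": "density", "C(env):C(density)": "env_x_density",
                  "C(env):C(rep):C(density)": "env_block_x_density",
                  "C(line)": "genotype", "C(line):C(density)": "genotype_x_density",
                  "C(line):C(env)": "genotype_x_env",
                  "C(line):C(density):C(env)": "genotype_x_density_x_env",
                  "Residual": "residual"}
    aov = sm.stats.anova_lm(model, typ=1).reset_index()
    aov["source"] = aov["index"].map(rename)
    tab = pd.DataFrame({"source": aov["source"], "df": aov["df"].astype(int),
                        "ss": aov["sum_sq"],
                        "ms": aov["sum_sq"] / aov["df"].replace(0, np.nan),
                        "F": aov["F"], "p": aov["PR(>F)"]})
    tab.attrs.update(g=pheno["line"].nunique(), d=pheno["density"].nunique(),
                     r=pheno["rep"].nunique(), e=pheno["env"].nunique(),
                     ss_total=float(((pheno["value"] - pheno["value"].mean()) ** 2).sum()))
    return tab


def anova_split_block(pheno: pd.DataFrame, scope: str = "single") -> pd.DataFrame:
    """Split-block ANOVA table.

    ``scope='single'`` expects one environment (sources: block, density,
    block x density error, genotype, genotype x density, residual);
    ``scope='joint'`` pools environments and adds the E, E-block, E x D and
    the genotype x environment strata.  Balanced data take the closed-form
    marginal-mean path; anything else is routed to sequential least squares
    with a warning.
    """
    if scope not in ("single", "joint"):
        raise ValueError("scope must be 'single' or 'joint'")
    if scope == "single":
        if pheno["env"].nunique() > 1:
            raise ValueError("single-environment scope got multiple environments")
        cols = ["line", "density", "rep"]
        return (_anova_single(pheno) if _is_balanced(pheno, cols)
                else _anova_unbalanced(pheno, scope))
    cols = ["env", "line", "density", "rep"]
    return (_anova_joint(pheno) if _is_balanced(pheno, cols)
            else _anova_unbalanced(pheno, scope))


def _ms(tab: pd.DataFrame, source: str) -> float:
    row = tab.loc[tab["source"] == source]
    if row.empty:
        raise KeyError(f"ANOVA table lacks source '{source}'")
    return float(row["ms"].iloc[0])


def estimate_varcomp(tab: pd.DataFrame, g: int | None = None, d: int | None = None,
                     e: int | None = None, r: int | None = None) -> VarianceComponents:
    """Variance components from expected mean squares (method of moments).

    Single environment:  s2_res = MS_res, s2_GD = (MS_GD - MS_res)/r,
    s2_G = (MS_G - MS_GD)/(d r).  Joint adds
    s2_GDE = (MS_GDE - MS_res)/r, s2_GD = (MS_GD - MS_GDE)/(e r),
    s2_GE = (MS_GE - MS_GDE)/(d r),
    s2_G = (MS_G - MS_GD - MS_GE + MS_GDE)/(d e r).
    Negative estimates are truncated to 0 and logged in ``truncated``.
    """
    d = d if d is not None else tab.attrs.get("d")
    r = r if r is not None else tab.attrs.get("r")
    e = e if e is not None else tab.attrs.get("e", 1)
    joint = "genotype_x_env" in set(tab["source"])
    truncated: list = []

    def clip(name, v):
        if v < 0:
            truncated.append((name, float(v)))
            return 0.0
        return float(v)

    ms_res = _ms(tab, "residual")
    if not joint:
        s_gd = clip("sigma2_GD", (_ms(tab, "genotype_x_density") - ms_res) / r)
        s_g = clip("sigma2_G", (_ms(tab, "genotype") - _ms(tab, "genotype_x_density")) / (d * r))
        return VarianceComponents(s_g, s_gd, float(ms_res), truncated=truncated)
    ms_gde = _ms(tab, "genotype_x_density_x_env")
    s_gde = clip("sigma2_GDE", (ms_gde - ms_res) / r)
    s_gd = clip("sigma2_GD", (_ms(tab, "genotype_x_density") - ms_gde) / (e * r))
    s_ge = clip("sigma2_GE", (_ms(tab, "genotype_x_env") - ms_gde) / (d * r))
    s_g = clip("sigma2_G",
               (_ms(tab, "genotype") - _ms(tab, "genotype_x_density")
                - _ms(tab, "genotype_x_env") + ms_gde) / (d * e * r))
    return VarianceComponents(s_g, s_gd, float(ms_res), sigma2_GE=s_ge,
                              sigma2_GDE=s_gde, truncated=truncated)


def heritability(vc: VarianceComponents, d: int, r: int, e: int | None = None,
                 include_ge: bool = False) -> Heritability:
    """Broad-sense heritability on a line-mean basis.

    With ``e`` given the joint formula is used; it carries no s2_GE term
    unless ``include_ge=True`` adds s2_GE/e to the denominator.
    """
    if d < 1 or r < 1 or (e is not None and e < 1):
        raise ValueError("d, r, e must be positive")
    if e is None:
        denom = vc.sigma2_G + vc.sigma2_GD / d + vc.sigma2_res / (d * r)
        scope = "single"
    else:
        if vc.sigma2_GDE is None:
            raise ValueError("joint heritability needs sigma2_GDE")
        denom = (vc.sigma2_G + vc.sigma2_GD / d + vc.sigma2_GDE / (d * e)
                 + vc.sigma2_res / (e * d * r))
        if include_ge:
            denom += (vc.sigma2_GE or 0.0) / e
        scope = "joint"
    if denom <= 0:
        return Heritability(np.nan, scope, d, r, e, defined=False)
    return Heritability(float(vc.sigma2_G / denom), scope, d, r, e)
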