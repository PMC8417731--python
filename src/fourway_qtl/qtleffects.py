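"""Moment decomposition of a QTL's effects across two planting densities.

Given phenotypes y_ijk for allele class i (the line's founder origin at the
QTL), density j and replicate k, the decomposition is

    mu..   = grand mean
    G_i    = mean over (j, k) - mu..          (allele effect)
    D_j    = mean over (i, k) - mu..          (density effect)
    GD_ij  = mu_ij - mu.. - G_i - D_j         (allele x density interaction)
    s2_G   = sum_i f_i G_i^2
    s2_D   = (1/d) sum_j D_j^2
    s2_GD  = sum_ij f_ij GD_ij^2
    s2_p   = mean of (y - mu..)^2
    PVE_A  = 100 s2_G / s2_p,   PVE_AD = 100 s2_GD / s2_p

with f_i, f_ij the observed class frequencies (1/g and 1/(g d) when
balanced).  In a balanced 2-density design sum_j GD_ij = 0 per allele, so
the interaction column under D2 is exactly minus the one under D1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .linkscan import FounderProbMatrix, QTLCall

__all__ = [
    "EffectDecomposition",
    "assign_allele_class",
    "decompose_density_effects",
    "per_environment_effect_table",
]


@dataclass
class EffectDecomposition:
    grand_mean: float
    classes: list
    densities: list
    G: np.ndarray  # per class
    D: np.ndarray  # per density
    GD: np.ndarray  # classes x densities
    cell_means: np.ndarray
    f_i: np.ndarray
    f_ij: np.ndarray
    sigma2_G: float
    sigma2_D: float
    sigma2_GD: float
    sigma2_p: float
    pve_a: float  # percent; nan when undefined
    pve_ad: float
    defined: bool = True
    balanced: bool = True
    g: int = 0
    d: int = 0
    warnings_: list = field(default_factory=list)


def assign_allele_class(founder_probs: np.ndarray, min_prob: float = 0.7) -> np.ndarray:
    """Hard founder-class call per line from posteriors (n, 4).

    Returns classes 1..4, or 0 for lines whose posterior maximum is below
    ``min_prob`` (excluded from the decomposition).
    """
    P = np.asarray(founder_probs, dtype=float)
    cls = np.argmax(P, axis=1) + 1
    cls[P.max(axis=1) < min_prob] = 0
    return cls


def decompose_density_effects(y: pd.DataFrame,
                              equal_frequencies: bool = False) -> EffectDecomposition:
    """Decompose (class, density, value) records into the moment components.

    ``y`` needs columns ``cls``, ``density``, ``value`` (replicates are just
    extra rows).  Unbalanced tables fall back to weighted marginal means
    with a warning; ``equal_frequencies=True`` forces f_i = 1/g and
    f_ij = 1/(g d) regardless of the observed counts.
    """
    if not {"cls", "density", "value"}.issubset(y.columns):
        raise ValueError("need columns cls, density, value")
    y = y[y["cls"] != 0]
    classes = sorted(y["cls"].unique())
    densities = sorted(y["density"].unique())
    g, d = len(classes), len(densities)
    if g < 2:
        raise ValueError("need at least 2 allele classes")
    counts = y.groupby(["cls", "density"]).size().unstack("density")
    counts = counts.reindex(index=classes, columns=densities)
    msgs = []
    if counts.isna().any().any() or (counts == 0).any().any():
        raise ValueError("every present class x density cell must be nonempty")
    balanced = counts.nunique().nunique() == 1 and counts.iloc[:, 0].nunique() == 1
    if not balanced:
        msgs.append("unbalanced class x density table; weighted marginal means used")
        warnings.warn(msgs[-1])

    v = y["value"].to_numpy(dtype=float)
    mu = float(v.mean())
    cell = (y.groupby(["cls", "density"])["value"].mean()
            .unstack("density").reindex(index=classes, columns=densities)
            .to_numpy())
    G = y.groupby("cls")["value"].mean().reindex(classes).to_numpy() - mu
    D = y.groupby("density")["value"].mean().reindex(densities).to_numpy() - mu
    GD = cell - mu - G[:, None] - D[None, :]

    n = counts.to_numpy().sum()
    if equal_frequencies:
        f_i = np.full(g, 1.0 / g)
        f_ij = np.full((g, d), 1.0 / (g * d))
    else:
        f_ij = counts.to_numpy() / n
        f_i = f_ij.sum(axis=1)
    s_g = float((f_i * G ** 2).sum())
    s_d = float((D ** 2).sum() / d)
    s_gd = float((f_ij * GD ** 2).sum())
    s_p = float(((v - mu) ** 2).mean())
    if s_p <= 0:
        msgs.append("zero phenotypic variance; PVEs undefined")
        return EffectDecomposition(mu, classes, densities, G, D, GD, cell, f_i, f_ij,
                                   s_g, s_d, s_gd, s_p, np.nan, np.nan,
                                   defined=False, balanced=balanced, g=g, d=d,
                                   warnings_=msgs)
    return EffectDecomposition(mu, classes, densities, G, D, GD, cell, f_i, f_ij,
                               s_g, s_d, s_gd, s_p,
                               100.0 * s_g / s_p, 100.0 * s_gd / s_p,
                               balanced=balanced, g=g, d=d, warnings_=msgs)


def per_environment_effect_table(calls: list[QTLCall], probs: FounderProbMatrix,
                                 pheno: pd.DataFrame, min_prob: float = 0.7,
                                 line_ids: list | None = None) -> pd.DataFrame:
    """One decomposition per (QTL region, environment), plus per-env totals.

    Interaction columns are reported as GD_ij per density; in a balanced
    two-density design the D2 column is exactly the negative of the D1
    column.  Totals are the per-environment column sums of PVE_A and PVE_AD.
    """
    if line_ids is None:
        line_ids = sorted(pheno["line"].unique())
    gmap = probs.gmap
    seen, rows = set(), []
    for c in calls:
        key = c.name or (c.chrom, c.start_bp, c.end_bp)
        if key in seen:
            continue
        seen.add(key)
        ci = gmap.chrom_ids.index(c.chrom)
        on = probs.chrom_idx == ci
        j = np.flatnonzero(on)[int(np.argmin(np.abs(probs.positions_cm[on] - c.peak_cm)))]
        cls = assign_allele_class(probs.probs[:, j, :], min_prob=min_prob)
        cls_map = dict(zip(line_ids, cls))
        for env, sub in pheno.groupby("env", sort=True):
            tab = sub.assign(cls=sub["line"].map(cls_map)).dropna(subset=["cls"])
            tab = tab.astype({"cls": int})
            try:
                dec = decompose_density_effects(tab[["cls", "density", "value"]])
            except ValueError:
                continue
            row = {"qtl": key if isinstance(key, str) else str(key), "env": env,
                   "n_excluded": int((cls == 0).sum()),
                   "pve_a": dec.pve_a, "pve_ad": dec.pve_ad}
            for i in range(1, 5):
                row[f"add{i}"] = dec.G[dec.classes.index(i)] if i in dec.classes else np.nan
            for jdx, dens in enumerate(dec.densities):
                for i in range(1, 5):
                    row[f"add{i}_x_{dens}"] = (dec.GD[dec.classes.index(i), jdx]
                                               if i in dec.classes else np.nan)
            rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    totals = (out.groupby("env")[["pve_a", "pve_ad"]].sum().reset_index()
              .assign(qtl="Total"))
    return pd.concat([out, totals], ignore_index=True).sort_values(
        ["env", "qtl"], key=lambda s: s.eq("Total") if s.name == "qtl" else s
    ).reset_index(drop=True)
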