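"""Single-marker association scan and LD-decay utility.

This is a deliberately simple marker-based stand-in for multi-locus GWAS:
per marker, the trait is regressed on the 0/1 allele of the homozygous RILs,

    LOD = (n/2) log10(RSS0/RSS1),   r2 = 100 (1 - RSS1/RSS0)

with the allele-substitution coefficient reported as the effect.  Markers
with minor allele frequency <= ``maf_min`` are dropped before testing and
records keep the configured method label so multi-method support counts can
be exercised downstream.  No kinship or structure correction is applied:
the four-way RIL pedigree is known and carries no population structure.

``ld_decay`` bins pairwise allele-indicator r2 by physical distance and
reports the first distance at which the mean drops below a threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QTNRecord", "LDResult", "marker_scan", "name_qtn", "ld_decay",
           "qtn_to_frame"]


@dataclass
class QTNRecord:
    marker: str
    chrom: object
    bp: int
    treatment: str
    method: str
    effect: float
    lod: float
    r2: float  # percent
    maf: float
    trait_kind: str = "NN"
    name: str = ""


@dataclass
class LDResult:
    bin_edges: np.ndarray  # bp
    mean_r2: np.ndarray
    n_pairs: np.ndarray
    decay_distance: float  # bp at which mean r2 crosses the threshold
    threshold: float


def marker_scan(snp: np.ndarray, trait, marker_ids, chroms, bps,
                maf_min: float = 0.05, lod_min: float = 3.0,
                treatment: str = "", method: str = "single-marker",
                trait_kind: str = "NN") -> tuple[list[QTNRecord], dict]:
    """Per-marker regression scan; returns (records over lod_min, counts).

    ``snp`` is (n_lines, n_markers) 0/1; monomorphic markers are skipped and
    counted, markers with MAF <= maf_min dropped before testing.
    """
    X = np.asarray(snp, dtype=float)
    y = np.asarray(trait, dtype=float)
    n = y.size
    if X.shape[0] != n:
        raise ValueError("trait length does not match genotype rows")
    freq = X.mean(axis=0)
    maf = np.minimum(freq, 1.0 - freq)
    mono = maf == 0
    keep = (~mono) & (maf > maf_min)
    counts = {"n_markers": X.shape[1], "n_monomorphic": int(mono.sum()),
              "n_maf_dropped": int(((~mono) & ~keep).sum())}
    yc = y - y.mean()
    rss0 = float((yc ** 2).sum())
    Xc = X - freq[None, :]
    sxx = (Xc ** 2).sum(axis=0)
    sxy = Xc.T @ yc
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxy / sxx, 0.0)
    rss1 = rss0 - beta * sxy
    rss1 = np.clip(rss1, 1e-300, None)
    lod = np.where(keep, (n / 2.0) * np.log10(rss0 / rss1), 0.0)
    r2 = np.where(keep, 100.0 * (1.0 - rss1 / rss0), 0.0)
    recs = [QTNRecord(marker=marker_ids[i], chrom=chroms[i], bp=int(bps[i]),
                      treatment=treatment, method=method, effect=float(beta[i]),
                      lod=float(lod[i]), r2=float(r2[i]), maf=float(maf[i]),
                      trait_kind=trait_kind)
            for i in np.flatnonzero(keep & (lod >= lod_min))]
    return recs, counts


def name_qtn(records: list[QTNRecord]) -> list[QTNRecord]:
    """Per-chromosome sequence numbers by bp order, one counter per trait kind;
    detections of the same marker share a number."""
    markers: dict = {}
    for rec in records:
        markers.setdefault((rec.chrom, rec.bp, rec.trait_kind), []).append(rec)
    counters: dict = {}
    for (chrom, bp, kind), recs in sorted(markers.items(),
                                          key=lambda kv: (str(kv[0][0]), kv[0][1])):
        k = counters.get((chrom, kind), 0) + 1
        counters[(chrom, kind)] = k
        cn = str(chrom).replace("Chr", "").lstrip("0") or "0"
        name = f"qnNN-{cn}-{k}" if kind == "NN" else f"qnRDNN-{cn}-{k}"
        for rec in recs:
            rec.name = name
    return records


def qtn_to_frame(records: list[QTNRecord]) -> pd.DataFrame:
    cols = ["qtn", "marker", "chrom", "bp", "treatment", "method",
            "effect", "lod", "r2", "maf"]
    return pd.DataFrame([{
        "qtn": r.name, "marker": r.marker, "chrom": r.chrom, "bp": r.bp,
        "treatment": r.treatment, "method": r.method, "effect": r.effect,
        "lod": r.lod, "r2": r.r2, "maf": r.maf} for r in records], columns=cols)


def ld_decay(snp: np.ndarray, bps, chroms=None, r2_threshold: float = 0.1,
             max_dist: float = 5_000_000.0, n_bins: int = 20) -> LDResult:
    """Mean pairwise r2 binned by physical distance, within chromosomes.

    The decay distance is the linearly interpolated point where the binned
    mean first crosses ``r2_threshold`` (nan if it never does).
    """
    X = np.asarray(snp, dtype=float)
    bps = np.asarray(bps, dtype=float)
    chroms = np.zeros(X.shape[1]) if chroms is None else np.asarray(chroms)
    poly = X.std(axis=0) > 0
    dists, r2s = [], []
    for c in np.unique(chroms):
        idx = np.flatnonzero((chroms == c) & poly)
        if idx.size < 2:
            continue
        sub = X[:, idx]
        corr = np.corrcoef(sub.T)
        pos = bps[idx]
        dd = np.abs(pos[:, None] - pos[None, :])
        iu = np.triu_indices(idx.size, k=1)
        d, r = dd[iu], corr[iu] ** 2
        ok = d <= max_dist
        dists.append(d[ok])
        r2s.append(r[ok])
    if not dists or sum(d.size for d in dists) == 0:
        raise ValueError("no marker pairs within max_dist")
    d = np.concatenate(dists)
    r2 = np.concatenate(r2s)
    edges = np.linspace(0, max_dist, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    mean_r2 = np.full(n_bins, np.nan)
    npairs = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = which == b
        npairs[b] = sel.sum()
        if npairs[b]:
            mean_r2[b] = r2[sel].mean()
    centers = 0.5 * (edges[:-1] + edges[1:])
    decay = np.nan
    valid = ~np.isnan(mean_r2)
    vc, vm = centers[valid], mean_r2[valid]
    for i in range(vm.size):
        if vm[i] < r2_threshold:
            if i == 0:
                decay = float(vc[0])
            else:
                x0, x1, y0, y1 = vc[i - 1], vc[i], vm[i - 1], vm[i]
                decay = float(x0 + (y0 - r2_threshold) * (x1 - x0) / (y0 - y1))
            break
    return LDResult(bin_edges=edges, mean_r2=mean_r2, n_pairs=npairs,
                    decay_distance=decay, threshold=r2_threshold)
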