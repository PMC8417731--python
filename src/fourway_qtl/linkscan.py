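"""Four-founder genome scan: founder posteriors, IM/ICIM scans, QTL calling.

The latent variable at every genome position is which of the four founders a
line's (homozygous) chromosome segment descends from.  A hidden Markov model
along each chromosome recovers the posterior over founders from biallelic
SNP data; transitions between adjacent positions use the selfed-RIL
expansion r* = 2r/(1+2r) of the Haldane single-meiosis recombination
fraction r for the cM gap, and emissions compare the line's observed allele
with each founder's allele (mismatch floor eps).

The scan itself is a Haley-Knott-style regression of the trait on the four
founder-posterior dosages at each 1-cM grid position:

    LOD = (n/2) * log10(RSS0 / RSS1),    PVE = 100 * (1 - RSS1/RSS0)

with RSS0 the intercept-only fit.  Per-position founder effects (Add1..Add4)
are reported as deviations from their unweighted mean (sum-to-zero
convention).  The ICIM-style variant first picks background marker
cofactors by stepwise selection, then rescans the trait adjusted by
cofactors lying outside a window around the evaluation point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .simdata import GeneticMap, ParentalHaplotypes, haldane

__all__ = [
    "FounderProbMatrix",
    "ScanResult",
    "QTLCall",
    "infer_founder_probs",
    "im_scan",
    "icim_scan",
    "call_qtl",
    "name_qtl",
    "scan_to_frame",
    "calls_to_frame",
]

EPS_EMISSION = 1e-3
N_FOUNDERS = 4


@dataclass
class FounderProbMatrix:
    """Posterior founder-origin probabilities on a cM evaluation grid.

    ``probs`` has shape (n_lines, n_positions, 4); rows sum to 1.
    ``chrom_idx`` maps each grid position to its chromosome index in ``gmap``.
    """

    probs: np.ndarray
    positions_cm: np.ndarray
    chrom_idx: np.ndarray
    gmap: GeneticMap

    def __post_init__(self):
        s = self.probs.sum(axis=2)
        if not np.allclose(s, 1.0, atol=1e-9):
            raise ValueError("posterior vectors must sum to 1")

    def at_marker(self, concat_marker_index: int) -> np.ndarray:
        """Posterior (n_lines, 4) at a map marker (markers are grid points)."""
        for ci, sl in self.gmap.chrom_slices():
            if sl.start <= concat_marker_index < sl.stop:
                cm = float(np.asarray(self.gmap.cm[ci])[concat_marker_index - sl.start])
                on = (self.chrom_idx == ci) & np.isclose(self.positions_cm, cm)
                j = int(np.nonzero(on)[0][0])
                return self.probs[:, j, :]
        raise IndexError(concat_marker_index)


@dataclass
class ScanResult:
    positions_cm: np.ndarray
    chrom_idx: np.ndarray
    lod: np.ndarray
    effects: np.ndarray  # (n_positions, 4) sum-to-zero founder effects
    pve: np.ndarray  # percent, per position
    rss0: float
    rss1: np.ndarray
    n: int
    degenerate: np.ndarray = field(default=None)  # bool per position
    gmap: GeneticMap = None


@dataclass
class QTLCall:
    chrom: object
    peak_cm: float
    lod: float
    pve: float
    adds: tuple  # Add1..Add4
    left_marker: str
    right_marker: str
    start_bp: int
    end_bp: int
    treatment: str
    method: str  # "IM" | "ICIM"
    trait_kind: str  # "NN" | "RD"
    name: str = ""
    xref: str = ""


def _transition(d_cm: float) -> np.ndarray:
    """Founder-origin transition over a cM gap in a selfed four-way RIL."""
    r = float(haldane(d_cm))
    rstar = 2.0 * r / (1.0 + 2.0 * r)
    T = np.full((N_FOUNDERS, N_FOUNDERS), rstar / 3.0)
    np.fill_diagonal(T, 1.0 - rstar)
    return T


def _emissions(geno_chunk, parents_chunk, founder_coded: bool) -> np.ndarray:
    """Emission likelihoods (n_lines, n_markers, 4)."""
    n, m = geno_chunk.shape
    out = np.empty((n, m, N_FOUNDERS))
    if founder_coded:
        out[:] = 0.0  # point-mass emission: the origin is observed exactly
        missing = ~np.isin(geno_chunk, [1, 2, 3, 4])
        valid = np.where(missing, 1, geno_chunk)
        np.put_along_axis(out, (valid - 1)[:, :, None], 1.0, axis=2)
        out[missing] = 1.0
    else:
        obs = geno_chunk[:, :, None]
        fa = parents_chunk.T[None, :, :]  # (1, m, 4)
        out[:] = np.where(obs == fa, 1.0, EPS_EMISSION)
        out[(obs < 0)[:, :, 0] | np.isnan(geno_chunk.astype(float))] = 1.0
    return out


def infer_founder_probs(genotypes, gmap: GeneticMap,
                        parents: ParentalHaplotypes | None = None,
                        step_cm: float = 1.0) -> FounderProbMatrix:
    """Forward-backward founder-origin posteriors on a step_cm grid.

    ``genotypes`` is (n_lines, n_markers): biallelic 0/1 when ``parents`` is
    given, founder codes 1..4 otherwise (point-mass emissions).  The grid
    covers each chromosome end to end inclusive and always contains the
    marker positions.
    """
    geno = np.asarray(genotypes)
    if geno.shape[1] != gmap.n_markers:
        raise ValueError("genotype columns do not match the map")
    founder_coded = parents is None
    n = geno.shape[0]
    all_pos, all_ci, all_probs = [], [], []
    for ci, sl in gmap.chrom_slices():
        mcm = np.asarray(gmap.cm[ci], dtype=float)
        lo, hi = float(mcm.min()), float(mcm.max())
        grid = np.arange(lo, hi + step_cm * 0.5, step_cm) if hi > lo else np.array([lo])
        pos = np.unique(np.concatenate([grid, [hi], mcm]))
        is_marker = np.isclose(pos[:, None], mcm[None, :], atol=1e-9)
        k = pos.size
        em = np.ones((n, k, N_FOUNDERS))
        pchunk = parents.alleles[:, sl] if parents is not None else None
        marker_em = _emissions(geno[:, sl], pchunk, founder_coded)
        for j in range(k):
            hits = np.nonzero(is_marker[j])[0]
            for h in hits:
                em[:, j, :] *= marker_em[:, h, :]
        Ts = [_transition(pos[j + 1] - pos[j]) for j in range(k - 1)]
        alpha = np.empty((n, k, N_FOUNDERS))
        a = em[:, 0, :] * (1.0 / N_FOUNDERS)
        alpha[:, 0, :] = a / a.sum(axis=1, keepdims=True)
        for j in range(1, k):
            a = (alpha[:, j - 1, :] @ Ts[j - 1]) * em[:, j, :]
            alpha[:, j, :] = a / a.sum(axis=1, keepdims=True)
        beta = np.ones((n, k, N_FOUNDERS))
        for j in range(k - 2, -1, -1):
            b = (beta[:, j + 1, :] * em[:, j + 1, :]) @ Ts[j].T
            beta[:, j, :] = b / b.sum(axis=1, keepdims=True)
        post = alpha * beta
        post /= post.sum(axis=2, keepdims=True)
        all_pos.append(pos)
        all_ci.append(np.full(k, ci))
        all_probs.append(post)
    return FounderProbMatrix(probs=np.concatenate(all_probs, axis=1),
                             positions_cm=np.concatenate(all_pos),
                             chrom_idx=np.concatenate(all_ci), gmap=gmap)


def _fit_position(P: np.ndarray, y: np.ndarray, rss0: float):
    """OLS of the trait on the four posterior dosages at one position.

    Returns (rss1, sum-to-zero effects, degenerate flag).  Because dosage
    rows sum to 1 the fit absorbs the intercept; effects are recovered as
    deviations of the minimum-norm coefficient vector from its mean, which
    at a fully informative position equals the founder-class mean deviations.
    """
    coef, res, rank, _ = np.linalg.lstsq(P, y, rcond=None)
    fitted = P @ coef
    rss1 = float(((y - fitted) ** 2).sum())
    if rank <= 1 or rss1 >= rss0 - 1e-12 * max(rss0, 1.0):
        return min(rss1, rss0), np.zeros(N_FOUNDERS), True
    return rss1, coef - coef.mean(), False


def im_scan(probs: FounderProbMatrix, trait, step_cm: float = 1.0) -> ScanResult:
    """Interval-mapping scan: trait regressed on founder posteriors per position."""
    y = np.asarray(trait, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 lines")
    if n != probs.probs.shape[0]:
        raise ValueError("trait length does not match the posterior matrix")
    rss0 = float(((y - y.mean()) ** 2).sum())
    k = probs.probs.shape[1]
    lod = np.zeros(k)
    eff = np.zeros((k, N_FOUNDERS))
    pve = np.zeros(k)
    rss1 = np.full(k, rss0)
    degen = np.zeros(k, dtype=bool)
    for j in range(k):
        r1, e, dg = _fit_position(probs.probs[:, j, :], y, rss0)
        rss1[j] = r1
        eff[j] = e
        degen[j] = dg
        if not dg and r1 > 0:
            lod[j] = max(0.0, (n / 2.0) * np.log10(rss0 / r1))
            pve[j] = 100.0 * (1.0 - r1 / rss0)
    return ScanResult(positions_cm=probs.positions_cm, chrom_idx=probs.chrom_idx,
                      lod=lod, effects=eff, pve=pve, rss0=rss0, rss1=rss1,
                      n=n, degenerate=degen, gmap=probs.gmap)


def _marker_dosages(probs: FounderProbMatrix):
    """Per-marker founder-dosage design blocks (n, 3) in contrast coding,
    with marker chromosome index and cM position."""
    blocks, chroms, cms = [], [], []
    gmap = probs.gmap
    for ci, sl in gmap.chrom_slices():
        for local, cm in enumerate(np.asarray(gmap.cm[ci], dtype=float)):
            P = probs.at_marker(sl.start + local)
            blocks.append(P[:, :3] - P[:, 3:4])
            chroms.append(ci)
            cms.append(cm)
    return blocks, np.asarray(chroms), np.asarray(cms, dtype=float)


def _stepwise_cofactors(blocks, y, alpha_in, alpha_out, max_cof):
    """Forward-backward stepwise selection of marker blocks by partial F test."""
    n = y.size
    selected: list[int] = []

    def rss_of(idx_set):
        X = np.column_stack([np.ones(n)] + [blocks[i] for i in idx_set]) \
            if idx_set else np.ones((n, 1))
        fitted = X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(((y - fitted) ** 2).sum()), X.shape[1]

    cur_rss, cur_p = rss_of(selected)
    changed = True
    while changed and len(selected) < max_cof:
        changed = False
        best = (None, 1.0, cur_rss, cur_p)
        for i in range(len(blocks)):
            if i in selected:
                continue
            r, p_ = rss_of(selected + [i])
            df2 = n - p_
            if df2 <= 0 or r <= 0:
                continue
            F = ((cur_rss - r) / (p_ - cur_p)) / (r / df2)
            pval = float(stats.f.sf(F, p_ - cur_p, df2))
            if pval < best[1]:
                best = (i, pval, r, p_)
        if best[0] is not None and best[1] < alpha_in:
            selected.append(best[0])
            cur_rss, cur_p = best[2], best[3]
            changed = True
        # backward pass
        for i in list(selected):
            rest = [j for j in selected if j != i]
            r, p_ = rss_of(rest)
            df2 = n - cur_p
            if df2 <= 0 or cur_rss <= 0:
                continue
            F = ((r - cur_rss) / (cur_p - p_)) / (cur_rss / df2)
            pval = float(stats.f.sf(F, cur_p - p_, df2))
            if pval > alpha_out:
                selected = rest
                cur_rss, cur_p = r, p_
                changed = True
    return selected


def icim_scan(probs: FounderProbMatrix, trait, step_cm: float = 1.0,
              alpha_in: float = 0.001, alpha_out: float = 0.002,
              window_cm: float = 10.0) -> ScanResult:
    """ICIM-style two-stage scan.

    Stage 1 selects background marker cofactors (founder-dosage blocks) by
    stepwise regression; stage 2 rescans the trait adjusted by the selected
    cofactors that lie outside +/- window_cm of the evaluation position (a
    cofactor never adjusts its own region).  With no cofactors selected the
    result reduces exactly to ``im_scan``.
    """
    y = np.asarray(trait, dtype=float)
    n = y.size
    if n < 10:
        raise ValueError("need at least 10 lines")
    blocks, bchrom, bcm = _marker_dosages(probs)
    max_cof = max(1, n // 10)
    selected = _stepwise_cofactors(blocks, y, alpha_in, alpha_out, max_cof)
    if not selected:
        return im_scan(probs, y, step_cm)

    k = probs.probs.shape[1]
    lod = np.zeros(k)
    eff = np.zeros((k, N_FOUNDERS))
    pve = np.zeros(k)
    rss1 = np.zeros(k)
    degen = np.zeros(k, dtype=bool)
    cache: dict = {}
    for j in range(k):
        ci, cm = probs.chrom_idx[j], probs.positions_cm[j]
        outside = tuple(i for i in selected
                        if bchrom[i] != ci or abs(bcm[i] - cm) > window_cm)
        if outside not in cache:
            X = np.column_stack([np.ones(n)] + [blocks[i] for i in outside]) \
                if outside else np.ones((n, 1))
            resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
            cache[outside] = resid + y.mean()  # keep the trait scale
        y_adj = cache[outside]
        r0 = float(((y_adj - y_adj.mean()) ** 2).sum())
        r1, e, dg = _fit_position(probs.probs[:, j, :], y_adj, r0)
        rss1[j] = r1
        eff[j] = e
        degen[j] = dg
        if not dg and r1 > 0 and r0 > 0:
            lod[j] = max(0.0, (n / 2.0) * np.log10(r0 / r1))
            pve[j] = 100.0 * (1.0 - r1 / r0)
    rss0 = float(((y - y.mean()) ** 2).sum())
    return ScanResult(positions_cm=probs.positions_cm, chrom_idx=probs.chrom_idx,
                      lod=lod, effects=eff, pve=pve, rss0=rss0, rss1=rss1,
                      n=n, degenerate=degen, gmap=probs.gmap)


def _peak_interval(gmap: GeneticMap, ci: int, peak_cm: float):
    """Flanking-marker pair (ids and bp endpoints) containing the peak."""
    cm = np.asarray(gmap.cm[ci], dtype=float)
    ids = gmap.marker_ids[ci]
    bp = gmap.bp[ci] if gmap.bp is not None else np.rint(cm * 1e6).astype(np.int64)
    right = int(np.searchsorted(cm, peak_cm, side="left"))
    right = min(max(right, 1), len(cm) - 1) if len(cm) > 1 else 0
    left = right - 1 if len(cm) > 1 else 0
    if len(cm) > 1 and np.isclose(cm[right], peak_cm) and right < len(cm) - 1:
        left, right = right, right + 1
    return ids[left], ids[right], int(bp[left]), int(bp[right])


def call_qtl(scan: ScanResult, lod_threshold: float = 3.0, treatment: str = "",
             method: str = "IM", trait_kind: str = "NN") -> list[QTLCall]:
    """Maximal contiguous runs with LOD >= threshold become calls.

    The peak is the leftmost argmax within a run; the reported support is
    the marker interval containing the peak, with the map's bp endpoints
    (inclusive as printed).
    """
    calls: list[QTLCall] = []
    gmap = scan.gmap
    for ci in np.unique(scan.chrom_idx):
        on = scan.chrom_idx == ci
        pos, lod = scan.positions_cm[on], scan.lod[on]
        eff, pve = scan.effects[on], scan.pve[on]
        above = lod >= lod_threshold
        if not above.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate([[0], above.view(np.int8), [0]])))
        for s, e in zip(edges[::2], edges[1::2]):
            seg = slice(s, e)
            peak = s + int(np.argmax(lod[seg]))
            lm, rm, sbp, ebp = _peak_interval(gmap, int(ci), float(pos[peak]))
            calls.append(QTLCall(
                chrom=gmap.chrom_ids[int(ci)], peak_cm=float(pos[peak]),
                lod=float(lod[peak]), pve=float(pve[peak]),
                adds=tuple(np.round(eff[peak], 6)), left_marker=lm, right_marker=rm,
                start_bp=sbp, end_bp=ebp, treatment=treatment, method=method,
                trait_kind=trait_kind))
    return calls


def name_qtl(calls: list[QTLCall], merge: str = "overlap") -> list[QTLCall]:
    """Assign shared sequence numbers to calls in the same marker region.

    Calls whose marker intervals overlap (``merge='overlap'``) or coincide
    (``merge='identity'``) on a chromosome form one region.  Each trait kind
    (NN / RD) keeps its own per-chromosome counter, ordered by region start
    bp; a region detected for both traits carries the other name as a
    cross-reference (the ``qlNN-6-1 (qlRDNN-6-1)`` style).
    """
    if merge not in ("overlap", "identity"):
        raise ValueError("merge must be 'overlap' or 'identity'")
    by_chrom: dict = {}
    for c in calls:
        by_chrom.setdefault(c.chrom, []).append(c)
    for chrom, cs in by_chrom.items():
        cs.sort(key=lambda c: (c.start_bp, c.end_bp))
        regions: list[list[QTLCall]] = []
        for c in cs:
            placed = False
            for reg in regions:
                if merge == "identity":
                    hit = any(c.start_bp == o.start_bp and c.end_bp == o.end_bp for o in reg)
                else:
                    hit = any(c.start_bp <= o.end_bp and o.start_bp <= c.end_bp for o in reg)
                if hit:
                    reg.append(c)
                    placed = True
                    break
            if not placed:
                regions.append([c])
        regions.sort(key=lambda reg: min(c.start_bp for c in reg))
        counters = {"NN": 0, "RD": 0}
        for reg in regions:
            kinds = sorted({c.trait_kind for c in reg})
            nums = {}
            for kind in kinds:
                counters[kind] += 1
                nums[kind] = counters[kind]
            cn = str(chrom).replace("Chr", "").lstrip("0") or "0"
            names = {k: (f"qlNN-{cn}-{v}" if k == "NN" else f"qlRDNN-{cn}-{v}")
                     for k, v in nums.items()}
            for c in reg:
                c.name = names[c.trait_kind]
                other = [v for k, v in names.items() if k != c.trait_kind]
                c.xref = other[0] if other else ""
    return calls


def scan_to_frame(scan: ScanResult) -> pd.DataFrame:
    return pd.DataFrame({
        "chrom": [scan.gmap.chrom_ids[int(i)] for i in scan.chrom_idx],
        "cm": scan.positions_cm, "lod": scan.lod, "pve": scan.pve,
        "add1": scan.effects[:, 0], "add2": scan.effects[:, 1],
        "add3": scan.effects[:, 2], "add4": scan.effects[:, 3],
    })


def calls_to_frame(calls: list[QTLCall]) -> pd.DataFrame:
    rows = [{
        "qtl": c.name, "xref": c.xref, "chrom": c.chrom,
        "start_bp": c.start_bp, "end_bp": c.end_bp,
        "length_bp": c.end_bp - c.start_bp, "treatment": c.treatment,
        "method": c.method, "lod": c.lod, "pve": c.pve,
        "add1": c.adds[0], "add2": c.adds[1], "add3": c.adds[2], "add4": c.adds[3],
    } for c in calls]
    cols = ["qtl", "xref", "chrom", "start_bp", "end_bp", "length_bp",
            "treatment", "method", "lod", "pve", "add1", "add2", "add3", "add4"]
    return pd.DataFrame(rows, columns=cols)
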