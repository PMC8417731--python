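"""Founder-posterior HMM, IM/ICIM scans and QTL calling.

The HMM posterior between two informative markers is checked against a
direct two-marker enumeration over the four founder origins; scan effect
estimates at a fully informative marker are checked against the
sum-to-zero class-mean oracle computed from founder groups.
"""

import numpy as np
import pytest

from fourway_qtl import simdata
from fourway_qtl.linkscan import (QTLCall, ScanResult, call_qtl, haldane,
                                  icim_scan, im_scan, infer_founder_probs,
                                  name_qtl)
from fourway_qtl.simdata import GeneticMap


def _map_two_markers(d_cm):
    return GeneticMap(chrom_ids=["c1"], marker_ids=[["a", "b"]],
                      cm=[np.array([0.0, d_cm])],
                      bp=[np.array([1, 2 + int(d_cm * 1e4)])])


def test_founder_coded_input_gives_point_mass(gmap):
    geno = np.full((12, gmap.n_markers), 2)
    probs = infer_founder_probs(geno, gmap)
    # at marker positions the posterior is (numerically) a point mass
    assert probs.probs[:, :, 1].min() > 0.99
    assert np.allclose(probs.probs.sum(axis=2), 1.0, atol=1e-9)


def test_midpoint_posterior_matches_two_marker_enumeration():
    """P(origin at midpoint | founder 1 at 0 cM, founder 2 at 20 cM) by direct
    enumeration over transition products."""
    d = 20.0
    gmap = _map_two_markers(d)
    geno = np.array([[1, 2]])
    probs = infer_founder_probs(geno, gmap, step_cm=10.0)
    j = np.flatnonzero(np.isclose(probs.positions_cm, 10.0))[0]

    r = float(haldane(10.0))
    rstar = 2 * r / (1 + 2 * r)
    T = np.full((4, 4), rstar / 3)
    np.fill_diagonal(T, 1 - rstar)
    joint = T[0, :] * T[:, 1]  # left origin 1 (index 0), right origin 2 (index 1)
    expected = joint / joint.sum()
    assert np.allclose(probs.probs[0, j, :], expected, atol=1e-9)


def test_snp_round_trip_recovers_true_founder(gmap, population, founder_probs):
    """Posteriors inferred from the SNP matrix put >=0.95 mass on the true
    founder, averaged over lines, at positions flanked by informative
    markers (true origin constant across the flanking window)."""
    truth = population.homozygous_labels
    masses = []
    for ci, sl in gmap.chrom_slices():
        for local in (6, 12, 19):
            m = sl.start + local
            steady = ((truth[:, m - 1] == truth[:, m])
                      & (truth[:, m] == truth[:, m + 1]))
            P = founder_probs.at_marker(m)
            masses.append(P[steady, :][np.arange(steady.sum()), truth[steady, m] - 1])
    assert np.concatenate(masses).mean() >= 0.95


def test_marker_map_mismatch_rejected(gmap):
    with pytest.raises(ValueError):
        infer_founder_probs(np.ones((5, 3)), gmap)


# ------------------------------------------------------------------------ scan

def _informative_probs(labels, gmap):
    return infer_founder_probs(labels, gmap)


def test_identical_posteriors_give_lod_zero():
    gmap = _map_two_markers(10.0)
    geno = np.full((20, 2), 3)
    probs = infer_founder_probs(geno, gmap)
    res = im_scan(probs, np.random.default_rng(0).normal(size=20))
    assert np.allclose(res.lod, 0.0)
    assert res.degenerate.all()


def test_effects_match_class_mean_oracle(gmap, population, founder_probs):
    """At a fully informative marker the Add_i equal the sum-to-zero founder
    class-mean deviations, and LOD matches the direct RSS computation."""
    labels = population.homozygous_labels
    probs = _informative_probs(labels, gmap)
    rng = np.random.default_rng(2)
    cls = labels[:, 0]
    y = np.array([1.0, -0.5, 0.3, 0.0])[cls - 1] + rng.normal(0, 1, population.n_lines)
    res = im_scan(probs, y)
    j = np.flatnonzero((probs.chrom_idx == 0) & np.isclose(probs.positions_cm, 0.0))[0]
    class_means = np.array([y[cls == c].mean() for c in [1, 2, 3, 4]])
    oracle = class_means - class_means.mean()
    assert np.allclose(res.effects[j], oracle, atol=1e-8)
    fitted = class_means[cls - 1]
    rss1 = ((y - fitted) ** 2).sum()
    rss0 = ((y - y.mean()) ** 2).sum()
    assert res.lod[j] == pytest.approx(len(y) / 2 * np.log10(rss0 / rss1), abs=1e-8)


def test_lod_invariant_to_affine_trait_transform(gmap, population):
    probs = _informative_probs(population.homozygous_labels, gmap)
    y = np.random.default_rng(3).normal(14, 2, population.n_lines)
    a = im_scan(probs, y)
    b = im_scan(probs, 3.0 * y - 7.0)
    assert np.allclose(a.lod, b.lod, atol=1e-8)


def test_doubling_effect_does_not_decrease_median_peak_lod(gmap):
    meds = []
    for scale in (1.0, 2.0):
        peaks = []
        for seed in range(8):
            rng = np.random.default_rng(100 + seed)
            fm = simdata.simulate_fwril(gmap, 144, rng=rng)
            labels = fm.homozygous_labels
            probs = _informative_probs(labels, gmap)
            cls = labels[:, 7]
            y = scale * np.array([1.0, -1.0, 0.0, 0.0])[cls - 1] + rng.normal(0, 2, 144)
            peaks.append(im_scan(probs, y).lod.max())
        meds.append(np.median(peaks))
    assert meds[1] >= meds[0]


# ------------------------------------------------------------------------ ICIM

def test_icim_without_cofactors_reduces_to_im(gmap, population):
    probs = _informative_probs(population.homozygous_labels, gmap)
    y = np.random.default_rng(4).normal(size=population.n_lines)
    im = im_scan(probs, y)
    ic = icim_scan(probs, y, alpha_in=1e-12)  # nothing can enter
    assert np.allclose(im.lod, ic.lod)
    assert np.allclose(im.effects, ic.effects)


def test_cofactor_never_adjusts_its_own_region(population):
    """With a window covering the whole (single) chromosome, every same-chrom
    cofactor is excluded everywhere, so ICIM must equal plain IM even though
    cofactors are selected."""
    gmap1 = simdata.build_map(1, 100.0, 26)
    fm = simdata.simulate_fwril(gmap1, 144, rng=np.random.default_rng(5))
    labels = fm.homozygous_labels
    probs = _informative_probs(labels, gmap1)
    cls = labels[:, 12]
    y = np.array([2.0, -1.0, 0.0, -1.0])[cls - 1] + \
        np.random.default_rng(6).normal(0, 1, 144)
    im = im_scan(probs, y)
    ic = icim_scan(probs, y, alpha_in=0.01, alpha_out=0.02, window_cm=200.0)
    assert np.allclose(im.lod, ic.lod)


def test_icim_separates_linked_qtl():
    """Two QTL 60 cM apart on one chromosome: ICIM calls both at LOD >= 3 in
    >=80% of seeds; the plain-IM rate is reported for comparison."""
    gmap1 = simdata.build_map(1, 100.0, 26)
    hits_icim = hits_im = 0
    n_seeds = 15
    for seed in range(n_seeds):
        rng = np.random.default_rng(300 + seed)
        fm = simdata.simulate_fwril(gmap1, 200, rng=rng)
        labels = fm.homozygous_labels
        probs = _informative_probs(labels, gmap1)
        c1 = labels[:, 5]   # 20 cM
        c2 = labels[:, 20]  # 80 cM
        y = (np.array([2.0, -2.0, 0.0, 0.0])[c1 - 1]
             + np.array([0.0, 0.0, 2.0, -2.0])[c2 - 1]
             + rng.normal(0, 1.5, 200))

        def both_found(res):
            calls = call_qtl(res, lod_threshold=3.0)
            peaks = [c.peak_cm for c in calls]
            return (any(abs(p - 20) <= 10 for p in peaks)
                    and any(abs(p - 80) <= 10 for p in peaks)
                    and len(calls) >= 2)

        hits_im += both_found(im_scan(probs, y))
        hits_icim += both_found(icim_scan(probs, y))
    print(f"both-QTL detection rate: IM {hits_im / n_seeds:.2f}, "
          f"ICIM {hits_icim / n_seeds:.2f}")
    assert hits_icim / n_seeds >= 0.8


# --------------------------------------------------------------------- calling

def _synthetic_scan(lod, gmap):
    k = len(lod)
    return ScanResult(positions_cm=np.arange(k, dtype=float),
                      chrom_idx=np.zeros(k, dtype=int), lod=np.asarray(lod, float),
                      effects=np.zeros((k, 4)), pve=np.zeros(k), rss0=1.0,
                      rss1=np.ones(k), n=100, degenerate=np.zeros(k, bool),
                      gmap=gmap)


def test_subthreshold_scan_yields_no_calls():
    gmap = simdata.build_map(1, 30.0, 31)
    scan = _synthetic_scan(np.full(31, 2.9), gmap)
    assert call_qtl(scan) == []


def test_two_runs_give_two_calls_with_leftmost_peaks():
    gmap = simdata.build_map(1, 30.0, 31)
    lod = np.zeros(31)
    lod[3:7] = [3.5, 4.0, 4.0, 3.2]   # tie -> leftmost argmax at 4 cM
    lod[15:18] = [3.1, 5.0, 3.1]
    calls = call_qtl(_synthetic_scan(lod, gmap))
    assert len(calls) == 2
    assert calls[0].peak_cm == pytest.approx(4.0)
    assert calls[1].peak_cm == pytest.approx(16.0)


def test_overlapping_treatments_share_sequence_number():
    def mk(start, end, kind, treatment):
        return QTLCall(chrom="Chr03", peak_cm=10.0, lod=4.0, pve=11.0,
                       adds=(0, 0, 0, 0), left_marker="l", right_marker="r",
                       start_bp=start, end_bp=end, treatment=treatment,
                       method="IM", trait_kind=kind)
    calls = name_qtl([mk(100, 200, "NN", "E1D1"), mk(150, 250, "NN", "E2D2"),
                      mk(150, 250, "RD", "E2RD"), mk(1000, 1100, "NN", "E3D1")])
    names = {(c.treatment, c.trait_kind): c.name for c in calls}
    assert names[("E1D1", "NN")] == names[("E2D2", "NN")] == "qlNN-3-1"
    assert names[("E2RD", "RD")] == "qlRDNN-3-1"
    assert names[("E1D1", "NN")] != [c for c in calls if c.start_bp == 1000][0].name
    # shared region carries the cross-reference
    assert [c for c in calls if c.trait_kind == "RD"][0].xref == "qlNN-3-1"


def test_identity_merge_keeps_distinct_intervals_separate():
    def mk(start, end):
        return QTLCall(chrom="Chr01", peak_cm=1.0, lod=4.0, pve=5.0,
                       adds=(0, 0, 0, 0), left_marker="l", right_marker="r",
                       start_bp=start, end_bp=end, treatment="E1D1",
                       method="IM", trait_kind="NN")
    overlap = name_qtl([mk(100, 200), mk(150, 250)], merge="overlap")
    assert overlap[0].name == overlap[1].name
    identity = name_qtl([mk(100, 200), mk(150, 250)], merge="identity")
    assert identity[0].name != identity[1].name
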