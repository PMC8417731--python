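"""Four-way RIL simulator: genotypes, founder tracking, split-block phenotypes.

The population emulated here is a four-way recombinant inbred line (FW-RIL)
family: two founder pairs are crossed (P1 x P2 and P3 x P4), the two F1s are
intercrossed, and the double-cross progeny are selfed by single-seed descent
(SSD) until essentially homozygous.  Founder origin is tracked per haplotype
through every meiosis, so the output genotypes carry the latent founder
labels {1..4} that the genome scan later has to recover from SNP data.

Crossovers are placed as a Poisson process along the genetic map (rate 1 per
100 cM, no interference), i.e. the Haldane map function links cM distance to
recombination fraction.  Phenotypes are generated from the split-block model
read forward: grand mean, environment, main block, density, QTL allele and
allele-by-density effects, plus independent GE / GDE / residual noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "ParentalHaplotypes",
    "FounderMatrix",
    "QTLSpec",
    "DesignSpec",
    "build_map",
    "haldane",
    "simulate_parental_haplotypes",
    "simulate_fwril",
    "founder_to_snp",
    "simulate_phenotypes",
    "default_design",
    "default_qtl",
    "write_genotype_csv",
    "write_map_csv",
    "write_pheno_csv",
]

N_FOUNDERS = 4


def haldane(d_cm):
    """Recombination fraction for a map distance in cM (no interference)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


@dataclass
class GeneticMap:
    """Ordered marker map: one entry per chromosome.

    ``chrom_ids`` are arbitrary labels; ``cm`` arrays must be nondecreasing
    within a chromosome and ``bp`` arrays, when present, strictly increasing.
    """

    chrom_ids: list
    marker_ids: list  # list of lists, one per chromosome
    cm: list  # list of float arrays
    bp: list | None = None  # list of int arrays or None

    def __post_init__(self):
        if not self.chrom_ids:
            raise ValueError("map must contain at least one chromosome")
        for c, pos in zip(self.chrom_ids, self.cm):
            pos = np.asarray(pos, dtype=float)
            if pos.size < 1:
                raise ValueError(f"chromosome {c} has no markers")
            if np.any(np.diff(pos) < 0):
                raise ValueError(f"cM positions decrease on chromosome {c}")
        if self.bp is not None:
            for c, pos in zip(self.chrom_ids, self.bp):
                pos = np.asarray(pos)
                if pos.size > 1 and np.any(np.diff(pos) <= 0):
                    raise ValueError(f"bp positions not increasing on chromosome {c}")

    @property
    def n_chrom(self) -> int:
        return len(self.chrom_ids)

    @property
    def n_markers(self) -> int:
        return int(sum(len(m) for m in self.marker_ids))

    def chrom_slices(self):
        """Yield (chrom index, slice into the concatenated marker axis)."""
        start = 0
        for i, ids in enumerate(self.marker_ids):
            yield i, slice(start, start + len(ids))
            start += len(ids)

    def all_marker_ids(self) -> list:
        return [m for ids in self.marker_ids for m in ids]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.chrom_ids):
            bp = self.bp[i] if self.bp is not None else [np.nan] * len(self.marker_ids[i])
            for mid, cm, b in zip(self.marker_ids[i], self.cm[i], bp):
                rows.append((c, mid, float(cm), b))
        return pd.DataFrame(rows, columns=["chrom", "marker", "cm", "bp"])

    def marker_index(self, chrom, cm_pos) -> int:
        """Concatenated index of the marker nearest ``cm_pos`` on ``chrom``."""
        ci = self.chrom_ids.index(chrom)
        for i, sl in self.chrom_slices():
            if i == ci:
                pos = np.asarray(self.cm[ci], dtype=float)
                return sl.start + int(np.argmin(np.abs(pos - cm_pos)))
        raise KeyError(chrom)


@dataclass
class ParentalHaplotypes:
    """Fully homozygous founder genomes: alleles (4, n_markers) coded 0/1."""

    alleles: np.ndarray

    def __post_init__(self):
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape[0] != N_FOUNDERS:
            raise ValueError("exactly 4 founders required")
        if not np.isin(self.alleles, [0, 1]).all():
            raise ValueError("founder alleles must be 0/1")


@dataclass
class FounderMatrix:
    """Founder-of-origin labels per line, marker and haplotype.

    ``labels`` has shape (n_lines, n_markers, 2) with values in {1..4};
    after the forced-homozygosis step both haplotypes are equal, and
    ``homozygous_labels`` gives the collapsed (n_lines, n_markers) view.
    """

    labels: np.ndarray
    line_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.isin(self.labels, [1, 2, 3, 4]).all():
            raise ValueError("founder labels must lie in {1..4}")
        if not self.line_ids:
            self.line_ids = [f"L{i + 1:03d}" for i in range(self.labels.shape[0])]

    @property
    def n_lines(self) -> int:
        return self.labels.shape[0]

    @property
    def homozygous_labels(self) -> np.ndarray:
        if not (self.labels[:, :, 0] == self.labels[:, :, 1]).all():
            raise ValueError("matrix contains heterozygous loci")
        return self.labels[:, :, 0]


@dataclass
class QTLSpec:
    """A planted QTL: position plus four founder-allele effects and their
    allele-by-density interaction (4 x n_densities), in node-count units."""

    chrom: object
    cm: float
    effects: np.ndarray  # (4,)
    interaction: np.ndarray | None = None  # (4, n_densities)
    name: str = "q"

    def __post_init__(self):
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (N_FOUNDERS,):
            raise ValueError("effects must have length 4")
        if self.interaction is not None:
            self.interaction = np.asarray(self.interaction, dtype=float)
            if self.interaction.shape[0] != N_FOUNDERS:
                raise ValueError("interaction must be 4 x n_densities")


@dataclass
class DesignSpec:
    """Split-block field design: densities are main plots within replicate
    blocks, genotypes are subplots; repeated over environments."""

    n_lines: int = 144
    env_labels: tuple = ("E1", "E2", "E3", "E4", "E5")
    env_effects: tuple = (0.8, -1.0, -1.4, -0.9, 0.2)
    density_labels: tuple = ("D1", "D2")
    density_effects: tuple = (-0.6, 0.6)
    n_reps: int = 3
    block_effects: tuple = (0.2, 0.0, -0.2)
    var_ge: float = 0.8
    var_gde: float = 0.9
    var_resid: float = 2.25  # residual SD ~1.5 nodes
    mu: float = 14.0
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1 or len(self.density_labels) < 1:
            raise ValueError("need >=1 replicate and >=1 density")
        for v in (self.var_ge, self.var_gde, self.var_resid):
            if v < 0:
                raise ValueError("variances must be nonnegative")
        if len(self.block_effects) != self.n_reps:
            raise ValueError("one block effect per replicate required")
        if len(self.env_effects) != len(self.env_labels):
            raise ValueError("one effect per environment required")
        if len(self.density_effects) != len(self.density_labels):
            raise ValueError("one effect per density required")


def build_map(n_chrom, chrom_length_cm, n_markers_per_chrom, bp_per_cm=1_000_000.0) -> GeneticMap:
    """Evenly spaced markers from 0 to ``chrom_length_cm`` on every chromosome."""
    if n_chrom < 1 or n_markers_per_chrom < 1:
        raise ValueError("counts must be positive")
    if chrom_length_cm < 0:
        raise ValueError("chromosome length must be nonnegative")
    if n_markers_per_chrom == 1:
        cm = np.array([0.0])
    else:
        cm = np.linspace(0.0, chrom_length_cm, n_markers_per_chrom)
    bp = np.rint(cm * bp_per_cm).astype(np.int64)
    chrom_ids = [f"Chr{c + 1:02d}" for c in range(n_chrom)]
    return GeneticMap(
        chrom_ids=chrom_ids,
        marker_ids=[[f"{c}_M{i + 1}" for i in range(n_markers_per_chrom)] for c in chrom_ids],
        cm=[cm.copy() for _ in chrom_ids],
        bp=[bp.copy() for _ in chrom_ids],
    )


def simulate_parental_haplotypes(gmap: GeneticMap, rng: np.random.Generator) -> ParentalHaplotypes:
    """Founder SNP alleles drawn i.i.d. Bernoulli(0.5) per founder and marker."""
    return ParentalHaplotypes(rng.integers(0, 2, size=(N_FOUNDERS, gmap.n_markers), dtype=np.int8))


def _gametes(hap: np.ndarray, gmap: GeneticMap, rng: np.random.Generator) -> np.ndarray:
    """One gamete per individual from a (n, m, 2) haplotype-pair array.

    Crossovers fall independently in each marker interval with the Haldane
    probability for its cM length; chromosomes assort independently.
    """
    n = hap.shape[0]
    out = np.empty(hap.shape[:2], dtype=hap.dtype)
    for ci, sl in gmap.chrom_slices():
        pos = np.asarray(gmap.cm[ci], dtype=float)
        k = pos.size
        start = rng.integers(0, 2, size=n)
        if k > 1:
            r = haldane(np.diff(pos))
            switches = rng.random((n, k - 1)) < r
            idx = (start[:, None] + np.concatenate(
                [np.zeros((n, 1), dtype=np.int64), np.cumsum(switches, axis=1)], axis=1)) % 2
        else:
            idx = start[:, None]
        out[:, sl] = np.take_along_axis(hap[:, sl, :], idx[..., None], axis=2)[..., 0]
    return out


def simulate_fwril(gmap: GeneticMap, n_lines: int, n_selfing_generations: int = 5,
                   rng: np.random.Generator | None = None, seed: int | None = None) -> FounderMatrix:
    """Simulate the (P1xP2) x (P3xP4) pedigree followed by SSD selfing.

    Each line descends from an independent double-cross seed.  After the
    final selfing generation, residual heterozygosity is fixed by drawing
    one more meiotic gamete and doubling it: marginally a fair coin per
    heterozygous locus, but linkage-respecting, so completely linked loci
    never fix to different founders.
    """
    if n_lines < 1:
        raise ValueError("n_lines must be >= 1")
    if n_selfing_generations < 1:
        raise ValueError("need at least one selfing generation")
    if rng is None:
        rng = np.random.default_rng(seed)
    m = gmap.n_markers
    f1_12 = np.broadcast_to(np.array([1, 2], dtype=np.int8), (n_lines, m, 2)).copy()
    f1_34 = np.broadcast_to(np.array([3, 4], dtype=np.int8), (n_lines, m, 2)).copy()
    dc = np.stack([_gametes(f1_12, gmap, rng), _gametes(f1_34, gmap, rng)], axis=2)
    for _ in range(n_selfing_generations):
        dc = np.stack([_gametes(dc, gmap, rng), _gametes(dc, gmap, rng)], axis=2)
    fixed = _gametes(dc, gmap, rng)
    return FounderMatrix(labels=np.stack([fixed, fixed], axis=2))


def founder_to_snp(fm: FounderMatrix, parents: ParentalHaplotypes) -> np.ndarray:
    """Map founder labels to founder SNP alleles: (n_lines, n_markers) 0/1."""
    labels = fm.homozygous_labels
    if parents.alleles.shape[1] != labels.shape[1]:
        raise ValueError("marker sets of genotypes and parents differ")
    return np.take_along_axis(parents.alleles.T[None, :, :],
                              (labels - 1)[:, :, None], axis=2)[:, :, 0]


def _qtl_genotype(fm: FounderMatrix, gmap: GeneticMap, q: QTLSpec) -> np.ndarray:
    """Founder class (1..4) of each line at the marker nearest the QTL."""
    return fm.homozygous_labels[:, gmap.marker_index(q.chrom, q.cm)]


def simulate_phenotypes(fm: FounderMatrix, gmap: GeneticMap, qtl: list[QTLSpec],
                        design: DesignSpec,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Split-block phenotypes read forward from the joint ANOVA model.

    Each record is mu + E_e + R_r + D_j + sum_q [a_i(q) + ad_i(q),j]
    + GE_ei + GDE_eij + eps, with GE, GDE and eps drawn independently at the
    variances in ``design``.  Returns a long table
    (line, env, density, rep, value).
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    n = fm.n_lines
    envs, dens = design.env_labels, design.density_labels
    ne, nd, nr = len(envs), len(dens), design.n_reps

    genetic = np.zeros((n, nd))
    for q in qtl:
        cls = _qtl_genotype(fm, gmap, q) - 1
        genetic += q.effects[cls][:, None]
        if q.interaction is not None:
            if q.interaction.shape[1] != nd:
                raise ValueError("interaction matrix width must equal n_densities")
            genetic += q.interaction[cls, :]

    ge = rng.normal(0.0, np.sqrt(design.var_ge), size=(ne, n))
    gde = rng.normal(0.0, np.sqrt(design.var_gde), size=(ne, n, nd))
    eps = rng.normal(0.0, np.sqrt(design.var_resid), size=(ne, n, nd, nr))

    value = (design.mu
             + np.asarray(design.env_effects)[:, None, None, None]
             + np.asarray(design.density_effects)[None, None, :, None]
             + np.asarray(design.block_effects)[None, None, None, :]
             + genetic[None, :, :, None]
             + ge[:, :, None, None]
             + gde[:, :, :, None]
             + eps)

    idx = pd.MultiIndex.from_product(
        [envs, fm.line_ids, dens, range(1, nr + 1)],
        names=["env", "line", "density", "rep"])
    out = pd.DataFrame({"value": value.ravel()}, index=idx).reset_index()
    return out[["line", "env", "density", "rep", "value"]]


def default_design(seed: int = 0, n_lines: int = 144) -> DesignSpec:
    """The study conditions: 144 lines, 5 environments x 2 densities x 3 reps."""
    return DesignSpec(n_lines=n_lines, seed=seed)


def default_qtl(gmap: GeneticMap) -> list[QTLSpec]:
    """Three QTL with four-allele effects and a density interaction, sized so
    that treatment means and SDs land in the observed soybean MSNN range
    (means ~12-17 nodes, SD ~1.7-3.2)."""
    chroms = [gmap.chrom_ids[i % gmap.n_chrom] for i in range(3)]
    length = float(np.asarray(gmap.cm[0]).max())
    inter = np.array([[0.4, -0.4], [0.0, 0.0], [-0.4, 0.4], [0.0, 0.0]])
    return [
        QTLSpec(chroms[0], 0.3 * length, effects=(1.5, -0.5, -0.5, -0.5),
                interaction=inter, name="q1"),
        QTLSpec(chroms[1], 0.7 * length, effects=(-0.8, 0.8, 0.4, -0.4), name="q2"),
        QTLSpec(chroms[2], 0.5 * length, effects=(0.0, -1.0, 0.5, 0.5),
                interaction=0.5 * inter, name="q3"),
    ]


def write_genotype_csv(path, fm: FounderMatrix, gmap: GeneticMap,
                       parents: ParentalHaplotypes | None = None) -> None:
    """Lines x markers CSV; founder codes by default, 0/1 alleles if parents given."""
    mat = founder_to_snp(fm, parents) if parents is not None else fm.homozygous_labels
    pd.DataFrame(mat, index=pd.Index(fm.line_ids, name="line"),
                 columns=gmap.all_marker_ids()).to_csv(path)


def write_map_csv(path, gmap: GeneticMap) -> None:
    gmap.to_frame().to_csv(path, index=False)


def read_map_csv(path) -> GeneticMap:
    mp = pd.read_csv(path)
    chrom_ids = list(mp["chrom"].unique())
    return GeneticMap(
        chrom_ids=chrom_ids,
        marker_ids=[mp.loc[mp["chrom"] == c, "marker"].tolist() for c in chrom_ids],
        cm=[mp.loc[mp["chrom"] == c, "cm"].to_numpy(dtype=float) for c in chrom_ids],
        bp=[mp.loc[mp["chrom"] == c, "bp"].to_numpy(dtype=np.int64) for c in chrom_ids])


def read_genotype_csv(path) -> pd.DataFrame:
    """Lines x markers matrix as written by ``write_genotype_csv``."""
    return pd.read_csv(path, index_col=0)


def write_parents_csv(path, parents: ParentalHaplotypes, gmap: GeneticMap) -> None:
    pd.DataFrame(parents.alleles, index=[f"P{i + 1}" for i in range(N_FOUNDERS)],
                 columns=gmap.all_marker_ids()).to_csv(path)


def read_parents_csv(path) -> ParentalHaplotypes:
    return ParentalHaplotypes(pd.read_csv(path, index_col=0).to_numpy())


def write_pheno_csv(path, pheno: pd.DataFrame) -> None:
    pheno.to_csv(path, index=False)
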