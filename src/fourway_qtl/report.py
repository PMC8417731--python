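"""Cross-result logic: stability, candidate rules, co-location, Venn tallies,
candidate-gene windows.

A QTL/QTN is "stable" (default rule) when its support set is repeated in at
least one dimension — methods, densities (D1/D2/RD) or environments; the
strict rule demands repetition in all three.  Candidate selection follows
two filters: linkage QTL must be stable, explain >10% of the phenotypic
variance and span <600 kb; association QTN must be multi-method,
multi-environment or co-located with a linkage interval, and have r2 >10%.
Candidate windows extend each interval by 100 kb on either side (the LD
scale), clamped at zero, and genes intersect a window by half-open overlap.
Coordinates are 0-based half-open internally and printed 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StabilityRecord",
    "Window",
    "classify_stability",
    "select_candidates",
    "colocate",
    "venn_tallies",
    "candidate_windows",
    "intersect_genes",
    "read_bed",
    "read_gff3_genes",
]

PVE_MIN = 10.0  # percent
MAX_INTERVAL_BP = 600_000
FLANK_BP = 100_000


@dataclass
class StabilityRecord:
    qtl_id: str
    methods: frozenset
    densities: frozenset
    environments: frozenset
    stable: bool
    rule: str  # "default" | "strict"


@dataclass
class Window:
    chrom: object
    start: int  # 0-based half-open
    end: int
    source_id: str = ""

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("window start must precede end")


def _treatment_split(t: str) -> tuple[str, str]:
    """Split 'E2D1' / 'E4RD' into (environment, density-or-RD)."""
    for tag in ("D1", "D2", "RD"):
        if t.endswith(tag):
            return t[: -len(tag)], tag
    raise ValueError(f"unrecognized treatment label: {t}")


def classify_stability(records: pd.DataFrame, rule: str = "default") -> list[StabilityRecord]:
    """Support-set stability per QTL id.

    ``records`` needs columns ``id``, ``method``, ``treatment`` (E*D1/E*D2/
    E*RD).  Default rule: stable iff >=2 distinct values in at least one of
    {methods, densities, environments}; strict: all three dimensions.
    """
    if rule not in ("default", "strict"):
        raise ValueError("rule must be 'default' or 'strict'")
    out = []
    for qid, g in records.groupby("id", sort=True):
        envs, dens = zip(*(_treatment_split(t) for t in g["treatment"]))
        methods = frozenset(g["method"])
        denss = frozenset(dens)
        envss = frozenset(envs)
        multi = [len(methods) >= 2, len(denss) >= 2, len(envss) >= 2]
        stable = all(multi) if rule == "strict" else any(multi)
        out.append(StabilityRecord(qid, methods, denss, envss, stable, rule))
    return out


def select_candidates(stability: list[StabilityRecord], calls: pd.DataFrame,
                      qtns: pd.DataFrame | None = None,
                      colocated_ids: set | None = None) -> pd.DataFrame:
    """Apply the candidate filters; returns one row per id with a rule trace.

    ``calls`` (linkage): columns id, pve, start_bp, end_bp — candidate iff
    stable AND max PVE > 10% AND interval length < 600 kb.
    ``qtns`` (association): columns id, r2 — candidate iff (>=2 methods OR
    >=2 environments OR co-located with a linkage interval) AND r2 > 10%.
    """
    stab = {s.qtl_id: s for s in stability}
    rows = []
    for qid, g in calls.groupby("id", sort=True):
        s = stab.get(qid)
        length = int(g["end_bp"].max() - g["start_bp"].min())
        pve = float(g["pve"].max())
        checks = {"stable": bool(s and s.stable), "pve_gt_10": pve > PVE_MIN,
                  "length_lt_600kb": length < MAX_INTERVAL_BP}
        rows.append({"id": qid, "kind": "linkage", "pve": pve, "length_bp": length,
                     **checks, "candidate": all(checks.values()),
                     "trace": ";".join(f"{k}={v}" for k, v in checks.items())})
    if qtns is not None and len(qtns):
        colocated_ids = colocated_ids or set()
        for qid, g in qtns.groupby("id", sort=True):
            s = stab.get(qid)
            support = bool(s and (len(s.methods) >= 2 or len(s.environments) >= 2)) \
                or qid in colocated_ids
            r2 = float(g["r2"].max())
            checks = {"multi_support_or_colocated": support, "r2_gt_10": r2 > PVE_MIN}
            rows.append({"id": qid, "kind": "association", "pve": r2,
                         "length_bp": 0, **checks, "candidate": all(checks.values()),
                         "trace": ";".join(f"{k}={v}" for k, v in checks.items())})
    return pd.DataFrame(rows)


def colocate(calls: pd.DataFrame, qtns: pd.DataFrame) -> pd.DataFrame:
    """(QTN, QTL) pairs where the QTN position falls inside the QTL's
    physical marker interval, endpoints inclusive, same chromosome."""
    rows = []
    for _, q in qtns.iterrows():
        hit = calls[(calls["chrom"] == q["chrom"])
                    & (calls["start_bp"] <= q["bp"])
                    & (q["bp"] <= calls["end_bp"])]
        for _, c in hit.iterrows():
            rows.append({"qtn_id": q["id"], "qtl_id": c["id"], "chrom": q["chrom"],
                         "bp": int(q["bp"]), "start_bp": int(c["start_bp"]),
                         "end_bp": int(c["end_bp"])})
    out = pd.DataFrame(rows, columns=["qtn_id", "qtl_id", "chrom", "bp",
                                      "start_bp", "end_bp"])
    return out.drop_duplicates(["qtn_id", "qtl_id"]).reset_index(drop=True)


def venn_tallies(supports: dict) -> dict:
    """Counts of distinct ids per region of the set partition.

    ``supports`` maps id -> iterable of labels (e.g. densities or
    environments the id was seen in).  Keys of the result are sorted
    '+'-joined label combinations; values are id counts; 'total' is the
    number of distinct ids.
    """
    regions: dict = {}
    for qid, labels in supports.items():
        key = "+".join(sorted(set(labels)))
        if key:
            regions[key] = regions.get(key, 0) + 1
    regions["total"] = len([k for k, v in supports.items() if set(v)])
    return regions


def candidate_windows(candidates: pd.DataFrame, flank_bp: int = FLANK_BP) -> list[Window]:
    """100-kb-flanked windows around candidate intervals, clamped at 0.

    ``candidates`` needs columns id, chrom, start_bp, end_bp (half-open).
    """
    out = []
    for _, row in candidates.iterrows():
        start = max(0, int(row["start_bp"]) - flank_bp)
        end = int(row["end_bp"]) + flank_bp
        out.append(Window(chrom=row["chrom"], start=start, end=end,
                          source_id=str(row["id"])))
    return out


def intersect_genes(windows: list[Window], annotation: pd.DataFrame) -> pd.DataFrame:
    """Genes whose span overlaps a window (half-open overlap test).

    ``annotation`` needs columns chrom, start, end, gene_id (0-based
    half-open, as produced by ``read_bed`` / ``read_gff3_genes``).
    """
    rows = []
    for w in windows:
        hit = annotation[(annotation["chrom"] == w.chrom)
                         & (annotation["start"] < w.end)
                         & (w.start < annotation["end"])]
        for _, g in hit.iterrows():
            rows.append({"window_id": w.source_id, "chrom": w.chrom,
                         "gene_id": g["gene_id"], "gene_start": int(g["start"]),
                         "gene_end": int(g["end"])})
    return pd.DataFrame(rows, columns=["window_id", "chrom", "gene_id",
                                       "gene_start", "gene_end"])


def read_bed(path) -> pd.DataFrame:
    """BED (>=3 columns, 0-based half-open); column 4 is the gene id if present."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    n_bad = 0
    if df.shape[1] < 3:
        raise ValueError("BED needs at least 3 columns")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["gene_id"] = df.iloc[:, 3] if df.shape[1] > 3 else [
        f"feature_{i}" for i in range(len(df))]
    ok = pd.to_numeric(out["start"], errors="coerce").notna() \
        & pd.to_numeric(out["end"], errors="coerce").notna()
    n_bad = int((~ok).sum())
    out = out[ok].astype({"start": int, "end": int}).reset_index(drop=True)
    out.attrs["n_skipped"] = n_bad
    return out


def read_gff3_genes(path) -> pd.DataFrame:
    """Gene features from GFF3, converted to 0-based half-open coordinates."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "source", "type", "start", "end",
                            "score", "strand", "phase", "attrs"],
                     dtype=str)
    n_bad = int(df[["start", "end"]].isna().any(axis=1).sum())
    df = df[df["type"] == "gene"].copy()
    start = pd.to_numeric(df["start"], errors="coerce")
    end = pd.to_numeric(df["end"], errors="coerce")
    ok = start.notna() & end.notna()
    n_bad += int((~ok).sum())
    df = df[ok]
    gid = df["attrs"].str.extract(r"ID=([^;]+)")[0].fillna("unknown")
    out = pd.DataFrame({"chrom": df["chrom"].to_numpy(),
                        "start": (start[ok].astype(int) - 1).to_numpy(),
                        "end": end[ok].astype(int).to_numpy(),
                        "gene_id": gid.to_numpy()})
    out.attrs["n_skipped"] = n_bad
    return out
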