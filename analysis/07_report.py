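"""Cross-result report: stability, candidates, co-location, Venn tallies,
candidate windows and gene intersection.

Classifies every named QTL/QTN by its support across methods, densities
(D1/D2/RD) and environments, applies the candidate filters (stable, PVE >
10%, interval < 600 kb for linkage; multi-support or co-location plus
r2 > 10% for association), pairs QTN positions with QTL intervals, tallies
the density and environment Venn partitions, and intersects 100-kb-flanked
candidate windows with a small synthetic gene annotation.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from fourway_qtl import report

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "report"
OUT.mkdir(parents=True, exist_ok=True)

calls = pd.read_csv(ROOT / "linkage" / "qtl_calls.csv").rename(columns={"qtl": "id"})
qtns = pd.read_csv(ROOT / "qtn_records.csv").rename(columns={"qtn": "id"})

stab_l = report.classify_stability(calls[["id", "method", "treatment"]])
stab_a = report.classify_stability(qtns[["id", "method", "treatment"]])
coloc = report.colocate(calls, qtns)
coloc.to_csv(OUT / "colocation.csv", index=False)

cand = report.select_candidates(stab_l + stab_a, calls, qtns,
                                set(coloc["qtn_id"]))
cand.to_csv(OUT / "candidates.csv", index=False)

tallies = {
    "linkage_by_density": report.venn_tallies({s.qtl_id: s.densities for s in stab_l}),
    "linkage_by_environment": report.venn_tallies({s.qtl_id: s.environments for s in stab_l}),
    "assoc_by_density": report.venn_tallies({s.qtl_id: s.densities for s in stab_a}),
    "assoc_by_environment": report.venn_tallies({s.qtl_id: s.environments for s in stab_a}),
}
(OUT / "venn.json").write_text(json.dumps(tallies, indent=2) + "\n")

sel = cand[cand["candidate"] & (cand["kind"] == "linkage")]
regions = (calls[calls["id"].isin(sel["id"])]
           .groupby("id").agg(chrom=("chrom", "first"),
                              start_bp=("start_bp", "min"),
                              end_bp=("end_bp", "max")).reset_index())
windows = report.candidate_windows(regions, flank_bp=100_000)
with open(OUT / "windows.bed", "w") as fh:
    for w in windows:
        fh.write(f"{w.chrom}\t{w.start}\t{w.end}\t{w.source_id}\n")

# synthetic gene annotation: evenly tiled gene models per chromosome, purely
# positional stand-in for a real genome annotation
rows = []
for chrom in calls["chrom"].unique():
    for k, start in enumerate(range(0, 13_000_000, 200_000)):
        rows.append({"chrom": chrom, "start": start, "end": start + 50_000,
                     "gene_id": f"synth.{chrom}.{k + 1:03d}"})
ann = pd.DataFrame(rows)
genes = report.intersect_genes(windows, ann)
genes.to_csv(OUT / "window_genes.csv", index=False)

n_stable = sum(s.stable for s in stab_l)
print(f"linkage: {len(stab_l)} QTL, {n_stable} stable, "
      f"{len(sel)} candidate after PVE/length filters")
print(f"association: {len(stab_a)} QTN, "
      f"{int((cand['candidate'] & (cand['kind'] == 'association')).sum())} candidate; "
      f"{coloc['qtn_id'].nunique()} QTN co-located with QTL intervals")
print("density Venn (linkage):", tallies["linkage_by_density"])
print("environment Venn (linkage):", tallies["linkage_by_environment"])
print(f"{len(windows)} candidate windows covering "
      f"{genes['gene_id'].nunique()} synthetic gene models")
print(f"wrote report tables to {OUT}")
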