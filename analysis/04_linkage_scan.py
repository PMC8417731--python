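"""Genome scans: founder posteriors, IM and ICIM, QTL calling and naming.

Infers founder-origin posteriors from the SNP matrix on a 1-cM grid, scans
every treatment (each environment's D1 and D2 line means plus the RD trait)
with both the plain interval-mapping regression and the cofactor-adjusted
ICIM-style scan, calls QTL at LOD >= 3, and assigns region-merged names
(qlNN-* for the node-number trait, qlRDNN-* for response to density).
"""

from pathlib import Path

import pandas as pd

from fourway_qtl import linkscan, simdata

ROOT = Path(__file__).resolve().parents[1] / "results"
SIM = ROOT / "sim"
OUT = ROOT / "linkage"
OUT.mkdir(parents=True, exist_ok=True)

gmap = simdata.read_map_csv(SIM / "map.csv")
parents = simdata.read_parents_csv(SIM / "parents.csv")
snp = simdata.read_genotype_csv(SIM / "genotypes_snp.csv")
phe = pd.read_csv(SIM / "phenotypes.csv")
rd = pd.read_csv(ROOT / "rd.csv")
lines = list(snp.index)

probs = linkscan.infer_founder_probs(snp.to_numpy(), gmap, parents, step_cm=1.0)

traits = {}
lm = phe.groupby(["env", "density", "line"])["value"].mean()
for (env, dens), g in lm.groupby(["env", "density"]):
    traits[(f"{env}{dens}", "NN")] = g.droplevel(["env", "density"]).reindex(lines)
for env, g in rd.groupby("env"):
    traits[(f"{env}RD", "RD")] = g.set_index("line")["RD"].reindex(lines)

all_calls = []
for (treatment, kind), y in sorted(traits.items()):
    for method, fn in [("IM", linkscan.im_scan), ("ICIM", linkscan.icim_scan)]:
        res = fn(probs, y.to_numpy())
        all_calls += linkscan.call_qtl(res, lod_threshold=3.0,
                                       treatment=treatment, method=method,
                                       trait_kind=kind)
linkscan.name_qtl(all_calls)

tab = linkscan.calls_to_frame(all_calls).sort_values(["chrom", "start_bp", "qtl"])
tab.to_csv(OUT / "qtl_calls.csv", index=False)
print(f"{len(tab)} detections over {tab['qtl'].nunique()} named QTL "
      f"({(tab['method'] == 'ICIM').sum()} ICIM, {(tab['method'] == 'IM').sum()} IM)")
print(tab[["qtl", "chrom", "start_bp", "end_bp", "treatment", "method",
           "lod", "pve"]].round(2).to_string(index=False))
print(f"wrote {OUT / 'qtl_calls.csv'}")
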