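#!/usr/bin/env python
"""Compare GWAS hits with the largest GBLUP and emBayesB marker effects.

On each full cohort: single-marker GWAS at the trait's threshold; RR-BLUP
and emBayesB marker effects; then, for the same number k of markers (GWAS
hits vs each method's top-|effect| markers), the additive variance the
subset explains relative to the all-marker kernel, each estimated by REML.
Writes the comparison table, marker-effect TSVs and Manhattan-style plots
under results/gwas/.
"""

import argparse
import pathlib

import numpy as np
import pandas as pd

from croaker_gs import published
from croaker_gs.embayesb import fit_embayesb
from croaker_gs.gblup import MarkerEffects, solve_rrblup
from croaker_gs.genotype_data import allele_frequencies, read_genotypes, standardize
from croaker_gs.gwas import (
    plot_manhattan,
    significant_markers,
    single_marker_scan,
    top_effect_markers,
)
from croaker_gs.reml import fit_reml, variance_explained
from croaker_gs.gblup import build_g_matrix


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--qc", type=pathlib.Path, default=pathlib.Path("results/qc"))
    ap.add_argument("--cohorts", type=pathlib.Path,
                    default=pathlib.Path("results/cohorts"))
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results/gwas"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    rows = []
    for name in ("bw", "bl", "hufa"):
        g = read_genotypes(str(args.qc / f"{name}.genotypes.tsv"),
                           sidecar=str(args.qc / f"{name}.markers.tsv"))
        phen = pd.read_csv(args.cohorts / f"{name}.phenotypes.tsv", sep="\t")
        y, sex = phen.iloc[:, 1].to_numpy(float), phen["sex"].to_numpy(int)
        qtl_ids = set(pd.read_csv(args.cohorts / f"{name}.qtl.tsv",
                                  sep="\t")["marker_id"])
        W = np.column_stack([np.ones(len(y)), (sex == 2).astype(float)])
        threshold = published.GWAS_THRESHOLDS[name]

        scan = single_marker_scan(y, sex, g)
        scan.table.to_csv(args.out / f"{name}.assoc.tsv", sep="\t", index=False)
        hits = significant_markers(scan, threshold)
        k = len(hits)
        print(f"== {name}: {k} significant markers at p < {threshold:g} ==")
        if k < 2:
            print("  too few hits for a variance comparison; skipping cohort")
            continue

        f = allele_frequencies(g.codes)
        xs = standardize(g.codes, freqs=f, monomorphic="zero")
        h2 = fit_reml(y, W, build_g_matrix(g.codes).G).h2
        rr = solve_rrblup(y, sex, xs, h2,
                          marker_ids=list(g.markers["marker_id"]))
        em = fit_embayesb(y, sex, xs, h2_init=h2, seed=args.seed)
        em_eff = MarkerEffects(effects=em.effects, method="embayesb",
                               marker_ids=list(g.markers["marker_id"]))
        eff_table = g.markers.copy()
        eff_table["rrblup"], eff_table["embayesb"] = rr.effects, em.effects
        eff_table["inclusion_prob"] = em.inclusion_prob
        eff_table.to_csv(args.out / f"{name}.effects.tsv", sep="\t", index=False)

        subsets = {
            "gwas": hits,
            "gblup": top_effect_markers(rr, k, g.markers),
            "embayesb": top_effect_markers(em_eff, k, g.markers),
        }
        for method, ids in subsets.items():
            ve = variance_explained(y, W, g, ids)
            rows.append({"cohort": name, "method": method, "n_snps": k,
                         "v_subset": round(ve.v_sub, 3),
                         "v_all": round(ve.v_all, 3),
                         "proportion_pct": round(100 * ve.proportion, 1),
                         "true_qtls_in_subset": len(qtl_ids & set(ids))})
            print(f"  {method:9s}: V_sub={ve.v_sub:8.3f}  "
                  f"({100*ve.proportion:5.1f}% of V_A)  "
                  f"true QTLs captured: {len(qtl_ids & set(ids))}")

        for method, eff in (("gblup", rr.effects), ("embayesb", em.effects)):
            plot_manhattan(g.markers, np.abs(eff), f"|effect| ({method})",
                           str(args.out / f"{name}.{method}.manhattan.png"),
                           highlight=hits,
                           title=f"{name}: {method} effects, GWAS hits marked")

    pd.DataFrame(rows).to_csv(args.out / "variance_explained.tsv",
                              sep="\t", index=False)


if __name__ == "__main__":
    main()
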