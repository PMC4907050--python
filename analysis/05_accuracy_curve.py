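#!/usr/bin/env python
"""Accuracy-curve fits: published abilities (desk-scale) and simulated CV means.

Part 1 refits the linearized accuracy curve to the study's printed mean
abilities with its printed heritabilities, recovering the published
effective locus counts M and the required training sizes for accuracy 0.8.
Part 2 applies the identical machinery to the synthetic cross-validation
means from step 04, using the full-cohort REML h² from step 03, and compares
the fitted M with the simulator's true QTL count.
"""

import argparse
import pathlib

import pandas as pd

from croaker_gs import published
from croaker_gs.accuracy_curve import curve_table, fit_curve

TARGET = published.TARGET_ACCURACY


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cv", type=pathlib.Path, default=pathlib.Path("results/cv"))
    ap.add_argument("--herit", type=pathlib.Path,
                    default=pathlib.Path("results/heritability.tsv"))
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fits = {}
    for (trait, method), abilities in published.MEAN_ABILITIES.items():
        pts = list(zip(published.TRAINING_SIZES, abilities))
        fits[(trait, method)] = fit_curve(pts, published.HERITABILITY[trait])
    table = curve_table(fits, targets=(TARGET,))
    table.to_csv(args.out / "accuracy_curve_published.tsv", sep="\t", index=False)
    print("Refit of the study's printed abilities:")
    print(table.to_string(index=False))
    col = f"required_N@{TARGET:g}"
    print(f"smallest training size reaching accuracy {TARGET}: "
          f"{table[col].min()}\n")

    herit = pd.read_csv(args.herit, sep="\t")
    sim_fits = {}
    truths = {"bw": 30, "bl": 30}   # preset QTL counts
    for trait in ("bw", "bl"):
        summ = pd.read_csv(args.cv / f"{trait}.summary.tsv", sep="\t")
        h2 = float(herit.query("cohort == @trait and n_records == 500")["h2"].iloc[0])
        for method in ("gblup", "embayesb"):
            sub = summ[summ["method"] == method].sort_values("n_train")
            sim_fits[(trait, method)] = fit_curve(
                list(zip(sub["n_train"], sub["mean"])), h2)
    sim_table = curve_table(sim_fits, targets=(TARGET,))
    sim_table["M_true"] = [truths[t] for t, _ in sim_fits]
    sim_table.to_csv(args.out / "accuracy_curve_simulated.tsv", sep="\t", index=False)
    print("Fit to the synthetic cross-validation means:")
    print(sim_table.to_string(index=False))


if __name__ == "__main__":
    main()
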