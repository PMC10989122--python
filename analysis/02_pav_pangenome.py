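#!/usr/bin/env python
"""Call gene presence/absence from the coverage table, classify genes into
core/softcore/shell/cloud, and fit pan/core growth curves.

Reads results/cohort/inputs/, writes PAV tables under
results/cohort/results/ and prints the class breakdown and the estimated
pan-genome size.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from pansvkit import io, pav

ap = argparse.ArgumentParser()
ap.add_argument("--datadir", type=Path, default=Path("results/cohort"))
args = ap.parse_args()
inputs, results = args.datadir / "inputs", args.datadir / "results"
results.mkdir(parents=True, exist_ok=True)

coverage = io.read_table(inputs / "coverage.tsv", "coverage")
matrix = pav.build_pav_matrix(coverage)
classes = pav.classify_pav(matrix)
counts = pav.pav_class_counts(classes)
classes.to_csv(results / "pav_classes.tsv", sep="\t", index=False)

truth = pd.read_csv(inputs / "pav_truth.tsv", sep="\t", index_col=0)
called = matrix.to_frame().reindex(index=truth.index,
                                   columns=truth.columns)
concordance = (called.to_numpy() == truth.to_numpy()).mean()

traj = pav.pan_core_trajectories(matrix, n_orders=100, seed=0)
traj.to_csv(results / "growth_curve.tsv", sep="\t", index=False)
pan_fit = pav.fit_growth_curve(traj[traj.kind == "pan"], model="power")
core_fit = pav.fit_growth_curve(traj[traj.kind == "core"],
                                model="exponential")
with open(results / "growth_fit.json", "w") as fh:
    json.dump({"pan": pan_fit.__dict__, "core": core_fit.__dict__}, fh,
              indent=1)

n = len(matrix.genes)
print(f"PAV matrix: {n} genes x {len(matrix.samples)} samples; "
      f"concordance with truth {concordance:.2%}")
print(f"classes: {counts['core']} core ({counts['core'] / n:.2%}), "
      f"{counts['softcore']} softcore, {counts['shell']} shell, "
      f"{counts['cloud']} cloud")
state = "closed" if pan_fit.closed else "open"
print(f"pan curve y = A x^B + C: B = {pan_fit.B:.3f} -> {state} "
      f"pan-genome, estimated total {pan_fit.asymptote:.0f} genes")
print(f"core curve y = A e^(Bx) + C: floor {core_fit.C:.0f} genes")
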