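"""End-to-end demo pipeline over one simulated cohort.

Runs every analysis stage on the synthetic inputs of a single
:class:`~pansvkit.simulate.SimulationConfig`: gene PAV calling and
pan-genome modeling, the two selection-scan contrasts, dAF ranking around
the strongest planted locus, TE-SV association, LTR insertion dating, a
windowed F_ST sweep scan, and the F2 single-marker association. All inputs
and result tables are written under ``outdir`` and a summary dict of
headline quantities is returned (and written as ``summary.json``).

Outputs are byte-identical across runs with the same seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import ltr, pav, selection, simulate, sweep, tesv
from .regions import Interval


def run_demo(config: simulate.SimulationConfig, outdir) -> dict:
    out = Path(outdir)
    inputs = out / "inputs"
    results = out / "results"
    results.mkdir(parents=True, exist_ok=True)

    cohort = simulate.simulate_cohort(config)
    simulate.write_cohort(cohort, inputs)
    summary: dict = {"seed": config.seed, "n_samples": len(cohort.metadata)}

    # ---- PAV + pan-genome modeling -----------------------------------
    called = pav.build_pav_matrix(cohort.coverage)
    truth_df = cohort.pav_truth.to_frame()
    called_df = called.to_frame().reindex(index=truth_df.index,
                                          columns=truth_df.columns)
    concordance = float(
        (called_df.to_numpy() == truth_df.to_numpy()).mean())
    classes = pav.classify_pav(called)
    counts = pav.pav_class_counts(classes)
    classes.to_csv(results / "pav_classes.tsv", sep="\t", index=False,
                   float_format="%.6f")
    traj = pav.pan_core_trajectories(called, n_orders=100, seed=config.seed)
    traj.to_csv(results / "growth_curve.tsv", sep="\t", index=False,
                float_format="%.4f")
    pan_fit = pav.fit_growth_curve(traj[traj.kind == "pan"], model="power")
    core_fit = pav.fit_growth_curve(traj[traj.kind == "core"],
                                    model="exponential")
    with open(results / "growth_fit.json", "w") as fh:
        json.dump({"pan": pan_fit.__dict__, "core": core_fit.__dict__},
                  fh, indent=1, sort_keys=True)
        fh.write("\n")
    summary["pav_concordance"] = concordance
    summary["pav_class_counts"] = counts
    summary["core_gene_fraction"] = counts["core"] / len(called.genes)
    summary["pan_asymptote"] = pan_fit.asymptote
    summary["pan_closed"] = pan_fit.closed

    # ---- selection scans ---------------------------------------------
    filtered = selection.maf_filter(cohort.sv_matrix)
    summary["n_sv"] = cohort.sv_matrix.n_records
    summary["n_sv_after_maf"] = filtered.n_records
    planted = cohort.truth["planted_svs"]
    scans = {}
    for name, contrast in (("domestication", ("wild", "native")),
                           ("improvement", ("native", "commercial"))):
        res = selection.scan_selection(filtered, cohort.metadata, contrast)
        res.to_csv(results / f"selection_{name}.tsv", sep="\t",
                   index=False, float_format="%.6g")
        sel = res[res.selected]
        scans[name] = res
        summary[f"n_selected_{name}"] = int(res.selected.sum())
        summary[f"n_increased_{name}"] = int(
            (sel.direction == "increased").sum())
        summary[f"n_decreased_{name}"] = int(
            (sel.direction == "decreased").sum())
    # recovery of planted SVs in the contrast where they differentiate
    recovered = set()
    for res in scans.values():
        recovered |= set(res[res.selected].sv_id) & set(planted)
    summary["planted_recovered"] = sorted(recovered)
    imp = scans["improvement"].set_index("sv_id")
    planted_fst = {sv: float(imp.fst.get(sv, np.nan)) for sv in planted}
    summary["planted_fst_improvement"] = planted_fst
    summary["planted_svs"] = {k: list(v) for k, v in planted.items()}

    # ---- dAF ranking around the strongest planted locus --------------
    strongest = max(planted, key=lambda s: abs(planted[s][1] - planted[s][2]))
    target = next(r for r in cohort.sv_matrix.records if r.id == strongest)
    region = Interval(target.interval.chrom,
                      max(0, target.interval.start - 10_000),
                      target.interval.end + 10_000)
    daf = selection.delta_af(cohort.sv_matrix, cohort.metadata,
                             "native", "commercial", region)
    daf.to_csv(results / "delta_af.tsv", sep="\t", index=False,
               float_format="%.6f")
    summary["top_delta_af"] = float(daf.delta_af.iloc[0])
    summary["top_delta_af_is_planted"] = bool(
        daf.variant.iloc[0] == strongest)

    # ---- TE-SV association -------------------------------------------
    overlap = tesv.sv_te_overlap(cohort.sv_matrix.records, cohort.tes)
    overlap.to_csv(results / "te_overlap.tsv", sep="\t", index=False,
                   float_format="%.6f")
    co = tesv.cooccurrence_scan(cohort.sv_matrix.records, cohort.tes,
                                config.layout)
    co.to_csv(results / "cooccurrence.tsv", sep="\t", index=False,
              float_format="%.6g")
    ctx = tesv.classify_context(cohort.sv_matrix.records, cohort.genes)
    ctx.to_csv(results / "sv_context.tsv", sep="\t", index=False)
    matched = tesv.match_intact_derived(cohort.sv_matrix.records,
                                        cohort.tes)
    truth_ids = set(cohort.truth["intact_derived_ids"])
    summary["n_intact_derived"] = len(matched)
    summary["intact_derived_exact"] = bool(matched == truth_ids)
    eligible = overlap[overlap.eligible]
    if len(eligible):
        summary["frac_sv_te_overlap"] = float(
            (eligible.overlap_class != "none").mean())
        summary["frac_sv_high_te_overlap"] = float(
            (eligible.overlap_class.isin(("high", "intact_derived"))).mean())
    summary["cooccurrence_chi2"] = {
        int(r.window_size): float(r.chi2) for r in co.itertuples()}
    summary["cooccurrence_p"] = {
        int(r.window_size): float(r.p) for r in co.itertuples()}

    # ---- LTR dating ---------------------------------------------------
    ages = ltr.date_ltr_fasta(inputs / "ltr_pairs.fasta")
    ages.to_csv(results / "ltr_ages.tsv", sep="\t", index=False,
                float_format="%.6g")
    true_k = cohort.truth["ltr_true_K"]
    ages = ages.assign(true_K=[true_k[e] for e in ages.element])
    mean_age = ages.groupby("true_K").T_years.mean()
    summary["ltr_mean_age_myr_by_true_K"] = {
        f"{k:g}": float(v) / 1e6 for k, v in mean_age.items()}

    # ---- windowed F_ST sweep scan around the strongest locus ----------
    chrom = target.interval.chrom
    chrom_len = config.layout.length_of(chrom)
    on_chrom = [j for j, r in enumerate(cohort.sv_matrix.records)
                if r.interval.chrom == chrom]
    positions = np.array([cohort.sv_matrix.records[j].interval.start
                          for j in on_chrom])
    groups_arr = np.array([0 if m.group == "native" else
                           (1 if m.group == "commercial" else -1)
                           for m in cohort.metadata])
    keep = groups_arr >= 0
    dosages = cohort.sv_matrix.dosages[keep][:, on_chrom].T
    scan = sweep.windowed_scan(positions, dosages, chrom_len, "fst",
                               group_index=groups_arr[keep])
    scan.to_csv(results / "fst_windows.tsv", sep="\t", index=False,
                float_format="%.6g")
    peak = scan.loc[scan.value.idxmax()]
    strong = [r for r in cohort.sv_matrix.records
              if r.id in planted
              and abs(planted[r.id][1] - planted[r.id][2]) >= 0.5
              and r.interval.chrom == chrom]
    summary["fst_scan_peak_start"] = int(peak.start)
    summary["fst_scan_peak_contains_planted"] = bool(any(
        peak.start <= r.interval.start < peak.end for r in strong))

    # ---- F2 single-marker association ---------------------------------
    assoc = sweep.single_marker_glm(cohort.phenotypes.weight,
                                    cohort.marker,
                                    cohort.phenotypes.sex,
                                    marker_id="planted_marker",
                                    trait="weight")
    pd.DataFrame([assoc.__dict__]).to_csv(results / "association.tsv",
                                          sep="\t", index=False,
                                          float_format="%.6g")
    summary["marker_r2"] = assoc.r2
    summary["marker_p"] = assoc.p
    summary["true_marker_v"] = cohort.truth["f2"]["v"]

    with open(results / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return summary
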