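#!/usr/bin/env python
"""Generate the synthetic study inputs with planted ground truth.

Writes the PSI time course, the RBP cpm table, the perturbation
experiment, the toy loci FASTAs and all truth tables under
results/data/, in the pipeline's text formats. Downstream scripts
(02-08) consume these files.
"""

import os

import pandas as pd

import splicedyn.synthetic_data as sd
from splicedyn.core_io import write_expr_table, write_psi_table, write_sample_map

SEED = 20240917
OUT = os.path.join(os.path.dirname(__file__), "..", "results", "data")


def main() -> None:
    os.makedirs(OUT, exist_ok=True)

    specs = sd.default_trajectory_specs()
    t, truth = sd.simulate_timecourse(
        300, specs, n_unregulated=600, coverage_mean=200, noise_sd_psi=1.0,
        seed=SEED)
    write_psi_table(t, f"{OUT}/timecourse_psi.tsv")
    write_sample_map(t.samples, f"{OUT}/timecourse_samples.tsv")
    truth.events.to_csv(f"{OUT}/timecourse_truth.tsv", sep="\t")
    print(f"time course: {t.psi.shape[0]} events × {t.psi.shape[1]} samples "
          f"({len(specs)} planted clusters × 300 events + 600 unregulated)")

    expr, rtruth = sd.simulate_rbp_expression(
        specs, 10, 10, 500, noise_sd=0.3, seed=SEED + 1,
        n_low_expressed=20, n_low_variance=20)
    write_expr_table(expr, f"{OUT}/rbp_cpm.tsv")
    rtruth.rbps.to_csv(f"{OUT}/rbp_truth.tsv", sep="\t")
    print(f"RBP table: {expr.values.shape[0]} genes "
          f"(120 planted regulators, 500 nulls, 40 filter-fated)")

    pt, design, ptruth = sd.simulate_perturbation(
        300, 300, 400, effect_ddpsi=20.0, rep_noise_sd=2.0, seed=SEED + 2)
    write_psi_table(pt, f"{OUT}/perturbation_psi.tsv")
    write_sample_map(pt.samples, f"{OUT}/perturbation_samples.tsv")
    ptruth.perturbation.to_csv(f"{OUT}/perturbation_truth.tsv", sep="\t")
    with open(f"{OUT}/perturbation_design.tsv", "w") as fh:
        fh.write("role\tcondition\n")
        fh.write(f"baseline\t{design.baseline}\n")
        fh.write(f"control_end\t{design.control_end}\n")
        for arm in design.treatment_ends:
            fh.write(f"treatment_end\t{arm}\n")
    print(f"perturbation: {pt.psi.shape[0]} events, two shRNA arms, "
          f"planted |ΔΔPSI| = 20")

    loci = sd.simulate_loci(300, 300, "TTTTT", p_plant=0.8, seed=SEED + 3)
    loci_dir = f"{OUT}/loci"
    os.makedirs(loci_dir, exist_ok=True)
    loci.write_fastas(loci_dir)
    windows = loci.feature_windows()
    from splicedyn.core_io import write_fasta
    write_fasta({k: w["ss5"] for k, w in windows.items()},
                f"{loci_dir}/ss5.fa")
    write_fasta({k: w["ss3"] for k, w in windows.items()},
                f"{loci_dir}/ss3.fa")
    lengths = pd.DataFrame(
        {k: {"exon_length": len(w["exon"]),
             "up_intron_length": len(w["intron_up"]),
             "down_intron_length": len(w["intron_down"])}
         for k, w in loci.full.items()}).T
    lengths.index.name = "locus_id"
    lengths.to_csv(f"{OUT}/loci_lengths.tsv", sep="\t")
    loci.truth.loci.to_csv(f"{OUT}/loci_truth.tsv", sep="\t")
    print("loci: 300 regulated (motif planted at intron_down −120..−80, "
          "p=0.8) + 300 control, FASTA per map region")


if __name__ == "__main__":
    main()
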