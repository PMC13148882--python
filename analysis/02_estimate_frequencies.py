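#!/usr/bin/env python
"""Genotype, combination and HWE-derived allele frequencies for the study cohort.

Reads results/study_calls.tsv (from 01_build_cohorts.py), tabulates phenotype
and two-locus combination frequencies, derives q = sqrt(f_null) and p = 1 - q,
and attaches delta-method and bootstrap uncertainty.  Writes the two report
tables plus an uncertainty table under results/.
"""

from pathlib import Path

from nullmark.cohort_io import read_calls
from nullmark.freq_estimation import allele_uncertainty, phenotype_frequencies
from nullmark.pipeline import render_combination_table, render_genotype_allele_table

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
LOCI = ["GSTM1", "GSTT1"]


def main() -> None:
    cohort = read_calls(RESULTS / "study_calls.tsv")

    genotype_table = render_genotype_allele_table(cohort, LOCI)
    (RESULTS / "genotype_allele_table.tsv").write_text(genotype_table)
    combo_table = render_combination_table(cohort, *LOCI)
    (RESULTS / "combination_table.tsv").write_text(combo_table)
    print(genotype_table)
    print(combo_table)

    lines = ["locus\tq\tse_q_delta\tci95_delta\tci95_bootstrap"]
    for locus in LOCI:
        lf = phenotype_frequencies(cohort, locus)
        se, ci_d = allele_uncertainty(lf.n, lf.f_null, method="delta")
        _, ci_b = allele_uncertainty(lf.n, lf.f_null, method="bootstrap", seed=7)
        lines.append(
            f"{locus}\t{lf.q:.4f}\t{se:.4f}\t[{ci_d[0]:.4f}, {ci_d[1]:.4f}]\t"
            f"[{ci_b[0]:.4f}, {ci_b[1]:.4f}]"
        )
    text = "\n".join(lines) + "\n"
    (RESULTS / "allele_uncertainty.tsv").write_text(text)
    print(text)
    print("-> results/genotype_allele_table.tsv, combination_table.tsv, allele_uncertainty.tsv")


if __name__ == "__main__":
    main()
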