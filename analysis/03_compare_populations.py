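#!/usr/bin/env python
"""Contingency comparisons of the study cohort against the global panel.

For each locus, reconstructs null/positive counts for every panel population
with a published sample size and runs Pearson chi-square (Fisher's exact when
the smallest expected count is below 5).  Panel rows without n (Tarahumara,
Mestizos) or without the locus (Murcia at GSTM1) are skipped — a published
frequency without a sample size cannot be turned back into counts, so those
published comparisons cannot be reconstructed here.

Writes results/comparisons_<locus>.tsv and prints the regional highlights.
"""

import logging
from pathlib import Path

from nullmark.cohort_io import load_reference_panel, read_calls
from nullmark.comparison_stats import compare_panel
from nullmark.freq_estimation import phenotype_frequencies
from nullmark.pipeline import comparisons_frame

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
HIGHLIGHTS = [
    "Urban/admixed (Venezuela)",
    "Pemon (ethnic group, Venezuela)",
    "Wayuu (ethnic group, Venezuela)",
    "Colombia",
    "Mexico (central)",
    "Ibo (Abuja)",
    "Portuguese",
    "Spanish (Madrid)",
    "Italian (Rome)",
    "Korean (Seoul)",
]


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(message)s")
    cohort = read_calls(RESULTS / "study_calls.tsv")
    panel = load_reference_panel()

    for locus in ("GSTM1", "GSTT1"):
        lf = phenotype_frequencies(cohort, locus, label="current study")
        results = compare_panel(lf, panel, locus, method_policy="auto")
        frame = comparisons_frame(results)
        out = RESULTS / f"comparisons_{locus}.tsv"
        frame.to_csv(out, sep="\t", index=False, float_format="%.6g")
        print(f"\n{locus}: {len(results)} comparisons -> {out.relative_to(ROOT)}")
        shown = frame[frame["population"].isin(HIGHLIGHTS)]
        print(shown.to_string(index=False))
        n_sig = int((frame["p_value"] < 0.05).sum())
        print(f"{locus}: {n_sig}/{len(frame)} comparisons significant at p < 0.05 (unadjusted)")


if __name__ == "__main__":
    main()
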