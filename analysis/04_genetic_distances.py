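#!/usr/bin/env python
"""Nei identity/distance between the study cohort and reference populations.

Computes per-locus and average Nei standard distances (on HWE-derived allele
profiles, q = sqrt of the null-genotype frequency) for two pair sets that the
frequency panel supports:

* the Venezuelan subgroups (urban/admixed and the five indigenous groups);
* a global selection (Portugal, Ibo, Murcia, central Mexico, Beijing).

Also assembles the full average-D matrix over every panel population with both
loci, which feeds the projection/clustering step.
"""

from pathlib import Path

from nullmark.cohort_io import load_reference_panel, read_calls
from nullmark.freq_estimation import phenotype_frequencies
from nullmark.genetic_distance import build_matrix, pairwise_entry, profiles_from_null_freqs

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

VENEZUELAN = [
    "Wayuu (ethnic group, Venezuela)",
    "Pemon (ethnic group, Venezuela)",
    "Urban/admixed (Venezuela)",
    "Bari (ethnic group, Venezuela)",
    "Warao (ethnic group, Venezuela)",
    "Panare (ethnic group, Venezuela)",
]
GLOBAL = [
    "Portuguese",
    "Ibo (Abuja)",
    "Spanish (Murcia)",
    "Mexico (central)",
    "Chinese (Beijing)",
]
SUBSET = [
    "current study",
    "Urban/admixed (Venezuela)",
    "Wayuu (ethnic group, Venezuela)",
    "Pemon (ethnic group, Venezuela)",
    "Colombia",
    "Mexico (central)",
    "Portuguese",
    "Spanish (Madrid)",
    "Italian (Rome)",
    "Ibo (Abuja)",
    "Yoruba (Abuja)",
    "Chinese (Beijing)",
    "Japanese (Tokyo)",
]


def entry_rows(current, panel, pairs):
    rows = ["population\tD_GSTM1\tD_GSTT1\tD_average"]
    for pop in pairs:
        rec = panel.get(pop)
        entry = pairwise_entry(
            "current study", current, pop, profiles_from_null_freqs(rec.null_freq)
        )
        d_m = entry.d_per_locus.get("GSTM1")
        d_t = entry.d_per_locus.get("GSTT1")
        fmt = lambda d: "--" if d is None else f"{d:.4f}"
        rows.append(f"{pop}\t{fmt(d_m)}\t{fmt(d_t)}\t{entry.d_average:.4f}"
                    if d_m is not None and d_t is not None
                    else f"{pop}\t{fmt(d_m)}\t{fmt(d_t)}\t--")
    return "\n".join(rows) + "\n"


def main() -> None:
    cohort = read_calls(RESULTS / "study_calls.tsv")
    panel = load_reference_panel()
    current = {
        locus: profiles_from_null_freqs({locus: phenotype_frequencies(cohort, locus).f_null})[locus]
        for locus in ("GSTM1", "GSTT1")
    }

    vz = entry_rows(current, panel, VENEZUELAN)
    (RESULTS / "distances_venezuelan.tsv").write_text(vz)
    print("Nei distance to Venezuelan reference groups:\n" + vz)

    gl = entry_rows(current, panel, GLOBAL)
    (RESULTS / "distances_global.tsv").write_text(gl)
    print("Nei distance to global references:\n" + gl)

    focal = [phenotype_frequencies(cohort, l, label="current study") for l in ("GSTM1", "GSTT1")]
    matrix = build_matrix(panel, focal, ["GSTM1", "GSTT1"], focal_label="current study")

    # The full 96-population matrix is bulky and regenerable: park it under
    # scratch/; keep the readable subset used by the structure step in results/.
    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    matrix.write_tsv(scratch / "distance_matrix_full.tsv")
    matrix.write_phylip(scratch / "distance_matrix_full.phy")
    subset = matrix.subset([p for p in SUBSET if p in matrix.labels])
    subset.write_tsv(RESULTS / "distance_matrix_subset.tsv")
    print(f"full matrix: {len(matrix)} populations -> scratch/distance_matrix_full.tsv (+ .phy); "
          f"{len(subset)}-population subset -> results/distance_matrix_subset.tsv")


if __name__ == "__main__":
    main()
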