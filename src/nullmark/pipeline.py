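"""End-to-end orchestration: frequencies -> comparisons -> distances -> structure.

``run_all`` executes the full analysis from a call table and a reference
panel, writing every artifact plus a MANIFEST and a provenance log.  Outputs
are deliberately free of timestamps so that two runs with the same config and
seed are byte-identical — determinism is part of the contract, and the log
records a content hash per artifact to make that auditable.

Report tables mirror the conventional layout of null-marker studies:
a per-locus genotype/allele table (observed counts, observed frequencies at
4 decimals, HWE-derived p and q) and a two-locus combination table with
percentages at 2 decimals.  Internally everything is computed at full
precision; rounding happens only here.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .cohort_io import Cohort, ReferencePanel, load_reference_panel, read_calls, read_panel
from .comparison_stats import TestResult, compare_panel
from .freq_estimation import (
    CombinationTable,
    LocusFrequency,
    allele_uncertainty,
    combination_frequencies,
    format_allele_pair,
    format_percent,
    phenotype_frequencies,
    round_half_up,
)
from .genetic_distance import build_matrix
from .structure_viz import classical_mds, upgma

__all__ = [
    "RunConfig",
    "run_all",
    "render_genotype_allele_table",
    "render_combination_table",
    "comparisons_frame",
]

logger = logging.getLogger(__name__)


def render_genotype_allele_table(cohort: Cohort, loci: Sequence[str]) -> str:
    """TSV mirroring the genotype/allele summary table of null-marker reports.

    One positive and one null row per locus with observed counts, observed
    frequencies (half-up, 4 d.p.) and the HWE-derived allele frequencies
    (q truncated at 4 d.p., p printed as its complement).
    """
    lines = ["locus\tgenotype\tobserved_n\tobserved_frequency\testimated_allele_frequency"]
    for locus in loci:
        lf = phenotype_frequencies(cohort, locus)
        q_str, p_str = format_allele_pair(lf.q)
        f_pos = round_half_up(1 - lf.f_null, 4)
        f_null = round_half_up(lf.f_null, 4)
        lines.append(
            f"{locus}\tpositive\t{lf.n - lf.n_null}\t{f_pos:.4f}\tp (+): {p_str}"
        )
        lines.append(f"{locus}\tnull\t{lf.n_null}\t{f_null:.4f}\tq (-): {q_str}")
    return "\n".join(lines) + "\n"


def render_combination_table(cohort: Cohort, locus_a: str, locus_b: str) -> str:
    """TSV mirroring the genotype-combination table (percentages, 2 d.p. half-up)."""
    lines = ["genotype\tn\tfrequency_percent"]
    for locus in (locus_a, locus_b):
        lf = phenotype_frequencies(cohort, locus)
        lines.append(f"{locus} positive\t{lf.n - lf.n_null}\t{format_percent(1 - lf.f_null)}")
        lines.append(f"{locus} null\t{lf.n_null}\t{format_percent(lf.f_null)}")
    combo = combination_frequencies(cohort, locus_a, locus_b)
    names = {
        ("present", "present"): f"{locus_a}+/{locus_b}+",
        ("present", "null"): f"{locus_a}+/{locus_b} null",
        ("null", "present"): f"{locus_a} null/{locus_b}+",
        ("null", "null"): f"{locus_a} null/{locus_b} null",
    }
    for key in CombinationTable.KEYS:
        lines.append(
            f"{names[key]}\t{combo.counts[key]}\t{format_percent(combo.frequencies[key])}"
        )
    return "\n".join(lines) + "\n"


def comparisons_frame(results: Sequence[TestResult]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        {
            "population": [r.label_b for r in results],
            "method": [r.method for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "min_expected": [r.min_expected for r in results],
            "provenance": [r.provenance for r in results],
        }
    )


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    calls: str
    outdir: str
    loci: list[str] = field(default_factory=lambda: ["GSTM1", "GSTT1"])
    panel: str | None = None  # None -> packaged reference panel
    focal_label: str = "current study"
    method_policy: str = "auto"
    count_policy: str = "round_nearest"
    yates: bool = False
    ci_method: str = "delta"
    n_boot: int = 2000
    mds_k: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.loci:
            raise ValueError("loci must be non-empty")
        if not Path(self.calls).exists():
            raise FileNotFoundError(f"calls file not found: {self.calls}")
        if self.panel is not None and not Path(self.panel).exists():
            raise FileNotFoundError(f"panel file not found: {self.panel}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: RunConfig) -> dict:
    """Run the full analysis; return the MANIFEST dict.

    Stages: read inputs -> frequency tables -> per-locus panel comparisons ->
    average-D distance matrix -> classical MDS -> UPGMA Newick.  On a stage
    failure the MANIFEST records the artifacts completed so far plus the
    failed stage, then the exception propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "status": "running",
        "version": __version__,
        "seed": config.seed,
        "policies": {
            "method": config.method_policy,
            "counts": config.count_policy,
            "yates": config.yates,
            "ci": config.ci_method,
        },
        "artifacts": [],
    }
    log_lines: list[str] = [f"nullmark {__version__} run: loci={','.join(config.loci)} seed={config.seed}"]

    def record(stage: str, path: Path) -> None:
        digest = _sha256(path)
        manifest["artifacts"].append({"stage": stage, "path": path.name, "sha256": digest})
        log_lines.append(f"{stage}: wrote {path.name} sha256={digest}")

    def finish(status: str, failed_stage: str | None = None) -> None:
        manifest["status"] = status
        if failed_stage:
            manifest["failed_stage"] = failed_stage
        (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2) + "\n")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")

    stage = "read_inputs"
    try:
        cohort = read_calls(config.calls)
        panel = read_panel(config.panel) if config.panel else load_reference_panel()
        log_lines.append(
            f"{stage}: cohort n={cohort.n} loci={','.join(cohort.loci)}; "
            f"panel populations={len(panel)}"
        )

        stage = "frequencies"
        freq_path = outdir / "frequencies.tsv"
        lines = [
            "locus\tn\tn_null\tf_null\tq\tp\tse_q\tci_low\tci_high"
        ]
        focal: list[LocusFrequency] = []
        for locus in config.loci:
            lf = phenotype_frequencies(cohort, locus, label=config.focal_label)
            se, ci = allele_uncertainty(
                lf.n,
                lf.f_null,
                method=config.ci_method,
                n_boot=config.n_boot,
                seed=config.seed,
            )
            lf.se_q, lf.ci_q = se, ci
            focal.append(lf)
            lines.append(
                f"{locus}\t{lf.n}\t{lf.n_null}\t{lf.f_null:.10g}\t{lf.q:.10g}\t"
                f"{lf.p:.10g}\t{se:.10g}\t{ci[0]:.10g}\t{ci[1]:.10g}"
            )
        freq_path.write_text("\n".join(lines) + "\n")
        record(stage, freq_path)

        report_path = outdir / "genotype_allele_table.tsv"
        report_path.write_text(render_genotype_allele_table(cohort, config.loci))
        record(stage, report_path)
        if len(config.loci) >= 2:
            combo_path = outdir / "combination_table.tsv"
            combo_path.write_text(render_combination_table(cohort, config.loci[0], config.loci[1]))
            record(stage, combo_path)

        stage = "comparisons"
        comparable = any(rec.n is not None for rec in panel)
        if comparable:
            for lf in focal:
                results = compare_panel(
                    lf,
                    panel,
                    lf.locus,
                    method_policy=config.method_policy,
                    count_policy=config.count_policy,
                    yates=config.yates,
                )
                path = outdir / f"comparisons_{lf.locus}.tsv"
                comparisons_frame(results).to_csv(path, sep="\t", index=False, float_format="%.10g")
                record(stage, path)
        else:
            log_lines.append(
                f"{stage}: skipped — no panel population has a published sample size"
            )

        stage = "distance"
        matrix = build_matrix(panel, focal, config.loci, focal_label=config.focal_label)
        dist_path = outdir / "distance_matrix.tsv"
        matrix.write_tsv(dist_path)
        record(stage, dist_path)

        stage = "mds"
        mds = classical_mds(matrix, k=config.mds_k)
        coords_path = outdir / "mds_coordinates.tsv"
        mds.write_tsv(coords_path)
        log_lines.append(
            f"{stage}: k={mds.k} negative_inertia={mds.negative_inertia:.6g} "
            f"reconstruction_error={mds.reconstruction_error:.6g}"
        )
        record(stage, coords_path)

        stage = "upgma"
        tree = upgma(matrix)
        tree_path = outdir / "upgma_tree.nwk"
        tree.write_newick(tree_path)
        record(stage, tree_path)
    except Exception:
        finish("failed", failed_stage=stage)
        raise

    finish("complete")
    return manifest
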