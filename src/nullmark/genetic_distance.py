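"""Nei's standard genetic identity and distance for biallelic null markers.

For one locus with allele-frequency vectors (p_a, q_a) and (p_b, q_b), Nei's
normalized identity is

    I = (p_a p_b + q_a q_b) / sqrt((p_a^2 + q_a^2)(p_b^2 + q_b^2))

and the standard distance is D = -ln(I).  I lies in (0, 1] for any pair of
biallelic profiles that are not fixed for opposite alleles; at opposite
fixation I = 0 and D = +inf, which is represented explicitly (never clamped)
and excluded from multi-locus averages with a warning.

Profiles are derived from published null-genotype frequencies through the
HWE square-root estimator (q = sqrt(f_null)): distances operate on *allele*
frequencies, not genotype frequencies.  Multi-locus distance is the
arithmetic mean of per-locus D over loci with data on both sides; loci
missing on either side are excluded and recorded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_io import ReferencePanel
from .freq_estimation import LocusFrequency, estimate_null_allele

__all__ = [
    "LocusAlleleProfile",
    "DistanceEntry",
    "DistanceMatrix",
    "nei_identity",
    "nei_distance",
    "average_distance",
    "pairwise_entry",
    "build_matrix",
    "profiles_from_null_freqs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LocusAlleleProfile:
    """Biallelic allele frequencies at one locus: functional (p) and null (q)."""

    locus: str
    p: float
    q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0 and 0.0 <= self.p <= 1.0):
            raise ValueError(f"{self.locus}: allele frequencies outside [0,1]")
        if abs(self.p + self.q - 1.0) > 1e-9:
            raise ValueError(f"{self.locus}: p + q must equal 1, got {self.p + self.q}")

    @classmethod
    def from_null_genotype_freq(cls, locus: str, f_null: float) -> "LocusAlleleProfile":
        """HWE-derived profile: q = sqrt(f_null), p = 1 - q."""
        q, p = estimate_null_allele(f_null)
        return cls(locus=locus, p=p, q=q)


def profiles_from_null_freqs(null_freq: Mapping[str, float]) -> dict[str, LocusAlleleProfile]:
    return {
        locus: LocusAlleleProfile.from_null_genotype_freq(locus, f)
        for locus, f in null_freq.items()
    }


def nei_identity(a: LocusAlleleProfile, b: LocusAlleleProfile) -> float:
    """Single-locus normalized identity I in [0, 1].

    The denominator sqrt((p_a^2+q_a^2)(p_b^2+q_b^2)) is at least 1/2 for any
    biallelic profile, so the ratio is always well defined.
    """
    num = a.p * b.p + a.q * b.q
    den = math.sqrt((a.p**2 + a.q**2) * (b.p**2 + b.q**2))
    # Guard tiny floating overshoot above 1 for near-identical profiles.
    return min(num / den, 1.0)


def nei_distance(a: LocusAlleleProfile, b: LocusAlleleProfile) -> float:
    """Nei's standard distance D = -ln(I); +inf at opposite fixation (I = 0)."""
    identity = nei_identity(a, b)
    if identity == 0.0:
        return math.inf
    return -math.log(identity)


def average_distance(d_per_locus: Mapping[str, float]) -> float:
    """Arithmetic mean of finite per-locus distances.

    Infinite entries (opposite fixation) are excluded with a warning rather
    than silently clamped; raises if no locus has a finite distance.
    """
    finite = {k: v for k, v in d_per_locus.items() if math.isfinite(v)}
    dropped = sorted(set(d_per_locus) - set(finite))
    if dropped:
        logger.warning("excluding infinite distance at loci %s from average", dropped)
    if not finite:
        raise ValueError("no locus with a finite distance to average")
    return sum(finite.values()) / len(finite)


@dataclass
class DistanceEntry:
    """Pairwise identity/distance between two populations, per locus and averaged."""

    pop_a: str
    pop_b: str
    identity_per_locus: dict[str, float]
    d_per_locus: dict[str, float]
    d_average: float
    loci_skipped: list[str] = field(default_factory=list)


def pairwise_entry(
    pop_a: str,
    profiles_a: Mapping[str, LocusAlleleProfile],
    pop_b: str,
    profiles_b: Mapping[str, LocusAlleleProfile],
    loci: Sequence[str] | None = None,
) -> DistanceEntry:
    """Compute I and D per shared locus plus the average distance."""
    requested = list(loci) if loci is not None else sorted(set(profiles_a) | set(profiles_b))
    shared = [l for l in requested if l in profiles_a and l in profiles_b]
    skipped = [l for l in requested if l not in shared]
    if skipped:
        logger.info("%s vs %s: skipping loci without data on both sides: %s", pop_a, pop_b, skipped)
    if not shared:
        raise ValueError(f"{pop_a} vs {pop_b}: no shared loci with data")
    identity = {l: nei_identity(profiles_a[l], profiles_b[l]) for l in shared}
    d = {l: nei_distance(profiles_a[l], profiles_b[l]) for l in shared}
    return DistanceEntry(
        pop_a=pop_a,
        pop_b=pop_b,
        identity_per_locus=identity,
        d_per_locus=d,
        d_average=average_distance(d),
        loci_skipped=skipped,
    )


@dataclass
class DistanceMatrix:
    """Symmetric labeled matrix of pairwise distances with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} does not match {n} labels")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal must be zero")
        finite = np.isfinite(self.values)
        if not np.allclose(
            np.where(finite, self.values, 0.0), np.where(finite.T, self.values.T, 0.0), atol=1e-12
        ) or not (finite == finite.T).all():
            raise ValueError("distance matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("distances must be non-negative")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def has_infinite(self) -> bool:
        return bool(np.isinf(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def subset(self, labels: Iterable[str]) -> "DistanceMatrix":
        labels = list(labels)
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(labels, self.values[np.ix_(idx, idx)])

    def write_tsv(self, path: str | Path, *, ndigits: int | None = None) -> None:
        frame = self.to_frame()
        if ndigits is not None:
            frame = frame.round(ndigits)
        frame.to_csv(path, sep="\t", index_label="population")

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP distance-matrix format for interoperability with tree tools."""
        with Path(path).open("w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for label, row in zip(self.labels, self.values):
                name = label.replace(" ", "_")[:10].ljust(10)
                fh.write(name + "  " + "  ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def from_entries(cls, labels: Sequence[str], entries: Mapping[tuple[str, str], float]) -> "DistanceMatrix":
        n = len(labels)
        values = np.zeros((n, n))
        for (a, b), d in entries.items():
            i, j = labels.index(a), labels.index(b)
            values[i, j] = values[j, i] = d
        return cls(list(labels), values)


def build_matrix(
    panel: ReferencePanel,
    focal: Sequence[LocusFrequency] | None = None,
    loci: Sequence[str] | None = None,
    *,
    focal_label: str = "current study",
) -> DistanceMatrix:
    """Assemble an average-D matrix over the focal cohort plus panel populations.

    Allele profiles are derived from each population's null-genotype
    frequencies via q = sqrt(f_null).  Panel rows missing any requested locus
    are excluded with a logged notice (their pairwise average would not be
    comparable to the rest of the matrix).
    """
    if loci is None:
        if focal:
            loci = [lf.locus for lf in focal]
        else:
            loci = panel.loci
    loci = list(loci)
    if not loci:
        raise ValueError("no loci requested")

    profiles: dict[str, dict[str, LocusAlleleProfile]] = {}
    labels: list[str] = []
    if focal:
        by_locus = {lf.locus: lf for lf in focal}
        missing = [l for l in loci if l not in by_locus]
        if missing:
            raise ValueError(f"focal cohort lacks requested loci: {missing}")
        profiles[focal_label] = {
            l: LocusAlleleProfile.from_null_genotype_freq(l, by_locus[l].f_null) for l in loci
        }
        labels.append(focal_label)
    for rec in panel:
        if any(not rec.has(l) for l in loci):
            logger.info("excluding %s from matrix: missing locus data", rec.population)
            continue
        profiles[rec.population] = {
            l: LocusAlleleProfile.from_null_genotype_freq(l, rec.null_freq[l]) for l in loci
        }
        labels.append(rec.population)
    if not labels:
        raise ValueError("no populations with data at the requested loci")

    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = {l: nei_distance(profiles[labels[i]][l], profiles[labels[j]][l]) for l in loci}
            values[i, j] = values[j, i] = average_distance(d)
    return DistanceMatrix(labels, values)
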