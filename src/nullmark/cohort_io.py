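"""Reading and writing cohort call tables and population frequency panels.

Two delimited-text formats are supported:

* **call tables** — one row per individual, one column per locus, each cell a
  presence/absence phenotype.  A dominant deletion marker assayed by
  conventional PCR cannot distinguish homozygous functional carriers from
  heterozygotes, so the phenotype is binary: the locus product is either
  amplified (PRESENT) or absent (NULL, i.e. homozygous deletion).
* **frequency panels** — one row per population with a sample size and the
  observed null-*genotype* frequency per locus.  A packaged panel compiled
  from the published global survey of GSTM1/GSTT1 deletion frequencies ships
  with the package (``load_reference_panel``).

Missing panel cells are first-class: a population may lack data for a locus
(blank cell) or lack a published sample size, and downstream modules decide
what each gap makes impossible (no n: no contingency test; no frequency at a
locus: no distance at that locus).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "PRESENT",
    "NULL",
    "DEFAULT_ALPHABET",
    "Cohort",
    "PopulationRecord",
    "ReferencePanel",
    "read_calls",
    "write_calls",
    "read_panel",
    "write_panel",
    "load_reference_panel",
    "REFERENCE_PANEL_NAME",
]

PRESENT = "present"
NULL = "null"

#: Default mapping from cell tokens (lower-cased) to phenotypes.
DEFAULT_ALPHABET: dict[str, str] = {
    "1": PRESENT,
    "+": PRESENT,
    "present": PRESENT,
    "positive": PRESENT,
    "pos": PRESENT,
    "0": NULL,
    "-": NULL,
    "−": NULL,  # unicode minus, common in transcribed tables
    "null": NULL,
    "absent": NULL,
    "neg": NULL,
}

REFERENCE_PANEL_NAME = "table3_panel.tsv"


@dataclass
class Cohort:
    """A set of unrelated individuals typed for one or more null-allele loci.

    ``calls`` is a boolean DataFrame indexed by sample id with one column per
    locus; ``True`` marks the null (homozygous deletion) phenotype.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        if self.calls.index.has_duplicates:
            dupes = self.calls.index[self.calls.index.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dupes)}")

    @property
    def n(self) -> int:
        return len(self.calls)

    @property
    def loci(self) -> list[str]:
        return list(self.calls.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.index)

    def require_locus(self, locus: str) -> None:
        if locus not in self.calls.columns:
            raise KeyError(
                f"locus {locus!r} not typed in this cohort (have {self.loci})"
            )

    def null_count(self, locus: str) -> int:
        self.require_locus(locus)
        return int(self.calls[locus].sum())


def read_calls(
    path: str | Path,
    *,
    delimiter: str = "\t",
    sample_column: str | None = None,
    alphabet: Mapping[str, str] | None = None,
) -> Cohort:
    """Read a per-sample call table.

    The first column is the sample id unless ``sample_column`` names another
    header.  Cell tokens are interpreted through ``alphabet`` (defaults to
    :data:`DEFAULT_ALPHABET`, case-insensitive).  Unknown tokens and duplicate
    sample ids are hard errors naming the offending cell/row.
    """
    alphabet = {k.lower(): v for k, v in (alphabet or DEFAULT_ALPHABET).items()}
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, expected a header row") from None
        header = [h.strip() for h in header]
        id_col = sample_column if sample_column is not None else header[0]
        if id_col not in header:
            raise ValueError(f"{path}: sample-id column {id_col!r} not in header")
        id_idx = header.index(id_col)
        loci = [h for i, h in enumerate(header) if i != id_idx]

        ids: list[str] = []
        rows: list[list[bool]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(row)}"
                )
            ids.append(row[id_idx].strip())
            calls: list[bool] = []
            for i, cell in enumerate(row):
                if i == id_idx:
                    continue
                token = cell.strip().lower()
                try:
                    phen = alphabet[token]
                except KeyError:
                    raise ValueError(
                        f"{path}:{lineno}: unknown call token {cell.strip()!r} "
                        f"in column {header[i]!r}"
                    ) from None
                calls.append(phen == NULL)
            rows.append(calls)

    frame = pd.DataFrame(rows, index=pd.Index(ids, name=id_col), columns=loci, dtype=bool)
    return Cohort(frame)


def write_calls(cohort: Cohort, path: str | Path, *, delimiter: str = "\t") -> None:
    """Write a cohort back to a call table using 'present'/'null' tokens."""
    out = cohort.calls.map(lambda is_null: NULL if is_null else PRESENT)
    out.to_csv(path, sep=delimiter)


@dataclass
class PopulationRecord:
    """One population's published summary: size and per-locus null-genotype frequency.

    ``n`` may be None (size not published); ``null_freq`` omits loci with no
    published frequency.
    """

    population: str
    n: int | None
    null_freq: dict[str, float]
    region: str | None = None

    def __post_init__(self) -> None:
        if self.n is not None and self.n < 1:
            raise ValueError(f"{self.population}: n must be >= 1, got {self.n}")
        for locus, f in self.null_freq.items():
            if not (0.0 <= f <= 1.0) or math.isnan(f):
                raise ValueError(
                    f"{self.population}: null frequency for {locus} outside [0,1]: {f}"
                )

    def has(self, locus: str) -> bool:
        return locus in self.null_freq


@dataclass
class ReferencePanel:
    """Ordered collection of :class:`PopulationRecord` with unique labels."""

    records: list[PopulationRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.population in seen:
                raise ValueError(f"duplicate population label: {rec.population!r}")
            seen.add(rec.population)

    def __iter__(self) -> Iterator[PopulationRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def populations(self) -> list[str]:
        return [r.population for r in self.records]

    @property
    def loci(self) -> list[str]:
        loci: list[str] = []
        for rec in self.records:
            for locus in rec.null_freq:
                if locus not in loci:
                    loci.append(locus)
        return loci

    def get(self, population: str) -> PopulationRecord:
        for rec in self.records:
            if rec.population == population:
                return rec
        raise KeyError(f"population {population!r} not in panel")

    def subset(self, populations: Iterable[str]) -> "ReferencePanel":
        return ReferencePanel(
            [self.get(p) for p in populations], provenance=self.provenance
        )

    def to_frame(self) -> pd.DataFrame:
        loci = self.loci
        rows = []
        for rec in self.records:
            row: dict[str, object] = {
                "population": rec.population,
                "region": rec.region if rec.region is not None else "",
                "n": rec.n,
            }
            for locus in loci:
                row[locus] = rec.null_freq.get(locus)
            rows.append(row)
        return pd.DataFrame(rows)


def _parse_panel_rows(
    rows: Sequence[Sequence[str]], header: Sequence[str], source: str
) -> list[PopulationRecord]:
    lower = [h.strip().lower() for h in header]
    if "population" not in lower:
        raise ValueError(f"{source}: panel header must contain a 'population' column")
    pop_idx = lower.index("population")
    region_idx = lower.index("region") if "region" in lower else None
    n_idx = lower.index("n") if "n" in lower else None
    locus_cols = [
        (i, header[i].strip())
        for i in range(len(header))
        if i not in {pop_idx, region_idx, n_idx}
    ]

    records: list[PopulationRecord] = []
    for lineno, row in enumerate(rows, start=2):
        if not row or all(not c.strip() for c in row):
            continue
        population = row[pop_idx].strip()
        region = row[region_idx].strip() or None if region_idx is not None else None
        n: int | None = None
        if n_idx is not None:
            raw_n = row[n_idx].strip()
            if raw_n and raw_n != "-":
                try:
                    n = int(raw_n)
                except ValueError:
                    raise ValueError(
                        f"{source}:{lineno}: non-integer sample size {raw_n!r}"
                    ) from None
        null_freq: dict[str, float] = {}
        for i, locus in locus_cols:
            cell = row[i].strip() if i < len(row) else ""
            if not cell or cell in {"-", "--"}:
                continue
            try:
                f = float(cell)
            except ValueError:
                raise ValueError(
                    f"{source}:{lineno}: non-numeric frequency {cell!r} for {locus}"
                ) from None
            if not (0.0 <= f <= 1.0):
                raise ValueError(
                    f"{source}:{lineno}: frequency {f} for {locus} outside [0,1]"
                )
            null_freq[locus] = f
        records.append(
            PopulationRecord(population=population, n=n, null_freq=null_freq, region=region)
        )
    return records


def read_panel(
    path: str | Path, *, delimiter: str = "\t", provenance: str | None = None
) -> ReferencePanel:
    """Read a population frequency panel.

    Expected columns: ``population``, optional ``region`` and ``n``, and one
    column per locus holding null-genotype frequencies.  Blank cells (or "-")
    mean "not published" and are kept missing, never coerced to 0.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty panel file") from None
        records = _parse_panel_rows(list(reader), header, str(path))
    return ReferencePanel(records, provenance=provenance or str(path))


def write_panel(panel: ReferencePanel, path: str | Path, *, delimiter: str = "\t") -> None:
    """Write a panel in the same schema ``read_panel`` accepts (round-trip safe)."""
    loci = panel.loci
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(["population", "region", "n", *loci])
        for rec in panel.records:
            row = [
                rec.population,
                rec.region or "",
                "" if rec.n is None else str(rec.n),
            ]
            for locus in loci:
                f = rec.null_freq.get(locus)
                row.append("" if f is None else repr(f))
            writer.writerow(row)


def load_reference_panel() -> ReferencePanel:
    """Load the packaged global GSTM1/GSTT1 null-genotype frequency panel."""
    ref = resources.files("nullmark.data").joinpath(REFERENCE_PANEL_NAME)
    with resources.as_file(ref) as path:
        return read_panel(
            path,
            provenance="packaged global survey of GSTM1/GSTT1 null genotype frequencies",
        )
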