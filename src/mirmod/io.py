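"""Readers and writers for the external formats the pipeline touches.

Everything downstream consumes only the in-memory types defined here:
:class:`LibraryDesign` rows describing the factorial experiment,
:class:`SequenceRecord` for FASTA/FASTQ sequences, :class:`ExpressionMatrix`
for count/abundance tables tied to a design, and :class:`DegradomeProfile`
for per-transcript 5'-end read piles.

Conventions
-----------
* All transcript coordinates are 1-based and fully closed; miRNA positions
  are numbered 1..L from the 5' end.
* Sequences are normalized to uppercase RNA (T -> U) in memory; FASTA files
  are written back with the alphabet they were read with.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

GENOTYPES = ("ST", "SS")
TIMEPOINTS_H = (0.5, 3.0, 8.0, 27.0)
CONDITIONS = ("CT", "NaCl")
REPLICATES = (1, 2, 3)

#: Genotype-contrast classes for candidate salt-tolerance modules: a pair is
#: differentially expressed in one genotype while the other genotype shows the
#: partner either flat ("little changed") or below the expressed threshold.
MODULE_CLASSES = (
    "DE_in_ST_flat_in_SS",
    "DE_in_SS_flat_in_ST",
    "ST_specific_expression",
    "SS_specific_expression",
)

_VALID_CHARS = set("ACGUN")


class FormatError(ValueError):
    """A file violated the expected tabular/sequence format."""


class DesignError(ValueError):
    """An experiment design sheet violated the factorial-design contract."""


def _norm_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _norm_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class SequenceRecord:
    """A named nucleotide sequence, stored internally as uppercase RNA."""

    id: str
    seq: str
    description: str = ""
    written_as_dna: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.seq:
            raise FormatError(f"sequence record {self.id!r} with empty sequence")
        norm = _norm_rna(self.seq)
        bad = set(norm) - _VALID_CHARS
        if bad:
            raise FormatError(
                f"sequence record {self.id!r} contains non-nucleotide characters {sorted(bad)}"
            )
        object.__setattr__(self, "seq", norm)

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class LibraryDesign:
    """One sequencing library in the 2 genotypes x 4 timepoints x 2 conditions x 3 replicates design."""

    library_id: str
    genotype: str
    timepoint_h: float
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise DesignError(f"unknown genotype {self.genotype!r} (expected one of {GENOTYPES})")
        if float(self.timepoint_h) not in TIMEPOINTS_H:
            raise DesignError(
                f"unknown timepoint {self.timepoint_h!r} h (expected one of {TIMEPOINTS_H})"
            )
        if self.condition not in CONDITIONS:
            raise DesignError(f"unknown condition {self.condition!r} (expected one of {CONDITIONS})")
        if int(self.replicate) not in REPLICATES:
            raise DesignError(f"replicate must be 1..3, got {self.replicate!r}")
        object.__setattr__(self, "timepoint_h", float(self.timepoint_h))
        object.__setattr__(self, "replicate", int(self.replicate))

    @property
    def key(self) -> tuple:
        return (self.genotype, self.timepoint_h, self.condition, self.replicate)


def full_factorial_design() -> list[LibraryDesign]:
    """The canonical 48-library design with deterministic library ids."""
    designs = []
    for g in GENOTYPES:
        for t in TIMEPOINTS_H:
            for c in CONDITIONS:
                for r in REPLICATES:
                    tp = f"{t:g}".replace(".", "p")
                    designs.append(
                        LibraryDesign(f"{g}_T{tp}_{c}_r{r}", g, t, c, r)
                    )
    return designs


def validate_design(designs: Sequence[LibraryDesign]) -> bool:
    """Reject duplicate (genotype, timepoint, condition, replicate) cells.

    Returns True when the sheet covers the complete 48-library factorial.
    """
    seen: dict[tuple, str] = {}
    ids = set()
    for d in designs:
        if d.library_id in ids:
            raise DesignError(f"duplicate library_id {d.library_id!r}")
        ids.add(d.library_id)
        if d.key in seen:
            raise DesignError(
                f"duplicate design cell {d.key} in libraries {seen[d.key]!r} and {d.library_id!r}"
            )
        seen[d.key] = d.library_id
    expected = len(GENOTYPES) * len(TIMEPOINTS_H) * len(CONDITIONS) * len(REPLICATES)
    return len(designs) == expected


def read_design(path: str | Path) -> list[LibraryDesign]:
    """Read a TSV design sheet (library_id, genotype, timepoint_h, condition, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["library_id", "genotype", "timepoint_h", "condition", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"design sheet {path} missing columns {missing}")
    designs = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            designs.append(
                LibraryDesign(
                    str(row.library_id),
                    str(row.genotype),
                    float(row.timepoint_h),
                    str(row.condition),
                    int(row.replicate),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: malformed design row at line {i}: {exc}") from exc
    validate_design(designs)
    return designs


def write_design(designs: Sequence[LibraryDesign], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "library_id": [d.library_id for d in designs],
            "genotype": [d.genotype for d in designs],
            "timepoint_h": [f"{d.timepoint_h:g}" for d in designs],
            "condition": [d.condition for d in designs],
            "replicate": [d.replicate for d in designs],
        }
    )
    df.to_csv(path, sep="\t", index=False)


@dataclass
class ExpressionMatrix:
    """Features x libraries values bound to a library design.

    ``values`` columns are always in design order, whatever the file order.
    """

    values: pd.DataFrame
    design: list[LibraryDesign] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [d.library_id for d in self.design]
        if list(self.values.columns) != ids:
            self.values = self.values.loc[:, ids]

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    def libraries(self, genotype: str | None = None, timepoint_h: float | None = None,
                  condition: str | None = None) -> list[str]:
        out = []
        for d in self.design:
            if genotype is not None and d.genotype != genotype:
                continue
            if timepoint_h is not None and d.timepoint_h != float(timepoint_h):
                continue
            if condition is not None and d.condition != condition:
                continue
            out.append(d.library_id)
        return out


def read_counts(path: str | Path, design: Sequence[LibraryDesign]) -> ExpressionMatrix:
    """Read a feature x library count TSV; columns must match the design exactly."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    design_ids = [d.library_id for d in design]
    extra = [c for c in df.columns if c not in design_ids]
    if extra:
        raise FormatError(f"{path}: columns not in design: {extra}")
    absent = [c for c in design_ids if c not in df.columns]
    if absent:
        raise FormatError(f"{path}: design libraries missing from file: {absent}")
    if df.isna().any().any():
        raise FormatError(f"{path}: missing cells are not allowed")
    if (df.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative values are not allowed")
    return ExpressionMatrix(df.loc[:, design_ids], list(design))


def write_counts(matrix: ExpressionMatrix, path: str | Path, float_format: str = "%.6g") -> None:
    matrix.values.to_csv(path, sep="\t", float_format=float_format)


@dataclass
class DegradomeProfile:
    """Per-transcript 5'-end read counts: 1-based position -> count (>= 1)."""

    transcript_id: str
    positions: dict[int, int] = field(default_factory=dict)
    length: int | None = None

    def __post_init__(self) -> None:
        for pos, count in self.positions.items():
            if pos < 1:
                raise FormatError(
                    f"degradome position {pos} on {self.transcript_id}: positions are 1-based"
                )
            if count < 1:
                raise FormatError(
                    f"degradome count {count} at {self.transcript_id}:{pos}: stored counts are >= 1"
                )
            if self.length is not None and pos > self.length:
                raise FormatError(
                    f"degradome position {pos} beyond {self.transcript_id} length {self.length}"
                )

    def count_at(self, pos: int) -> int:
        return self.positions.get(pos, 0)

    def max_count(self) -> int:
        return max(self.positions.values()) if self.positions else 0


def read_degradome(path: str | Path) -> dict[str, DegradomeProfile]:
    """Read a degradome 5'-end table (transcript_id, position, count).

    Rows with the same (transcript, position) are summed.
    """
    df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str})
    required = ["transcript_id", "position", "count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"degradome table {path} missing columns {missing}")
    if len(df) == 0:
        return {}
    for col in ("position", "count"):
        vals = df[col]
        if not (vals == vals.astype(int)).all():
            raise FormatError(f"degradome table {path}: non-integer values in {col!r}")
    if (df["position"] < 1).any():
        raise FormatError(f"degradome table {path}: positions are 1-based (found < 1)")
    if (df["count"] < 0).any():
        raise FormatError(f"degradome table {path}: negative counts")
    agg = df.groupby(["transcript_id", "position"])["count"].sum()
    profiles: dict[str, DegradomeProfile] = {}
    for (tx, pos), count in agg.items():
        if count < 1:
            continue
        profiles.setdefault(tx, DegradomeProfile(tx, {})).positions[int(pos)] = int(count)
    return profiles


def write_degradome(profiles: Mapping[str, DegradomeProfile], path: str | Path) -> None:
    rows = []
    for tx in sorted(profiles):
        prof = profiles[tx]
        for pos in sorted(prof.positions):
            rows.append((tx, pos, prof.positions[pos]))
    pd.DataFrame(rows, columns=["transcript_id", "position", "count"]).to_csv(
        path, sep="\t", index=False
    )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    with _open_text(path) as fh:
        records = [
            SequenceRecord(rec.id, str(rec.seq), rec.description,
                           written_as_dna="T" in str(rec.seq).upper())
            for rec in SeqIO.parse(fh, "fasta")
        ]
    if not records and Path(path).stat().st_size > 0:
        raise FormatError(f"{path}: no FASTA records parsed")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            seq = _norm_dna(rec.seq) if rec.written_as_dna else rec.seq
            fh.write(f">{rec.id}\n{seq}\n")


def read_fastq_sequences(path: str | Path) -> list[str]:
    """Read sequences from FASTQ; qualities are parsed but discarded."""
    with _open_text(path) as fh:
        return [str(rec.seq).upper() for rec in SeqIO.parse(fh, "fastq")]


def map_tags_to_transcripts(tags: Iterable[str], transcripts: Sequence[SequenceRecord]
                            ) -> dict[str, list[tuple[str, int]]]:
    """Exact-substring placement of degradome tags on transcripts.

    Returns tag -> list of (transcript_id, 1-based position of tag 5' end).
    Genome-scale alignment is out of scope; this helper supports only exact
    matches and assigns every occurrence it finds.
    """
    hits: dict[str, list[tuple[str, int]]] = {}
    for tag in tags:
        tag_rna = _norm_rna(tag)
        found = []
        for tx in transcripts:
            start = tx.seq.find(tag_rna)
            while start != -1:
                found.append((tx.id, start + 1))
                start = tx.seq.find(tag_rna, start + 1)
        hits[tag] = found
    return hits
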