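"""Readers and writers for the package's external formats.

Formats handled: multi-record FASTA (via Biopython), CISBP-RNA motif text
files ("Pos A C G U" header, one probability row per position), and
tab-separated tables for transcript annotation and nuclear:cytosolic
fold-changes. Sequences are canonicalized to the DNA alphabet on read
(uppercase, U -> T, residual ambiguity codes -> N) so downstream scanning
never converts per call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .exceptions import DataError, ValidationError
from .genomic import canonical_biotype, canonical_chromosome

__all__ = [
    "TranscriptRecord",
    "FoldChangeTable",
    "read_fasta",
    "write_fasta",
    "normalize_sequence",
    "read_annotation",
    "build_transcript_records",
    "read_pwm",
    "write_pwm",
    "read_pwm_collection",
    "read_foldchange_table",
    "load_feature_label_dataset",
]

_CANONICAL = frozenset("ACGTN")
# IUPAC one-letter codes that may appear in cDNA; anything ambiguous -> N
_IUPAC = frozenset("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class TranscriptRecord:
    """One lncRNA transcript with its canonical sequence and annotation."""

    transcript_id: str
    sequence: str
    biotype: str = "other"
    chromosome: str = "other"

    def __post_init__(self) -> None:
        if not self.transcript_id:
            raise ValidationError("transcript_id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"{self.transcript_id}: empty sequence")
        bad = set(self.sequence) - _CANONICAL
        if bad:
            raise ValidationError(
                f"{self.transcript_id}: non-canonical characters {sorted(bad)}"
            )


@dataclass(frozen=True)
class FoldChangeTable:
    """Per-cell-type nuclear:cytosolic log2 fold-changes.

    n_samples is the number of fractionation RNA-seq samples behind the
    cell type and serves as the aggregation weight.
    """

    cell_type: str
    entries: Mapping[str, float]
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValidationError(
                f"{self.cell_type}: n_samples must be >= 2, got {self.n_samples}"
            )
        for tid, value in self.entries.items():
            if not np.isfinite(value):
                raise ValidationError(f"{self.cell_type}/{tid}: non-finite l2fc")


def normalize_sequence(raw: str) -> str:
    """Canonicalize a raw nucleotide string.

    Uppercase, U -> T, any other IUPAC ambiguity code -> N. Idempotent.
    Raises on empty input or characters outside the IUPAC alphabet; warns
    when the result is all N.
    """
    if not raw:
        raise DataError("empty sequence")
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - _IUPAC
    if bad:
        raise DataError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    seq = "".join(b if b in _CANONICAL else "N" for b in seq)
    if set(seq) == {"N"}:
        warnings.warn("sequence is all-N after normalization", stacklevel=2)
    return seq


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, raw sequence) pairs, order preserved."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with path.open() as handle:
        for line in handle:
            if line.strip():
                if not line.startswith(">"):
                    raise DataError(f"{path}: sequence line before any FASTA header")
                break
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    with path.open() as handle:
        for offset, rec in enumerate(SeqIO.parse(handle, "fasta")):
            if not rec.id:
                raise DataError(f"{path}: record {offset} has an empty id")
            if len(rec.seq) == 0:
                raise DataError(f"{path}: record {rec.id!r} (offset {offset}) is empty")
            if rec.id in seen:
                raise DataError(
                    f"{path}: duplicate id {rec.id!r} at offsets {seen[rec.id]} and {offset}"
                )
            seen[rec.id] = offset
            records.append((rec.id, str(rec.seq)))
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    path = Path(path)
    seq_records = [
        SeqRecord(Seq(seq), id=tid, description="") for tid, seq in records
    ]
    with path.open("w") as handle:
        SeqIO.write(seq_records, handle, "fasta")


def read_annotation(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a transcript annotation TSV into id -> (biotype, chromosome).

    Requires columns transcript_id, biotype, chromosome. Unknown biotypes
    map to "other" with a warning; chromosome names are normalized
    ("chr7" -> "7"). Duplicate ids with conflicting values are rejected.
    """
    table = pd.read_csv(path, sep="\t", dtype=str)
    required = {"transcript_id", "biotype", "chromosome"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"{path}: missing annotation columns {sorted(missing)}")
    mapping: dict[str, tuple[str, str]] = {}
    for row in table.itertuples(index=False):
        value = (canonical_biotype(row.biotype), canonical_chromosome(row.chromosome))
        previous = mapping.get(row.transcript_id)
        if previous is not None and previous != value:
            raise DataError(
                f"{path}: conflicting annotation for {row.transcript_id!r}: "
                f"{previous} vs {value}"
            )
        mapping[row.transcript_id] = value
    return mapping


def build_transcript_records(
    fasta_records: Iterable[tuple[str, str]],
    annotation: Mapping[str, tuple[str, str]],
) -> list[TranscriptRecord]:
    """Join sequences with annotation; reject unannotated ids as a batch."""
    fasta_records = list(fasta_records)
    missing = [tid for tid, _ in fasta_records if tid not in annotation]
    if missing:
        raise DataError(f"transcripts missing annotation: {missing}")
    return [
        TranscriptRecord(
            transcript_id=tid,
            sequence=normalize_sequence(seq),
            biotype=annotation[tid][0],
            chromosome=annotation[tid][1],
        )
        for tid, seq in fasta_records
    ]


def read_pwm(path: str | Path, pseudocount: float = 1e-3):
    """Read one CISBP-RNA text motif into a PWM (U column stored under T)."""
    from .motifs import PWM  # local import keeps module deps one-way

    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        raise DataError(f"{path}: empty motif file")
    header = lines[0].split()
    if len(header) != 5 or header[0].lower() != "pos":
        raise DataError(f"{path}: expected header 'Pos A C G U', got {lines[0]!r}")
    rows: list[list[float]] = []
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != 5:
            raise DataError(f"{path}: expected 5 columns, got {len(parts)}: {ln!r}")
        try:
            rows.append([float(x) for x in parts[1:]])
        except ValueError as exc:
            raise DataError(f"{path}: non-numeric probability in {ln!r}") from exc
    if not rows:
        raise DataError(f"{path}: motif has no positions")
    probs = np.asarray(rows, dtype=np.float64)
    if (probs < 0).any():
        raise DataError(f"{path}: negative probability entry")
    sums = probs.sum(axis=1)
    if np.any(sums <= 0):
        raise DataError(f"{path}: all-zero probability row")
    if np.any(np.abs(sums - 1.0) > 1e-3):
        warnings.warn(f"{path.name}: PWM rows renormalized to sum to 1", stacklevel=2)
        probs = probs / sums[:, None]
    return PWM(motif_id=path.stem, probs=probs, pseudocount=pseudocount)


def write_pwm(pwm, path: str | Path) -> None:
    path = Path(path)
    lines = ["Pos\tA\tC\tG\tU"]
    for i, row in enumerate(pwm.probs, start=1):
        lines.append("\t".join([str(i)] + [f"{x:.10f}" for x in row]))
    path.write_text("\n".join(lines) + "\n")


def read_pwm_collection(path: str | Path, pseudocount: float = 1e-3) -> list:
    """Read a directory of motif files (or a single file) into sorted PWMs."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.is_file())
        if not files:
            raise DataError(f"{path}: no motif files found")
        pwms = [read_pwm(p, pseudocount) for p in files]
    else:
        pwms = [read_pwm(path, pseudocount)]
    ids = [p.motif_id for p in pwms]
    if len(set(ids)) != len(ids):
        raise DataError(f"{path}: duplicate motif ids")
    return sorted(pwms, key=lambda p: p.motif_id)


def read_foldchange_table(
    path: str | Path, cell_type: str, n_samples: int
) -> FoldChangeTable:
    """Read a per-cell-type TSV of transcript_id, l2fc.

    Rows with non-finite l2fc are dropped with a warning.
    """
    table = pd.read_csv(path, sep="\t")
    missing = {"transcript_id", "l2fc"} - set(table.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    l2fc = pd.to_numeric(table["l2fc"], errors="coerce")
    keep = np.isfinite(l2fc)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"{cell_type}: dropped {n_dropped} rows with non-finite l2fc "
            f"({int(keep.sum())} retained)",
            stacklevel=2,
        )
    entries = dict(zip(table.loc[keep, "transcript_id"], l2fc[keep].astype(float)))
    return FoldChangeTable(cell_type=cell_type, entries=entries, n_samples=n_samples)


def load_feature_label_dataset(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Load an assembled feature + label table (TSV).

    Expects a transcript_id column, a label column over
    {nuclear, cytosolic}, and numeric feature columns (everything else).
    Returns (features, labels). This is the entry point for externally
    assembled datasets such as the published supplementary table.
    """
    table = pd.read_csv(path, sep="\t")
    required = {"transcript_id", "label"}
    missing = required - set(table.columns)
    if missing:
        raise DataError(f"{path}: missing columns {sorted(missing)}")
    labels = table["label"].astype(str)
    bad = set(labels.unique()) - {"nuclear", "cytosolic"}
    if bad:
        raise DataError(f"{path}: unknown labels {sorted(bad)}")
    features = table.drop(columns=["transcript_id", "label"])
    features.index = pd.Index(table["transcript_id"], name="transcript_id")
    non_numeric = [
        c for c in features.columns if not pd.api.types.is_numeric_dtype(features[c])
    ]
    if non_numeric:
        raise DataError(f"{path}: non-numeric feature columns {non_numeric}")
    labels.index = features.index
    return features, labels
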