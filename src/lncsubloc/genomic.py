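"""Genomic-context features and feature-matrix assembly.

lncRNA biotype (genomic context relative to protein-coding genes) and
chromosome are encoded as one-hot blocks, plus a derived binary flag
marking transcripts that lie sense to a proximal protein-coding gene
(sense_intronic or sense_overlapping) — the single most informative
feature class for nuclear retention.

The assembled feature matrix is a pandas DataFrame (rows = transcripts in
input order) with a JSON-serializable column-name manifest; a hash of the
manifest travels with every trained model so a model can never silently
score a matrix with misaligned columns.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, ValidationError
from .kmers import KmerRegistry, enumerate_kmers, kmer_frequency_vector
from .motifs import PWM, motif_feature_vector, sorted_motif_ids

BIOTYPE_CATEGORIES: tuple[str, ...] = (
    "lincRNA",
    "antisense",
    "sense_intronic",
    "sense_overlapping",
    "other",
)
SENSE_PROXIMAL_BIOTYPES = frozenset({"sense_intronic", "sense_overlapping"})

_BIOTYPE_ALIASES = {
    "lincrna": "lincRNA",
    "intergenic": "lincRNA",
    "long_intergenic_noncoding": "lincRNA",
    "antisense": "antisense",
    "antisense_rna": "antisense",
    "sense_intronic": "sense_intronic",
    "sense_overlapping": "sense_overlapping",
}

CHROMOSOME_CATEGORIES: tuple[str, ...] = tuple(str(i) for i in range(1, 23)) + (
    "X",
    "Y",
    "MT",
    "other",
)
_CHROM_SET = frozenset(CHROMOSOME_CATEGORIES[:-1])


def canonical_biotype(raw: str) -> str:
    """Map an annotation biotype string to a model category.

    Unknown biotypes fall back to "other" with a warning.
    """
    key = raw.strip().lower()
    if key in _BIOTYPE_ALIASES:
        return _BIOTYPE_ALIASES[key]
    warnings.warn(f"unknown biotype {raw!r} mapped to 'other'", stacklevel=2)
    return "other"


def canonical_chromosome(raw: str) -> str:
    """Normalize a chromosome name ('chr7' -> '7'; unplaced -> 'other')."""
    name = raw.strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    name = name.upper()
    if name == "M":
        name = "MT"
    return name if name in _CHROM_SET else "other"


def encode_biotype(biotype: str) -> np.ndarray:
    """One-hot over BIOTYPE_CATEGORIES plus trailing is_sense_proximal flag."""
    category = biotype if biotype in BIOTYPE_CATEGORIES else "other"
    vec = np.zeros(len(BIOTYPE_CATEGORIES) + 1, dtype=np.float64)
    vec[BIOTYPE_CATEGORIES.index(category)] = 1.0
    vec[-1] = 1.0 if category in SENSE_PROXIMAL_BIOTYPES else 0.0
    return vec


def encode_chromosome(chrom: str) -> np.ndarray:
    category = chrom if chrom in CHROMOSOME_CATEGORIES else "other"
    vec = np.zeros(len(CHROMOSOME_CATEGORIES), dtype=np.float64)
    vec[CHROMOSOME_CATEGORIES.index(category)] = 1.0
    return vec


def biotype_column_names() -> list[str]:
    return [f"biotype_{c}" for c in BIOTYPE_CATEGORIES] + ["is_sense_proximal"]


def chromosome_column_names() -> list[str]:
    return [f"chrom_{c}" for c in CHROMOSOME_CATEGORIES]


@dataclass
class FeatureMatrix:
    """Feature table plus the manifest that pins its column registry."""

    data: pd.DataFrame
    manifest: dict

    @property
    def registry_hash(self) -> str:
        payload = json.dumps(
            {"columns": self.manifest["columns"], "config": self.manifest["config"]},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.float64)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.data.to_csv(path, sep="\t", index_label="transcript_id")
        manifest = dict(self.manifest)
        manifest["registry_hash"] = self.registry_hash
        manifest_path = path.with_suffix(path.suffix + ".manifest.json")
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        data = pd.read_csv(path, sep="\t", index_col="transcript_id")
        manifest_path = path.with_suffix(path.suffix + ".manifest.json")
        if not manifest_path.exists():
            raise DataError(f"missing feature manifest {manifest_path}")
        manifest = json.loads(manifest_path.read_text())
        if list(data.columns) != manifest["columns"]:
            raise DataError("feature matrix columns do not match manifest registry")
        return cls(data=data, manifest=manifest)


def assemble_feature_matrix(
    records: Sequence,
    pwms: Iterable[PWM] = (),
    registry: KmerRegistry | None = None,
    alpha: float = 0.8,
    threshold_mode: str = "max_fraction",
    kmer_mode: str = "frequency",
) -> FeatureMatrix:
    """Featurize annotated transcripts into the full model input matrix.

    Column order: k-mer block, motif block, biotype block (incl. the
    sense-proximal flag), chromosome block. Row order follows the input.
    Records lacking annotation (empty biotype/chromosome) are rejected
    together, by ID.
    """
    records = list(records)
    if not 0.0 < alpha <= 1.0:
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    if registry is None:
        registry = enumerate_kmers(2, 5)
    pwms = list(pwms)
    missing = [r.transcript_id for r in records if not r.biotype or not r.chromosome]
    if missing:
        raise ValidationError(f"transcripts missing annotation: {missing}")
    ids = [r.transcript_id for r in records]
    if len(set(ids)) != len(ids):
        raise DataError("duplicate transcript ids in feature assembly")

    motif_cols = [f"rbp_{m}" for m in sorted_motif_ids(pwms)] if pwms else []
    columns = (
        registry.column_names
        + motif_cols
        + biotype_column_names()
        + chromosome_column_names()
    )
    rows = np.empty((len(records), len(columns)), dtype=np.float64)
    for i, rec in enumerate(records):
        blocks = [kmer_frequency_vector(rec.sequence, registry, mode=kmer_mode)]
        if pwms:
            blocks.append(
                motif_feature_vector(pwms, rec.sequence, alpha, threshold_mode).astype(
                    np.float64
                )
            )
        blocks.append(encode_biotype(rec.biotype))
        blocks.append(encode_chromosome(rec.chromosome))
        rows[i] = np.concatenate(blocks)

    data = pd.DataFrame(rows, index=pd.Index(ids, name="transcript_id"), columns=columns)
    manifest = {
        "columns": columns,
        "config": {
            "k_min": registry.k_min,
            "k_max": registry.k_max,
            "kmer_mode": kmer_mode,
            "alpha": alpha,
            "threshold_mode": threshold_mode,
            "n_motifs": len(motif_cols),
            "biotype_categories": list(BIOTYPE_CATEGORIES),
            "chromosome_categories": list(CHROMOSOME_CATEGORIES),
        },
    }
    return FeatureMatrix(data=data, manifest=manifest)
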