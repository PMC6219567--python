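"""Synthetic data generators with planted structure.

Every pipeline stage is testable without external downloads: transcripts
carry a planted nuclear-retention pentamer (AGCCC by default, a motif
known to drive nuclear localization) inserted at class-specific Poisson
rates; fold-change tables draw each transcript's true nuclear:cytosolic
l2fc from a two-component mixture (nuclear mean above cytosolic) and add
per-cell-type Gaussian noise, with optional detection dropout mimicking
transcripts absent from a cell type. All generators are deterministic
under a fixed seed.

What this emulates — and what it does not: sequences are i.i.d.
background plus motif insertions, with none of the grammar of real
transcripts (splice structure, polyA, repeat content), and class signal
enters only through the planted motif and optional GC shift. Passing
tests on this material demonstrates the pipeline's correctness, not
real-data performance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .genomic import BIOTYPE_CATEGORIES, CHROMOSOME_CATEGORIES
from .io import FoldChangeTable, TranscriptRecord
from .motifs import PWM

__all__ = [
    "SyntheticSpec",
    "generate_transcripts",
    "generate_foldchange_tables",
    "generate_fixture_pwms",
]

_MAX_PLACEMENT_RETRIES = 50


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the planted-motif transcript generator."""

    n_per_class: int = 1000
    length_range: tuple[int, int] = (200, 1000)
    planted_motif: str = "AGCCC"
    nuclear_motif_rate: float = 3.0
    cytosolic_motif_rate: float = 0.0
    gc_bias: float = 0.0  # added to nuclear-class GC fraction (baseline 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 0:
            raise ValidationError("n_per_class must be non-negative")
        lo, hi = self.length_range
        if lo > hi or lo < len(self.planted_motif):
            raise ValidationError(
                "length_range must satisfy motif width <= min <= max"
            )
        if self.nuclear_motif_rate < 0 or self.cytosolic_motif_rate < 0:
            raise ValidationError("motif rates must be non-negative")
        if not set(self.planted_motif) <= set("ACGT"):
            raise ValidationError("planted motif must be over {A,C,G,T}")
        if not -0.25 <= self.gc_bias <= 0.25:
            raise ValidationError("gc_bias must be in [-0.25, 0.25]")


def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _plant_motifs(seq: list[str], motif: str, count: int, rng) -> None:
    """Insert `count` non-overlapping motif copies at uniform positions."""
    width = len(motif)
    occupied: list[tuple[int, int]] = []
    for _ in range(count):
        placed = False
        for _ in range(_MAX_PLACEMENT_RETRIES):
            start = int(rng.integers(0, len(seq) - width + 1))
            if all(start + width <= a or start >= b for a, b in occupied):
                seq[start : start + width] = list(motif)
                occupied.append((start, start + width))
                placed = True
                break
        if not placed:
            warnings.warn("could not place a motif copy without overlap; skipped",
                          stacklevel=3)


def generate_transcripts(
    spec: SyntheticSpec,
) -> tuple[list[TranscriptRecord], dict[str, str]]:
    """Generate annotated transcripts with class-specific planted motifs.

    Returns (records, truth) where truth maps transcript_id to the planted
    class ("nuclear"/"cytosolic"). Background bases are i.i.d. with a
    class GC fraction of 0.5 + gc_bias (nuclear) / 0.5 (cytosolic); motif
    copy numbers are Poisson at the class rate. Biotypes and chromosomes
    are drawn uniformly from the model categories.
    """
    rng = np.random.default_rng(spec.seed)
    bases = np.array(list("ACGT"))
    records: list[TranscriptRecord] = []
    truth: dict[str, str] = {}
    class_specs = [
        ("nuclear", spec.nuclear_motif_rate, 0.5 + spec.gc_bias),
        ("cytosolic", spec.cytosolic_motif_rate, 0.5),
    ]
    for label, rate, gc in class_specs:
        probs = _base_probs(gc)
        for i in range(spec.n_per_class):
            length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
            seq = list(bases[rng.choice(4, size=length, p=probs)])
            n_copies = int(rng.poisson(rate))
            if n_copies:
                _plant_motifs(seq, spec.planted_motif, n_copies, rng)
            tid = f"SYN_{label.upper()[:3]}_{i:05d}"
            records.append(
                TranscriptRecord(
                    transcript_id=tid,
                    sequence="".join(seq),
                    biotype=BIOTYPE_CATEGORIES[int(rng.integers(len(BIOTYPE_CATEGORIES)))],
                    chromosome=CHROMOSOME_CATEGORIES[
                        int(rng.integers(len(CHROMOSOME_CATEGORIES)))
                    ],
                )
            )
            truth[tid] = label
    return records, truth


def generate_foldchange_tables(
    truth: dict[str, str],
    n_celltypes: int = 5,
    class_means: tuple[float, float] = (3.0, -1.0),
    noise_sd: float = 0.3,
    dropout_rate: float = 0.0,
    seed: int = 0,
    n_samples_range: tuple[int, int] = (2, 8),
) -> list[FoldChangeTable]:
    """Per-cell-type fold-change tables around class-specific true l2fc.

    Each transcript's true l2fc is its class mean (nuclear first in
    class_means); each cell type observes truth + N(0, noise_sd), and each
    observation is independently dropped at dropout_rate (not detected in
    that cell type). Sample counts per cell type are drawn uniformly from
    n_samples_range and act as aggregation weights downstream.
    """
    if n_celltypes < 1:
        raise ValidationError("n_celltypes must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be non-negative")
    if not 0.0 <= dropout_rate <= 1.0:
        raise ValidationError("dropout_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = list(truth)
    mean_by_class = {"nuclear": class_means[0], "cytosolic": class_means[1]}
    true_l2fc = np.array([mean_by_class[truth[t]] for t in ids])
    tables: list[FoldChangeTable] = []
    for c in range(n_celltypes):
        observed = true_l2fc + rng.normal(0.0, noise_sd, size=len(ids))
        detected = rng.random(len(ids)) >= dropout_rate
        entries = {
            tid: float(val)
            for tid, val, keep in zip(ids, observed, detected)
            if keep
        }
        n_samples = int(rng.integers(n_samples_range[0], n_samples_range[1] + 1))
        tables.append(
            FoldChangeTable(cell_type=f"cell_{c}", entries=entries, n_samples=n_samples)
        )
    if all(len(t.entries) == 0 for t in tables):
        warnings.warn("all fold-change tables are empty (dropout too high)",
                      stacklevel=2)
    return tables


def generate_fixture_pwms(motifs: list[str], softness: float = 0.0) -> list[PWM]:
    """Consensus-based PWMs: probability (1 - softness) on the consensus
    base, softness/3 spread over the rest. softness 0 gives an exact
    consensus matcher under the 80%-of-maximum rule."""
    if not 0.0 <= softness < 0.75:
        raise ValidationError("softness must be in [0, 0.75)")
    pwms: list[PWM] = []
    for m, motif in enumerate(motifs):
        if not motif or not set(motif) <= set("ACGT"):
            raise ValidationError(f"invalid consensus motif {motif!r}")
        probs = np.full((len(motif), 4), softness / 3.0)
        for i, base in enumerate(motif):
            probs[i, "ACGT".index(base)] = 1.0 - softness
        pwms.append(PWM(motif_id=f"fixture_{m:03d}_{motif}", probs=probs))
    return pwms
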