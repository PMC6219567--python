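"""Differential-localization labeling from fold-change tables.

Per-cell-type nuclear:cytosolic log2 fold-changes are aggregated across
cell types with a weighted average (weights = samples per cell type,
restricted to cell types where the transcript was detected). Because
lncRNAs are predominantly nuclear-enriched, the labeling thresholds are
asymmetric: the first and fourth quartile of the aggregated distribution
(fixed at 0 and 2.8 for the original data). Transcripts strictly below
the lower threshold are cytosolic, strictly above the upper are nuclear,
everything else — including exact boundary values — stays unlabeled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import FoldChangeTable

__all__ = [
    "SplitSpec",
    "aggregate_l2fc",
    "derive_thresholds",
    "assign_labels",
    "split_dataset",
]

LABELS = ("nuclear", "cytosolic", "unlabeled")


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test partition specification."""

    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    stratify: bool = False

    def __post_init__(self) -> None:
        if len(self.fractions) != 3 or any(f < 0 for f in self.fractions):
            raise ValidationError("fractions must be three non-negative numbers")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValidationError("fractions must sum to 1")


def aggregate_l2fc(tables: Iterable[FoldChangeTable]) -> pd.DataFrame:
    """Sample-size-weighted mean l2fc per transcript across cell types.

    Only cell types where a transcript is detected enter its average
    (absence is treated as missing, not as zero). Returns a DataFrame
    indexed by transcript_id with columns aggregated_l2fc and
    n_celltypes_detected; transcripts detected nowhere are simply absent.
    """
    tables = list(tables)
    if not tables or all(len(t.entries) == 0 for t in tables):
        raise ValidationError("no fold-change entries to aggregate")
    weighted_sum: dict[str, float] = {}
    weight_total: dict[str, float] = {}
    n_detected: dict[str, int] = {}
    for table in tables:
        w = float(table.n_samples)
        for tid, value in table.entries.items():
            weighted_sum[tid] = weighted_sum.get(tid, 0.0) + w * value
            weight_total[tid] = weight_total.get(tid, 0.0) + w
            n_detected[tid] = n_detected.get(tid, 0) + 1
    ids = list(weighted_sum)
    return pd.DataFrame(
        {
            "aggregated_l2fc": [weighted_sum[t] / weight_total[t] for t in ids],
            "n_celltypes_detected": [n_detected[t] for t in ids],
        },
        index=pd.Index(ids, name="transcript_id"),
    )


def derive_thresholds(values: Sequence[float] | np.ndarray) -> tuple[float, float]:
    """First and third quartile of the aggregated l2fc distribution.

    Linear-interpolation quantile definition. Callers may instead pass
    fixed thresholds straight to assign_labels (the original data used
    0 and 2.8).
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size < 4:
        raise ValidationError(f"need >= 4 values to derive quartiles, got {arr.size}")
    q1, q3 = np.quantile(arr, [0.25, 0.75], method="linear")
    if q1 == q3:
        warnings.warn("degenerate l2fc distribution: Q1 == Q3", stacklevel=2)
    return float(q1), float(q3)


def assign_labels(
    aggregated: pd.DataFrame | Mapping[str, float],
    thresholds: tuple[float, float],
) -> pd.DataFrame:
    """Label transcripts from aggregated l2fc with strict thresholds.

    cytosolic iff l2fc < lower; nuclear iff l2fc > upper; otherwise
    unlabeled (boundary values are unlabeled).
    """
    lower, upper = thresholds
    if lower > upper:
        raise ValidationError(f"inverted thresholds: {lower} > {upper}")
    if isinstance(aggregated, pd.DataFrame):
        result = aggregated.copy()
    else:
        result = pd.DataFrame(
            {"aggregated_l2fc": pd.Series(dict(aggregated), name="aggregated_l2fc")}
        )
        result.index.name = "transcript_id"
    l2fc = result["aggregated_l2fc"].to_numpy()
    label = np.where(l2fc < lower, "cytosolic", np.where(l2fc > upper, "nuclear", "unlabeled"))
    result["label"] = label
    counts = result["label"].value_counts()
    result.attrs["label_counts"] = {k: int(counts.get(k, 0)) for k in LABELS}
    result.attrs["thresholds"] = (float(lower), float(upper))
    return result


def _partition_sizes(n: int, fractions: tuple[float, float, float]) -> list[int]:
    """Integer partition sizes for (train, val, test).

    Floor of each share; leftover seats go one at a time in fixed
    train > val > test priority to partitions with a positive fractional
    remainder.
    """
    exact = [f * n for f in fractions]
    sizes = [int(np.floor(e)) for e in exact]
    remainders = [e - s for e, s in zip(exact, sizes)]
    leftover = n - sum(sizes)
    order = [i for i in range(3) if remainders[i] > 1e-12] or [0, 1, 2]
    j = 0
    while leftover > 0:
        sizes[order[j % len(order)]] += 1
        leftover -= 1
        j += 1
    return sizes


def split_dataset(
    ids: Sequence[str],
    spec: SplitSpec,
    labels: Mapping[str, str] | None = None,
) -> tuple[list[str], list[str], list[str]]:
    """Random disjoint, exhaustive train/val/test split.

    Deterministic given the seed. With spec.stratify, the split is applied
    within each label group (labels then required) and the partitions are
    concatenated.
    """
    ids = list(ids)
    if len(ids) < 3:
        raise ValidationError(f"need >= 3 ids to split, got {len(ids)}")
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate ids in split input")
    if spec.stratify:
        if labels is None:
            raise ValidationError("stratified split requires labels")
        groups: dict[str, list[str]] = {}
        for tid in ids:
            groups.setdefault(labels[tid], []).append(tid)
        train: list[str] = []
        val: list[str] = []
        test: list[str] = []
        for g, (name, members) in enumerate(sorted(groups.items())):
            sub = SplitSpec(fractions=spec.fractions, seed=spec.seed + g, stratify=False)
            t, v, s = split_dataset(members, sub)
            train += t
            val += v
            test += s
        return train, val, test
    rng = np.random.default_rng(spec.seed)
    shuffled = [ids[i] for i in rng.permutation(len(ids))]
    n_train, n_val, _ = _partition_sizes(len(ids), spec.fractions)
    return (
        shuffled[:n_train],
        shuffled[n_train : n_train + n_val],
        shuffled[n_train + n_val :],
    )
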