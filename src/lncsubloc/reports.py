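"""Summary reports over predictions and fold-change tables.

Two tables back the standard figures of a localization study: the
per-biotype percentage of transcripts predicted nuclear, and a
transcript-by-cell-type l2fc matrix (long format) with cell types ordered
by complete-linkage clustering on their pairwise localization
correlation.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .exceptions import DataError
from .io import FoldChangeTable

__all__ = ["biotype_localization_summary", "localization_heatmap_table"]

REFERENCE_PERCENT = 50.0  # the nuclear/cytosolic majority boundary


def biotype_localization_summary(
    predictions: pd.DataFrame, annotation: Mapping[str, tuple[str, str]]
) -> pd.DataFrame:
    """Percent of transcripts predicted nuclear, per biotype.

    `predictions` must carry a label column indexed by transcript_id.
    Returns columns (biotype, n, percent_nuclear, reference_pct); biotype
    groups with no predicted transcripts are omitted with a warning.
    """
    if "label" not in predictions.columns:
        raise DataError("predictions table needs a 'label' column")
    common = [tid for tid in predictions.index if tid in annotation]
    if not common:
        raise DataError("no overlap between predictions and annotation")
    biotypes = pd.Series({tid: annotation[tid][0] for tid in common})
    labels = predictions.loc[common, "label"]
    rows = []
    seen = set()
    for biotype, group in labels.groupby(biotypes):
        seen.add(biotype)
        rows.append(
            {
                "biotype": biotype,
                "n": len(group),
                "percent_nuclear": 100.0 * float(np.mean(group == "nuclear")),
                "reference_pct": REFERENCE_PERCENT,
            }
        )
    all_biotypes = {b for b, _ in annotation.values()}
    for absent in sorted(all_biotypes - seen):
        warnings.warn(f"biotype {absent!r} has no predicted transcripts; omitted",
                      stacklevel=2)
    return pd.DataFrame(rows).sort_values("percent_nuclear", ascending=False,
                                          ignore_index=True)


def localization_heatmap_table(
    tables: Iterable[FoldChangeTable],
) -> tuple[pd.DataFrame, list[str]]:
    """Long-format transcript x cell-type l2fc table plus cell-type order.

    Missing (not detected) combinations carry NaN; transcripts detected in
    no cell type are dropped with a warning. Cell types are ordered by
    complete-linkage clustering on 1 - Pearson correlation of their shared
    l2fc profiles (a single cell type keeps identity order).
    """
    tables = list(tables)
    if not tables:
        raise DataError("no fold-change tables given")
    wide = pd.DataFrame({t.cell_type: pd.Series(dict(t.entries)) for t in tables})
    empty_rows = wide.isna().all(axis=1)
    if empty_rows.any():
        warnings.warn(
            f"dropped {int(empty_rows.sum())} transcripts detected in no cell type",
            stacklevel=2,
        )
        wide = wide.loc[~empty_rows]
    if wide.shape[1] == 1:
        order = list(wide.columns)
    else:
        corr = wide.corr(min_periods=2).to_numpy()
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        dist = np.clip(1.0 - corr, 0.0, 2.0)
        dist = (dist + dist.T) / 2.0
        tree = linkage(squareform(dist, checks=False), method="complete")
        order = [wide.columns[i] for i in leaves_list(tree)]
    long = (
        wide[order]
        .reset_index(names="transcript_id")
        .melt(id_vars="transcript_id", var_name="cell_type", value_name="l2fc")
    )
    return long, order
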