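"""Two-sample differential statistics and the filter stage of the pipeline.

Fold changes follow the signed-ratio convention common in microarray
reporting: the ratio of group means is reported as +r when group 2 is r-fold
above group 1 and as -r when it is r-fold below, so ``|fc| >= 1`` always and
equal means give +1.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import (
    DataKind,
    DesignError,
    DiffStatsTable,
    ExpressionDataset,
    TWO_SAMPLE_KINDS,
)

logger = logging.getLogger(__name__)


def signed_fold_change(mean_g1: float, mean_g2: float) -> float:
    """Signed ratio of two positive group means (+up / -down, |fc| >= 1)."""
    if mean_g1 <= 0 or mean_g2 <= 0:
        raise ValueError("signed fold change requires positive group means")
    if mean_g2 >= mean_g1:
        return mean_g2 / mean_g1
    return -mean_g1 / mean_g2


def two_sample_stats(
    dataset: ExpressionDataset,
    log2_values: bool = False,
    adjust_p: bool = False,
) -> DiffStatsTable:
    """Per-entity t-test and signed fold change for a two-sample dataset.

    Paired designs use the paired t-test on per-pair differences; unpaired
    designs use Welch's t-test.  P-values are two-tailed.  With
    ``log2_values=True`` the matrix is taken as log2 expression and the fold
    change is the sign-preserving ratio ``2**|mean difference|``.  Entities
    with zero variance are reported with p = 1 when the group means agree
    (t = 0) and are otherwise excluded with a warning.  ``adjust_p`` appends a
    Benjamini-Hochberg column ``p_adj``.
    """
    if dataset.data_kind is DataKind.STATS_ONLY:
        assert dataset.stats is not None
        return dataset.stats
    if dataset.data_kind not in TWO_SAMPLE_KINDS:
        raise DesignError(
            f"two-sample statistics undefined for kind {dataset.data_kind.value}"
        )
    g1 = dataset.samples_in_group("G1")
    g2 = dataset.samples_in_group("G2")
    if len(g1) < 2 or len(g2) < 2:
        raise DesignError("need at least 2 samples per group")

    frame = dataset.to_frame()
    a = frame[g1].to_numpy()
    if dataset.data_kind is DataKind.PAIRED2:
        # order G2 columns to match the declared pairing
        assert dataset.pair_of_sample is not None
        b = frame[[dataset.pair_of_sample[s] for s in g1]].to_numpy()
    else:
        b = frame[g2].to_numpy()

    rows = {}
    dropped = []
    for i, entity in enumerate(dataset.entity_ids):
        x, y = a[i], b[i]
        m1, m2 = float(np.mean(x)), float(np.mean(y))
        if dataset.data_kind is DataKind.PAIRED2:
            diff = y - x
            if np.allclose(diff.std(ddof=1), 0.0):
                if np.allclose(diff.mean(), 0.0):
                    t, p = 0.0, 1.0
                else:
                    dropped.append(entity)
                    continue
            else:
                t, p = sps.ttest_rel(y, x)
        else:
            if np.allclose(x.std(ddof=1), 0.0) and np.allclose(y.std(ddof=1), 0.0):
                if np.allclose(m1, m2):
                    t, p = 0.0, 1.0
                else:
                    dropped.append(entity)
                    continue
            else:
                t, p = sps.ttest_ind(y, x, equal_var=False)
        if log2_values:
            d = m2 - m1
            fc = float(np.sign(d) * 2 ** abs(d)) if d != 0 else 1.0
        else:
            fc = signed_fold_change(m1, m2)
        rows[entity] = {"mean_g1": m1, "mean_g2": m2, "t": float(t), "p": float(p), "fc": fc}

    if dropped:
        logger.warning(
            "excluded %d degenerate zero-variance entities: %s%s",
            len(dropped),
            dropped[:5],
            "..." if len(dropped) > 5 else "",
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    if adjust_p and len(table):
        table["p_adj"] = _benjamini_hochberg(table["p"].to_numpy())
    return DiffStatsTable(table)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(adjusted, 0, 1)
    return out


def filter_two_sample(stats: DiffStatsTable, p_max: float, min_abs_fc: float = 1.0) -> set[str]:
    """Ids with p <= p_max and |fc| >= min_abs_fc."""
    if not 0 < p_max <= 1:
        raise ValueError("p_max must lie in (0, 1]")
    if min_abs_fc < 1:
        raise ValueError("min_abs_fc must be >= 1")
    t = stats.table
    keep = (t["p"] <= p_max) & (t["fc"].abs() >= min_abs_fc)
    return set(t.index[keep])


def filter_multisample(dataset: ExpressionDataset, min_mean: float) -> set[str]:
    """Ids whose mean expression across samples is at least ``min_mean``.

    Removes poorly expressed entities (e.g. rows that are mostly zero) from
    multisample or TCGA-style data before pairwise scoring.
    """
    if dataset.data_kind not in (DataKind.MULTISAMPLE, DataKind.TCGA):
        raise DesignError("expression-level filter applies to multisample/tcga data")
    means = dataset.values.mean(axis=1)
    return {e for e, m in zip(dataset.entity_ids, means) if m >= min_mean}
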