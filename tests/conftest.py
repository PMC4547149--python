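import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mirtarnet import (
    DataKind,
    EntityKind,
    ExpressionDataset,
    SyntheticConfig,
    generate_synthetic,
)


@pytest.fixture(scope="session")
def paired_bundle():
    """Paired two-sample bundle at the study defaults (seed 7)."""
    return generate_synthetic(SyntheticConfig(mode="paired2", seed=7))


@pytest.fixture(scope="session")
def multisample_bundle():
    """Multisample bundle with 30 samples for model-fitting tests (seed 7)."""
    return generate_synthetic(
        SyntheticConfig(mode="multisample", n_samples=30, seed=7)
    )


def make_dataset(values, entity_kind=EntityKind.MRNA, data_kind=DataKind.MULTISAMPLE,
                 entity_prefix="e", **kwargs):
    values = np.asarray(values, dtype=float)
    return ExpressionDataset(
        entity_kind=entity_kind,
        data_kind=data_kind,
        entity_ids=[f"{entity_prefix}{i}" for i in range(values.shape[0])],
        sample_ids=[f"s{j}" for j in range(values.shape[1])],
        values=values,
        **kwargs,
    )


@pytest.fixture
def paired_dataset_factory():
    """Build a tiny paired two-sample dataset from (pre, post) row tuples."""

    def build(rows, entity_kind=EntityKind.MIRNA):
        pre = np.array([r[0] for r in rows], dtype=float)
        post = np.array([r[1] for r in rows], dtype=float)
        n = pre.shape[1]
        sample_ids = [f"p{i}" for i in range(n)] + [f"q{i}" for i in range(n)]
        return ExpressionDataset(
            entity_kind=entity_kind,
            data_kind=DataKind.PAIRED2,
            entity_ids=[f"e{i}" for i in range(len(rows))],
            sample_ids=sample_ids,
            values=np.hstack([pre, post]),
            group_of_sample={s: ("G1" if s.startswith("p") else "G2") for s in sample_ids},
            pair_of_sample={f"p{i}": f"q{i}" for i in range(n)},
        )

    return build


def brute_force_mic(x, y, alpha=0.6):
    """Independent exhaustive MIC: every grid with p*q <= ceil(n**alpha).

    Grid lines are placed between consecutive distinct values on each axis;
    plain nested loops, no shared code with the implementation under test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    cap = math.ceil(n**alpha)
    xs = np.unique(x)
    ys = np.unique(y)

    def codes(v, vals, cuts):
        edges = [(vals[c - 1] + vals[c]) / 2 for c in cuts]
        return np.searchsorted(edges, v)

    best = 0.0
    for p in range(2, cap // 2 + 1):
        for q in range(2, cap // p + 1):
            for xc in itertools.combinations(range(1, len(xs)), p - 1):
                bx = codes(x, xs, xc)
                for yc in itertools.combinations(range(1, len(ys)), q - 1):
                    by = codes(y, ys, yc)
                    joint = np.zeros((p, q))
                    for a, b in zip(bx, by):
                        joint[a, b] += 1
                    P = joint / n
                    px = P.sum(axis=1)
                    py = P.sum(axis=0)
                    info = 0.0
                    for i in range(p):
                        for j in range(q):
                            if P[i, j] > 0:
                                info += P[i, j] * math.log2(P[i, j] / (px[i] * py[j]))
                    best = max(best, info / math.log2(min(p, q)))
    return best


def brute_force_ksg(x, y, k):
    """Direct-counting KSG variant-1 evaluation with explicit loops."""
    from scipy.special import digamma

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    total = 0.0
    for i in range(n):
        d = [max(abs(x[i] - x[j]), abs(y[i] - y[j])) for j in range(n) if j != i]
        eps = sorted(d)[k - 1]
        nx = sum(1 for j in range(n) if j != i and abs(x[i] - x[j]) < eps)
        ny = sum(1 for j in range(n) if j != i and abs(y[i] - y[j]) < eps)
        total += digamma(nx + 1) + digamma(ny + 1)
    return float(digamma(k) + digamma(n) - total / n)


def random_stats_table(rng, ids):
    """Random DiffStatsTable-shaped frame with signed fold changes."""
    from mirtarnet import DiffStatsTable

    fc_mag = rng.uniform(1.0, 4.0, size=len(ids))
    sign = rng.choice([-1.0, 1.0], size=len(ids))
    fc = np.where(fc_mag == 1.0, 1.0, sign * fc_mag)
    table = pd.DataFrame(
        {
            "mean_g1": rng.uniform(1, 10, size=len(ids)),
            "mean_g2": rng.uniform(1, 10, size=len(ids)),
            "t": rng.normal(size=len(ids)),
            "p": rng.uniform(size=len(ids)),
            "fc": fc,
        },
        index=list(ids),
    )
    return DiffStatsTable(table)
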