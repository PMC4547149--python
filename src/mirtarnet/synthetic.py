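"""Seeded generator of miRNA-mRNA expression bundles with planted targets.

The generator emulates the down-regulation model the predictors assume:
miRNA profiles are i.i.d. lognormal, and each mRNA is a positive baseline
minus ``gamma_true`` times the expression of each miRNA that truly targets
it, plus Gaussian noise, floored at a small positive value.  In paired
two-sample mode, entities participating in true pairs additionally receive
planted group fold changes (miRNA up, mRNA down in group 2) so that
differential-expression and direction filters have signal to act on.

A candidate database covering the true pairs plus a configurable number of
decoy pairs is emitted alongside, standing in for a sequence-prediction
lookup; it is synthetic and is labelled as such wherever it is written out.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import (
    DataKind,
    EntityKind,
    ExpressionDataset,
    SequenceTargetDB,
    SequenceTargetRecord,
    write_expression_dataset,
    write_sequence_target_db,
)

EXPRESSION_FLOOR = 1e-3  # keeps fold-change ratios defined


@dataclass
class SyntheticConfig:
    n_mirna: int = 50
    n_mrna: int = 500
    n_samples: int = 20  # for paired2 mode: total samples = 2 * n_pairs
    n_pairs: int = 10
    n_true_pairs: int = 10
    gamma_true: float = 1.0
    noise_sd: float = 0.3
    mode: str = "multisample"  # or "paired2"
    decoy_candidates_per_true: int = 9
    mirna_fc: float = 2.5  # planted group-2 multiplier for true-pair miRNAs
    mrna_fc: float = 2.0  # planted group-2 divisor for true-pair mRNAs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("multisample", "paired2"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.n_true_pairs > self.n_mirna * self.n_mrna:
            raise ValueError("more true pairs than possible (miRNA x mRNA)")
        if min(self.n_mirna, self.n_mrna, self.n_true_pairs) < 1:
            raise ValueError("counts must be positive")
        if self.gamma_true <= 0 or self.noise_sd <= 0:
            raise ValueError("gamma_true and noise_sd must be positive")


@dataclass
class SyntheticBundle:
    mirna_ds: ExpressionDataset
    mrna_ds: ExpressionDataset
    true_pairs: set[tuple[str, str]]
    candidate_db: SequenceTargetDB
    config: SyntheticConfig = field(repr=False, default=None)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "mirna": outdir / "mirna_expression.tsv",
            "mrna": outdir / "mrna_expression.tsv",
            "truth": outdir / "true_pairs.tsv",
            "candidates": outdir / "synthetic_candidate_db.tsv",
        }
        write_expression_dataset(self.mirna_ds, paths["mirna"])
        write_expression_dataset(self.mrna_ds, paths["mrna"])
        with open(paths["truth"], "w") as fh:
            fh.write("mirna_id\tmrna_id\n")
            for m, g in sorted(self.true_pairs):
                fh.write(f"{m}\t{g}\n")
        write_sequence_target_db(self.candidate_db, paths["candidates"])
        return paths


def generate_synthetic(config: SyntheticConfig) -> SyntheticBundle:
    """Draw one bundle; all randomness flows from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    mirna_ids = [f"mir-{i:03d}" for i in range(config.n_mirna)]
    mrna_ids = [f"GENE{i:04d}" for i in range(config.n_mrna)]

    if config.mode == "paired2":
        n_samples = 2 * config.n_pairs
        sample_ids = [f"S{i:02d}_pre" for i in range(config.n_pairs)] + [
            f"S{i:02d}_post" for i in range(config.n_pairs)
        ]
        group_of_sample = {
            s: ("G1" if s.endswith("_pre") else "G2") for s in sample_ids
        }
        pair_of_sample = {
            f"S{i:02d}_pre": f"S{i:02d}_post" for i in range(config.n_pairs)
        }
    else:
        n_samples = config.n_samples
        sample_ids = [f"S{i:02d}" for i in range(n_samples)]
        group_of_sample = None
        pair_of_sample = None

    # choose true pairs without replacement over the product space
    flat = rng.choice(config.n_mirna * config.n_mrna, size=config.n_true_pairs, replace=False)
    true_idx = [(int(f) // config.n_mrna, int(f) % config.n_mrna) for f in flat]
    true_pairs = {(mirna_ids[i], mrna_ids[j]) for i, j in true_idx}

    if config.mode == "paired2":
        # paired samples share a per-subject expression level; pre and post
        # differ by planted fold changes plus multiplicative measurement noise
        base = rng.lognormal(mean=1.0, sigma=0.5, size=(config.n_mirna, config.n_pairs))
        meas = lambda shape: np.exp(rng.normal(0.0, 0.1, size=shape))  # noqa: E731
        Z = np.hstack([base * meas(base.shape), base * meas(base.shape)])
        g2 = np.array([s.endswith("_post") for s in sample_ids])
        for i in {i for i, _ in true_idx}:  # once per entity, even if in several pairs
            Z[i, g2] *= config.mirna_fc
    else:
        Z = rng.lognormal(mean=1.0, sigma=0.5, size=(config.n_mirna, n_samples))

    baseline = rng.lognormal(mean=2.0, sigma=0.3, size=config.n_mrna)
    X = np.tile(baseline[:, None], (1, n_samples)) + rng.normal(
        0.0, config.noise_sd, size=(config.n_mrna, n_samples)
    )
    for i, j in true_idx:
        X[j] -= config.gamma_true * Z[i]

    if config.mode == "paired2":
        for j in {j for _, j in true_idx}:
            X[j, g2] /= config.mrna_fc

    Z = np.maximum(Z, EXPRESSION_FLOOR)
    X = np.maximum(X, EXPRESSION_FLOOR)

    kind = DataKind.PAIRED2 if config.mode == "paired2" else DataKind.MULTISAMPLE
    mirna_ds = ExpressionDataset(
        entity_kind=EntityKind.MIRNA,
        data_kind=kind,
        entity_ids=mirna_ids,
        sample_ids=list(sample_ids),
        values=Z,
        group_of_sample=dict(group_of_sample) if group_of_sample else None,
        pair_of_sample=dict(pair_of_sample) if pair_of_sample else None,
    )
    mrna_ds = ExpressionDataset(
        entity_kind=EntityKind.MRNA,
        data_kind=kind,
        entity_ids=mrna_ids,
        sample_ids=list(sample_ids),
        values=X,
        group_of_sample=dict(group_of_sample) if group_of_sample else None,
        pair_of_sample=dict(pair_of_sample) if pair_of_sample else None,
    )

    # candidate database: every true pair plus decoys drawn from non-true pairs
    records = [
        SequenceTargetRecord(m, g, "human", "targetscan") for m, g in sorted(true_pairs)
    ]
    n_decoys = config.decoy_candidates_per_true * config.n_true_pairs
    taken = set(true_idx)
    decoys = []
    while len(decoys) < n_decoys:
        i = int(rng.integers(config.n_mirna))
        j = int(rng.integers(config.n_mrna))
        if (i, j) in taken:
            continue
        taken.add((i, j))
        decoys.append((i, j))
    records += [
        SequenceTargetRecord(mirna_ids[i], mrna_ids[j], "human", "targetscan")
        for i, j in sorted(decoys)
    ]
    return SyntheticBundle(
        mirna_ds=mirna_ds,
        mrna_ds=mrna_ds,
        true_pairs=true_pairs,
        candidate_db=SequenceTargetDB(records),
        config=config,
    )
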