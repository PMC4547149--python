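"""Direction filtering, threshold/top-N selection and cross-algorithm merging.

The merged product is an interaction table shaped like a published support
matrix: one row per (miRNA, mRNA) pair with a TRUE/FALSE flag per prediction
algorithm, so a pair retained by the intersection of some algorithms still
shows which of the others supported it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .assoc import ScoreTable
from .data_io import DesignError, DiffStatsTable
from .genmir import GenMiRFit

ALGORITHMS = (
    "correlation",
    "genmir",
    "mine",
    "targetscan",
    "microrna_org",
    "mutual_information",
    "mic",
)

Pair = tuple[str, str]


class DirectionOption(str, Enum):
    UP_MIR_DOWN_MRNA = "up_mir_down_mrna"
    DOWN_MIR_UP_MRNA = "down_mir_up_mrna"
    OPPOSITE = "opposite"
    ALL = "all"


@dataclass
class SelectionSpec:
    """Either a score threshold or a top-N cut, with an explicit ordering.

    ``ordering`` gives the sort direction for top-N and the accepted side for
    a threshold: ``ascending`` keeps scores <= threshold (used for
    correlation, where the most negative associations rank first),
    ``descending`` keeps scores >= threshold (mutual information, MIC,
    posterior target probability).
    """

    mode: str  # "threshold" | "top_n"
    threshold: Optional[float] = None
    n: Optional[int] = None
    ordering: str = "descending"

    def __post_init__(self) -> None:
        if self.mode not in ("threshold", "top_n"):
            raise ValueError(f"unknown selection mode {self.mode!r}")
        if self.ordering not in ("ascending", "descending"):
            raise ValueError(f"unknown ordering {self.ordering!r}")
        if self.mode == "threshold" and self.threshold is None:
            raise ValueError("threshold mode requires a threshold")
        if self.mode == "top_n" and (self.n is None or self.n < 1):
            raise ValueError("top_n mode requires a positive n")
        if (self.threshold is None) == (self.n is None):
            raise ValueError("exactly one of threshold/n must be set")


DEFAULT_ORDERING = {
    "correlation": "ascending",
    "mutual_information": "descending",
    "mic": "descending",
    "mine": "descending",
    "genmir": "descending",
}


@dataclass
class PredictionResult:
    """The selected pair set of one algorithm; sequence sources carry no score."""

    algorithm: str
    pairs: list[tuple[str, str, Optional[float]]]

    def __post_init__(self) -> None:
        keys = [(m, g) for m, g, _ in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate pair in prediction result")

    def pair_set(self) -> set[Pair]:
        return {(m, g) for m, g, _ in self.pairs}

    def score_of(self, pair: Pair) -> Optional[float]:
        for m, g, s in self.pairs:
            if (m, g) == pair:
                return s
        return None


@dataclass
class InteractionTable:
    """One row per pair with per-algorithm boolean support flags."""

    frame: pd.DataFrame  # columns: mirna_id, mrna_id, <algo flags>, optional scores/fc
    algorithms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.frame.duplicated(subset=["mirna_id", "mrna_id"]).any():
            raise ValueError("duplicate (miRNA, mRNA) row in interaction table")
        if not self.algorithms:
            self.algorithms = [c for c in self.frame.columns if c in ALGORITHMS]
        support = self.frame[self.algorithms].sum(axis=1)
        if len(self.frame) and (support < 1).any():
            raise ValueError("every interaction row needs at least one supporting algorithm")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "InteractionTable":
        df = df.copy()
        algos = [c for c in df.columns if c in ALGORITHMS]
        for c in algos:
            if df[c].dtype == object:
                df[c] = df[c].astype(str).str.upper().map({"TRUE": True, "FALSE": False})
            df[c] = df[c].astype(bool)
        return cls(frame=df, algorithms=algos)

    def pair_set(self) -> set[Pair]:
        return set(zip(self.frame["mirna_id"], self.frame["mrna_id"]))

    def mirna_ids(self) -> set[str]:
        return set(self.frame["mirna_id"])

    def mrna_ids(self) -> set[str]:
        return set(self.frame["mrna_id"])

    def support_of(self, pair: Pair) -> int:
        row = self.frame[
            (self.frame["mirna_id"] == pair[0]) & (self.frame["mrna_id"] == pair[1])
        ]
        return int(row[self.algorithms].sum(axis=1).iloc[0])

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        for c in self.algorithms:
            out[c] = out[c].map({True: "TRUE", False: "FALSE"})
        out.to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.frame)


def _fc_sign(fc: float) -> int:
    if fc > 1:
        return 1
    if fc < -1:
        return -1
    return 0  # |fc| = 1: neither up- nor down-regulated


def apply_direction_filter(
    pairs: Iterable[Pair],
    mirna_stats: Optional[DiffStatsTable],
    mrna_stats: Optional[DiffStatsTable],
    option: DirectionOption | str,
) -> set[Pair]:
    """Keep pairs whose fold-change signs match the requested direction.

    A miRNA represses its targets, so the biologically expected patterns are
    up-regulated miRNA with down-regulated mRNA and vice versa; ``OPPOSITE``
    is the union of the two and ``ALL`` keeps everything.  Pairs whose fold
    change is exactly +/-1 (no change) match no directional option.
    """
    option = DirectionOption(option)
    pairs = set(pairs)
    if option is DirectionOption.ALL:
        return pairs
    if mirna_stats is None or mrna_stats is None:
        raise DesignError("directional filtering requires both stats tables")
    known_mi = set(mirna_stats.entity_ids)
    known_mr = set(mrna_stats.entity_ids)
    missing = [p for p in pairs if p[0] not in known_mi or p[1] not in known_mr]
    if missing:
        raise DesignError(f"pairs without fold-change stats: {sorted(missing)[:5]}")

    wanted = {
        DirectionOption.UP_MIR_DOWN_MRNA: {(1, -1)},
        DirectionOption.DOWN_MIR_UP_MRNA: {(-1, 1)},
        DirectionOption.OPPOSITE: {(1, -1), (-1, 1)},
    }[option]
    return {
        (m, g)
        for m, g in pairs
        if (_fc_sign(mirna_stats.fc_of(m)), _fc_sign(mrna_stats.fc_of(g))) in wanted
    }


def select_interactions(
    scores: Union[ScoreTable, GenMiRFit],
    spec: SelectionSpec,
    algorithm: Optional[str] = None,
) -> PredictionResult:
    """Apply a threshold or top-N cut to an algorithm's score table.

    Top-N ordering is most-negative-first for correlation and highest-first
    for the other scores; ties break deterministically on (mirna_id,
    mrna_id).  N larger than the number of scored pairs keeps everything.
    """
    if isinstance(scores, GenMiRFit):
        rows = scores.beta_table()[["mirna_id", "mrna_id", "score"]]
        algorithm = algorithm or "genmir"
    else:
        rows = scores.rows
        if algorithm is None:
            if scores.method in ("pearson", "spearman"):
                algorithm = "correlation"
            elif scores.method == "mic":
                algorithm = "mine"  # the published column name for MIC support
            else:
                algorithm = scores.method
    ascending = spec.ordering == "ascending"

    if spec.mode == "threshold":
        if ascending:
            kept = rows[rows["score"] <= spec.threshold]
        else:
            kept = rows[rows["score"] >= spec.threshold]
    else:
        kept = rows.sort_values(
            ["score", "mirna_id", "mrna_id"],
            ascending=[ascending, True, True],
            kind="mergesort",
        ).head(spec.n)
    pairs = [
        (str(r.mirna_id), str(r.mrna_id), float(r.score)) for r in kept.itertuples()
    ]
    return PredictionResult(algorithm=algorithm, pairs=pairs)


def sequence_result(db, algorithm: str) -> PredictionResult:
    """Wrap a sequence-database pair list as a score-less prediction result."""
    return PredictionResult(
        algorithm=algorithm, pairs=[(m, g, None) for m, g in sorted(db.pairs())]
    )


def combine_results(
    results: Sequence[PredictionResult],
    mode: str = "intersection",
    selected: Optional[Iterable[str]] = None,
    mirna_stats: Optional[DiffStatsTable] = None,
    mrna_stats: Optional[DiffStatsTable] = None,
) -> InteractionTable:
    """Merge per-algorithm results into one support-flag table.

    ``selected`` names the algorithms whose intersection (or union) defines
    the retained pair set; the flags of every supplied algorithm are still
    recorded on each retained row.  Fold changes are attached per node when
    stats tables are given.
    """
    if mode not in ("intersection", "union"):
        raise ValueError(f"unknown combine mode {mode!r}")
    by_algo = {r.algorithm: r for r in results}
    if len(by_algo) != len(results):
        raise ValueError("duplicate algorithm in results")
    selected = list(selected) if selected is not None else list(by_algo)
    if not selected:
        raise DesignError("at least one algorithm must be selected")
    unknown = set(selected) - set(by_algo)
    if unknown:
        raise DesignError(f"selected algorithms without results: {sorted(unknown)}")

    sets = [by_algo[a].pair_set() for a in selected]
    kept = set.intersection(*sets) if mode == "intersection" else set.union(*sets)

    algorithms = [r.algorithm for r in results]
    rows = []
    for m, g in sorted(kept):
        row: dict = {"mirna_id": m, "mrna_id": g}
        for r in results:
            row[r.algorithm] = (m, g) in r.pair_set()
            score = r.score_of((m, g))
            if score is not None:
                row[f"score_{r.algorithm}"] = score
        if mirna_stats is not None and m in set(mirna_stats.entity_ids):
            row["fc_mirna"] = mirna_stats.fc_of(m)
        if mrna_stats is not None and g in set(mrna_stats.entity_ids):
            row["fc_mrna"] = mrna_stats.fc_of(g)
        rows.append(row)
    columns = ["mirna_id", "mrna_id"] + algorithms
    frame = pd.DataFrame(rows)
    if frame.empty:
        frame = pd.DataFrame(columns=columns)
    for a in algorithms:
        frame[a] = frame[a].astype(bool) if len(frame) else frame.get(a, pd.Series(dtype=bool))
    return InteractionTable(frame=frame, algorithms=algorithms)
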