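"""Readers and writers for expression matrices and sequence-target tables.

Five input dialects are supported for expression data: paired two-sample,
unpaired two-sample, statistics-only (p-value and fold change without
underlying expression), multisample, and a TCGA-style matrix whose columns
are sample barcodes.  The canonical on-disk form of every expression dialect
is a TSV whose first column holds entity ids and whose header row holds
sample ids; group membership and pairing are declared by the caller (or a
sidecar config), never inferred from the file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SPECIES_VOCABULARY = frozenset(
    {
        "human",
        "mouse",
        "rat",
        "rhesus",
        "frog",
        "dog",
        "cow",
        "chimpanzee",
        "chicken",
    }
)


class EntityKind(str, Enum):
    MIRNA = "miRNA"
    MRNA = "mRNA"


class DataKind(str, Enum):
    PAIRED2 = "paired2"
    UNPAIRED2 = "unpaired2"
    STATS_ONLY = "stats_only"
    MULTISAMPLE = "multisample"
    TCGA = "tcga"


TWO_SAMPLE_KINDS = (DataKind.PAIRED2, DataKind.UNPAIRED2)


class FormatError(ValueError):
    """The file violates the dialect grammar (bad cell, duplicate id...)."""


class DesignError(ValueError):
    """Group/pairing declaration is inconsistent with the data."""


class CapabilityError(ValueError):
    """The requested operation is undefined for this data kind."""


@dataclass
class DiffStatsTable:
    """Per-entity two-sample statistics.

    ``fc`` uses the signed ratio convention: +r means group 2 is r-fold above
    group 1, -r means r-fold below; ``|fc| >= 1`` by construction and equal
    means give +1.
    """

    table: pd.DataFrame  # index: entity id; columns: mean_g1, mean_g2, t, p, fc

    REQUIRED = ("p", "fc")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise FormatError(f"stats table missing required column {col!r}")
        p = self.table["p"].to_numpy(dtype=float)
        if np.any((p < 0) | (p > 1)):
            raise FormatError("p-values must lie in [0, 1]")
        if self.table.index.has_duplicates:
            raise FormatError("duplicate entity id in stats table")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.table.index)

    def p_of(self, entity_id: str) -> float:
        return float(self.table.at[entity_id, "p"])

    def fc_of(self, entity_id: str) -> float:
        return float(self.table.at[entity_id, "fc"])

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="id")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DiffStatsTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class ExpressionDataset:
    """An entity-by-sample expression matrix plus its design metadata."""

    entity_kind: EntityKind
    data_kind: DataKind
    entity_ids: list[str]
    sample_ids: list[str]
    values: Optional[np.ndarray] = None
    group_of_sample: Optional[dict[str, str]] = None  # sample -> "G1" | "G2"
    pair_of_sample: Optional[dict[str, str]] = None  # G1 sample -> G2 sample
    stats: Optional[DiffStatsTable] = None

    def __post_init__(self) -> None:
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise FormatError("duplicate entity id")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample id")
        if self.data_kind is DataKind.STATS_ONLY:
            if self.values is not None:
                raise DesignError("stats_only dataset must not carry a value matrix")
            if self.stats is None:
                raise DesignError("stats_only dataset requires a stats table")
        else:
            if self.values is None:
                raise DesignError(f"{self.data_kind.value} dataset requires values")
            self.values = np.asarray(self.values, dtype=float)
            if self.values.shape != (len(self.entity_ids), len(self.sample_ids)):
                raise FormatError(
                    f"value matrix shape {self.values.shape} does not match "
                    f"{len(self.entity_ids)} entities x {len(self.sample_ids)} samples"
                )
            if not np.all(np.isfinite(self.values)):
                raise FormatError("non-finite expression value")
        if self.data_kind in TWO_SAMPLE_KINDS:
            self._validate_two_sample_design()

    def _validate_two_sample_design(self) -> None:
        if not self.group_of_sample:
            raise DesignError("two-sample dataset requires a group declaration")
        missing = set(self.sample_ids) - set(self.group_of_sample)
        if missing:
            raise DesignError(f"samples without group assignment: {sorted(missing)}")
        bad = {g for g in self.group_of_sample.values() if g not in ("G1", "G2")}
        if bad:
            raise DesignError(f"unknown group labels: {sorted(bad)}")
        g1 = self.samples_in_group("G1")
        g2 = self.samples_in_group("G2")
        if self.data_kind is DataKind.PAIRED2:
            if len(g1) != len(g2):
                raise DesignError(
                    f"paired design needs equal group sizes, got {len(g1)} vs {len(g2)}"
                )
            if not self.pair_of_sample:
                raise DesignError("paired design requires a pairing declaration")
            if set(self.pair_of_sample) != set(g1) or set(
                self.pair_of_sample.values()
            ) != set(g2):
                raise DesignError("pairing must be a bijection from G1 onto G2 samples")

    def samples_in_group(self, group: str) -> list[str]:
        assert self.group_of_sample is not None
        return [s for s in self.sample_ids if self.group_of_sample[s] == group]

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def row(self, entity_id: str) -> np.ndarray:
        if self.values is None:
            raise CapabilityError("dataset carries no expression values")
        return self.values[self.entity_ids.index(entity_id)]

    def subset(self, keep_ids: Sequence[str]) -> "ExpressionDataset":
        """Restrict to the given entities, preserving original row order."""
        keep = set(keep_ids)
        idx = [i for i, e in enumerate(self.entity_ids) if e in keep]
        return ExpressionDataset(
            entity_kind=self.entity_kind,
            data_kind=self.data_kind,
            entity_ids=[self.entity_ids[i] for i in idx],
            sample_ids=list(self.sample_ids),
            values=None if self.values is None else self.values[idx],
            group_of_sample=dict(self.group_of_sample) if self.group_of_sample else None,
            pair_of_sample=dict(self.pair_of_sample) if self.pair_of_sample else None,
            stats=DiffStatsTable(self.table_rows(keep)) if self.stats is not None else None,
        )

    def table_rows(self, keep: set[str]) -> pd.DataFrame:
        assert self.stats is not None
        return self.stats.table.loc[[e for e in self.stats.entity_ids if e in keep]]

    def to_frame(self) -> pd.DataFrame:
        if self.values is None:
            raise CapabilityError("dataset carries no expression values")
        return pd.DataFrame(self.values, index=self.entity_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class SequenceTargetRecord:
    mirna_id: str
    gene_symbol: str
    species: str
    source: str  # "targetscan" | "microrna_org"
    score: Optional[float] = None  # mirSVR score for microrna_org records


@dataclass
class SequenceTargetDB:
    """Candidate miRNA-target pairs from sequence-based predictors."""

    records: list[SequenceTargetRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str, str, str]] = set()
        unique: list[SequenceTargetRecord] = []
        for r in self.records:
            key = (r.mirna_id, r.gene_symbol, r.species, r.source)
            if key in seen:
                continue
            seen.add(key)
            unique.append(r)
        self.records = unique

    def pairs(self) -> set[tuple[str, str]]:
        return {(r.mirna_id, r.gene_symbol) for r in self.records}

    def candidates_by_mrna(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for r in self.records:
            out.setdefault(r.gene_symbol, set()).add(r.mirna_id)
        return out

    def __len__(self) -> int:
        return len(self.records)


def _read_matrix_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate entity id(s): {dup}")

    def parse(cell):
        try:
            return float(cell)  # exact round-trip, unlike pandas' fast parser
        except (TypeError, ValueError):
            return None

    numeric = df.map(parse)
    mask = numeric.isna().to_numpy()
    if mask.any():
        bad = np.argwhere(mask)[0]
        raise FormatError(
            f"non-numeric cell at row {df.index[bad[0]]!r}, column {df.columns[bad[1]]!r}"
        )
    return numeric.astype(float)


def read_expression_dataset(
    path: str | Path,
    data_kind: DataKind | str,
    entity_kind: EntityKind | str,
    group_of_sample: Optional[Mapping[str, str]] = None,
    pair_of_sample: Optional[Mapping[str, str]] = None,
) -> ExpressionDataset:
    """Read one of the five expression dialects from a TSV file.

    ``group_of_sample`` / ``pair_of_sample`` carry the experimental design for
    the two-sample kinds.  The statistics-only dialect expects columns named
    ``p`` (or ``p-value``) and ``fc`` (or ``fold-change``) instead of samples.
    """
    data_kind = DataKind(data_kind)
    entity_kind = EntityKind(entity_kind)
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)

    if data_kind is DataKind.STATS_ONLY:
        df = pd.read_csv(path, sep="\t", index_col=0)
        rename = {"p-value": "p", "pvalue": "p", "fold-change": "fc", "foldchange": "fc"}
        df = df.rename(columns=lambda c: rename.get(str(c).lower(), str(c).lower()))
        for col in ("p", "fc"):
            if col not in df.columns:
                raise FormatError(f"stats_only file missing column {col!r}")
        if df.index.has_duplicates:
            raise FormatError("duplicate entity id")
        stats = DiffStatsTable(df[[c for c in ("mean_g1", "mean_g2", "t", "p", "fc") if c in df.columns]])
        ds = ExpressionDataset(
            entity_kind=entity_kind,
            data_kind=data_kind,
            entity_ids=[str(i) for i in df.index],
            sample_ids=[],
            stats=stats,
        )
        logger.info("read %d entities (stats only) from %s", ds.n_entities, path)
        return ds

    df = _read_matrix_tsv(path)
    if group_of_sample is not None:
        missing = set(group_of_sample) - set(map(str, df.columns))
        if missing:
            raise DesignError(f"declared samples absent from header: {sorted(missing)}")
    ds = ExpressionDataset(
        entity_kind=entity_kind,
        data_kind=data_kind,
        entity_ids=[str(i) for i in df.index],
        sample_ids=[str(c) for c in df.columns],
        values=df.to_numpy(),
        group_of_sample=dict(group_of_sample) if group_of_sample else None,
        pair_of_sample=dict(pair_of_sample) if pair_of_sample else None,
    )
    logger.info(
        "read %d entities x %d samples (%s) from %s",
        ds.n_entities,
        ds.n_samples,
        data_kind.value,
        path,
    )
    return ds


def write_expression_dataset(dataset: ExpressionDataset, path: str | Path) -> None:
    """Write the canonical TSV dialect (entity id column + sample header)."""
    if dataset.data_kind is DataKind.STATS_ONLY:
        assert dataset.stats is not None
        dataset.stats.to_tsv(path)
        return
    # %.17g round-trips any double bit-exactly
    dataset.to_frame().to_csv(path, sep="\t", index_label="id", float_format="%.17g")


def match_tcga_barcodes(
    mirna_ds: ExpressionDataset,
    mrna_ds: ExpressionDataset,
    prefix_length: int = 15,
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Align two TCGA-style datasets on a barcode prefix.

    Columns whose first ``prefix_length`` characters agree are treated as the
    same biological sample; unmatched columns are dropped.  Both returned
    datasets carry the truncated barcodes as sample ids, in a common order.
    """
    if prefix_length < 1:
        raise ValueError("prefix_length must be >= 1")
    mi = {s[:prefix_length]: s for s in mirna_ds.sample_ids}
    mr = {s[:prefix_length]: s for s in mrna_ds.sample_ids}
    if len(mi) != mirna_ds.n_samples or len(mr) != mrna_ds.n_samples:
        raise DesignError("barcode prefixes are not unique at the given length")
    shared = sorted(set(mi) & set(mr))
    if not shared:
        raise DesignError("no barcodes shared between the two datasets")

    def _restrict(ds: ExpressionDataset, colmap: dict[str, str]) -> ExpressionDataset:
        cols = [ds.sample_ids.index(colmap[b]) for b in shared]
        return ExpressionDataset(
            entity_kind=ds.entity_kind,
            data_kind=DataKind.TCGA,
            entity_ids=list(ds.entity_ids),
            sample_ids=list(shared),
            values=ds.values[:, cols],
        )

    return _restrict(mirna_ds, mi), _restrict(mrna_ds, mr)


_SEQ_COLUMNS = {
    "targetscan": ("mirna_id", "gene_symbol", "species"),
    "microrna_org": ("mirna_id", "gene_symbol", "species", "mirsvr_score"),
}


def read_sequence_target_db(path: str | Path, source: str) -> SequenceTargetDB:
    """Read a TargetScan-style or microRNA.org-style candidate table.

    TargetScan rows carry (miRBase id, gene symbol, species); microRNA.org
    rows additionally carry a mirSVR score.  Unknown species are kept with a
    warning.
    """
    if source not in _SEQ_COLUMNS:
        raise ValueError(f"unknown sequence source {source!r}")
    df = pd.read_csv(path, sep="\t")
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in _SEQ_COLUMNS[source]:
        if col not in df.columns:
            raise FormatError(f"{source} table missing column {col!r}")
    records = []
    for row in df.itertuples(index=False):
        species = str(getattr(row, "species"))
        if species not in SPECIES_VOCABULARY:
            logger.warning("unknown species %r in %s record; keeping", species, source)
        records.append(
            SequenceTargetRecord(
                mirna_id=str(getattr(row, "mirna_id")),
                gene_symbol=str(getattr(row, "gene_symbol")),
                species=species,
                source=source,
                score=float(getattr(row, "mirsvr_score"))
                if source == "microrna_org"
                else None,
            )
        )
    db = SequenceTargetDB(records)
    logger.info("read %d %s records from %s", len(db), source, path)
    return db


def write_sequence_target_db(db: SequenceTargetDB, path: str | Path) -> None:
    rows = [
        {
            "mirna_id": r.mirna_id,
            "gene_symbol": r.gene_symbol,
            "species": r.species,
            "source": r.source,
            "mirsvr_score": "" if r.score is None else r.score,
        }
        for r in db.records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_case_study_tables():
    """Load the packaged case-study interaction tables.

    Returns the (nonasthmatic, asthmatic) fibroblast tables: per-pair support
    flags for correlation, GenMiR++, MINE, TargetScan and microRNA.org, as
    published for airway fibroblasts exposed to obese visceral
    adipocyte-derived exosomes.
    """
    from .interactions import InteractionTable

    out = []
    for name in ("case_study_nonasthmatic.tsv", "case_study_asthmatic.tsv"):
        with resources.files("mirtarnet.data").joinpath(name).open() as fh:
            df = pd.read_csv(fh, sep="\t")
        out.append(InteractionTable.from_frame(df))
        logger.info("loaded %d case-study rows from %s", len(df), name)
    return tuple(out)
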