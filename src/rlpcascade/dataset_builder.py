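"""Training-set assembly for the three cascade stages.

Stage 1 (RLP vs NRLP) pairs kinase-truncated receptor kinases (the
receptor-like-protein architecture: ectodomain + TM + short cytoplasmic
region) against disjoint random subsets of a background negative pool —
3 negative splits x 6 feature types = 18 training sets at defaults.
Stage 2 (RLP vs RLK) pairs the same truncations against full-length
receptor kinases — 6 sets.  Stage 3 (subfamily) labels the truncations by
ectodomain subfamily and down-samples over-represented classes into 10
subsets — 60 sets.  Class imbalance inside any one set is handled by
SMOTE oversampling of the minority class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .features import DEFAULT_PROPERTY_TABLE, FEATURE_TYPES, PropertyGroupTable, featurize
from .seqio import SequenceRecord, TopologyAnnotation
from .topology import passes_rlk_dataset_filter


class DatasetError(ValueError):
    pass


# ---------------------------------------------------------------------------
# class scheme

#: The named receptor subfamily labels of the default scheme (ectodomain
#: families of plant receptor kinases); smaller subfamilies are grouped
#: under ``Other-RLP``.
PRIMARY_SUBFAMILIES = (
    "L-Lectin-RLP",
    "LRR-RLP",
    "S-domain-RLP",
    "Malectin-RLP",
    "Salt-stress-response/antifungal-RLP",
    "WAK-RLP",
    "B-Lectin-RLP",
    "Unknown-RLP",
    "PAN-RLP",
    "Ethylene-responsive-RLP",
    "Thaumatin-RLP",
    "RCC1-RLP",
    "Glycosyl-hydrolases-RLP",
    "C-Lectin-RLP",
    "GDPDL-RLP",
)

OTHER_LABEL = "Other-RLP"


@dataclass(frozen=True)
class ClassScheme:
    """Ordered subfamily labels; input subfamilies below ``min_members``
    map to the grouped remainder label."""

    labels: tuple[str, ...]
    min_members: int = 20

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise DatasetError("duplicate labels in class scheme")

    @classmethod
    def default(cls) -> "ClassScheme":
        return cls(labels=PRIMARY_SUBFAMILIES + (OTHER_LABEL,))

    @classmethod
    def from_counts(
        cls,
        subfamilies: Mapping[str, int] | pd.Series,
        min_members: int = 20,
        n_primary: int = 15,
    ) -> "ClassScheme":
        """Data-driven scheme: the ``n_primary`` largest subfamilies with at
        least ``min_members`` members become named classes, the rest group
        under the remainder label."""
        counts = pd.Series(dict(subfamilies)).sort_values(ascending=False)
        named = [
            label
            for label, n in counts.items()
            if n >= min_members and label != OTHER_LABEL
        ][:n_primary]
        return cls(labels=tuple(named) + (OTHER_LABEL,), min_members=min_members)

    def assign(self, subfamily: str) -> str:
        return subfamily if subfamily in self.labels else OTHER_LABEL


# ---------------------------------------------------------------------------
# positive-class extraction and redundancy filtering


def extract_stage1_positive(
    record: SequenceRecord, ann: TopologyAnnotation
) -> SequenceRecord:
    """Truncate a receptor kinase at its kinase domain.

    Keeps residues 1..(kinase start - 1): signal peptide, ectodomain, TM
    segment and the upstream cytoplasmic region — the receptor-like-protein
    architecture used as the cascade's positive class.
    """
    if ann.kinase_domain is None:
        raise DatasetError(f"record {record.id!r} has no kinase-domain annotation")
    if not passes_rlk_dataset_filter(ann):
        raise DatasetError(
            f"record {record.id!r} fails the SP + single-TM training filter"
        )
    if ann.kinase_domain.start <= 1:
        raise DatasetError(
            f"record {record.id!r}: kinase domain starts at position 1, "
            "truncation would be empty"
        )
    return SequenceRecord(
        id=record.id,
        residues=record.residues[: ann.kinase_domain.start - 1],
        description=record.description,
    )


def _identity(aligner: Align.PairwiseAligner, a: str, b: str) -> float:
    """Global-alignment identity: matches / alignment columns."""
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def redundancy_filter(
    records: Sequence[SequenceRecord], threshold: float = 0.85
) -> list[SequenceRecord]:
    """Greedy longest-first clustering: keep a record iff its identity to
    every previously kept record is <= ``threshold``.

    Exact global alignment (match 1, mismatch 0, gap open -10, extend -1)
    replaces word-filter approximations; ties on length break by id so the
    result is deterministic.
    """
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-10,
        extend_gap_score=-1,
    )
    ordered = sorted(records, key=lambda r: (-len(r.residues), r.id))
    kept: list[SequenceRecord] = []
    for rec in ordered:
        if all(
            _identity(aligner, rec.residues, other.residues) <= threshold
            for other in kept
        ):
            kept.append(rec)
    return kept


# ---------------------------------------------------------------------------
# training sets


@dataclass
class TrainingSet:
    """One (dataset x feature type) training table for a cascade stage."""

    stage: str  # rlp_vs_nrlp | rlp_vs_rlk | subfamily
    dataset_id: str
    feature_type: str
    X: pd.DataFrame
    y: pd.Series
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.X) != len(self.y):
            raise DatasetError("X and y lengths differ")
        overlap = set()
        if self.stage != "subfamily":
            labels = self.y.unique()
            if len(labels) == 2:
                a, b = labels
                overlap = set(self.y[self.y == a].index) & set(
                    self.y[self.y == b].index
                )
        if overlap:
            raise DatasetError(
                f"sequence ids in both classes of {self.dataset_id}: {overlap}"
            )

    @property
    def classes(self) -> list[str]:
        return sorted(self.y.unique())


def _feature_tables(
    records: Sequence[SequenceRecord],
    feature_types: Sequence[str],
    table: PropertyGroupTable,
) -> dict[str, pd.DataFrame]:
    return {ft: featurize(records, ft, table) for ft in feature_types}


def build_stage1_sets(
    positives: Sequence[SequenceRecord],
    negative_pool: Sequence[SequenceRecord],
    n_splits: int = 3,
    feature_types: Sequence[str] = FEATURE_TYPES,
    seed: int = 0,
    table: PropertyGroupTable = DEFAULT_PROPERTY_TABLE,
) -> list[TrainingSet]:
    """Pair the positives with ``n_splits`` disjoint random negative subsets.

    Yields ``n_splits * len(feature_types)`` sets (18 at defaults).  The
    negative pool must be id-disjoint from the positives.
    """
    pos_ids = {r.id for r in positives}
    clash = pos_ids & {r.id for r in negative_pool}
    if clash:
        raise DatasetError(f"ids in both positive and negative pools: {clash}")
    if not positives:
        raise DatasetError("no positive examples")
    rng = np.random.default_rng(seed)
    pool = list(negative_pool)
    rng.shuffle(pool)
    per_split = len(positives)
    if len(pool) < per_split * n_splits:
        per_split = len(pool) // n_splits
        warnings.warn(
            "negative pool smaller than positives x splits; "
            f"using {per_split} negatives per split"
        )
    splits = [
        pool[i * per_split : (i + 1) * per_split] for i in range(n_splits)
    ]
    pos_tables = _feature_tables(positives, feature_types, table)
    out = []
    for s, negs in enumerate(splits, start=1):
        neg_tables = _feature_tables(negs, feature_types, table)
        for ft in feature_types:
            X = pd.concat([pos_tables[ft], neg_tables[ft]])
            y = pd.Series(
                ["RLP"] * len(positives) + ["NRLP"] * len(negs), index=X.index
            )
            out.append(
                TrainingSet(
                    stage="rlp_vs_nrlp",
                    dataset_id=f"{ft}_{s}",
                    feature_type=ft,
                    X=X,
                    y=y,
                    provenance=list(X.index),
                )
            )
    return out


def build_stage2_set(
    positives_ecto: Sequence[SequenceRecord],
    rlk_full: Sequence[SequenceRecord],
    feature_types: Sequence[str] = FEATURE_TYPES,
    table: PropertyGroupTable = DEFAULT_PROPERTY_TABLE,
) -> list[TrainingSet]:
    """Truncated receptors (positive) vs full-length receptor kinases
    (negative); one set per feature type.

    The same source protein may appear on both sides (truncated vs full
    length), so negative ids get an ``RLK:`` prefix to keep rows distinct.
    """
    if not positives_ecto:
        raise DatasetError("no positive examples")
    if not rlk_full:
        raise DatasetError("no RLK negatives")
    rlk_renamed = [
        SequenceRecord(id=f"RLK:{r.id}", residues=r.residues) for r in rlk_full
    ]
    pos_tables = _feature_tables(positives_ecto, feature_types, table)
    neg_tables = _feature_tables(rlk_renamed, feature_types, table)
    out = []
    for ft in feature_types:
        X = pd.concat([pos_tables[ft], neg_tables[ft]])
        y = pd.Series(
            ["RLP"] * len(positives_ecto) + ["RLK"] * len(rlk_renamed),
            index=X.index,
        )
        out.append(
            TrainingSet(
                stage="rlp_vs_rlk",
                dataset_id=ft,
                feature_type=ft,
                X=X,
                y=y,
                provenance=list(X.index),
            )
        )
    return out


def build_stage3_sets(
    positives_ecto: Sequence[SequenceRecord],
    subfamily_by_id: Mapping[str, str],
    scheme: ClassScheme,
    n_subsets: int = 10,
    per_class_cap: int = 500,
    feature_types: Sequence[str] = FEATURE_TYPES,
    seed: int = 0,
    table: PropertyGroupTable = DEFAULT_PROPERTY_TABLE,
) -> list[TrainingSet]:
    """Subfamily-labelled truncations, over-represented classes independently
    down-sampled to ``per_class_cap`` in each of ``n_subsets`` subsets.

    Yields ``n_subsets * len(feature_types)`` sets (60 at defaults); classes
    at or below the cap pass through intact in every subset.
    """
    missing = [r.id for r in positives_ecto if r.id not in subfamily_by_id]
    if missing:
        raise DatasetError(f"records without subfamily labels: {missing[:5]}")
    labels = {}
    for r in positives_ecto:
        raw = subfamily_by_id[r.id]
        if raw not in scheme.labels and scheme.assign(raw) != OTHER_LABEL:
            raise DatasetError(f"label {raw!r} absent from scheme")
        labels[r.id] = scheme.assign(raw)
    tables = _feature_tables(positives_ecto, feature_types, table)
    y_all = pd.Series(labels)
    rng = np.random.default_rng(seed)
    out = []
    for s in range(1, n_subsets + 1):
        chosen: list[str] = []
        for cls in scheme.labels:
            ids = list(y_all.index[y_all == cls])
            if len(ids) > per_class_cap:
                ids = list(rng.choice(ids, size=per_class_cap, replace=False))
            chosen.extend(ids)
        for ft in feature_types:
            X = tables[ft].loc[chosen]
            out.append(
                TrainingSet(
                    stage="subfamily",
                    dataset_id=f"{ft}_{s}",
                    feature_type=ft,
                    X=X,
                    y=y_all.loc[chosen],
                    provenance=chosen,
                )
            )
    return out


# ---------------------------------------------------------------------------
# class balancing and fold assignment


def smote(
    X: np.ndarray | pd.DataFrame,
    y: Sequence,
    k: int = 5,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling.

    Every class is brought up to the majority count by interpolating
    synthetic rows ``x + u * (x_nn - x)``, ``u ~ U[0, 1)``, between a
    minority row and one of its ``k`` nearest minority neighbours
    (Euclidean).  Original rows are never modified; ``k`` is reduced to
    ``minority size - 1`` when the class is smaller than ``k + 1``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DatasetError("SMOTE needs at least two classes")
    target = counts.max()
    rng = np.random.default_rng(seed)
    X_out, y_out = [X], [y]
    for cls, count in zip(classes, counts):
        deficit = target - count
        if deficit == 0:
            continue
        if count < 2:
            raise DatasetError(
                f"class {cls!r} has a single member; SMOTE has no neighbour"
            )
        X_cls = X[y == cls]
        k_eff = min(k, count - 1)
        nn = NearestNeighbors(n_neighbors=k_eff + 1).fit(X_cls)
        neighbours = nn.kneighbors(X_cls, return_distance=False)[:, 1:]
        base_idx = rng.integers(0, count, size=deficit)
        nbr_pick = rng.integers(0, k_eff, size=deficit)
        u = rng.random(deficit)
        base = X_cls[base_idx]
        nbr = X_cls[neighbours[base_idx, nbr_pick]]
        X_out.append(base + u[:, None] * (nbr - base))
        y_out.append(np.full(deficit, cls, dtype=y.dtype))
    return np.vstack(X_out), np.concatenate(y_out)


def assign_folds(
    y: Sequence, n_folds: int = 10, seed: int = 0
) -> np.ndarray:
    """Stratified fold labels in ``0..n_folds-1``; reduced (with a warning)
    when the rarest class has fewer members than ``n_folds``."""
    y = np.asarray(y)
    _, counts = np.unique(y, return_counts=True)
    min_count = counts.min()
    if min_count < n_folds:
        n_folds = max(2, int(min_count))
        warnings.warn(
            f"rarest class has {min_count} members; reducing to {n_folds} folds"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for f, (_, val_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        folds[val_idx] = f
    return folds
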