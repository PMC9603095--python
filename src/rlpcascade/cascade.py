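"""The cascade as a fit/predict modelling object.

:class:`RLPCascade` is constructed from a labelled corpus (sequences,
topology annotations, role/subfamily labels); ``fit`` builds the 18/6/60
training sets, cross-validates the candidate algorithms on each, selects
champions and returns a :class:`CascadeResults` carrying the fitted
members, their selection metrics and the prediction machinery.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
import pandas as pd

from . import bayes_ensemble as be
from .config import CascadeConfig
from .dataset_builder import (
    ClassScheme,
    TrainingSet,
    build_stage1_sets,
    build_stage2_set,
    build_stage3_sets,
    extract_stage1_positive,
    redundancy_filter,
)
from .features import FeatureError, compute_features
from .models import MemberModel, cross_validate, metrics_table, select_champion, train_member
from .seqio import (
    REPORT_COLUMNS,
    SequenceRecord,
    TopologyAnnotation,
    read_annotations,
    read_fasta,
    write_prediction_report,
)
from .topology import passes_rlk_dataset_filter, resolve_topology

STAGES = ("rlp_vs_nrlp", "rlp_vs_rlk", "subfamily")


class CascadeError(ValueError):
    pass


def _derive_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31))


class RLPCascade:
    """Three-stage receptor-like-protein classifier, built from a corpus.

    Parameters
    ----------
    records : sequence of SequenceRecord
        All corpus sequences (receptor kinases, receptor-like proteins and
        non-receptor backgrounds).
    annotations : mapping id -> TopologyAnnotation
        Topology (and kinase-domain) annotations; receptor-kinase records
        must carry a kinase-domain interval.
    labels : DataFrame with columns id, role, subfamily
        ``role`` in {RLK, RLP, NRLP}; ``subfamily`` is the receptor
        subfamily for RLK/RLP rows (NRLP rows may carry a group name).
    """

    def __init__(
        self,
        records: Sequence[SequenceRecord],
        annotations: Mapping[str, TopologyAnnotation],
        labels: pd.DataFrame,
        config: Optional[CascadeConfig] = None,
        scheme: Optional[ClassScheme] = None,
    ) -> None:
        self.records = list(records)
        self.annotations = dict(annotations)
        self.labels = labels.reset_index(drop=True)
        self.config = config or CascadeConfig()
        missing = {"id", "role", "subfamily"} - set(self.labels.columns)
        if missing:
            raise CascadeError(f"label table missing columns {missing}")
        self._by_id = {r.id: r for r in self.records}
        if scheme is None:
            counts = (
                self.labels.loc[self.labels["role"] == "RLK", "subfamily"]
                .value_counts()
                .to_dict()
            )
            if not counts:
                raise CascadeError("corpus has no RLK-labelled records")
            scheme = ClassScheme.from_counts(
                counts, min_members=self.config.scheme_min_members
            )
        self.scheme = scheme

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_corpus(cls, corpus, config: Optional[CascadeConfig] = None,
                    scheme: Optional[ClassScheme] = None) -> "RLPCascade":
        return cls(corpus.records, corpus.annotations, corpus.labels,
                   config=config, scheme=scheme)

    @classmethod
    def from_files(
        cls,
        fasta,
        annotations_tsv,
        labels_tsv,
        config: Optional[CascadeConfig] = None,
    ) -> "RLPCascade":
        records = read_fasta(fasta)
        annotations = read_annotations(annotations_tsv)
        labels = pd.read_csv(labels_tsv, sep="\t", dtype=str)
        return cls(records, annotations, labels, config=config)

    # -- dataset assembly --------------------------------------------------

    def _positives_and_pools(self):
        cfg = self.config
        rlk_ids = self.labels.loc[self.labels["role"] == "RLK", "id"]
        positives = []
        rlk_full = []
        for seq_id in rlk_ids:
            rec = self._by_id.get(seq_id)
            ann = self.annotations.get(seq_id)
            if rec is None or ann is None or ann.kinase_domain is None:
                continue
            if not passes_rlk_dataset_filter(ann):
                continue
            positives.append(extract_stage1_positive(rec, ann))
            rlk_full.append(rec)
        if not positives:
            raise CascadeError(
                "no usable receptor-kinase positives (need kinase-domain "
                "annotations, a signal peptide and a single TM segment)"
            )
        nrlp_ids = set(self.labels.loc[self.labels["role"] == "NRLP", "id"])
        negative_pool = [r for r in self.records if r.id in nrlp_ids]
        if cfg.redundancy_filter:
            positives = redundancy_filter(positives, cfg.redundancy_threshold)
            negative_pool = redundancy_filter(
                negative_pool, cfg.redundancy_threshold
            )
            kept = {p.id for p in positives}
            rlk_full = [r for r in rlk_full if r.id in kept]
        return positives, rlk_full, negative_pool

    def build_training_sets(self, seed: int = 0) -> dict[str, list[TrainingSet]]:
        """Assemble all three stages' training sets (18/6/60 at defaults)."""
        cfg = self.config
        positives, rlk_full, negative_pool = self._positives_and_pools()
        subfamily_by_id = dict(zip(self.labels["id"], self.labels["subfamily"]))
        rng = np.random.default_rng(seed)
        stage1 = build_stage1_sets(
            positives,
            negative_pool,
            n_splits=cfg.n_negative_splits,
            feature_types=cfg.feature_types,
            seed=_derive_seed(rng),
        )
        stage2 = build_stage2_set(
            positives, rlk_full, feature_types=cfg.feature_types
        )
        stage3 = build_stage3_sets(
            positives,
            subfamily_by_id,
            self.scheme,
            n_subsets=cfg.n_subfamily_subsets,
            per_class_cap=cfg.per_class_cap,
            feature_types=cfg.feature_types,
            seed=_derive_seed(rng),
        )
        return {"rlp_vs_nrlp": stage1, "rlp_vs_rlk": stage2, "subfamily": stage3}

    # -- fitting -----------------------------------------------------------

    def _fit_stage(
        self, sets: Sequence[TrainingSet], rng: np.random.Generator,
        n_folds: int,
    ) -> tuple[list[MemberModel], list[dict]]:
        members, champion_records = [], []
        for ts in sets:
            cv_seed = _derive_seed(rng)
            records = [
                cross_validate(
                    ts,
                    alg,
                    n_folds=n_folds,
                    seed=cv_seed,
                    average=self.config.metrics_average,
                )
                for alg in self.config.algorithms
            ]
            champion = select_champion(records)
            member = train_member(
                ts,
                champion["Algorithm"],
                seed=_derive_seed(rng),
                metrics={k: v for k, v in champion.items()},
            )
            members.append(member)
            champion_records.append(champion)
        return members, champion_records

    def fit(self, seed: int = 0) -> "CascadeResults":
        """Train champions for every training set of every stage."""
        rng = np.random.default_rng(seed)
        sets = self.build_training_sets(seed=_derive_seed(rng))
        stage_members: dict[str, list[MemberModel]] = {}
        stage_records: dict[str, list[dict]] = {}
        for stage in STAGES:
            if stage == "subfamily" and any(
                pd.isna(x) for x in self.labels["subfamily"]
            ):
                raise CascadeError("subfamily labels missing for stage 3")
            members, records = self._fit_stage(
                sets[stage], rng, n_folds=self.config.selection_folds
            )
            stage_members[stage] = members
            stage_records[stage] = records
        return CascadeResults(
            config=self.config,
            scheme=self.scheme,
            stage1_members=stage_members["rlp_vs_nrlp"],
            stage2_members=stage_members["rlp_vs_rlk"],
            stage3_members=stage_members["subfamily"],
            selection_metrics={
                stage: metrics_table(records)
                for stage, records in stage_records.items()
            },
            seed=seed,
        )

    def crossval(self, seed: int = 0, n_folds: Optional[int] = None) -> dict:
        """Per-set champion metrics under the full cross-validation protocol
        (10-fold by default); one table per stage."""
        if n_folds is None:
            n_folds = self.config.crossval_folds
        rng = np.random.default_rng(seed)
        sets = self.build_training_sets(seed=_derive_seed(rng))
        tables = {}
        for stage in STAGES:
            records = []
            for ts in sets[stage]:
                cv_seed = _derive_seed(rng)
                candidates = [
                    cross_validate(
                        ts,
                        alg,
                        n_folds=n_folds,
                        seed=cv_seed,
                        average=self.config.metrics_average,
                    )
                    for alg in self.config.algorithms
                ]
                records.append(select_champion(candidates))
            tables[stage] = metrics_table(records)
        return tables


@dataclass
class CascadeResults:
    """Fitted cascade: champion members per stage plus prediction logic."""

    config: CascadeConfig
    scheme: ClassScheme
    stage1_members: list[MemberModel]
    stage2_members: list[MemberModel]
    stage3_members: list[MemberModel]
    selection_metrics: dict[str, pd.DataFrame] = field(default_factory=dict)
    seed: int = 0

    # -- prediction --------------------------------------------------------

    def _feature_vectors(self, record: SequenceRecord) -> dict[str, np.ndarray]:
        needed = {
            m.feature_type
            for m in (
                self.stage1_members + self.stage2_members + self.stage3_members
            )
        }
        return {
            ft: compute_features(record.residues, ft) for ft in sorted(needed)
        }

    def predict_record(
        self,
        record: SequenceRecord,
        annotation: Optional[TopologyAnnotation] = None,
    ) -> dict:
        """Classify one sequence; returns a prediction-report row dict."""
        cfg = self.config
        ann = resolve_topology(record, annotation, cfg.topology)
        sp = ann.sp
        tm = bool(ann.tm_segments)
        try:
            vectors = self._feature_vectors(record)
        except FeatureError as exc:
            warnings.warn(
                f"record {record.id!r} failed featurization ({exc}); "
                "reporting NRLP"
            )
            return self._degenerate_row(record.id, sp, tm)
        votes1 = be.stage_vote(self.stage1_members, vectors, "RLP")
        post1 = be.beta_binomial_posterior(
            votes1, cfg.bayes_alpha0, cfg.bayes_beta0
        )
        votes2 = be.stage_vote(self.stage2_members, vectors, "RLP")
        post2 = be.beta_binomial_posterior(
            votes2, cfg.bayes_alpha0, cfg.bayes_beta0
        )
        counts = be.subfamily_vote(self.stage3_members, vectors, self.scheme)
        post3 = be.dirichlet_multinomial_posterior(
            counts,
            classes=self.scheme.labels,
            alpha0=[cfg.dirichlet_alpha0] * len(self.scheme.labels),
        )
        decision = be.decide(
            sp,
            tm,
            post1.mean,
            post2.mean,
            post3,
            cutoffs=cfg.cutoffs,
            weights=cfg.decision_weights,
            prior=cfg.decision_prior,
        )
        if decision.classification == "NRLP":
            classification = "NRLP"
        elif decision.classification == "Undefined":
            classification = "(Undefined)"
        else:
            classification = f"({decision.classification})"
        subfam_pass = post3.map_probability >= cfg.cutoff_c3
        return {
            "Accession": record.id,
            "SP": "Y" if sp else "N",
            "TM": "Y" if tm else "N",
            "RLP-NRLP": "RLP" if post1.mean >= cfg.cutoff_c1 else "NRLP",
            "RLP-NRLP Probability": post1.mean,
            "RLP-RLK": "RLP" if post2.mean >= cfg.cutoff_c2 else "RLK-like",
            "RLP-RLK Probability": post2.mean,
            "RLP-Subfamily": post3.map_label if subfam_pass else "Undefined",
            "RLP-Subfamily Probability": post3.map_probability,
            "Classification": classification,
            "Decision Probability": decision.decision_probability,
        }

    def _degenerate_row(self, seq_id: str, sp: bool, tm: bool) -> dict:
        cfg = self.config
        a0, b0 = cfg.decision_prior
        w = np.asarray(cfg.decision_weights, dtype=float)
        bits = np.array([int(sp), int(tm), 0, 0, 0])
        a = a0 + float(w @ bits)
        b = b0 + float(w @ (1 - bits))
        k = len(self.scheme.labels)
        prior_mean = cfg.bayes_alpha0 / (cfg.bayes_alpha0 + cfg.bayes_beta0)
        return {
            "Accession": seq_id,
            "SP": "Y" if sp else "N",
            "TM": "Y" if tm else "N",
            "RLP-NRLP": "NRLP",
            "RLP-NRLP Probability": prior_mean,
            "RLP-RLK": "RLK-like",
            "RLP-RLK Probability": prior_mean,
            "RLP-Subfamily": "Undefined",
            "RLP-Subfamily Probability": 1.0 / k,
            "Classification": "NRLP",
            "Decision Probability": a / (a + b),
        }

    def predict(
        self,
        records: Sequence[SequenceRecord],
        annotations: Optional[Mapping[str, TopologyAnnotation]] = None,
    ) -> pd.DataFrame:
        """Prediction report: one row per input sequence, input order."""
        annotations = annotations or {}
        rows = [
            self.predict_record(rec, annotations.get(rec.id)) for rec in records
        ]
        return pd.DataFrame(rows, columns=REPORT_COLUMNS)

    def predict_to_report(
        self,
        records: Sequence[SequenceRecord],
        path,
        annotations: Optional[Mapping[str, TopologyAnnotation]] = None,
    ) -> pd.DataFrame:
        report = self.predict(records, annotations)
        write_prediction_report(report.to_dict("records"), path)
        return report

    # -- reporting ---------------------------------------------------------

    @property
    def members(self) -> list[MemberModel]:
        return self.stage1_members + self.stage2_members + self.stage3_members

    def summary(self) -> str:
        lines = [
            "RLP cascade fit",
            "===============",
            f"subfamily scheme: {len(self.scheme.labels)} classes "
            f"({len(self.scheme.labels) - 1} named + grouped remainder)",
            f"seed: {self.seed}",
            "",
            f"{'stage':<14} {'members':>7} {'mean MCC':>9} {'mean ACC':>9}",
        ]
        stage_names = {
            "rlp_vs_nrlp": self.stage1_members,
            "rlp_vs_rlk": self.stage2_members,
            "subfamily": self.stage3_members,
        }
        for stage, members in stage_names.items():
            mcc = np.mean([m.metrics["MCC"] for m in members if m.metrics])
            acc = np.mean([m.metrics["ACC"] for m in members if m.metrics])
            lines.append(
                f"{stage:<14} {len(members):>7d} {mcc:>9.3f} {acc:>9.3f}"
            )
        lines.append("")
        algos = pd.Series([m.algorithm_id for m in self.members]).value_counts()
        lines.append(
            "champions by algorithm: "
            + ", ".join(f"{a} x{n}" for a, n in algos.items())
        )
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, bundle_dir) -> None:
        """Write the model bundle: JSON manifest + serialized members."""
        bundle = Path(bundle_dir)
        bundle.mkdir(parents=True, exist_ok=True)
        manifest = {
            "seed": self.seed,
            "scheme": {
                "labels": list(self.scheme.labels),
                "min_members": self.scheme.min_members,
            },
            "config": {
                "feature_types": list(self.config.feature_types),
                "algorithms": list(self.config.algorithms),
                "cutoffs": self.config.cutoffs,
            },
            "members": [m.manifest() for m in self.members],
        }
        with open(bundle / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        for stage, table in self.selection_metrics.items():
            table.to_csv(
                bundle / f"metrics_{stage}.tsv", sep="\t", index=False
            )
        joblib.dump(self, bundle / "cascade.joblib")

    @classmethod
    def load(cls, bundle_dir) -> "CascadeResults":
        results = joblib.load(Path(bundle_dir) / "cascade.joblib")
        if not isinstance(results, cls):
            raise CascadeError("bundle does not contain a fitted cascade")
        return results
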