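"""Synthetic labelled corpora with receptor-like architectures.

The generator emulates the sequence anatomy the cascade assumes:

* RLK-like: signal peptide + subfamily-specific ectodomain + one TM helix
  + juxtamembrane linker + kinase-domain tail (a fixed synthetic consensus
  with per-copy substitutions);
* RLP-like: the same minus the kinase tail (short cytoplasmic tail);
* NRLP backgrounds: globular (no SP/TM), secreted (SP only), polytopic
  (three TM helices), and uniform-random decoys.

Subfamily signal is carried by ectodomain residue composition plus an
implanted consensus motif, mirroring the premise that ectodomains
distinguish receptor subfamilies.  Everything is a pure function of
(parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset_builder import ClassScheme
from .seqio import (
    CANONICAL_ALPHABET,
    Interval,
    SequenceRecord,
    TopologyAnnotation,
)

_ALPHABET = np.array(list(CANONICAL_ALPHABET))

#: Typical globular-protein residue frequencies (rounded; renormalised).
_BACKGROUND = {
    "A": 0.083, "C": 0.014, "D": 0.055, "E": 0.067, "F": 0.039,
    "G": 0.071, "H": 0.023, "I": 0.059, "K": 0.058, "L": 0.097,
    "M": 0.024, "N": 0.040, "P": 0.047, "Q": 0.039, "R": 0.055,
    "S": 0.066, "T": 0.053, "V": 0.069, "W": 0.011, "X": 0.0,
    "Y": 0.029,
}
BACKGROUND_DISTRIBUTION = np.array(
    [_BACKGROUND[a] for a in CANONICAL_ALPHABET], dtype=float
)
BACKGROUND_DISTRIBUTION /= BACKGROUND_DISTRIBUTION.sum()

_HYDROPHOBIC = np.array(list("LIVFA"))
_HYDROPHOBIC_W = np.array([0.45, 0.2, 0.2, 0.1, 0.05])
_LOOP_POOL = np.array(list("KRSTNQED"))

#: Fixed synthetic kinase-domain consensus (250 aa).  Not a real kinase
#: profile — its contractual role is only to make the kinase-bearing and
#: kinase-free architectures distinguishable and the truncation rule
#: exercisable.
_KINASE_RNG = np.random.default_rng(20_220_913)
KINASE_CONSENSUS = "".join(
    _KINASE_RNG.choice(_ALPHABET, size=250, p=BACKGROUND_DISTRIBUTION)
)


@dataclass(frozen=True)
class FamilyProfile:
    """Residue distribution + consensus motif defining one subfamily."""

    name: str
    distribution: np.ndarray  # 20-vector over CANONICAL_ALPHABET, sums to 1
    motif: Optional[str] = None
    motif_sub_rate: float = 0.1
    length_range: tuple[int, int] = (120, 300)

    def __post_init__(self) -> None:
        dist = np.asarray(self.distribution, dtype=float)
        if dist.shape != (20,) or abs(dist.sum() - 1.0) > 1e-9:
            raise ValueError("distribution must be a 20-vector summing to 1")
        lo, hi = self.length_range
        if lo > hi:
            raise ValueError("length_range min > max")


def sample_sequence(profile: FamilyProfile, rng: np.random.Generator) -> str:
    """Draw one ectodomain-style sequence from a family profile."""
    lo, hi = profile.length_range
    length = int(rng.integers(lo, hi + 1))
    residues = rng.choice(_ALPHABET, size=length, p=profile.distribution)
    if profile.motif and length >= len(profile.motif):
        pos = int(rng.integers(0, length - len(profile.motif) + 1))
        for i, m in enumerate(profile.motif):
            if rng.random() < profile.motif_sub_rate:
                residues[pos + i] = rng.choice(_ALPHABET)
            else:
                residues[pos + i] = m
    return "".join(residues)


def _sp_block(rng: np.random.Generator) -> str:
    """Signal peptide: n-region (M + charged) + h-region + small cleavage zone."""
    h_len = int(rng.integers(12, 19))
    h = rng.choice(_HYDROPHOBIC, size=h_len, p=_HYDROPHOBIC_W)
    return "MK" + "".join(h) + "ASA"


def _tm_block(rng: np.random.Generator, length: int = 21) -> str:
    return "".join(rng.choice(_HYDROPHOBIC, size=length, p=_HYDROPHOBIC_W))


def _loop(rng: np.random.Generator, lo: int, hi: int) -> str:
    return "".join(rng.choice(_LOOP_POOL, size=int(rng.integers(lo, hi + 1))))


def _background(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return "".join(rng.choice(_ALPHABET, size=length, p=BACKGROUND_DISTRIBUTION))


def _mutated_kinase(rng: np.random.Generator, sub_rate: float = 0.1) -> str:
    out = list(KINASE_CONSENSUS)
    for i in range(len(out)):
        if rng.random() < sub_rate:
            out[i] = str(rng.choice(_ALPHABET))
    return "".join(out)


def build_rlk(
    profile: FamilyProfile, rng: np.random.Generator, seq_id: str = "rlk"
) -> tuple[SequenceRecord, TopologyAnnotation]:
    """One receptor-kinase-like sequence with its true topology annotation."""
    sp = _sp_block(rng)
    ecto = sample_sequence(profile, rng)
    tm = _tm_block(rng)
    juxta = _loop(rng, 10, 30)
    kinase = _mutated_kinase(rng)
    residues = sp + ecto + tm + juxta + kinase
    tm_start = len(sp) + len(ecto) + 1
    kin_start = len(sp) + len(ecto) + len(tm) + len(juxta) + 1
    ann = TopologyAnnotation(
        sp=True,
        sp_cleavage=len(sp),
        tm_segments=[Interval(tm_start, tm_start + len(tm) - 1)],
        kinase_domain=Interval(kin_start, len(residues)),
        source="external",
    )
    return SequenceRecord(id=seq_id, residues=residues), ann


def build_rlp(
    profile: FamilyProfile, rng: np.random.Generator, seq_id: str = "rlp"
) -> tuple[SequenceRecord, TopologyAnnotation]:
    """One receptor-like-protein sequence: RLK anatomy minus the kinase tail."""
    sp = _sp_block(rng)
    ecto = sample_sequence(profile, rng)
    tm = _tm_block(rng)
    tail = _loop(rng, 5, 30)
    residues = sp + ecto + tm + tail
    tm_start = len(sp) + len(ecto) + 1
    ann = TopologyAnnotation(
        sp=True,
        sp_cleavage=len(sp),
        tm_segments=[Interval(tm_start, tm_start + len(tm) - 1)],
        kinase_domain=None,
        source="external",
    )
    return SequenceRecord(id=seq_id, residues=residues), ann


def build_globular(rng: np.random.Generator, seq_id: str):
    rec = SequenceRecord(id=seq_id, residues=_background(rng, 150, 500))
    return rec, TopologyAnnotation(sp=False, source="external")


def build_secreted(rng: np.random.Generator, seq_id: str):
    sp = _sp_block(rng)
    rec = SequenceRecord(id=seq_id, residues=sp + _background(rng, 150, 400))
    return rec, TopologyAnnotation(sp=True, sp_cleavage=len(sp), source="external")


def build_polytopic(rng: np.random.Generator, seq_id: str):
    parts = [_loop(rng, 20, 60)]
    tms = []
    pos = len(parts[0])
    for _ in range(3):
        tm = _tm_block(rng)
        tms.append(Interval(pos + 1, pos + len(tm)))
        loop = _loop(rng, 20, 60)
        parts.extend([tm, loop])
        pos += len(tm) + len(loop)
    rec = SequenceRecord(id=seq_id, residues="".join(parts))
    return rec, TopologyAnnotation(sp=False, tm_segments=tms, source="external")


def build_decoy(
    rng: np.random.Generator,
    seq_id: str,
    length_range: tuple[int, int] = (200, 600),
):
    """Uniform-random amino acid sequence (the negative-control decoy)."""
    length = int(rng.integers(length_range[0], length_range[1] + 1))
    rec = SequenceRecord(
        id=seq_id, residues="".join(rng.choice(_ALPHABET, size=length))
    )
    return rec, TopologyAnnotation(sp=False, source="external")


def sample_decoys(
    n: int, rng: np.random.Generator, length_range: tuple[int, int] = (200, 600)
) -> list[SequenceRecord]:
    return [build_decoy(rng, f"decoy_{i:04d}", length_range)[0] for i in range(n)]


def default_profiles(scheme: Optional[ClassScheme] = None) -> list[FamilyProfile]:
    """One profile per scheme label: a distinct enriched signature residue
    (30% frequency) and a 5-residue consensus motif; signature sets are
    disjoint across subfamilies so classes are separable by composition."""
    if scheme is None:
        scheme = ClassScheme.default()
    profiles = []
    for i, label in enumerate(scheme.labels):
        signature = CANONICAL_ALPHABET[i % 20]
        dist = np.full(20, 0.70 / 19)
        dist[CANONICAL_ALPHABET.index(signature)] = 0.30
        motif = signature * 4 + CANONICAL_ALPHABET[(i + 7) % 20]
        profiles.append(
            FamilyProfile(name=label, distribution=dist, motif=motif)
        )
    return profiles


NRLP_GROUPS = ("globular", "secreted", "polytopic", "decoy")
_NRLP_BUILDERS = {
    "globular": build_globular,
    "secreted": build_secreted,
    "polytopic": build_polytopic,
    "decoy": build_decoy,
}


@dataclass
class Corpus:
    """A labelled synthetic corpus: sequences, true topologies, labels.

    ``labels`` columns: id, role (RLK/RLP/NRLP), subfamily (receptor
    subfamily, or the NRLP group name).
    """

    records: list[SequenceRecord]
    annotations: dict[str, TopologyAnnotation]
    labels: pd.DataFrame

    def by_role(self, role: str) -> list[SequenceRecord]:
        wanted = set(self.labels.loc[self.labels["role"] == role, "id"])
        return [r for r in self.records if r.id in wanted]

    def subfamily_of(self) -> dict[str, str]:
        return dict(zip(self.labels["id"], self.labels["subfamily"]))


def build_benchmark(
    n_per_class: int = 24,
    scheme: Optional[ClassScheme] = None,
    seed: int = 0,
    n_nrlp_per_group: Optional[int] = None,
    profiles: Optional[Sequence[FamilyProfile]] = None,
) -> Corpus:
    """Generate the default labelled corpus.

    Per subfamily: ``n_per_class`` RLK-like and ``n_per_class`` RLP-like
    sequences.  The four NRLP groups are sized (by default) so the pool
    supports three disjoint stage-1 negative splits against the RLK-derived
    positives.
    """
    if n_per_class < 10:
        raise ValueError("n_per_class must be >= 10")
    if scheme is None:
        scheme = ClassScheme.default()
    if profiles is None:
        profiles = default_profiles(scheme)
    if n_nrlp_per_group is None:
        n_positives = n_per_class * len(scheme.labels)
        n_nrlp_per_group = -(-3 * n_positives // len(NRLP_GROUPS))  # ceil
    rng = np.random.default_rng(seed)
    records: list[SequenceRecord] = []
    annotations: dict[str, TopologyAnnotation] = {}
    rows = []
    for profile in profiles:
        tag = profile.name.replace("/", "_")
        for i in range(n_per_class):
            rec, ann = build_rlk(profile, rng, seq_id=f"RLK_{tag}_{i:03d}")
            records.append(rec)
            annotations[rec.id] = ann
            rows.append({"id": rec.id, "role": "RLK", "subfamily": profile.name})
        for i in range(n_per_class):
            rec, ann = build_rlp(profile, rng, seq_id=f"RLP_{tag}_{i:03d}")
            records.append(rec)
            annotations[rec.id] = ann
            rows.append({"id": rec.id, "role": "RLP", "subfamily": profile.name})
    for group in NRLP_GROUPS:
        builder = _NRLP_BUILDERS[group]
        for i in range(n_nrlp_per_group):
            rec, ann = builder(rng, f"NRLP_{group}_{i:04d}")
            records.append(rec)
            annotations[rec.id] = ann
            rows.append({"id": rec.id, "role": "NRLP", "subfamily": group})
    return Corpus(
        records=records, annotations=annotations, labels=pd.DataFrame(rows)
    )


def write_corpus(corpus: Corpus, fasta, annotations_tsv, labels_tsv) -> None:
    from .seqio import write_annotations, write_fasta

    write_fasta(corpus.records, fasta)
    write_annotations(corpus.annotations, annotations_tsv)
    corpus.labels.to_csv(labels_tsv, sep="\t", index=False)
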