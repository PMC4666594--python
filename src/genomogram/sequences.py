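"""Sequence and mutation-table I/O, mutation application, synthetic datasets.

This module handles the data plumbing around the classification pipeline:
reading and writing FASTA files, applying COSMIC-style point mutations
(single-base substitutions and small deletions) to reference coding
sequences, generating a fully synthetic labelled dataset that mimics the
class structure of a curated somatic-mutation corpus (one normal class plus
gene x mutation-type classes), and stratified 70/15/15 splitting.

Coordinates in :class:`MutationRecord` are 1-based inclusive, the convention
COSMIC and HGVS users expect; all internal indexing is 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = "ACGT"

__all__ = [
    "DnaSequence",
    "MutationRecord",
    "LabeledDataset",
    "GeneProfile",
    "SimulationConfig",
    "read_fasta",
    "write_fasta",
    "read_mutation_table",
    "write_mutation_table",
    "apply_mutation",
    "simulate_dataset",
    "split_dataset",
    "default_gene_profiles",
    "default_class_counts",
]


class SequenceError(ValueError):
    """Raised for malformed sequences or stale mutation coordinates."""


@dataclass(frozen=True)
class DnaSequence:
    """A validated DNA sequence over {A, C, G, T} with an optional class label."""

    id: str
    bases: str
    label: str | None = None

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        if len(bases) == 0:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        for offset, ch in enumerate(bases, start=1):
            if ch not in ALPHABET:
                raise SequenceError(
                    f"record {self.id!r}: invalid character {ch!r} at offset {offset}"
                )
        object.__setattr__(self, "bases", bases)

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def n(self) -> int:
        return len(self.bases)

    def with_label(self, label: str) -> "DnaSequence":
        return replace(self, label=label)


@dataclass(frozen=True)
class MutationRecord:
    """A single somatic mutation: substitution or deletion, 1-based position."""

    gene_id: str
    kind: str  # "substitution" | "deletion"
    position: int  # 1-based inclusive
    ref: str = ""
    alt: str = ""
    del_length: int = 1

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise SequenceError("substitution requires single-base ref and alt")
            if self.ref == self.alt:
                raise SequenceError("substitution ref and alt must differ")
        elif self.kind == "deletion":
            if self.alt:
                raise SequenceError("deletion must have empty alt")
            if self.del_length < 1:
                raise SequenceError("deletion length must be >= 1")
        else:
            raise SequenceError(f"unknown mutation kind {self.kind!r}")
        if self.position < 1:
            raise SequenceError("position is 1-based and must be >= 1")

    @property
    def descriptor(self) -> str:
        if self.kind == "substitution":
            return f"{self.position}{self.ref}>{self.alt}"
        return f"{self.position}del{self.del_length}"


@dataclass
class LabeledDataset:
    """An ordered collection of labelled sequences with a fixed class list."""

    samples: list[DnaSequence]
    class_names: list[str]

    def __post_init__(self) -> None:
        known = set(self.class_names)
        for s in self.samples:
            if s.label not in known:
                raise ValueError(f"sample {s.id!r} has unknown label {s.label!r}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def counts(self) -> dict[str, int]:
        out = {c: 0 for c in self.class_names}
        for s in self.samples:
            out[s.label] += 1
        return out

    def subset(self, indices: Iterable[int]) -> "LabeledDataset":
        return LabeledDataset([self.samples[i] for i in indices], list(self.class_names))


# ---------------------------------------------------------------------------
# FASTA and table I/O


def read_fasta(path: str | Path) -> list[DnaSequence]:
    """Read a multi-record FASTA file into validated :class:`DnaSequence` objects.

    Ambiguity codes (including N) are rejected: the downstream indicator
    encoding is defined only over the four unambiguous bases. The error names
    the offending record and 1-based offset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return [DnaSequence(id=r.id, bases=str(r.seq)) for r in records]


def write_fasta(seqs: Sequence[DnaSequence], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Biopython wraps at 60; kept for API symmetry


MUTATION_COLUMNS = ["gene_id", "kind", "position", "ref", "alt", "del_length"]


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read a TSV mutation table (columns: gene_id kind position ref alt del_length)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in MUTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"mutation table missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            MutationRecord(
                gene_id=row.gene_id,
                kind=row.kind,
                position=int(row.position),
                ref=row.ref,
                alt=row.alt,
                del_length=int(row.del_length) if row.del_length else 1,
            )
        )
    return out


def write_mutation_table(records: Sequence[MutationRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (m.gene_id, m.kind, m.position, m.ref, m.alt, m.del_length)
            for m in records
        ],
        columns=MUTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Mutation mechanics


def apply_mutation(seq: DnaSequence, m: MutationRecord) -> DnaSequence:
    """Apply one mutation to a sequence, returning a new sequence.

    Substitutions check the reference allele at the stated position and fail
    loudly on mismatch (the usual symptom of stale coordinates); deletions
    remove ``del_length`` bases starting at ``position`` and must not overrun
    the sequence end.
    """
    i = m.position - 1
    if not (0 <= i < seq.n):
        raise SequenceError(
            f"position {m.position} out of range for {seq.id!r} (N={seq.n})"
        )
    if m.kind == "substitution":
        if seq.bases[i] != m.ref:
            raise SequenceError(
                f"ref mismatch at {seq.id!r}:{m.position}: "
                f"expected {m.ref!r}, found {seq.bases[i]!r}"
            )
        bases = seq.bases[:i] + m.alt + seq.bases[i + 1 :]
    else:
        if i + m.del_length > seq.n:
            raise SequenceError(
                f"deletion {m.descriptor} overruns end of {seq.id!r} (N={seq.n})"
            )
        bases = seq.bases[:i] + seq.bases[i + m.del_length :]
    return DnaSequence(id=f"{seq.id}|{m.descriptor}", bases=bases, label=seq.label)


# ---------------------------------------------------------------------------
# Synthetic dataset generation


@dataclass(frozen=True)
class GeneProfile:
    """A synthetic reference gene: length and base-composition probabilities."""

    name: str
    length: int
    base_probs: tuple[float, float, float, float]  # order A, C, G, T

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("gene length must be positive")
        p = np.asarray(self.base_probs, dtype=float)
        if p.shape != (4,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
            raise ValueError("base_probs must be 4 nonnegative values summing to 1")


# Gene lengths follow the coding-sequence lengths of the ten most frequently
# mutated lung-cancer biomarker genes; compositions are spread so GC content
# ranges over [0.3, 0.7], making the genes separable by texture, as real
# biomarker genes are by their distinct power spectra.
_GENE_LENGTHS = {
    "TP53": 1182,
    "EGFR": 3633,
    "KRAS": 567,
    "KMT2C": 14736,
    "CDKN2A": 471,
    "NF1": 8457,
    "STK11": 1302,
    "KMT2D": 16614,
    "ZNF521": 3936,
    "SMARCA4": 4944,
}


def default_gene_profiles() -> list[GeneProfile]:
    names = list(_GENE_LENGTHS)
    gcs = np.linspace(0.3, 0.7, len(names))
    profiles = []
    for k, (name, gc) in enumerate(zip(names, gcs)):
        at = 1.0 - gc
        # alternate the within-pair skew so neighbouring GC levels still differ
        skew = 0.6 if k % 2 == 0 else 0.4
        probs = (at * skew, gc * (1 - skew), gc * skew, at * (1 - skew))
        profiles.append(GeneProfile(name, _GENE_LENGTHS[name], probs))
    return profiles


NORMAL_CLASS = "Normal"

# Per-class unique sample counts of the emulated mutation corpus (total 534).
_DEFAULT_CLASS_COUNTS: dict[str, int] = {
    NORMAL_CLASS: 100,
    "TP53 Deletion": 32,
    "TP53 Substitution": 35,
    "EGFR Deletion": 35,
    "EGFR Substitution": 27,
    "KRAS Substitution": 28,
    "KMT2C Substitution": 35,
    "NF1 Substitution": 35,
    "CDKN2A Substitution": 35,
    "STK11 Deletion": 32,
    "STK11 Substitution": 35,
    "KMT2D Substitution": 35,
    "ZNF521 Substitution": 35,
    "SMARCA4 Substitution": 35,
}


def default_class_counts() -> dict[str, int]:
    return dict(_DEFAULT_CLASS_COUNTS)


@dataclass
class SimulationConfig:
    """Settings for the synthetic mutation-dataset generator."""

    genes: list[GeneProfile] = field(default_factory=default_gene_profiles)
    class_counts: dict[str, int] = field(default_factory=default_class_counts)
    deletion_length_range: tuple[int, int] = (1, 20)

    def __post_init__(self) -> None:
        gene_names = {g.name for g in self.genes}
        lo, hi = self.deletion_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid deletion length range")
        shortest = min(g.length for g in self.genes)
        if hi >= shortest:
            raise ValueError("deletion range exceeds shortest gene")
        for cls, count in self.class_counts.items():
            if count < 1:
                raise ValueError(f"class {cls!r} has sample count < 1")
            if cls == NORMAL_CLASS:
                continue
            gene, _, kind = cls.rpartition(" ")
            if gene not in gene_names:
                raise ValueError(f"class {cls!r} references unknown gene {gene!r}")
            if kind.lower() not in ("substitution", "deletion"):
                raise ValueError(f"class {cls!r} has unknown mutation kind")


def _random_reference(profile: GeneProfile, rng: np.random.Generator) -> DnaSequence:
    idx = rng.choice(4, size=profile.length, p=profile.base_probs)
    bases = "".join(ALPHABET[i] for i in idx)
    return DnaSequence(id=profile.name, bases=bases)


def simulate_dataset(
    config: SimulationConfig | None = None, seed: int = 0
) -> LabeledDataset:
    """Generate a labelled synthetic dataset emulating a somatic-mutation corpus.

    Each reference gene is drawn once from its composition profile. Every
    mutated sample is its reference carrying exactly one mutation event at a
    seeded-random position; the normal class consists of unmutated copies of
    the references, cycled so 100 normal samples over 10 genes yields exact
    duplicates (mirroring curated normal records, which repeat the same
    reference coding sequences). Reproducible bit-for-bit for a given seed.
    """
    if config is None:
        config = SimulationConfig()
    rng = np.random.default_rng(seed)
    references = {g.name: _random_reference(g, rng) for g in config.genes}
    gene_order = [g.name for g in config.genes]

    samples: list[DnaSequence] = []
    class_names = list(config.class_counts)
    for cls in class_names:
        count = config.class_counts[cls]
        if cls == NORMAL_CLASS:
            for k in range(count):
                ref = references[gene_order[k % len(gene_order)]]
                samples.append(
                    DnaSequence(id=f"{ref.id}|normal{k}", bases=ref.bases, label=cls)
                )
            continue
        gene, _, kind = cls.rpartition(" ")
        kind = kind.lower()
        ref = references[gene]
        lo, hi = config.deletion_length_range
        for k in range(count):
            if kind == "substitution":
                pos = int(rng.integers(1, ref.n + 1))
                old = ref.bases[pos - 1]
                alt = rng.choice([b for b in ALPHABET if b != old])
                m = MutationRecord(gene, "substitution", pos, ref=old, alt=str(alt))
            else:
                length = int(rng.integers(lo, hi + 1))
                pos = int(rng.integers(1, ref.n - length + 2))
                m = MutationRecord(gene, "deletion", pos, del_length=length)
            mutated = apply_mutation(ref, m)
            samples.append(
                DnaSequence(id=f"{mutated.id}|s{k}", bases=mutated.bases, label=cls)
            )
    return LabeledDataset(samples, class_names)


# ---------------------------------------------------------------------------
# Stratified splitting


def split_dataset(
    ds: LabeledDataset,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Stratified train/validation/test split.

    Within each class, the validation and test partitions each receive
    ``floor(fraction * class_size)`` samples and the remainder goes to
    training; class members are shuffled with the seed before assignment.
    Partitions are disjoint and their union is the input dataset.
    """
    f_train, f_val, f_test = fractions
    if not np.isclose(f_train + f_val + f_test, 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    val_idx: list[int] = []
    test_idx: list[int] = []
    for cls in ds.class_names:
        members = [i for i, s in enumerate(ds.samples) if s.label == cls]
        if not members:
            continue
        n = len(members)
        n_val = int(np.floor(f_val * n))
        n_test = int(np.floor(f_test * n))
        if n_val == 0 or n_test == 0:
            warnings.warn(
                f"class {cls!r} too small to appear in all partitions; "
                "remainder assigned to train",
                stacklevel=2,
            )
        order = rng.permutation(n)
        shuffled = [members[j] for j in order]
        val_idx.extend(shuffled[:n_val])
        test_idx.extend(shuffled[n_val : n_val + n_test])
        train_idx.extend(shuffled[n_val + n_test :])
    return ds.subset(train_idx), ds.subset(val_idx), ds.subset(test_idx)
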