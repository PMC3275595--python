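"""Labelled 20-mer peptide datasets and the cleaning pipeline.

Benchmark-style epitope datasets are collections of fixed-length (20
residue) peptides labelled epitope (1) or non-epitope (0).  Cleaning
follows the conventional protocol: exact-duplicate removal (first
occurrence kept), removal of sequences with non-standard symbols or wrong
length, and random down-sampling of the majority negative class to a
balanced set.  No homology reduction is applied — sequences sharing less
than 100% identity are all retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .scales import STANDARD_RESIDUES

PEPTIDE_LENGTH = 20
_RESIDUE_SET = frozenset(STANDARD_RESIDUES)


class InvalidPeptideError(ValueError):
    """Raised when a sequence violates the fixed-length standard-residue contract."""


def validate_peptide(sequence: str, length: int = PEPTIDE_LENGTH) -> str:
    """Uppercase and validate a peptide; returns the canonical sequence."""
    seq = sequence.strip().upper()
    if len(seq) != length:
        raise InvalidPeptideError(f"expected a {length}-mer, got length {len(seq)}: {seq!r}")
    bad = set(seq) - _RESIDUE_SET
    if bad:
        raise InvalidPeptideError(f"non-standard residues {sorted(bad)} in {seq!r}")
    return seq


@dataclass(frozen=True)
class PeptideRecord:
    """A labelled fixed-length peptide. ``label`` is 1 (epitope) or 0 (non-epitope)."""

    sequence: str
    label: int
    source: str = ""

    def is_valid(self, length: int = PEPTIDE_LENGTH) -> bool:
        return len(self.sequence) == length and set(self.sequence) <= _RESIDUE_SET


@dataclass
class Dataset:
    """A named collection of :class:`PeptideRecord`."""

    records: list[PeptideRecord]
    name: str = "dataset"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PeptideRecord]:
        return iter(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def labels(self) -> np.ndarray:
        return np.array([r.label for r in self.records], dtype=np.int64)

    @property
    def n_positive(self) -> int:
        return sum(1 for r in self.records if r.label == 1)

    @property
    def n_negative(self) -> int:
        return sum(1 for r in self.records if r.label == 0)

    def subset(self, label: int) -> "Dataset":
        return Dataset([r for r in self.records if r.label == label],
                       name=f"{self.name}/{'epitope' if label == 1 else 'non-epitope'}")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sequence": self.sequences,
                "label": [r.label for r in self.records],
                "source": [r.source for r in self.records],
            }
        )


@dataclass
class CleaningReport:
    """Per-stage record counts emitted by the cleaning operations."""

    n_input: int = 0
    n_output: int = 0
    n_duplicates_removed: int = 0
    n_invalid_symbol: int = 0
    n_wrong_length: int = 0
    n_label_conflicts: int = 0
    n_negatives_removed: int = 0
    stages: list[str] = field(default_factory=list)


def deduplicate(
    records: Sequence[PeptideRecord], report: CleaningReport | None = None
) -> list[PeptideRecord]:
    """Drop later records whose sequence is 100% identical to an earlier one.

    Deduplication is label-blind: if the same sequence appears with both
    labels, the first occurrence wins and the conflict is warned about.
    """
    seen: dict[str, int] = {}
    kept: list[PeptideRecord] = []
    conflicts = 0
    for rec in records:
        if rec.sequence in seen:
            if rec.label != seen[rec.sequence]:
                conflicts += 1
            continue
        seen[rec.sequence] = rec.label
        kept.append(rec)
    if conflicts:
        warnings.warn(
            f"{conflicts} duplicate sequence(s) carried conflicting labels; "
            "first occurrence kept",
            stacklevel=2,
        )
    if report is not None:
        report.n_duplicates_removed += len(records) - len(kept)
        report.n_label_conflicts += conflicts
        report.stages.append(f"deduplicate: {len(records)} -> {len(kept)}")
    return kept


def filter_valid(
    records: Sequence[PeptideRecord],
    length: int = PEPTIDE_LENGTH,
    report: CleaningReport | None = None,
) -> list[PeptideRecord]:
    """Remove records whose sequence has the wrong length or non-standard symbols."""
    kept: list[PeptideRecord] = []
    n_len = n_sym = 0
    for rec in records:
        seq = rec.sequence.strip().upper()
        if len(seq) != length:
            n_len += 1
            continue
        if not set(seq) <= _RESIDUE_SET:
            n_sym += 1
            continue
        kept.append(replace(rec, sequence=seq))
    if report is not None:
        report.n_wrong_length += n_len
        report.n_invalid_symbol += n_sym
        report.stages.append(f"filter_valid: {len(records)} -> {len(kept)}")
    return kept


def balance(
    records: Sequence[PeptideRecord],
    seed: int,
    name: str = "dataset",
    report: CleaningReport | None = None,
) -> Dataset:
    """Randomly remove negatives until positive and negative counts are equal.

    The benchmark situation has at least as many negatives as positives;
    the converse raises, since randomly discarding scarce positives is
    never what the protocol intends.
    """
    pos = [r for r in records if r.label == 1]
    neg = [r for r in records if r.label == 0]
    if len(pos) > len(neg):
        raise ValueError(
            f"more positives ({len(pos)}) than negatives ({len(neg)}); "
            "balancing removes negatives only"
        )
    rng = np.random.default_rng(seed)
    keep_idx = set(rng.choice(len(neg), size=len(pos), replace=False).tolist())
    kept_neg = [r for i, r in enumerate(neg) if i in keep_idx]
    out = pos + kept_neg
    # preserve the original record order
    order = {id(r): i for i, r in enumerate(records)}
    out.sort(key=lambda r: order[id(r)])
    if report is not None:
        report.n_negatives_removed += len(neg) - len(kept_neg)
        report.stages.append(f"balance: {len(records)} -> {len(out)}")
    return Dataset(out, name=name)


def merge(datasets: Sequence[Dataset], name: str = "combo") -> Dataset:
    """Concatenate datasets and drop exact-sequence duplicates across them.

    The caller is expected to re-balance afterwards, since deduplication
    can leave the classes unequal.
    """
    if not datasets:
        raise ValueError("merge requires at least one dataset")
    records: list[PeptideRecord] = []
    for ds in datasets:
        records.extend(ds.records)
    return Dataset(deduplicate(records), name=name)


def clean(
    records: Sequence[PeptideRecord], seed: int, name: str = "dataset"
) -> tuple[Dataset, CleaningReport]:
    """Full pipeline: deduplicate -> filter invalid -> balance classes."""
    report = CleaningReport(n_input=len(records))
    out = deduplicate(records, report)
    out = filter_valid(out, report=report)
    ds = balance(out, seed=seed, name=name, report=report)
    report.n_output = len(ds)
    return ds, report


# ---------------------------------------------------------------------------
# I/O


def read_tsv(path: str | Path, name: str | None = None) -> Dataset:
    """Read a two-column TSV (sequence <TAB> label in {0,1}); '#' lines skipped."""
    path = Path(path)
    records: list[PeptideRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'sequence<TAB>label'")
            if parts[0].lower() == "sequence":  # header row
                continue
            label = int(parts[1])
            if label not in (0, 1):
                raise ValueError(f"{path}:{lineno}: label must be 0 or 1, got {parts[1]}")
            records.append(PeptideRecord(parts[0].upper(), label, source=path.stem))
    return Dataset(records, name=name or path.stem)


def write_tsv(dataset: Dataset, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sequence\tlabel\n")
        for rec in dataset.records:
            fh.write(f"{rec.sequence}\t{rec.label}\n")


def read_fasta(path: str | Path, name: str | None = None) -> Dataset:
    """Read peptides from FASTA; labels from an 'epitope'/'non-epitope' header token."""
    from Bio import SeqIO

    path = Path(path)
    records: list[PeptideRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description.lower()
        if "non-epitope" in desc or "non_epitope" in desc or "nonepitope" in desc:
            label = 0
        elif "epitope" in desc:
            label = 1
        else:
            raise ValueError(
                f"FASTA header {rec.description!r} carries no epitope/non-epitope token"
            )
        records.append(PeptideRecord(str(rec.seq).upper(), label, source=path.stem))
    return Dataset(records, name=name or path.stem)


def write_fasta(dataset: Dataset, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for i, rec in enumerate(dataset.records):
            tag = "epitope" if rec.label == 1 else "non-epitope"
            fh.write(f">{dataset.name}_{i} {tag}\n{rec.sequence}\n")


def load_dataset(path: str | Path, name: str | None = None) -> Dataset:
    """Dispatch on file extension: .fa/.fasta -> FASTA, anything else -> TSV."""
    suffix = Path(path).suffix.lower()
    if suffix in (".fa", ".fasta", ".faa"):
        return read_fasta(path, name=name)
    return read_tsv(path, name=name)
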