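"""Peptide data model, I/O, window scanning and dataset-assembly rules.

CD4 T-cell epitope mapping studies test overlapping peptides (typically
15-mers) spanning an antigen.  This module provides the containers for
those peptides and their immunogenicity labels, plus the assembly rules
used to build training sets from raw assay outcomes: negative selection,
deconstruction of long epitopes into component 15-mers, 9-mer redundancy
filtering between training and evaluation data, and common-motif-aware
cross-validation fold assignment (peptides sharing a 9-mer are never
split across folds).
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard amino acids, alphabetical by one-letter code.
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
#: Alphabet including the unknown-residue placeholder.
AA_ALPHABET_X = AA_ALPHABET + "X"

_VALID_CHARS = frozenset(AA_ALPHABET_X)


class PeptideError(ValueError):
    """Raised when a sequence violates the peptide alphabet or length rules."""


def _validate_sequence(sequence: str) -> str:
    if not isinstance(sequence, str) or len(sequence) == 0:
        raise PeptideError("peptide sequence must be a non-empty string")
    seq = sequence.upper()
    bad = set(seq) - _VALID_CHARS
    if bad:
        raise PeptideError(
            f"sequence {sequence!r} contains non-amino-acid characters: {sorted(bad)}"
        )
    return seq


@dataclass(frozen=True)
class Peptide:
    """An amino-acid peptide, optionally anchored to its source protein.

    Parameters
    ----------
    sequence : str
        Uppercase amino-acid sequence over ``ACDEFGHIKLMNPQRSTVWY`` plus
        ``X`` for unknown residues.
    source_id : str, optional
        Identifier of the source protein/antigen.
    offset : int, optional
        0-based start position within the source protein.
    """

    sequence: str
    source_id: str | None = None
    offset: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _validate_sequence(self.sequence))
        if self.offset is not None and self.offset < 0:
            raise PeptideError("offset must be non-negative")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_unknown(self) -> bool:
        """True if the sequence contains the unknown residue ``X``."""
        return "X" in self.sequence


@dataclass(frozen=True)
class LabeledPeptide:
    """A peptide with a binary immunogenicity label (1 = epitope)."""

    peptide: Peptide
    label: int
    study_id: str = ""

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise PeptideError(f"label must be 0 or 1, got {self.label!r}")

    @property
    def sequence(self) -> str:
        return self.peptide.sequence


@dataclass(frozen=True)
class AssayRecord:
    """One (peptide, donor, test) outcome from a screening assay."""

    peptide: Peptide
    donor_id: str
    outcome: int
    protein_id: str

    def __post_init__(self) -> None:
        if self.outcome not in (0, 1):
            raise PeptideError(f"outcome must be 0 or 1, got {self.outcome!r}")


@dataclass
class FoldAssignment:
    """Mapping from peptide sequence to cross-validation fold index."""

    folds: dict[str, int]
    n_folds: int

    def __getitem__(self, sequence: str) -> int:
        return self.folds[sequence]

    def fold_sizes(self) -> list[int]:
        sizes = [0] * self.n_folds
        for f in self.folds.values():
            sizes[f] += 1
        return sizes


# ---------------------------------------------------------------------------
# Window scanning


def scan_overlapping_kmers(
    protein: str, k: int = 15, step: int = 5, source_id: str | None = None
) -> list[Peptide]:
    """Scan a protein into overlapping k-mer windows.

    Windows start at offsets ``0, step, 2*step, ...`` and must fit entirely
    within the protein.  The default ``k=15, step=5`` reproduces 15-mers
    overlapping by 10 residues, the tiling used to build tetramer-derived
    negative sets.
    """
    if k < 1 or step < 1:
        raise PeptideError("k and step must be >= 1")
    seq = _validate_sequence(protein)
    return [
        Peptide(seq[o : o + k], source_id=source_id, offset=o)
        for o in range(0, len(seq) - k + 1, step)
    ]


def deconstruct_long_epitope(epitope: Peptide | str, k: int = 15, step: int = 1) -> list[Peptide]:
    """Dissect an epitope of length >= k into its component k-mers.

    Long epitopes reported in mapping studies are broken into the
    composing 15-mers so they are comparable with 15-mer screens; each
    component inherits the parent's label downstream.  Default step is 1
    (maximal coverage).
    """
    seq = epitope.sequence if isinstance(epitope, Peptide) else _validate_sequence(epitope)
    src = epitope.source_id if isinstance(epitope, Peptide) else None
    if len(seq) < k:
        raise PeptideError(f"epitope of length {len(seq)} cannot be dissected into {k}-mers")
    return scan_overlapping_kmers(seq, k=k, step=step, source_id=src)


def build_tetramer_negatives(positive: Peptide | str, source_protein: str) -> list[LabeledPeptide]:
    """Build the negative set for one tetramer-confirmed positive 15-mer.

    The source protein is scanned into 15-mers overlapping by 10 residues
    (step 5); every scanned window whose *sequence* equals the positive is
    excluded, and the remaining windows are returned with label 0.
    """
    pos_seq = positive.sequence if isinstance(positive, Peptide) else _validate_sequence(positive)
    if len(pos_seq) != 15:
        raise PeptideError("tetramer positives must be 15-mers")
    windows = scan_overlapping_kmers(source_protein, k=15, step=5)
    return [
        LabeledPeptide(p, 0, study_id="tetramer")
        for p in windows
        if p.sequence != pos_seq
    ]


# ---------------------------------------------------------------------------
# Negative selection from assay records


def select_negatives(records: Sequence[AssayRecord]) -> list[LabeledPeptide]:
    """Select negative peptides from raw assay outcomes.

    A peptide qualifies as a negative control only if

    1. every assay of the peptide is negative,
    2. its source protein has at least one peptide positive in at least
       one assay (so lack of recognition is not explained by the protein
       being absent from presentation), and
    3. no (peptide, donor) pair gave contradictory outcomes — such
       peptides are dropped from the dataset entirely.
    """
    by_pep: dict[str, list[AssayRecord]] = defaultdict(list)
    for r in records:
        by_pep[r.peptide.sequence].append(r)

    # rule (iii): contradictory (peptide, donor) outcomes
    contradictory: set[str] = set()
    for seq, recs in by_pep.items():
        donor_outcomes: dict[str, set[int]] = defaultdict(set)
        for r in recs:
            donor_outcomes[r.donor_id].add(r.outcome)
        if any(len(v) > 1 for v in donor_outcomes.values()):
            contradictory.add(seq)

    proteins_with_positive = {
        r.protein_id
        for r in records
        if r.outcome == 1 and r.peptide.sequence not in contradictory
    }

    negatives: list[LabeledPeptide] = []
    seen: set[str] = set()
    for seq, recs in by_pep.items():
        if seq in contradictory or seq in seen:
            continue
        if any(r.outcome == 1 for r in recs):
            continue
        if not any(r.protein_id in proteins_with_positive for r in recs):
            continue
        seen.add(seq)
        negatives.append(LabeledPeptide(recs[0].peptide, 0))
    return negatives


# ---------------------------------------------------------------------------
# k-mer redundancy


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shares_common_kmer(a: str, b: str, k: int = 9) -> bool:
    """True iff some length-k substring of ``a`` occurs within ``b``."""
    if k < 1:
        raise PeptideError("k must be >= 1")
    if len(a) < k or len(b) < k:
        return False
    return not _kmers(a, k).isdisjoint(_kmers(b, k))


def remove_cross_redundancy(
    train: Sequence[LabeledPeptide],
    eval_set: Sequence[LabeledPeptide],
    k: int = 9,
) -> list[LabeledPeptide]:
    """Drop training peptides sharing any k-mer with an evaluation peptide.

    Training/validation redundancy inflates cross-study performance
    estimates; the filter removes every training peptide that shares a
    common 9-mer (by default) with any evaluation peptide.  The
    evaluation set is untouched.  Idempotent.
    """
    eval_kmers: set[str] = set()
    for lp in eval_set:
        eval_kmers |= _kmers(lp.sequence, k)
    return [lp for lp in train if _kmers(lp.sequence, k).isdisjoint(eval_kmers)]


def cluster_and_assign_folds(
    peptides: Sequence[LabeledPeptide],
    k: int = 9,
    n_folds: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    """Assign peptides to CV folds such that 9-mer-sharing peptides co-fold.

    Peptides sharing a common k-mer are connected; connected components
    are assigned whole to folds by greedy bin packing (largest component
    first into the currently smallest fold).  Components of equal size
    are shuffled with the seed; the assignment is otherwise deterministic.
    """
    if n_folds < 2:
        raise PeptideError("n_folds must be >= 2")
    seqs = sorted({lp.sequence for lp in peptides})
    index = {s: i for i, s in enumerate(seqs)}

    # union-find over peptides sharing any k-mer
    parent = list(range(len(seqs)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    kmer_owner: dict[str, int] = {}
    for s in seqs:
        i = index[s]
        for km in _kmers(s, k):
            if km in kmer_owner:
                union(kmer_owner[km], i)
            else:
                kmer_owner[km] = i

    components: dict[int, list[int]] = defaultdict(list)
    for i in range(len(seqs)):
        components[find(i)].append(i)
    comp_list = sorted(components.values(), key=lambda c: (-len(c), min(c)))

    if n_folds > len(comp_list):
        warnings.warn(
            f"{n_folds} folds requested but only {len(comp_list)} "
            "redundancy components exist; some folds will be empty",
            stacklevel=2,
        )

    # shuffle within equal-size groups only
    rng = np.random.default_rng(seed)
    shuffled: list[list[int]] = []
    i = 0
    while i < len(comp_list):
        j = i
        while j < len(comp_list) and len(comp_list[j]) == len(comp_list[i]):
            j += 1
        group = comp_list[i:j]
        rng.shuffle(group)
        shuffled.extend(group)
        i = j

    fold_sizes = [0] * n_folds
    assignment: dict[str, int] = {}
    for comp in shuffled:
        f = int(np.argmin(fold_sizes))
        fold_sizes[f] += len(comp)
        for idx in comp:
            assignment[seqs[idx]] = f
    return FoldAssignment(folds=assignment, n_folds=n_folds)


# ---------------------------------------------------------------------------
# I/O


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences from FASTA into an ordered {id: sequence} dict."""
    return {
        rec.id: _validate_sequence(str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_labeled_tsv(path: str | Path) -> list[LabeledPeptide]:
    """Read a labeled-peptide TSV (columns: peptide, label, study_id[, protein_id, offset])."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "study_id": str})
    required = {"peptide", "label"}
    missing = required - set(df.columns)
    if missing:
        raise PeptideError(f"{path}: missing required columns {sorted(missing)}")
    out: list[LabeledPeptide] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            pep = Peptide(
                row.peptide,
                source_id=str(getattr(row, "protein_id", "")) or None
                if "protein_id" in df.columns
                else None,
                offset=int(row.offset)
                if "offset" in df.columns and not pd.isna(getattr(row, "offset"))
                else None,
            )
            out.append(
                LabeledPeptide(
                    pep,
                    int(row.label),
                    study_id=str(row.study_id) if "study_id" in df.columns else "",
                )
            )
        except (PeptideError, ValueError) as exc:
            raise PeptideError(f"{path}: line {i}: {exc}") from exc
    return out


def write_labeled_tsv(peptides: Iterable[LabeledPeptide], path: str | Path) -> None:
    rows = [
        {
            "peptide": lp.sequence,
            "label": lp.label,
            "study_id": lp.study_id,
            "protein_id": lp.peptide.source_id or "",
            "offset": "" if lp.peptide.offset is None else lp.peptide.offset,
        }
        for lp in peptides
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_assay_tsv(path: str | Path) -> list[AssayRecord]:
    """Read assay outcomes (columns: peptide, donor_id, outcome, protein_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "donor_id": str, "protein_id": str})
    missing = {"peptide", "donor_id", "outcome", "protein_id"} - set(df.columns)
    if missing:
        raise PeptideError(f"{path}: missing required columns {sorted(missing)}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(
                AssayRecord(
                    Peptide(row.peptide, source_id=row.protein_id),
                    donor_id=row.donor_id,
                    outcome=int(row.outcome),
                    protein_id=row.protein_id,
                )
            )
        except (PeptideError, ValueError) as exc:
            raise PeptideError(f"{path}: line {i}: {exc}") from exc
    return out
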