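"""Synthetic labeled-peptide and HLA-percentile generators.

The generators emulate the structure of CD4 epitope screening data so
every pipeline stage is testable offline: immunogenic 15-mers carry a
planted 9-residue recognition core drawn from a position-weight matrix
(by default enriching positively charged residues R/K and depleting
D/E, the charge signature that distinguishes real epitopes from
non-recognized peptides), non-recognized peptides are pure background,
and per-peptide HLA percentile ranks are drawn with a calibrated,
independent correlation to the labels so the two scoring channels can
be combined meaningfully.

Everything is deterministic under a master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .evaluation import StudySet
from .peptides import AA_ALPHABET, LabeledPeptide, Peptide

#: SwissProt-like background amino-acid frequencies (alphabetical order).
SWISSPROT_FREQS = np.array(
    [
        0.0826, 0.0137, 0.0546, 0.0672, 0.0386, 0.0708, 0.0227, 0.0593,
        0.0581, 0.0965, 0.0241, 0.0406, 0.0472, 0.0393, 0.0553, 0.0665,
        0.0535, 0.0687, 0.0110, 0.0292,
    ]
)
SWISSPROT_FREQS = SWISSPROT_FREQS / SWISSPROT_FREQS.sum()

UNIFORM_FREQS = np.full(20, 1.0 / 20.0)

_AA = np.array(list(AA_ALPHABET))
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


@dataclass
class MotifModel:
    """Planted recognition motif: a PWM plus a mixing strength lambda.

    Each core position is drawn from the PWM column with probability
    ``strength`` and from the background otherwise; strength 0 is pure
    background, strength 1 a full PWM draw.
    """

    pwm: np.ndarray  # (core_length, 20), rows sum to 1
    strength: float = 0.9

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 20:
            raise ValueError("PWM must have shape (core_length, 20)")
        if not np.allclose(self.pwm.sum(axis=1), 1.0):
            raise ValueError("PWM rows must sum to 1")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must lie in [0, 1]")

    @property
    def core_length(self) -> int:
        return int(self.pwm.shape[0])


def default_motif_model(strength: float = 0.9) -> MotifModel:
    """9-mer recognition core with the charge signature of real epitopes.

    Anchor-like positions concentrate on hydrophobic residues (F/I/L at
    the core start, mirroring a P1-style anchor), central and
    C-terminal positions favour R/K, and D/E probability is suppressed
    everywhere.
    """
    preferred = ["F", "I", "L", "N", "K", "V", "R", "K", "R"]
    secondary = ["L", "V", "M", "Q", "R", "I", "K", "R", "K"]
    pwm = np.full((9, 20), 1.0, dtype=float)
    for row, (p1, p2) in enumerate(zip(preferred, secondary)):
        pwm[row, _AA_INDEX[p1]] = 40.0
        pwm[row, _AA_INDEX[p2]] = 12.0
        pwm[row, _AA_INDEX["D"]] = 0.2
        pwm[row, _AA_INDEX["E"]] = 0.2
    pwm /= pwm.sum(axis=1, keepdims=True)
    return MotifModel(pwm=pwm, strength=strength)


def generate_background_peptide(
    length: int = 15,
    aa_freqs: np.ndarray | None = None,
    rng: np.random.Generator | None = None,
) -> Peptide:
    """Draw a peptide with i.i.d. residues from the background distribution."""
    freqs = UNIFORM_FREQS if aa_freqs is None else np.asarray(aa_freqs, dtype=float)
    if freqs.shape != (20,) or not np.isclose(freqs.sum(), 1.0) or (freqs < 0).any():
        raise ValueError("aa_freqs must be a length-20 probability vector")
    rng = rng or np.random.default_rng()
    return Peptide("".join(rng.choice(_AA, size=length, p=freqs)))


def _sample_core(motif: MotifModel, freqs: np.ndarray, rng: np.random.Generator) -> str:
    chars = []
    for row in range(motif.core_length):
        p = motif.pwm[row] if rng.random() < motif.strength else freqs
        chars.append(rng.choice(_AA, p=p))
    return "".join(chars)


def generate_labeled_dataset(
    n_pos: int,
    n_neg: int,
    motif: MotifModel | None = None,
    seed: int = 0,
    length: int = 15,
    aa_freqs: np.ndarray | None = None,
    study_id: str = "synthetic",
) -> list[LabeledPeptide]:
    """Labeled 15-mer set with a planted core in the positives.

    Positives embed a PWM-sampled core at a uniformly random offset
    within a background peptide; negatives are pure background.
    Deterministic for a fixed seed.
    """
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    motif = motif or default_motif_model()
    if motif.core_length > length:
        raise ValueError("motif core longer than the peptide")
    freqs = UNIFORM_FREQS if aa_freqs is None else np.asarray(aa_freqs, dtype=float)
    rng = np.random.default_rng(seed)
    out: list[LabeledPeptide] = []
    for _ in range(n_pos):
        base = list(generate_background_peptide(length, freqs, rng).sequence)
        off = int(rng.integers(0, length - motif.core_length + 1))
        core = _sample_core(motif, freqs, rng)
        base[off : off + motif.core_length] = core
        out.append(LabeledPeptide(Peptide("".join(base)), 1, study_id=study_id))
    for _ in range(n_neg):
        out.append(
            LabeledPeptide(generate_background_peptide(length, freqs, rng), 0, study_id=study_id)
        )
    return out


def generate_hla_scores(
    labels: Sequence[int],
    target_auc: float = 0.7,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Per-peptide HLA percentile ranks with a calibrated label correlation.

    Latent binding scores are binormal: negatives ~ N(0, 1), positives
    shifted *lower* by delta where ``AUC = Phi(delta / sqrt(2))``, then
    mapped through the pooled empirical CDF onto [0, 100] so positives
    land at low percentiles (lower = stronger predicted binding).
    """
    if not 0.5 <= target_auc < 1.0:
        raise ValueError("target_auc must lie in [0.5, 1)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    y = np.asarray(labels)
    delta = norm.ppf(target_auc) * np.sqrt(2.0)
    latent = rng.normal(0.0, 1.0, y.size)
    latent[y == 1] -= delta
    # pooled empirical CDF -> percentile in [0, 100]
    ranks = latent.argsort().argsort().astype(float)
    return 100.0 * ranks / max(y.size - 1, 1)


@dataclass
class SyntheticStudy:
    """One synthetic validation study with peptides, labels and HLA scores."""

    study_id: str
    peptides: list[LabeledPeptide]
    hla_scores: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def to_study_set(self) -> StudySet:
        return StudySet(
            self.study_id,
            positives=[lp.sequence for lp in self.peptides if lp.label == 1],
            negatives=[lp.sequence for lp in self.peptides if lp.label == 0],
        )


def generate_study_collection(
    n_studies: int = 57,
    pos_range: tuple[int, int] = (2, 28),
    neg_range: tuple[int, int] = (2, 60),
    motif: MotifModel | None = None,
    hla_target_auc: float = 0.7,
    seed: int = 0,
    aa_freqs: np.ndarray | None = None,
) -> list[SyntheticStudy]:
    """Independent synthetic validation studies (stand-in for literature sets).

    Study sizes are drawn uniformly from the given ranges, which default
    to the spread seen in real overlapping-peptide validation studies
    (a handful to a few dozen epitopes, up to dozens of negatives).
    Per-study seeds derive from the master seed.
    """
    if n_studies < 2:
        raise ValueError("n_studies must be >= 2")
    motif = motif or default_motif_model(strength=0.5)
    master = np.random.SeedSequence(seed)
    studies = []
    for i, child in enumerate(master.spawn(n_studies)):
        state = child.generate_state(2)
        rng = np.random.default_rng(child)
        n_pos = int(rng.integers(pos_range[0], pos_range[1] + 1))
        n_neg = int(rng.integers(neg_range[0], neg_range[1] + 1))
        data = generate_labeled_dataset(
            n_pos,
            n_neg,
            motif=motif,
            seed=int(state[0] % (2**31)),
            aa_freqs=aa_freqs,
            study_id=f"study{i + 1:03d}",
        )
        # de-duplicate sequences within a study (labels must be unambiguous)
        seen: dict[str, LabeledPeptide] = {}
        for lp in data:
            seen.setdefault(lp.sequence, lp)
        data = list(seen.values())
        labels = [lp.label for lp in data]
        hla = generate_hla_scores(
            labels, target_auc=hla_target_auc, rng=np.random.default_rng(int(state[1] % (2**31)))
        )
        studies.append(
            SyntheticStudy(
                study_id=f"study{i + 1:03d}",
                peptides=data,
                hla_scores={lp.sequence: float(h) for lp, h in zip(data, hla)},
                seed=int(state[0] % (2**31)),
            )
        )
    return studies


def write_fixture_manifest(path: str | Path, **params) -> None:
    """Record generator parameters and seeds alongside emitted fixtures."""
    Path(path).write_text(json.dumps(params, indent=1, sort_keys=True, default=str))
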