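"""Motif-alignment neural network for CD4 T-cell immunogenicity.

A single-hidden-layer network (5 hidden neurons, sigmoid activations)
scores every length-L window ("core") of a peptide and takes the
maximum: the network simultaneously learns *where* the informative motif
sits in each peptide and *what* it looks like.  Training targets are 1.0
for immunogenic and 0.0 for non-recognized peptides, and each SGD
presentation backpropagates through the currently best-scoring core.

Ensembles average networks trained from multiple random seeds, with both
a sparse (one-hot) and a BLOSUM50-based residue encoding, across the
folds of a common-motif-aware cross-validation (peptides sharing a 9-mer
never straddle a train/test split).  The ensemble mean output in (0, 1)
is the raw immunogenicity score; higher means more immunogenic.

The scikit-learn estimator façade is :class:`MotifAlignClassifier`;
:func:`train_network`, :func:`cross_validate` and
:func:`motif_length_scan` are the underlying primitives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import evaluation
from ._kernels import train_sgd
from .peptides import (
    AA_ALPHABET,
    FoldAssignment,
    LabeledPeptide,
    PeptideError,
    cluster_and_assign_folds,
)

SCHEMES = ("sparse", "blosum")
N_HIDDEN = 5  # fixed architecture: one hidden layer of 5 sigmoid units
_BLOSUM_SCALE = 5.0

_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


def _build_tables() -> dict[str, np.ndarray]:
    """Per-residue encoding rows, indexed by AA_ALPHABET order; X -> zeros."""
    sparse = np.zeros((21, 20))
    sparse[:20] = np.eye(20)
    blosum = np.zeros((21, 20))
    mat = substitution_matrices.load("BLOSUM50")
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            blosum[i, j] = mat[a, b] / _BLOSUM_SCALE
    return {"sparse": sparse, "blosum": blosum}


_TABLES = _build_tables()


def _residue_indices(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(c, 20) for c in seq], dtype=np.int64)


def encode_core(core: str, scheme: str = "sparse") -> np.ndarray:
    """Encode a motif core as the concatenation of per-residue vectors.

    ``sparse`` is one-hot; ``blosum`` is the residue's BLOSUM50 row
    divided by 5.  Unknown residues (X) encode as all-zero blocks.
    """
    if scheme not in _TABLES:
        raise ValueError(f"unknown encoding scheme {scheme!r}")
    table = _TABLES[scheme]
    return table[_residue_indices(core)].ravel()


def encode_offsets(seq: str, L: int, scheme: str) -> np.ndarray:
    """All length-L core encodings of a peptide, shape (len-L+1, 20*L)."""
    if len(seq) < L:
        raise PeptideError(f"peptide of length {len(seq)} shorter than motif length {L}")
    rows = _TABLES[scheme][_residue_indices(seq)]
    n_off = len(seq) - L + 1
    return np.stack([rows[o : o + L].ravel() for o in range(n_off)])


def _encode_dataset(
    seqs: Sequence[str], L: int, scheme: str
) -> tuple[np.ndarray, np.ndarray]:
    """Padded (n, max_off, 20L) core tensor plus per-peptide offset counts."""
    n_off = np.array([len(s) - L + 1 for s in seqs], dtype=np.int64)
    if (n_off < 1).any():
        raise PeptideError(f"all peptides must be at least {L} residues long")
    X = np.zeros((len(seqs), int(n_off.max()), 20 * L))
    for i, s in enumerate(seqs):
        X[i, : n_off[i]] = encode_offsets(s, L, scheme)
    return X, n_off


@dataclass
class Hyperparams:
    """Training hyper-parameters for one motif network."""

    learning_rate: float = 0.05
    max_epochs: int = 300
    patience: int = 40
    val_fraction: float = 0.1


@dataclass
class MotifNetwork:
    """One trained core-alignment network."""

    motif_length: int
    scheme: str
    W1: np.ndarray  # (20L, 5)
    b1: np.ndarray  # (5,)
    W2: np.ndarray  # (5,)
    b2: float
    seed: int
    meta: dict = field(default_factory=dict)

    def forward_score(self, peptide: str) -> tuple[float, int]:
        """Network output maximised over core offsets.

        Returns ``(score, best_offset)``; ties go to the lowest offset.
        """
        X = encode_offsets(peptide, self.motif_length, self.scheme)
        h = 1.0 / (1.0 + np.exp(-(X @ self.W1 + self.b1)))
        out = 1.0 / (1.0 + np.exp(-(h @ self.W2 + self.b2)))
        best = int(np.argmax(out))
        return float(out[best]), best

    def batch_scores(self, X: np.ndarray, n_off: np.ndarray) -> np.ndarray:
        """Scores for an encoded dataset (padding offsets are masked out)."""
        h = 1.0 / (1.0 + np.exp(-(X @ self.W1 + self.b1)))
        out = 1.0 / (1.0 + np.exp(-(h @ self.W2 + self.b2)))
        mask = np.arange(X.shape[1])[None, :] >= n_off[:, None]
        out[mask] = -np.inf
        return out.max(axis=1)


@dataclass
class Ensemble:
    """A bag of motif networks whose mean output is the immunogenicity score."""

    networks: list[MotifNetwork]

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValueError("ensemble must contain at least one network")
        lengths = {n.motif_length for n in self.networks}
        if len(lengths) > 1:
            raise ValueError(f"ensemble members disagree on motif length: {lengths}")

    @property
    def motif_length(self) -> int:
        return self.networks[0].motif_length

    def predict(self, peptides: Sequence[str]) -> np.ndarray:
        """Mean raw score in (0, 1) for each peptide; higher = more immunogenic."""
        return self._predict_subset(peptides, range(len(self.networks)))

    def _predict_subset(self, peptides: Sequence[str], members: Iterable[int]) -> np.ndarray:
        members = list(members)
        L = self.motif_length
        cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        total = np.zeros(len(peptides))
        for m in members:
            net = self.networks[m]
            if net.scheme not in cache:
                cache[net.scheme] = _encode_dataset(list(peptides), L, net.scheme)
            X, n_off = cache[net.scheme]
            total += net.batch_scores(X, n_off)
        return total / len(members)


@dataclass
class CVResult:
    """Out-of-fold predictions and AUCs from common-motif cross-validation."""

    sequences: list[str]
    labels: np.ndarray
    oof: np.ndarray  # out-of-fold raw scores, aligned with sequences
    fold_of: np.ndarray  # fold index per peptide
    auc: float  # pooled over all out-of-fold predictions
    fold_aucs: list[float]  # NaN where a fold is single-class


def _holdout_split(
    labels: np.ndarray, val_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified inner hold-out used for the early-stopping snapshot."""
    val: list[int] = []
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        n_val = int(round(val_fraction * idx.size))
        if idx.size >= 2:
            n_val = min(max(n_val, 1), idx.size - 1)
        else:
            n_val = 0
        if n_val:
            val.extend(rng.permutation(idx)[:n_val].tolist())
    val_idx = np.array(sorted(val), dtype=np.int64)
    train_idx = np.setdiff1d(np.arange(labels.size, dtype=np.int64), val_idx)
    return train_idx, val_idx


def train_network(
    data: Sequence[LabeledPeptide],
    L: int = 9,
    scheme: str = "sparse",
    seed: int = 0,
    hyperparams: Hyperparams | None = None,
) -> MotifNetwork:
    """Train one motif-alignment network on labeled peptides.

    Deterministic for a fixed seed: the seed drives weight initialisation,
    the inner hold-out split and the per-epoch presentation order.
    """
    hp = hyperparams or Hyperparams()
    seqs = [lp.sequence for lp in data]
    y = np.array([lp.label for lp in data], dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both labels")
    X, n_off = _encode_dataset(seqs, L, scheme)
    rng = np.random.default_rng(seed)
    train_idx, val_idx = _holdout_split(y.astype(int), hp.val_fraction, rng)
    W1, b1, W2, b2, epochs_run, best_crit = train_sgd(
        X,
        n_off,
        y,
        train_idx,
        val_idx,
        N_HIDDEN,
        hp.learning_rate,
        hp.max_epochs,
        hp.patience,
        int(seed) % (2**31),
    )
    return MotifNetwork(
        motif_length=L,
        scheme=scheme,
        W1=W1,
        b1=b1,
        W2=W2,
        b2=float(b2),
        seed=seed,
        meta={
            "epochs_run": int(epochs_run),
            "holdout_criterion": float(best_crit),
            "learning_rate": hp.learning_rate,
            "n_train": int(train_idx.size),
        },
    )


def _member_seed(master: int, fold: int, seed_no: int, scheme: str) -> int:
    ss = np.random.SeedSequence([int(master), fold, seed_no, SCHEMES.index(scheme)])
    return int(ss.generate_state(1)[0] % (2**31))


def cross_validate(
    data: Sequence[LabeledPeptide],
    L: int = 9,
    n_folds: int = 5,
    n_seeds: int = 10,
    schemes: Sequence[str] = SCHEMES,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
    folds: FoldAssignment | None = None,
) -> tuple[CVResult, Ensemble]:
    """Common-motif cross-validation of the motif network ensemble.

    Folds are built so that peptides sharing a 9-mer stay together.  For
    each fold, ``n_seeds x len(schemes)`` networks are trained on the
    remaining folds; the fold's peptides are scored by the mean of
    exactly those networks (never by a network that saw them).  The
    returned production ensemble contains all trained networks.
    """
    seqs = [lp.sequence for lp in data]
    y = np.array([lp.label for lp in data], dtype=np.float64)
    if folds is None:
        folds = cluster_and_assign_folds(data, k=9, n_folds=n_folds, seed=seed)
    fold_of = np.array([folds[s] for s in seqs], dtype=np.int64)

    oof = np.full(len(seqs), np.nan)
    all_nets: list[MotifNetwork] = []
    for f in range(folds.n_folds):
        test_mask = fold_of == f
        if not test_mask.any():
            continue
        train_data = [lp for lp, m in zip(data, test_mask) if not m]
        test_seqs = [s for s, m in zip(seqs, test_mask) if m]
        fold_nets: list[MotifNetwork] = []
        for scheme in schemes:
            for s_no in range(n_seeds):
                net = train_network(
                    train_data,
                    L=L,
                    scheme=scheme,
                    seed=_member_seed(seed, f, s_no, scheme),
                    hyperparams=hyperparams,
                )
                net.meta["fold"] = f
                net.meta["seed_no"] = s_no
                fold_nets.append(net)
        bag = Ensemble(fold_nets)
        oof[test_mask] = bag.predict(test_seqs)
        all_nets.extend(fold_nets)

    fold_aucs: list[float] = []
    for f in range(folds.n_folds):
        m = fold_of == f
        if m.any() and len(np.unique(y[m])) == 2:
            fold_aucs.append(evaluation.auc(oof[m], y[m]))
        else:
            fold_aucs.append(float("nan"))
    pooled = evaluation.auc(oof, y)
    result = CVResult(
        sequences=seqs, labels=y, oof=oof, fold_of=fold_of, auc=pooled, fold_aucs=fold_aucs
    )
    return result, Ensemble(all_nets)


def motif_length_scan(
    data: Sequence[LabeledPeptide],
    L_range: Sequence[int] = tuple(range(1, 16)),
    n_folds: int = 5,
    n_seeds: int = 10,
    schemes: Sequence[str] = SCHEMES,
    hyperparams: Hyperparams | None = None,
    seed: int = 0,
):
    """Cross-validated AUC for each candidate motif length.

    Returns a pandas DataFrame with one row per motif length: pooled CV
    AUC plus the mean and SD of the per-fold AUCs.
    """
    import pandas as pd

    rows = []
    for L in L_range:
        cv, _ = cross_validate(
            data,
            L=L,
            n_folds=n_folds,
            n_seeds=n_seeds,
            schemes=schemes,
            hyperparams=hyperparams,
            seed=seed,
        )
        fa = np.asarray(cv.fold_aucs)
        rows.append(
            {
                "motif_length": L,
                "auc": cv.auc,
                "fold_auc_mean": float(np.nanmean(fa)),
                "fold_auc_sd": float(np.nanstd(fa, ddof=1)),
            }
        )
    return pd.DataFrame(rows)


def predict_immunogenicity(ensemble: Ensemble, peptides: Sequence[str] | str) -> np.ndarray | float:
    """Raw ensemble immunogenicity score(s) in (0, 1); higher = more immunogenic."""
    if isinstance(peptides, str):
        return float(ensemble.predict([peptides])[0])
    return ensemble.predict(peptides)


# ---------------------------------------------------------------------------
# Serialization — JSON with exact float round-trip


def ensemble_to_json(ensemble: Ensemble) -> str:
    doc = {
        "format": "cd4imm-motif-ensemble",
        "version": 1,
        "motif_length": ensemble.motif_length,
        "n_hidden": N_HIDDEN,
        "networks": [
            {
                "scheme": net.scheme,
                "seed": net.seed,
                "W1": net.W1.tolist(),
                "b1": net.b1.tolist(),
                "W2": net.W2.tolist(),
                "b2": net.b2,
                "meta": net.meta,
            }
            for net in ensemble.networks
        ],
    }
    return json.dumps(doc, indent=1, sort_keys=True)


def ensemble_from_json(text: str) -> Ensemble:
    doc = json.loads(text)
    if doc.get("format") != "cd4imm-motif-ensemble":
        raise ValueError("not a cd4imm model document")
    nets = [
        MotifNetwork(
            motif_length=doc["motif_length"],
            scheme=nd["scheme"],
            W1=np.array(nd["W1"]),
            b1=np.array(nd["b1"]),
            W2=np.array(nd["W2"]),
            b2=float(nd["b2"]),
            seed=nd["seed"],
            meta=nd.get("meta", {}),
        )
        for nd in doc["networks"]
    ]
    return Ensemble(nets)


def save_model(ensemble: Ensemble, path: str | Path) -> None:
    Path(path).write_text(ensemble_to_json(ensemble))


def load_model(path: str | Path) -> Ensemble:
    return ensemble_from_json(Path(path).read_text())


# ---------------------------------------------------------------------------
# scikit-learn estimator façade


class MotifAlignClassifier(BaseEstimator, ClassifierMixin):
    """Motif-alignment network ensemble as a scikit-learn classifier.

    ``fit`` runs common-motif cross-validation (peptides sharing a 9-mer
    are kept in the same fold) and keeps *all* trained networks as the
    production ensemble — there is no refit on the full data, so the
    fitted model is exactly the model the cross-validated AUC describes.

    Parameters
    ----------
    motif_length : int, default 9
        Length L of the scored core; the peptide score is the maximum
        network output over all length-L windows.
    n_seeds : int, default 10
        Random restarts per (fold, encoding scheme).
    encodings : sequence of {"sparse", "blosum"}
        Residue encodings to ensemble over.
    n_folds : int, default 5
        Cross-validation folds.
    learning_rate, max_epochs, patience, val_fraction
        SGD hyper-parameters (early stopping snapshots the best inner
        hold-out AUC).
    random_state : int, default 0
        Master seed; fit is bitwise reproducible given the same value.

    Attributes
    ----------
    ensemble_ : Ensemble
        All trained networks.
    cv_result_ : CVResult
        Out-of-fold predictions and per-fold/pooled AUCs.
    oof_auc_ : float
        Pooled cross-validated AUC.
    classes_ : ndarray of shape (2,)
    """

    def __init__(
        self,
        motif_length: int = 9,
        n_seeds: int = 10,
        encodings: Sequence[str] = SCHEMES,
        n_folds: int = 5,
        learning_rate: float = 0.05,
        max_epochs: int = 300,
        patience: int = 40,
        val_fraction: float = 0.1,
        random_state: int = 0,
    ) -> None:
        self.motif_length = motif_length
        self.n_seeds = n_seeds
        self.encodings = encodings
        self.n_folds = n_folds
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.val_fraction = val_fraction
        self.random_state = random_state

    def _as_labeled(self, X, y) -> list[LabeledPeptide]:
        from .peptides import Peptide

        X = list(X)
        y = np.asarray(y)
        if len(X) != y.size:
            raise ValueError("X and y length mismatch")
        if not set(np.unique(y)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        return [LabeledPeptide(Peptide(s), int(t)) for s, t in zip(X, y)]

    def fit(self, X, y):
        """Fit on peptide sequences X (iterable of str) and binary labels y."""
        data = self._as_labeled(X, y)
        hp = Hyperparams(
            learning_rate=self.learning_rate,
            max_epochs=self.max_epochs,
            patience=self.patience,
            val_fraction=self.val_fraction,
        )
        cv, ens = cross_validate(
            data,
            L=self.motif_length,
            n_folds=self.n_folds,
            n_seeds=self.n_seeds,
            schemes=tuple(self.encodings),
            hyperparams=hp,
            seed=self.random_state,
        )
        self.cv_result_ = cv
        self.ensemble_ = ens
        self.oof_auc_ = cv.auc
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        """Raw ensemble score in (0, 1); higher = more immunogenic."""
        check_is_fitted(self, "ensemble_")
        return self.ensemble_.predict(list(X))

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_function(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) >= 0.5).astype(int)
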