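"""Percentile-style scoring and combination with HLA class II binding.

The raw network output in (0, 1) (higher = more immunogenic) is mapped
to the 0-100 immunogenicity percentile scale::

    Imm_score = (1 - nn_raw) * 100          # lower = more immunogenic

Population-level HLA class II binding is summarised as the median
percentile rank across seven representative DR alleles (HLA_score, also
0-100, lower = stronger binder).  The two channels are merged by a
convex combination::

    Combined = alpha * Imm_score + (1 - alpha) * HLA_score

with alpha = 0.4 by default.  ``alpha_sweep`` evaluates the mean
per-study AUC over a grid of alpha values; at alpha = 0 the combination
degenerates to HLA binding alone, at alpha = 1 to the immunogenicity
score alone.

Per-allele percentile ranks are normally supplied precomputed (TSV with
columns peptide, allele, percentile_rank).  ``ToyAllelePredictor`` is a
small position-weight-matrix binding model with percentile calibration
against a random-peptide background, so the full pipeline runs without
any external binding predictor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .evaluation import StudySet
from .peptides import AA_ALPHABET

DEFAULT_ALPHA = 0.4

#: Seven DR alleles representative of binding motifs common in the
#: general population (the "7-allele method" reference panel).
DEFAULT_ALLELES = (
    "HLA-DRB1*03:01",
    "HLA-DRB1*07:01",
    "HLA-DRB1*15:01",
    "HLA-DRB3*01:01",
    "HLA-DRB3*02:02",
    "HLA-DRB4*01:01",
    "HLA-DRB5*01:01",
)


def imm_score_from_nn(nn_raw):
    """Convert raw network output in [0, 1] to the 0-100 Imm_score.

    ``Imm_score = (1 - nn_raw) * 100``; lower = more immunogenic.
    """
    arr = np.asarray(nn_raw, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("nn_raw must lie in [0, 1]")
    out = (1.0 - arr) * 100.0
    return float(out) if np.isscalar(nn_raw) or arr.ndim == 0 else out


def hla_median_percentile(percentiles: Mapping[str, float] | Sequence[float]) -> float:
    """Median per-allele binding percentile rank (the 7-allele HLA_score)."""
    vals = (
        np.array(list(percentiles.values()), dtype=float)
        if isinstance(percentiles, Mapping)
        else np.asarray(percentiles, dtype=float)
    )
    if vals.size == 0:
        raise ValueError("at least one allele percentile required")
    if np.any((vals < 0) | (vals > 100)):
        raise ValueError("percentile ranks must lie in [0, 100]")
    if vals.size != 7:
        warnings.warn(f"expected 7 allele percentiles, got {vals.size}", stacklevel=2)
    return float(np.median(vals))


def combined_score(imm, hla, alpha: float = DEFAULT_ALPHA):
    """Combined = alpha * Imm_score + (1 - alpha) * HLA_score."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must lie in [0, 1], got {alpha}")
    imm_a = np.asarray(imm, dtype=float)
    hla_a = np.asarray(hla, dtype=float)
    if np.any((imm_a < 0) | (imm_a > 100)) or np.any((hla_a < 0) | (hla_a > 100)):
        raise ValueError("scores must lie on the 0-100 scale")
    out = alpha * imm_a + (1.0 - alpha) * hla_a
    return float(out) if out.ndim == 0 else out


@dataclass
class AlphaSweepResult:
    """Mean per-study AUC as a function of the combination weight alpha."""

    grid: np.ndarray
    mean_auc: np.ndarray
    per_study: pd.DataFrame  # one row per study, one column per alpha

    @property
    def best_alpha(self) -> float:
        return float(self.grid[int(np.argmax(self.mean_auc))])

    def plot(self, path) -> None:
        """Cosmetic mean-AUC-vs-alpha line chart (requires matplotlib)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.plot(self.grid, self.mean_auc, marker="o", ms=3)
        ax.axvline(DEFAULT_ALPHA, ls=":", color="grey")
        ax.set_xlabel(r"$\alpha$")
        ax.set_ylabel("mean per-study AUC")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def alpha_sweep(
    study_sets: Sequence[StudySet],
    imm_scores: Mapping[str, float],
    hla_scores: Mapping[str, float],
    grid: Sequence[float] | None = None,
) -> AlphaSweepResult:
    """Sweep alpha over [0, 1] and report the mean per-study AUC at each value.

    AUC orientation is "lower = epitope" throughout (percentile scores).
    Studies with single-class labels are excluded from the mean with a
    warning.  The endpoints reproduce the single-method AUCs exactly.
    """
    if grid is None:
        grid = np.round(np.linspace(0.0, 1.0, 21), 10)
    grid = np.asarray(sorted(grid), dtype=float)
    if grid[0] != 0.0 or grid[-1] != 1.0:
        raise ValueError("alpha grid must include 0 and 1")

    rows = {}
    for st in study_sets:
        imm = np.array([imm_scores[p] for p in st.peptides], dtype=float)
        hla = np.array([hla_scores[p] for p in st.peptides], dtype=float)
        labels = st.labels
        if len(np.unique(labels)) < 2:
            warnings.warn(f"study {st.study_id} is single-class; excluded", stacklevel=2)
            continue
        rows[st.study_id] = [
            evaluation.auc(combined_score(imm, hla, a), labels, orientation="lower")
            for a in grid
        ]
    per_study = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"{a:g}" for a in grid]
    )
    per_study.index.name = "study_id"
    mean_auc = per_study.mean(axis=0).to_numpy()
    return AlphaSweepResult(grid=grid, mean_auc=mean_auc, per_study=per_study)


# ---------------------------------------------------------------------------
# HLA percentile I/O


def read_hla_percentiles(path: str | Path) -> dict[str, float]:
    """Read per-allele percentile ranks and aggregate to the median HLA_score.

    TSV columns: peptide, allele, percentile_rank.  Returns
    {peptide: median percentile across its alleles}.
    """
    df = pd.read_csv(path, sep="\t", dtype={"peptide": str, "allele": str})
    missing = {"peptide", "allele", "percentile_rank"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    return {
        pep: hla_median_percentile(g["percentile_rank"].to_list())
        for pep, g in df.groupby("peptide", sort=True)
    }


def write_score_table(
    path: str | Path,
    peptides: Sequence[str],
    nn_raw: Sequence[float],
    hla: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    extra: Mapping[str, Sequence] | None = None,
) -> pd.DataFrame:
    """Write the aggregated per-peptide score TSV and return it as a frame."""
    imm = imm_score_from_nn(np.asarray(nn_raw))
    comb = combined_score(imm, np.asarray(hla, dtype=float), alpha)
    df = pd.DataFrame(
        {
            "peptide": list(peptides),
            "nn_raw": np.asarray(nn_raw, dtype=float),
            "imm_score": imm,
            "hla_score": np.asarray(hla, dtype=float),
            "combined": comb,
        }
    )
    if extra:
        for k, v in extra.items():
            df[k] = list(v)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return df


# ---------------------------------------------------------------------------
# Toy per-allele binding predictor (keeps the pipeline runnable offline)


_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}


class ToyAllelePredictor:
    """Position-weight-matrix stand-in for a per-allele class II binding predictor.

    Each allele is a 9x20 log-weight matrix; the raw binding score of a
    peptide is the best 9-mer window sum, and the percentile rank is
    calibrated against a background of random peptides scored under the
    same matrix (0 = binds better than every background peptide, i.e.
    strongest binder — the usual percentile-rank convention).

    Follows the fit/predict idiom: ``fit`` draws and scores the
    background, ``predict_percentiles`` returns per-allele ranks.
    """

    CORE = 9

    def __init__(
        self,
        alleles: Sequence[str] = DEFAULT_ALLELES,
        n_background: int = 2000,
        random_state: int = 0,
    ) -> None:
        self.alleles = tuple(alleles)
        self.n_background = n_background
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "alleles": self.alleles,
            "n_background": self.n_background,
            "random_state": self.random_state,
        }

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _raw(self, peptide: str, matrix: np.ndarray) -> float:
        if len(peptide) < self.CORE:
            raise ValueError(f"peptide shorter than {self.CORE} residues")
        idx = np.array([_AA_INDEX.get(c, -1) for c in peptide])
        best = -np.inf
        for o in range(len(peptide) - self.CORE + 1):
            win = idx[o : o + self.CORE]
            s = sum(matrix[p, a] for p, a in enumerate(win) if a >= 0)
            best = max(best, s)
        return float(best)

    def fit(self, background_peptides: Sequence[str] | None = None):
        """Draw allele matrices and calibrate percentile backgrounds."""
        rng = np.random.default_rng(self.random_state)
        self.matrices_ = {a: rng.normal(0.0, 1.0, (self.CORE, 20)) for a in self.alleles}
        if background_peptides is None:
            letters = np.array(list(AA_ALPHABET))
            background_peptides = [
                "".join(rng.choice(letters, 15)) for _ in range(self.n_background)
            ]
        self.background_scores_ = {
            a: np.array([self._raw(p, m) for p in background_peptides])
            for a, m in self.matrices_.items()
        }
        return self

    def percentile_rank(self, raw: float, background_scores: np.ndarray) -> float:
        """100 x fraction of background scoring strictly better (0 = best)."""
        bg = np.asarray(background_scores, dtype=float)
        if bg.size == 0:
            raise ValueError("background scores must be non-empty")
        return float(100.0 * np.mean(bg > raw))

    def predict_percentiles(self, peptide: str) -> dict[str, float]:
        """Per-allele percentile ranks for one peptide."""
        if not hasattr(self, "matrices_"):
            raise RuntimeError("predictor not fitted; call fit() first")
        return {
            a: self.percentile_rank(self._raw(peptide, m), self.background_scores_[a])
            for a, m in self.matrices_.items()
        }

    def hla_scores(self, peptides: Sequence[str]) -> dict[str, float]:
        """Median-of-alleles HLA_score per peptide."""
        return {
            p: hla_median_percentile(self.predict_percentiles(p)) for p in peptides
        }
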