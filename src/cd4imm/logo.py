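"""Two-sample logo: per-position residue enrichment between peptide sets.

Compares epitopes against non-recognized peptides position by position
over the N-terminal 15 residues.  For each (position, residue) cell a
two-sample t-test (Welch) is run on the per-peptide binary indicator
"residue present at this position"; cells with p below the cutoff
(default 0.01, uncorrected) are flagged enriched (more frequent in
epitopes) or depleted.  Subset stability re-runs the analysis on five
80% subsamples and reports per-cell concordance with the full data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .peptides import AA_ALPHABET

LOGO_LENGTH = 15


def truncate_to_15(peptides: Sequence[str]) -> list[str]:
    """Keep the N-terminal 15 residues of each peptide (all must be >= 15)."""
    out = []
    for p in peptides:
        if len(p) < LOGO_LENGTH:
            raise ValueError(f"peptide {p!r} shorter than {LOGO_LENGTH} residues")
        out.append(p[:LOGO_LENGTH])
    return out


def _indicator_matrix(peptides: list[str]) -> np.ndarray:
    """(n_peptides, 15, 20) binary indicators; X residues count nowhere."""
    idx = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    M = np.zeros((len(peptides), LOGO_LENGTH, 20), dtype=float)
    for n, p in enumerate(peptides):
        for pos, c in enumerate(p):
            j = idx.get(c)
            if j is not None:
                M[n, pos, j] = 1.0
    return M


def two_sample_logo(
    pos_set: Sequence[str],
    neg_set: Sequence[str],
    p_cutoff: float = 0.01,
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per-(position, residue) enrichment table between two 15-mer sets.

    Returns a DataFrame with columns position (1-based), residue,
    freq_pos, freq_neg, delta, p_value and status in
    {enriched, depleted, neutral}.  Enriched means significantly more
    frequent in ``pos_set`` (epitopes).  ``bonferroni=True`` divides the
    cutoff by the number of tested cells (off by default, matching the
    raw p < 0.01 convention).
    """
    if not pos_set or not neg_set:
        raise ValueError("both peptide sets must be non-empty")
    pos = truncate_to_15(list(pos_set))
    neg = truncate_to_15(list(neg_set))
    P = _indicator_matrix(pos)
    N = _indicator_matrix(neg)
    cutoff = p_cutoff / (LOGO_LENGTH * 20) if bonferroni else p_cutoff

    rows = []
    for position in range(LOGO_LENGTH):
        for j, residue in enumerate(AA_ALPHABET):
            a = P[:, position, j]
            b = N[:, position, j]
            fp, fn = float(a.mean()), float(b.mean())
            if a.sum() == 0 and b.sum() == 0:
                p_val = 1.0
            else:
                t = stats.ttest_ind(a, b, equal_var=False)
                p_val = float(t.pvalue)
                if np.isnan(p_val):
                    # zero variance in both groups: identical constant
                    # indicators give p = 1, separated constants give 0
                    p_val = 0.0 if fp != fn else 1.0
            delta = fp - fn
            if p_val < cutoff and delta > 0:
                status = "enriched"
            elif p_val < cutoff and delta < 0:
                status = "depleted"
            else:
                status = "neutral"
            rows.append(
                {
                    "position": position + 1,
                    "residue": residue,
                    "freq_pos": fp,
                    "freq_neg": fn,
                    "delta": delta,
                    "p_value": p_val,
                    "status": status,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class StabilityReport:
    """Concordance of subset logos with the full-data logo."""

    full: pd.DataFrame
    concordance: pd.DataFrame  # per-cell fraction of subsets agreeing on status
    n_subsets: int
    fraction: float


def subset_stability(
    pos_set: Sequence[str],
    neg_set: Sequence[str],
    n_subsets: int = 5,
    fraction: float = 0.8,
    seed: int = 0,
    p_cutoff: float = 0.01,
) -> StabilityReport:
    """Check logo robustness on repeated 80% subsamples.

    Each subset keeps ``fraction`` of each class (drawn without
    replacement, seeded).  The report gives, per (position, residue)
    cell, the fraction of subsets whose enriched/depleted/neutral status
    matches the full-data logo.
    """
    full = two_sample_logo(pos_set, neg_set, p_cutoff=p_cutoff)
    rng = np.random.default_rng(seed)
    agree = np.zeros(len(full))
    for _ in range(n_subsets):
        pos_idx = rng.permutation(len(pos_set))[: max(1, int(round(fraction * len(pos_set))))]
        neg_idx = rng.permutation(len(neg_set))[: max(1, int(round(fraction * len(neg_set))))]
        sub = two_sample_logo(
            [pos_set[i] for i in pos_idx],
            [neg_set[i] for i in neg_idx],
            p_cutoff=p_cutoff,
        )
        agree += (sub["status"].to_numpy() == full["status"].to_numpy()).astype(float)
    conc = full[["position", "residue", "status"]].copy()
    conc["concordance"] = agree / n_subsets
    return StabilityReport(full=full, concordance=conc, n_subsets=n_subsets, fraction=fraction)


def write_logo_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def render_logo(table: pd.DataFrame, path) -> None:
    """Cosmetic bar rendering of a logo table (requires matplotlib).

    Enriched residues are drawn upward, depleted downward, bar height
    proportional to the frequency difference. The TSV table is the
    canonical output; this is a convenience view only.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.5))
    for position, g in table[table["status"] != "neutral"].groupby("position"):
        up = down = 0.0
        for _, row in g.sort_values("delta", ascending=False).iterrows():
            h = row["delta"]
            base = up if h > 0 else down
            ax.bar(position, h, bottom=base, width=0.8,
                   color="tab:red" if h > 0 else "tab:blue", edgecolor="white")
            y = base + h / 2
            ax.text(position, y, row["residue"], ha="center", va="center", fontsize=7)
            if h > 0:
                up += h
            else:
                down += h
    ax.axhline(0, color="black", lw=0.8)
    ax.set_xlim(0.25, LOGO_LENGTH + 0.75)
    ax.set_xticks(range(1, LOGO_LENGTH + 1))
    ax.set_xlabel("position")
    ax.set_ylabel("frequency difference\n(epitopes − non-epitopes)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
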