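"""Dataset diagnostics: per-position residue composition, frequency-
difference logos, positional chi-square tests with Benjamini-Hochberg
correction, and Shannon entropy.

Analyses default to 9-mers (the dominant length class in MHC-I data)
but take the length as a parameter.  Entropy is in nats, so a position
ranges from 0 (complete conservation) to ln 20 ~ 3 (uniform usage of
all twenty residues).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .aaindex import CANONICAL_AA

AA_LIST = list(CANONICAL_AA)


def _of_length(peptides: Sequence[str], length: int) -> list[str]:
    kept = [p.upper() for p in peptides if len(p) == length]
    if not kept:
        raise ValueError(f"no peptides of length {length}")
    return kept


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position residue counts and relative frequencies."""

    length: int
    counts: pd.DataFrame  # positions x 20, ints
    freqs: pd.DataFrame   # positions x 20, rows sum to 1

    @classmethod
    def from_peptides(cls, peptides: Sequence[str], length: int = 9) -> "PositionFrequencyMatrix":
        kept = _of_length(peptides, length)
        counts = np.zeros((length, 20), dtype=int)
        index = {aa: i for i, aa in enumerate(AA_LIST)}
        for p in kept:
            for pos, residue in enumerate(p):
                counts[pos, index[residue]] += 1
        counts_df = pd.DataFrame(
            counts, index=range(1, length + 1), columns=AA_LIST
        )
        freqs = counts_df / counts_df.sum(axis=1).to_numpy()[:, None]
        return cls(length=length, counts=counts_df, freqs=freqs)


def frequency_difference_logo(
    set_a: Sequence[str], set_b: Sequence[str], length: int = 9
) -> pd.DataFrame:
    """Signed per-position frequency differences (A minus B).

    Positive entries mark enrichment in set A, negative in set B; each
    position's entries sum to zero.  Use ``.abs().sum(axis=1)`` for the
    per-position total absolute difference.
    """
    fa = PositionFrequencyMatrix.from_peptides(set_a, length).freqs
    fb = PositionFrequencyMatrix.from_peptides(set_b, length).freqs
    return fa - fb


def total_absolute_difference(diff: pd.DataFrame) -> pd.Series:
    """Per-position sum of absolute frequency differences."""
    return diff.abs().sum(axis=1).rename("total_abs_diff")


def positionwise_chi_square(
    set_a: Sequence[str], set_b: Sequence[str], length: int = 9
) -> pd.DataFrame:
    """Per-position 2 x 20 chi-square tests of residue composition,
    BH-adjusted across positions.

    Residues unobserved in both sets at a position are dropped before
    testing (their expected counts would be zero).
    """
    ca = PositionFrequencyMatrix.from_peptides(set_a, length).counts
    cb = PositionFrequencyMatrix.from_peptides(set_b, length).counts
    rows = []
    for pos in range(1, length + 1):
        table = np.vstack([ca.loc[pos].to_numpy(), cb.loc[pos].to_numpy()])
        usable = table.sum(axis=0) > 0
        table = table[:, usable]
        if table.shape[1] < 2:
            statistic, p = 0.0, 1.0
        else:
            statistic, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append({"position": pos, "chi2": float(statistic), "p": float(p)})
    out = pd.DataFrame(rows)
    out["p_adjusted"] = benjamini_hochberg(out["p"].to_numpy())
    return out


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Step-up BH-adjusted p-values (monotone in the raw p-values)."""
    return multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")[1]


def positional_entropy(peptides: Sequence[str], length: int = 9) -> pd.Series:
    """Per-position plug-in Shannon entropy in nats, with 0*log 0 = 0."""
    counts = PositionFrequencyMatrix.from_peptides(peptides, length).counts
    values = [
        float(stats.entropy(counts.loc[pos].to_numpy()))
        for pos in counts.index
    ]
    return pd.Series(values, index=counts.index, name="entropy_nats")


def characterization_summary(
    set_a: Sequence[str], set_b: Sequence[str], length: int = 9
) -> pd.DataFrame:
    """One row per position: total absolute frequency difference,
    per-set entropies, chi-square statistic and raw/adjusted p."""
    diff = frequency_difference_logo(set_a, set_b, length)
    summary = positionwise_chi_square(set_a, set_b, length)
    summary["total_abs_diff"] = total_absolute_difference(diff).to_numpy()
    summary["entropy_a"] = positional_entropy(set_a, length).to_numpy()
    summary["entropy_b"] = positional_entropy(set_b, length).to_numpy()
    return summary


def plot_frequency_difference(diff: pd.DataFrame, ax=None):
    """Render a simple signed frequency-difference logo with matplotlib:
    stacked per-residue bars, positive up (enriched in A), negative
    down (enriched in B)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.2 * len(diff), 4))
    positions = diff.index.to_numpy()
    for sign in (1, -1):
        bottoms = np.zeros(len(diff))
        for aa in diff.columns:
            heights = diff[aa].to_numpy()
            heights = np.where(np.sign(heights) == sign, heights, 0.0)
            ax.bar(positions, heights, bottom=bottoms, width=0.8,
                   label=aa if sign == 1 else None)
            bottoms += heights
    ax.axhline(0, color="black", linewidth=0.8)
    ax.set_xlabel("position")
    ax.set_ylabel("frequency difference (A - B)")
    ax.set_xticks(positions)
    return ax
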