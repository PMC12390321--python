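"""Training-set assembly against a reference proteome.

Positives are T-cell-confirmed 9-11-mers that are non-self (at least one
mismatch to the reference proteome); negatives are MHC-presented-only
peptides retained when they carry 1-3 mismatches, excluding anything in
the positive set.  The negative pool is then subsampled to a 1:3.5
positive:negative ratio while preserving the positive set's length
distribution.

Mismatch counting is pure Hamming over equal-length windows (no gaps).
The fast path uses pigeonhole seeding: a peptide within 3 mismatches of
a window must share one of its four exact chunks with the proteome, so
an exact chunk-position index prunes the scan; distances above 3 fall
back to a vectorized full scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .aaindex import CANONICAL_AA
from .encoding import MAX_LENGTH, MIN_LENGTH, PeptideError, _validate_peptide

#: Mismatch band the negative class must fall in (non-self but near-self).
NEGATIVE_MISMATCH_RANGE = (1, 3)
DEFAULT_RATIO = 3.5

_SEED_CHUNKS = 4  # pigeonhole: <=3 mismatches leave one of 4 chunks exact


@dataclass(frozen=True)
class EpitopeRecord:
    """One assay record: a peptide and how it was observed."""

    peptide: str
    assay_class: str  # "tcell_positive" | "presented_only"
    source_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "peptide", _validate_peptide(self.peptide))
        if self.assay_class not in ("tcell_positive", "presented_only"):
            raise ValueError(f"unknown assay_class {self.assay_class!r}")


class ReferenceProteome:
    """Reference protein sequences with an exact chunk index for fast
    minimum-Hamming lookup."""

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("empty proteome")
        self.sequences = {pid: seq.upper() for pid, seq in sequences.items()}
        self._arrays = {
            pid: np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            for pid, seq in self.sequences.items()
        }
        self._chunk_index: dict[int, dict[str, list[tuple[str, int]]]] = {}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "ReferenceProteome":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(records)

    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def _index_for(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._chunk_index:
            index: dict[str, list[tuple[str, int]]] = {}
            for pid, seq in self.sequences.items():
                for pos in range(len(seq) - k + 1):
                    index.setdefault(seq[pos : pos + k], []).append((pid, pos))
            self._chunk_index[k] = index
        return self._chunk_index[k]

    def _scan_min(self, peptide: str) -> int:
        """Exact minimum Hamming distance by a vectorized full window scan."""
        pep = np.frombuffer(peptide.encode("ascii"), dtype=np.uint8)
        L = len(pep)
        best = L
        for arr in self._arrays.values():
            if len(arr) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(arr, L)
            mismatches = (windows != pep).sum(axis=1).min()
            if mismatches < best:
                best = int(mismatches)
                if best == 0:
                    return 0
        return best

    def _seeded_min(self, peptide: str, cap: int) -> int | None:
        """Minimum Hamming distance if it is <= cap, else None.

        Splits the peptide into ``cap + 1`` chunks; any window within
        ``cap`` mismatches matches at least one chunk exactly.
        """
        L = len(peptide)
        n_chunks = cap + 1
        bounds = np.linspace(0, L, n_chunks + 1).astype(int)
        best: int | None = None
        pep = np.frombuffer(peptide.encode("ascii"), dtype=np.uint8)
        for c in range(n_chunks):
            lo, hi = bounds[c], bounds[c + 1]
            chunk = peptide[lo:hi]
            index = self._index_for(hi - lo)
            for pid, pos in index.get(chunk, ()):
                start = pos - lo
                arr = self._arrays[pid]
                if start < 0 or start + L > len(arr):
                    continue
                d = int((arr[start : start + L] != pep).sum())
                if best is None or d < best:
                    best = d
                    if best == 0:
                        return 0
        return best if best is not None and best <= cap else None


def min_mismatch_to_proteome(peptide: str, proteome: ReferenceProteome) -> int:
    """Minimum Hamming distance from ``peptide`` to any equal-length
    window of any reference protein (0 means exact substring match)."""
    peptide = _validate_peptide(peptide)
    if all(len(s) < len(peptide) for s in proteome.sequences.values()):
        raise ValueError("no protein long enough to compare against")
    cap = NEGATIVE_MISMATCH_RANGE[1]
    seeded = proteome._seeded_min(peptide, cap)
    if seeded is not None:
        return seeded
    return proteome._scan_min(peptide)


def _unique_valid(records: Iterable[EpitopeRecord], assay_class: str) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    for rec in records:
        if rec.assay_class != assay_class:
            continue
        if rec.peptide not in seen:
            seen.add(rec.peptide)
            out.append(rec.peptide)
    return out


def build_positive_set(
    records: Iterable[EpitopeRecord], proteome: ReferenceProteome
) -> list[str]:
    """Unique T-cell-positive 9-11-mers with at least one mismatch to
    the reference proteome (self peptides removed), in input order."""
    return [
        p
        for p in _unique_valid(records, "tcell_positive")
        if min_mismatch_to_proteome(p, proteome) >= 1
    ]


def build_negative_set(
    records: Iterable[EpitopeRecord],
    proteome: ReferenceProteome,
    positives: Sequence[str],
) -> list[str]:
    """Unique presented-only peptides with 1-3 mismatches to the
    proteome, excluding any peptide in the positive set."""
    lo, hi = NEGATIVE_MISMATCH_RANGE
    positive_set = set(positives)
    out = []
    for p in _unique_valid(records, "presented_only"):
        if p in positive_set:
            continue
        if lo <= min_mismatch_to_proteome(p, proteome) <= hi:
            out.append(p)
    return out


@dataclass
class TrainingDataset:
    """Assembled positive/negative peptide sets ready for encoding."""

    positives: list[str]
    negatives: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"classes overlap: {sorted(overlap)[:3]} ...")

    @property
    def ratio(self) -> float:
        return len(self.negatives) / len(self.positives)

    def length_histogram(self) -> pd.DataFrame:
        rows = []
        for label, peptides in (("positive", self.positives), ("negative", self.negatives)):
            counts = pd.Series([len(p) for p in peptides]).value_counts()
            for length, n in counts.items():
                rows.append({"label": label, "length": int(length), "count": int(n)})
        return pd.DataFrame(rows).sort_values(["label", "length"], ignore_index=True)

    def to_frame(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame({"peptide": self.positives, "label": 1}),
            pd.DataFrame({"peptide": self.negatives, "label": 0}),
        ]
        df = pd.concat(frames, ignore_index=True)
        df["length"] = df["peptide"].str.len()
        return df


def _largest_remainder_quota(shares: np.ndarray, total: int) -> np.ndarray:
    """Apportion ``total`` among strata proportionally to ``shares``."""
    exact = shares / shares.sum() * total
    quotas = np.floor(exact).astype(int)
    remainder = total - quotas.sum()
    if remainder > 0:
        order = np.argsort(-(exact - quotas), kind="stable")
        quotas[order[:remainder]] += 1
    return quotas


def subsample_to_ratio(
    positives: Sequence[str],
    negatives: Sequence[str],
    ratio: float = DEFAULT_RATIO,
    seed: int = 0,
) -> TrainingDataset:
    """Subsample negatives to ``floor(ratio * n_positives)``, stratified
    by peptide length so the negative length distribution matches the
    positive one as closely as largest-remainder rounding allows.

    Sampling is without replacement, seeded, and tie-broken by input
    order within each length stratum.
    """
    n_target = math.floor(ratio * len(positives))
    if len(negatives) < n_target:
        raise ValueError(
            f"need {n_target} negatives for ratio {ratio}, have {len(negatives)}"
        )
    pos_lengths = pd.Series([len(p) for p in positives])
    strata = pos_lengths.value_counts().sort_index()
    quotas = _largest_remainder_quota(strata.to_numpy(float), n_target)

    neg_by_length: dict[int, list[str]] = {}
    for p in negatives:
        neg_by_length.setdefault(len(p), []).append(p)

    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    for length, quota in zip(strata.index, quotas):
        pool = neg_by_length.get(int(length), [])
        if len(pool) < quota:
            raise ValueError(
                f"length stratum {length}: need {quota} negatives, have {len(pool)}"
            )
        idx = rng.choice(len(pool), size=int(quota), replace=False)
        chosen.extend(pool[i] for i in sorted(idx))
    return TrainingDataset(positives=list(positives), negatives=chosen)


def read_epitope_csv(path: str | Path, assay_class: str | None = None) -> list[EpitopeRecord]:
    """Read records from a CSV with columns ``peptide,assay_class[,source_id]``.

    If the file has no ``assay_class`` column, ``assay_class`` must be
    supplied and is applied to every row.
    """
    df = pd.read_csv(path)
    if "peptide" not in df.columns:
        raise ValueError(f"{path}: missing 'peptide' column")
    if "assay_class" not in df.columns:
        if assay_class is None:
            raise ValueError(f"{path}: no assay_class column and none supplied")
        df["assay_class"] = assay_class
    if "source_id" not in df.columns:
        df["source_id"] = ""
    return [
        EpitopeRecord(peptide=row.peptide, assay_class=row.assay_class,
                      source_id=str(row.source_id))
        for row in df.itertuples()
    ]
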