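"""Seeded synthetic generators for every input the package consumes:
AAindex1-format property tables, labeled peptide sets with a planted
class signal, random proteomes with planted self peptides, mutation
tables and survival cohorts.

The planted peptide signal enriches hydrophobic residues at chosen
positions of the positive class, emulating the hydrophobicity signal
that dominates real immunogenicity data; everything else is uniform.
All generators are pure functions of their seed and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aaindex import CANONICAL_AA

#: Residues with positive Kyte-Doolittle hydropathy.
HYDROPHOBIC_AA = "ACFILMV"

_AA = np.array(list(CANONICAL_AA))
_HYDRO_IDX = np.array([CANONICAL_AA.index(a) for a in HYDROPHOBIC_AA])


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study conditions.

    ``effect_size`` is the probability that a signal-position residue of
    a positive peptide is drawn from the hydrophobic set instead of the
    uniform background; ``signal_positions`` are 1-based.  Survival
    times are exponential with ``baseline_hazard`` per day, scaled by
    ``hazard_ratio`` for the high-biomarker half of the cohort, with
    independent uniform censoring at rate ``censoring_rate``.
    """

    seed: int = 0
    n_positive: int = 2000
    n_negative: int = 7000
    length_mix: tuple[tuple[int, float], ...] = ((9, 0.69), (10, 0.21), (11, 0.10))
    signal_positions: tuple[int, ...] = (1, 5, 7)
    effect_size: float = 0.9
    proteome_length: int = 5000
    n_patients: int = 100
    baseline_hazard: float = math.log(2) / 365.0  # median survival ~1 year
    hazard_ratio: float = 1.0
    censoring_rate: float = 0.2

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.length_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("length_mix proportions must sum to 1")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValueError("effect_size must be in [0, 1]")


def _sample_lengths(rng: np.random.Generator, n: int, length_mix) -> np.ndarray:
    lengths = np.array([l for l, _ in length_mix])
    weights = np.array([w for _, w in length_mix])
    return rng.choice(lengths, size=n, p=weights)


def _random_peptides(
    rng: np.random.Generator,
    n: int,
    length_mix,
    signal_positions: tuple[int, ...] = (),
    effect_size: float = 0.0,
) -> list[str]:
    lengths = _sample_lengths(rng, n, length_mix)
    peptides = []
    for L in lengths:
        idx = rng.integers(0, 20, size=L)
        for pos in signal_positions:
            if pos <= L and rng.random() < effect_size:
                idx[pos - 1] = rng.choice(_HYDRO_IDX)
        peptides.append("".join(_AA[idx]))
    return peptides


def make_labeled_peptides(spec: FixtureSpec) -> pd.DataFrame:
    """Peptide table with a planted class signal.

    Positives draw signal-position residues from the hydrophobic set
    with probability ``effect_size``; negatives are fully uniform.
    Returns columns ``peptide, label``.
    """
    rng = np.random.default_rng(spec.seed)
    positives = _random_peptides(
        rng, spec.n_positive, spec.length_mix, spec.signal_positions, spec.effect_size
    )
    negatives = _random_peptides(rng, spec.n_negative, spec.length_mix)
    return pd.DataFrame(
        {
            "peptide": positives + negatives,
            "label": [1] * len(positives) + [0] * len(negatives),
        }
    )


def make_property_table(seed: int, n_props: int = 60, n_missing: int = 4) -> str:
    """AAindex1-format flat-file text with ``n_props`` records, of
    which ``n_missing`` contain NA values.

    Values are standard normal per property, so parse -> filter ->
    z-scale is close to an identity on the moments at large n.
    """
    if n_props < 10:
        raise ValueError("need at least 10 properties")
    if not 0 <= n_missing <= n_props:
        raise ValueError("n_missing must be within [0, n_props]")
    rng = np.random.default_rng(seed)
    missing_records = set(rng.choice(n_props, size=n_missing, replace=False).tolist())
    lines: list[str] = []
    for i in range(n_props):
        values = rng.standard_normal(20).round(3)
        tokens = [f"{v:.3f}" for v in values]
        if i in missing_records:
            for j in rng.choice(20, size=int(rng.integers(1, 4)), replace=False):
                tokens[j] = "NA"
        lines.append(f"H SYNT{i:06d}")
        lines.append(f"D Synthetic property scale {i}")
        lines.append(
            "I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V"
        )
        lines.append("   " + "  ".join(tokens[:10]))
        lines.append("   " + "  ".join(tokens[10:]))
        lines.append("//")
    return "\n".join(lines) + "\n"


def make_proteome(
    seed: int,
    total_length: int = 5000,
    planted_peptides: tuple[str, ...] = (),
    protein_length: int = 250,
) -> tuple[str, pd.DataFrame]:
    """Random proteome FASTA text plus a ground-truth mismatch table.

    Planted peptides are written into the proteins as exact substrings
    (min mismatch 0).  For each planted peptide, 1-, 2- and 3-mismatch
    variants are generated and their exact minimum Hamming distance to
    the proteome is recorded by a brute-force scan, giving an oracle
    table with columns ``peptide, true_distance``.
    """
    rng = np.random.default_rng(seed)
    for p in planted_peptides:
        if len(p) > protein_length:
            raise ValueError(f"planted peptide {p!r} longer than a protein")
    n_proteins = max(1, total_length // protein_length)
    proteins = [
        "".join(rng.choice(_AA, size=protein_length)) for _ in range(n_proteins)
    ]
    # sequential non-overlapping placement so plants never clobber each other
    cursors = [int(rng.integers(0, 20)) for _ in range(n_proteins)]
    for i, peptide in enumerate(planted_peptides):
        target = i % n_proteins
        start = cursors[target]
        if start + len(peptide) > protein_length:
            raise ValueError("too many planted peptides for the proteome size")
        s = proteins[target]
        proteins[target] = s[:start] + peptide + s[start + len(peptide):]
        cursors[target] = start + len(peptide) + 1

    fasta_lines = []
    for i, seq in enumerate(proteins):
        fasta_lines.append(f">SYNPROT{i:04d} synthetic random protein")
        for j in range(0, len(seq), 60):
            fasta_lines.append(seq[j : j + 60])
    fasta = "\n".join(fasta_lines) + "\n"

    rows = []
    for peptide in planted_peptides:
        rows.append({"peptide": peptide, "true_distance": 0})
        for k in (1, 2, 3):
            variant = _mutate(rng, peptide, k)
            rows.append(
                {
                    "peptide": variant,
                    "true_distance": _brute_force_min(variant, proteins),
                }
            )
    oracle = pd.DataFrame(rows, columns=["peptide", "true_distance"])
    return fasta, oracle


def _mutate(rng: np.random.Generator, peptide: str, k: int) -> str:
    positions = rng.choice(len(peptide), size=k, replace=False)
    residues = list(peptide)
    for pos in positions:
        alternatives = [a for a in CANONICAL_AA if a != residues[pos]]
        residues[pos] = alternatives[int(rng.integers(0, 19))]
    return "".join(residues)


def _brute_force_min(peptide: str, proteins: list[str]) -> int:
    """Plain per-window Hamming scan (reference oracle)."""
    L = len(peptide)
    best = L
    for seq in proteins:
        for start in range(len(seq) - L + 1):
            d = sum(a != b for a, b in zip(peptide, seq[start : start + L]))
            if d < best:
                best = d
    return best


def make_survival_cohort(spec: FixtureSpec) -> pd.DataFrame:
    """Synthetic patient cohort with exponential survival.

    Patients get a uniform biomarker in [0, 1]; the upper half (by the
    cohort median) has its death hazard multiplied by ``hazard_ratio``.
    Censoring replaces a patient's time with a uniform draw below it at
    rate ``censoring_rate``.  Columns: ``patient_id, os_days, event,
    n_mutations, maxmean_score``.
    """
    if spec.hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    biomarker = rng.uniform(0, 1, size=n)
    high = biomarker > np.median(biomarker)
    hazard = spec.baseline_hazard * np.where(high, spec.hazard_ratio, 1.0)
    times = rng.exponential(1.0 / hazard)
    censored = rng.random(n) < spec.censoring_rate
    os_days = np.where(censored, rng.uniform(0, times), times)
    n_mutations = rng.negative_binomial(5, 5 / (5 + 120.0), size=n)  # mean ~120
    return pd.DataFrame(
        {
            "patient_id": [f"PT{i:03d}" for i in range(n)],
            "os_days": np.round(os_days, 1),
            "event": (~censored).astype(int),
            "n_mutations": n_mutations,
            "maxmean_score": biomarker,
        }
    )


def make_mutation_table(
    seed: int, n_patients: int = 5, mutations_per_patient: int = 3,
    flank: int = 12,
) -> pd.DataFrame:
    """Per-patient mutation table with mutant protein windows
    (single-residue substitutions centered in random flanks)."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        for j in range(mutations_per_patient):
            window = "".join(rng.choice(_AA, size=2 * flank + 1))
            rows.append(
                {
                    "patient_id": f"PT{i:03d}",
                    "mutation_id": f"MUT{i:03d}_{j}",
                    "mutant_protein_window": window,
                    "span_start": flank + 1,
                    "span_end": flank + 1,
                }
            )
    return pd.DataFrame(rows)


def make_benchmark_table(
    seed: int,
    n_positive: int = 67,
    n_negative_recorded: int = 534,
    n_positive_elsewhere: int = 92,
) -> pd.DataFrame:
    """Benchmark-style scored peptide table: positives, recorded
    negatives, and a subset of negatives flagged as positive in other
    assays (to be removed by the exclusion filter).  Scores are noisy
    in a way that ranks positives higher on average."""
    rng = np.random.default_rng(seed)
    peptides = _random_peptides(
        rng, n_positive + n_negative_recorded, ((9, 0.5), (10, 0.3), (11, 0.2))
    )
    labels = np.array([1] * n_positive + [0] * n_negative_recorded)
    flagged = np.zeros(len(labels), dtype=bool)
    neg_idx = np.flatnonzero(labels == 0)
    flagged[rng.choice(neg_idx, size=n_positive_elsewhere, replace=False)] = True
    scores = np.clip(rng.normal(0.35 + 0.25 * labels, 0.18), 0, 1)
    return pd.DataFrame(
        {
            "peptide": peptides,
            "label": labels,
            "positive_elsewhere": flagged,
            "score": scores,
        }
    )
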