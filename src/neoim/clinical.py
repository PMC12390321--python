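"""Downstream clinical analyses.

Three workflows built on the fitted immunogenicity model:

* the max-mean tumor immunogenicity biomarker — for each mutation,
  average the immunogenicity score over every 9-11-mer window covering
  an altered residue, then take the maximum of those per-mutation means
  across the tumor (the score of its most immunogenic region);
* survival stratification — median split of a per-patient biomarker
  within mutation-burden subgroups, Kaplan-Meier curves and the
  two-sample logrank test;
* vaccine-design comparison — per-patient true-positive hit rates for
  two epitope-selection arms, compared with a paired z-test on the
  per-patient hit-rate differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .encoding import MAX_LENGTH, MIN_LENGTH, _validate_peptide

Scorer = Callable[[Sequence[str]], np.ndarray]

DEFAULT_MUTATION_THRESHOLD = 100  # mutations per exome


@dataclass(frozen=True)
class MutationContext:
    """A mutation with its mutant protein sequence context.

    ``mutated_span`` is the 1-based inclusive range of altered residues
    within ``mutant_protein_window`` (a multi-residue span represents
    frameshift/fusion neo-sequence).
    """

    patient_id: str
    mutation_id: str
    mutant_protein_window: str
    mutated_span: tuple[int, int]

    def __post_init__(self) -> None:
        window = self.mutant_protein_window.upper()
        object.__setattr__(self, "mutant_protein_window", window)
        _validate_peptide(window, lengths=(1, 100_000))
        start, end = self.mutated_span
        if not (1 <= start <= end <= len(window)):
            raise ValueError(
                f"mutation {self.mutation_id}: span {self.mutated_span} outside "
                f"window of length {len(window)}"
            )


def enumerate_covering_peptides(context: MutationContext) -> list[str]:
    """All unique 9-11-mer windows containing at least one altered
    residue, ordered by length then start position.

    A window shorter than 9 residues yields an empty list with a
    warning (nothing is enumerable).
    """
    window = context.mutant_protein_window
    if len(window) < MIN_LENGTH:
        warnings.warn(
            f"mutation {context.mutation_id}: window shorter than {MIN_LENGTH} "
            "residues, no peptides enumerated",
            stacklevel=2,
        )
        return []
    span_start, span_end = context.mutated_span  # 1-based inclusive
    seen: set[str] = set()
    peptides: list[str] = []
    for length in range(MIN_LENGTH, MAX_LENGTH + 1):
        for start in range(len(window) - length + 1):  # 0-based
            first, last = start + 1, start + length
            if first <= span_end and last >= span_start:  # overlaps the span
                peptide = window[start : start + length]
                if peptide not in seen:
                    seen.add(peptide)
                    peptides.append(peptide)
    return peptides


def tumor_maxmean(mutations: Iterable[MutationContext], scorer: Scorer) -> float:
    """The max-mean tumor immunogenicity biomarker.

    ``scorer`` maps a peptide list to immunogenicity scores in [0, 1]
    (e.g. ``results.score_peptides`` from a fitted model).  Returns the
    highest per-mutation mean score; adding mutations can only raise it.
    """
    means: list[float] = []
    for context in mutations:
        peptides = enumerate_covering_peptides(context)
        if not peptides:
            continue
        scores = np.asarray(scorer(peptides), dtype=float)
        means.append(float(scores.mean()))
    if not means:
        raise ValueError("no scorable peptides in any mutation")
    return max(means)


def patient_maxmean_table(
    mutations: pd.DataFrame, scorer: Scorer
) -> pd.DataFrame:
    """Per-patient max-mean biomarker from a mutation table with columns
    ``patient_id, mutation_id, mutant_protein_window, span_start, span_end``."""
    rows = []
    for patient_id, group in mutations.groupby("patient_id", sort=False):
        contexts = [
            MutationContext(
                patient_id=str(patient_id),
                mutation_id=str(r.mutation_id),
                mutant_protein_window=r.mutant_protein_window,
                mutated_span=(int(r.span_start), int(r.span_end)),
            )
            for r in group.itertuples()
        ]
        rows.append(
            {"patient_id": patient_id, "maxmean_score": tumor_maxmean(contexts, scorer)}
        )
    return pd.DataFrame(rows)


def median_split(records: pd.DataFrame, biomarker_field: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split patients at the median biomarker value.

    Values <= median go to the low group (ties at the median land low,
    a deterministic convention), values > median to the high group.
    Returns ``(high, low)``.
    """
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    values = records[biomarker_field].to_numpy(dtype=float)
    if np.all(values == values[0]):
        raise ValueError(f"all {biomarker_field!r} values identical; split undefined")
    median = float(np.median(values))
    low = records.loc[values <= median]
    high = records.loc[values > median]
    return high, low


@dataclass
class LogrankResult:
    """Kaplan-Meier curves for two groups and their logrank comparison."""

    km_a: pd.DataFrame  # columns: time, survival
    km_b: pd.DataFrame
    statistic: float
    p_value: float


def km_logrank(
    group_a: pd.DataFrame,
    group_b: pd.DataFrame,
    time_col: str = "os_days",
    event_col: str = "event",
) -> LogrankResult:
    """Kaplan-Meier product-limit estimates and the two-sample logrank
    test (chi-square with 1 df)."""
    if group_a.empty or group_b.empty:
        raise ValueError("both groups must be nonempty")
    events_total = group_a[event_col].sum() + group_b[event_col].sum()
    if events_total == 0:
        raise ValueError("no observed events in either group")

    curves = []
    for group in (group_a, group_b):
        km = KaplanMeierFitter()
        km.fit(group[time_col], group[event_col])
        curve = km.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        curves.append(curve)
    test = logrank_test(
        group_a[time_col], group_b[time_col],
        event_observed_A=group_a[event_col], event_observed_B=group_b[event_col],
    )
    return LogrankResult(
        km_a=curves[0],
        km_b=curves[1],
        statistic=float(test.test_statistic),
        p_value=float(test.p_value),
    )


def stratified_survival_analysis(
    records: pd.DataFrame,
    biomarker_field: str,
    mutation_threshold: int = DEFAULT_MUTATION_THRESHOLD,
    time_col: str = "os_days",
    event_col: str = "event",
) -> dict[str, LogrankResult]:
    """Median-split survival comparison within the low- and
    high-mutation-burden subgroups (burden cut at ``mutation_threshold``
    mutations per exome)."""
    out: dict[str, LogrankResult] = {}
    low_burden = records.loc[records["n_mutations"] <= mutation_threshold]
    high_burden = records.loc[records["n_mutations"] > mutation_threshold]
    for name, subgroup in (("low_burden", low_burden), ("high_burden", high_burden)):
        if len(subgroup) < 2:
            continue
        high, low = median_split(subgroup, biomarker_field)
        out[name] = km_logrank(high, low, time_col=time_col, event_col=event_col)
    return out


@dataclass(frozen=True)
class PairedZResult:
    mean_hit_rate_a: float
    mean_hit_rate_b: float
    mean_difference: float
    z: float
    p_value: float
    n_patients: int


def _hit_rates(designs: pd.DataFrame) -> pd.Series:
    """Per-patient fraction of selected epitopes with a confirmed
    immune response, from columns ``patient_id, responded``."""
    if designs.empty:
        raise ValueError("empty design table")
    grouped = designs.groupby("patient_id")["responded"]
    counts = grouped.count()
    if (counts < 1).any():
        raise ValueError("every patient needs at least one epitope")
    return grouped.mean()


def hitrate_paired_z(
    designs_a: pd.DataFrame, designs_b: pd.DataFrame
) -> PairedZResult:
    """Paired z-test on per-patient hit-rate differences (arm B minus
    arm A): z = mean(d) / (sd(d) / sqrt(n)) with the sample sd, p
    two-sided normal.

    Raises on fewer than two patients, mismatched patient sets, or a
    degenerate zero-variance difference vector.
    """
    rates_a = _hit_rates(designs_a)
    rates_b = _hit_rates(designs_b)
    if set(rates_a.index) != set(rates_b.index):
        raise ValueError("the two arms cover different patient sets")
    rates_b = rates_b.reindex(rates_a.index)
    d = (rates_b - rates_a).to_numpy(dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("need at least 2 patients for a paired test")
    if np.allclose(d, d.mean()) and not np.allclose(d, 0):
        raise ValueError("degenerate: all per-patient differences identical (sd = 0)")
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        # identical designs: no evidence either way
        z, p = 0.0, 1.0
    else:
        z = float(d.mean() / (sd / np.sqrt(n)))
        p = float(2 * stats.norm.sf(abs(z)))
    return PairedZResult(
        mean_hit_rate_a=float(rates_a.mean()),
        mean_hit_rate_b=float(rates_b.mean()),
        mean_difference=float(d.mean()),
        z=z,
        p_value=p,
        n_patients=n,
    )
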