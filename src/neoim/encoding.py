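"""Physicochemical encoding of 9-11-mer peptides.

Each residue is embedded in 10 dimensions by PCA over a z-scaled
amino-acid x property matrix (AAindex1 scales with incomplete properties
removed).  A peptide of length L fills slots 1..L of 11 N-terminally
anchored position slots; the trailing slots of 9- and 10-mers are
zero-imputed.  Eight whole-peptide descriptors (molecular weight,
aromaticity, instability index, isoelectric point, GRAVY, and helix /
turn / sheet fractions, all via Bio.SeqUtils.ProtParam) complete the
ordered 118-dimensional feature vector:

    11 slots x 10 components + 8 global descriptors = 118.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .aaindex import CANONICAL_AA, PropertyMatrix

N_COMPONENTS = 10
N_SLOTS = 11
GLOBAL_DESCRIPTOR_NAMES = (
    "molecular_weight",
    "aromaticity",
    "instability_index",
    "isoelectric_point",
    "gravy",
    "helix_fraction",
    "turn_fraction",
    "sheet_fraction",
)
N_FEATURES = N_SLOTS * N_COMPONENTS + len(GLOBAL_DESCRIPTOR_NAMES)

MIN_LENGTH, MAX_LENGTH = 9, 11

#: Ordered labels of the 118 feature vector entries.
FEATURE_LABELS: tuple[str, ...] = tuple(
    f"pos{slot}_pc{pc}" for slot in range(1, N_SLOTS + 1) for pc in range(1, N_COMPONENTS + 1)
) + GLOBAL_DESCRIPTOR_NAMES


class PeptideError(ValueError):
    """Invalid peptide sequence (length or alphabet)."""


def _validate_peptide(peptide: str, lengths: tuple[int, int] = (MIN_LENGTH, MAX_LENGTH)) -> str:
    peptide = peptide.upper()
    lo, hi = lengths
    if not lo <= len(peptide) <= hi:
        raise PeptideError(
            f"peptide {peptide!r} has length {len(peptide)}, expected {lo}-{hi}"
        )
    for residue in peptide:
        if residue not in CANONICAL_AA:
            raise PeptideError(f"peptide {peptide!r}: nonstandard residue {residue!r}")
    return peptide


@dataclass
class ResidueEncoder:
    """Fitted per-residue 10-dimensional embedding.

    ``embedding[i]`` is the projection of amino acid ``CANONICAL_AA[i]``
    onto the first 10 principal components of the z-scaled property
    matrix; ``loadings`` maps a z-scaled property row to that embedding.
    """

    property_ids: tuple[str, ...]
    means: np.ndarray              # (P',)
    sds: np.ndarray                # (P',)
    loadings: np.ndarray           # (P', n_components)
    embedding: np.ndarray          # (20, n_components)
    variance_explained: np.ndarray  # (n_components,)
    amino_acids: str = CANONICAL_AA
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {aa: i for i, aa in enumerate(self.amino_acids)}

    @property
    def n_components(self) -> int:
        return self.embedding.shape[1]

    def vector(self, residue: str) -> np.ndarray:
        try:
            return self.embedding[self._index[residue]]
        except KeyError:
            raise PeptideError(f"nonstandard residue {residue!r}") from None

    def save(self, path: str | Path) -> None:
        """Serialize to a single .npz archive (round-trip lossless)."""
        np.savez(
            path,
            property_ids=np.array(self.property_ids),
            means=self.means,
            sds=self.sds,
            loadings=self.loadings,
            embedding=self.embedding,
            variance_explained=self.variance_explained,
            amino_acids=np.array(self.amino_acids),
        )

    @classmethod
    def load(cls, path: str | Path) -> "ResidueEncoder":
        with np.load(path, allow_pickle=False) as archive:
            return cls(
                property_ids=tuple(archive["property_ids"].tolist()),
                means=archive["means"],
                sds=archive["sds"],
                loadings=archive["loadings"],
                embedding=archive["embedding"],
                variance_explained=archive["variance_explained"],
                amino_acids=str(archive["amino_acids"]),
            )


def fit_residue_encoder(
    props: PropertyMatrix, n_components: int = N_COMPONENTS, seed: int | None = None
) -> ResidueEncoder:
    """Fit the per-residue PCA embedding.

    Incomplete properties are dropped, the remainder z-scaled across the
    20 amino acids (population variance), and the residues projected on
    the leading ``n_components`` principal components, ordered by
    decreasing explained variance.  Each component is oriented so that
    its largest-magnitude loading is positive, making the fit
    reproducible across linear-algebra backends.  The fit is exactly
    deterministic; ``seed`` is accepted for interface stability and
    unused.

    Raises
    ------
    ValueError
        If fewer than ``n_components`` complete properties remain, or a
        retained property is constant across amino acids.
    """
    complete = props.filter_complete()
    if complete.n_properties < n_components:
        raise ValueError(
            f"only {complete.n_properties} complete properties; "
            f"need at least {n_components}"
        )
    X = complete.values.astype(float)
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # population (ddof=0), fixed for reproducibility
    constant = np.flatnonzero(sds <= 1e-10 * (np.abs(means) + 1))
    if constant.size:
        bad = ", ".join(complete.properties[i] for i in constant[:5])
        raise ValueError(f"constant properties (z-scaling undefined): {bad}")
    Z = (X - means) / sds

    # PCA on the 20 observations via SVD of the centered (column means are
    # already 0 after z-scaling) matrix.
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    total_variance = float((S**2).sum())
    ratio = (S[:n_components] ** 2) / total_variance
    loadings = Vt[:n_components].T            # (P', k)
    scores = U[:, :n_components] * S[:n_components]

    # deterministic sign: largest-|loading| entry of each component positive
    for k in range(n_components):
        pivot = np.argmax(np.abs(loadings[:, k]))
        if loadings[pivot, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1

    return ResidueEncoder(
        property_ids=complete.properties,
        means=means,
        sds=sds,
        loadings=loadings,
        embedding=scores,
        variance_explained=ratio,
    )


def global_descriptors(peptide: str) -> np.ndarray:
    """Eight whole-peptide descriptors, in the fixed order of
    :data:`GLOBAL_DESCRIPTOR_NAMES`.

    Molecular weight is in daltons (monoisotopic-average residue masses
    minus the waters lost on condensation, as computed by ProtParam);
    aromaticity is the F/W/Y fraction; GRAVY is the mean Kyte-Doolittle
    hydropathy.
    """
    peptide = _validate_peptide(peptide, lengths=(1, 10_000))
    analysis = ProteinAnalysis(peptide)
    helix, turn, sheet = analysis.secondary_structure_fraction()
    return np.array(
        [
            analysis.molecular_weight(),
            analysis.aromaticity(),
            analysis.instability_index(),
            analysis.isoelectric_point(),
            analysis.gravy(),
            helix,
            turn,
            sheet,
        ]
    )


@dataclass(frozen=True)
class FeatureVector:
    """A peptide with its ordered 118-dimensional feature vector."""

    peptide: str
    values: np.ndarray
    slot_labels: tuple[str, ...] = FEATURE_LABELS

    def __post_init__(self) -> None:
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}")


def encode_peptide(peptide: str, encoder: ResidueEncoder) -> FeatureVector:
    """Encode one 9-11-mer into its 118-dimensional feature vector.

    Residues 1..L fill slots 1..L in sequence order; for 9- and 10-mers
    the trailing slots are exactly zero.
    """
    peptide = _validate_peptide(peptide)
    positional = np.zeros((N_SLOTS, encoder.n_components))
    for i, residue in enumerate(peptide):
        positional[i] = encoder.vector(residue)
    values = np.concatenate([positional.ravel(), global_descriptors(peptide)])
    return FeatureVector(peptide=peptide, values=values)


def encode_peptides(peptides: list[str] | pd.Series, encoder: ResidueEncoder) -> pd.DataFrame:
    """Encode a batch of peptides into a (n, 118) feature frame.

    The index holds the peptides; columns follow :data:`FEATURE_LABELS`.
    """
    rows = [encode_peptide(p, encoder).values for p in peptides]
    return pd.DataFrame(rows, index=list(peptides), columns=list(FEATURE_LABELS))
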