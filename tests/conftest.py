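import numpy as np
import pytest

from neoim import simulate as sim
from neoim.aaindex import parse_property_table
from neoim.encoding import fit_residue_encoder


@pytest.fixture(scope="session")
def property_matrix():
    """A parsed synthetic AAindex table: 60 properties, 4 with NA."""
    return parse_property_table(sim.make_property_table(seed=7, n_props=60, n_missing=4))


@pytest.fixture(scope="session")
def encoder(property_matrix):
    return fit_residue_encoder(property_matrix)


@pytest.fixture(scope="session")
def small_planted_data(encoder):
    """Planted-signal peptides (reduced size for unit tests) with their
    feature matrix."""
    from neoim.encoding import encode_peptides

    spec = sim.FixtureSpec(seed=21, n_positive=300, n_negative=900)
    table = sim.make_labeled_peptides(spec)
    X = encode_peptides(table["peptide"].tolist(), encoder)
    return table, X


@pytest.fixture(scope="session")
def proteome_with_oracle(tmp_path_factory):
    """A 5 kaa synthetic proteome with planted peptides and a
    brute-force ground-truth distance table."""
    from neoim.dataset import ReferenceProteome

    planted = ("ACDEFGHIK", "WWWWWYYYYK", "MKTAYIAKQRQ")
    fasta, oracle = sim.make_proteome(seed=3, total_length=5000, planted_peptides=planted)
    path = tmp_path_factory.mktemp("proteome") / "ref.fasta"
    path.write_text(fasta)
    return ReferenceProteome.from_fasta(path), oracle, planted


def brute_force_min_mismatch(peptide: str, proteome) -> int:
    """Independent exhaustive per-window Hamming scan (test oracle)."""
    L = len(peptide)
    best = L
    for seq in proteome.sequences.values():
        for start in range(len(seq) - L + 1):
            d = sum(a != b for a, b in zip(peptide, seq[start : start + L]))
            best = min(best, d)
    return best


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
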