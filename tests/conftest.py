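import numpy as np
import pytest

import phyloconv as pc


@pytest.fixture(scope="session")
def wag():
    return pc.build_model("WAG", gamma_shape=1.0, n_categories=4)


@pytest.fixture(scope="session")
def sim_tree():
    return pc.default_tree()


@pytest.fixture(scope="session")
def small_gene(sim_tree, wag):
    """One simulated 200-residue gene on the packaged tree."""
    return pc.simulate_alignment(sim_tree, wag, 200, seed=12345, gene_id="g_small")


@pytest.fixture(scope="session")
def small_fit(small_gene, sim_tree):
    spec = pc.build_model(
        "WAG", frequencies="empirical", alignment=small_gene,
        gamma_shape=1.0, n_categories=4,
    )
    return pc.fit_gene(small_gene, sim_tree, spec)


def make_aln(seqs: dict[str, str], tag: str = "aa", gene_id: str = "g") -> pc.Alignment:
    taxa = list(seqs)
    if tag == "codon":
        mat = np.array(
            [[s[i : i + 3] for i in range(0, len(s), 3)] for s in seqs.values()],
            dtype="U3",
        )
    else:
        mat = np.array([list(s) for s in seqs.values()], dtype="U1")
    return pc.Alignment(taxa, mat, tag, gene_id)
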