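import pytest

from knockkit import FixtureSpec, design_genome, generate_fixture
from knockkit.markers import builtin_marker


@pytest.fixture(scope="session")
def small_world():
    """A small synthetic genome with giants and edge genes, fully designed.

    20 genes on 4 contigs: one giant (>50 kb) ORF, two genes truncated by a
    contig edge, the rest interior with clean flanks. Designs carry tails and
    verified junction screens.
    """
    spec = FixtureSpec(
        seed=1,
        n_contigs=4,
        n_genes=20,
        n_giant_genes=1,
        edge_gene_count=2,
        contig_length_range=(150_000, 200_000),
    )
    genome, genes = generate_fixture(spec)
    marker = builtin_marker("pyr4")
    designs, summary = design_genome(genome, genes, marker_system=marker, screen=True)
    return {
        "spec": spec,
        "genome": genome,
        "genes": genes,
        "marker": marker,
        "designs": designs,
        "summary": summary,
    }


@pytest.fixture(scope="session")
def full_design(small_world):
    """One interior full-status design with tails and a screen."""
    return next(
        d for d in small_world["designs"]
        if d.status == "full" and d.flanks.mode == "standard" and d.screen
    )


@pytest.fixture(scope="session")
def giant_design(small_world):
    return next(
        d for d in small_world["designs"] if d.flanks.mode == "internal_3prime"
    )
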