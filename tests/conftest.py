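import numpy as np
import pytest

from trnaswitch.records import TRNAGeneRecord


def make_sequence(rng: np.random.Generator, length: int = 72) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def make_record(
    seq: str,
    anticodon_start: int = 33,
    gene_id: str = "Sp_tRNA-Arg-CCT-1-1",
    species: str = "Sp",
    cove: float = 60.0,
    aa: str = "Arg",
) -> TRNAGeneRecord:
    return TRNAGeneRecord(
        gene_id=gene_id,
        species_id=species,
        amino_acid=aa,
        anticodon=seq[anticodon_start : anticodon_start + 3],
        anticodon_start=anticodon_start,
        sequence=seq,
        cove_score=cove,
    )


def random_record(
    rng: np.random.Generator, gene_id: str, length: int = 72, species: str = "Sp"
) -> TRNAGeneRecord:
    seq = make_sequence(rng, length)
    start = int(rng.integers(0, length - 2))
    return make_record(
        seq, anticodon_start=start, gene_id=gene_id, species=species
    )


def brute_force_patristic(tree) -> dict[tuple[str, str], float]:
    """Independent patristic oracle: shortest paths on the tree's edge graph."""
    import networkx as nx

    g = nx.Graph()
    for node in tree.traverse(include_self=False):
        g.add_edge(id(node.parent), id(node), weight=node.length or 0.0)
    tips = {t.name: id(t) for t in tree.tips()}
    lengths = dict(nx.all_pairs_dijkstra_path_length(g, weight="weight"))
    out = {}
    for a, na in tips.items():
        for b, nb in tips.items():
            out[(a, b)] = 0.0 if a == b else lengths[na][nb]
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20231203)
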