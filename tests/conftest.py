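import pandas as pd
import pytest

from exoregulon import synth


@pytest.fixture(scope="session")
def small_dataset():
    """A compact seeded study: 200 kb genome, 160 genes, 20 planted sites.

    Background is denser than the genome-scale default so that the top-5%
    noise floor still sits at the background level (as it does at full
    genome size, where background positions vastly outnumber site positions).
    """
    return synth.simulate_dataset(
        genome_spec=synth.GenomeSpec(length=200_000, n_genes=160),
        read_model=synth.ReadModel(background_rate=0.03),
        n_sites=20,
        regulatory_fraction=0.6,
        n_direct=8,
        seed=11,
    )


@pytest.fixture()
def toy_genes():
    """Six genes on both strands with operons, for hand-checkable assignments."""
    rows = [
        ("gA", "+", 1000, 1600, "op1", "C"),
        ("gB", "+", 1700, 2400, "op1", "E"),
        ("gC", "-", 3000, 3800, "op2", "K"),
        ("gD", "+", 4800, 5600, "op3", "K"),
        ("gE", "-", 6000, 6700, "op4", "P"),
        ("gF", "+", 7000, 7900, "op5", "S"),
    ]
    return pd.DataFrame(
        [
            {"gene_id": g, "name": g, "strand": s, "start": a, "end": b,
             "operon_id": op, "cog": c}
            for g, s, a, b, op, c in rows
        ]
    )
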