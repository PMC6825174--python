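import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from phyloprimer import simulate


@pytest.fixture(scope="session")
def planted_single_motif():
    """20 sequences x 200 aa with a 9-mer at 90% per-column conservation.

    Background residues diverge at rate 0.95 (effectively i.i.d.), so only the
    planted columns carry signal.
    """
    spec = simulate.FamilySpec(
        n_species=20,
        protein_length=200,
        rates=[0.95] * 20,
        motifs=[simulate.PlantedMotif("WLQHPNGKC", 80, 0.9)],
        seed=11,
    )
    prot, cds, truth = simulate.simulate_family(spec)
    return prot, cds, truth


@pytest.fixture(scope="session")
def family6():
    """6-species family with 3 fully conserved planted motifs and codon wobble."""
    prot, cds, truth = simulate.simulate_family(simulate.demo_family_spec(seed=7))
    return prot, cds, truth


@pytest.fixture(scope="session")
def planted_expression():
    expr, truth = simulate.simulate_expression(simulate.ExprSpec(seed=5))
    return expr, truth
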