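import io

import pytest

from ystrkit import (
    YFILER_PLUS_PANEL,
    read_genotype_table,
    simulate_populations,
)
from ystrkit.simulate import SimulationConfig

EXAMPLE_TSV = "\t".join(["SampleID", "Population", *YFILER_PLUS_PANEL.loci]) + "\n"


def _row(sample_id, population, overrides=None):
    """One genotype row built on the founder-like base haplotype."""
    from ystrkit.simulate import FOUNDER_HAPLOTYPE

    cells = []
    for locus in YFILER_PLUS_PANEL.loci:
        if overrides and locus in overrides:
            cells.append(overrides[locus])
        else:
            reps = FOUNDER_HAPLOTYPE[locus]
            cells.append(",".join(str(int(r)) for r in reps))
    return "\t".join([sample_id, population, *cells]) + "\n"


@pytest.fixture
def example_table():
    """Small two-population table with every artifact class represented."""
    text = EXAMPLE_TSV
    text += _row("A1", "CKT", {"DYS19": "15,17"})  # duplicated single-copy
    text += _row("A2", "CKT", {"DYS627": "19.2"})  # intermediate allele
    text += _row("A3", "CKT", {"DYS448": "-"})  # null allele
    text += _row("A4", "CKT", {"DYS385": "18,13"})  # unsorted multicopy cell
    text += _row("B1", "SUT", {"DYS576": "19"})  # differs only outside Yfiler
    text += _row("B2", "SUT", {"DYS390": "25"})
    text += _row("B3", "SUT")
    return text


@pytest.fixture
def example_samples(example_table):
    return read_genotype_table(io.StringIO(example_table), YFILER_PLUS_PANEL)


@pytest.fixture(scope="session")
def simulated_pair():
    """Two moderately diverged SMM populations, artifact-free."""
    cfg = SimulationConfig(
        n_samples=(25, 25), divergence_generations=(0, 200),
        within_generations=100, seed=11,
    )
    samples, truth = simulate_populations(cfg)
    return samples, truth
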