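"""Shared fixtures: a hand-built mini-plastome and the default synthetic run."""

from __future__ import annotations

import pytest

from plastedit.curated import build_curated_reference
from plastedit.plastome import GeneFeature, PlastomeSequence, revcomp
from plastedit.simulate import SimulationConfig, simulate_dataset

# spliced coding sequences of the two hand-built genes (60 bp each)
SPLICED_P = "ATGTCGCATCCAGTC" + "GCT" * 13 + "TAATAA"
SPLICED_M = "ATGCCATCGCATGTC" + "GCT" * 13 + "TAATAA"


@pytest.fixture(scope="session")
def mini_genome() -> PlastomeSequence:
    """400 bp genome hosting a 2-exon plus CDS, a minus CDS and an rRNA locus."""
    bases = list("A" * 400)
    bases[10:40] = SPLICED_P[:30]   # geneP exon 1: 11-40
    bases[60:90] = SPLICED_P[30:]   # geneP exon 2: 61-90
    bases[100:160] = revcomp(SPLICED_M)  # geneM (minus): 101-160
    bases[200:260] = ("ACGT" * 15)  # rrnX: 201-260
    return PlastomeSequence(id="mini", bases="".join(bases))


@pytest.fixture(scope="session")
def mini_features() -> list[GeneFeature]:
    return [
        GeneFeature(gene="geneP", ftype="CDS", strand="+", exons=((11, 40), (61, 90))),
        GeneFeature(gene="geneP", ftype="intron", strand="+", exons=((41, 60),)),
        GeneFeature(gene="geneM", ftype="CDS", strand="-", exons=((101, 160),)),
        GeneFeature(gene="rrnX", ftype="rRNA", strand="+", exons=((201, 260),)),
    ]


@pytest.fixture(scope="session")
def curated_ref():
    return build_curated_reference()


@pytest.fixture(scope="session")
def default_run():
    """The standard study-condition simulation (seed 1), shared across tests."""
    config = SimulationConfig(seed=1)
    reference, pileups = simulate_dataset(config)
    return config, reference, pileups


@pytest.fixture(scope="session")
def clean_run():
    """Artifact-free, error-free simulation: edits are the only signal."""
    config = SimulationConfig(
        seed=7, genome_length=12_000, n_genes=4, n_edit_sites=10,
        coverage={"total": 100.0, "rrna_depleted": 100.0, "mrna": 8.0},
        samples=("S1",), libraries=("total",),
        carryover_rate=0.0, base_error=0.0,
        n_rrna_mod_sites=0, junction_rate=0.0,
    )
    reference, pileups = simulate_dataset(config)
    return config, reference, pileups
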