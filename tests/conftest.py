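"""Shared synthetic-data fixtures: a mini genome with planted unique and
duplicated segments, and a mini transcriptome with isoforms."""

from __future__ import annotations

import numpy as np
import pytest

from probecraft.fixtures import (FixtureSpec, PlantedDuplication, PlantedGene,
                                 generate_fixture)


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=probs)])


@pytest.fixture(scope="session")
def chromatin_fixture():
    """Two 6-kb contigs; three 300-nt chromatin targets on ctg1; a 150-nt
    segment of target 2 duplicated onto ctg2; a plus-strand gene over
    target 3 and a minus-strand gene downstream (for antisense tests)."""
    spec = FixtureSpec(
        seed=11, n_contigs=2, contig_length=6000, gc_target=55.0,
        planted_genes=(
            PlantedGene("G1", "TX1", "ctg1", 2500, 2900, "+",
                        exons=((2550, 2700),)),
            PlantedGene("G2", "TX2", "ctg1", 3500, 3900, "-",
                        exons=((3550, 3700),)),
        ),
        planted_duplications=(
            PlantedDuplication("ctg1", 1550, 1700, "ctg2", 4000),
        ),
    )
    return generate_fixture(spec)


@pytest.fixture(scope="session")
def rna_fixture():
    """One 9-kb contig with five genes; G5 has two isoforms sharing an
    exon. Spliced lengths are a few hundred nt so each transcript yields
    several probes."""
    genes = (
        PlantedGene("G1", "TX1", "ctg1", 200, 900, "+", ((250, 650),)),
        PlantedGene("G2", "TX2", "ctg1", 1200, 1900, "+", ((1250, 1650),)),
        PlantedGene("G3", "TX3", "ctg1", 2200, 2900, "-", ((2250, 2650),)),
        PlantedGene("G4", "TX4", "ctg1", 3200, 3900, "+", ((3250, 3650),)),
        PlantedGene("G5", "TX5A", "ctg1", 4200, 5200, "+",
                    ((4250, 4550), (4700, 4900))),
        PlantedGene("G5", "TX5B", "ctg1", 5400, 5800, "+", ((5450, 5750),)),
    )
    # NB: TX5B is a second G5 transcript at a separate locus (the generator
    # forbids overlapping spans); isoform sharing is exercised separately.
    return generate_fixture(FixtureSpec(seed=23, n_contigs=1,
                                        contig_length=9000, gc_target=55.0,
                                        planted_genes=genes))


@pytest.fixture(scope="session")
def chromatin_dir(chromatin_fixture, tmp_path_factory):
    d = tmp_path_factory.mktemp("chromatin_fx")
    chromatin_fixture.write(d)
    return d


@pytest.fixture(scope="session")
def rna_dir(rna_fixture, tmp_path_factory):
    d = tmp_path_factory.mktemp("rna_fx")
    rna_fixture.write(d)
    return d
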