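import numpy as np
import pandas as pd
import pytest

from rdhprofiler import synthetic as syn
from rdhprofiler import coverage as cov


@pytest.fixture(scope="session")
def small_catalog():
    """20 genomes x 100 groups with 0.04 copies/genome of the target."""
    return syn.generate_reference_catalog(
        n_genomes=20, n_groups=100, universal_fraction=0.35,
        target_family_rate=0.04, seed=1)


@pytest.fixture(scope="session")
def small_markers(small_catalog):
    return cov.select_universal_single_copy(small_catalog)


@pytest.fixture(scope="session")
def small_metagenome(small_catalog):
    """Interval-only metagenome from the small community."""
    contigs, reads, calls, placements, truth = syn.generate_metagenome(
        small_catalog, None, n_clones=1200, seed=2, emit_sequences=False)
    return calls, placements, truth


@pytest.fixture()
def planted_community():
    """Sequence-level community with planted rdhA/rdhB loci and decoys."""
    cat = syn.generate_reference_catalog(10, 40, 0.3, 0.0, seed=5)
    contigs, reads, calls, placements, _ = syn.generate_metagenome(
        cat, None, n_clones=20, seed=6)
    contigs, calls, planted = syn.plant_rdh_loci(
        contigs, calls, n_rdhA=10, motif_config=syn.MotifConfig(tat_prob=0.0),
        with_rdhB=1.0, seed=7,
        decoy_kinds=("long", "few_tm", "far"))
    return contigs, calls, planted


def translate_gene(contigs: dict, row) -> str:
    from Bio.Seq import Seq
    return str(Seq(contigs[row.contig][row.start:row.end]).translate())
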