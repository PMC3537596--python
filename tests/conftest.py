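"""Shared fixtures: small synthetic communities generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

import metasep as ms


def make_reads(seqs1: list[str], seqs2: list[str] | None = None) -> ms.ReadPairSet:
    """Hand-built ReadPairSet; mate 2 defaults to the reverse complement."""
    from metasep.lmer_core import revcomp

    if seqs2 is None:
        seqs2 = [revcomp(s) for s in seqs1]
    return ms.ReadPairSet(
        ids=[f"r{i}" for i in range(len(seqs1))],
        mates1=list(seqs1),
        mates2=list(seqs2),
        L=len(seqs1[0]),
    )


@pytest.fixture(scope="session")
def single_genome_sim():
    """One clean 20 kb genome at effective coverage 20, error-free."""
    spec = ms.CommunitySpec(genome_lengths=[20_000], coverage=20.0, seed=42)
    truth, reads, origin = ms.simulate(spec)
    return spec, truth, reads, origin


@pytest.fixture(scope="session")
def two_genome_sim():
    """Two 20 kb genomes, no planted repeats, equal abundance."""
    spec = ms.CommunitySpec(genome_lengths=[20_000, 20_000], coverage=20.0, seed=7)
    truth, reads, origin = ms.simulate(spec)
    return spec, truth, reads, origin


@pytest.fixture(scope="session")
def repeat_genome_sim():
    """One 40 kb genome with 5% duplicated content (copy number 2)."""
    spec = ms.CommunitySpec(
        genome_lengths=[40_000],
        coverage=20.0,
        individual_repeat_fraction=0.05,
        seed=13,
    )
    truth, reads, origin = ms.simulate(spec)
    return spec, truth, reads, origin


@pytest.fixture(scope="session")
def single_counts(single_genome_sim):
    _, _, reads, _ = single_genome_sim
    return ms.count_lmers(reads, 20)
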