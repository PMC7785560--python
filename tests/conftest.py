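"""Shared fixtures: toy germline and simulated datasets (all seeded)."""

from __future__ import annotations

import numpy as np
import pytest

from igrescue import make_toy_germline, simulate_repertoire
from igrescue.simulate import (
    FragmentModel,
    fragment_and_damage,
    make_igseq_reads,
    make_rnaseq_reads,
)


@pytest.fixture(scope="session")
def germline():
    return make_toy_germline(seed=7)


@pytest.fixture(scope="session")
def dominant_repertoire(germline):
    """Heavy-chain repertoire: dominant clone at 0.6 over 50 background."""
    return simulate_repertoire(
        germline, 51, 0.6, shm_rate=0.02, seed=11, locus="IGH",
        dominant_nonsilent_shm=15,
    )


def single_clone_readset(
    germline,
    seed: int,
    n_shm: int = 15,
    coverage: float = 20.0,
    error_rate: float = 0.0,
    damage_rate: float = 0.0,
    read_len: int = 180,
    paired: bool = False,
):
    """One clone, fragmented at the given coverage; returns (clone, reads)."""
    clones = simulate_repertoire(
        germline, 1, 1.0, seed=seed, locus="IGH", dominant_nonsilent_shm=n_shm
    )
    clone = clones[0]
    model = FragmentModel(
        meanlog=float(np.log(120.0)), sdlog=0.25, min_len=60, max_len=180,
        damage_rate=damage_rate,
    )
    n_frag = int(coverage * len(clone.full_transcript_nt) / 120)
    frags, _ = fragment_and_damage(clones, model, n_frag, seed=seed + 1)
    r1, r2, _ = make_rnaseq_reads(
        frags, read_len=read_len, paired=paired, error_rate=error_rate,
        seed=seed + 2,
    )
    return clone, r1 + (r2 or [])


@pytest.fixture(scope="session")
def noisy_scenario(germline, dominant_repertoire):
    """Dominant clone at 30x with 0.5% read error and FFPE damage."""
    clones = dominant_repertoire
    c0 = clones[0]
    model = FragmentModel(
        meanlog=float(np.log(120.0)), sdlog=0.25, min_len=60, max_len=180,
        damage_rate=0.002,
    )
    n_frag = int(30 * len(c0.full_transcript_nt) / 120 / 0.6)
    frags, _ = fragment_and_damage(clones, model, n_frag, seed=21)
    r1, r2, _ = make_rnaseq_reads(
        frags, read_len=150, paired=True, error_rate=0.005, seed=22
    )
    return clones, r1 + r2


@pytest.fixture(scope="session")
def igseq_small(germline, dominant_repertoire):
    """2000 Ig-seq read pairs of the dominant-clone repertoire, 0.5% error."""
    r1, r2, truth = make_igseq_reads(
        dominant_repertoire, n_reads=2000, error_rate=0.005, seed=5
    )
    return r1, r2, truth
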