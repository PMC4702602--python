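"""Shared fixtures: small synthetic genomes, truth tables and tag tracks.

Simulations are session-scoped so that expensive fixtures (the full
geometry-recovery datasets) are built once per run.
"""

from __future__ import annotations

import numpy as np
import pytest

from exoorg import simdata
from exoorg.io_formats import TagTrack


@pytest.fixture(scope="session")
def sim_genome_truth():
    """300-kb genome with 250 isolated sites (150 cobound, 100 GATA1-only)."""
    genome = simdata.generate_genome(300_000, 0.42, seed=101)
    spec = simdata.SiteSpec(n_cobound=150, n_gata_only=100, n_tal_only=0,
                            min_site_separation=600)
    genome, truth = simdata.embed_sites(genome, spec, seed=102)
    return genome, truth


@pytest.fixture(scope="session")
def gata_exo_track(sim_genome_truth):
    """GATA1 ChIP-exo tags under the two-cross-link model (-8 major/+8 minor)."""
    genome, truth = sim_genome_truth
    model = simdata.gata1_model(background_rate=1e-4)
    return simdata.simulate_exo_tags(genome, truth, model,
                                     mean_tags_per_site=50, seed=103)


@pytest.fixture(scope="session")
def tal_exo_track(sim_genome_truth):
    """TAL1 ChIP-exo tags (-21/-13 equal weights) over the cobound sites."""
    genome, truth = sim_genome_truth
    model = simdata.tal1_model(background_rate=1e-4)
    return simdata.simulate_exo_tags(genome, truth, model,
                                     mean_tags_per_site=50, seed=104)


@pytest.fixture(scope="session")
def anchors(sim_genome_truth):
    """Oriented WGATAA reference points of all truth sites."""
    _, truth = sim_genome_truth
    return truth.rename(columns={"ref_point": "point",
                                 "motif_strand": "strand"})[
        ["chrom", "point", "strand"]]


def make_track(positions, chrom="c", length=1000):
    """TagTrack from a list of (strand, position[, count]) tuples."""
    track = TagTrack({chrom: length})
    for entry in positions:
        strand, pos = entry[:2]
        count = entry[2] if len(entry) > 2 else 1
        track.add(chrom, strand, pos, count)
    return track


@pytest.fixture
def rng():
    return np.random.default_rng(7)
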