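import numpy as np
import pytest

from breakdomains.simulate import GenomeModel, SynthConfig
from breakdomains.tracks import ProbeTrack


@pytest.fixture
def small_config():
    """A fast two-chromosome configuration with the same structure as the
    full-size defaults (used where absolute scale does not matter)."""
    return SynthConfig(
        seed=0,
        chromosomes=(("chr1", 6_000_000), ("chr6", 4_000_000)),
        n_dsb_sites=6,
        domain_halfwidth_mean=200_000.0,
        domain_halfwidth_sd=40_000.0,
        holes_per_domain=2,
        n_cohesin_peaks=60,
        n_genes=120,
    )


@pytest.fixture
def tiny_genome():
    return GenomeModel((("chr1", 100_000), ("chr6", 60_000)), probe_spacing=100)


def build_track(genome: GenomeModel, fill=0.0, seed=None, sd=0.0, name="t") -> ProbeTrack:
    """Constant or Gaussian-noise track over a genome's probe grid."""
    rng = np.random.default_rng(seed if seed is not None else 0)
    t = ProbeTrack(name=name)
    for chrom in genome.lengths():
        pos = genome.probes(chrom)
        vals = np.full(pos.size, float(fill))
        if sd > 0:
            vals = vals + rng.normal(0.0, sd, pos.size)
        t.add_chromosome(chrom, pos, vals)
    return t


@pytest.fixture
def noise_track_pair(tiny_genome):
    return (build_track(tiny_genome, seed=1, sd=0.3, name="a"),
            build_track(tiny_genome, seed=2, sd=0.3, name="b"))
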