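import numpy as np
import pytest

from cleavenet import simulate as sim
from cleavenet import tracks as trk


@pytest.fixture(scope="session")
def small_spec():
    """A fast desk simulation: 4 x 60 kb chromosomes, 100k reads."""
    return sim.SimulationSpec(n_chroms=4, chrom_length=60_000,
                              peak_spacing=4_000, depth=100_000, seed=11)


@pytest.fixture(scope="session")
def small_world(small_spec):
    """(spec, genome, peaks, rates, sites, track) for the small simulation."""
    genome, peaks = sim.generate_genome(small_spec)
    rates = sim.true_cut_rate(genome, small_spec, peaks)
    sites = sim.sample_cut_sites(rates, small_spec.depth, seed=1, assay="ATAC")
    track = trk.build_coverage(sites, genome, "ATAC")
    return small_spec, genome, peaks, rates, sites, track


@pytest.fixture(scope="session")
def tiny_model_world(small_world):
    """A quickly trained tiny factorized model over the small simulation."""
    from cleavenet.training import train_bias_model, train_residual
    spec, genome, peaks, rates, sites, track = small_world
    cands = trk.enumerate_candidate_bins(genome, 514, 300)
    negs = trk.gc_match_negatives(cands, peaks, trk.RegionSet(), genome, seed=3)
    arch = dict(input_len=514, output_len=200, max_epochs=6)
    bias, _ = train_bias_model(genome, track, negs, peaks,
                               motif_pwms=spec.motifs,
                               model_params=dict(n_filters=16, **arch), seed=5)
    model = train_residual(genome, track, peaks, negs, bias,
                           model_params=dict(n_filters=16, **arch), seed=9)
    return spec, genome, peaks, track, negs, model
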