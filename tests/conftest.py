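import numpy as np
import pytest

from chiralseq import ContigPair, Interval, make_mirror_benchmark
from chiralseq.design import MsiLocusSpec
from chiralseq.sim import PlantedFeature, SimGenomeSpec, simulate_genome


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


@pytest.fixture(scope="session")
def mirror_benchmark():
    """8 x 1.8 kb chiral template pairs at 200x with the standard
    (high-slippage) error preset — shared by the metrics tests."""
    return make_mirror_benchmark(n_pairs=8, length=1800, coverage=200,
                                 error_model="standard", seed=7)


@pytest.fixture(scope="session")
def msi_setup():
    """A genome with an (A)x25 microsatellite and its locus/region specs."""
    genome, _ = simulate_genome(
        SimGenomeSpec(
            contigs=(("chrM", 4000, 0.45),),
            features=(PlantedFeature("chrM", 1900, "A", 25),),
            seed=11,
        )
    )
    seq = genome["chrM"]
    region = Interval("chrM", 1000, 2800)
    locus = MsiLocusSpec(locus=Interval("chrM", 1900, 1925), unit="A", ref_copies=25)
    return {"genome": genome, "seq": seq, "region": region,
            "region_seq": seq[1000:2800], "locus": locus}


@pytest.fixture()
def small_pair():
    rng = np.random.default_rng(13)
    seq = random_seq(rng, 500)
    return ContigPair("t", "t_rev", seq)
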