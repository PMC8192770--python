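import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "repro",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("repro")

from dnapreview import access_sim as ac
from dnapreview import address_design as ad
from dnapreview import fixtures as fx
from dnapreview import preview_codec as pc
from dnapreview import thermo as th


@pytest.fixture(scope="session")
def books():
    return pc.build_codebook(with_alternate=True)


@pytest.fixture(scope="session")
def screened_pair():
    """Forward/reverse base primers chosen by the simulated tunability screen."""
    rng = np.random.default_rng(11)
    candidates = [th.design_random_primer(rng=rng) for _ in range(16)]
    ranked = ac.screen_primers_for_tunability(
        candidates,
        stringent=ac.PREVIEW_CONDITION,
        promiscuous=ac.PCRCondition(45.0, 250.0),
    )
    return ranked[0][1], ranked[1][1]


@pytest.fixture(scope="session")
def address_set(screened_pair):
    return ad.generate_address_set(
        base_pair=screened_pair, hd_levels=[0, 4, 6],
        rng=np.random.default_rng(23),
    )


@pytest.fixture(scope="session")
def small_jpeg():
    return fx.make_progressive_jpeg(fx.SyntheticImageSpec(64, 64, "noise", 75, 3))


@pytest.fixture(scope="session")
def encoded_library(small_jpeg, address_set):
    """A three-partition encoded library shared across access/decoding tests."""
    rng = np.random.default_rng(29)
    flank_f = th.design_random_primer(rng=rng).seq
    flank_r = th.design_random_primer(rng=rng).seq
    strands, manifest, partitions = pc.encode_file(
        small_jpeg, address_set, flank_f, flank_r, partition_spec=[1, 5, 4]
    )
    return {
        "jpeg": small_jpeg,
        "strands": strands,
        "manifest": manifest,
        "partitions": partitions,
        "references": {s.record_id: s.seq for s in strands},
        "tier_of": {k + 1: t for k, t in enumerate(manifest.tiers)},
        "address_set": None,
    }
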