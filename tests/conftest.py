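"""Shared fixtures: small synthetic designs with known ground truth."""

from __future__ import annotations

import random

import pytest
from hypothesis import HealthCheck, settings

from revnano.contactmap import ContactMap
from revnano.seqio import Design, make_design, wc_partner
from revnano.synthgen import RasterSpec, forward_design, implant_decoy

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def raster():
    """Default engineered raster fixture: (design, ground truth)."""
    return forward_design(RasterSpec(seed=0))


@pytest.fixture(scope="session")
def raster_linear():
    return forward_design(RasterSpec(seed=1, circular=False))


@pytest.fixture(scope="session")
def raster_three_section():
    return forward_design(
        RasterSpec(helix_rows=3, columns=64, staple_pattern="three_section", seed=2)
    )


@pytest.fixture(scope="session")
def decoy_fixture():
    """Partial-coverage design with a lure binding site for staple 0:
    (design, ground truth, lure start, lure length)."""
    spec = RasterSpec(helix_rows=4, columns=104, staple_pattern="custom",
                      section_lengths=(16, 16), seed=0)
    design, gt = forward_design(spec)
    lured, y, L = implant_decoy(design, gt, staple_id=0, overshoot=1)
    return lured, gt, y, L


def random_design(seed: int, n: int = 120, n_staples: int = 2,
                  staple_len: int = 24) -> Design:
    """A random scaffold plus staples copied as complements of scaffold
    windows (guaranteeing at least one route each)."""
    rng = random.Random(seed)
    scaffold_seq = "".join(rng.choice("ACGT") for _ in range(n))
    staples = []
    for _ in range(n_staples):
        start = rng.randrange(n - staple_len)
        window = scaffold_seq[start:start + staple_len]
        staples.append("".join(wc_partner(b) for b in reversed(window)))
    return make_design(scaffold_seq, staples, circular=rng.random() < 0.5)


def manual_contact_map(design: Design, pairs: list[tuple[int, int, int]]) -> ContactMap:
    """Build a contact map from (scaffold base, staple id, staple base) triples."""
    cm = ContactMap.empty(design.scaffold.n, design.scaffold.circular,
                          design.scaffold.material)
    for sb, sid, stb in pairs:
        cm.set_pair(sb, sid, stb)
    return cm
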