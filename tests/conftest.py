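import datetime

import numpy as np
import pytest

from msgnet.data import AnimalGroup, Sighting
from msgnet.simulate import SimConfig, SpeciesSpec

FLAT = (1.0, 1.0, 1.0, 1.0)
#: strong shared preference for grassland (row mean 1)
GRASSY = (3.4, 0.2, 0.2, 0.2)


def flat_pool(n: int, grassy: tuple[int, ...] = ()) -> tuple[SpeciesSpec, ...]:
    """Equal-abundance species pool; selected indices get a grassland bias."""
    return tuple(
        SpeciesSpec(f"sp{i}", 1.0 / n, GRASSY if i in grassy else FLAT)
        for i in range(n)
    )


def neutral_config(seed: int, n_groups: int = 200, grassy=(), affinity=None) -> SimConfig:
    """Generator null: no affinities, no scenario effects, flat habitats
    unless ``grassy`` plants a shared habitat preference.  The higher base
    joining rate keeps pairwise co-occurrence counts well above the testing
    threshold at these small group numbers."""
    return SimConfig(
        n_groups=n_groups,
        species=flat_pool(5, grassy),
        affinity=affinity or {},
        beta_lhr=0.0,
        beta_ndvi_small=0.0,
        beta_ndvi_large=0.0,
        base_join_logodds=-1.5,
        seed=seed,
    )


def make_group(gid: str, species: dict[str, int] | list[str], habitat="grassland", **kw):
    members = {s: 1 for s in species} if isinstance(species, (list, tuple, set)) else species
    return AnimalGroup(group_id=gid, members=members, habitat=habitat, **kw)


def make_sighting(species="zebra", x=0.0, y=0.0, count=1, habitat="grassland",
                  date=datetime.date(2015, 3, 1)):
    return Sighting(species=species, x=x, y=y, date=date, count=count, habitat=habitat)


@pytest.fixture
def tiny_groups():
    """Three groups: {A,B}, {A}, {B,C}."""
    return [
        make_group("g1", ["a", "b"]),
        make_group("g2", ["a"]),
        make_group("g3", ["b", "c"]),
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
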