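import numpy as np
import pytest

import dwibench as db
from dwibench.simulate import PopulationSpec, sample_subject


@pytest.fixture(scope="session")
def schemes():
    return db.standard_schemes()


@pytest.fixture(scope="session")
def small_atlas():
    """12 tracts (4 mirrored pairs + 4 midline) on a 24^3 grid."""
    return db.build_atlas((24, 24, 24), 12, seed=3)


@pytest.fixture(scope="session")
def tiny_atlas():
    """6 tracts on a 16^3 grid, for the cheapest end-to-end paths."""
    return db.build_atlas((16, 16, 16), 6, seed=202)


@pytest.fixture(scope="session")
def tissue_dki(small_atlas):
    pop = PopulationSpec(n_hc=2, n_sle=2)
    return sample_subject(pop, small_atlas, "HC", seed=11)


@pytest.fixture(scope="session")
def tissue_dti(small_atlas):
    pop = PopulationSpec(n_hc=2, n_sle=2)
    return sample_subject(pop, small_atlas, "HC", seed=11, with_kurtosis=False)


def affected_set(atlas, n_merged):
    """First n merged tracts, expanded to their left/right members."""
    merged = atlas.merged_names()[:n_merged]
    out = []
    for name in atlas.tract_names:
        base = name
        for suf in ("_left", "_right"):
            if name.endswith(suf):
                base = name[: -len(suf)]
        if base in merged or name in merged:
            out.append(name)
    return tuple(out), merged
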