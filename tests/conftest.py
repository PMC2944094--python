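import numpy as np
import pytest
from hypothesis import settings

from rifkit import standardize, synthetic

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_study():
    """6x6 lattice, constant RR 1, deterministic seed."""
    spec = synthetic.SimulationSpec(lattice_n=6, seed=3)
    return synthetic.simulate_counts(spec)


@pytest.fixture(scope="session")
def small_study_oe(small_study):
    """Per-area (ids, observed, expected) arrays for the 6x6 null study."""
    e = standardize.expected_count(small_study.population, small_study.reference,
                                  by_area=True)
    ids = list(e.index)
    o = (small_study.counts.data.groupby("area_id")["events"].sum()
         .reindex(ids).fillna(0).to_numpy(float))
    return ids, o, e.to_numpy()


@pytest.fixture(scope="session")
def block_study():
    """10x10 lattice with a 3x3 block of true RR 3 and E = 50 per cell.

    Counts are drawn directly at the area level (one Poisson per area) so
    the expected counts are exactly 50 by construction.
    """
    areas, adjacency = synthetic.make_lattice(10)
    rng = np.random.default_rng(7)

    def rc(a):
        r, c = a[1:].split("c")
        return int(r), int(c)

    truth = np.array([3.0 if (3 <= rc(a)[0] < 6 and 3 <= rc(a)[1] < 6) else 1.0
                      for a in areas.area_ids])
    e = np.full(len(truth), 50.0)
    o = rng.poisson(e * truth).astype(float)
    return areas, adjacency, o, e, truth
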