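import numpy as np
import pytest

from cavorient.records import CavityRecord, NestRecord


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_cavities():
    """One site with all three stages at known bearings."""
    recs = []
    for i, ang in enumerate([250.0, 260.0, 270.0, 280.0]):
        recs.append(CavityRecord("A", f"c{i}", "complete", False, ang))
    for i, ang in enumerate([10.0, 120.0, 200.0]):
        recs.append(CavityRecord("A", f"s{i}", "start", False, ang))
    recs.append(CavityRecord("A", "n0", "complete", True, 265.0))
    return recs


@pytest.fixture
def nest_records(rng):
    """200 plain nest records over 20 clusters, direction-independent success."""
    recs = []
    k = 0
    for c in range(20):
        for y in range(10):
            eggs = int(rng.integers(2, 5))
            hatch = int(rng.binomial(eggs, 0.7))
            fledge = int(rng.binomial(hatch, 0.8)) if hatch else 0
            recs.append(
                NestRecord(
                    cluster_id=f"cl{c:02d}",
                    year=2000 + y,
                    direction_deg=float(rng.uniform(0, 360)),
                    adults=int(rng.integers(2, 6)),
                    eggs=eggs,
                    hatchlings=hatch,
                    fledglings=fledge,
                )
            )
            k += 1
    return recs


def write_cavity_csv(path, rows):
    header = "site,cavity_id,stage,is_nest,orientation_deg\n"
    path.write_text(header + "\n".join(rows) + "\n")
    return path
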