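import numpy as np
import pytest

from ihcprior.synth import CLASS_NAMES, PatchRecord, PatchTruth, generate_dataset
from ihcprior.traineval import ExperimentConfig, compare_prior


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_records():
    """A small balanced 32px dataset shared by cheap training smoke tests."""
    return generate_dataset({c: 6 for c in CLASS_NAMES}, patch_size=32, seed=7)


def make_stub_records(counts: dict[str, int]) -> list[PatchRecord]:
    """Lightweight records (1x1 images) for split-arithmetic tests."""
    records = []
    img = np.full((1, 1, 3), 255, dtype=np.uint8)
    truth = PatchTruth(0, 0, 0.0, 0.0)
    for label, n in counts.items():
        for i in range(n):
            records.append(
                PatchRecord(id=f"{label}-{i}", image=img, label=label, truth=truth, seed=i)
            )
    return records


@pytest.fixture(scope="session")
def desk_experiment():
    """The desk-scale study: prior-guided vs no-prior, 3 seeds each.

    Trains 6 small networks on the default synthetic 4-class task
    (400 train / 160 validation patches); shared session-wide because it is
    by far the most expensive fixture.
    """
    cfg = ExperimentConfig()
    with_prior, no_prior, table = compare_prior(cfg)
    return {"config": cfg, "with_prior": with_prior, "no_prior": no_prior, "table": table}
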