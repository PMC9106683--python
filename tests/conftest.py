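import pytest
from hypothesis import settings

from socbalance import DegradationStage, Horizon, SoilProfile, StageEnsemble

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def make_profile(stage="S0", replicate="r1", crack=0.0, layers=None):
    """Build a profile from (label, top, bottom, soc, bd) tuples."""
    layers = layers or [
        ("Ah1", 0.0, 5.0, 60.0, 0.7),
        ("Ah2", 5.0, 15.0, 50.0, 0.85),
        ("Bw", 15.0, 35.0, 30.0, 1.1),
    ]
    return SoilProfile(
        stage=DegradationStage.from_label(stage),
        replicate=replicate,
        crack_depth=crack,
        horizons=[
            Horizon(label=l, top_depth=t, bottom_depth=b, soc_content=c, bulk_density=d)
            for l, t, b, c, d in layers
        ],
    )


@pytest.fixture
def reference_profile():
    return make_profile()


@pytest.fixture
def reference_ensemble():
    return StageEnsemble(
        stage=DegradationStage.S0,
        profiles=[make_profile(replicate=f"r{i}") for i in range(1, 5)],
    )
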