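import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def field_totals():
    """Published per-plant totals of nine field-grown plants, three methods."""
    from palmleaf import load_field_totals

    df = load_field_totals()
    return {
        "M1": df["total_photo_clustered"].to_numpy(),
        "M2": df["total_meter_clustered"].to_numpy(),
        "M3": df["total_meter_all"].to_numpy(),
        "plant_id": df["plant_id"].tolist(),
    }


@pytest.fixture(scope="session")
def greenhouse_totals():
    """Published per-plant totals of six greenhouse plants: hybrid vs photo."""
    from palmleaf import load_greenhouse_totals

    df = load_greenhouse_totals()
    return {
        "hybrid": df["total_hybrid"].to_numpy(),
        "photo": df["total_photo"].to_numpy(),
        "plant_id": df["plant_id"].tolist(),
    }


@pytest.fixture(scope="session")
def default_leaf_family():
    """50 size-varying leaves of the default palmate architecture, with the
    mild per-lobe jitter of real foliage."""
    from palmleaf import SyntheticLeafSpec

    rng = np.random.default_rng(11)
    sizes = rng.uniform(6.0, 16.0, 50)
    return [
        SyntheticLeafSpec(
            central_lobe_length=float(sizes[i]),
            angle_jitter_deg=3.0,
            ratio_jitter=0.05,
            seed=i,
        )
        for i in range(50)
    ]
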