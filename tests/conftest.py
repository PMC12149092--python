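import numpy as np
import pytest

from vgeeg.features import FeatureRow
from vgeeg.synthetic import CohortSpec


@pytest.fixture(scope="session")
def small_cohort_spec() -> CohortSpec:
    """Tiny alpha-contrast cohort used by pipeline-level tests."""
    return CohortSpec(
        n_subjects_per_class=2,
        n_channels=4,
        sampling_rate=128.0,
        duration=20.0,
        band_amplitudes_per_class={"alpha": (0.5, 2.0), "theta": (0.8, 0.8)},
        noise_exponent=1.0,
        noise_scale=0.5,
        seed=42,
    )


def random_sequence(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random strictly-increasing-s point sequence for visibility tests."""
    s = np.cumsum(rng.uniform(0.5, 1.5, size=n))
    y = rng.uniform(0, 10, size=n)
    return np.column_stack([s, y])


def separable_rows(
    n_rows: int,
    n_channels: int = 2,
    n_bands: int = 5,
    feats_per_group: int = 1,
    shift: float = 3.0,
    seed: int = 0,
) -> list[FeatureRow]:
    """Linearly separable toy feature rows with a (channel, band) layout."""
    rng = np.random.default_rng(seed)
    bands = ("delta", "theta", "alpha", "beta", "gamma")[:n_bands]
    layout = tuple(
        (f"ch{c}", b, f"f{k}")
        for c in range(n_channels)
        for b in bands
        for k in range(feats_per_group)
    )
    rows = []
    for i in range(n_rows):
        y = i % 2
        v = rng.normal(0, 1, len(layout)) + (shift if y else -shift)
        rows.append(FeatureRow(f"s{i:03d}", 0, v, y, "vg_only", layout))
    return rows
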