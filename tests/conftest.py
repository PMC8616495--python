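import numpy as np
import pytest

from aggremap import imaging, synth


@pytest.fixture(scope="session")
def small_movie():
    """A small but realistic synthetic movie shared across tests."""
    model = synth.KineticsModel(a_inf=0.4, k=1.0)
    geometry = synth.AcquisitionGeometry(duration=1.5, image_shape=(256, 256))
    well = synth.SyntheticWell(n_cells=120, seed=7)
    return synth.render_movie(well, model, geometry, seed=7)


@pytest.fixture(scope="session")
def small_movie_result(small_movie):
    cfg = imaging.SegmentationConfig.for_synthetic()
    return imaging.process_movie(small_movie.frames, cfg)


@pytest.fixture(scope="session")
def line_parameters():
    """A plausible 25-line aggregation-parameter table."""
    import pandas as pd

    rng = np.random.default_rng(42)
    n = 25
    return pd.DataFrame(
        {
            "area_2h": np.clip(rng.normal(0.7, 0.15, n), 0.05, 1.0),
            "auc": np.clip(rng.normal(11.0, 2.5, n), 1.0, None),
            "circularity_end": np.clip(rng.normal(0.55, 0.12, n), 0.05, 1.0),
        },
        index=[f"LINE{i:02d}" for i in range(n)],
    )


def rasterized_disk(radius: int, pad: int = 10) -> np.ndarray:
    n = radius + pad
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    return (xx * xx + yy * yy) <= radius * radius


def rasterized_ellipse(a: int, b: int, pad: int = 10) -> np.ndarray:
    n = max(a, b) + pad
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1]
    return (xx / a) ** 2 + (yy / b) ** 2 <= 1.0
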