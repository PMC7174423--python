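import numpy as np
import pytest

from ragweed.grids import GridSpec, PointSample, RasterGrid


@pytest.fixture
def spec4() -> GridSpec:
    """Small 4x4 lattice with 10 km cells, origin at the north-west corner."""
    return GridSpec(origin_x=0.0, origin_y=40_000.0, n_rows=4, n_cols=4)


@pytest.fixture
def spec3() -> GridSpec:
    return GridSpec(origin_x=0.0, origin_y=30_000.0, n_rows=3, n_cols=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def make_grid(spec: GridSpec, values, mask=None) -> RasterGrid:
    return RasterGrid(spec, np.asarray(values, dtype=float), mask)


def brute_force_idw(points, spec, power=2.0):
    """All-pairs IDW oracle: plain loops, no spatial index, k = n."""
    xs, ys = spec.cell_centres()
    out = np.zeros(spec.shape)
    eps = spec.cell_size / 1000.0
    for i in range(spec.n_rows):
        for j in range(spec.n_cols):
            num = den = 0.0
            exact = None
            for p in points:
                d = np.hypot(xs[i, j] - p.x, ys[i, j] - p.y)
                if d < eps:
                    exact = p.value
                    break
                w = d ** (-power)
                num += w * p.value
                den += w
            out[i, j] = exact if exact is not None else num / den
    return out


@pytest.fixture
def five_points() -> list[PointSample]:
    return [
        PointSample("a", 3_000.0, 37_000.0, 12.0),
        PointSample("b", 21_000.0, 8_000.0, 40.0),
        PointSample("c", 33_000.0, 29_000.0, 7.5),
        PointSample("d", 11_000.0, 18_000.0, 95.0),
        PointSample("e", 38_000.0, 2_000.0, 61.0),
    ]
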