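import numpy as np
import pytest

from carpetprf import (HRFSpec, PredictionBank, RunDesign, SearchGrid,
                       build_aperture_movie)


@pytest.fixture(scope="session")
def design():
    return RunDesign()


@pytest.fixture(scope="session")
def movie(design):
    return build_aperture_movie(design)


@pytest.fixture(scope="session")
def hrf():
    return HRFSpec()


@pytest.fixture(scope="session")
def bank(movie, hrf, design):
    return PredictionBank.build(SearchGrid(), movie, hrf, design)


def snap_rect_to_grid(rect, grid):
    """The rectangle a centre-sampled raster actually encodes: the union of
    the cells whose centres fall inside `rect` (same area, centre shifted by
    at most half a cell per edge)."""
    x1, x2, y1, y2 = rect
    h = grid.cell_deg / 2
    xc = grid.x_centers[(grid.x_centers >= x1) & (grid.x_centers <= x2)]
    yc = grid.y_centers[(grid.y_centers >= y1) & (grid.y_centers <= y2)]
    if xc.size == 0 or yc.size == 0:
        return None
    return (xc.min() - h, xc.max() + h, yc.min() - h, yc.max() + h)


def gaussian_rect_overlap_exact(x0, y0, sigma, rect):
    """Closed-form Gaussian mass over an axis-aligned rectangle.

    Separable integral: 2*pi*sigma^2 times the product of 1-D normal CDF
    differences along x and y.  Independent oracle for the raster overlap.
    """
    from scipy.stats import norm
    x1, x2, y1, y2 = rect
    fx = norm.cdf((x2 - x0) / sigma) - norm.cdf((x1 - x0) / sigma)
    fy = norm.cdf((y2 - y0) / sigma) - norm.cdf((y1 - y0) / sigma)
    return 2.0 * np.pi * sigma ** 2 * fx * fy
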