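"""Gaussian pRF forward model: receptive-field profile, aperture overlap,
haemodynamic convolution, and predicted BOLD time series.

A vertex's population receptive field (pRF) is a 2-D isotropic Gaussian
with centre (x0, y0) and size sigma, all in degrees of visual angle.  The
neural drive on each volume is the overlap of that profile with the binary
stimulus aperture; convolving the drive with a canonical double-gamma HRF
and sampling at volume onsets gives the predicted time series, linear in
the response amplitude beta.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .geometry import ApertureMovie, RunDesign, VisualFieldGrid

__all__ = [
    "PRFParams",
    "HRFSpec",
    "gaussian_field",
    "neural_overlap",
    "hrf_kernel",
    "predict_timeseries",
]


@dataclass(frozen=True)
class PRFParams:
    """Gaussian pRF parameters.

    x0, y0 and sigma are in degrees of visual angle; beta scales the
    (unit-amplitude) neural overlap into normalized-BOLD units and baseline
    shifts it.  The Gaussian carries no normalization constant -- any such
    factor is absorbed into beta.
    """

    x0: float
    y0: float
    sigma: float
    beta: float = 1.0
    baseline: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be strictly positive")
        if not np.isfinite(self.beta):
            raise ValueError("beta must be finite")


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma HRF: 6 s peak, 16 s undershoot, ratio 6."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length_s: float = 32.0
    dt_s: float = 0.1

    def __post_init__(self) -> None:
        if self.dt_s <= 0 or self.kernel_length_s <= 0:
            raise ValueError("dt_s and kernel_length_s must be positive")


def gaussian_field(params: PRFParams, grid: VisualFieldGrid) -> np.ndarray:
    """Evaluate the pRF profile exp(-((x-x0)^2+(y-y0)^2)/(2 sigma^2)) on the grid.

    Returns an (n_y, n_x) array; peak value 1 at the centre, un-normalized.
    """
    if params.sigma <= 0:
        raise ValueError("sigma must be strictly positive")
    gx = np.exp(-((grid.x_centers - params.x0) ** 2) / (2.0 * params.sigma ** 2))
    gy = np.exp(-((grid.y_centers - params.y0) ** 2) / (2.0 * params.sigma ** 2))
    return np.outer(gy, gx)


def neural_overlap(movie: ApertureMovie, field: np.ndarray) -> np.ndarray:
    """Per-volume overlap: sum of the pRF field over 'on' cells, times cell area.

    For a pRF fully inside the grid a full-field frame yields the total
    Gaussian mass 2*pi*sigma^2.
    """
    field = np.asarray(field)
    if field.shape != movie.frames.shape[1:]:
        raise ValueError(
            f"field shape {field.shape} does not match movie grid "
            f"{movie.frames.shape[1:]}")
    flat = movie.frames.reshape(movie.n_frames, -1).astype(float)
    return flat @ field.ravel() * movie.grid.cell_area


def hrf_kernel(spec: HRFSpec | None = None) -> np.ndarray:
    """Double-gamma HRF sampled at dt_s over kernel_length_s, peak-normalized.

    kernel(t) = g(t; peak) - g(t; undershoot) / ratio with gamma-pdf lobes
    of shape delay/dispersion and scale dispersion; maximum scaled to 1.
    """
    spec = spec or HRFSpec()
    t = np.arange(0.0, spec.kernel_length_s + spec.dt_s / 2, spec.dt_s)
    peak = sps.gamma.pdf(t, a=spec.peak_delay_s / spec.peak_dispersion_s,
                         scale=spec.peak_dispersion_s)
    under = sps.gamma.pdf(t, a=spec.undershoot_delay_s / spec.undershoot_dispersion_s,
                          scale=spec.undershoot_dispersion_s)
    kernel = peak - under / spec.peak_undershoot_ratio
    return kernel / kernel.max()


def _convolve_drive(drive: np.ndarray, design: RunDesign,
                    spec: HRFSpec) -> np.ndarray:
    """Convolve a per-retained-volume drive with the HRF at dt resolution.

    The run's blank dummy period is part of the convolution history (the
    drive there is zero), matching the physical situation of a run that
    starts with a blank screen.  Returns samples at retained-volume onsets.
    """
    up = int(round(design.tr_s / spec.dt_s))
    if not np.isclose(up * spec.dt_s, design.tr_s):
        raise ValueError("dt_s must divide tr_s")
    n_dummy = design.n_dummy_volumes
    full = np.concatenate([np.zeros(n_dummy), np.asarray(drive, dtype=float)])
    dense = np.repeat(full, up)
    conv = np.convolve(dense, hrf_kernel(spec))[: dense.size]
    onsets = (n_dummy + np.arange(design.n_volumes_retained)) * up
    return conv[onsets] * spec.dt_s


def predict_timeseries(params: PRFParams, movie: ApertureMovie,
                       hrf: HRFSpec | None = None,
                       design: RunDesign | None = None) -> np.ndarray:
    """Predicted BOLD series: beta * HRF-convolved overlap + baseline.

    One value per retained volume; the model is linear in beta.
    """
    hrf = hrf or HRFSpec()
    design = design or movie.design
    drive = neural_overlap(movie, gaussian_field(params, movie.grid))
    return params.beta * _convolve_drive(drive, design, hrf) + params.baseline
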