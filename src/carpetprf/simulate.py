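"""Ground-truth retinotopic maps and simulated multi-run fMRI time series.

The generator emulates the statistical structure the analysis assumes:
a known Gaussian pRF per vertex (with area labels V1-V3 and sizes growing
up the hierarchy), four stimulus conditions sharing identical bar geometry
but differing in response amplitude (the high-contrast mapping stimulus
far exceeding the low-contrast and illusion conditions), per-area gain
differences producing the V1 < V2 < V3 signal-to-noise gradient, four runs
per condition, and per-run linear drift plus serially correlated (AR(1))
Gaussian noise.  Gaze traces for fixation-stability checks are simulated
as centred Gaussian jitter.

All randomness descends from one root seed via `numpy.random.SeedSequence`
spawning, with fixed stream order (truth, runs, gaze), so the same
(config, seed) pair reproduces the dataset bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .geometry import ApertureMovie, CarpetSpec, RunDesign, build_aperture_movie
from .model import HRFSpec
from .fitting import _FastPredictor

__all__ = [
    "NoiseModel",
    "SyntheticDataset",
    "DEFAULT_CONDITION_GAINS",
    "DEFAULT_AREA_GAINS",
    "sample_ground_truth",
    "simulate_runs",
    "simulate_gaze",
    "make_dataset",
]

AREAS = ("V1", "V2", "V3")

# Condition amplitudes: the physical high-contrast mapping stimulus evokes a
# far stronger response than the low-contrast luminance and the two illusion
# conditions; Kanizsa is set slightly above occlusion.  Area gains encode the
# V1 < V2 < V3 response gradient.  These are calibration knobs reproducing
# ordinal relations, not measured values.
DEFAULT_CONDITION_GAINS = {"mapping": 1.0, "luminance": 0.25,
                           "kanizsa": 0.25, "occlusion": 0.20}
DEFAULT_AREA_GAINS = {"V1": 0.7, "V2": 1.0, "V3": 1.3}

# Per-area additive shift of the pRF size range (deg): sizes grow V1 < V2 < V3.
AREA_SIGMA_SHIFT = {"V1": 0.0, "V2": 0.2, "V3": 0.45}


@dataclass(frozen=True)
class NoiseModel:
    """Per-volume noise: stationary AR(1) with sd `white_sd`, plus a linear
    drift whose total change over a run is uniform in +-drift_slope_range."""

    white_sd: float = 5.5
    ar1_rho: float = 0.3
    drift_slope_range: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar1_rho < 1.0:
            raise ValueError("ar1_rho must be in [0, 1)")
        if self.white_sd < 0:
            raise ValueError("white_sd must be non-negative")


@dataclass
class SyntheticDataset:
    ground_truth: pd.DataFrame
    series: dict[str, np.ndarray]          # condition -> (runs, vertices, vols)
    design: RunDesign
    seed: int
    condition_gains: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONDITION_GAINS))
    area_gains: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AREA_GAINS))
    noise: NoiseModel = field(default_factory=NoiseModel)


def _in_band(x: np.ndarray, y: np.ndarray, inner: float,
             outer: float) -> np.ndarray:
    return ((np.abs(x) >= inner) & (np.abs(x) <= outer)
            & (np.abs(y) >= inner) & (np.abs(y) <= outer))


def sample_ground_truth(n_per_area: int = 100,
                        carpet: CarpetSpec | None = None,
                        sigma_range: tuple[float, float] = (0.4, 0.9),
                        seed: int | np.random.SeedSequence = 0,
                        band_fraction: float = 0.8,
                        band: tuple[float, float] = (0.75, 3.0),
                        beta: float = 1.0) -> pd.DataFrame:
    """Draw ground-truth pRFs for V1, V2 and V3.

    Centres are uniform over the carpet square (+- occluder half-side); a
    fraction `band_fraction` is forced inside the analysis band
    (inner <= |x|, |y| <= outer from either cardinal axis), the remainder
    deliberately outside it so the ROI filter has something to reject.
    Sizes are uniform in `sigma_range` shifted upward per area
    (V1 < V2 < V3).  Deterministic per seed.
    """
    if n_per_area <= 0:
        raise ValueError("n_per_area must be positive")
    lo, hi = sigma_range
    if not (0 < lo <= hi):
        raise ValueError("sigma_range must be positive and ordered")
    carpet = carpet or CarpetSpec()
    half = carpet.occluder_side_deg / 2.0
    inner, outer = band
    outer = min(outer, half)
    rng = np.random.default_rng(seed)

    rows = []
    vid = 0
    for area in AREAS:
        n_band = int(round(band_fraction * n_per_area))
        xs = np.empty(n_per_area)
        ys = np.empty(n_per_area)
        # in-band: magnitudes uniform in [inner, outer] per axis, random signs
        xs[:n_band] = (rng.uniform(inner, outer, n_band)
                       * rng.choice([-1.0, 1.0], n_band))
        ys[:n_band] = (rng.uniform(inner, outer, n_band)
                       * rng.choice([-1.0, 1.0], n_band))
        # out-of-band: rejection-sample the square until outside the band
        k = n_band
        while k < n_per_area:
            cx, cy = rng.uniform(-half, half, 2)
            if not _in_band(np.array(cx), np.array(cy), inner, outer):
                xs[k], ys[k] = cx, cy
                k += 1
        shift = AREA_SIGMA_SHIFT[area]
        sig = rng.uniform(lo + shift, hi + shift, n_per_area)
        for i in range(n_per_area):
            rows.append(dict(vertex_id=vid, area=area, x0=xs[i], y0=ys[i],
                             sigma=sig[i], beta=beta, baseline=0.0))
            vid += 1
    return pd.DataFrame(rows)


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...],
               sd: float, rho: float) -> np.ndarray:
    """Stationary AR(1) series along the last axis, marginal sd `sd`.

    x[0] is drawn from the stationary distribution and later samples follow
    x[t] = rho*x[t-1] + e[t] with innovation sd sd*sqrt(1-rho^2), so every
    sample has marginal sd `sd` and lag-1 autocorrelation rho.
    """
    if sd == 0.0:
        return np.zeros(shape)
    x0 = rng.normal(0.0, sd, shape[:-1] + (1,))
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - rho ** 2), shape)
    if rho == 0.0 or shape[-1] == 1:
        out = innov
        out[..., :1] = x0
        return out
    # lfilter with initial condition zi = rho*x0 implements the recursion
    out, _ = lfilter([1.0], [1.0, -rho], innov[..., 1:], axis=-1,
                     zi=rho * x0)
    return np.concatenate([x0, out], axis=-1)


def simulate_runs(truth: pd.DataFrame,
                  design: RunDesign | None = None,
                  movie: ApertureMovie | None = None,
                  hrf: HRFSpec | None = None,
                  noise: NoiseModel | None = None,
                  condition_gains: dict[str, float] | None = None,
                  area_gains: dict[str, float] | None = None,
                  n_runs: int = 4,
                  seed: int | np.random.SeedSequence = 0) -> SyntheticDataset:
    """Generate multi-run time series for every condition.

    Per vertex and run: the noiseless prediction with beta scaled by
    condition_gain x area_gain, plus a linear drift with per-run slope
    uniform in +-drift_slope_range, plus stationary AR(1) noise.
    """
    if n_runs < 0:
        raise ValueError("n_runs must be non-negative")
    design = design or RunDesign()
    movie = movie if movie is not None else build_aperture_movie(design)
    hrf = hrf or HRFSpec()
    noise = noise or NoiseModel()
    condition_gains = dict(condition_gains or DEFAULT_CONDITION_GAINS)
    area_gains = dict(area_gains or DEFAULT_AREA_GAINS)

    fp = _FastPredictor(movie, hrf, design)
    n_vert = len(truth)
    n_vol = design.n_volumes_retained
    unit = np.stack([fp.unit_prediction(r.x0, r.y0, r.sigma)
                     for r in truth.itertuples()]) if n_vert else \
        np.empty((0, n_vol))
    gain_a = truth["area"].map(area_gains).to_numpy() if n_vert else \
        np.empty(0)
    beta = truth["beta"].to_numpy() if n_vert else np.empty(0)
    baseline = truth["baseline"].to_numpy() if n_vert else np.empty(0)

    rng = np.random.default_rng(seed)
    tnorm = (np.arange(n_vol) / max(n_vol - 1, 1)) - 0.5
    series: dict[str, np.ndarray] = {}
    for cond in sorted(condition_gains):
        g = condition_gains[cond]
        amp = (g * gain_a * beta)[:, None] * unit + baseline[:, None]
        runs = np.empty((n_runs, n_vert, n_vol))
        for r in range(n_runs):
            slopes = rng.uniform(-noise.drift_slope_range,
                                 noise.drift_slope_range, n_vert)
            drift = slopes[:, None] * tnorm[None, :]
            eps = _ar1_noise(rng, (n_vert, n_vol), noise.white_sd,
                             noise.ar1_rho)
            runs[r] = amp + drift + eps
        series[cond] = runs

    truth = truth.copy()
    pred_sd = unit.std(axis=1) if n_vert else np.empty(0)
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = np.where(noise.white_sd > 0,
                       gain_a * beta * pred_sd / max(noise.white_sd, 1e-300),
                       np.inf)
    truth["snr"] = snr
    return SyntheticDataset(ground_truth=truth, series=series, design=design,
                            seed=seed if isinstance(seed, int) else -1,
                            condition_gains=condition_gains,
                            area_gains=area_gains, noise=noise)


def simulate_gaze(duration_s: float = 225.0, rate_hz: float = 60.0,
                  sd_deg: float = 0.3,
                  seed: int | np.random.SeedSequence = 0) -> pd.DataFrame:
    """Gaze samples under steady fixation: centred Gaussian jitter.

    Returns a DataFrame with columns t_s, x_deg, y_deg; duration 225 s at
    60 Hz gives 13,500 samples.
    """
    if duration_s <= 0 or rate_hz <= 0 or sd_deg < 0:
        raise ValueError("duration, rate and sd must be positive")
    n = int(round(duration_s * rate_hz))
    rng = np.random.default_rng(seed)
    return pd.DataFrame({
        "t_s": np.arange(n) / rate_hz,
        "x_deg": rng.normal(0.0, sd_deg, n),
        "y_deg": rng.normal(0.0, sd_deg, n),
    })


def make_dataset(n_per_area: int = 100, seed: int = 0,
                 noise: NoiseModel | None = None,
                 condition_gains: dict[str, float] | None = None,
                 area_gains: dict[str, float] | None = None,
                 n_runs: int = 4,
                 design: RunDesign | None = None,
                 **truth_kwargs) -> SyntheticDataset:
    """One-call generator: ground truth + runs, streams spawned from `seed`."""
    root = np.random.SeedSequence(seed)
    truth_ss, runs_ss, _gaze_ss = root.spawn(3)
    design = design or RunDesign()
    truth = sample_ground_truth(n_per_area=n_per_area, seed=truth_ss,
                                **truth_kwargs)
    ds = simulate_runs(truth, design=design, noise=noise,
                       condition_gains=condition_gains,
                       area_gains=area_gains, n_runs=n_runs, seed=runs_ss)
    ds.seed = seed
    return ds
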