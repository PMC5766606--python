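"""Coarse-to-fine pRF parameter estimation.

Each vertex's multi-run time series is linearly detrended, z-scored and
averaged across runs.  A coarse stage then picks, from a precomputed bank
of unit-amplitude predictions on a parameter grid, the (x0, y0, sigma)
whose prediction correlates best with the averaged series; a fine stage
refines that seed with a derivative-free simplex search over
(x0, y0, log sigma), solving amplitude (beta) and baseline per candidate
by ordinary least squares.  Goodness of fit is the squared Pearson
correlation between the final prediction and the data.

`PRFMapper` packages the whole procedure as a scikit-learn estimator:
``fit`` consumes a (vertex x volume) or (vertex x run x volume) array and
exposes per-vertex fitted parameters as trailing-underscore attributes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .geometry import ApertureMovie, RunDesign, build_aperture_movie
from .model import HRFSpec, PRFParams, _convolve_drive

__all__ = [
    "SearchGrid",
    "FitResult",
    "PredictionBank",
    "PRFMapper",
    "preprocess_runs",
    "coarse_fit",
    "fine_fit",
    "derive_polar_ecc",
    "fit_dataset",
]

DEFAULT_SIGMAS = (0.2, 0.3, 0.45, 0.67, 1.0, 1.5, 2.25)


@dataclass(frozen=True)
class SearchGrid:
    """Coarse-stage candidate grid; sigma candidates are log-spaced."""

    x0: tuple[float, ...] = tuple(np.arange(-4.0, 4.0 + 1e-9, 0.25))
    y0: tuple[float, ...] = tuple(np.arange(-4.0, 4.0 + 1e-9, 0.25))
    sigma: tuple[float, ...] = DEFAULT_SIGMAS

    def __post_init__(self) -> None:
        if not (len(self.x0) and len(self.y0) and len(self.sigma)):
            raise ValueError("search grid must be non-empty")
        if min(self.sigma) <= 0:
            raise ValueError("sigma candidates must be positive")


@dataclass
class FitResult:
    """Fitted pRF for one vertex, with derived position parameters."""

    params: PRFParams
    r_squared: float
    polar_rad: float
    ecc_deg: float
    converged: bool
    zero_variance: bool = False

    def as_row(self) -> dict:
        p = self.params
        # negative amplitudes are kept but flagged: an anti-correlated fit
        # is not a retinotopic response
        return dict(x0=p.x0, y0=p.y0, sigma=p.sigma, beta=p.beta,
                    baseline=p.baseline, r_squared=self.r_squared,
                    polar_rad=self.polar_rad, ecc_deg=self.ecc_deg,
                    converged=self.converged, beta_negative=p.beta < 0)


def preprocess_runs(runs: np.ndarray) -> np.ndarray:
    """Detrend, normalize and average a vertex's runs.

    Per run: subtract the least-squares line over volumes, then z-score
    (mean 0, sd 1, population sd); finally average across runs elementwise.
    A run with zero variance after detrending is flagged with a warning and
    contributes an all-zero row.
    """
    runs = np.atleast_2d(np.asarray(runs, dtype=float))
    if runs.ndim != 2 or runs.shape[0] < 1:
        raise ValueError("runs must be a (n_runs, n_volumes) array")
    t = np.arange(runs.shape[1], dtype=float)
    t = t - t.mean()
    denom = (t * t).sum()
    out = np.empty_like(runs)
    for i, run in enumerate(runs):
        slope = (t * (run - run.mean())).sum() / denom
        detr = run - run.mean() - slope * t
        sd = detr.std()
        if sd == 0.0:
            warnings.warn("zero-variance run after detrending; set to zero",
                          RuntimeWarning, stacklevel=2)
            out[i] = 0.0
        else:
            out[i] = detr / sd
    return out.mean(axis=0)


def derive_polar_ecc(x0: float, y0: float) -> tuple[float, float]:
    """Polar angle (atan2(y0, x0); 0 = right horizontal meridian,
    counter-clockwise positive) and eccentricity sqrt(x0^2 + y0^2).
    (0, 0) maps to polar angle 0 by convention."""
    if x0 == 0.0 and y0 == 0.0:
        return 0.0, 0.0
    return math.atan2(y0, x0), math.hypot(x0, y0)


class _FastPredictor:
    """Unit-amplitude prediction for arbitrary (x0, y0, sigma), fast.

    Exploits two structural facts: each aperture frame is a rasterized
    axis-aligned rectangle, so it factorizes into a row mask x column mask
    and the Gaussian overlap separates into 1-D sums; and the neural drive
    is constant within each volume, so the dt-resolution HRF convolution
    collapses to a TR-resolution kernel (the response, sampled at volume
    onsets, to a single volume of drive).  Output is identical to
    `predict_timeseries` with beta=1, baseline=0 to machine precision.
    """

    def __init__(self, movie: ApertureMovie, hrf: HRFSpec,
                 design: RunDesign) -> None:
        self.movie = movie
        self.hrf = hrf
        self.design = design
        frames = movie.frames
        rows = frames.any(axis=2)          # (F, n_y)
        cols = frames.any(axis=1)          # (F, n_x)
        recon = rows[:, :, None] & cols[:, None, :]
        self._separable = bool((recon == frames.astype(bool)).all())
        self._rows = rows.astype(float)
        self._cols = cols.astype(float)
        self._xc = movie.grid.x_centers
        self._yc = movie.grid.y_centers
        self._area = movie.grid.cell_area
        impulse = np.zeros(design.n_volumes_retained)
        impulse[0] = 1.0
        self._tr_kernel = np.trim_zeros(
            _convolve_drive(impulse, design, hrf), trim="b")

    def drive(self, x0: float, y0: float, sigma: float) -> np.ndarray:
        gx = np.exp(-((self._xc - x0) ** 2) / (2.0 * sigma ** 2))
        gy = np.exp(-((self._yc - y0) ** 2) / (2.0 * sigma ** 2))
        if self._separable:
            return (self._rows @ gy) * (self._cols @ gx) * self._area
        field = np.outer(gy, gx).ravel()
        flat = self.movie.frames.reshape(self.movie.n_frames, -1)
        return flat @ field * self._area

    def unit_prediction(self, x0: float, y0: float, sigma: float) -> np.ndarray:
        d = self.drive(x0, y0, sigma)
        return np.convolve(d, self._tr_kernel)[: d.size]


@dataclass
class PredictionBank:
    """Unit predictions for every coarse-grid candidate.

    Candidates are ordered x0-major, then y0, then sigma, which fixes the
    tie-break order of the coarse stage.
    """

    search: SearchGrid
    params: np.ndarray                      # (n_candidates, 3): x0, y0, sigma
    predictions: np.ndarray                 # (n_candidates, n_volumes)
    _centered: np.ndarray = field(repr=False, default=None)
    _norms: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        c = self.predictions - self.predictions.mean(axis=1, keepdims=True)
        self._centered = c
        self._norms = np.linalg.norm(c, axis=1)

    @classmethod
    def build(cls, search: SearchGrid, movie: ApertureMovie,
              hrf: HRFSpec | None = None,
              design: RunDesign | None = None) -> "PredictionBank":
        hrf = hrf or HRFSpec()
        design = design or movie.design
        fp = _FastPredictor(movie, hrf, design)
        grid = [(x, y, s) for x in search.x0 for y in search.y0
                for s in search.sigma]
        params = np.array(grid)
        preds = np.empty((len(grid), design.n_volumes_retained))
        for i, (x, y, s) in enumerate(grid):
            preds[i] = fp.unit_prediction(x, y, s)
        return cls(search=search, params=params, predictions=preds)

    def correlations(self, averaged: np.ndarray) -> np.ndarray:
        """Pearson r of the averaged series against every bank prediction."""
        a = averaged - averaged.mean()
        na = np.linalg.norm(a)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (self._centered @ a) / (self._norms * na)
        return np.nan_to_num(r, nan=-np.inf)


def coarse_fit(averaged: np.ndarray,
               bank: PredictionBank) -> tuple[PRFParams, float]:
    """Best coarse-grid candidate by Pearson correlation.

    Ties break to the first candidate in (x0, y0, sigma) raster order.
    """
    if bank.predictions.size == 0:
        raise ValueError("empty prediction bank")
    r = bank.correlations(np.asarray(averaged, dtype=float))
    best = int(np.argmax(r))
    x, y, s = bank.params[best]
    return PRFParams(x0=x, y0=y, sigma=s), float(r[best])


def _ols_beta_baseline(averaged: np.ndarray,
                       unit_pred: np.ndarray) -> tuple[float, float]:
    p = unit_pred - unit_pred.mean()
    denom = (p * p).sum()
    if denom == 0.0:
        return 0.0, float(averaged.mean())
    beta = float((p * (averaged - averaged.mean())).sum() / denom)
    baseline = float(averaged.mean() - beta * unit_pred.mean())
    return beta, baseline


def fine_fit(averaged: np.ndarray, init: PRFParams,
             movie: ApertureMovie, hrf: HRFSpec | None = None,
             design: RunDesign | None = None,
             xatol: float = 1e-3, fatol: float = 1e-3,
             maxfev: int = 400,
             _predictor: "_FastPredictor | None" = None) -> FitResult:
    """Refine a coarse seed by Nelder-Mead over (x0, y0, log sigma).

    Maximizes R^2 (squared Pearson correlation of the unit prediction with
    the averaged series); beta and baseline are solved by OLS at the
    optimum.  On simplex failure the coarse values are returned with
    ``converged=False``.
    """
    hrf = hrf or HRFSpec()
    design = design or movie.design
    averaged = np.asarray(averaged, dtype=float)
    fp = _predictor or _FastPredictor(movie, hrf, design)

    a = averaged - averaged.mean()
    na = np.linalg.norm(a)
    if na == 0.0:
        return FitResult(params=init, r_squared=0.0,
                         polar_rad=derive_polar_ecc(init.x0, init.y0)[0],
                         ecc_deg=derive_polar_ecc(init.x0, init.y0)[1],
                         converged=False, zero_variance=True)

    half_extent = movie.grid.x_max_deg
    log_sigma_lo, log_sigma_hi = math.log(0.05), math.log(10.0)

    def neg_r2(theta: np.ndarray) -> float:
        x, y, ls = theta
        # generous plausibility bounds: keep the simplex off the flat
        # far-field / vanishing-sigma plateaus where beta would blow up
        if (abs(x) > half_extent or abs(y) > half_extent
                or not log_sigma_lo <= ls <= log_sigma_hi):
            return 0.0
        p = fp.unit_prediction(x, y, math.exp(ls))
        pc = p - p.mean()
        nv = np.linalg.norm(pc)
        if nv == 0.0:
            return 0.0
        r = (pc @ a) / (nv * na)
        return -(r * r)

    # explicit initial simplex scaled to the coarse grid spacing; scipy's
    # default perturbation is relative, so a zero coordinate (log sigma = 0
    # at the sigma = 1 grid point) would get a degenerate first step
    steps = np.array([0.25, 0.25, 0.2])

    def simplex_at(centre: np.ndarray) -> np.ndarray:
        sim = np.tile(centre, (4, 1))
        sim[1:] += np.diag(steps)
        return sim

    x0vec = np.array([init.x0, init.y0, math.log(init.sigma)])
    res = minimize(neg_r2, x0vec, method="Nelder-Mead",
                   options=dict(xatol=xatol, fatol=fatol, maxfev=maxfev,
                                initial_simplex=simplex_at(x0vec)))
    if res.success:
        # restart once from the solution: a fresh simplex escapes the
        # premature collapse Nelder-Mead is prone to on ridged surfaces
        res = minimize(neg_r2, res.x, method="Nelder-Mead",
                       options=dict(xatol=xatol, fatol=fatol, maxfev=maxfev,
                                    initial_simplex=simplex_at(
                                        np.asarray(res.x))))
    if res.success and -res.fun >= -neg_r2(x0vec):
        x, y, sigma = res.x[0], res.x[1], math.exp(res.x[2])
        converged = True
    else:
        x, y, sigma = init.x0, init.y0, init.sigma
        converged = False

    unit = fp.unit_prediction(x, y, sigma)
    beta, baseline = _ols_beta_baseline(averaged, unit)
    r2 = -neg_r2(np.array([x, y, math.log(sigma)]))
    polar, ecc = derive_polar_ecc(x, y)
    return FitResult(params=PRFParams(x0=float(x), y0=float(y),
                                      sigma=float(sigma), beta=beta,
                                      baseline=baseline),
                     r_squared=float(r2), polar_rad=polar, ecc_deg=ecc,
                     converged=converged)


class PRFMapper(BaseEstimator):
    """Scikit-learn style estimator for coarse-to-fine pRF mapping.

    Parameters
    ----------
    movie : ApertureMovie, optional
        Binary stimulus aperture; defaults to the standard carpet bar design.
    hrf : HRFSpec, optional
        Haemodynamic response; canonical double-gamma by default.
    search : SearchGrid, optional
        Coarse-stage candidate grid.
    bank : PredictionBank, optional
        Precomputed coarse predictions (rebuilt from `search` if omitted);
        pass one to share across several fits of the same design.
    preprocess : bool
        If True (default), 3-D input (vertex x run x volume) is detrended,
        z-scored and run-averaged; 2-D input is assumed already averaged.

    Attributes
    ----------
    x0_, y0_, sigma_, beta_, baseline_ : ndarray of shape (n_vertices,)
    r_squared_, polar_, ecc_ : ndarray of shape (n_vertices,)
    converged_ : boolean ndarray of shape (n_vertices,)
    results_ : pandas.DataFrame, one row per vertex.
    """

    def __init__(self, movie: ApertureMovie | None = None,
                 hrf: HRFSpec | None = None,
                 search: SearchGrid | None = None,
                 bank: PredictionBank | None = None,
                 preprocess: bool = True,
                 maxfev: int = 400):
        self.movie = movie
        self.hrf = hrf
        self.search = search
        self.bank = bank
        self.preprocess = preprocess
        self.maxfev = maxfev

    def _resolve(self):
        movie = self.movie if self.movie is not None else build_aperture_movie()
        hrf = self.hrf or HRFSpec()
        search = self.search or SearchGrid()
        bank = self.bank or PredictionBank.build(search, movie, hrf,
                                                movie.design)
        return movie, hrf, search, bank

    def fit(self, X: np.ndarray, y=None) -> "PRFMapper":
        """Estimate one pRF per vertex.

        X is (n_vertices, n_volumes) of averaged series, or
        (n_vertices, n_runs, n_volumes) of raw runs when preprocessing
        is enabled.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            if not self.preprocess:
                raise ValueError("3-D input requires preprocess=True")
            if X.shape[0] == 0:
                X = X.reshape(0, X.shape[2])
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", RuntimeWarning)
                    X = np.stack([preprocess_runs(v) for v in X])
        if X.ndim != 2:
            raise ValueError("X must be 2-D (vertex x volume) or 3-D "
                             "(vertex x run x volume)")
        movie, hrf, search, bank = self._resolve()
        if X.shape[1] != movie.design.n_volumes_retained:
            raise ValueError(
                f"expected {movie.design.n_volumes_retained} volumes, "
                f"got {X.shape[1]}")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite values")

        fp = _FastPredictor(movie, hrf, movie.design)
        results = []
        for series in X:
            seed, _ = coarse_fit(series, bank)
            results.append(fine_fit(series, seed, movie, hrf, movie.design,
                                    maxfev=self.maxfev, _predictor=fp))
        self._assign(results)
        self.n_features_in_ = X.shape[1]
        self._predictor_ = fp
        return self

    def _assign(self, results: list[FitResult]) -> None:
        rows = [r.as_row() for r in results]
        self.results_ = pd.DataFrame(rows)
        for col in ("x0", "y0", "sigma", "beta", "baseline", "r_squared",
                    "converged", "beta_negative"):
            arr = self.results_[col].to_numpy() if rows else np.array([])
            setattr(self, f"{col}_", arr)
        self.polar_ = (self.results_["polar_rad"].to_numpy()
                       if rows else np.array([]))
        self.ecc_ = (self.results_["ecc_deg"].to_numpy()
                     if rows else np.array([]))

    def predict(self, X=None) -> np.ndarray:
        """Predicted time series for the fitted vertices (X is ignored)."""
        check_is_fitted(self, "results_")
        preds = [self.beta_[i] * self._predictor_.unit_prediction(
                     self.x0_[i], self.y0_[i], self.sigma_[i])
                 + self.baseline_[i]
                 for i in range(len(self.x0_))]
        return (np.stack(preds) if preds
                else np.empty((0, self.n_features_in_)))

    def score(self, X=None, y=None) -> float:
        """Mean goodness of fit (R^2) across vertices."""
        check_is_fitted(self, "results_")
        return float(np.mean(self.r_squared_)) if len(self.r_squared_) else 0.0


def fit_dataset(dataset, movie: ApertureMovie | None = None,
                hrf: HRFSpec | None = None,
                search: SearchGrid | None = None,
                conditions: list[str] | None = None) -> pd.DataFrame:
    """Fit every vertex of every condition of a synthetic (or loaded) dataset.

    `dataset` needs ``series`` (condition -> (n_runs, n_vertices, n_volumes)
    array), ``ground_truth`` (a DataFrame with vertex_id and area), and
    ``design``.  Returns a tidy table with one row per vertex x condition;
    deterministic given its inputs.
    """
    movie = movie if movie is not None else build_aperture_movie(dataset.design)
    hrf = hrf or HRFSpec()
    search = search or SearchGrid()
    bank = PredictionBank.build(search, movie, hrf, movie.design)
    mapper = PRFMapper(movie=movie, hrf=hrf, search=search, bank=bank)

    tables = []
    for cond in (conditions or sorted(dataset.series)):
        runs = np.asarray(dataset.series[cond])      # (runs, vertices, vols)
        X = runs.transpose(1, 0, 2)
        mapper.fit(X)
        tbl = mapper.results_.copy()
        tbl.insert(0, "condition", cond)
        tbl.insert(0, "area", dataset.ground_truth["area"].to_numpy())
        tbl.insert(0, "vertex_id", dataset.ground_truth["vertex_id"].to_numpy())
        tables.append(tbl)
    if not tables:
        return pd.DataFrame()
    return pd.concat(tables, ignore_index=True)
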