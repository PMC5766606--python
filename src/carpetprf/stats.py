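"""Map-coherence statistics: ROI filtering, responsive-vertex proportions,
prediction correlations with a vertex-shuffle permutation test,
between-condition parameter consistency, and gaze-stability MAD.

The central question these statistics answer is whether a stimulus
condition yields a *coherent* retinotopic map: observed time courses should
correlate with the predictions of each vertex's own reference pRF better
than with the predictions of other vertices.  The permutation test shuffles
the vertex-to-prediction assignment to build the null distribution of the
Fisher-z averaged correlation.  Parameter consistency between conditions
uses Spearman rank correlation for scalar parameters and a circular
correlation coefficient for polar angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ROIBand",
    "PermutationResult",
    "roi_filter",
    "responsive_fraction",
    "fisher_z_mean",
    "prediction_correlation",
    "permutation_test",
    "circular_correlation",
    "parameter_correlations",
    "gaze_mad",
]

_Z_CLIP = 1.0 - 1e-12


@dataclass(frozen=True)
class ROIBand:
    """Analysis band: distance from either cardinal axis, in degrees.

    Keeps pRF centres inside four quadrant rectangles that lie within the
    carpet but clear of the cardinal "plus sign" and the carpet edges.
    """

    inner_deg: float = 0.75
    outer_deg: float = 3.0

    def __post_init__(self) -> None:
        if not 0 < self.inner_deg < self.outer_deg:
            raise ValueError("need 0 < inner_deg < outer_deg")


@dataclass
class PermutationResult:
    """Observed Fisher-z mean correlation against its shuffle null."""

    observed_zbar: float
    null_zbars: np.ndarray
    p_value: float
    n_perm: int
    seed: int | None = None


def roi_filter(fits: pd.DataFrame, band: ROIBand | None = None) -> np.ndarray:
    """Boolean mask keeping vertices with inner <= |x0| <= outer and
    inner <= |y0| <= outer (bounds inclusive).

    Centres should come from the reference (mapping or ground-truth)
    condition so the same neural population is analysed in every condition.
    """
    band = band or ROIBand()
    for col in ("x0", "y0"):
        if col not in fits:
            raise KeyError(f"fits table lacks required column {col!r}")
    ax = np.abs(fits["x0"].to_numpy(dtype=float))
    ay = np.abs(fits["y0"].to_numpy(dtype=float))
    return ((ax >= band.inner_deg) & (ax <= band.outer_deg)
            & (ay >= band.inner_deg) & (ay <= band.outer_deg))


def responsive_fraction(fits: pd.DataFrame, mask: np.ndarray | None = None,
                        threshold: float = 0.05) -> float:
    """Fraction of (masked) vertices with R^2 strictly above `threshold`."""
    r2 = fits["r_squared"].to_numpy(dtype=float)
    if mask is not None:
        r2 = r2[np.asarray(mask, dtype=bool)]
    if r2.size == 0:
        raise ValueError("responsive_fraction undefined on empty selection")
    return float(np.mean(r2 > threshold))


def fisher_z_mean(r: np.ndarray) -> float:
    """tanh(mean(atanh(r))): the Fisher z-converted average correlation.

    r = +-1 is clipped to 1 - 1e-12 in magnitude before atanh.
    """
    r = np.clip(np.asarray(r, dtype=float), -_Z_CLIP, _Z_CLIP)
    return float(np.tanh(np.mean(np.arctanh(r))))


def _row_correlations(obs: np.ndarray, pred: np.ndarray
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Per-row Pearson r between matching rows; flags zero-variance rows."""
    o = obs - obs.mean(axis=1, keepdims=True)
    p = pred - pred.mean(axis=1, keepdims=True)
    no = np.linalg.norm(o, axis=1)
    np_ = np.linalg.norm(p, axis=1)
    ok = (no > 0) & (np_ > 0)
    r = np.zeros(obs.shape[0])
    r[ok] = np.einsum("ij,ij->i", o[ok], p[ok]) / (no[ok] * np_[ok])
    return r, ok


def prediction_correlation(observed: np.ndarray, predictions: np.ndarray
                           ) -> tuple[np.ndarray, float, int]:
    """Correlate each vertex's observed series with its own reference
    prediction.

    `observed` and `predictions` are aligned (n_vertices, n_volumes) arrays;
    predictions normally come from pRF parameters estimated in the
    high-contrast mapping condition.  Returns (per-vertex r, Fisher-z mean
    over valid vertices, number of skipped zero-variance vertices).
    """
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
    if observed.shape != predictions.shape:
        raise ValueError("observed and predictions must be aligned")
    r, ok = _row_correlations(observed, predictions)
    if not ok.any():
        raise ValueError("no vertex with non-zero variance")
    return r, fisher_z_mean(r[ok]), int((~ok).sum())


def permutation_test(observed: np.ndarray, predictions: np.ndarray,
                     n_perm: int = 10_000,
                     seed: int | np.random.Generator | None = 0
                     ) -> PermutationResult:
    """Vertex-shuffle permutation test of map coherence.

    The observed statistic is the Fisher-z mean of vertex-matched
    correlations; each null iteration permutes the vertex-to-prediction
    assignment uniformly at random and recomputes it.  One-sided
    p = (#{null >= observed} + 1) / (n_perm + 1), so the test asks whether
    correlations are vertex-specific rather than merely non-zero.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    observed = np.atleast_2d(np.asarray(observed, dtype=float))
    predictions = np.atleast_2d(np.asarray(predictions, dtype=float))
    if observed.shape[0] < 2:
        raise ValueError("need at least 2 vertices to permute")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    o = observed - observed.mean(axis=1, keepdims=True)
    p = predictions - predictions.mean(axis=1, keepdims=True)
    no = np.linalg.norm(o, axis=1)
    np_ = np.linalg.norm(p, axis=1)
    ok = (no > 0) & (np_ > 0)
    if ok.sum() < 2:
        raise ValueError("need at least 2 vertices with variance")
    o, p = o[ok], p[ok]
    no, np_ = no[ok], np_[ok]
    # full cross-correlation matrix lets every permutation be a gather
    rmat = (o / no[:, None]) @ (p / np_[:, None]).T
    n = rmat.shape[0]
    observed_zbar = fisher_z_mean(np.diag(rmat))

    idx = np.arange(n)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = fisher_z_mean(rmat[idx, perm])
    p_value = (float((null >= observed_zbar).sum()) + 1.0) / (n_perm + 1.0)
    return PermutationResult(observed_zbar=observed_zbar, null_zbars=null,
                             p_value=p_value, n_perm=n_perm,
                             seed=seed if isinstance(seed, int) else None)


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Circular correlation for paired angles (radians).

    rho = sum sin(a-abar) sin(b-bbar) / sqrt(sum sin^2(a-abar) sum
    sin^2(b-bbar)) with circular means abar, bbar; invariant to rotating
    either vector and to jointly negating both.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("need two equal-length angle vectors, n >= 3")
    abar = np.angle(np.exp(1j * a).mean())
    bbar = np.angle(np.exp(1j * b).mean())
    sa = np.sin(a - abar)
    sb = np.sin(b - bbar)
    denom = np.sqrt((sa ** 2).sum() * (sb ** 2).sum())
    if denom == 0.0:
        raise ValueError("zero circular variance; correlation undefined")
    return float((sa * sb).sum() / denom)


CIRCULAR_PARAMS = frozenset({"polar_rad", "polar"})
DEFAULT_PARAMS = ("polar_rad", "ecc_deg", "sigma", "beta", "r_squared")


def parameter_correlations(fits: pd.DataFrame,
                           mask: np.ndarray | None = None,
                           parameters: tuple[str, ...] = DEFAULT_PARAMS,
                           by_area: bool = True) -> pd.DataFrame:
    """Between-condition consistency of fitted pRF parameters.

    `fits` is a tidy table (vertex_id, area, condition, parameters...).
    For every area, parameter and unordered condition pair, computes the
    vertex-wise Spearman rank correlation -- except for polar angle, which
    uses `circular_correlation`.  Pairs with fewer than 3 complete vertices
    yield NaN.  Returns a tidy DataFrame (area, parameter, cond_a, cond_b,
    r, n).
    """
    fits = fits if mask is None else fits.loc[np.asarray(mask, dtype=bool)]
    conditions = sorted(fits["condition"].unique())
    areas = sorted(fits["area"].unique()) if by_area else ["all"]
    rows = []
    for area in areas:
        sub = fits if not by_area else fits[fits["area"] == area]
        wide = {c: sub[sub["condition"] == c].set_index("vertex_id")
                for c in conditions}
        for param in parameters:
            for i, ca in enumerate(conditions):
                for cb in conditions[i + 1:]:
                    joined = wide[ca][[param]].join(
                        wide[cb][[param]], how="inner",
                        lsuffix="_a", rsuffix="_b").dropna()
                    n = len(joined)
                    if n < 3:
                        r = np.nan
                    else:
                        va = joined[f"{param}_a"].to_numpy()
                        vb = joined[f"{param}_b"].to_numpy()
                        if param in CIRCULAR_PARAMS:
                            try:
                                r = circular_correlation(va, vb)
                            except ValueError:
                                r = np.nan
                        else:
                            r = sps.spearmanr(va, vb).statistic
                    rows.append(dict(area=area, parameter=param,
                                     cond_a=ca, cond_b=cb,
                                     r=float(r) if r == r else np.nan, n=n))
    return pd.DataFrame(rows)


def gaze_mad(trace: pd.DataFrame) -> tuple[float, float]:
    """Median absolute deviation of gaze samples, per axis, in degrees.

    median(|x - median(x)|) with no consistency scaling; the fixation
    compliance criterion is MAD below 0.5 deg on both axes.
    """
    if len(trace) == 0:
        raise ValueError("empty gaze trace")
    x = trace["x_deg"].to_numpy(dtype=float)
    y = trace["y_deg"].to_numpy(dtype=float)
    return (float(np.median(np.abs(x - np.median(x)))),
            float(np.median(np.abs(y - np.median(y)))))
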