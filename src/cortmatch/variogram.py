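"""Smoothed empirical variograms of parcel maps.

The semivariogram gamma(h) summarises spatial autocorrelation: half the
average squared difference between map values at parcels separated by
distance ~h. Rather than hard distance bins, contributions are averaged
with a Gaussian kernel centred on each of ``nh`` uniformly spaced lags,
which stabilises the estimate at lags where pairs are sparse:

    gamma(h_k) = sum_ij w_k(d_ij) * v_ij / sum_ij w_k(d_ij),
    v_ij = (x_i - x_j)^2 / 2,   w_k(d) = exp(-(d - h_k)^2 / (2 b^2)).

Lags run from the smallest positive pairwise distance to the ``pv``-th
percentile of pairwise distances (distant pairs are sparse and noisy);
the bandwidth b is ``bandwidth_factor`` times the lag spacing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import BrainMap, ParcelGeometry

__all__ = [
    "VariogramParams",
    "VariogramEstimate",
    "VariogramEngine",
    "smoothed_variogram",
    "variogram_band",
]


@dataclass(frozen=True)
class VariogramParams:
    """nh: number of uniformly spaced lags; pv: percentile of pairwise
    distances used as the maximum lag; bandwidth_factor: Gaussian kernel
    bandwidth as a multiple of the lag spacing."""

    nh: int = 25
    pv: float = 25.0
    bandwidth_factor: float = 3.0

    def __post_init__(self):
        if self.nh < 2:
            raise ValueError("nh must be >= 2")
        if not (0 < self.pv <= 100):
            raise ValueError("pv must be in (0, 100]")
        if self.bandwidth_factor <= 0:
            raise ValueError("bandwidth_factor must be positive")


@dataclass(frozen=True)
class VariogramEstimate:
    lags: np.ndarray
    gamma: np.ndarray

    def __post_init__(self):
        lags = np.asarray(self.lags, dtype=float)
        gamma = np.asarray(self.gamma, dtype=float)
        if lags.shape != gamma.shape or lags.ndim != 1:
            raise ValueError("lags and gamma must be 1-D of equal length")
        if np.any(np.diff(lags) <= 0) or lags[0] <= 0:
            raise ValueError("lags must be strictly increasing and positive")
        if gamma.min() < 0:
            raise ValueError("gamma must be non-negative")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "gamma", gamma)


class VariogramEngine:
    """Precomputed kernel weights for repeated variogram evaluation on one
    geometry. Evaluating an ensemble of maps is then a single matrix product."""

    def __init__(self, geometry: ParcelGeometry, params: VariogramParams | None = None):
        params = params or VariogramParams()
        P = geometry.n_parcels
        if P < 3:
            raise ValueError("need at least 3 parcels")
        iu = np.triu_indices(P, k=1)
        d = geometry.dist[iu]
        pos = d[d > 0]
        if pos.size == 0:
            raise ValueError("all pairwise distances are zero")
        dmin = pos.min()
        dmax = np.percentile(d, params.pv)
        if dmax <= dmin:
            raise ValueError(
                "degenerate lag range: max lag <= min positive distance "
                "(raise pv or supply a richer geometry)"
            )
        lags = np.linspace(dmin, dmax, params.nh)
        b = params.bandwidth_factor * (lags[1] - lags[0])
        # pairs beyond the last lag + 10 bandwidths carry kernel weight
        # < exp(-50) at every lag; dropping them changes nothing numerically
        keep = d <= lags[-1] + 10.0 * b
        iu = (iu[0][keep], iu[1][keep])
        d = d[keep]
        W = np.exp(-((d[None, :] - lags[:, None]) ** 2) / (2.0 * b * b))
        self.geometry = geometry
        self.params = params
        self.lags = lags
        self.bandwidth = b
        self._iu = iu
        self._W = W
        self._wsum = W.sum(axis=1)

    def gamma(self, values: np.ndarray) -> np.ndarray:
        return self.gamma_many(np.asarray(values, dtype=float)[None, :])[0]

    def gamma_many(self, rows: np.ndarray) -> np.ndarray:
        """Variograms of many maps at once: rows (n, P) -> (n, nh)."""
        rows = np.asarray(rows, dtype=float)
        v = rows[:, self._iu[0]]
        v -= rows[:, self._iu[1]]
        np.square(v, out=v)
        out = v @ self._W.T
        out /= 2.0 * self._wsum
        return out

    def estimate(self, brain_map: BrainMap) -> VariogramEstimate:
        return VariogramEstimate(lags=self.lags, gamma=self.gamma(brain_map.values))


def smoothed_variogram(
    brain_map: BrainMap,
    geometry: ParcelGeometry | None = None,
    params: VariogramParams | None = None,
) -> VariogramEstimate:
    """Smoothed empirical variogram of a parcel map (see module docstring)."""
    geometry = geometry or brain_map.geometry
    if not geometry.same_parcellation(brain_map.geometry):
        raise ValueError("map not aligned to the supplied geometry")
    return VariogramEngine(geometry, params).estimate(brain_map)


def variogram_band(
    estimates: list[VariogramEstimate] | np.ndarray,
    lo: float = 0.05,
    hi: float = 0.95,
    lags: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-lag empirical (lo, hi) quantile band of a variogram ensemble.

    Accepts a list of :class:`VariogramEstimate` sharing identical lags, or
    an (n, nh) gamma array with explicit ``lags``. Quantiles use linear
    interpolation between order statistics. Returns (lags, lo_curve, hi_curve).
    """
    if not (0 <= lo < hi <= 1):
        raise ValueError("need 0 <= lo < hi <= 1")
    if isinstance(estimates, np.ndarray):
        if lags is None:
            raise ValueError("gamma array input requires explicit lags")
        gammas = estimates
    else:
        if not estimates:
            raise ValueError("empty ensemble")
        lags = estimates[0].lags
        for e in estimates[1:]:
            if not np.array_equal(e.lags, lags):
                raise ValueError("ensemble variograms have mismatched lags")
        gammas = np.vstack([e.gamma for e in estimates])
    lo_curve = np.quantile(gammas, lo, axis=0)
    hi_curve = np.quantile(gammas, hi, axis=0)
    return np.asarray(lags), lo_curve, hi_curve
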