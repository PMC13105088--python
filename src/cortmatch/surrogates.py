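"""Variogram-matched surrogate maps: spatially autocorrelated null models.

Smooth brain maps violate the exchangeability assumption behind naive
permutation tests — nearby parcels carry similar values, so shuffling
values across space destroys autocorrelation and inflates false-positive
rates when correlating two smooth maps. The generator here builds null
maps that are random with respect to the target's topography but match
its spatial autocorrelation, summarised by the variogram:

1. randomly permute the target's values across parcels;
2. for each candidate neighbourhood fraction delta, smooth the permuted
   map by a kernel-weighted average over each parcel's k = round(delta*P)
   nearest neighbours;
3. regress the target's variogram on each candidate's variogram
   (gamma_target ~ alpha * gamma_candidate + beta) and keep the delta
   with the smallest squared error;
4. form the surrogate  y = sqrt(|alpha|) * smoothed + sqrt(|beta|) * eps
   with eps i.i.d. standard normal, standardised per surrogate — the
   linear variogram identity gamma(a*x + noise) = a^2 gamma(x) + var(noise)
   makes y's variogram approximate the target's;
5. optionally re-impose the target's exact value distribution by mapping
   the surrogate's ranks onto the sorted target values.

One seeded generator streams all permutations and noise; surrogate i is
reproducible from (seed, i) via independent child streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import BrainMap, ParcelGeometry
from .variogram import VariogramEngine, VariogramParams

__all__ = [
    "SurrogateParams",
    "SurrogateFit",
    "SurrogateEnsemble",
    "SurrogateGenerator",
    "generate_surrogate",
    "generate_ensemble",
]

KERNELS = ("exponential", "gaussian", "uniform", "inverse-distance")
DEFAULT_DELTAS = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1))


@dataclass(frozen=True)
class SurrogateParams:
    n_surrogates: int = 1000
    deltas: tuple[float, ...] = DEFAULT_DELTAS
    kernel: str = "exponential"
    resample_values: bool = False
    seed: int = 0
    vparams: VariogramParams = field(default_factory=VariogramParams)

    def __post_init__(self):
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if not self.deltas or any(not (0 < d <= 1) for d in self.deltas):
            raise ValueError("deltas must be non-empty fractions in (0, 1]")
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}")


@dataclass(frozen=True)
class SurrogateFit:
    """Variogram-matching regression for one surrogate."""

    chosen_delta: float
    alpha: float
    beta: float
    sse: float

    def __post_init__(self):
        if self.sse < 0:
            raise ValueError("sse must be non-negative")


@dataclass(frozen=True)
class SurrogateEnsemble:
    """S surrogate maps (rows) matched to one target's variogram."""

    maps: np.ndarray
    params: SurrogateParams
    fits: tuple[SurrogateFit, ...]
    target_name: str
    geometry: ParcelGeometry

    def __post_init__(self):
        maps = np.asarray(self.maps, dtype=float)
        if maps.ndim != 2 or maps.shape[0] != self.params.n_surrogates:
            raise ValueError("maps must be (n_surrogates, P)")
        if maps.shape[1] != self.geometry.n_parcels:
            raise ValueError("surrogate length does not match geometry")
        if not np.all(np.isfinite(maps)):
            raise ValueError("non-finite surrogate values")
        object.__setattr__(self, "maps", maps)

    @property
    def n_surrogates(self) -> int:
        return self.maps.shape[0]

    def check_target(self, target: BrainMap) -> None:
        if self.target_name != target.name or not self.geometry.same_parcellation(
            target.geometry
        ):
            raise ValueError(
                f"ensemble was generated from {self.target_name!r}, "
                f"not from {target.name!r} on this parcellation"
            )


def _smoothing_matrix(
    dist: np.ndarray, k: int, kernel: str
) -> np.ndarray:
    """Row-stochastic P x P matrix averaging each parcel over its k nearest
    neighbours (self excluded) with kernel weights."""
    P = dist.shape[0]
    if k > P - 1:
        raise ValueError(f"k={k} exceeds the {P - 1} available neighbours")
    order = np.argsort(dist, axis=1, kind="stable")
    nbrs = order[:, 1 : k + 1]  # self sits at column 0 (distance 0)
    rows = np.repeat(np.arange(P), k)
    d = dist[rows, nbrs.ravel()].reshape(P, k)
    dk = d[:, -1][:, None]
    if kernel == "exponential":
        w = np.exp(-d / dk)
    elif kernel == "gaussian":
        w = np.exp(-(d**2) / (2.0 * dk**2))
    elif kernel == "uniform":
        w = np.ones_like(d)
    else:  # inverse-distance
        w = 1.0 / d
    S = np.zeros((P, P))
    S[rows, nbrs.ravel()] = (w / w.sum(axis=1, keepdims=True)).ravel()
    return S


class SurrogateGenerator:
    """Precomputes the smoothing matrices and variogram kernel for one
    (target, geometry, params) so surrogates are a handful of matrix
    products each; batches of surrogates share the heavy linear algebra."""

    def __init__(
        self,
        target: BrainMap,
        geometry: ParcelGeometry | None = None,
        params: SurrogateParams | None = None,
    ):
        geometry = geometry or target.geometry
        if not geometry.same_parcellation(target.geometry):
            raise ValueError("target not aligned to the supplied geometry")
        params = params or SurrogateParams()
        x = target.values
        if np.ptp(x) == 0:
            raise ValueError("target map has zero variance")
        P = geometry.n_parcels
        self.target = target
        self.geometry = geometry
        self.params = params
        self.engine = VariogramEngine(geometry, params.vparams)
        self.gamma_target = self.engine.gamma(x)
        self._sorted_target = np.sort(x)
        self._smoothers = [
            _smoothing_matrix(geometry.dist, max(1, round(d * P)), params.kernel)
            for d in params.deltas
        ]
        self._children = np.random.SeedSequence(params.seed).spawn(
            params.n_surrogates
        )

    def _rng(self, index: int) -> np.random.Generator:
        return np.random.Generator(np.random.PCG64(self._children[index]))

    def batch(self, indices: Sequence[int]) -> tuple[np.ndarray, list[SurrogateFit]]:
        """Generate the surrogates with the given stream indices."""
        x = self.target.values
        P = x.size
        B = len(indices)
        perms = np.empty((B, P))
        noise = np.empty((B, P))
        for row, i in enumerate(indices):
            rng = self._rng(i)
            perms[row] = x[rng.permutation(P)]
            noise[row] = rng.standard_normal(P)
        noise -= noise.mean(axis=1, keepdims=True)
        sd = noise.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        noise /= sd

        gt = self.gamma_target
        nd = len(self._smoothers)
        smoothed = np.empty((nd, B, P))
        alpha = np.empty((nd, B))
        beta = np.empty((nd, B))
        sse = np.empty((nd, B))
        for j, S in enumerate(self._smoothers):
            cand = perms @ S.T
            smoothed[j] = cand
            gc = self.engine.gamma_many(cand)  # (B, nh)
            gc_mean = gc.mean(axis=1)
            gc_var = gc.var(axis=1)
            cov = (gc * gt).mean(axis=1) - gc_mean * gt.mean()
            with np.errstate(divide="ignore", invalid="ignore"):
                a = np.where(gc_var > 0, cov / np.where(gc_var > 0, gc_var, 1.0), 0.0)
            b = gt.mean() - a * gc_mean
            resid = gt[None, :] - a[:, None] * gc - b[:, None]
            alpha[j], beta[j] = a, b
            sse[j] = (resid**2).sum(axis=1)

        best = np.argmin(sse, axis=0)
        cols = np.arange(B)
        a_best = alpha[best, cols]
        b_best = beta[best, cols]
        sm_best = smoothed[best, cols, :]
        surr = np.sqrt(np.abs(a_best))[:, None] * sm_best + np.sqrt(
            np.abs(b_best)
        )[:, None] * noise
        if self.params.resample_values:
            # map surrogate ranks onto the sorted target values
            order = np.argsort(surr, axis=1, kind="stable")
            ranks = np.empty_like(order)
            np.put_along_axis(ranks, order, np.arange(P)[None, :], axis=1)
            surr = self._sorted_target[ranks]
        fits = [
            SurrogateFit(
                chosen_delta=float(self.params.deltas[best[r]]),
                alpha=float(a_best[r]),
                beta=float(b_best[r]),
                sse=float(sse[best[r], r]),
            )
            for r in range(B)
        ]
        return surr, fits

    def ensemble(self, batch_size: int = 512) -> SurrogateEnsemble:
        S = self.params.n_surrogates
        maps = np.empty((S, self.geometry.n_parcels))
        fits: list[SurrogateFit] = []
        for start in range(0, S, batch_size):
            idx = range(start, min(start + batch_size, S))
            maps[start : start + len(idx)], batch_fits = self.batch(list(idx))
            fits.extend(batch_fits)
        return SurrogateEnsemble(
            maps=maps,
            params=self.params,
            fits=tuple(fits),
            target_name=self.target.name,
            geometry=self.geometry,
        )


def generate_surrogate(
    target: BrainMap,
    geometry: ParcelGeometry | None = None,
    params: SurrogateParams | None = None,
    index: int = 0,
) -> tuple[BrainMap, SurrogateFit]:
    """Generate the ``index``-th surrogate of the seeded stream."""
    gen = SurrogateGenerator(target, geometry, params)
    maps, fits = gen.batch([index])
    surr = BrainMap(
        name=f"{target.name}_surrogate{index}",
        values=maps[0],
        geometry=gen.geometry,
    )
    return surr, fits[0]


def generate_ensemble(
    target: BrainMap,
    geometry: ParcelGeometry | None = None,
    params: SurrogateParams | None = None,
) -> SurrogateEnsemble:
    """Generate the full seeded ensemble (reproducible from target + params)."""
    return SurrogateGenerator(target, geometry, params).ensemble()
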