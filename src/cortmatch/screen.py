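"""Spearman screen of a target map against a panel of feature maps.

Each feature's observed Spearman correlation with the target is referred
to a null distribution of correlations between that feature and the
target's variogram-matched surrogates (one shared ensemble; the null is
generated from the target only). Two-sided p-values use the doubled
add-one tail convention, and the screen reports significance under three
rules applied to the same p-values: Bonferroni, Benjamini–Hochberg FDR,
and an uncorrected threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geometry import BrainMap
from .surrogates import SurrogateEnsemble

__all__ = [
    "ScreenResult",
    "spearman",
    "surrogate_pvalue_two_sided",
    "naive_permutation_null",
    "bh_fdr",
    "run_screen",
    "pvalue_histogram",
]


@dataclass(frozen=True)
class ScreenResult:
    """Per-feature screen records, sorted by ascending p.

    ``table`` columns: name, rho, p, sig_bonferroni, sig_fdr,
    sig_uncorrected. ``null_rhos`` maps feature name -> S-vector of null
    correlations when retained.
    """

    table: pd.DataFrame
    alphas: tuple[float, float, float]
    n_surrogates: int
    null_rhos: dict[str, np.ndarray] | None = None

    @property
    def n_features(self) -> int:
        return len(self.table)


def _ranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, axis=-1)


def spearman(x: BrainMap | np.ndarray, y: BrainMap | np.ndarray) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    xv = x.values if isinstance(x, BrainMap) else np.asarray(x, dtype=float)
    yv = y.values if isinstance(y, BrainMap) else np.asarray(y, dtype=float)
    if isinstance(x, BrainMap) and isinstance(y, BrainMap):
        x.check_aligned(y)
    if xv.size < 3 or xv.size != yv.size:
        raise ValueError("need aligned vectors of length >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero-variance input")
    rho = stats.spearmanr(xv, yv).statistic
    return float(rho)


def _null_spearmans(feature_values: np.ndarray, surrogate_ranks: np.ndarray) -> np.ndarray:
    """Spearman of one feature against each pre-ranked surrogate row."""
    fr = _ranks(feature_values)
    fr = (fr - fr.mean()) / fr.std()
    sr = surrogate_ranks
    z = (sr - sr.mean(axis=1, keepdims=True)) / sr.std(axis=1, keepdims=True)
    return z @ fr / fr.size


def surrogate_pvalue_two_sided(
    rho_obs: float, null_rhos: np.ndarray, method: str = "doubled-tail"
) -> float:
    """Two-sided surrogate p-value.

    Default 'doubled-tail': p = min(1, 2*min(1+#{null<=obs},
    1+#{null>=obs})/(S+1)). The add-one count makes p strictly positive
    (the observed statistic is counted as a member of its own null), and
    doubling the smaller tail yields a valid two-sided test. The
    'abs-tail' alternative compares |rho| against |null| directly; the two
    agree closely for near-symmetric nulls.
    """
    null_rhos = np.asarray(null_rhos, dtype=float)
    S = null_rhos.size
    if S < 1:
        raise ValueError("empty null distribution")
    if method == "abs-tail":
        return (1 + int(np.sum(np.abs(null_rhos) >= abs(rho_obs)))) / (S + 1)
    if method != "doubled-tail":
        raise ValueError("method must be 'doubled-tail' or 'abs-tail'")
    lo = 1 + int(np.sum(null_rhos <= rho_obs))
    hi = 1 + int(np.sum(null_rhos >= rho_obs))
    return min(1.0, 2.0 * min(lo, hi) / (S + 1))


def naive_permutation_null(
    target: BrainMap, feature: BrainMap, n_perm: int, rng: np.random.Generator
) -> float:
    """Two-sided p from a value-permutation null that ignores spatial
    autocorrelation (the procedure the surrogate test exists to replace)."""
    rho_obs = spearman(target, feature)
    tr = _ranks(target.values)
    fr = _ranks(feature.values)
    tr = (tr - tr.mean()) / tr.std()
    fr = (fr - fr.mean()) / fr.std()
    P = tr.size
    perms = np.array([rng.permutation(P) for _ in range(n_perm)])
    null = (tr[perms] @ fr) / P
    return surrogate_pvalue_two_sided(rho_obs, null)


def bh_fdr(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection flags at level ``alpha``."""
    pvals = np.asarray(pvals, dtype=float)
    if np.any((pvals <= 0) | (pvals > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    reject, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    return reject


def run_screen(
    target: BrainMap,
    features: list[BrainMap],
    ensemble: SurrogateEnsemble,
    alphas: tuple[float, float, float] = (0.05, 0.05, 0.01),
    keep_nulls: bool = False,
) -> ScreenResult:
    """Correlate the target with every feature and test against the shared
    surrogate null. Bonferroni compares p to alpha_bf / n_features; the
    reported p-values themselves are never modified."""
    ensemble.check_target(target)
    for f in features:
        target.check_aligned(f)
    if not features:
        raise ValueError("empty feature panel")
    a_bf, a_fdr, a_unc = alphas
    surrogate_ranks = _ranks(ensemble.maps)
    rows = []
    nulls: dict[str, np.ndarray] = {}
    for f in features:
        rho = spearman(target, f)
        null = _null_spearmans(f.values, surrogate_ranks)
        p = surrogate_pvalue_two_sided(rho, null)
        rows.append({"name": f.name, "rho": rho, "p": p})
        if keep_nulls:
            nulls[f.name] = null
    df = pd.DataFrame(rows)
    F = len(df)
    df["sig_bonferroni"] = df["p"] <= a_bf / F
    df["sig_fdr"] = bh_fdr(df["p"].to_numpy(), alpha=a_fdr)
    df["sig_uncorrected"] = df["p"] <= a_unc
    df = df.sort_values("p", kind="stable").reset_index(drop=True)
    return ScreenResult(
        table=df,
        alphas=alphas,
        n_surrogates=ensemble.n_surrogates,
        null_rhos=nulls or None,
    )


def pvalue_histogram(
    result: ScreenResult, bins: int | np.ndarray = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of screen p-values over [0, 1] (right-open bins except the
    last). Returns (counts, bin_edges)."""
    if result.n_features == 0:
        raise ValueError("empty screen result")
    edges = (
        np.linspace(0, 1, bins + 1) if np.isscalar(bins) else np.asarray(bins)
    )
    counts, edges = np.histogram(result.table["p"].to_numpy(), bins=edges)
    return counts, edges
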