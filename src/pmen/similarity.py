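"""Absolute-Pearson similarity and random-matrix-theory threshold detection.

The co-occurrence network is cut from the matrix of absolute Pearson
correlations |r| between OTU relative-abundance profiles.  The similarity
threshold St — the minimal |r| retained as a link — is chosen by the
random-matrix-theory criterion: as the threshold rises, the nearest-
neighbour spacing distribution (NNSD) of the unfolded eigenvalues of the
thresholded matrix crosses from Gaussian-orthogonal-ensemble statistics
(level repulsion, the signature of a noise-dominated random system) to
Poisson statistics (uncorrelated level spacings, the signature of a
modular, system-specific structure).  St is the smallest threshold at
which a chi-square goodness-of-fit test stops rejecting the Poisson
spacing law, stably over the next two grid points.

Spectral unfolding rescales the eigenvalues so the local mean level
spacing is one everywhere, which is what makes the universal Poisson /
Wigner spacing laws comparable across spectra: e_i = N * F(lambda_i) with
F a smooth monotone fit to the empirical cumulative spectral function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

__all__ = [
    "SimilarityMatrix",
    "ThresholdScan",
    "pearson_similarity",
    "unfold_spectrum",
    "nnsd_chi_square",
    "scan_threshold",
]

#: minimum matrix order at which spacing statistics are still meaningful
MIN_SPECTRUM_SIZE = 30


class SpectrumTooSmallError(ValueError):
    """Too few eigenvalues for spacing statistics; the threshold scan must stop."""


@dataclass
class SimilarityMatrix:
    """Symmetric |Pearson r| matrix with the correlation signs kept aside.

    `sim` holds |r| in [0, 1] with a unit diagonal; `sign` holds the sign
    of the underlying r in {-1, 0, +1} so that the network built later can
    distinguish co-occurrence (positive) from co-exclusion (negative)
    links.
    """

    otu_ids: list[str]
    sim: np.ndarray
    sign: np.ndarray

    def __post_init__(self) -> None:
        self.sim = np.asarray(self.sim, dtype=float)
        self.sign = np.asarray(self.sign)
        n = len(self.otu_ids)
        if self.sim.shape != (n, n) or self.sign.shape != (n, n):
            raise ValueError("similarity matrices must be square and match otu_ids")
        if not np.allclose(self.sim, self.sim.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if np.any(self.sim < -1e-12) or np.any(self.sim > 1 + 1e-12):
            raise ValueError("similarities must lie in [0, 1]")
        if not np.allclose(np.diag(self.sim), 1.0):
            raise ValueError("similarity diagonal must be exactly 1")
        np.fill_diagonal(self.sim, 1.0)
        self.sim = np.clip(self.sim, 0.0, 1.0)

    @property
    def order(self) -> int:
        return len(self.otu_ids)

    def signed(self) -> np.ndarray:
        """The signed correlation matrix sign * |r|."""
        return self.sim * self.sign


@dataclass
class ThresholdScan:
    """Audit trail of an RMT threshold scan plus the chosen St."""

    trace: pd.DataFrame  # threshold, order, chi2_poisson, p_poisson, chi2_goe, p_goe, accepted
    st: float | None
    alpha: float
    stability: int = 2
    params: dict = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        self.trace.to_csv(path, sep="\t", index=False, float_format="%.6g")


def pearson_similarity(table) -> SimilarityMatrix:
    """|Pearson r| between all OTU abundance profiles across samples.

    Zero-variance OTU rows cannot be correlated and are dropped with a
    warning; fewer than 3 samples is an error.
    """
    import warnings

    if table.n_samples < 3:
        raise ValueError("Pearson similarity needs at least 3 samples")
    values = table.values
    var = values.var(axis=1)
    keep = var > 0
    if not keep.all():
        dropped = [o for o, k in zip(table.otu_ids, keep) if not k]
        warnings.warn(
            f"dropping {len(dropped)} zero-variance OTU row(s)", stacklevel=2
        )
    otu_ids = [o for o, k in zip(table.otu_ids, keep) if k]
    r = np.atleast_2d(np.corrcoef(values[keep]))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return SimilarityMatrix(otu_ids=otu_ids, sim=np.abs(r), sign=np.sign(r).astype(int))


def _collapse_degenerate(eigenvalues: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Collapse eigenvalue clusters closer than `tol` to a single level."""
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    if lam.size == 0:
        return lam
    keep = np.concatenate(([True], np.diff(lam) > tol))
    return lam[keep]


def _drop_detached_levels(lam: np.ndarray) -> np.ndarray:
    """Exclude eigenvalues far above the bulk before unfolding.

    Thresholded correlation matrices carry a few large module (Perron)
    eigenvalues detached from the bulk.  These levels are non-universal —
    they encode the planted structure, not level statistics — and a smooth
    unfolding cannot track the density gap around them, so they are
    excluded from the spacing analysis.  "Detached" = above the bulk's
    75th percentile by more than five times the 10-90 percentile span.
    """
    span = np.percentile(lam, 90) - np.percentile(lam, 10)
    keep = lam <= np.percentile(lam, 75) + 5.0 * span
    if keep.sum() >= MIN_SPECTRUM_SIZE:
        return lam[keep]
    return lam


def unfold_spectrum(eigenvalues: np.ndarray, knots: int | None = None) -> np.ndarray:
    """Unfold a spectrum so the mean nearest-neighbour spacing is one.

    A monotone cubic (PCHIP) spline is fit through a thinned set of points
    of the empirical cumulative spectral function, and each eigenvalue is
    mapped through it: e_i = F_smooth(lambda_i) counts how many levels lie
    below lambda_i on a smoothed scale.  Near-degenerate eigenvalues
    (gap < 1e-10) are collapsed first so spacing statistics are not
    dominated by numerically repeated levels, and detached module
    eigenvalues are excluded (see `_drop_detached_levels`).
    """
    lam = _collapse_degenerate(eigenvalues)
    n = lam.size
    if n < MIN_SPECTRUM_SIZE:
        raise SpectrumTooSmallError(
            f"only {n} distinct eigenvalues; need >= {MIN_SPECTRUM_SIZE} "
            "(stop the threshold scan)"
        )
    lam = _drop_detached_levels(lam)
    n = lam.size
    if knots is None:
        knots = max(3, math.ceil(n / 20))
    # interior + end knots on the empirical cumulative spectral function
    idx = np.unique(np.linspace(0, n - 1, knots + 2).round().astype(int))
    x = lam[idx]
    y = idx + 1.0  # cumulative level count at each knot
    # guard against duplicate abscissae after collapsing
    x, unique_idx = np.unique(x, return_index=True)
    y = y[unique_idx]
    spline = PchipInterpolator(x, y)
    unfolded = np.asarray(spline(lam), dtype=float)
    return np.maximum.accumulate(unfolded)


def _law_cdf(d: np.ndarray, law: str) -> np.ndarray:
    """CDF of the nearest-neighbour spacing law at spacings `d`."""
    d = np.asarray(d, dtype=float)
    if law == "poisson":
        # P(d) = exp(-d): uncorrelated levels
        return 1.0 - np.exp(-d)
    if law == "goe":
        # Wigner surmise P(d) = (pi d / 2) exp(-pi d^2 / 4): level repulsion
        return 1.0 - np.exp(-np.pi * d * d / 4.0)
    raise ValueError(f"unknown spacing law {law!r}")


def nnsd_chi_square(unfolded: np.ndarray, law: str, bin_width: float = 0.1,
                    range_max: float = 3.0,
                    min_expected: float = 5.0) -> tuple[float, float]:
    """Chi-square goodness of fit of the NNSD against a universal spacing law.

    Spacings d_i = e_{i+1} - e_i are binned on [0, range_max] (plus an open
    tail bin) and compared to the expected bin mass under the Poisson law
    exp(-d) or the GOE Wigner surmise.  Adjacent bins are pooled until each
    expected count reaches `min_expected` (Cochran's rule — without pooling
    the chi-square approximation is anti-conservative in the sparse tail);
    degrees of freedom = pooled bin count - 1 (no parameter is estimated).
    """
    unfolded = np.asarray(unfolded, dtype=float)
    spacings = np.diff(unfolded)
    if spacings.size == 0:
        raise ValueError("empty spacing set")
    edges = np.arange(0.0, range_max + bin_width / 2, bin_width)
    observed = np.append(np.histogram(spacings, bins=edges)[0],
                         int(np.sum(spacings >= range_max)))
    cdf = _law_cdf(edges, law)
    prob = np.append(np.diff(cdf), 1.0 - cdf[-1])
    expected = prob * spacings.size
    pooled_o: list[float] = []
    pooled_e: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            pooled_o.append(acc_o)
            pooled_e.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0:  # leftover tail mass joins the last pooled bin
        if pooled_e:
            pooled_o[-1] += acc_o
            pooled_e[-1] += acc_e
        else:
            pooled_o.append(acc_o)
            pooled_e.append(acc_e)
    obs_arr = np.asarray(pooled_o)
    exp_arr = np.asarray(pooled_e)
    statistic = float(np.sum((obs_arr - exp_arr) ** 2 / exp_arr))
    df = max(1, len(exp_arr) - 1)
    pvalue = float(stats.chi2.sf(statistic, df))
    return statistic, pvalue


def _prune(sim: np.ndarray, threshold: float) -> np.ndarray:
    """Zero entries below `threshold` and drop rows/cols with no survivor."""
    m = sim.copy()
    off = m < threshold
    np.fill_diagonal(off, False)
    m[off] = 0.0
    deg = (m > 0).sum(axis=0) - 1  # off-diagonal survivors per row
    keep = deg > 0
    return m[np.ix_(keep, keep)]


def scan_threshold(similarity: SimilarityMatrix, grid_start: float = 0.30,
                   grid_stop: float = 0.99, grid_step: float = 0.01,
                   alpha: float = 0.05, min_order: int = MIN_SPECTRUM_SIZE,
                   stability: int = 2) -> ThresholdScan:
    """Scan candidate thresholds and pick St by the RMT Poisson criterion.

    For each grid value s (ascending) the similarity matrix is thresholded
    at s, rows/columns without an off-diagonal survivor are removed, and
    the NNSD of the unfolded eigenvalues of the pruned weighted matrix is
    tested against the Poisson law.  The chosen St is the smallest s whose
    Poisson p-value exceeds `alpha` and stays above `alpha` for the next
    `stability` grid points — a guard against single-point acceptances
    driven by binning noise.  The scan stops when the pruned matrix drops
    below `min_order`.
    """
    n_steps = int(round((grid_stop - grid_start) / grid_step)) + 1
    grid = np.round(grid_start + grid_step * np.arange(n_steps), 10)
    rows = []
    pvals: list[float] = []
    for s in grid:
        pruned = _prune(similarity.sim, s)
        order = pruned.shape[0]
        if order < min_order:
            break
        eigenvalues = np.linalg.eigvalsh(pruned)
        try:
            unfolded = unfold_spectrum(eigenvalues)
        except SpectrumTooSmallError:
            break
        chi2_p, p_p = nnsd_chi_square(unfolded, "poisson")
        chi2_g, p_g = nnsd_chi_square(unfolded, "goe")
        rows.append(
            dict(threshold=float(s), order=order, chi2_poisson=chi2_p,
                 p_poisson=p_p, chi2_goe=chi2_g, p_goe=p_g, accepted=False)
        )
        pvals.append(p_p)
    trace = pd.DataFrame(
        rows, columns=["threshold", "order", "chi2_poisson", "p_poisson",
                       "chi2_goe", "p_goe", "accepted"],
    )
    st = None
    for i in range(len(pvals)):
        window = pvals[i:i + stability + 1]
        if len(window) >= 1 and all(p > alpha for p in window) and (
            len(window) == stability + 1 or i + stability >= len(pvals)
        ):
            st = float(trace.loc[i, "threshold"])
            trace.loc[i, "accepted"] = True
            break
    params = dict(grid_start=grid_start, grid_stop=grid_stop, grid_step=grid_step,
                  alpha=alpha, min_order=min_order, stability=stability)
    if st is None:
        raise RuntimeError(
            "no threshold accepted by the Poisson spacing criterion before the "
            f"matrix shrank below order {min_order}; scan trace:\n{trace.to_string()}"
        )
    return ThresholdScan(trace=trace, st=st, alpha=alpha, stability=stability,
                         params=params)
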