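"""Structured covariance estimation via James-Stein-type shrinkage.

The per-peptide data matrix X (replicates x 2I columns, condition-1 fragments
followed by condition-2 fragments) yields sample correlations that are shrunk
toward zero and sample variances shrunk toward their median, with intensities
estimated from the data (Schafer-Strimmer / Opgen-Rhein-Strimmer).  Combined
with the cross-replicate term d -- estimated globally from summarized peptide
quantities via a KDE-mode / split-quantile procedure -- this gives the
structured covariance (a, b, d) feeding the shrinkage t statistic.

All heavy lifting is implemented batched over a leading axis so that the
bootstrap (and whole-dataset fits) run without Python-level loops.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .generative import CovStructure

__all__ = [
    "PeptideBlock",
    "ShrinkageFit",
    "DEstimate",
    "InsufficientReplicatesError",
    "sample_moments",
    "estimate_lambda_corr",
    "estimate_lambda_var",
    "shrink_covariance",
    "pool_conditions",
    "kde_mode",
    "split_quantile_sd",
    "estimate_d",
    "assemble_cov",
    "variance_of_L",
]


class InsufficientReplicatesError(ValueError):
    """Raised when a peptide block has fewer than 2 replicates."""


@dataclass(frozen=True)
class PeptideBlock:
    """Complete two-condition data matrix for one peptide.

    ``X`` has shape (R, 2I): rows are replicates, columns are log10 fragment
    quantities ordered (condition 1, fragments 1..I, condition 2, fragments
    1..I).  Both conditions must contribute the same replicate count.
    """

    peptide: str
    X: np.ndarray

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D (replicates x 2I) matrix")
        if X.shape[1] % 2 != 0 or X.shape[1] < 2:
            raise ValueError("X must have an even number of columns (2 conditions)")
        if X.shape[0] < 2:
            raise InsufficientReplicatesError(
                f"peptide {self.peptide!r}: need >= 2 replicates, got {X.shape[0]}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("X must contain no missing or non-finite entries")
        object.__setattr__(self, "X", X)

    @property
    def n_replicates(self) -> int:
        return self.X.shape[0]

    @property
    def n_fragments(self) -> int:
        return self.X.shape[1] // 2


class SampleMoments(NamedTuple):
    mean: np.ndarray
    cov: np.ndarray
    corr: np.ndarray
    zero_variance: np.ndarray  # bool mask of degenerate (constant) columns


@dataclass(frozen=True)
class ShrinkageFit:
    """Result of shrinking one peptide block's covariance."""

    sample_cov: np.ndarray      # (2I, 2I)
    sample_corr: np.ndarray     # (2I, 2I), degenerate columns flagged 0
    lambda_corr: float
    lambda_var: float
    s_median: float
    corr_shrunk: np.ndarray     # (2I, 2I)
    cov_shrunk: np.ndarray      # (2I, 2I)
    zero_variance: np.ndarray   # (2I,) bool

    @property
    def n_fragments(self) -> int:
        return self.sample_cov.shape[0] // 2


@dataclass(frozen=True)
class DEstimate:
    """Diagnostics of the cross-replicate covariance estimate d."""

    z: np.ndarray               # (C, R, P) normalized log10 peptide quantities
    median_by_condition: np.ndarray
    median_overall: float
    z_bar: np.ndarray           # (C, P) replicate means
    mode: float
    var_total: float            # Var-hat(mu + delta + zeta)
    sd_mu: float                # split-quantile SD of mu
    d: float                    # max(0, var_total - sd_mu**2)


# ---------------------------------------------------------------------------
# batched core


def _as_batch(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return X[None] if X.ndim == 2 else X


def _batch_moments(Xb: np.ndarray):
    """Means, unbiased covariances and correlations for a (B, R, m) stack.

    Correlations involving zero-variance columns are set to 0 off-diagonal
    (their diagonal stays 1 only through the shrunk-correlation convention).
    """
    B, R, m = Xb.shape
    mean = Xb.mean(axis=1)
    xc = Xb - mean[:, None, :]
    cov = np.einsum("bri,brj->bij", xc, xc) / (R - 1)
    var = np.einsum("bii->bi", cov)
    sd = np.sqrt(np.maximum(var, 0.0))
    zero = sd <= 0.0
    sd_safe = np.where(zero, 1.0, sd)
    corr = cov / (sd_safe[:, :, None] * sd_safe[:, None, :])
    degenerate = zero[:, :, None] | zero[:, None, :]
    corr = np.where(degenerate, 0.0, corr)
    return mean, cov, corr, xc, sd_safe, zero


def _batch_lambdas(Xb: np.ndarray):
    """Shrinkage intensities (lambda_corr, lambda_var) per batch element.

    lambda_corr = clip(sum_{i!=j} Var-hat(r_ij) / sum_{i!=j} r_ij^2, 0, 1)
    with Var-hat(r_ij) = R/(R-1)^3 * sum_k (w_kij - w-bar_ij)^2 computed from
    products of standardized columns; zero-variance columns contribute 0 to
    both sums.  lambda_var analogous with squared deviations and the median
    variance target.  A zero denominator maps to intensity 1.
    """
    B, R, m = Xb.shape
    _, cov, corr, xc, sd_safe, zero = _batch_moments(Xb)
    xt = xc / sd_safe[:, None, :]
    xt = np.where(zero[:, None, :], 0.0, xt)

    w = np.einsum("bri,brj->brij", xt, xt)
    w_bar = w.mean(axis=1)
    var_r = R / (R - 1) ** 3 * ((w - w_bar[:, None]) ** 2).sum(axis=1)
    off = ~np.eye(m, dtype=bool)
    num_c = (var_r * off).sum(axis=(1, 2))
    den_c = (corr ** 2 * off).sum(axis=(1, 2))
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(den_c > 0, num_c / den_c, 1.0)
    lam = np.clip(lam, 0.0, 1.0)

    v = xc ** 2
    var_s = R / (R - 1) ** 3 * ((v - v.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.einsum("bii->bi", cov)
    s_median = np.median(s, axis=1)
    den_v = ((s - s_median[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam_v = np.where(den_v > 0, var_s.sum(axis=1) / den_v, 1.0)
    lam_v = np.clip(lam_v, 0.0, 1.0)
    return lam, lam_v, cov, corr, s, s_median, zero


def _batch_shrunk_cov(Xb: np.ndarray):
    """Shrunk covariance stack (B, m, m) plus intensities and diagnostics."""
    lam, lam_v, cov, corr, s, s_median, zero = _batch_lambdas(Xb)
    m = Xb.shape[2]
    eye = np.eye(m, dtype=bool)
    corr_shrunk = (1.0 - lam)[:, None, None] * corr
    corr_shrunk[:, eye] = 1.0
    s_shrunk = (1.0 - lam_v)[:, None] * s + lam_v[:, None] * s_median[:, None]
    sd_shrunk = np.sqrt(np.maximum(s_shrunk, 0.0))
    cov_shrunk = corr_shrunk * sd_shrunk[:, :, None] * sd_shrunk[:, None, :]
    return cov_shrunk, lam, lam_v, cov, corr, s_median, zero, corr_shrunk


def _variance_of_L_terms(
    a_sum: np.ndarray, b_sum: np.ndarray, d: float, R: int, I: int
) -> np.ndarray:
    return 2.0 / R * a_sum - 2.0 / R * b_sum + 2.0 * I ** 2 * (R - 1) / R * d


def batched_L_and_se(Xb: np.ndarray, d: float) -> tuple[np.ndarray, np.ndarray]:
    """Estimate (L-hat, SE(L-hat)) for every block of a (B, R, 2I) stack.

    Runs the full shrinkage pipeline per block (intensities, shrunk
    covariance, condition pooling, structured-variance formula) with the
    cross-replicate term ``d`` held fixed.  Non-positive plug-in variances are
    floored at a small positive epsilon.
    """
    Xb = _as_batch(Xb)
    B, R, m = Xb.shape
    I = m // 2
    cov_shrunk, *_ = _batch_shrunk_cov(Xb)
    pooled = (cov_shrunk[:, :I, :I] + cov_shrunk[:, I:, I:]) / 2.0
    cross = cov_shrunk[:, :I, I:]
    a_sum = pooled.sum(axis=(1, 2)) + I * I * d
    b_sum = cross.sum(axis=(1, 2))
    var_L = _variance_of_L_terms(a_sum, b_sum, d, R, I)
    mean_var = np.einsum("bii->bi", cov_shrunk).mean(axis=1)
    eps = np.maximum(1e-12 * mean_var, 1e-300)
    var_L = np.where(var_L > 0, var_L, eps)
    mean = Xb.mean(axis=1)
    L = (mean[:, :I] - mean[:, I:]).sum(axis=1)
    return L, np.sqrt(var_L)


# ---------------------------------------------------------------------------
# public single-block operations


def sample_moments(block: PeptideBlock) -> SampleMoments:
    """Column means, unbiased sample covariance and correlation of a block.

    Correlations of zero-variance columns are defined as 0 off-diagonal and
    reported through the ``zero_variance`` flag.
    """
    mean, cov, corr, _, _, zero = _batch_moments(_as_batch(block.X))
    if zero[0].any():
        warnings.warn(
            f"peptide {block.peptide!r}: zero-variance column(s); their "
            "correlations are defined as 0",
            stacklevel=2,
        )
    return SampleMoments(mean[0], cov[0], corr[0], zero[0])


def estimate_lambda_corr(block: PeptideBlock) -> float:
    """Correlation-shrinkage intensity lambda-hat in [0, 1]."""
    lam, _, *_ = _batch_lambdas(_as_batch(block.X))
    return float(lam[0])


def estimate_lambda_var(block: PeptideBlock) -> float:
    """Variance-shrinkage intensity lambda-hat_v in [0, 1]."""
    _, lam_v, *_ = _batch_lambdas(_as_batch(block.X))
    return float(lam_v[0])


def shrink_covariance(block: PeptideBlock) -> ShrinkageFit:
    """Shrink the block's sample correlations toward 0 and variances toward
    their median, returning the full fit."""
    (cov_shrunk, lam, lam_v, cov, corr, s_median, zero, corr_shrunk) = (
        _batch_shrunk_cov(_as_batch(block.X))
    )
    return ShrinkageFit(
        sample_cov=cov[0],
        sample_corr=corr[0],
        lambda_corr=float(lam[0]),
        lambda_var=float(lam_v[0]),
        s_median=float(s_median[0]),
        corr_shrunk=corr_shrunk[0],
        cov_shrunk=cov_shrunk[0],
        zero_variance=zero[0],
    )


def pool_conditions(fit: ShrinkageFit) -> np.ndarray:
    """Average the two within-condition shrunk covariance blocks (I x I)."""
    I = fit.n_fragments
    pooled = (fit.cov_shrunk[:I, :I] + fit.cov_shrunk[I:, I:]) / 2.0
    return (pooled + pooled.T) / 2.0


class KdeMode(NamedTuple):
    mode: float
    degenerate: bool


def kde_mode(values, grid_size: int = 512) -> KdeMode:
    """Argmax of a Gaussian-kernel density estimate.

    Bandwidth is the rule of thumb 0.9 * min(sd, IQR/1.34) * n^(-1/5); the
    density is evaluated on a ``grid_size``-point grid spanning the data range
    +/- 3 bandwidths, ties broken toward the smallest grid point.  Fewer than
    two distinct values returns that value with ``degenerate=True``.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("kde_mode needs at least one value")
    if np.unique(v).size < 2:
        return KdeMode(float(v[0]), True)
    n = v.size
    sd = float(np.std(v, ddof=1))
    iqr = float(np.subtract(*np.percentile(v, [75, 25])))
    width = min(sd, iqr / 1.34) if iqr > 0 else sd
    if width <= 0:
        width = sd
    bw = 0.9 * width * n ** (-0.2)
    grid = np.linspace(v.min() - 3 * bw, v.max() + 3 * bw, grid_size)
    dens = np.empty(grid_size)
    step = max(1, int(2**22 // max(n, 1)))  # cap the (grid x n) work matrix
    for start in range(0, grid_size, step):
        chunk = grid[start : start + step]
        dens[start : start + step] = np.exp(
            -0.5 * ((chunk[:, None] - v[None, :]) / bw) ** 2
        ).sum(axis=1)
    return KdeMode(float(grid[int(np.argmax(dens))]), False)


_P_GRID = np.round(np.arange(0.30, 1.00, 0.01), 2)  # 0.30 .. 0.99


def split_quantile_sd(values, mode: float, p_grid: np.ndarray = _P_GRID) -> float:
    """Half-sample quantile estimate of the SD of the symmetric component.

    Splits values at ``mode`` into Z1 = {mode - v : v <= mode} and
    Z2 = {v - mode : v > mode} and returns the minimum over sides and the
    probability grid of quantile(Z_s, p) / PhiInv(0.5 + p/2).  An empty side
    is excluded from the minimum.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("split_quantile_sd needs at least one value")
    z1 = mode - v[v <= mode]
    z2 = v[v > mode] - mode
    denom = stats.norm.ppf(0.5 + p_grid / 2.0)
    candidates = []
    for z in (z1, z2):
        if z.size:
            candidates.append(np.quantile(z, p_grid) / denom)
    return float(np.min(np.concatenate(candidates)))


def estimate_d(y: np.ndarray) -> DEstimate:
    """Estimate the cross-replicate covariance d from peptide summaries.

    ``y`` has shape (C, R, P): log10 summarized peptide quantities for one
    two-condition comparison.  Quantities are median-normalized per condition
    (removing the fixed condition offset), averaged over replicates, and the
    variance of the symmetric peptide-mean component -- obtained from the KDE
    mode and split-quantile SD -- is subtracted from the total variance of the
    replicate means.  The result is clamped at 0.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 3:
        raise ValueError("y must have shape (conditions, replicates, peptides)")
    C, R, P = y.shape
    if C * P < 2:
        raise ValueError("need at least 2 peptide-condition means to estimate d")
    m_c = np.median(y.reshape(C, -1), axis=1)
    m = float(np.median(y))
    z = y - m_c[:, None, None] + m
    z_bar = z.mean(axis=1)  # (C, P)
    flat = z_bar.ravel()
    var_total = float(np.var(flat, ddof=1))
    mode = kde_mode(flat).mode
    sd_mu = split_quantile_sd(flat, mode)
    d = max(0.0, var_total - sd_mu ** 2)
    return DEstimate(
        z=z,
        median_by_condition=m_c,
        median_overall=m,
        z_bar=z_bar,
        mode=mode,
        var_total=var_total,
        sd_mu=sd_mu,
        d=d,
    )


def assemble_cov(fit: ShrinkageFit, d: float) -> CovStructure:
    """Assemble the structured covariance from a fit and the global d-hat:
    a = d + pooled within-condition block, b = cross-condition block."""
    I = fit.n_fragments
    pooled = pool_conditions(fit)
    return CovStructure(a=d + pooled, b=fit.cov_shrunk[:I, I:].copy(), d=d)


def variance_of_L(cov: CovStructure, R: int, I: int) -> float:
    """Structured-covariance variance of L-hat:

        (2/R) sum(a) - (2/R) sum(b) + (2 I^2 (R-1)/R) d,

    floored at a small positive epsilon (with a warning) if non-positive.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    if cov.n_fragments != I:
        raise ValueError(
            f"covariance is {cov.n_fragments}x{cov.n_fragments}, expected I={I}"
        )
    value = float(_variance_of_L_terms(cov.a.sum(), cov.b.sum(), cov.d, R, I))
    if value <= 0:
        eps = max(1e-12 * float(np.mean(np.diag(cov.a))), 1e-300)
        warnings.warn(
            f"non-positive plug-in Var(L) = {value:.3g}; floored at {eps:.3g}",
            stacklevel=2,
        )
        return eps
    return value
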