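"""Peptide-level tests: shrinkage t with bootstrap degrees-of-freedom, plus
classical feature-based paired t and two-step Welch t baselines."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .shrinkage import (
    DEstimate,
    PeptideBlock,
    assemble_cov,
    batched_L_and_se,
    estimate_d,
    shrink_covariance,
    variance_of_L,
)

__all__ = [
    "TestResult",
    "BootstrapConfig",
    "summarize_peptide",
    "shrinkage_estimate_L",
    "a_R_schedule",
    "df_from_bootstrap_variance",
    "bootstrap_df",
    "shrinkage_t_test",
    "paired_t_test",
    "independent_t_test",
    "blocks_from_array",
    "summarized_log_quantities",
    "estimate_d_from_blocks",
    "run_tests",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of one peptide-level two-condition test."""

    __test__ = False  # not a pytest class, despite the name

    peptide: str
    estimate: float          # L-hat, log10 units
    se: float
    t: float
    df: float                # may be math.inf (normal reference)
    pvalue: float
    method: str
    flags: tuple[str, ...] = ()
    diagnostics: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BootstrapConfig:
    """Settings for the additive bootstrap degrees-of-freedom estimate."""

    n_boot: int = 100
    a_r: float | None = None  # None -> a_R_schedule(R)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if self.a_r is not None and self.a_r <= 0:
            raise ValueError("a_r must be > 0")


def summarize_peptide(
    quantities: np.ndarray, n_top: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sum the top ``n_top`` fragments per run and return (q, y = log10 q).

    ``quantities`` is (n_fragments, n_runs) -- or 1-D for a single run.
    Fragments are ranked by mean quantity across all provided runs
    (descending, ties broken by row index); fewer than ``n_top`` fragments
    are summed as-is without padding.
    """
    q = np.asarray(quantities, dtype=float)
    single = q.ndim == 1
    if single:
        q = q[:, None]
    if q.ndim != 2 or q.shape[0] == 0:
        raise ValueError("quantities must be a (fragments x runs) array")
    if np.any(q.sum(axis=0) <= 0):
        raise ValueError("each run needs at least one positive fragment quantity")
    order = np.lexsort((np.arange(q.shape[0]), -q.mean(axis=1)))
    top = order[: min(n_top, q.shape[0])]
    summed = q[top].sum(axis=0)
    y = np.log10(summed)
    if single:
        return float(summed[0]), float(y[0])
    return summed, y


def shrinkage_estimate_L(block: PeptideBlock) -> float:
    """Group mean-difference estimate sum_i (xbar_1i - xbar_2i)."""
    I = block.n_fragments
    mean = block.X.mean(axis=0)
    return float((mean[:I] - mean[I:]).sum())


def a_R_schedule(R: int) -> float:
    """Bootstrap stabilization constant a_R = 2.4 * R^(-3/2) (a_4 = 0.3)."""
    if R < 2:
        raise ValueError("R must be >= 2")
    return 2.4 * R ** -1.5


def df_from_bootstrap_variance(s2: float) -> float:
    """Map the bootstrap-statistic variance s*^2 to Student-t df:
    2 s*^2 / (s*^2 - 1) for s*^2 > 1, infinity otherwise."""
    if s2 > 1.0:
        return 2.0 * s2 / (s2 - 1.0)
    return math.inf


def bootstrap_df(
    block: PeptideBlock, d: float, cfg: BootstrapConfig
) -> tuple[float, float]:
    """Additive-bootstrap degrees-of-freedom (nu, s*^2) for one block.

    Resamples whole replicate rows with replacement, recomputes L-hat and the
    shrinkage SE per resample (d held fixed), stabilizes the denominator with
    a_R, and converts the bootstrap-statistic variance to df.
    """
    R = block.n_replicates
    a_r = cfg.a_r if cfg.a_r is not None else a_R_schedule(R)
    rng = np.random.default_rng(cfg.seed)
    idx = rng.integers(0, R, size=(cfg.n_boot, R))
    L, se = batched_L_and_se(block.X[idx], d)
    t_boot = L / (se + a_r)
    s2 = float(np.var(t_boot, ddof=1))
    return df_from_bootstrap_variance(s2), s2


def _two_sided_p(t: float, df: float) -> float:
    if math.isinf(df):
        return float(2.0 * stats.norm.sf(abs(t)))
    return float(2.0 * stats.t.sf(abs(t), df))


def shrinkage_t_test(
    block: PeptideBlock, d: float, cfg: BootstrapConfig
) -> TestResult:
    """Shrinkage t test for one peptide given the global d-hat."""
    R, I = block.n_replicates, block.n_fragments
    fit = shrink_covariance(block)
    cov = assemble_cov(fit, d)
    var_L = variance_of_L(cov, R, I)
    se = math.sqrt(var_L)
    L = shrinkage_estimate_L(block)
    t = L / se
    df, s2 = bootstrap_df(block, d, cfg)
    return TestResult(
        peptide=block.peptide,
        estimate=L,
        se=se,
        t=t,
        df=df,
        pvalue=_two_sided_p(t, df),
        method="shrinkage",
        diagnostics={
            "lambda_corr": fit.lambda_corr,
            "lambda_var": fit.lambda_var,
            "d": d,
            "s2_boot": s2,
            "a_r": cfg.a_r if cfg.a_r is not None else a_R_schedule(R),
        },
    )


def paired_t_test(block: PeptideBlock) -> TestResult:
    """Feature-based paired t test over all I*R fragment-replicate pairs."""
    I = block.n_fragments
    diffs = (block.X[:, :I] - block.X[:, I:]).ravel()
    n = diffs.size
    if n < 2:
        raise ValueError("paired t test needs at least 2 paired differences")
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    flags: tuple[str, ...] = ()
    if sd == 0.0:
        # Degenerate: identical differences.  Zero mean -> no evidence.
        if mean == 0.0:
            t, p = 0.0, 1.0
        else:
            t, p = math.copysign(math.inf, mean), 0.0
        flags = ("degenerate_sd",)
        se = 0.0
    else:
        se = sd / math.sqrt(n)
        t = mean / se
        p = _two_sided_p(t, n - 1)
    return TestResult(
        peptide=block.peptide,
        estimate=mean,
        se=se,
        t=t,
        df=float(n - 1),
        pvalue=p,
        method="paired",
        flags=flags,
    )


def independent_t_test(
    y1: Sequence[float], y2: Sequence[float], peptide: str = ""
) -> TestResult:
    """Two-step Welch t test on summarized per-run peptide quantities."""
    a = np.asarray(y1, dtype=float)
    b = np.asarray(y2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 summarized values per condition")
    res = stats.ttest_ind(a, b, equal_var=False)
    se = math.sqrt(a.var(ddof=1) / a.size + b.var(ddof=1) / b.size)
    t = float(res.statistic)
    if not np.isfinite(t):  # identical constant groups
        t = 0.0
    return TestResult(
        peptide=peptide,
        estimate=float(a.mean() - b.mean()),
        se=se,
        t=t,
        df=float(res.df),
        pvalue=float(res.pvalue) if np.isfinite(res.pvalue) else 1.0,
        method="independent",
    )


# ---------------------------------------------------------------------------
# dataset-level drivers


def blocks_from_array(x: np.ndarray, peptide_ids: Sequence[str] | None = None):
    """Turn a simulated (2, R, P, I) log10 array into P peptide blocks."""
    if x.ndim != 4 or x.shape[0] != 2:
        raise ValueError("x must have shape (2, R, P, I)")
    _, R, P, I = x.shape
    stacked = np.concatenate([x[0], x[1]], axis=2)  # (R, P, 2I)
    if peptide_ids is None:
        peptide_ids = [f"pep_{p}" for p in range(P)]
    return [PeptideBlock(peptide_ids[p], stacked[:, p, :]) for p in range(P)]


def summarized_log_quantities(blocks: Sequence[PeptideBlock]) -> np.ndarray:
    """y[c, r, p] = log10 of the summed fragment quantities of each block."""
    R = blocks[0].n_replicates
    I = blocks[0].n_fragments
    y = np.empty((2, R, len(blocks)))
    for p, block in enumerate(blocks):
        f = 10.0 ** block.X
        y[0, :, p] = np.log10(f[:, :I].sum(axis=1))
        y[1, :, p] = np.log10(f[:, I:].sum(axis=1))
    return y


def estimate_d_from_blocks(blocks: Sequence[PeptideBlock]) -> DEstimate:
    """Global d-hat for one comparison from all of its complete blocks."""
    return estimate_d(summarized_log_quantities(blocks))


def run_tests(
    blocks: Sequence[PeptideBlock],
    method: str = "shrinkage",
    cfg: BootstrapConfig | None = None,
    d: float | None = None,
) -> list[TestResult]:
    """Apply one method to every block of a comparison.

    For the shrinkage method, ``d`` defaults to the global estimate from all
    blocks; per-peptide bootstrap seeds are spawned deterministically from
    ``cfg.seed``.
    """
    if method == "shrinkage":
        cfg = cfg or BootstrapConfig()
        if d is None:
            d = estimate_d_from_blocks(blocks).d
        seeds = np.random.SeedSequence(cfg.seed).spawn(len(blocks))
        out = []
        for block, ss in zip(blocks, seeds):
            cfg_p = BootstrapConfig(
                n_boot=cfg.n_boot, a_r=cfg.a_r, seed=ss.generate_state(1)[0]
            )
            out.append(shrinkage_t_test(block, d, cfg_p))
        return out
    if method == "paired":
        return [paired_t_test(block) for block in blocks]
    if method == "independent":
        y = summarized_log_quantities(blocks)
        return [
            independent_t_test(y[0, :, p], y[1, :, p], peptide=block.peptide)
            for p, block in enumerate(blocks)
        ]
    raise ValueError(f"unknown method {method!r}")
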