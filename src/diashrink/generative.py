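"""Hierarchical generative model for fragment-level DIA-MS quantities.

The observed log10 fragment quantity decomposes additively as

    x[c, r, p, i] = mu_p[p] + delta[c] + zeta[c, p] + e[c, r, p] + xi[c, r, p, i]

where

* ``mu_p`` is the peptide's true mean log10 quantity, drawn from N(mu, sigma^2);
* ``delta[c]`` is a fixed per-condition offset (``delta[0] == 0`` by convention);
* ``zeta = log10(u)`` with ``u ~ Beta(alpha0, beta0)`` the data-acquisition
  rate, drawn once per (condition, peptide) and shared by all replicates;
* ``e ~ N(0, sigma_cp^2)`` is the per-run sampling error;
* ``xi = log10(w)`` with ``w`` a Dirichlet-distributed ionization-efficiency
  vector over the top-I fragment ions, possibly correlated across conditions
  at equal replicate index.

The linear-scale quantity is ``f = 10**x``, and by construction the fragment
shares ``f / sum_i f`` reconstruct ``w``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import polygamma

__all__ = [
    "ModelParams",
    "LatentDraws",
    "FragmentTable",
    "CovStructure",
    "logbeta_variance",
    "logbeta_mean",
    "logdirichlet_cov",
    "sample_correlated_ionization",
    "simulate_arrays",
    "simulate_dataset",
    "true_cov_structure",
]

_LN10 = np.log(10.0)
_LN10_SQ = _LN10 ** 2

FRAGMENT_COLUMNS = (
    "protein",
    "precursor",
    "fragment",
    "condition",
    "replicate",
    "quantity",
    "log10_quantity",
)


@dataclass(frozen=True)
class ModelParams:
    """Hyperparameters of the hierarchical generative model.

    Defaults reproduce the reference simulation setting: I=3 fragment ions,
    P=500 peptides, R=4 replicates, sigma_cp=0.2, Beta(2, 10) acquisition
    rates, Dirichlet(2, 2, 2) ionization efficiencies, mu=5, sigma=1 and a
    cross-condition ionization correlation of rho=0.89.
    """

    n_conditions: int = 2
    n_replicates: int = 4
    n_peptides: int = 500
    n_fragments: int = 3
    mu: float = 5.0
    sigma: float = 1.0
    delta: tuple[float, ...] = (0.0, 0.0)
    sigma_cp: float = 0.2
    alpha0: float = 2.0
    beta0: float = 10.0
    alpha_dirichlet: tuple[float, ...] = (2.0, 2.0, 2.0)
    rho: float = 0.89

    def __post_init__(self) -> None:
        for name in ("n_conditions", "n_replicates", "n_peptides", "n_fragments"):
            value = getattr(self, name)
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {value!r}")
        if self.sigma < 0 or self.sigma_cp < 0:
            raise ValueError("sigma and sigma_cp must be >= 0")
        if self.alpha0 <= 0 or self.beta0 <= 0:
            raise ValueError("alpha0 and beta0 must be > 0")
        alpha = np.asarray(self.alpha_dirichlet, dtype=float)
        if alpha.ndim != 1 or alpha.size != self.n_fragments or np.any(alpha <= 0):
            raise ValueError(
                "alpha_dirichlet must be a positive vector of length n_fragments"
            )
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        delta = np.asarray(self.delta, dtype=float)
        if delta.ndim != 1 or delta.size != self.n_conditions:
            raise ValueError("delta must have one offset per condition")

    def with_delta(self, delta2: float) -> "ModelParams":
        """Two-condition convenience: offsets (0, delta2)."""
        if self.n_conditions != 2:
            raise ValueError("with_delta requires n_conditions == 2")
        return dataclasses.replace(self, delta=(0.0, float(delta2)))


@dataclass(frozen=True)
class LatentDraws:
    """Latent variables of one simulated dataset (test instrumentation).

    Array axes follow (condition, replicate, peptide[, fragment]); ``u_cp``
    and ``zeta_cp`` are (condition, peptide) because the acquisition rate is
    shared across replicates.
    """

    mu_p: np.ndarray          # (P,)
    u_cp: np.ndarray          # (C, P)
    zeta_cp: np.ndarray       # (C, P)
    w_cirp: np.ndarray        # (C, R, P, I)
    xi_cirp: np.ndarray       # (C, R, P, I)
    e_crp: np.ndarray         # (C, R, P)
    mu_tilde_cp: np.ndarray   # (C, P)
    delta_xi_irp: np.ndarray | None  # (R, P, I), conditions 1 - 2, None if C < 2

    def __post_init__(self) -> None:
        if np.any(self.u_cp <= 0) or np.any(self.u_cp > 1):
            raise ValueError("acquisition rates must lie in (0, 1]")
        if np.any(self.zeta_cp > 0):
            raise ValueError("zeta = log10(u) must be <= 0")
        sums = self.w_cirp.sum(axis=-1)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("ionization efficiencies must sum to 1 per draw")


@dataclass
class FragmentTable:
    """Long-format table of observed fragment quantities.

    One row per (protein, precursor, fragment, condition, replicate) with the
    linear-scale ``quantity`` and its ``log10_quantity`` companion.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"fragment table missing columns: {missing}")
        if np.any(self.frame["quantity"].to_numpy() <= 0):
            raise ValueError("fragment quantities must be strictly positive")
        key = ["precursor", "fragment", "condition", "replicate"]
        if self.frame.duplicated(subset=key).any():
            raise ValueError("duplicate (precursor, fragment, condition, replicate) rows")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def conditions(self) -> list:
        return sorted(self.frame["condition"].unique().tolist())

    def write_report(self, path) -> None:
        """Emit the table as a tab-separated long-format report."""
        cols = list(FRAGMENT_COLUMNS[:6])
        self.frame[cols].to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CovStructure:
    """Structured covariance of log10 fragment quantities.

    ``a[i1, i2]``: same condition, same replicate; ``b[i1, i2]``: different
    condition, same replicate; ``d``: same condition, different replicate
    (= Var(zeta)).  Different condition and different replicate entries are 0.
    """

    a: np.ndarray
    b: np.ndarray
    d: float

    def __post_init__(self) -> None:
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        if a.ndim != 2 or a.shape[0] != a.shape[1] or b.shape != a.shape:
            raise ValueError("a and b must be square matrices of equal shape")
        if not np.allclose(a, a.T, atol=1e-8):
            raise ValueError("a must be symmetric")
        if self.d < 0:
            raise ValueError("d must be >= 0")
        if np.any(np.diag(a) < self.d - 1e-8):
            raise ValueError("diagonal of a must be >= d")
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)

    @property
    def n_fragments(self) -> int:
        return self.a.shape[0]


def logbeta_variance(alpha0: float, beta0: float) -> float:
    """Variance of log10(u) for u ~ Beta(alpha0, beta0).

    Equals (trigamma(alpha0) - trigamma(alpha0 + beta0)) / ln(10)^2.
    """
    if alpha0 <= 0 or beta0 <= 0:
        raise ValueError("beta shape parameters must be > 0")
    return float(
        (polygamma(1, alpha0) - polygamma(1, alpha0 + beta0)) / _LN10_SQ
    )


def logbeta_mean(alpha0: float, beta0: float) -> float:
    """Mean of log10(u) for u ~ Beta(alpha0, beta0) (digamma difference)."""
    if alpha0 <= 0 or beta0 <= 0:
        raise ValueError("beta shape parameters must be > 0")
    return float((polygamma(0, alpha0) - polygamma(0, alpha0 + beta0)) / _LN10)


def logdirichlet_cov(alpha: Sequence[float]) -> np.ndarray:
    """Covariance matrix of log10 of the coordinates of a Dirichlet(alpha).

    Diagonal entries are (trigamma(alpha_i) - trigamma(alpha_tot)) / ln(10)^2
    and off-diagonal entries -trigamma(alpha_tot) / ln(10)^2.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 1 or alpha.size < 1 or np.any(alpha <= 0):
        raise ValueError("alpha must be a positive vector")
    alpha_tot = alpha.sum()
    cov = np.full((alpha.size, alpha.size), -polygamma(1, alpha_tot))
    cov[np.diag_indices_from(cov)] += polygamma(1, alpha)
    return cov / _LN10_SQ


def _correlated_dirichlet_gammas(
    alpha: np.ndarray,
    rho: float,
    n_conditions: int,
    size: tuple[int, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Gamma bricks G[c] = A + B[c] for the shared/idiosyncratic coupling.

    A_i ~ Gamma(rho * alpha_i) is shared across conditions, B_ci ~
    Gamma((1 - rho) * alpha_i) is condition specific; normalizing each G[c]
    gives exact Dirichlet(alpha) marginals, independence at rho=0 and equality
    at rho=1.  Draw order: A first, then B for c = 1..C.
    """
    shape = size + (alpha.size,)
    shared = rng.gamma(np.broadcast_to(rho * alpha, shape))
    out = np.empty((n_conditions,) + shape)
    for c in range(n_conditions):
        out[c] = shared + rng.gamma(np.broadcast_to((1.0 - rho) * alpha, shape))
    return out


def sample_correlated_ionization(
    alpha: Sequence[float],
    rho: float,
    n: int,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n pairs of cross-condition-coupled Dirichlet(alpha) vectors.

    Each of the returned (n, I) arrays is marginally Dirichlet(alpha); the
    coupling strength increases with rho, with exact independence at rho=0
    and elementwise equality at rho=1.  The post-normalization correlation
    Corr(w_1i, w_2i) is approximately (not exactly) rho.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 1 or np.any(alpha <= 0):
        raise ValueError("alpha must be a positive vector")
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g = _correlated_dirichlet_gammas(alpha, rho, 2, (int(n),), rng)
    w = g / g.sum(axis=-1, keepdims=True)
    return w[0], w[1]


def simulate_arrays(
    params: ModelParams, seed: int | np.random.Generator | None
) -> tuple[np.ndarray, LatentDraws]:
    """Simulate the log10 quantity array x of shape (C, R, P, I) plus latents.

    Randomness is governed entirely by ``seed``; draws are made in a fixed,
    documented order (mu_p; u by condition; e; shared then per-condition
    ionization gammas) so datasets are bit-reproducible.
    """
    rng = np.random.default_rng(seed)
    C, R, P, I = (
        params.n_conditions,
        params.n_replicates,
        params.n_peptides,
        params.n_fragments,
    )
    alpha = np.asarray(params.alpha_dirichlet, dtype=float)
    delta = np.asarray(params.delta, dtype=float)

    mu_p = rng.normal(params.mu, params.sigma, size=P)
    u_cp = rng.beta(params.alpha0, params.beta0, size=(C, P))
    e_crp = rng.normal(0.0, params.sigma_cp, size=(C, R, P))
    g = _correlated_dirichlet_gammas(alpha, params.rho, C, (R, P), rng)
    w_cirp = g / g.sum(axis=-1, keepdims=True)

    zeta_cp = np.log10(u_cp)
    xi_cirp = np.log10(w_cirp)
    x = (
        mu_p[None, None, :, None]
        + delta[:, None, None, None]
        + zeta_cp[:, None, :, None]
        + e_crp[..., None]
        + xi_cirp
    )
    latents = LatentDraws(
        mu_p=mu_p,
        u_cp=u_cp,
        zeta_cp=zeta_cp,
        w_cirp=w_cirp,
        xi_cirp=xi_cirp,
        e_crp=e_crp,
        mu_tilde_cp=mu_p[None, :] + delta[:, None] + zeta_cp,
        delta_xi_irp=(xi_cirp[0] - xi_cirp[1]) if C >= 2 else None,
    )
    return x, latents


def fragment_table_from_array(x: np.ndarray) -> FragmentTable:
    """Build the canonical long-format table from an x array (C, R, P, I)."""
    C, R, P, I = x.shape
    c_idx, r_idx, p_idx, i_idx = np.unravel_index(np.arange(x.size), x.shape)
    frame = pd.DataFrame(
        {
            "protein": np.char.add("prot_", p_idx.astype(str)),
            "precursor": np.char.add("pep_", p_idx.astype(str)),
            "fragment": i_idx + 1,
            "condition": np.char.add("c", (c_idx + 1).astype(str)),
            "replicate": r_idx + 1,
            "quantity": 10.0 ** x.ravel(),
            "log10_quantity": x.ravel(),
        }
    )
    return FragmentTable(frame)


def simulate_dataset(
    params: ModelParams, seed: int | np.random.Generator | None
) -> tuple[FragmentTable, LatentDraws]:
    """Simulate a complete fragment-level dataset.

    Returns the long-format :class:`FragmentTable` (conditions labeled
    ``c1..cC``, replicates ``1..R``, fragments ``1..I``) together with all
    latent draws for instrumentation.
    """
    if seed is None:
        raise ValueError("a seed is mandatory for reproducible simulation")
    x, latents = simulate_arrays(params, seed)
    return fragment_table_from_array(x), latents


def true_cov_structure(
    params: ModelParams,
    n_mc: int = 100_000,
    seed: int | np.random.Generator | None = 0,
) -> CovStructure:
    """Population covariance structure implied by the model parameters.

    ``d`` and the within-condition block of ``a`` are analytic (trigamma
    expressions); the cross-condition block ``b`` depends on the coupling
    mechanism behind rho and is estimated by Monte Carlo with ``n_mc`` paired
    ionization draws.
    """
    if n_mc < 10_000:
        raise ValueError("n_mc must be >= 10000 for a stable Monte Carlo block")
    d = logbeta_variance(params.alpha0, params.beta0)
    xi_cov = logdirichlet_cov(params.alpha_dirichlet)
    a = d + params.sigma_cp ** 2 + xi_cov
    w1, w2 = sample_correlated_ionization(
        params.alpha_dirichlet, params.rho, n_mc, seed
    )
    l1 = np.log10(w1)
    l2 = np.log10(w2)
    l1c = l1 - l1.mean(axis=0)
    l2c = l2 - l2.mean(axis=0)
    b = l1c.T @ l2c / (n_mc - 1)
    b = (b + b.T) / 2.0  # population block is symmetric; average out MC noise
    return CovStructure(a=a, b=b, d=d)
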