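"""Post-test aggregation: dose-response p-value combination, local false
discovery rate scoring, protein-level min-aggregation and volcano tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .testing import TestResult

__all__ = [
    "ComparisonSeries",
    "ScoredProtein",
    "combine_dose_response",
    "local_fdr",
    "aggregate_protein",
    "volcano_table",
]

_LOG10_2 = np.log10(2.0)


@dataclass(frozen=True)
class ComparisonSeries:
    """Ordered pairwise comparisons of one peptide along a dose sequence."""

    pvalues: tuple[float, ...]
    signs: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.pvalues) == 0:
            raise ValueError("comparison series must be nonempty")
        if len(self.signs) != len(self.pvalues):
            raise ValueError("pvalues and signs must have equal length")
        if any(not 0.0 < p <= 1.0 for p in self.pvalues):
            raise ValueError("p-values must lie in (0, 1]")
        if any(s not in (-1, 1) for s in self.signs):
            raise ValueError("signs must be -1 or +1")


@dataclass(frozen=True)
class ScoredProtein:
    protein: str
    peptides: tuple[str, ...]
    peptide_scores: tuple[float, ...]
    score: float

    def __post_init__(self) -> None:
        if not self.peptides:
            raise ValueError("a scored protein needs at least one peptide")
        if any(self.score > s for s in self.peptide_scores):
            raise ValueError("protein score must not exceed any peptide score")


def combine_dose_response(series: ComparisonSeries) -> float:
    """Combine consecutive pairwise p-values into a dose-response score.

    With s_m the sign of the estimate attaining the minimum p-value (ties
    resolved toward the earliest comparison), returns

        prod_{i: s_i = s_m} p_i * prod_{j: s_j != s_m} (1 - 0.5 p_j).
    """
    p = np.asarray(series.pvalues, dtype=float)
    s = np.asarray(series.signs, dtype=int)
    s_m = s[int(np.argmin(p))]
    same = s == s_m
    return float(np.prod(p[same]) * np.prod(1.0 - 0.5 * p[~same]))


def local_fdr(
    pvalues: Sequence[float],
    signs: Sequence[float],
    monotone: bool = True,
) -> np.ndarray:
    """Local false discovery rate of signed z-scores derived from p-values.

    z = sign * PhiInv(1 - p/2); lfdr(z) = clip(pi0 * phi(z) / f(z), 0, 1)
    with f a Gaussian-KDE density of the observed z and pi0 a Storey-type
    null-proportion estimate min(1, #{p > 0.5} / (0.5 m)).  With
    ``monotone=True`` an isotonic pass per tail enforces that larger |z|
    never receives a larger lfdr.
    """
    p = np.asarray(pvalues, dtype=float)
    s = np.sign(np.asarray(signs, dtype=float))
    s[s == 0] = 1.0
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvalues must be a nonempty vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    if m < 50:
        warnings.warn(
            f"only {m} p-values; lfdr estimates will be unstable", stacklevel=2
        )
    z = s * stats.norm.isf(p / 2.0)
    pi0 = min(1.0, float(np.mean(p > 0.5)) / 0.5)
    if np.unique(z).size > 1:
        dens = stats.gaussian_kde(z, bw_method="silverman")(z)
    else:
        dens = np.full(m, stats.norm.pdf(z))
    dens = np.maximum(dens, 1e-300)
    lfdr = np.clip(pi0 * stats.norm.pdf(z) / dens, 0.0, 1.0)
    if monotone and m >= 2:
        for mask, increasing in ((z >= 0, False), (z < 0, True)):
            if mask.sum() >= 2:
                iso = IsotonicRegression(
                    increasing=increasing, out_of_bounds="clip"
                )
                lfdr[mask] = iso.fit_transform(z[mask], lfdr[mask])
        lfdr = np.clip(lfdr, 0.0, 1.0)
    return lfdr


def aggregate_protein(
    peptide_scores: Mapping[str, float], peptide_to_protein: Mapping[str, str]
) -> list[ScoredProtein]:
    """Assign each protein the minimum score over its scored peptides.

    Proteins whose peptides all lack scores are omitted with a warning.
    Output is sorted by protein id, independent of peptide order.
    """
    members: dict[str, list[str]] = {}
    for peptide, protein in peptide_to_protein.items():
        members.setdefault(protein, []).append(peptide)
    out = []
    for protein in sorted(members):
        scored = sorted(p for p in members[protein] if p in peptide_scores)
        if not scored:
            warnings.warn(
                f"protein {protein!r} has no scored peptides; omitted",
                stacklevel=2,
            )
            continue
        scores = tuple(float(peptide_scores[p]) for p in scored)
        out.append(
            ScoredProtein(
                protein=protein,
                peptides=tuple(scored),
                peptide_scores=scores,
                score=min(scores),
            )
        )
    return out


def volcano_table(
    results: Sequence[TestResult],
    scores: Sequence[float],
    lfdr_cutoff: float = 0.01,
    log2fc_cutoff: float = 1.0,
) -> pd.DataFrame:
    """Volcano-plot table: log2 fold change vs -log10 lfdr, with the
    significance flag lfdr <= cutoff and |log2 FC| >= cutoff."""
    if len(results) != len(scores):
        raise ValueError("results and scores must be aligned")
    scores = np.asarray(scores, dtype=float)
    log2fc = np.array([r.estimate for r in results]) / _LOG10_2
    with np.errstate(divide="ignore"):
        neg_log10 = -np.log10(scores)
    return pd.DataFrame(
        {
            "id": [r.peptide for r in results],
            "log2_fold_change": log2fc,
            "lfdr": scores,
            "neg_log10_lfdr": neg_log10,
            "significant": (scores <= lfdr_cutoff)
            & (np.abs(log2fc) >= log2fc_cutoff),
        }
    )
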