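"""Reading and writing of long-format quantification reports and result
tables, vendor column mapping, and selection of complete peptide blocks."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .generative import FRAGMENT_COLUMNS, FragmentTable
from .shrinkage import PeptideBlock
from .testing import TestResult

__all__ = [
    "ColumnMap",
    "ComparisonSpec",
    "COLUMN_MAPS",
    "read_fragment_report",
    "select_complete_blocks",
    "write_results",
    "read_results",
]

log = logging.getLogger(__name__)

RESULT_COLUMNS = ("peptide", "method", "estimate", "se", "t", "df", "pvalue", "flags")


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical roles to report column names."""

    protein: str = "protein"
    precursor: str = "precursor"
    fragment: str = "fragment"
    condition: str = "condition"
    replicate: str = "replicate"
    quantity: str = "quantity"
    decoy_column: str | None = None  # rows with a truthy value here are dropped

    def roles(self) -> dict[str, str]:
        return {
            "protein": self.protein,
            "precursor": self.precursor,
            "fragment": self.fragment,
            "condition": self.condition,
            "replicate": self.replicate,
            "quantity": self.quantity,
        }


# Best-effort defaults for common vendor fragment-level exports; override via
# config for other versions.
COLUMN_MAPS: dict[str, ColumnMap] = {
    "canonical": ColumnMap(),
    "spectronaut": ColumnMap(
        protein="PG.ProteinGroups",
        precursor="EG.PrecursorId",
        fragment="F.FrgIon",
        condition="R.Condition",
        replicate="R.Replicate",
        quantity="F.PeakArea",
        decoy_column="EG.IsDecoy",
    ),
    "maxquant": ColumnMap(
        protein="Proteins",
        precursor="Modified sequence",
        fragment="Fragment",
        condition="Experiment",
        replicate="Replicate",
        quantity="Intensity",
    ),
    "skyline": ColumnMap(
        protein="Protein Name",
        precursor="Peptide Modified Sequence",
        fragment="Fragment Ion",
        condition="Condition",
        replicate="Replicate Name",
        quantity="Area",
    ),
}


@dataclass(frozen=True)
class ComparisonSpec:
    """The two condition levels to compare (and an optional dose chain)."""

    condition_a: str
    condition_b: str
    dose_order: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.condition_a == self.condition_b:
            raise ValueError("comparison levels must be distinct")


def _detect_sep(path) -> str:
    with open(path, "r") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_fragment_report(path, colmap: ColumnMap | None = None) -> FragmentTable:
    """Read a delimited (tab or comma, auto-detected) fragment report.

    Rows with non-positive, missing or unparseable quantities are dropped
    with counts logged; duplicate (precursor, fragment, condition, replicate)
    rows raise an error listing the offenders.
    """
    colmap = colmap or ColumnMap()
    raw = pd.read_csv(path, sep=_detect_sep(path))
    roles = colmap.roles()
    missing = [col for col in roles.values() if col not in raw.columns]
    if missing:
        raise ValueError(f"report {path} is missing mapped column(s): {missing}")
    if colmap.decoy_column is not None and colmap.decoy_column in raw.columns:
        n_decoy = int(raw[colmap.decoy_column].astype(bool).sum())
        if n_decoy:
            log.info("dropping %d decoy rows", n_decoy)
            raw = raw[~raw[colmap.decoy_column].astype(bool)]
    frame = pd.DataFrame({role: raw[col].to_numpy() for role, col in roles.items()})
    quantity = pd.to_numeric(frame["quantity"], errors="coerce")
    bad = ~(quantity > 0)
    if bad.any():
        log.info(
            "dropping %d rows with missing/non-positive/unparseable quantity",
            int(bad.sum()),
        )
        frame = frame[~bad.to_numpy()]
        quantity = quantity[~bad]
    frame = frame.reset_index(drop=True)
    frame["quantity"] = quantity.to_numpy(dtype=float)
    key = ["precursor", "fragment", "condition", "replicate"]
    dup = frame.duplicated(subset=key, keep=False)
    if dup.any():
        offenders = frame.loc[dup, key].drop_duplicates().head(10)
        raise ValueError(
            "duplicate (precursor, fragment, condition, replicate) rows:\n"
            f"{offenders.to_string(index=False)}"
        )
    frame["log10_quantity"] = np.log10(frame["quantity"].to_numpy())
    return FragmentTable(frame[list(FRAGMENT_COLUMNS)])


def select_complete_blocks(
    table: FragmentTable,
    spec: ComparisonSpec,
    n_fragments: int,
) -> tuple[list[PeptideBlock], dict[str, list[str]]]:
    """Build per-peptide (R x 2I) blocks for one two-condition comparison.

    A peptide qualifies when exactly ``n_fragments`` fragments are observed in
    every (condition, replicate) of the comparison and both conditions carry
    the same replicate count.  Replicates are paired across conditions by
    sorted label order.  Returns the blocks plus a reason -> peptides summary
    of the skips; raises if no peptide qualifies.
    """
    frame = table.frame
    frame = frame[frame["condition"].isin([spec.condition_a, spec.condition_b])]
    blocks: list[PeptideBlock] = []
    skipped: dict[str, list[str]] = {"incomplete": [], "unequal_replicates": []}
    for peptide, g in frame.groupby("precursor", sort=True):
        wide = g.pivot_table(
            index="replicate",
            columns=["condition", "fragment"],
            values="log10_quantity",
            aggfunc="first",
        )
        reps = {
            cond: sorted(
                g.loc[g["condition"] == cond, "replicate"].unique().tolist()
            )
            for cond in (spec.condition_a, spec.condition_b)
        }
        if len(reps[spec.condition_a]) != len(reps[spec.condition_b]):
            skipped["unequal_replicates"].append(str(peptide))
            continue
        frags = {
            cond: sorted(
                g.loc[g["condition"] == cond, "fragment"].unique().tolist()
            )
            for cond in (spec.condition_a, spec.condition_b)
        }
        if (
            len(frags[spec.condition_a]) != n_fragments
            or frags[spec.condition_a] != frags[spec.condition_b]
        ):
            skipped["incomplete"].append(str(peptide))
            continue
        cols_a = [(spec.condition_a, f) for f in frags[spec.condition_a]]
        cols_b = [(spec.condition_b, f) for f in frags[spec.condition_b]]
        try:
            Xa = wide.loc[reps[spec.condition_a], cols_a].to_numpy(dtype=float)
            Xb = wide.loc[reps[spec.condition_b], cols_b].to_numpy(dtype=float)
        except KeyError:
            skipped["incomplete"].append(str(peptide))
            continue
        X = np.hstack([Xa, Xb])
        if np.isnan(X).any():
            skipped["incomplete"].append(str(peptide))
            continue
        if X.shape[0] < 2:
            skipped.setdefault("insufficient_replicates", []).append(
                str(peptide)
            )
            continue
        blocks.append(PeptideBlock(str(peptide), X))
    for reason, peptides in skipped.items():
        if peptides:
            log.info("skipped %d peptide(s): %s", len(peptides), reason)
    if not blocks:
        raise ValueError(
            f"no complete peptide blocks for comparison "
            f"{spec.condition_a!r} vs {spec.condition_b!r}"
        )
    return blocks, skipped


def _format_df(df: float) -> str:
    return "Inf" if math.isinf(df) else repr(float(df))


def write_results(results: Sequence[TestResult], path) -> None:
    """Write results as a tab-separated table with a stable column order.

    Infinite degrees-of-freedom serialize as the literal token ``Inf``; the
    file round-trips through :func:`read_results`.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.peptide,
                        r.method,
                        repr(float(r.estimate)),
                        repr(float(r.se)),
                        repr(float(r.t)),
                        _format_df(r.df),
                        repr(float(r.pvalue)),
                        ";".join(r.flags) if r.flags else "NA",
                    ]
                )
                + "\n"
            )


def read_results(path) -> list[TestResult]:
    """Read a results table written by :func:`write_results`."""
    frame = pd.read_csv(path, sep="\t", keep_default_na=False)
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            TestResult(
                peptide=str(row.peptide),
                estimate=float(row.estimate),
                se=float(row.se),
                t=float(row.t),
                df=math.inf if str(row.df) == "Inf" else float(row.df),
                pvalue=float(row.pvalue),
                method=str(row.method),
                flags=() if row.flags == "NA" else tuple(str(row.flags).split(";")),
            )
        )
    return out
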