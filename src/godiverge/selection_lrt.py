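"""Likelihood-ratio tests for branch-specific positive selection.

Consumes per-gene log-likelihoods from two nested codon-model fits run
externally (e.g. a one-ratio null against a branch/site alternative): the
statistic 2·(lnL_alt − lnL_null) is referred to a chi-square distribution
with caller-supplied degrees of freedom.  Fitting the codon models themselves
is out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable

import math

import pandas as pd
from scipy import stats

__all__ = ["LrtRecord", "lrt", "batch_lrt", "read_lnl_table"]


@dataclass(frozen=True)
class LrtRecord:
    gene_id: str
    lnl_null: float
    lnl_alt: float
    df: int
    stat: float
    p_value: float
    clamped: bool = False


def lrt(
    lnl_null: float,
    lnl_alt: float,
    df: int,
    gene_id: str = "",
    mixture_boundary: bool = False,
) -> LrtRecord:
    """One likelihood-ratio test: stat = max(0, 2·(lnL_alt − lnL_null)),
    p = chi-square(df) upper tail.

    A negative raw difference (alternative fit worse than the null — a
    numerical optimisation artefact) is clamped to 0 and flagged.  With
    ``mixture_boundary`` the p-value is halved (the 50:50 point-mass/chi-square
    mixture appropriate when the null pins a parameter at its boundary);
    the plain chi-square reference is the default.
    """
    if not (math.isfinite(lnl_null) and math.isfinite(lnl_alt)):
        raise ValueError(f"{gene_id or 'LRT'}: non-finite log-likelihood")
    if df < 1:
        raise ValueError("df must be a positive integer")
    raw = 2.0 * (lnl_alt - lnl_null)
    clamped = raw < 0
    stat = max(0.0, raw)
    p = float(stats.chi2.sf(stat, df))
    if mixture_boundary:
        p = 1.0 if stat == 0 else 0.5 * p
    return LrtRecord(gene_id, lnl_null, lnl_alt, df, stat, min(p, 1.0), clamped)


def batch_lrt(
    table: pd.DataFrame,
    df: int,
    alpha: float = 0.05,
    mixture_boundary: bool = False,
) -> pd.DataFrame:
    """LRT per gene over a (gene_id, lnl_null, lnl_alt) table.

    Returns records sorted ascending by p-value with a boolean
    ``significant`` column at the supplied alpha.  Duplicate gene ids are an
    error (each gene must appear in exactly one nested fit pair).
    """
    required = {"gene_id", "lnl_null", "lnl_alt"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns {sorted(missing)}")
    dup = table["gene_id"][table["gene_id"].duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate gene_id(s): {sorted(set(dup))}")
    records = [
        lrt(row.lnl_null, row.lnl_alt, df, gene_id=row.gene_id, mixture_boundary=mixture_boundary)
        for row in table.itertuples(index=False)
    ]
    out = pd.DataFrame([asdict(r) for r in records])
    if out.empty:
        out = pd.DataFrame(
            columns=["gene_id", "lnl_null", "lnl_alt", "df", "stat", "p_value", "clamped"]
        )
    else:
        out = out.sort_values(["p_value", "gene_id"], kind="mergesort").reset_index(drop=True)
    out["significant"] = out["p_value"] < alpha if len(out) else pd.Series(dtype=bool)
    return out


def read_lnl_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})
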