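"""Normalization, fold changes and two-library differential-expression calls.

miRNA counts are normalized to reads per million (RPM = count / total clean
reads x 1e6); gene counts to reads per kilobase per million mapped reads
(RPKM = 1e9 x C / (N x L)).  A normalized value of exactly 0 in one condition
is revised to 0.01 before the fold change is taken, and entities whose
normalized values are below 1 in both conditions are excluded from the
differential analysis.

Significance between the two pooled libraries uses the exact Audic-Claverie
count-comparison statistic: conditional on observing x reads in a library of
N1 total reads, the count y in a library of N2 reads has mass

    p(y | x) = (N2/N1)^y * (x+y)! / (x! y! (1 + N2/N1)^(x+y+1)),

evaluated in log-space; the reported P-value doubles the smaller tail and is
capped at 1.  Entities are called up/down when the fold change (treated /
control) exceeds 1.5 or falls below 2/3 (strict inequalities) with P < 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

ZERO_REVISION = 0.01
FOLD_HI = 1.5
FOLD_LO = 2.0 / 3.0
ALPHA = 0.05


@dataclass
class CountPair:
    """Raw counts of one entity in the control (x, N1) and treated (y, N2)
    libraries, with the library totals."""

    x: int
    y: int
    N1: int
    N2: int

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("counts must be non-negative")
        if self.N1 < 1 or self.N2 < 1:
            raise ValueError("library totals must be >= 1")
        if self.x > self.N1 or self.y > self.N2:
            raise ValueError("count exceeds its library total")


@dataclass
class GeneCount:
    """Reads mapped to a gene (C) out of N library reads, gene length L."""

    C: int
    N: int
    L: int

    def __post_init__(self) -> None:
        if self.L < 1 or self.N < 1:
            raise ValueError("gene length and library total must be >= 1")
        if not 0 <= self.C <= self.N:
            raise ValueError("gene count outside [0, N]")


def rpm(count: float, total_clean: int) -> float:
    """Reads per million: count / total_clean x 1e6, unrounded."""
    if total_clean < 1:
        raise ValueError("total_clean must be >= 1")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / total_clean * 1e6


def rpkm(gc: GeneCount) -> float:
    """Reads per kilobase per million mapped reads: 1e9 x C / (N x L)."""
    return 1e9 * gc.C / (gc.N * gc.L)


def revise_and_filter(norm_control: float, norm_treated: float,
                      ) -> tuple[tuple[float, float], bool]:
    """Apply the zero-revision and low-expression exclusion rules.

    A value of exactly 0 becomes 0.01; the entity is excluded iff both
    pre-revision values are below 1.
    """
    if norm_control < 0 or norm_treated < 0:
        raise ValueError("normalized values must be non-negative")
    excluded = norm_control < 1 and norm_treated < 1
    pair = (norm_control if norm_control != 0 else ZERO_REVISION,
            norm_treated if norm_treated != 0 else ZERO_REVISION)
    return pair, excluded


def fold_change(revised_pair: tuple[float, float]) -> float:
    """Treated / control ratio of the revised normalized values."""
    control, treated = revised_pair
    if control <= 0:
        raise ValueError("control value must be positive after revision")
    return treated / control


def _log_pmf(k: np.ndarray, x: int, log_ratio: float,
             log1p_ratio: float) -> np.ndarray:
    return (k * log_ratio + gammaln(x + k + 1) - gammaln(x + 1)
            - gammaln(k + 1) - (x + k + 1) * log1p_ratio)


def two_library_pvalue(cp: CountPair, mode: Literal["raw", "rpm"] = "raw",
                       ) -> float:
    """Two-sided Audic-Claverie P-value for a count observed in each of two
    libraries.

    ``mode='raw'`` (default) applies the statistic to the raw counts with
    N1/N2 as the library-size correction.  ``mode='rpm'`` first rescales the
    counts to a common depth (rounding to the nearest integer) and drops the
    library-size ratio; this mirrors pipelines that feed normalized values
    into the same formula, at the cost of the exact-count interpretation.

    The smaller of the lower tail (sum of p(k|x) for k <= y) and the upper
    tail (k >= y) is doubled and capped at 1.  All sums run in log space, so
    large counts stay finite.
    """
    x, y, n1, n2 = cp.x, cp.y, cp.N1, cp.N2
    if mode == "rpm":
        scale = 1e6
        x = round(x / n1 * scale)
        y = round(y / n2 * scale)
        n1 = n2 = int(scale)
    ratio = n2 / n1
    log_ratio = math.log(ratio)
    log1p_ratio = math.log1p(ratio)
    p_y = math.exp(float(_log_pmf(np.array([y]), x, log_ratio,
                                  log1p_ratio)[0]))
    mean = (x + 1) * ratio          # conditional expectation of y given x

    if y <= mean:
        # lower tail is the small one: sum it directly, complement the other
        ks = np.arange(0, y + 1)
        lower = min(1.0, math.exp(float(logsumexp(
            _log_pmf(ks, x, log_ratio, log1p_ratio)))))
        upper = min(1.0, max(0.0, 1.0 - lower + p_y))
    else:
        # upper tail is the small one: sum blocks until the remainder is
        # negligible relative to what has accumulated
        block, start, log_total = 2048, y, -np.inf
        while True:
            ks = np.arange(start, start + block)
            log_block = float(logsumexp(_log_pmf(ks, x, log_ratio,
                                                 log1p_ratio)))
            log_total = float(np.logaddexp(log_total, log_block))
            start += block
            if log_block < log_total - 45.0:
                break
        upper = min(1.0, math.exp(log_total))
        lower = min(1.0, max(0.0, 1.0 - upper + p_y))
    return min(1.0, 2.0 * min(lower, upper))


@dataclass
class ExpressionRow:
    entity_id: str
    kind: Literal["miRNA", "gene"]
    counts: CountPair | None
    norm_control: float
    norm_treated: float
    revised_control: bool = False
    revised_treated: bool = False
    excluded: bool = False
    fold: float = float("nan")
    p_value: float = float("nan")
    call: Literal["up", "down", "ns", ""] = ""


def build_rows(count_table: pd.DataFrame, totals: tuple[int, int],
               kind: Literal["miRNA", "gene"] = "miRNA",
               gene_lengths: pd.Series | None = None,
               pvalue_mode: Literal["raw", "rpm"] = "raw",
               ) -> list[ExpressionRow]:
    """Normalize a two-column count table and attach fold changes/P-values.

    ``count_table`` is indexed by entity_id with columns
    (count_control, count_treated); ``totals`` are the library totals used
    as the normalization denominators.  Gene rows use RPKM and require
    ``gene_lengths`` (bp, same index).
    """
    n1, n2 = totals
    rows: list[ExpressionRow] = []
    for entity_id, rec in count_table.iterrows():
        x, y = int(rec.iloc[0]), int(rec.iloc[1])
        cp = CountPair(x=x, y=y, N1=n1, N2=n2)
        if kind == "gene":
            if gene_lengths is None:
                raise ValueError("gene rows require gene_lengths")
            length = int(gene_lengths.loc[entity_id])
            nc = rpkm(GeneCount(C=x, N=n1, L=length))
            nt = rpkm(GeneCount(C=y, N=n2, L=length))
        else:
            nc = rpm(x, n1)
            nt = rpm(y, n2)
        (rc, rt), excluded = revise_and_filter(nc, nt)
        row = ExpressionRow(entity_id=str(entity_id), kind=kind, counts=cp,
                            norm_control=rc, norm_treated=rt,
                            revised_control=rc != nc, revised_treated=rt != nt,
                            excluded=excluded)
        if not excluded:
            row.fold = fold_change((rc, rt))
            row.p_value = two_library_pvalue(cp, mode=pvalue_mode)
        rows.append(row)
    return rows


def _call(fold: float, p: float, fold_hi: float, fold_lo: float,
          alpha: float) -> str:
    if p < alpha and fold > fold_hi:
        return "up"
    if p < alpha and fold < fold_lo:
        return "down"
    return "ns"


def call_dem(rows: Sequence[ExpressionRow], fold_hi: float = FOLD_HI,
             fold_lo: float = FOLD_LO, alpha: float = ALPHA,
             ) -> list[ExpressionRow]:
    """Differential-expression calls on non-excluded rows.

    up: fold > fold_hi and P < alpha; down: fold < fold_lo and P < alpha;
    otherwise ns.  All inequalities are strict; excluded rows keep an empty
    call.
    """
    for row in rows:
        row.call = "" if row.excluded else _call(row.fold, row.p_value,
                                                 fold_hi, fold_lo, alpha)
    return list(rows)


# genes use the identical decision rule
call_deg = call_dem


def rank_top(rows: Sequence[ExpressionRow], k: int,
             direction: Literal["up", "down"]) -> list[ExpressionRow]:
    """Top-k called rows by fold change (descending for up, ascending for
    down); ties broken by entity_id.  Returns all matches when k exceeds
    the available rows."""
    sel = [r for r in rows if r.call == direction]
    reverse = direction == "up"
    sel.sort(key=lambda r: ((-r.fold if reverse else r.fold), r.entity_id))
    return sel[:k] if k >= 0 else []


def rows_to_frame(rows: Sequence[ExpressionRow]) -> pd.DataFrame:
    """Full-precision tabular view (one row per entity)."""
    return pd.DataFrame([{
        "entity_id": r.entity_id, "kind": r.kind,
        "count_control": r.counts.x if r.counts else np.nan,
        "count_treated": r.counts.y if r.counts else np.nan,
        "norm_control": r.norm_control, "norm_treated": r.norm_treated,
        "excluded": r.excluded, "fold_change": r.fold,
        "p_value": r.p_value, "call": r.call,
    } for r in rows]).set_index("entity_id")
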