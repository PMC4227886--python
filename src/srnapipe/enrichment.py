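"""Term (GO-style) enrichment of gene sets by the upper-tail hypergeometric
test.

For a term annotating M of the N genome genes, the probability that a set of
n selected genes contains at least the observed m annotated genes is

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n)
      = Pr(X >= m),  X ~ Hypergeometric(N, M, n).

The sum is evaluated through log-gamma binomial coefficients, which keeps it
exact to machine precision for small counts and stable for genome-scale
ones.  Results are reported alongside -log10(P); no multiple-testing
correction enters the ranking (a Benjamini-Hochberg column is emitted for
transparency only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

P_FLOOR = 1e-300


@dataclass
class EnrichmentRow:
    term_id: str
    term_name: str
    N_genome: int
    n_deg: int
    M_term: int
    m_hit: int
    p_value: float
    neg_log10_p: float

    def __post_init__(self) -> None:
        if not (self.m_hit <= min(self.n_deg, self.M_term)
                and self.M_term <= self.N_genome
                and self.n_deg <= self.N_genome):
            raise ValueError("inconsistent enrichment counts")


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric probability Pr(X >= m).

    N: genes in the background genome; n: genes selected (e.g. DEG);
    M: genome genes annotated to the term; m: selected genes annotated.
    m = 0 gives P = 1 (the empty sum).
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= m <= min(n, M)):
        raise ValueError(f"inconsistent counts N={N} n={n} M={M} m={m}")
    lo = max(0, n - (N - M))
    if m <= lo:
        return 1.0                  # at least m hits are certain; empty sum
    i = np.arange(max(m, lo), min(n, M) + 1)
    if len(i) == 0:
        return 0.0
    log_terms = (_log_binom(M, i) + _log_binom(N - M, n - i)
                 - _log_binom(N, np.array([n]))[0])
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def _bh_fdr(pvals: Sequence[float]) -> list[float]:
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out.tolist()


def enrich(gene_set: Iterable[str], term_table: pd.DataFrame,
           background_size: int | None = None) -> list[EnrichmentRow]:
    """Enrichment of ``gene_set`` against a term-annotation table.

    ``term_table`` has columns (gene_id, term_id[, term_name]).  The
    background N defaults to the distinct genes of the annotation united
    with the query set; genes in the set that are absent from the
    annotation count toward n but toward no term's M.  One row per term
    with at least one hit, sorted by ascending P (ties by term_id).
    """
    genes = set(gene_set)
    if not genes:
        return []
    annotated = set(term_table["gene_id"])
    N = (background_size if background_size is not None
         else len(annotated | genes))
    if N < len(annotated | genes):
        raise ValueError("background_size smaller than the annotated universe")
    n = len(genes)
    names = {}
    if "term_name" in term_table.columns:
        names = (term_table.drop_duplicates("term_id")
                 .set_index("term_id")["term_name"].to_dict())
    rows: list[EnrichmentRow] = []
    for term_id, sub in term_table.groupby("term_id"):
        members = set(sub["gene_id"])
        m = len(genes & members)
        if m == 0:
            continue
        p = hypergeom_upper(N, n, len(members), m)
        p = max(p, P_FLOOR)
        rows.append(EnrichmentRow(term_id=str(term_id),
                                  term_name=str(names.get(term_id, "")),
                                  N_genome=N, n_deg=n, M_term=len(members),
                                  m_hit=m, p_value=p,
                                  neg_log10_p=-math.log10(p)))
    rows.sort(key=lambda r: (r.p_value, r.term_id))
    return rows


def enrich_targets(target_map: Mapping[str, Sequence[str]],
                   term_table: pd.DataFrame,
                   background_size: int | None = None) -> list[EnrichmentRow]:
    """Enrichment of the union of all predicted target genes.

    Duplicate (miRNA, gene) pairs collapse to one gene (set semantics).
    """
    gene_set = {g for genes in target_map.values() for g in genes}
    return enrich(gene_set, term_table, background_size)


def rows_to_frame(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    """Tabular view sorted by P, with a BH-FDR column for transparency
    (never used in ranking or calls)."""
    df = pd.DataFrame([{
        "term_id": r.term_id, "term_name": r.term_name, "N": r.N_genome,
        "n": r.n_deg, "M": r.M_term, "m": r.m_hit, "p_value": r.p_value,
        "neg_log10_p": r.neg_log10_p,
    } for r in rows])
    if not df.empty:
        df["bh_fdr"] = _bh_fdr(df["p_value"].tolist())
    return df
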