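"""Seed-based miRNA target prediction with reciprocal direction filtering.

Canonical seed sites in 3'UTRs, classified by the established site hierarchy:

- 8mer     : UTR reverse-complement match to miRNA positions 2-8 followed by
             an A opposite position 1;
- 7mer-m8  : reverse-complement match to positions 2-8;
- 7mer-A1  : reverse-complement match to positions 2-7 followed by an A;
- 6mer     : reverse-complement match to positions 2-7 only (recorded, but
             not target-qualifying by default).

Classes are mutually exclusive per site with 8mer taking precedence.  The
reciprocal prediction step scans up-regulated miRNAs only against the UTRs
of down-regulated genes and vice versa, reflecting the repressive action of
miRNAs on their targets.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._util import normalize_seq, revcomp

SITE_CLASSES = ("8mer", "7mer-m8", "7mer-A1", "6mer")
QUALIFYING = frozenset({"8mer", "7mer-m8", "7mer-A1"})


@dataclass(frozen=True)
class TargetSite:
    mirna_id: str
    gene_id: str
    site_class: str
    utr_offset: int                 # 0-based start of the match in the UTR
    seed_sequence: str              # mature positions 2-8, DNA alphabet


def seed_of(mature: str) -> str:
    """Seed region: mature positions 2-8 (1-based inclusive), 5'->3'."""
    seq = normalize_seq(mature)
    if len(seq) < 8:
        raise ValueError("mature sequence must be >= 8 nt for a seed")
    return seq[1:8]


def find_sites(mature: str, utr: str, mirna_id: str = "",
               gene_id: str = "") -> list[TargetSite]:
    """All canonical seed sites of one miRNA in one UTR.

    Overlapping sites are all reported; each offset receives exactly one
    class (8mer > 7mer-m8 > 7mer-A1 > 6mer).
    """
    seed = seed_of(mature)
    utr = normalize_seq(utr)
    if len(utr) < 7:
        raise ValueError("UTR must be >= 7 nt")
    m8 = revcomp(seed)              # 7 nt, matches positions 2-8
    m7 = revcomp(seed[:6])          # 6 nt, matches positions 2-7
    sites: list[TargetSite] = []
    prev7 = False
    for off in range(len(utr) - 5):
        window7 = utr[off:off + 7]
        window6 = utr[off:off + 6]
        cls = None
        if window7 == m8:
            nxt = utr[off + 7:off + 8]
            cls = "8mer" if nxt == "A" else "7mer-m8"
        elif window6 == m7 and not prev7:
            # a seed-2-8 match at off-1 contains this 6 nt match; report
            # the stronger site once instead of a nested sub-site
            nxt = utr[off + 6:off + 7]
            cls = "7mer-A1" if nxt == "A" else "6mer"
        prev7 = window7 == m8
        if cls:
            sites.append(TargetSite(mirna_id=mirna_id, gene_id=gene_id,
                                    site_class=cls, utr_offset=off,
                                    seed_sequence=seed))
    return sites


def reciprocal_predict(dem_calls: Mapping[str, str],
                       deg_calls: Mapping[str, str],
                       mature_sequences: Mapping[str, str],
                       utrs: Mapping[str, str],
                       qualifying: Iterable[str] = QUALIFYING,
                       ) -> dict[str, list[str]]:
    """Targets of differentially expressed miRNAs among opposite-direction
    differentially expressed genes.

    ``dem_calls`` / ``deg_calls`` map ids to 'up'/'down' (other values are
    ignored).  A gene is a predicted target of a miRNA when its UTR carries
    at least one qualifying site.  Output maps miRNA -> sorted gene list,
    keyed in sorted miRNA order.
    """
    qualifying = frozenset(qualifying)
    up_mirnas = sorted(k for k, v in dem_calls.items() if v == "up")
    down_mirnas = sorted(k for k, v in dem_calls.items() if v == "down")
    up_genes = sorted(k for k, v in deg_calls.items() if v == "up")
    down_genes = sorted(k for k, v in deg_calls.items() if v == "down")

    out: dict[str, list[str]] = {}
    for mirnas, genes in ((up_mirnas, down_genes), (down_mirnas, up_genes)):
        for mid in mirnas:
            mature = mature_sequences.get(mid)
            if mature is None:
                continue
            hits = []
            for gid in genes:
                utr = utrs.get(gid)
                if not utr or len(utr) < 7:
                    continue
                sites = find_sites(mature, utr, mirna_id=mid, gene_id=gid)
                if any(s.site_class in qualifying for s in sites):
                    hits.append(gid)
            if hits:
                out[mid] = hits
    return dict(sorted(out.items()))


def summarize_targets(target_map: Mapping[str, Sequence[str]],
                      term_table: pd.DataFrame | None = None,
                      term_filter: str | None = None,
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-miRNA target counts and per-gene in-degrees.

    With a ``term_table`` (columns gene_id, term_id, term_name) and a
    ``term_filter`` (term_id or term_name), targets are restricted to genes
    annotated to that term — e.g. only lipid-metabolism genes.
    """
    allowed: set[str] | None = None
    if term_table is not None and term_filter is not None:
        mask = ((term_table["term_id"] == term_filter)
                | (term_table.get("term_name", pd.Series(dtype=object))
                   == term_filter))
        allowed = set(term_table.loc[mask, "gene_id"])

    per_mirna_rows = []
    in_degree: dict[str, int] = defaultdict(int)
    for mid in sorted(target_map):
        genes = sorted(set(target_map[mid]))
        if allowed is not None:
            genes = [g for g in genes if g in allowed]
        per_mirna_rows.append({"mirna_id": mid, "n_targets": len(genes),
                               "targets": ",".join(genes)})
        for g in genes:
            in_degree[g] += 1
    per_mirna = pd.DataFrame(per_mirna_rows,
                             columns=["mirna_id", "n_targets", "targets"])
    per_gene = pd.DataFrame(
        [{"gene_id": g, "n_mirnas": c} for g, c in sorted(in_degree.items())],
        columns=["gene_id", "n_mirnas"])
    return per_mirna, per_gene
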