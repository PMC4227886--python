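"""Tiered annotation of collapsed small-RNA reads.

Each unique read is assigned exactly one tier by a fixed cascade:

1. ``known``            - matches a mature miRNA of the focal species;
2. ``homolog``          - matches a mature miRNA of another species;
3. ``ncrna_other``      - contained in a non-miRNA ncRNA reference record
                          (rRNA/tRNA/snoRNA/... decoys standing in for an
                          Rfam-style database);
4. ``novel_candidate``  - maps to the genome at <= max_loci exact loci and is
                          handed to the hairpin module for precursor
                          evaluation;
5. ``unannotated``      - none of the above (including multi-mapped reads).

Mature matching allows a small end-shift and substitution budget; reads are
strand-specific throughout, so a reverse-complement hit never counts.
BLAST/Bowtie of the original protocol are replaced by exact and shifted
substring matching, which is equivalent at the scales handled here and
deterministic.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import normalize_seq, revcomp

TIERS = ("known", "homolog", "ncrna_other", "novel_candidate", "unannotated")


@dataclass
class MatureMatch:
    name: str
    mismatches: int
    shift: int          # |5' shift| + |3' shift| of the best alignment
    all_names: list[str] = field(default_factory=list)


@dataclass
class AnnotationRecord:
    sequence: str
    tier: str
    matched_name: str = ""
    matched_precursors: list[str] = field(default_factory=list)
    ncrna_class: str = ""
    mismatches: int = 0
    loci: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tier not in TIERS:
            raise ValueError(f"unknown tier {self.tier!r}")
        if self.tier in ("known", "homolog") and not self.matched_name:
            raise ValueError(f"tier {self.tier} requires matched_name")
        if self.tier == "novel_candidate" and not self.loci:
            raise ValueError("tier novel_candidate requires a locus")


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def match_mature(sequences: Sequence[str], reference: Mapping[str, str],
                 max_shift: int = 2, max_mismatch: int = 1,
                 ) -> dict[str, MatureMatch]:
    """Match reads against a mature-miRNA reference.

    A read matches a mature record iff some ungapped alignment places both
    read ends within ``max_shift`` of the mature ends with at most
    ``max_mismatch`` substitutions in the overlap.  The best hit minimises
    (mismatches, total end shift, name); all hit names are retained.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    ref = {name: normalize_seq(s) for name, s in reference.items()}
    seqs = [normalize_seq(s) for s in sequences]

    by_len: dict[int, list[int]] = defaultdict(list)
    for i, s in enumerate(seqs):
        by_len[len(s)].append(i)
    enc = {length: np.vstack([_encode(seqs[i]) for i in idx])
           for length, idx in by_len.items()}

    best: dict[int, tuple[int, int, str]] = {}
    hits: dict[int, set[str]] = defaultdict(set)
    for name in sorted(ref):
        m = _encode(ref[name])
        M = len(m)
        for length, idx in by_len.items():
            A = enc[length]
            for d in range(-max_shift, max_shift + 1):
                e = d + length - M
                if abs(e) > max_shift:
                    continue
                rs, re = max(0, -d), min(length, M - d)
                if re - rs <= 0:
                    continue
                mism = (A[:, rs:re] != m[rs + d:re + d]).sum(axis=1)
                shift = abs(d) + abs(e)
                for row in np.flatnonzero(mism <= max_mismatch):
                    i = idx[row]
                    key = (int(mism[row]), shift, name)
                    hits[i].add(name)
                    if i not in best or key < best[i]:
                        best[i] = key
    out: dict[str, MatureMatch] = {}
    for i, (mm, shift, name) in best.items():
        out[seqs[i]] = MatureMatch(name=name, mismatches=mm, shift=shift,
                                   all_names=sorted(hits[i]))
    return out


def match_homolog(sequences: Sequence[str], other_reference: Mapping[str, str],
                  max_shift: int = 2, max_mismatch: int = 1,
                  ) -> dict[str, MatureMatch]:
    """Same contract as :func:`match_mature`, against other-species matures.

    The cascade calls this only on reads left unmatched at the known tier.
    """
    return match_mature(sequences, other_reference, max_shift, max_mismatch)


def classify_ncrna(sequences: Sequence[str],
                   ncrna_reference: Mapping[str, tuple[str, str]],
                   ) -> dict[str, str]:
    """Assign each read the class of any ncRNA decoy containing it exactly.

    ``ncrna_reference`` maps record name -> (class label, sequence).  When a
    read is contained in records of several classes the lexicographically
    smallest record name decides (deterministic tie-break).
    """
    ref = sorted((name, cls, normalize_seq(s))
                 for name, (cls, s) in ncrna_reference.items())
    out: dict[str, str] = {}
    for s in sequences:
        s = normalize_seq(s)
        for _name, cls, rseq in ref:
            if s in rseq:
                out[s] = cls
                break
    return out


def map_to_genome(sequences: Sequence[str], genome: Mapping[str, str],
                  max_loci: int = 5,
                  ) -> dict[str, list[tuple[str, int, int, str]]]:
    """Exact occurrences of each read on both genome strands.

    Returns 0-based half-open plus-strand intervals with strand '+'/'-'.
    Reads with more than ``max_loci`` occurrences get an empty locus list
    (multi-mapped: excluded from novel prediction).
    """
    gen = {c: normalize_seq(s) for c, s in genome.items()}
    out: dict[str, list[tuple[str, int, int, str]]] = {}
    for s in sequences:
        s = normalize_seq(s)
        loci: list[tuple[str, int, int, str]] = []
        for contig in sorted(gen):
            g = gen[contig]
            for query, strand in ((s, "+"), (revcomp(s), "-")):
                start = g.find(query)
                while start != -1:
                    loci.append((contig, start, start + len(s), strand))
                    start = g.find(query, start + 1)
        if len(loci) > max_loci:
            loci = []
        out[s] = loci
    return out


@dataclass
class FlankWindow:
    """One candidate precursor window around a genome-mapped read."""

    label: str                      # 'A' = [start-flank, end), 'B' = [start, end+flank)
    sequence: str                   # 5'->3' on the read's strand
    mature_offset: int              # 0-based offset of the read inside sequence
    mature_length: int
    locus: tuple[str, int, int, str]


def extract_flanks(locus: tuple[str, int, int, str],
                   genome: Mapping[str, str], flank: int = 80,
                   ) -> list[FlankWindow]:
    """Candidate precursor windows flanking a mapped read.

    Window A covers ``[start-flank, end)`` and window B ``[start, end+flank)``
    in plus-strand coordinates, clipped at contig edges.  Sequences are
    returned 5'->3' on the read's strand with the read offset recorded.
    """
    contig, start, end, strand = locus
    if contig not in genome:
        raise ValueError(f"unknown contig {contig!r}")
    g = normalize_seq(genome[contig])
    if not (0 <= start < end <= len(g)):
        raise ValueError(f"locus {locus} outside contig bounds (len {len(g)})")
    mat_len = end - start
    windows = []
    for label, w0, w1 in (("A", max(0, start - flank), end),
                          ("B", start, min(len(g), end + flank))):
        seq = g[w0:w1]
        if strand == "+":
            offset = start - w0
        else:
            seq = revcomp(seq)
            offset = w1 - end
        windows.append(FlankWindow(label=label, sequence=seq,
                                   mature_offset=offset,
                                   mature_length=mat_len, locus=locus))
    return windows


def annotate_cascade(unique_reads: Sequence, known_ref: Mapping[str, str],
                     other_ref: Mapping[str, str],
                     ncrna_ref: Mapping[str, tuple[str, str]],
                     genome: Mapping[str, str], *, max_shift: int = 2,
                     max_mismatch: int = 1, max_loci: int = 5,
                     mature_to_precursors: Mapping[str, list[str]] | None = None,
                     ) -> list[AnnotationRecord]:
    """Run the full cascade over collapsed unique reads.

    ``unique_reads`` are :class:`~srnapipe.preprocess.UniqueRead` objects (or
    anything with a ``sequence`` attribute).  Returns one record per read, in
    input order; the tier partition is exhaustive and exclusive.
    """
    seqs = [u.sequence for u in unique_reads]
    records: dict[str, AnnotationRecord] = {}

    known = match_mature(seqs, known_ref, max_shift, max_mismatch) if known_ref else {}
    for s, m in known.items():
        precs = (mature_to_precursors or {}).get(m.name, [])
        records[s] = AnnotationRecord(sequence=s, tier="known",
                                      matched_name=m.name,
                                      matched_precursors=list(precs),
                                      mismatches=m.mismatches)

    rest = [s for s in seqs if s not in records]
    homolog = match_homolog(rest, other_ref, max_shift, max_mismatch) if (rest and other_ref) else {}
    for s, m in homolog.items():
        records[s] = AnnotationRecord(sequence=s, tier="homolog",
                                      matched_name=m.name,
                                      mismatches=m.mismatches)

    rest = [s for s in seqs if s not in records]
    nc = classify_ncrna(rest, ncrna_ref) if rest and ncrna_ref else {}
    for s, cls in nc.items():
        records[s] = AnnotationRecord(sequence=s, tier="ncrna_other",
                                      ncrna_class=cls)

    rest = [s for s in seqs if s not in records]
    loci = map_to_genome(rest, genome, max_loci) if rest and genome else {}
    for s in rest:
        hit = loci.get(s, [])
        if hit:
            records[s] = AnnotationRecord(sequence=s, tier="novel_candidate",
                                          loci=hit)
        else:
            records[s] = AnnotationRecord(sequence=s, tier="unannotated")

    return [records[s] for s in seqs]


def tier_tally(records: Sequence[AnnotationRecord],
               unique_reads: Sequence) -> pd.DataFrame:
    """Unique- and total-read counts per tier and library."""
    counts = {u.sequence: u.count_per_library for u in unique_reads}
    libs = sorted({lib for c in counts.values() for lib in c})
    rows = []
    for tier in TIERS:
        recs = [r for r in records if r.tier == tier]
        row: dict[str, object] = {"tier": tier, "unique": len(recs)}
        for lib in libs:
            row[f"total_{lib}"] = sum(counts[r.sequence].get(lib, 0)
                                      for r in recs)
        rows.append(row)
    return pd.DataFrame(rows)


def known_summary(records: Sequence[AnnotationRecord],
                  unique_reads: Sequence) -> pd.DataFrame:
    """Per-library identification summary for the known tier.

    Columns mirror the customary overview layout: distinct miRNAs, distinct
    precursors, unique reads and total reads per library.
    """
    counts = {u.sequence: u.count_per_library for u in unique_reads}
    libs = sorted({lib for c in counts.values() for lib in c})
    rows = []
    for lib in libs:
        mirnas, precursors, uniq, total = set(), set(), 0, 0
        for r in records:
            if r.tier != "known":
                continue
            c = counts[r.sequence].get(lib, 0)
            if c > 0:
                mirnas.add(r.matched_name)
                precursors.update(r.matched_precursors)
                uniq += 1
                total += c
        rows.append({"library": lib, "miRNA": len(mirnas),
                     "precursor": len(precursors), "miRNA_unique": uniq,
                     "miRNA_total": total})
    return pd.DataFrame(rows)
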