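"""Raw small-RNA read cleanup and collapsing.

The stage order is fixed: 3' adapter trimming, quality filtering, the
15-30 nt length window, then collapsing of identical sequences into unique
reads carrying per-library counts.  Quality and length filters commute, so
their relative order is a convention, not a choice that affects output.
"""

from __future__ import annotations

import gzip
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._util import normalize_seq

MIN_LEN = 15
MAX_LEN = 30


@dataclass
class CleanReadSet:
    """Clean reads of one library after trimming and quality filtering."""

    library_id: str
    total_raw: int
    total_clean: int
    reads: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.total_clean > self.total_raw:
            raise ValueError("total_clean cannot exceed total_raw")


@dataclass
class UniqueRead:
    """A distinct 15-30 nt sequence with its count in each library."""

    sequence: str
    count_per_library: dict[str, int]

    def __post_init__(self) -> None:
        if not (MIN_LEN <= len(self.sequence) <= MAX_LEN):
            raise ValueError(f"unique read length {len(self.sequence)} outside "
                             f"[{MIN_LEN}, {MAX_LEN}]")
        counts = list(self.count_per_library.values())
        if any(c < 0 for c in counts) or not any(c > 0 for c in counts):
            raise ValueError("counts must be non-negative with at least one > 0")

    def total(self) -> int:
        return sum(self.count_per_library.values())


def trim_adapter(read: str, adapter3: str, min_overlap: int = 5,
                 require_adapter: bool = False) -> str | None:
    """Return the insert preceding the leftmost 3' adapter occurrence.

    The adapter is located either as a full exact substring or as a prefix of
    the adapter overlapping the read end by at least ``min_overlap`` bases.
    Returns None when the read is rejected (no adapter evidence while
    ``require_adapter`` is set, or the whole read is adapter).
    """
    if not adapter3:
        raise ValueError("adapter3 must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    read = normalize_seq(read)
    adapter3 = normalize_seq(adapter3)

    pos = read.find(adapter3)
    if pos == -1:
        # suffix of the read matching a prefix of the adapter
        max_ov = min(len(read), len(adapter3) - 1)
        for ov in range(max_ov, min_overlap - 1, -1):
            if read.endswith(adapter3[:ov]):
                pos = len(read) - ov
                break
    if pos == -1:
        return None if require_adapter else read
    if pos == 0:
        return None  # empty insert: read is all adapter
    return read[:pos]


def quality_filter(read: str, qualities: Sequence[int], threshold: float = 20.0,
                   max_n_fraction: float = 0.10) -> bool:
    """Keep a read iff its mean Phred score reaches ``threshold`` and its
    fraction of N calls does not exceed ``max_n_fraction``."""
    if len(qualities) != len(read):
        raise ValueError("quality string length differs from read length")
    if len(read) == 0:
        return False
    mean_q = sum(qualities) / len(qualities)
    n_frac = read.count("N") / len(read)
    return mean_q >= threshold and n_frac <= max_n_fraction


def length_filter(reads: Iterable[str], min_len: int = MIN_LEN,
                  max_len: int = MAX_LEN) -> list[str]:
    """Retain reads with min_len <= length <= max_len (both inclusive)."""
    return [r for r in reads if min_len <= len(r) <= max_len]


def _phred33(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


def clean_records(records: Iterable[tuple[str, str]], library_id: str,
                  adapter3: str, *, min_overlap: int = 5,
                  quality_threshold: float = 20.0,
                  require_adapter: bool = False) -> CleanReadSet:
    """Clean an iterable of (sequence, Phred+33 quality string) records.

    Adapter trimming then quality filtering; reads of any length are kept in
    ``total_clean`` — the 15-30 nt window is applied later, so that
    ``total_clean`` matches the 'clean reads' notion used as the RPM
    denominator (all clean reads, not only those inside the window).
    """
    total_raw = 0
    kept: list[str] = []
    for seq, qual in records:
        total_raw += 1
        trimmed = trim_adapter(seq, adapter3, min_overlap,
                               require_adapter=require_adapter)
        if trimmed is None:
            continue
        if quality_filter(trimmed, _phred33(qual)[: len(trimmed)],
                          quality_threshold):
            kept.append(trimmed)
    return CleanReadSet(library_id=library_id, total_raw=total_raw,
                        total_clean=len(kept), reads=kept)


def clean_fastq(path: str | Path, library_id: str, adapter3: str, *,
                min_overlap: int = 5, quality_threshold: float = 20.0,
                require_adapter: bool = False) -> CleanReadSet:
    """Read one FASTQ library (plain or gzipped, Phred+33) and clean it."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        records = ((seq, qual)
                   for _title, seq, qual in FastqGeneralIterator(fh))
        return clean_records(records, library_id, adapter3,
                             min_overlap=min_overlap,
                             quality_threshold=quality_threshold,
                             require_adapter=require_adapter)


def collapse_unique(clean_read_sets: Sequence[CleanReadSet],
                    min_len: int = MIN_LEN,
                    max_len: int = MAX_LEN) -> list[UniqueRead]:
    """Collapse identical 15-30 nt clean reads into counted unique reads.

    One record per distinct sequence; per-library counts conserve the number
    of in-window clean reads of that library.  Records are ordered by
    descending total count, ties lexicographic, for stable output.
    """
    if not clean_read_sets:
        raise ValueError("at least one library is required")
    per_lib: dict[str, Counter] = {}
    for crs in clean_read_sets:
        per_lib[crs.library_id] = Counter(
            length_filter(crs.reads, min_len, max_len))
    sequences = set()
    for counter in per_lib.values():
        sequences.update(counter)
    out = [
        UniqueRead(sequence=seq,
                   count_per_library={lib: per_lib[lib].get(seq, 0)
                                      for lib in per_lib})
        for seq in sequences
    ]
    out.sort(key=lambda u: (-u.total(), u.sequence))
    return out


def length_histogram(unique_reads: Sequence[UniqueRead],
                     min_len: int = MIN_LEN,
                     max_len: int = MAX_LEN) -> pd.DataFrame:
    """Total read count per length and library (index: length)."""
    libs: list[str] = []
    for u in unique_reads:
        for lib in u.count_per_library:
            if lib not in libs:
                libs.append(lib)
    hist = pd.DataFrame(0, index=range(min_len, max_len + 1), columns=libs,
                        dtype=int)
    hist.index.name = "length"
    for u in unique_reads:
        for lib, c in u.count_per_library.items():
            hist.loc[len(u.sequence), lib] += c
    return hist


def write_collapsed(unique_reads: Sequence[UniqueRead], fasta_path: str | Path,
                    tsv_path: str | Path) -> None:
    """Write collapsed reads as `>u{i}_x{total}` FASTA plus a count TSV."""
    with open(fasta_path, "w") as fa:
        for i, u in enumerate(unique_reads, start=1):
            fa.write(f">u{i}_x{u.total()}\n{u.sequence}\n")
    libs = sorted({lib for u in unique_reads for lib in u.count_per_library})
    rows = [{"sequence": u.sequence,
             **{f"count_{lib}": u.count_per_library.get(lib, 0)
                for lib in libs}}
            for u in unique_reads]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def counts_by_name(unique_reads: Sequence[UniqueRead],
                   names: Mapping[str, str]) -> pd.DataFrame:
    """Aggregate unique-read counts by an assigned name (e.g. miRNA id).

    ``names`` maps sequence -> entity name; unnamed sequences are dropped.
    """
    libs = sorted({lib for u in unique_reads for lib in u.count_per_library})
    acc: dict[str, dict[str, int]] = {}
    for u in unique_reads:
        name = names.get(u.sequence)
        if name is None:
            continue
        row = acc.setdefault(name, {lib: 0 for lib in libs})
        for lib, c in u.count_per_library.items():
            row[lib] += c
    df = pd.DataFrame.from_dict(acc, orient="index").fillna(0).astype(int)
    df.index.name = "entity_id"
    return df.sort_index()
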