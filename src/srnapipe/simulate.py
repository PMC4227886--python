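"""Synthetic inputs for the whole pipeline, with recorded ground truth.

The generator emulates the pooled two-library design of a small-RNA
sequencing experiment: one control and one treated library, each a single
pool, with planted per-entity fold changes between the two.  It produces

- a mature/hairpin miRNA reference for the focal species, a mature
  reference for other species (homolog tier), and ncRNA decoys standing in
  for an Rfam-style database;
- a genome with every miRNA precursor embedded at a recorded locus and
  non-overlapping gene models;
- two adapter-ligated FASTQ libraries with 18-24 nt miRNA inserts, ncRNA
  and length contaminants, and per-base substitution noise;
- a gene count table with planted differential expression;
- 3'UTRs with planted seed sites and a term-annotation table with one
  planted enriched term;
- a :class:`GroundTruth` record of everything planted.

All outputs are pure functions of (seed, config); random streams are split
per operation by name, so the draws of one operation never depend on
another having run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import hairpin
from ._util import revcomp, stream

BASES = np.array(list("ACGT"))

NCRNA_CLASSES = ("rRNA", "tRNA", "snoRNA", "snRNA")

TERM_NAMES = (
    "lipid metabolic process", "growth", "carbohydrate metabolic process",
    "ion binding", "oxidoreductase activity", "immune system process",
    "transferase activity", "biosynthetic process", "cell motility",
    "signal transduction", "lyase activity", "protein metabolic process",
)


class GenerationError(ValueError):
    """The generator could not satisfy its construction constraints."""


class SizingError(GenerationError):
    """A configured size is too small to place everything requested."""


@dataclass
class SimulationConfig:
    """Study conditions of a simulated two-library experiment.

    Defaults describe a pooled control/treated pair at test scale: 1e5
    reads per library, 18-24 nt miRNA inserts carrying a 3' adapter,
    planted fold changes of at least 3 (or at most 1/3) on the
    differential entities with expected counts of at least 30 per library,
    20% contaminant reads and a 0.1% per-base substitution rate.
    """

    seed: int = 1
    genome_length: int = 160_000
    n_known_mirnas: int = 20
    n_homolog_mirnas: int = 6
    n_novel_mirnas: int = 8
    n_genes: int = 60
    n_terms: int = 10
    depth_per_library: int = 100_000
    mrna_depth: int = 300_000
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"   # adapter is a config value;
    read_length: int = 36                      # no published sequence exists
    contaminant_fraction: float = 0.2
    substitution_rate: float = 0.001
    low_quality_fraction: float = 0.01
    n_ncrna_decoys: int = 30
    utr_length: int = 200
    fold_changes: dict[str, float] | None = None
    gene_fold_changes: dict[str, float] | None = None

    def known_names(self) -> list[str]:
        return [f"sim-miR-{i:03d}" for i in range(1, self.n_known_mirnas + 1)]

    def homolog_names(self) -> list[str]:
        return [f"oth-miR-{i:03d}"
                for i in range(1, self.n_homolog_mirnas + 1)]

    def novel_names(self) -> list[str]:
        return [f"sim-nov-{i:03d}" for i in range(1, self.n_novel_mirnas + 1)]

    def gene_names(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.n_genes + 1)]

    def resolved_fold_changes(self) -> dict[str, float]:
        """Planted miRNA fold changes (treated / control).

        Defaults plant clear up- and down-regulation (|log2 fold| >= log2 3)
        on a few known, homolog and novel miRNAs, plus one known miRNA that
        is essentially switched off (fold 0.001) to exercise the
        zero-revision path; everything else is null (fold 1).
        """
        if self.fold_changes is not None:
            fc = dict(self.fold_changes)
        else:
            fc = {}
            known = self.known_names()
            for name, f in zip(known, (3.0, 3.5, 4.0, 5.0, 0.30, 0.25, 0.001)):
                fc[name] = f
            hom = self.homolog_names()
            for name, f in zip(hom, (3.0, 0.30)):
                fc[name] = f
            nov = self.novel_names()
            for name, f in zip(nov, (3.0, 4.0, 0.25)):
                fc[name] = f
        self._check_entities(fc, self.known_names() + self.homolog_names()
                             + self.novel_names(), "fold_changes")
        return fc

    def resolved_gene_fold_changes(self) -> dict[str, float]:
        if self.gene_fold_changes is not None:
            fc = dict(self.gene_fold_changes)
        else:
            genes = self.gene_names()
            ups = (3.0, 3.5, 4.0, 4.5, 5.0, 3.0, 3.5, 4.0)
            downs = (0.30, 0.25, 0.20, 0.30, 0.25, 0.20, 0.30, 0.25)
            fc = {g: f for g, f in zip(genes, ups)}
            fc.update({g: f for g, f in zip(genes[len(ups):], downs)})
        self._check_entities(fc, self.gene_names(), "gene_fold_changes")
        return fc

    @staticmethod
    def _check_entities(fc: dict[str, float], names: Sequence[str],
                        what: str) -> None:
        unknown = set(fc) - set(names)
        if unknown:
            raise GenerationError(
                f"{what} keys not among generated entities: {sorted(unknown)}")
        if any(f <= 0 for f in fc.values()):
            raise GenerationError(f"{what} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class References:
    known_mature: dict[str, str]
    other_mature: dict[str, str]
    hairpins: dict[str, str]                 # precursor name -> sequence
    mature_to_precursors: dict[str, list[str]]
    arms: dict[str, str]                     # miRNA name -> '5p'/'3p'
    novel_mature: dict[str, str]             # ground truth only, not searched
    novel_hairpins: dict[str, str]
    ncrna: dict[str, tuple[str, str]]        # name -> (class, sequence)


@dataclass
class GroundTruth:
    """Everything planted, for recovery checks against pipeline output."""

    mature: dict[str, str] = field(default_factory=dict)
    fold_changes: dict[str, float] = field(default_factory=dict)
    de_direction: dict[str, str] = field(default_factory=dict)
    mirna_lambda: dict[str, tuple[float, float]] = field(default_factory=dict)
    mirna_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    mirna_loci: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    precursor_loci: dict[str, tuple[str, int, int, str]] = field(default_factory=dict)
    gene_lengths: dict[str, int] = field(default_factory=dict)
    gene_fold_changes: dict[str, float] = field(default_factory=dict)
    gene_direction: dict[str, str] = field(default_factory=dict)
    gene_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    planted_sites: list[dict] = field(default_factory=list)
    term_members: dict[str, list[str]] = field(default_factory=dict)
    enriched_term: str = ""
    designated_genes: list[str] = field(default_factory=list)
    library_sizes: tuple[int, int] = (0, 0)
    gene_totals: tuple[int, int] = (0, 0)

    def planted_dem(self, min_expected: float = 30.0,
                    min_fold: float = 3.0) -> list[str]:
        """Planted differential miRNAs meeting the recovery preconditions:
        fold >= min_fold or <= 1/min_fold, expected counts >= min_expected
        in both libraries."""
        out = []
        for name, f in self.fold_changes.items():
            lc, lt = self.mirna_lambda[name]
            if ((f >= min_fold or f <= 1.0 / min_fold)
                    and min(lc, lt) >= min_expected):
                out.append(name)
        return sorted(out)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, default=list)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        gt = cls(**{k: raw[k] for k in raw})
        for attr in ("mirna_lambda", "mirna_counts", "gene_counts"):
            setattr(gt, attr, {k: tuple(v)
                               for k, v in getattr(gt, attr).items()})
        for attr in ("mirna_loci", "precursor_loci"):
            setattr(gt, attr, {k: tuple(v)
                               for k, v in getattr(gt, attr).items()})
        gt.library_sizes = tuple(gt.library_sizes)
        gt.gene_totals = tuple(gt.gene_totals)
        return gt


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _direction(fold: float) -> str:
    if fold > 1.5:
        return "up"
    if fold < 2.0 / 3.0:
        return "down"
    return "ns"


def _make_hairpin(rng: np.random.Generator, mature: str, arm: str,
                  n_star_mismatches: int = 2) -> tuple[str, int]:
    """Mature + loop + imperfect star (or the 3p mirror image).

    The star strand carries a couple of substitutions away from the duplex
    ends, as real precursors do; this also keeps the star from being an
    exact reverse complement, so genome mapping of the mature stays unique.
    Returns (precursor, mature_offset).
    """
    loop = _rand_seq(rng, int(rng.integers(10, 15)))
    star = list(revcomp(mature))
    pos = rng.choice(np.arange(3, len(star) - 3), size=n_star_mismatches,
                     replace=False)
    for p in pos:
        alts = [b for b in "ACGT" if b != star[p]
                and hairpin.pair_weight(b, mature[len(mature) - 1 - p]) == 0]
        star[p] = str(rng.choice(alts))
    star_s = "".join(star)
    if arm == "5p":
        return mature + loop + star_s, 0
    return star_s + loop + mature, len(star_s) + len(loop)


def gen_mirna_reference(config: SimulationConfig, max_retries: int = 60,
                        ) -> References:
    """Mature and hairpin references whose precursors pass the hairpin
    module's own biogenesis evaluation (the generator retries draws until
    they do)."""
    rng = stream(config.seed, "reference")
    matures: dict[str, str] = {}
    hairpins: dict[str, str] = {}
    novel_m: dict[str, str] = {}
    novel_h: dict[str, str] = {}
    arms: dict[str, str] = {}
    seen: set[str] = set()

    # mature lengths centred on 22 nt, the canonical miRNA length
    lengths = (20, 21, 22, 23, 24)
    length_p = (0.10, 0.20, 0.40, 0.20, 0.10)

    def draw(name: str, want_hairpin: bool, idx: int) -> tuple[str, str | None]:
        arm = "5p" if idx % 2 == 0 else "3p"
        for _ in range(max_retries):
            mature = _rand_seq(rng, int(rng.choice(lengths, p=length_p)))
            if mature in seen or mature in config.adapter3:
                continue
            if not want_hairpin:
                seen.add(mature)
                return mature, None
            pre, off = _make_hairpin(rng, mature, arm)
            cand = hairpin.HairpinCandidate.from_sequence(pre, off,
                                                          len(mature))
            ev = hairpin.evaluate_precursor(cand)
            if ev.passed and ev.arm == arm:
                seen.add(mature)
                arms[name] = arm
                return mature, pre
        raise GenerationError(f"retry budget exhausted generating {name}")

    for i, name in enumerate(config.known_names()):
        mature, pre = draw(name, True, i)
        matures[name] = mature
        hairpins[f"{name}-pre"] = pre
    for i, name in enumerate(config.novel_names()):
        mature, pre = draw(name, True, i)
        novel_m[name] = mature
        novel_h[f"{name}-pre"] = pre
    other: dict[str, str] = {}
    for i, name in enumerate(config.homolog_names()):
        mature, _ = draw(name, False, i)
        other[name] = mature

    ncrna: dict[str, tuple[str, str]] = {}
    for i in range(config.n_ncrna_decoys):
        cls = NCRNA_CLASSES[i % len(NCRNA_CLASSES)]
        ncrna[f"decoy-{cls}-{i + 1:03d}"] = (
            cls, _rand_seq(rng, int(rng.integers(60, 121))))

    return References(
        known_mature=matures, other_mature=other, hairpins=hairpins,
        mature_to_precursors={n: [f"{n}-pre"] for n in matures},
        arms=arms, novel_mature=novel_m, novel_hairpins=novel_h, ncrna=ncrna)


def gen_genome(config: SimulationConfig, references: References,
               ) -> tuple[dict[str, str], "pd.DataFrame", GroundTruth]:
    """Genome with embedded precursors plus non-overlapping gene models.

    Precursor loci and gene intervals are 0-based half-open internally.
    Returns (genome, gene model table, partial ground truth with loci and
    gene lengths).
    """
    import pandas as pd

    rng = stream(config.seed, "genome")
    need = 10 * (config.n_known_mirnas + config.n_novel_mirnas) * 200
    if config.genome_length < need:
        raise SizingError(
            f"genome_length {config.genome_length} < required {need} "
            f"(10 x {config.n_known_mirnas + config.n_novel_mirnas} loci "
            f"x 200 bp)")

    genome = np.array(list(_rand_seq(rng, config.genome_length)))
    gt = GroundTruth()

    all_pre = {**{n: (references.known_mature[n.removesuffix("-pre")],
                      references.hairpins[n])
                  for n in references.hairpins},
               **{n: (references.novel_mature[n.removesuffix("-pre")],
                      references.novel_hairpins[n])
                  for n in references.novel_hairpins}}
    n_loci = len(all_pre)
    mir_region = config.genome_length // 2
    spacing = mir_region // (n_loci + 1) if n_loci else mir_region
    if n_loci and spacing < 400:
        raise SizingError(f"genome_length {config.genome_length} leaves "
                          f"{spacing} bp per precursor locus (< 400)")
    for i, (pre_name, (mature, pre)) in enumerate(sorted(all_pre.items())):
        strand = "+" if i % 2 == 0 else "-"
        pos = spacing * (i + 1) + int(rng.integers(0, spacing // 4))
        seg = pre if strand == "+" else revcomp(pre)
        genome[pos:pos + len(pre)] = list(seg)
        mir_name = pre_name.removesuffix("-pre")
        off = pre.find(mature)
        if strand == "+":
            locus = ("chr1", pos + off, pos + off + len(mature), "+")
        else:
            locus = ("chr1", pos + len(pre) - off - len(mature),
                     pos + len(pre) - off, "-")
        gt.mirna_loci[mir_name] = locus
        gt.precursor_loci[pre_name] = ("chr1", pos, pos + len(pre), strand)

    # gene models in the second half of the contig, single-exon, with the
    # terminal utr_length bases declared as 3'UTR
    rows = []
    cursor = mir_region + 200
    for gene in config.gene_names():
        length = int(rng.integers(500, 1501))
        if cursor + length > config.genome_length:
            raise SizingError(
                f"genome_length {config.genome_length} too small for "
                f"{config.n_genes} gene models (ran out at {gene})")
        rows.append({"gene_id": gene, "contig": "chr1", "start": cursor,
                     "end": cursor + length, "strand": "+",
                     "exon_length": length,
                     "utr_start": cursor + length - config.utr_length,
                     "utr_end": cursor + length})
        gt.gene_lengths[gene] = length
        cursor += length + int(rng.integers(50, 151))
    models = pd.DataFrame(rows)
    return {"chr1": "".join(genome)}, models, gt


def _apply_noise(rng: np.random.Generator, insert: str) -> str:
    pos = int(rng.integers(0, len(insert)))
    alt = str(rng.choice([b for b in "ACGT" if b != insert[pos]]))
    return insert[:pos] + alt + insert[pos + 1:]


def gen_libraries(config: SimulationConfig, references: References,
                  gt: GroundTruth | None = None,
                  ) -> tuple[list[tuple[str, str]], list[tuple[str, str]],
                             GroundTruth]:
    """Two FASTQ-ready libraries (lists of (sequence, quality)).

    Each miRNA read is its mature sequence (with per-base substitution
    noise) followed by the 3' adapter, truncated to the read length.
    Per-entity counts are Poisson with treated/control means in the planted
    fold-change ratio; the remainder of each library is filled with ncRNA
    decoy fragments and out-of-window length contaminants so that the total
    equals ``depth_per_library`` exactly.
    """
    if config.depth_per_library < 10_000:
        raise GenerationError("depth_per_library must be >= 1e4")
    rng = stream(config.seed, "libraries")
    gt = gt or GroundTruth()
    fc = config.resolved_fold_changes()
    entities = {**references.known_mature, **references.other_mature,
                **references.novel_mature}
    gt.mature.update(entities)
    gt.fold_changes = {n: fc.get(n, 1.0) for n in entities}
    gt.de_direction = {n: _direction(f) for n, f in gt.fold_changes.items()}

    # baseline expected counts: differential entities get means that keep
    # both conditions comfortably observable; nulls span a lognormal range
    lam_c: dict[str, float] = {}
    for name in sorted(entities):
        f = gt.fold_changes[name]
        if f > 1.5:
            lam_c[name] = float(rng.uniform(40, 150))
        elif f < 2 / 3:
            lam_c[name] = float(rng.uniform(120, 400))
        else:
            lam_c[name] = float(np.clip(rng.lognormal(np.log(60), 1.0),
                                        5, 800))
    budget = (1 - config.contaminant_fraction) * config.depth_per_library
    scale = budget / sum(lam_c.values())
    lam_c = {n: v * scale for n, v in lam_c.items()}
    lam_t = {n: lam_c[n] * gt.fold_changes[n] for n in lam_c}
    total_t = sum(lam_t.values())
    if total_t > 0.92 * config.depth_per_library:
        shrink = 0.92 * config.depth_per_library / total_t
        lam_c = {n: v * shrink for n, v in lam_c.items()}
        lam_t = {n: v * shrink for n, v in lam_t.items()}
    gt.mirna_lambda = {n: (lam_c[n], lam_t[n]) for n in lam_c}

    p_any = 1.0 - (1.0 - config.substitution_rate) ** 24

    libraries: list[list[tuple[str, str]]] = []
    for lib_idx, lam in enumerate((lam_c, lam_t)):
        reads: list[tuple[str, str]] = []
        labels: list[str] = []
        for name in sorted(entities):
            c = int(rng.poisson(lam[name]))
            if c == 0:
                continue
            insert = entities[name]
            template = (insert + config.adapter3)[:config.read_length]
            template += _rand_seq(rng, config.read_length - len(template))
            qual_hi = "I" * len(template)
            n_noise = int(rng.binomial(c, p_any)) if config.substitution_rate else 0
            n_lowq = int(rng.binomial(c, config.low_quality_fraction))
            for k in range(c):
                if k < n_noise:
                    noised = _apply_noise(rng, insert)
                    seq = (noised + config.adapter3)[:config.read_length]
                    seq += _rand_seq(rng, config.read_length - len(seq))
                else:
                    seq = template
                qual = ("#" * len(seq)) if k >= c - n_lowq else qual_hi[:len(seq)]
                reads.append((seq, qual))
                labels.append(name)
        slack = config.depth_per_library - len(reads)
        if not reads and slack > 0:
            raise GenerationError("no miRNA reads generated; expression "
                                  "levels or depth too low")
        if slack < 0:
            # more miRNA reads than the library holds: uniform thinning
            # keeps per-entity proportions unbiased
            keep = sorted(rng.choice(len(reads), config.depth_per_library,
                                     replace=False))
            reads = [reads[i] for i in keep]
            labels = [labels[i] for i in keep]
        elif config.contaminant_fraction == 0:
            # contaminant-free libraries: fill the depth by bootstrap
            # resampling of the generated miRNA reads
            extra = rng.integers(0, len(reads), size=slack)
            reads += [reads[i] for i in extra]
            labels += [labels[i] for i in extra]
        else:
            decoys = sorted(references.ncrna)
            for _ in range(slack):
                if decoys and rng.random() > 0.3:
                    _cls, dseq = references.ncrna[
                        decoys[int(rng.integers(0, len(decoys)))]]
                    flen = int(rng.integers(18, 29))
                    off = int(rng.integers(0, max(1, len(dseq) - flen)))
                    insert = dseq[off:off + flen]
                else:  # out-of-window length contaminant
                    flen = int(rng.integers(8, 15)) if rng.random() < 0.5 \
                        else int(rng.integers(31, 35))
                    insert = _rand_seq(rng, flen)
                seq = (insert + config.adapter3)[:config.read_length]
                seq += _rand_seq(rng, config.read_length - len(seq))
                reads.append((seq, "I" * len(seq)))
        perm = rng.permutation(len(reads))
        libraries.append([reads[i] for i in perm])
        tally: dict[str, int] = {}
        for name in labels:
            tally[name] = tally.get(name, 0) + 1
        for name in sorted(entities):
            c = tally.get(name, 0)
            prev = gt.mirna_counts.get(name, (0, 0))
            gt.mirna_counts[name] = ((c, prev[1]) if lib_idx == 0
                                     else (prev[0], c))
    gt.library_sizes = (len(libraries[0]), len(libraries[1]))
    return libraries[0], libraries[1], gt


def gen_gene_counts(config: SimulationConfig, gt: GroundTruth,
                    ) -> "pd.DataFrame":
    """Two-library gene count table with planted differential expression.

    Counts are Poisson with expected totals near ``mrna_depth`` per library;
    gene lengths must already be recorded (run :func:`gen_genome` first).
    """
    import pandas as pd

    rng = stream(config.seed, "genes")
    if not gt.gene_lengths:
        raise GenerationError("gene lengths missing; generate the genome first")
    fc = config.resolved_gene_fold_changes()
    gt.gene_fold_changes = {g: fc.get(g, 1.0) for g in config.gene_names()}
    gt.gene_direction = {g: _direction(f)
                         for g, f in gt.gene_fold_changes.items()}
    lam_c = {}
    for g in config.gene_names():
        f = gt.gene_fold_changes[g]
        if f > 1.5:
            base = float(rng.uniform(60, 250))
        elif f < 2 / 3:
            base = float(rng.uniform(200, 600))
        else:
            base = float(np.clip(rng.lognormal(np.log(150), 1.0), 10, 3000))
        lam_c[g] = base
    scale = config.mrna_depth / sum(lam_c.values())
    rows = []
    for g in config.gene_names():
        lc = lam_c[g] * scale
        lt = lc * gt.gene_fold_changes[g]
        x, y = int(rng.poisson(lc)), int(rng.poisson(lt))
        gt.gene_counts[g] = (x, y)
        rows.append({"gene_id": g, "count_control": x, "count_treated": y})
    df = pd.DataFrame(rows).set_index("gene_id")
    gt.gene_totals = (int(df["count_control"].sum()),
                      int(df["count_treated"].sum()))
    return df


_SITE_CYCLE = ("8mer", "7mer-m8", "7mer-A1")


def _site_sequence(mature: str, site_class: str) -> tuple[str, int]:
    """Planted site with guard bases so the class survives its context.

    A 7mer-m8 is followed by a non-A base (an A would upgrade it to 8mer);
    a 7mer-A1 is preceded by a base that cannot extend it into a 7mer-m8.
    Returns (string to insert, offset of the site proper within it).
    """
    from .targets import seed_of

    seed = seed_of(mature)
    m8 = revcomp(seed)
    if site_class == "8mer":
        return m8 + "A", 0
    if site_class == "7mer-m8":
        return m8 + "C", 0
    if site_class == "7mer-A1":
        guard = "C" if m8[0] != "C" else "G"
        return guard + revcomp(seed[:6]) + "A", 1
    raise GenerationError(f"unknown site class {site_class}")


def gen_utrs_and_terms(config: SimulationConfig, gt: GroundTruth,
                       references: References,
                       ) -> tuple[dict[str, str], "pd.DataFrame"]:
    """3'UTRs with planted seed sites and a term-annotation table.

    Sites are planted reciprocally: up-regulated known miRNAs into
    down-regulated genes, down-regulated known miRNAs into up-regulated
    genes.  One term (the first, 'lipid metabolic process') is planted as
    enriched among the targeted genes.
    """
    import pandas as pd

    rng = stream(config.seed, "utrs")
    up_mirnas = sorted(n for n in references.known_mature
                       if gt.de_direction.get(n) == "up")
    down_mirnas = sorted(n for n in references.known_mature
                         if gt.de_direction.get(n) == "down"
                         and min(gt.mirna_lambda[n]) >= 1)
    up_genes = sorted(g for g, d in gt.gene_direction.items() if d == "up")
    down_genes = sorted(g for g, d in gt.gene_direction.items() if d == "down")

    utrs = {g: _rand_seq(rng, config.utr_length)
            for g in config.gene_names()}
    min_len = 8 + 10
    if config.utr_length < min_len:
        raise SizingError(f"utr_length {config.utr_length} < {min_len} "
                          f"needed to place a seed site")

    planted: list[dict] = []
    occupied: dict[str, list[tuple[int, int]]] = {}
    k = 0

    def plant(mirna: str, genes: list[str], n_sites: int) -> None:
        nonlocal k
        chosen = list(rng.choice(genes, size=min(n_sites, len(genes)),
                                 replace=False))
        for gid in chosen:
            cls = _SITE_CYCLE[k % len(_SITE_CYCLE)]
            k += 1
            site, site_off = _site_sequence(references.known_mature[mirna],
                                            cls)
            taken = occupied.setdefault(str(gid), [])
            for _ in range(50):  # avoid clobbering an earlier planted site
                off = int(rng.integers(4, config.utr_length - len(site) - 4))
                if all(off + len(site) + 1 <= lo or off >= hi + 1
                       for lo, hi in taken):
                    break
            else:
                raise SizingError(f"UTR of {gid} too short to place "
                                  f"another seed site")
            taken.append((off, off + len(site)))
            u = utrs[gid]
            utrs[gid] = u[:off] + site + u[off + len(site):]
            planted.append({"mirna": mirna, "gene": str(gid),
                            "site_class": cls,
                            "utr_offset": off + site_off})

    for m in up_mirnas:
        plant(m, down_genes, 2)
    for m in down_mirnas:
        plant(m, up_genes, 2)
    gt.planted_sites = planted
    gt.designated_genes = sorted({p["gene"] for p in planted})

    # term table: the enriched term concentrates on the targeted genes
    term_ids = [f"T{i:02d}" for i in range(1, config.n_terms + 1)]
    term_names = {t: TERM_NAMES[i % len(TERM_NAMES)]
                  for i, t in enumerate(term_ids)}
    gt.enriched_term = term_ids[0]
    members: dict[str, set[str]] = {t: set() for t in term_ids}
    for g in gt.designated_genes:
        if rng.random() < 0.85:
            members[gt.enriched_term].add(g)
    others = [g for g in config.gene_names()
              if g not in gt.designated_genes]
    for g in others:
        if rng.random() < 0.05:
            members[gt.enriched_term].add(g)
    for g in config.gene_names():
        for t in rng.choice(term_ids[1:], size=int(rng.integers(0, 4)),
                            replace=False):
            members[str(t)].add(g)
    gt.term_members = {t: sorted(m) for t, m in members.items() if m}
    rows = [{"gene_id": g, "term_id": t, "term_name": term_names[t]}
            for t in term_ids for g in sorted(members[t])]
    return utrs, pd.DataFrame(rows)


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path,
                prefix: str = "r") -> None:
    with open(path, "w") as fh:
        for i, (seq, qual) in enumerate(reads, start=1):
            fh.write(f"@{prefix}{i:07d}\n{seq}\n+\n{qual}\n")


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n{records[name]}\n")


@dataclass
class SimulatedData:
    config: SimulationConfig
    references: References
    genome: dict[str, str]
    gene_models: "pd.DataFrame"
    library_control: list[tuple[str, str]]
    library_treated: list[tuple[str, str]]
    gene_counts: "pd.DataFrame"
    utrs: dict[str, str]
    term_table: "pd.DataFrame"
    ground_truth: GroundTruth


def simulate_all(config: SimulationConfig,
                 outdir: str | Path | None = None) -> SimulatedData:
    """Run every generator and optionally write the standard-format files
    (FASTA/FASTQ/TSV/JSON) to ``outdir``."""
    refs = gen_mirna_reference(config)
    genome, models, gt = gen_genome(config, refs)
    lib_a, lib_b, gt = gen_libraries(config, refs, gt)
    gene_counts = gen_gene_counts(config, gt)
    utrs, terms = gen_utrs_and_terms(config, gt, refs)
    data = SimulatedData(config=config, references=refs, genome=genome,
                         gene_models=models, library_control=lib_a,
                         library_treated=lib_b, gene_counts=gene_counts,
                         utrs=utrs, term_table=terms, ground_truth=gt)
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(refs.known_mature, out / "mature_focal.fa")
        write_fasta(refs.other_mature, out / "mature_other.fa")
        write_fasta(refs.hairpins, out / "hairpin_focal.fa")
        write_fasta({n: s for n, (_c, s) in refs.ncrna.items()},
                    out / "ncrna_decoys.fa")
        write_fasta(genome, out / "genome.fa")
        write_fasta(utrs, out / "utr.fa")
        write_fastq(lib_a, out / "control.fastq", "ctl")
        write_fastq(lib_b, out / "treated.fastq", "trt")
        gene_counts.to_csv(out / "gene_counts.tsv", sep="\t")
        terms.to_csv(out / "terms.tsv", sep="\t", index=False)
        gff = models.copy()
        gff["start"] = gff["start"] + 1          # 1-based closed on write
        gff["utr_start"] = gff["utr_start"] + 1
        gff.to_csv(out / "gene_models.tsv", sep="\t", index=False)
        gt.to_json(out / "ground_truth.json")
        config.to_yaml(out / "config.yaml")
    return data
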