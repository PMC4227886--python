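# Methods

This note documents the models, parameter choices and known limits of
`srnapipe`. The pipeline reproduces the analysis logic of a pooled
two-library small-RNA + mRNA experiment (one control pool, one treated
pool, no biological replicates) with deterministic, exactly testable
components in place of the heuristic external tools such a study would have
used (Bowtie/BLAST for mapping, mireap for hairpin prediction, miRanda for
targets, DESeq for mRNA P-values).

## Preprocessing

Reads are cleaned in a fixed order: 3′ adapter trimming, quality filtering,
the 15–30 nt length window, collapsing. Adapter matching is an exact
substring search for the full adapter plus an end-overlap search for
adapter prefixes of at least `min_overlap` (default 5) bases at the read
end; there is no mismatch tolerance by default because the synthetic reads
carry no adapter-side errors and exactness keeps the stage testable by
brute-force scan. Reads that are entirely adapter are discarded as empty
inserts. The quality criterion — mean Phred ≥ 20 and ≤ 10% N — is a
package choice; published protocols of this kind say only that low-quality
reads were removed (their stated Q30 filter applies to the mRNA libraries).
`total_clean` counts all clean reads, not just the 15–30 nt window, because
that is the denominator the RPM formula specifies. Quality and length
filters commute, so their order is a convention.

## Annotation cascade

Each unique read receives exactly one tier, in the fixed order known →
homolog → other-ncRNA → genome/novel → unannotated. Mature matching allows
an end shift of ≤ 2 nt and ≤ 1 substitution (configurable; exact mode
available), the common tolerance for isomiR-aware counting; the best hit
minimizes (mismatches, total shift, name). Matching is strand-specific.
ncRNA classification is exact substring containment in labelled decoy
records; genome mapping is exact text search on both strands with reads at
more than 5 loci set aside as multi-mapped. These exact searches replace
BLAST/Bowtie: at the scales this package targets they are equivalent and
fully deterministic.

## Hairpin model

Candidate windows (the read ± 80 nt, both flanks) are folded by weighted
base-pair maximization — GC=3, AU=2, GU=1, minimum loop 3, nested
structures only — a Nussinov-style dynamic program whose weights reproduce
the thermodynamic stability ordering GC > AU > GU while keeping the optimum
exactly checkable against enumeration. Traceback is deterministic (prefer
pairing the smallest outer index, then the smallest partner). This is a
deliberate simplification of minimum-free-energy folding: no stacking
energies, no pseudoknots, scores in pair units rather than kcal/mol, with
the energy cutoff expressed as normalized score (score/length ≥ 0.6).

A candidate passes when

1. the mature read lies on one arm: all its paired bases point the same
   way (5p arm pairs downstream, 3p upstream). Direction is used instead of
   strict containment between the stem's innermost pair because real duplex
   ends reach 1–2 nt into the terminal loop;
2. ≥ 14 mature bases pair **within the single dominant stem**. Under pair
   maximization almost every base of any window pairs somewhere, so a
   global count does not discriminate; concentration in one stem is the
   biogenesis signal;
3. that stem holds ≥ 60% of the paired bases within its own span (a single
   dominant helix, not a branched tangle). Pairs chain into one stem across
   bulges of at most `helix_gap` = 1 nt per side — chosen because the
   star-strand mismatches of real duplexes produce 1×1 interior loops,
   while the chance pseudo-stems of shuffled windows need wider bridges
   (measured false-pass rate on random 102 nt windows: 0.5–2.5% at gap 1
   versus 2–5.5% at gap 2);
4. normalized score ≥ 0.6.

Because pairing maximization over a full 102 nt window can bury the true
stem under flank self-pairing, `call_novel` also evaluates trimmed
sub-windows in 10 nt steps down to 25 nt beyond the mature (the room a loop
and star strand need), the way hairpin-excision tools scan candidate
precursor boundaries. The star sequence is the pairing partner of the
mature with the canonical 2 nt 3′ overhang on each duplex strand, anchored
at the nearest paired bases within a 4 nt tolerance.

One caveat recorded here because it is easy to assume otherwise: folding is
**not** invariant under reverse complementation once GU wobble scores —
the complement of a G:U pair is C:A, which cannot pair. Watson–Crick-only
structures mirror exactly; the suite tests precisely that.

## Expression statistics

RPM = c/N × 10⁶ over total clean reads; RPKM = 10⁹·C/(N·L) over exonic
length. The zero-revision rule replaces an exact 0 with 0.01 before the
ratio; entities below 1 in both conditions are excluded. Fold changes are
treated/control on the revised values, unrounded everywhere except the
report layer.

Significance uses the Audic–Claverie conditional statistic on **raw
counts** with the library totals as N₁/N₂. Published text of this lineage
says "normalized expression level", but feeding RPM into the formula with
N₁=N₂ degenerates the library-size correction, so raw-count mode is the
default and an `rpm` mode (counts rescaled to a common depth) is provided
for comparison. Tails are summed in log space with the smaller tail summed
directly (never by complement) so values down to ~1e-300 keep full absolute
precision; the smaller tail is doubled and capped at 1. The statistic is
orientation-fixed — it conditions on the control count — and is *not*
exactly symmetric under swapping the libraries (term-wise,
p(x|y; N₁/N₂) = (N₂/N₁)·p(y|x; N₂/N₁)); callers keep control first. It
depends on (x, y, N₂/N₁) only. No multiple-testing correction enters any
call, matching the source methodology; a Benjamini–Hochberg column is
emitted for transparency.

mRNA significance in the original workflow came from a replicate-aware
external package; here the same two-library statistic is applied to the
pooled gene counts and labelled as such in output metadata. It is a
documented stand-in, not a dispersion model.

## Targets and enrichment

Sites are canonical seed matches of mature positions 2–8 in 3′UTRs: 8mer
(seed match + A opposite position 1), 7mer-m8, 7mer-A1, and 6mer (recorded,
excluded from target calls by default to limit false positives at toy
scale). A 6 nt window nested inside a seed-2–8 match at the previous offset
is not reported separately. There is no alignment score, free energy or
conservation filter — seed matching is the only part of the original
tools' behaviour that is pinned down, and it is deterministic. Reciprocal
prediction scans up-miRNAs against down-genes' UTRs and vice versa,
reflecting repressive miRNA action.

Enrichment is the upper-tail hypergeometric P = Pr(X ≥ m) computed through
log-gamma binomial coefficients, exact to machine precision at the scales
used (the suite checks all configurations with N ≤ 25 against rational
enumeration and larger ones against an independent implementation). The
default background is the annotated universe united with the query set; the
pipeline passes the experiment's full gene count. P-values are floored at
1e-300 before −log₁₀.

## Synthetic data

The generator emulates the pooled design at test scale: two libraries of
1e5 reads (Phred+33, 36 nt, 3′ adapter `TGGAATTCTCGGGTGCCAAGG` — adapters
are never published for such studies, so this is a config value with an
arbitrary but standard-looking default), mature lengths drawn 20–24 nt with
mode 22, per-base substitution noise 0.1% (insert only — adapter-side
errors would only perturb trimming, which is not what the noise model
probes), 1% uniformly low-quality reads, and 20% contaminants split between
ncRNA decoy fragments and out-of-window lengths.

Planted conditions, fixed as the study conditions of the test suite: four
known miRNAs up at folds 3–5, two down at 0.25–0.30, one switched off
(fold 0.001, exercising the zero-revision path), one homolog up and one
down, two novel up and one down; eight genes up and eight down. All
differential entities receive expected counts ≥ 30 per library (≥ 40 on
the control side before the fold is applied). Null abundances are
lognormal. Precursors are mature + 10–14 nt loop + star with two
substitutions (so the star is not an exact reverse complement and genome
mapping of the mature stays unique); the generator redraws until each
precursor passes the package's own hairpin evaluation, and embeds them at
recorded loci on alternating strands. Per-entity counts are Poisson with
treated/control means in exactly the planted ratio; the depth is then met
by the contaminant filler, or — in contaminant-free configs — by uniform
thinning/bootstrap of the miRNA reads (proportion-preserving in
expectation). Seed sites are planted with guard bases so a chance flanking
base cannot upgrade a 7mer-m8 to an 8mer or absorb a 7mer-A1 into a
stronger site; one term is planted enriched among the targeted genes.

All generators are pure functions of (seed, config); each operation draws
from its own named substream, so adding or reordering operations never
perturbs another's output. Coordinates are 0-based half-open internally and
converted to 1-based closed only when writing the gene-model table.

What the generator does **not** emulate — and therefore what green tests do
not establish about real data: Illumina error profiles and quality-score
structure, biological replicates (the 4-birds-per-pool structure), isomiR
end heterogeneity, RNA editing, genome repeat structure, paralogous miRNA
families, or realistic UTR base composition. Recovery rates on this
generator bound what the algorithms can do when their assumptions hold, not
field performance.

## Problem sizes and determinism

Default test-scale sizes: 1e5 reads per library, 160 kb genome, 28 embedded
hairpins, 60 genes, 200 nt UTRs, 10 terms. A full simulate-plus-pipeline
run takes a few seconds on one CPU; the complete test suite, including an
end-to-end run and all oracle comparisons, runs in about a minute. Fixed
seeds make every reported number in the README reproducible bit for bit;
rounding (RPM to one decimal, fold changes to mixed publication precision,
scientific-notation P-values) happens only in the report layer.

## Known limitations

- No thermodynamic folding: borderline hairpins that an MFE model would
  accept or reject near its energy cutoff can be classified differently.
- The two-library statistic understates uncertainty relative to designs
  with replicates; it is the correct tool only for the pooled design it
  models.
- Exact genome mapping means sequencing errors silently demote novel-arm
  reads to unannotated rather than rescuing them with mismatched alignment.
- Target prediction has no scoring beyond seed class, so its specificity on
  real UTRs is that of seed matching alone.
- The printed-table fixtures can only validate rows whose published fold
  change is reproducible from the published normalized pair; rows computed
  upstream from unrounded values (e.g. a printed 13.99 against 14.18 from
  the rounded pair) are flagged and checked for direction only.
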