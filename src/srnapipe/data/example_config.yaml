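# Annotated simulation config for `srnapipe simulate` / `srnapipe run`.
# Every field is optional; omitted fields use the defaults shown here.

seed: 1                     # master seed; every generator stream derives from it
genome_length: 160000       # bp of the single simulated contig (miRNA loci in
                            # the first half, gene models in the second)
n_known_mirnas: 20          # focal-species matures with hairpins, searched first
n_homolog_mirnas: 6         # other-species matures (homolog tier)
n_novel_mirnas: 8           # hairpins embedded in the genome but absent from
                            # every reference: the novel-prediction targets
n_genes: 60                 # gene models / count-table rows
n_terms: 10                 # annotation terms; the first is planted enriched
depth_per_library: 100000   # reads per library (control and treated)
mrna_depth: 300000          # expected total gene counts per library
adapter3: TGGAATTCTCGGGTGCCAAGG   # 3' adapter ligated to every read
read_length: 36             # raw read length before trimming
contaminant_fraction: 0.2   # share of non-miRNA reads (ncRNA decoy fragments
                            # and out-of-window lengths)
substitution_rate: 0.001    # per-base substitution noise in the insert
low_quality_fraction: 0.01  # reads emitted with uniformly low Phred scores
n_ncrna_decoys: 30          # rRNA/tRNA/snoRNA/snRNA decoy records
utr_length: 200             # bp of each gene's 3'UTR

# Planted miRNA fold changes (treated / control).  Omit to use the default
# plan: four known miRNAs up (3-5x), two down (0.25-0.3x), one switched
# off, one homolog up and one down, two novel up and one down.
# fold_changes:
#   sim-miR-001: 3.0
#   sim-miR-005: 0.25

# Planted gene fold changes; default: 8 genes up (3-5x), 8 down (0.2-0.3x).
# gene_fold_changes:
#   G0001: 3.0
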