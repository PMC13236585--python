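# Methods

This note documents the models, parameters and numerical choices behind
`cazprofiler`, and what the synthetic benchmarks do and do not show.

## Family model calibration

Each CAZy (sub)family is represented by K = 5 fold-specific profile HMMs
plus one calibrated P-value cutoff. The pipeline per family:

1. **Module extraction** (when starting from full-length proteins and
   reference profiles): a domain hit is kept iff its independent E-value
   is ≤ 1e-15 *and* it covers ≥ 0.35 of the model
   ((hmm_to − hmm_from + 1)/model length); the envelope is excised as the
   module sequence. Near-duplicates can be removed by greedy centroid
   clustering at 0.99 identity before alignment.
2. **Blocking**: modules are clustered at 0.60 global-alignment identity
   (identity = exact matches / alignment columns, computed with edlib's
   Needleman–Wunsch path). Clustering is greedy centroid: sequences
   sorted longest-first; each joins the first centroid at or above the
   threshold, else founds a new cluster. Blocking groups are assigned to
   folds by greedy bin-packing (largest group into the currently smallest
   fold), so similar sequences never straddle a train/test boundary. With
   fewer than five blocking groups, individual sequences are shuffled
   (seeded) into folds instead — cross-validation without blocking.
3. **Fold models**: training modules shorter than 0.8 × the median
   training module length are dropped; the remaining rows of the family
   MSA (all-gap columns removed) feed `pyhmmer`'s Builder. The calibrator
   accepts pre-aligned families; it does not invoke an external aligner.
4. **Scoring and labelling**: held-out instances are *full-length*
   sequences, a more realistic search space than excised modules.
   Positives are the test fold's source sequences (a source also feeding
   a training module is excluded to avoid leakage); a parent family
   additionally counts all its subfamilies' sequences positive; a
   subfamily ignores its parent's sequences and counts sisters negative.
   An external decoy pool joins the negatives except for CBM families,
   which are non-catalytic and have no enzyme-style decoy complement.
   The score is the engine's per-target P-value (E-value divided by the
   effective search-space size); no hit scores +∞.
5. **Cutoff optimisation**: candidate thresholds are the distinct finite
   observed scores; classify positive iff score ≤ t; the sweep maximises
   F1 = 2·(recall·precision)/(recall+precision) (0 when undefined), ties
   broken toward the smallest, most conservative threshold. The family
   cutoff is the **median** of the per-fold optima — the per-fold optima
   must be aggregated somehow, and the median is robust to a single
   aberrant fold; the per-fold values are retained in the cutoff table
   for inspection. Families with mean fold F1 < 0.5 are
   rejected and excluded from annotation.
6. **Small families** (< 5 module sequences) skip cross-validation: they
   receive a single model built from all their modules (so the
   fold-majority threshold degenerates to 1) and the median final cutoff
   of their CAZy class's optimised families.

## Annotation

Every fold model is searched against every target; hits are filtered at
the family cutoff on the sequence-level P-value; the reported domains'
**envelope** coordinates contribute coverage. Overlapping envelopes from
the same fold are unioned first, so each fold casts at most one vote per
residue; a residue is kept when ≥ ⌈K/2⌉ folds cover it. Maximal runs of
consecutive kept residues become annotations — a single unkept residue
separates two annotations. Different families annotate the same target
independently (multi-domain genes are first-class). Envelopes rather
than aligned match states define coverage; envelopes are the engine's
own uncertainty-aware domain extent, at the cost of occasionally
extending a few residues into flanking sequence (visible as mean
held-out interval Jaccard ≈ 0.88 rather than ≈ 0.96 on the benchmark).
Protein-space intervals map to nucleotide catalogue coordinates by
residues r₁..r₂ → bases 3(r₁−1)+1 .. 3r₂ (frame 1, no introns).

## Profiling

Alignment records come from name-grouped SAM/BAM (samtools collate
semantics); duplicate- and QC-fail-flagged records are dropped,
secondary/supplementary alignments retained (multi-mappers matter when
counting against a catalogue). Identity is 100·(1 − NM/L) with L = CIGAR
M/=/X + I + D columns; the retention filters are strict: L > 45 bp and
identity > 97%.

Counting is per mate: weight w = 0.5 for a paired-end mate, 1.0 for a
single-end read. The k distinct domain instances a mate overlaps (≥ 1 bp,
across *all* its retained alignments) each receive w/k — equal splitting
conserves read mass, which the tests pin down (Σ family counts ≤ filtered
total, with equality when every read lands in a domain). Every retained
mate adds w to the filtered-read denominator exactly once. RPKM divides
the family count by (summed annotated domain length of the family / 10³)
× (filtered reads / 10⁶); domain length rather than whole-gene length is
used because counting itself is restricted to domain overlaps. A 0.01
pseudocount is added to RPKM before ratio/ordination statistics (never
before richness, which counts families strictly above 1 RPKM on raw
values).

## Substrate scheme

Families carry substrate labels at three nested levels (e.g. dietary
fibre → non-starch polysaccharide → cellulose), plus glycan origin and
function-at-origin tags. Polyspecificity is intentional: an abundance is
added to *each* of a family's substrates, so substrate sums are not a
partition of total RPKM. Families absent from the scheme aggregate under
the reserved `unannotated` key rather than disappearing. The loader
enforces a consistent hierarchy: one level-2 parent per level-3 substrate,
one level-1 parent per level-2.

## Genome-collection analytics

* Presence: a family is present in a taxon iff ≥ 20% (inclusive) of its
  genomes carry ≥ 1 copy.
* Substrate enrichment: per genus, the mean over genomes of the summed
  copy number of families carrying the substrate label, standardised
  across genera with the sample (n−1) standard deviation; zero variance
  reports missing z.
* Repertoire similarity: Jaccard index over presence sets of taxa with
  ≥ 4 genomes; two empty repertoires compare as identical (J = 1,
  logged).
* Co-occurrence: ORFs with ≥ 2 distinct families are selected first;
  for a family pair, index = #ORFs containing both / min(#ORFs containing
  each), per genus with ≥ 10 genomes; pairs at index ≥ 0.2 are flagged
  reportable. Per-family cardinalities are computed over the restricted
  (multi-family) ORF universe because that universe is selected before
  any counting; `cardinality_universe="all"` exposes the other reading.

## Synthetic benchmark: what it shows

`synthetic_fixtures` plants per-family 90-residue motifs with a two-layer
mutation structure — six clade ancestors per family at 0.45 divergence
(inter-clade identity ≈ 0.3, well under the 0.6 blocking threshold) and
members at 0.05 substitution (intra-clade identity ≈ 0.9) — embedded in
random flanks. One family carries two sub-motif subfamilies (ancestors at
0.30 divergence) to exercise hierarchy-aware labelling; subfamily holdout
truths include a parent-family row, since a subfamily module is by
definition also a parent-family module. The catalogue backtranslates
modules with a fixed codon table so protein truth maps exactly onto
nucleotide coordinates; reads (default 5,000 pairs of 100 bp) carry
substitution errors only, keeping NM and identity analytic. Expected
counts are computed by the generator's own interval bookkeeping, not by
the profiler — a genuine oracle. Exact depth scaling (for the RPKM
invariance check) duplicates identical fragments under fresh names.

Benchmark sizes (6 families × 30 members, 40 genes, 10⁴ mates, 45-genome
collection) were chosen so the full pipeline recalibrates and re-profiles
in seconds while still exercising blocking, hierarchy, multi-domain genes
and multi-mapping. What passing does **not** show: performance on real
CAZy diversity (insertions/deletions within modules, fragmented genes,
inter-family homology continua), realistic community abundance
distributions, platform-specific error models, or database-version
effects on which families survive calibration.

## Numerical choices and degenerate inputs

* P-value ties in the threshold sweep resolve to the smallest threshold.
* A fold with < 2 post-filter training sequences is skipped and logged;
  a family with no successful fold raises.
* An all-infinite score set returns cutoff 0.0 with zero metrics (nothing
  classifiable).
* Canberra 0/0 terms contribute 0 (scipy convention); richness and
  prevalence boundaries are strict > 1 RPKM and inclusive ≥ 1%
  respectively.
* All randomness (fold shuffling, generators) flows from explicit seeds;
  reruns are byte-identical.

## Known limitations

* The greedy centroid clusterer is O(n²) in the worst case and is meant
  for per-family module sets, not millions of sequences; the module
  boundaries match an external clusterer's contract so one can be swapped
  in.
* Fold-model MSAs are row-subsets of a single family alignment rather
  than fold-specific realignments.
* The annotation step loads targets into memory per search; catalogue-
  scale annotation should batch targets.
* Sequence-level (not per-domain) P-values gate annotation hits, so one
  strong domain can admit a weak secondary envelope on the same target;
  majority voting suppresses most of the effect.
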