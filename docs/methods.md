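# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage, what the synthetic generator does and does not emulate,
and the known limitations.

## Genome model and coordinates

A genome is a linear DNA string over {A,C,G,T,N} with an ordered list of
CDS gene models (0-based half-open coordinates internally; GFF3 is written
1-based inclusive, BED 0-based half-open). `N` contributes to length but
never matches in repeat, ITR or motif scans — conservative behaviour that
avoids spurious repeats in gap-filled regions. The fallback ORF caller is a
six-frame longest-ORF-per-stop scan with ATG/GTG/TTG starts (archaeal start
usage); it is deterministic and explicitly approximate — it does not model
RBS signals or overlapping genes, and an N-containing codon terminates the
reading run without producing an ORF.

## GC skew and replichores

Skew is `(G−C)/(G+C)` per window (default window = step = 1000 bp,
non-overlapping; chosen to resolve kilobase-scale features), defined as 0
when a window has no G or C so the cumulative sum stays continuous. Linear
Borg-type elements replicate inward from both termini; each replication
fork leaves its strand-composition signature, so the cumulative skew is
V-shaped with its extremum at the fork-meeting point. The switch point is
the interior global extremum of |cumulative skew| (first/last windows
excluded; ties broken toward the genome midpoint), reported as the end of
the extremal window. Genes are assigned to replichores by midpoint; the
coding fraction is the majority-strand share, which is undefined (NaN) for
a replichore that contains no genes — the operation errors only when the
genome has no genes at all.

## ITR detection

The left arm is compared against the reverse complement of the right end.
Rather than taking the longest prefix that stays under the mismatch budget
(which systematically over-extends past the true arm into random sequence
until the accumulated error catches up), the arm length maximises the
score `n − 4·d(n)`, where `d(n)` is the edit distance between the length-n
prefix and reverse-complemented suffix (edlib). With match +1 and edit −4,
random extension loses score (expected −2/bp), so the peak sits at the
biological arm end: exact for perfect arms, within ±50 bp at 2%
substitutions. The score is evaluated on a coarse grid (min_arm/20) and
refined base-by-base around the peak; the search stops after a long
score-stale stretch. Defaults: min_arm = 500 bp, max mismatch fraction
0.05; an arm is only reported if its identity is ≥ 1 − max_mismatch_frac.

## Curation QC

GC jumps: window-to-window GC differences above a threshold (default 8
percentage points — the source analyses describe "substantial" jumps
without a number, so the threshold is configurable) are flagged and
adjacent flags merged. Mirror blocks: exact off-diagonal self-matches are
seeded on 32-mers shared between the sequence and its reverse complement
(anchor stride k/2 guarantees an anchor inside any block ≥ 2k), extended
maximally, and deduplicated. A pair whose two blocks overlap is a
palindrome; it is canonicalised to its two halves. Annotated ITR arms are
excluded — they are genuine architecture, not amplification artifacts.

## Tandem repeats

A TR region is a maximal run of exact unit copies, reported at its
fundamental (smallest) period; harmonics are suppressed by containment in
an already-accepted smaller-period region. Partial trailing units extend
the region but do not add to the unit count (exact-match rule). Thresholds:
≥ 50 nt and ≥ 3 units (nucleotide), ≥ 16 aa and ≥ 3 units (amino acid); no
mismatches. Maximum searched period: 1000 nt / 200 aa (configurable;
bounded runtime, beyond observed unit sizes). The stored `unit` is the
leading unit of the region (so the region is literally `unit × count +
partial`); `canonical_unit` gives the lexicographically least rotation for
cross-genome identity. Per-genome summaries report regions/100 kbp and %TR
rounded to 2 decimals; the per-genome "unit count" is the sum of unit
counts over regions. Regions straddling a CDS boundary are counted as
`overlapping` by default, with an option to fold them into in-ORF.

## Protein subfamilies and marker classes

The all-vs-all similarity search is a reimplementation of the standard
profile: a shared-5-mer prefilter (≥ 2 distinct shared k-mers) followed by
Smith–Waterman local alignment (BLOSUM62, gap open −11 / extend −1 via
Bio.Align) and a Karlin–Altschul-style expectation value
`E = m·n·2^−bit`, `bit = (λS − ln K)/ln 2` with gapped constants
λ = 0.267, K = 0.041. Retained edges need E ≤ 0.001 and coverage ≥ 0.5,
coverage measured on the shorter sequence (the upstream tool's coverage
mode is not published; shorter-sequence coverage is the permissive reading
that keeps fragment/full-length pairs). Numeric parity with MMseqs2 is out
of reach and not attempted; thresholds match the published values.

Clustering is greedy set cover: repeatedly take the uncovered protein with
the most uncovered neighbours (ties: higher total degree, then
lexicographically smaller id — determinism) as representative of a new
subfamily containing it and its uncovered neighbours. Classes follow copy
counts over the declared genome set: marker = exactly 1 everywhere;
near marker = exactly 1 in all but one genome and absent there; multicopy
core = present everywhere with ≥ 2 copies in ≥ 1 genome; accessory
otherwise. The census also reports the fraction of proteins whose
subfamily spans ≥ 2 genomes ("has a homolog in another Borg"). "Core" is
reported as marker + near marker + multicopy (near markers occur in all
but one genome yet are conventionally counted in the core; both totals are
exposed so either convention can be read off).

Heme motifs: each cysteine anchor contributes at most one motif at the
smallest spacing n ∈ [2, 30] such that `C X_n C H`; n = 2 is canonical
CxxCH, n > 2 non-canonical; ≥ 3 canonical motifs ⇒ multiheme cytochrome.

## Colocalization

Two core subfamilies are colocalized in a genome when the minimum ordinal
distance over their member genes is ≤ 10 (window measured on the full
genome gene order; multicopy families use the minimum over pairs, so extra
copies never break an edge). An edge requires support in ≥ 5 genomes — the
source text says "a minimum of five" while a figure caption says "n > 5";
the inclusive reading is the default and both knobs are exposed. Clusters
are connected components of size ≥ 2 (networkx); isolated nodes are listed
separately.

## Discovery

Bins are searched against the marker reference set with the same alignment
machinery; "reasonably high confidence" is operationalised as bit score
≥ 50 and coverage ≥ 0.5 (configurable; no number is published). A bin is
accepted when ≥ 60% (inclusive) of the markers have a hit; markers hit by
≥ 2 proteins in one bin are flagged as duplicated (multi-element
mixtures). Strict markers only by default — near markers are not counted
toward the 60%. Contig filtering takes externally supplied per-contig GC,
coverage and classified-protein fractions; this package performs no
taxonomy lookups itself.

## Methylation motifs

Motif densities are both-strand occurrence counts per kbp of the linear
sequence counted once (ITR arms are near-identical but both are genuine
sequence; they are not double-discounted). This both-strand reading is
what makes a 71% template-strand share meaningful alongside a ~188/kbp
density. The non-coding fraction is computed over occurrences fully inside
genes: an occurrence is coding-strand when its strand equals the gene's.

`enrich_motifs` emulates the manual "extraneous base" refinement
automatically: site context windows (±(k_max−1), k_max = 6) are grouped by
the base at the modified position; each window position is tested
base-by-base for significant depletion against an empirical background
(one-sided two-proportion z-test, Bonferroni-corrected at α = 0.01 across
all position×base tests). The background is estimated from the two
outermost window positions on each side, conditioning it on the strand and
regional composition the sites actually come from — a genome-wide
background mis-calls flanks on strand-asymmetric genomes. Unconstrained
positions are dropped; the contiguous constrained run through the modified
base, with per-position surviving base sets collapsed to IUPAC codes, is
the minimal motif, ranked by observed/expected enrichment. Site counts are
capped at 1500 by even subsampling: planted signals are absolute (zero
occurrences of depleted bases) while first-order background correlations
would reach spurious significance at very large n. At least 100 usable
sites are required. Limitation: two motifs sharing the same modified base
(e.g. two different C-centred motifs) are merged into one degenerate
consensus.

## Abundance

Normalization divides each sample's mean coverages by the total bases
sequenced in that sample and multiplies by 10¹¹. Correlations are Pearson
on normalized coverage (not log-transformed, matching the published
procedure; a log option exists), require ≥ 3 samples, and skip constant
profiles with a warning. Host candidates are pairs with r strictly above
0.995; no multiple-testing correction is applied to this rule (raw
thresholds are what the source reports). Copy ratios divide normalized
coverages, with an aggregate mode summing numerator and denominator sets;
a zero host coverage yields NaN with a warning.

## Synthetic generator

The generator is the package's test bed: every feature is planted with
known coordinates and each detector is verified round-trip against that
truth. What it emulates, and how:

- **Background sequence**: a first-order Markov chain over ACGT whose
  stationary composition is calibrated (deterministic fixed-point, ~10⁻⁶
  closure) to three targets at once: GC content (default 0.33), both-strand
  YC+GR dinucleotide density (default 188/kbp) and the YC:GR ratio that
  sets the genic template-strand share (default 0.71). The single boost
  parameter raises P(C | Y), giving mild dinucleotide realism for motif
  tests. The chain targets are pre-compensated for dilution by the
  symmetric high-GC islands and by minority-strand genes, so the
  genome-level observables land on the planted values.
- **Architecture**: the two replichores are mirror-image chains (fwd
  strand C-rich left of the terminus, G-rich right of it), which
  simultaneously produces the V-shaped cumulative skew and the
  template-strand YC bias. The ITR is imposed by copying the left arm's
  reverse complement onto the right end; the three bases flanking each arm
  are pinned to mismatch so the planted arm is maximal and detection can
  be exact. High-GC islands (default 2 × 8 kbp at GC 0.50) are placed
  before the tandem repeats (an 8 kbp island cannot avoid 23 scattered
  TRs, the reverse packing order always fits), never straddling the
  replichore boundary.
- **Tandem repeats**: exact arrays with primitive (aperiodic) units of
  4–24 nt, unit counts ≥ max(3, ⌈50/len⌉), planted inside genes or in
  intergenic gaps, with flanking bases pinned so the array is maximal.
- **Cohort**: families are random-ancestor proteins (60–140 aa) mutated
  per member at rate 0.10, chosen so expected within-family identity is
  ≈ 81% — comfortably above the clustering thresholds — while between-family
  similarity is actively enforced to stay below them: any candidate protein
  sharing ≥ 2 five-mers with another family is re-drawn, which also keeps
  chance cross-family alignments below the E ≤ 0.001 / coverage ≥ 0.5
  retention rule. Markers sit at conserved gene-order slots (±1 jitter);
  a block of 7 markers occupies strictly consecutive slots with a 15-gene
  isolation gap so the colocalization stage has an exactly recoverable
  cluster; remaining families are densely spaced (realistic synteny
  chains); near markers are absent from one genome each (round-robin);
  multicopy extra copies sit adjacent to the primary copy. Cohort
  nucleotide filler uses the order-0 background (family structure does not
  depend on dinucleotide statistics), keeping 17-genome cohorts cheap.
- **Coverage**: host profiles are log-normal across samples (defaults: 83
  samples, 6 hosts, 8 Borgs); each Borg tracks its host × ratio (default
  8.8) × log-normal noise; per-sample sequencing totals are drawn so the
  normalization step is exercised round-trip.
- **Artifacts**: `mirror` appends the reverse complement of an internal
  block; `chimera` splices a 50%-GC foreign block; junctions recorded.

Generation is a pure function of (spec, seed); identical inputs give
byte-identical output.

What it does **not** emulate — and hence what passing tests do not show
about real data: read-level errors and assembly; genes are coordinate
intervals whose protein sequences are independent of the underlying
nucleotides (so gene-calling accuracy is untested beyond constructed
cases); repeat-length population variability; inexact (mismatched) tandem
repeats; real protein family structure (domains, indels, fragmentary
genes); taxonomy; and methylation signal chemistry (sites are positional
calls, not ionic-current data).

## Problem sizes

Tests and the acceptance script run at desk scale, chosen so the full
suite completes in minutes while leaving each planted feature at full
size: single-genome checks use 120–300 kbp genomes (2 kbp ITR, 70/30
replichore split), oracle-equivalence checks use 200 sequences of ≤ 5 kbp
against a naive O(n²·p) enumeration, cohort checks use 17 genomes of
~465 kbp with 50–100 aa proteins across 20 seeds, switch-point recovery
uses 100 replicates of 90–130 kbp, and coverage checks use the full
83-sample design. Real Borg genomes (0.6–1.1 Mbp) are the generator's
defaults and run in under a second per genome.

## Known limitations

- The similarity stage is quadratic in cohort size past the k-mer
  prefilter; it is built for dozens of genomes, not thousands.
- Mirror-block detection is exact-match only; diverged inverted
  segmental duplications are not flagged.
- The E-value uses pairwise m·n rather than a database-size correction,
  so absolute significances are not comparable to BLAST outputs.
- `enrich_motifs` reports one motif per modified-base letter and assumes
  a single dominant motif per group.
- The replichore model assumes exactly two replichores with terminal
  origins; elements with internal origins would need a different switch
  statistic.
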