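# Methods

`famscan` re-implements, as an offline and fully tested pipeline, the
computational core of a plant gene-family survey of the cyclic
nucleotide-gated channel (CNGC) type: motif-based family
identification, protein physicochemical characterization, Ka/Ks-based
duplication dating, exon–intron structure inference, promoter
cis-element scanning, neighbor-joining phylogeny with clade-group
assignment, and tissue-specificity summaries. This note documents the
models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic-data generators do and do not
emulate.

## Family identification by diagnostic motif

Plant CNGCs share their domain architecture (six transmembrane
segments plus a C-terminal cyclic nucleotide-binding domain, CNBD)
with Shaker-type AKT/KAT potassium channels, so domain presence alone
cannot identify the family. What is diagnostic is a short motif
spanning the phosphate-binding cassette (PBC) and hinge within the
CNBD. `famscan.motifs` compiles a hyphen-separated PROSITE dialect:
literal residues, bracketed alternative sets, the `X` wildcard, `(n)`
and `(n,m)` repeat counts. Two pattern files ship with the package: a
stringent maize-grade motif
(`L-X(2)-G-[ED]-ELL-[TSG]-W-[ACY]-L-X(10,20)-[SA]-X-T-X(7)-[EQ]-[AG]-F-X-L`)
and a broader plant consensus. The consensus contains `0` tokens
inside brackets and `X(0,1)` repeats; we read both as marking the
position optional (match 0 or 1 residues) — the only internally
consistent interpretation of the published strings, and an explicit
design choice rather than an established convention.

Scanning reports, for every start position, the shortest accepted
match (candidate lengths probed in ascending order), which makes the
output deterministic and directly checkable against a brute-force
matcher. The identification filter accepts a protein when it (i)
carries at least one motif hit, (ii) is at least 200 aa long, and
(iii) is not redundant with an already-kept candidate. Redundancy is
operationalized as identical sequence or ≥ 99% identity over the
shorter sequence in a global alignment, keeping the longer member —
an explicit, testable proxy for the manual redundancy curation such
surveys perform. The HMM/BLAST pre-search used with real proteomes is
replaced by whole-proteome motif scanning; callers may equally pass a
pre-filtered candidate list.

## Physicochemical properties

Molecular weight is the sum of average (not monoisotopic) residue
masses plus one water, using the ExPASy mass table; GRAVY is the mean
Kyte–Doolittle hydropathy; the theoretical pI is the root of the net
charge under the Bjellqvist pKa set (residue-specific N-terminal pKa,
C-terminus 3.55, side chains D/E/C/Y/H/K/R), found by bisection on
[0, 14] to |charge| < 1e−4. Net charge is strictly decreasing in pH,
so the root is unique. Ambiguity letters are rejected rather than
averaged: survey sequence sets should be clean, and failing loudly is
safer than silently shifting a reported mass. The test suite
cross-checks all three quantities against Biopython's ProtParam (an
independent implementation of the same ExPASy conventions); the one
tolerated difference is the 4th-decimal per-residue gap between the
ExPASy and IUPAC-1997 average mass tables.

## Ka/Ks and duplication dating

The estimator is Nei–Gojobori (1986) counting — the method behind the
DnaSP values such surveys report. Per codon, each position contributes
the fraction of its three single-nucleotide changes that are
synonymous to S (changes to stops count as nonsynonymous), the rest to
N, so S + N = 3 per codon; pair totals average the two sequences.
Observed differences average over all minimal substitution paths
between the two codons, excluding paths through stop codons and
renormalizing (falling back to the unrestricted average in the rare
case every path is blocked). Proportions are Jukes–Cantor corrected,
`K = −(3/4)·ln(1 − 4p/3)`; p ≥ 3/4 is flagged saturated. Codon
alignments are protein-guided (global BLOSUM62 alignment of the
translations, codons threaded back), which preserves frame by
construction; gapped codons are skipped.

Dates use the molecular clock `Mya = Ks / (2λ) · 1e−6` with
λ = 6.5 × 10⁻⁹ substitutions/site/year — the grass-lineage
synonymous clock rate conventional in these surveys. Ka/Ks < 1, = 1
(within 1e−9), and > 1 classify purifying, neutral, and positive
selection. Maximum-likelihood codon models (Goldman–Yang) are out of
scope.

## Exon–intron structure

The CDS is assumed to occur exactly (mismatch tolerance 0) inside its
genomic sequence as an exon chain with introns of ≥ 20 bp; this is
the regime of a survey's own CDS/DNA pairs, so a scoring spliced
aligner is unnecessary. The solver is a memoized depth-first chaining
over exact-substring anchors (12 bp); among exact chains it prefers
(1) fewest non-canonical (non-GT..AG) introns, (2) fewest introns,
(3) leftmost placement. Parsimony sits between the spec-level
canonical and leftmost rules because a pure leftmost rule would favour
chance-anchored spurious splits over the single-exon reading of an
intronless gene. The leftmost rule then resolves "sliding" introns
created by repeated junction bases. Exons shorter than the 12-bp
anchor (micro-exons) are outside the solver's scope. Both strands are
tried (plus first); intron phases are the cumulative coding length mod
3 at each junction, in transcription order.

## Promoter cis-elements

Promoters (conventionally the 1,500 bp upstream of the translation
start) are scanned against PLACE-style elements given as IUPAC
degenerate strings. All matches are reported, overlaps and
self-overlaps included, on both strands by default; a minus-strand hit
records the forward coordinate of its window and the strand-corrected
matched sequence. A 17-element mini-table (the shared and
gene-specific element ids a maize CNGC survey highlights, with
sequences entered from the public PLACE records) ships as a fixture;
the full PLACE database is not redistributed, and whole-database
counts (e.g. "137 elements") are database-version dependent by nature
and deliberately not asserted. The summary layer reports elements
shared by every promoter and elements unique to one gene.

## Phylogeny and groups

Distances are Poisson-corrected protein distances, `d = −ln(1 − p)`
with p the proportion of differing sites under pairwise (not
complete) deletion of gap columns; saturated pairs are flagged. Trees
are built with Saitou–Nei neighbor joining: minimal Q-criterion joins,
ties broken deterministically by the lexicographically smallest
representative-leaf pair, negative branch lengths clamped to zero with
the deficit moved to the sibling edge, and a final trifurcation (the
tree is unrooted). Bootstrap supports resample alignment columns with
a seeded generator; the support of each internal edge of the full-data
tree is the percentage of replicates containing the same bipartition,
serialized as integer internal-node labels. Because the input rows are
sorted internally and all tie-breaks are deterministic, supports are
bit-reproducible for a fixed seed and invariant to input row order.

Group assignment (the CNGC literature's Groups I, II, III, IVa, IVb)
is reference-guided: each query leaf takes the group of the smallest
bipartition side containing it that contains at least one reference
leaf, provided those references are unanimous; otherwise the leaf is
reported unplaced. The multiple sequence alignment itself is an input
(any aligner may produce it): alignment inference is not
re-implemented, and ML/Bayesian tree methods are out of scope.

## Expression specificity

Tissue specificity of FPKM profiles is quantified with the tau index,
`tau = Σ(1 − x_i/x_max)/(n − 1)`: 0 for uniform nonzero profiles, 1
for single-tissue expression, scale-invariant by construction. Genes
whose maximum FPKM is below 1.0 are flagged not expressed. The source
surveys describe tissue specificity only qualitatively; tau with the
FPKM ≥ 1 threshold is this package's explicit operationalization. No
trend statistic is computed for developmental time-courses.

## Synthetic data: what it emulates, and what it does not

`famscan.synth` generates every input class the pipeline consumes,
each a pure function of `(config, index)` with the ground truth
recorded: proteins with one motif expansion planted at a known
position (and rejection-sampled motif-free decoys), open reading
frames with planted GT..AG introns at known phases, duplicate CDS
pairs mutated by Poisson numbers of synonymous/nonsynonymous
single-nucleotide changes (transition/transversion bias 2.0, stops
rejected; truth = realized events per NG86 site, so the estimator's
Jukes–Cantor correction is genuinely tested), promoters with planted
element instances on random strands, group-structured alignments, and
FPKM matrices with planted specific/uniform/silent genes.

Defaults mirror the survey conditions: 12 family members + 11 decoys,
protein lengths 330–745 aa, 0–7 introns of 80–1,200 bp, 1,500-bp
promoters, duplicate pairs of 900 codons at target Ks 0.18 and
ω = 0.14, and a 12-gene × 6-tissue matrix (ear, embryo, endosperm,
pollen, root, tassel) with one silent gene.

Limitations to keep in mind when generalizing from passing tests:
backgrounds are uniform-composition (real maize sequence is GC- and
codon-biased, which mainly raises chance-match rates for short IUPAC
elements); the substitution process is single-nucleotide with ts/tv
bias, not a full codon model; planted exons are ≥ 30 bp; proteins are
i.i.d. residues rather than domain-structured, so decoys are "easy"
relative to real Shaker channels — the separation test exercises the
motif logic, not the hardness of real proteome screening; and FPKM
noise is log-normal without replicate structure.

## Problem sizes and numerical conventions

The shipped tests run the oracle comparisons at 100 random 30-codon
pairs (NG86 path enumeration), 50 random additive 4–8-taxon matrices
(NJ exactness via Robinson–Foulds = 0), 50 seeded 900-codon duplicate
pairs (Ks recovery within ±0.03 of target), 1,500-bp promoters against
a sliding-window oracle, and 25–100-replicate bootstraps for the
reproducibility and clade-support checks — sizes chosen so the whole
suite completes in well under a minute while keeping each estimate's
Monte-Carlo error far below the tolerance it is tested at. All
intervals are 0-based half-open internally; 1-based inclusive
coordinates appear only in rendered reports (GFF3, hit tables).
Bisection tolerances, tie-breaks, and saturation thresholds are stated
inline where they apply.
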