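# Methods

This note documents the models, conventions and numerical choices behind
`recombikit`, in the spirit of a methods appendix: what each component
computes, which parameters matter, and what the synthetic test data do and
do not establish about behaviour on real genomes.

## Coordinates and strand conventions

All internal intervals are 0-based half-open on the forward assembly
strand; GFF3 and the Phytozome-style TSV dialect (1-based inclusive) are
converted on read. "Upstream" is always defined on the coding strand: for
a minus-strand gene the upstream promoter window lies at *higher* genomic
coordinates, and all extracted subregion strings (whole gene, 5′-UTR,
ATG–Stop, 3′-UTR) are returned in mRNA sense. The ATG–Stop string is the
unspliced genomic span from start through stop codon; UTR strings are
spliced (segments concatenated). Gene length is measured from the start of
the 5′-UTR to the end of the 3′-UTR. Multi-transcript loci collapse to the
first-listed transcript; all transcript ids are retained on the model.
GC content divides by annotated (A/C/G/T) bases only, so ambiguity codes
neither count as G/C nor inflate the denominator.

## Tandem-repeat detection

A region `[s, e)` scored at period *p* is compared against a perfect
tiling of a consensus unit: for each phase (position mod *p*) the
consensus base is the majority base (ties to the alphabetically first;
N can never be consensus), and identity is the fraction of positions
matching the tiling. A region qualifies when identity ≥ `min_identity`
(default 0.90) and its length reaches the class cutoff — 10 bp for
mononucleotide repeats, 20 bp for di-/trinucleotide and for longer units
(tetra+) — with at least two full units always required. Reported hits
are containment-maximal; overlapping hits of the same period merge (the
merged hit reports the best component identity); and a hit whose interval
is covered by a hit of a smaller period dividing its own is suppressed as
a harmonic, so a dinucleotide run is not re-reported at periods 4, 6, 8.

The native detector bounds its search with `max_period` (default 8) and
`max_region` (default 500 bp). These bounds define the detector's scope:
repeat units longer than 8 bp and single repeat regions beyond 500 bp are
out of range, which is adequate for the short simple repeats the design
rules care about, but narrower than a general-purpose tandem-repeat
engine. The implementation exactly matches an exhaustive brute-force
enumeration of the same definitions (property-tested on >1,000 random and
repeat-enriched strings); a candidate-island prefilter based on lag-*p*
self-match density provides speed without changing results (a qualifying
region at identity *q* has lag-*p* match density ≥ 1 − 4(1 − *q*), so a
window below half that density cannot host one).

Whether identity should be measured against the consensus or between
adjacent copies is genuinely ambiguous in the field; consensus is used
here, and the worked example GGGGGTGGGG scores 9/10 = 0.90 either way.

## Inverted-repeat detection

An inverted repeat is a stem–spacer–stem structure: a stem of ≥ 10 bp
followed within ≤ 10 bp by its reverse complement, with ≤ 1 mismatch per
10 bp of stem, stem identity ≥ 0.90, and total length ≤ 210 bp. Two
sharpenings make the definition well-posed:

* **Stem terminal pairs must match.** Otherwise any 11-bp spacer could be
  re-described as a longer stem with one dangling edge mismatch, quietly
  defeating the spacer cap.
* **Containment maximality.** Every sub-stem of a long palindrome also
  satisfies the thresholds; only structures not properly contained in
  another qualifying structure are reported. Among co-extensive
  parameterisations of the same interval, the longest stem (then highest
  identity) is the representative.

The detector enumerates anti-diagonals of the complement-match matrix
(positions *i*, *j* with *i* + *j* constant pair in a stem), which makes
the per-diagonal work a handful of vector operations; a pigeonhole
prefilter (a stem with ≤ *k* mismatches per 10 bp contains a 10-window
with ≥ 10 − *k* matches) skips the vast majority of diagonals on
repeat-free sequence. The definition is symmetric under reverse
complement, and the implementation is property-tested against a
triple-loop brute-force oracle.

For per-gene counting, structures of total length ≥ 20 bp are counted
(at the default stem minimum of 10 bp this is all of them). Repeats that
cross the start or stop codon count at whole-gene level but in no
subregion. Global (interspersed) repeats are never computed internally; a
pre-masked interval BED can be supplied and is counted per gene with the
same full-containment rule.

## uORF classes

Classification walks codons from each upstream ATG through the spliced
5′-UTR and into the CDS: a stop wholly within the 5′-UTR makes a class 3
uORF (complete upstream ORF); otherwise an in-frame uATG is class 1
(potential N-terminal extension — the frame reads through into the main
ORF) and an out-of-frame uATG is class 2 (terminating inside the CDS, or
never meeting a stop). Reading frame is a transcript property, so the
spliced transcript is the substrate; the same functions accept unspliced
strings for annotation-free use. Stops are TAA/TAG/TGA; near-cognate
starts are ignored. The initiation-context flag (purine at −3 or G at +4)
is informational only — the motif is a declared convention, not a
validated predictor.

## Clone coverage

A clone covers a gene when the required interval — the gene span,
optionally extended upstream on the coding strand — lies entirely within
the clone's mapped interval. The headline coverage statistic uses
`upstream_bp = 0` (the gene body as drawn in gene-size analyses);
arm-aware searches use 3,000 bp so the entire homology window is inside
the clone. Both are one flag apart and both are reported, because the
published coverage figure does not state which definition it used. The
relaxed mode accepts clones terminating within the 3′-UTR (the stop codon
must still be inside). Ranking is by ascending clone length with
lexicographic clone-id tie-break, capped at five per gene.

## Homology-arm design

Every 50-mer lying fully inside the 2,000–3,000-bp upstream window is a
candidate (N-containing windows and windows containing the I-SceI
recognition site are dropped — the latter would be destroyed at cassette
linearisation). Hard filters: longest homopolymer run ≤ 5, longest
tandem dinucleotide unit count ≤ 4, GC within 0.40–0.70. Survivors rank
by the complexity score

    score = 2·|GC − 0.60| + 0.1·run + 0.1·dint   (ascending)

with ties broken by proximity to the −2,500-bp offset (the observed mean
upstream placement in practice) and then ascending genomic coordinate.
The score is a declared stand-in: the published tool names its complexity
features (runs, dinucleotide tandems, GC) but not its scoring function,
so this package's ranking is validated by its feature set and its
determinism, not by base-for-base agreement with any published arm table.
If fewer than five candidates survive, filters relax in the order
GC bounds → dinucleotide cap → homopolymer cap, and the relaxation is
recorded on the returned arms. A separate override places the arm on the
first 50 bp of the 5′-UTR for genes whose clone coverage forbids the
upstream window.

The 3′ arm is the 50 genomic bases immediately 5′ of the stop codon,
introns included — homology is to the clone's genomic DNA, not the mRNA —
and the annotated stop codon is verified first, failing loudly on
annotation drift. Cloning primers prepend the arms to the vector
annealing sequences (reverse primer: reverse complement of the 3′ arm),
which are read from annotated vector features so all five tagging vectors
work unmodified. Check primers are four conventional pairs (upstream
window, gene 5′ region, gene 3′ region, 3′ flank) with 200–800-bp
amplicons, each screened through the QC rules; unprimable regions are
reported rather than silently skipped.

## Primer QC thermodynamics

The four rules are literal: length ≤ 30 nt; secondary-structure ΔG above
−9 kcal/mol at 66 and 72 °C (worst case over both); at most 4 tandem
mono- or dinucleotide units; at most 4 consecutive 3′ G/C bases.

ΔG uses a unified nearest-neighbor ΔH/ΔS table (initiation and terminal
A·T terms included, no dangling ends), with ΔG(T) = ΔH − T·ΔS. Cross- and
self-dimers take the most stable single perfectly-matched run over all
ungapped antiparallel alignments; hairpins search stems ≥ 3 bp with loops
of 3–12 nt, adding an entropic loop-closure penalty. Structure energies
are evaluated at the table's native 1 M monovalent reference state. This
choice is deliberate: with a 50 mM salt entropy correction, even a fully
complementary 20-mer duplex melts above −9 kcal/mol at 66–72 °C, which
would leave the ΔG rule unable to flag anything — including a primer pair
that is its own reverse complement. At the reference state the floor
separates exactly the cases the rule is meant to catch (long or GC-rich
complementarity) from incidental 4–6-bp matches. The Tm estimate, which
is reporting-only, applies the conventional 50 mM correction at 500 nM
primer; no acceptance value depends on it, since the published mean
primer Tm came from an unstated model.

Failure categories order by severity: cross-dimer > self-dimer > hairpin
> length > repeats > 3′-GC.

## Vector models and construct simulation

A tagging vector is a circular GenBank record whose features map (via a
label-alias table) onto the roles: linker, fluorophore, affinity tag,
terminator, selection marker, ori, KanR, ccdB, I-SceI site, and the two
primer annealing sites. Validation requires exactly one I-SceI site
(canonical 18-bp recognition sequence TAGGGATAACAGGGTAAT — the published
description fixes its length and genome absence but not the sequence, so
the canonical site is a declared convention), unique annealing sites, and
ccdB outside the amplified path.

Cassette PCR yields `arm5 + amplified path + arm3`; the product must be
ccdB-free and carry the single I-SceI site. Assembly joins the retrieved
genomic region (5′ arm through the base before the stop codon) to the
cassette at both arms; each arm must occur exactly once in the region,
since a second occurrence would make recombination ambiguous. The
circular product's length is retrieved + cassette − 2×50 (shared arms
counted once); position 0 is the first retrieved base, and digests are
reported as sorted multisets so they are rotation-invariant. The fusion
frame is intact when the spliced coding length from ATG through the 3′
arm end is a multiple of 3 — the 3′-junction then translates
…(last codon)–GGLGGSGGR–(fluorophore M)…. Diagnostic-enzyme suggestions
keep enzymes cutting 1–3 times and rank by the minimum pairwise fragment
difference (single-fragment digests score the full length, putting
single cutters first), ties alphabetical.

## Statistics

Wilson score intervals are computed closed-form with a z parameter
(default 1.96) and cross-checked in the tests against numeric
root-finding of the score equation and against an independent
implementation. Clonability extrapolation applies per-size-bin success
rates from a tested panel to a genome-wide size distribution; bins
without attempts are excluded and genome bins without matching data are
flagged not-extrapolatable. The rank-sum comparison reports U as the
number of (a, b) pairs with a < b plus half-ties (so U = 0 means every a
exceeds every b), with a tie-corrected two-sided normal-approximation
p-value.

## Synthetic data: what it emulates and what it does not

The fixture generator builds chromosomes of intron-less genes (5′-UTR,
single-exon CDS, 3′-UTR) at GC 0.64 — a whole-gene compromise for a
genome whose coding regions run near 68% — each with a 3,500-bp upstream
flank so the full arm window exists. Planted features define the ground
truth: tandem repeats of each class, inverted repeats, a dinucleotide
repeat straddling the start codon (counted whole-gene only), uORFs of
each class, an exact clone-coverage fraction with three size-ranked
clones per covered gene and one clone terminating 10 bp inside a 3′-UTR,
and one engineered best arm window per gene (GC exactly 0.60, run ≤ 2, no
repeated dinucleotide unit, flanked by GC-saturated guard sequence so
every overlapping window filters out or scores worse).

Backgrounds are rejection-sampled to be repeat-free at default detection
parameters, and unwanted start/stop codons are removed by C-substitution
— replacing a base with C can never create an ATG or a stop codon, since
neither contains C — so recovered counts equal planted counts with zero
false positives. The generator re-detects every planted feature before
returning (`self_check`), making closure a construction guarantee rather
than a hope; identical seeds give byte-identical files.

What passing on these fixtures shows: the detectors, the coverage search,
the arm ranking and the construct simulation implement their definitions
exactly, at realistic GC and plausible gene sizes. What it does not show:
behaviour on real annotation pathologies (UTR introns, fragmented gene
models, mis-mapped clones), on repeat structures outside the native
detector's period/length bounds, or agreement with external repeat
engines — the genome-scale reproduction test covers the published
dataset-level numbers but requires the reference files locally.

Problem sizes: the default test fixture uses 8 genes (one per planted
pattern) on 2 chromosomes; the acceptance script regenerates a 50-gene
dataset with an 0.86 planted clone-coverage fraction and a 4.6-kbp
cassette model, which keeps a full pipeline run around a minute on one
CPU while exercising every pattern several times.

## Known limitations

* The native tandem detector's period/region bounds (8 bp / 500 bp) are
  narrower than genome-annotation engines; dataset-level repeat counts on
  real genomes will differ where long-unit or very long repeats matter.
* Secondary-structure energies use perfect-match runs only (no internal
  mismatches, bulges or partition function); the −9 kcal/mol rule is a
  screen, not a folding prediction.
* The uORF scanner requires an annotated 5′-UTR; genes without one
  (or with misannotated starts, the very problem uORF analysis flags)
  yield no records.
* Coverage statistics trust the clone placement map; mis-mapped clones
  are an upstream problem and are not re-mapped here.
* The clonability extrapolation is purely rate-based per bin; it carries
  the tested panel's ascertainment biases into the genome-wide estimate.
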