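# Methods

This note documents the models, conventions, numerical choices and known
limitations behind each analysis stage, and what the synthetic-data tests
do and do not demonstrate about real data.

## Coordinates, strands and the data model

All coordinates are 1-based closed intervals on a circular genome, the
GenBank convention. A feature crossing the coordinate origin is stored as a
single feature with `end < start` and serialized to GenBank as
`join(start..L,1..end)`. Strand labels are `F` (majority strand, as
annotation tables print it) and `R`; the internal canonical orientation is
`F`, and `R` features are reverse-complemented on extraction. Ambiguity
codes other than `N` are rejected at parse time; `N` bases are excluded
from composition numerators and denominators and skipped in codon tallies.
The GenBank reader handles a minimal dialect (LOCUS, FEATURES with
gene/CDS/tRNA/rRNA/misc_feature/D-loop, ORIGIN) through Biopython; other
keys are ignored with a logged warning. At most one control-region feature
is permitted per record.

## Junction ledger

The gap after feature *i* is `start(i+1) − end(i) − 1`, evaluated on the
circle (the wrap junction from the last feature back to the first is
included), with the representative taken in the centered window
(−L/2, L/2] so overlaps at the origin stay negative. When no feature nests
inside another, Σ feature lengths + Σ gaps = genome length; nesting is
rejected as an error because that identity breaks. Spacer/overlap
summaries exclude junctions flanking the control region by default,
matching the convention of counting intergenic spacers "except the
A+T-rich region"; an argument includes them.

The packaged reference table carries the published size and spacer columns
alongside the coordinates. Coordinates are authoritative; QC reports every
disagreement. In the packaged table these are: the atp6 row (printed size
696 vs 678 from its own coordinates) and the rrnL–trnV junction (printed
spacer 0 vs a 1-bp coordinate gap). The second conflict is irreducible —
no single-number correction makes the trnL1 overlap (−1), the rrnL size
(1385) and the rrnL spacer (0) simultaneously consistent — and it is why
the coordinate-derived spacer census (19 locations, 248 bp) differs from
the printed column's (18, 247 bp); the original running text claims
257 bp, which matches neither reading and is therefore only flagged, never
asserted.

Gene-order comparison uses rotation alignment: the query order is rotated
into the register minimizing position/strand mismatches against the
reference, and the mismatching genes are reported. Reflections are not
normalized, since strand is biological signal. No rearrangement-distance
metric (breakpoint/DCJ) is computed.

## Composition and skews

AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C); a zero denominator yields a
missing value rather than 0. Whole-genome statistics are computed on the F
strand including the control region; per-category rows concatenate the
strand-oriented (coding) gene sequences. This convention matters — skews
negate under reverse complement — and published tables rarely state
theirs, so it is fixed here and documented. Percentages are reported to
one decimal; full precision is kept internally.

Codon-position AT% indexes positions within the reading frame after
removing the start codon and the (complete or truncated) stop, identically
to the codon-usage extraction, so the two stages can never disagree about
frame.

## Codon usage and RSCU

The code table is NCBI translation table 5 (invertebrate mitochondrial:
AGA/AGG = Ser, ATA = Met, TGA = Trp; stops TAA/TAG only), taken from
Biopython, leaving 62 sense codons. Stop classification is forced by
length mod 3 plus terminal bases: in-frame genes must end TAA/TAG, one
base over frame must end T, two bases over must end TA (truncated stops,
completed to UAA by post-transcriptional polyadenylation); anything else
is flagged anomalous. Nonstandard initiation codons (e.g. the CGA of cox1)
are excluded from the tally like ATN starts, not counted and not errors.
Internal in-frame stops are reported per gene in QC output and excluded
from counts, never silently dropped. Synonymous families follow the
conventional figure layout with the six-fold amino acids split: Leu1
(CTN), Leu2 (TTA/TTG), Ser1 (AGN), Ser2 (TCN); the split lives in one
table (`codon_usage.FAMILY_OF`). RSCU is count × degeneracy / family
total, with a wholly unused family reported as missing for all members.

## Control-region scanners

All detectors work on the region-local sequence (first base = position 1)
and are position-covariant.

**Origin signature.** Every ATAGA occurrence followed within `max_gap`
(default 5) bases by a T-run of at least `min_t_run` is reported with the
run length. The default threshold is 10 rather than the reference
genome's 19-bp instance so that shorter orthologous runs are admitted;
both parameters are exposed.

**Microsatellites.** Maximal perfect tandem runs of a primitive 1–6 bp
unit with at least `min_copies` (default 5) complete copies; the unit is
normalized to its lexicographically minimal rotation, and runs expressible
with a shorter unit are suppressed (an (AT)n stretch is never reported as
ATAT).

**Tandem repeats.** A deliberately simple, fully specified relative of
classic tandem-repeat finders, implemented from scratch. For each
candidate period p the region is compared with its own p-shift; matching
positions score +2 and mismatches −3 (no indels — see limitations), and
the detector reports, per period, the greedy sequence of disjoint
maximum-score segments reaching `min_score` (default 20), recursing into
the flanks of each accepted segment. Ties prefer the smallest end, then
the smallest start. A segment [a, b] of the match array is the repeat
region [a, b+p] with fractional copy number (b−a+1+p)/p, a majority-rule
consensus per phase, and percent identity of the self-alignment.
Candidate periods are seeded by dinucleotides recurring at distance p;
under the default scores any segment with positive score must contain two
adjacent matches, so seeding provably loses nothing. Overlapping
detections at different periods are deduplicated by score (ties: shorter
period, then leftmost) when they overlap more than half of the shorter
span. The scoring parameters are this package's own defaults — the
classic programs' parameters do not transfer to a gapless model — and are
config-exposed.

**Stem-loops.** All maximal bulge-free hairpins: stems pair Watson–Crick
plus G·U when `allow_gu`, minimum stem 5 bp, loop 3–20 nt; maximality
holds inward (the innermost pair cannot move further in) and outward (the
stem cannot grow). Each hit carries flags for a TATA within 10 nt upstream
and a G(A)1–8T within 10 nt downstream, the two flanking motifs of the
secondary-strand initiation site. No thermodynamics: this is a
combinatorial detector, not a minimum-free-energy folder.

**Fixed motifs.** Presence/absence of ATACTAA in the trnS2–nad1 spacer,
AAGCCTTA within ±20 nt of the trnW/trnC junction (both strands searched),
and an A-run ≥ 9 in the 30 nt upstream of trnM.

## tRNA cloverleaf folding

The cloverleaf is parameterized as: acceptor stem 7 bp pairing the 5' end
against the 3' end offset by a 0–1 nt discriminator; spacer 0–4 nt; DHU
stem 0–4 bp with loop 3–12 nt (stem 0 = the trnS1(AGN)-type arm that
forms no stable stem, leaving the region unpaired); spacer 0–4 nt;
anticodon stem 5 bp with a 7-nt loop whose positions 3–5 hold the
annotated anticodon (which pins the arm absolutely); variable loop
0–23 nt; TΨC stem 0–6 bp with loop 3–9 nt. Pairs score WC +2, G·U +1,
mismatch −1, and the fold maximizes the total. Because the DHU and TΨC
placements contribute independently, each side is optimized separately —
mathematically identical to exhaustive joint search, which the tests
verify against a literal cross-product oracle. Tie-breaks are
deterministic: longer DHU stem, then longer TΨC stem, then leftmost
placements, then discriminator present. CCA tails are not expected on
mitochondrial tRNA genes and are trimmed when present (a sequence
genuinely ending in CCA would lose three bases; acceptable for this
domain). "Unmatched" pairs in the reporting sense are G·U + mismatches.

## Phylogenetics

Input is a pre-aligned amino-acid supermatrix or per-gene blocks
(concatenated in order, block provenance kept). Distances: p (mismatch
fraction) or Poisson correction −ln(1−p), the classic amino-acid default,
with per-pair deletion of gap-containing columns; a saturated pair (p = 1)
is missing and refused by tree building. Neighbor joining is standard
Saitou–Nei with ties on Q resolved to the lowest index pair and negative
branch lengths clamped to zero — determinism is preferred over emulating
any particular legacy implementation. Fitch parsimony treats gaps and X
as wildcards; trees are unrooted, stored rooted at a trifurcating hub
(score is invariant under the choice, which the tests check by rerooting).
The parsimony search is NNI steepest-descent hill climbing from the
neighbor-joining tree, with a depth-2 escape: when the climb stalls, new
climbs are launched from each NNI neighbor of the optimum and the search
continues if any lands lower. This is the package's own search design (no
reference strategy exists to copy) and attains the exhaustive optimum on
all tested 5-taxon instances. Bootstrap resamples columns with
replacement, builds a tree per replicate (NJ or MP), and reports the 50%
majority-rule consensus with per-split support in percent; splits are
canonicalized as the side excluding the lexicographically smallest taxon.
Outgroup rooting is presentation-only. Newick IO preserves topology,
lengths to 6 decimals, and supports.

## Synthetic data: what it emulates, and what passing tests show

`simulate_mitogenome` builds a complete genome on the reference
annotation's template (same coordinates, strands, anticodon positions,
start/stop codon assignments), so the junction ledger of every synthetic
genome reproduces the reference gaps exactly. Composition targets are
planted as exact base multisets per region (rRNA 84.1% AT with slightly
positive skews, spacers 90% AT, control region 95.8% AT); PCG bodies are
sampled codon-wise from position-specific base frequencies matching the
reference regime (87.7/72.9/75.2% AT by codon position, AT skew −0.148,
GC skew +0.037), rejecting stops; tRNAs are built arm-by-arm with
configurable G·U (5%) and mismatch (3%) rates per stem pair, an all-A
left region for the DHU-less trnS1, and the anticodon written at its
template position. The control region receives, by default: the ATAGA +
19-T origin signature, a duplicated 17-bp repeat with one substitution, a
decuplicated 8-bp ATATTAAT segment with 12 substitutions ("highly
divergent"), an (AT)7 microsatellite, and an 8-bp-stem/6-nt-loop hairpin
flanked by TATA and GAAAAT. Planted repeat elements are delimited by
single G/C guard bases so the AT-rich background cannot silently extend
them, repeat units and substitutions stay within the A/T alphabet so the
region's G+C budget is deterministic, the hairpin's innermost pair is
fixed G·C so its all-A loop cannot merge with arm bases into a spurious
poly-A, and when no poly-A element is requested any chance A-run ≥ 9 in
the 30 nt upstream of trnM is broken by count-preserving background
swaps (the reference genome lacks that element; it is plantable by
option).

Overlapping genes (e.g. the 11-bp atp8/atp6 overlap, the 8-bp trnW/trnC
overlap carrying the planted AAGCCTTA) are handled by writing hard
constraints (start/stop codons, junction motifs) first and letting each
subsequently generated feature adapt: tRNAs complement their free stem arm
against fixed bases, and PCGs sample codons conditionally on fixed
positions. If an overlap forces an in-frame stop, the genome is redrawn
(bounded retries on one seeded random stream, so generation stays
deterministic). Each generated tRNA is verified to fold back to its
planted pair-class counts, with free bases redrawn otherwise; this
verification guarantees the plant is score-optimal but means the
plant-recovery test for tRNAs is a consistency check, not an independent
correctness proof — correctness of the folder rests on the exhaustive
placement oracle.

The ledger records ground truth from the realized sequence (base counts
per region, per-gene codon multisets, tRNA pair classes, plant
coordinates), so composition and codon tests can demand exact equality.
What passing these tests shows: the pipeline's bookkeeping — extraction,
orientation, frame handling, counting, detection — is exact under known
structure. What it does not show: robustness to the messiness of real
data (sequencing error, ambiguous annotation boundaries, indel-containing
repeats, non-i.i.d. background). In particular the generator performs no
indel evolution, matching the tandem detector's gapless alignment model;
both are deliberate simplifications of the same scope.

The alignment simulator evolves sites independently under the 20-state
equal-rate model: along a branch of length b the end state differs from
the start with probability (19/20)(1 − e^(−20b/19)), uniform over the
other 19 states. It makes no attempt at realistic amino-acid exchange
matrices or rate heterogeneity; it exists to give tree reconstruction a
known truth.

## Problem sizes and tolerances

Test and acceptance-script problem sizes are chosen to give the checks
real coverage while keeping a full run under a minute: detector–oracle
equivalence uses 100 random 200–300-nt regions (tandem and stem-loop) and
50 random tRNAs (cloverleaf); phylogenetics uses 20 random additive trees
of 4–12 taxa (NJ must recover all exactly), 10 random 5-taxon
20-column parsimony instances (the search must match exhaustive
enumeration over all 15 topologies), and one 8-taxon, 2000-column
simulated alignment with 200 bootstrap replicates (every true split must
reach ≥ 90% support). Exact-recovery checks (codon multisets, base
counts, plant coordinates) use equality, not tolerances. The planted
tandem repeats are asserted to be majority-covered (> 50%) by detections
at the planted period: a score-threshold detector legitimately trims the
divergent edges of the decuplicated segment, and in a 95.8%-AT background
quasi-periodicity at all even periods makes cross-period dedup relabel
spans, so full-span coverage would over-claim.

## Known limitations

* The tandem-repeat model is gapless; repeats whose copies differ by
  indels are found only if the substitution-level signal within some
  frame reaches the score threshold.
* The cloverleaf folder requires the annotated anticodon position; it
  validates and scores annotated tRNAs but does not scan genomes for new
  ones, and it does not model bulges or thermodynamics.
* rRNA secondary structure is out of scope entirely.
* The phylogeny stage consumes alignments; it never builds them.
* GenBank support is a minimal dialect, single-record, nucleotide-only.
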