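# Methods

`tirpoly` detects and classifies DNA-transposon (Class II, TIR order)
insertion and excision polymorphisms between two closely related genome
assemblies, and ships a calibrated simulator that provides ground truth
for every stage. This note describes the models, the tunable parameters,
the numerical choices, and what the synthetic data do and do not show.

## Biological model

TIR-order DNA transposons move by cut-and-paste. Insertion duplicates the
target site, leaving a superfamily-diagnostic target-site duplication
(TSD) on both sides of the element:

| superfamily | code | TSD motif | TSD length | 5' TIR consensus |
|---|---|---|---|---|
| Mariner   | DTT | TA        | 2 | CTCCCTC   |
| Harbinger | DTH | TAA / TTA | 3 | GG(G/C)CC |
| Mutator   | DTM | variable  | 9 | GAG       |
| CACTA     | DTC | variable  | 3 | CACT(A/G) |
| hAT       | DTA | variable  | 8 | CA        |

Excision leaves a double-strand break whose repair determines the
footprint: perfect excision (both TSD copies retained; NHEJ), flanking
deletion (SSA/MMEJ resection), filler DNA copied from elsewhere in the
genome (SDSA), or a combination. A *precise* excision removes the element
plus one TSD copy and restores the pre-insertion sequence; by comparative
analysis alone it is indistinguishable from an insertion in the other
species, and the classifier deliberately reports it as one.

In a two-species comparison the expected insertion:excision ratio is 2:1,
not 1:1: an element that excises during replication and reinserts ahead of
the fork yields one gamete with two copies and one with a single copy plus
the footprint, so the new insertion is transmitted twice as often as the
visible excision.

## Pipeline

1. **Anchoring** (`genome_alignment.fragment_and_anchor`). The query
   assembly is cut into 5-kb fragments. Each fragment's best target locus
   is found by 12-mer diagonal voting; anchors are kept only on the same
   chromosome, same orientation, with hit identity >= 96%, and on the
   longest strictly increasing collinear chain. Hit identity is computed
   over alignment columns excluding gap runs > 50 bp, so a fragment
   containing a large polymorphism still anchors on its matching portion
   (the behaviour of split HSPs in a BLAST-style search). A fragment must
   align at least min(1800, 35%) of its length.
2. **Window alignment** (`align_window`). For each anchor, 12 kb of query
   (the fragment plus 7 kb of adjacent 3' sequence, overlapping the next
   fragment) is aligned to the corresponding target window with
   affine-gap Smith-Waterman: match +5, mismatch -4, gap open 30, gap
   extension 0.1 (a gap of length L costs 30 + 0.1(L-1)). The small
   extension penalty concentrates indels into single long gaps. Ns score
   as mismatches against everything, including other Ns.
3. **Quality filter** (`quality_trim`/`passes_quality`). Every candidate
   indel (> 50 bp gap run; nearby runs within 150 columns merged into one
   region, because an excised element sits next to its filler) must be
   flanked on both sides by >= 200 aligned columns matching at > 90%.
   Aligned-column walks skip background-scale gaps (<= 10 columns) but a
   longer gap ends them. Regions that fail only because they sit at a
   window edge are trimmed off rather than failing the window — the 7-kb
   overlap guarantees the neighbouring window sees them mid-window.
   N-adjacent regions are exempt here; the dedicated N filter downstream
   discards those events.
4. **Assembly** (`assemble_chromosome`). Passing windows are merged into
   one global alignment per chromosome. Seams between overlapping windows
   are placed only inside runs of >= 20 consecutive matching columns, so
   no indel is ever split across a seam; windows whose target placement
   disagrees with the running alignment by > 10 kb at the seam are dropped
   and logged.
5. **Indel extraction** (`indel_detection`). Maximal gap runs **strictly
   longer than 50 bp** become presence/absence events attributed to the
   sequence-bearing species. Same-species events separated by **fewer than
   4 bp** are fused (spacer bases included). Events whose sequence or
   10-bp flanks touch an N run are discarded into a side channel (feeding
   the hidden-TE extrapolation), as are events with **more than 80%** Ns.
6. **Classification** (`footprint`). Events are annotated against the TE
   library (1.5 kb of context on each side, since a window misalignment
   can split an event mid-element). For the best annotation the TSD test
   shifts the element borders by up to ±3 bp to maximise TSD agreement
   (fixed motifs exact; variable motifs >= 8 bp tolerate one mismatch
   between copies). The element is then excised in silico and the
   remainder aligned to the empty site; junction gap runs give the counts:
   exactly one redundant TSD copy missing → insertion; nothing missing →
   perfect excision; more missing → flanking deletion; empty-site bases
   matching neither flank → filler. Event borders strictly inside an
   element that continues into both flanks mean an internal deletion —
   unless the empty site has lost the element's termini, which instead
   indicates an excision whose filler happens to be TE-derived (terminal
   retention is the discriminator; an internally deleted element keeps
   both TIR ends).

### Junction reconstruction details

The two flanks are first anchored independently in the empty-site context
with seed-guided banded alignments (700 bp windows, escalated to 3600 bp
when the junction-adjacent portion fails to anchor — the signature of a
multi-kb flanking deletion). Anchoring the flanks separately matters:
with a 0.1 gap-extension penalty, an unrestricted local alignment of
partly unrelated sequences profitably chains chance matches across cheap
gaps. A small exact full-DP alignment over the junction neighbourhood
then yields the footprint. Aligned islands of <= 25 columns sandwiched
between gap runs are counted on both sides of the footprint regardless of
their match fraction: the aligner bridges a small filler against deleted
flank whenever that saves a gap-open, and it cherry-picks the
best-matching offset, so such pairings carry no signal. Mismatch-heavy
edges of long aligned stretches next to gaps are stripped the same way
when measuring messy footprints; the crisp insertion/perfect signatures
are taken from the unstripped analysis so that junction-adjacent
substitutions cannot dissolve them.

Residual measurement error: when a filler of a few bp chance-matches the
deleted flank at the offset the aligner picked, a base or two can bleed
between the deleted and filler counts, and a filler whose every base
happens to match may disappear entirely (a `both` event then reads as
`deletion`). This is an identifiability limit of comparative analysis,
not an implementation artefact; on zero-noise constructions with
non-matching fillers the measurements are exact.

## Statistics

* **Ratio test**: exact binomial test of the insertion count against
  p0 = expected/(expected+1) over n = insertions + excisions trials
  (two-sided, minimum-likelihood definition). The published analysis
  quotes a Fisher's exact test against the 2:1 expectation without
  defining the contingency table; since that construction is not
  recoverable, the binomial is the primary test here and an exact 2x2
  variant (observed vs rounded expected counts) is co-reported. The
  ratios themselves reproduce exactly; the p-values are not claimed to.
* **Relative activity/abundance**: activity = moved copies (insertions
  plus excisions, both species) / family copy number; abundance = family
  copies / all DNA-transposon copies. Groups I/II/III split at the
  medians among active families (the published grouping is visual, so the
  boundaries are configurable).
* **Fixation rate**: events since divergence / generations since
  divergence; under neutrality this equals the per-individual
  transposition rate. The reciprocal ("1 in N individuals") is taken on
  the display-rounded rate (3 decimals), matching how such rates are
  quoted: 2300/600000 → 0.004 → 1 in 250.
* **Gap attribution**: for every N run > 50 in the gapped assembly, both
  500-bp flanks are mapped onto the other assembly (hits >= 400 bp at
  >= 95% identity, same orientation, within 10 kb); the intervening
  segment is screened for TE homology and the TE-positive fraction is
  extrapolated to all gaps and to N-rich polymorphisms.
* **Gene context**: each polymorphism is assigned exon / intron /
  upstream (1000 bp 5' of the CDS) / downstream (500 bp 3') / intergenic,
  strand-aware, nearest CDS winning and ties broken by gene id.

## Simulator

The simulator emulates two assemblies diverged on the order of 600 k
years. Defaults are the study conditions:

* ancestor: i.i.d., 2 Mb, GC 0.44 (rice-like);
* shared TE copies: 20 per family, two families per superfamily with
  proper TIR/TSD structure, placed on a jittered grid so features stay
  >= ~3.5 kb apart (real TEs cluster and nest; see limitations);
* divergence: substitutions at 0.0035/bp per lineage (~0.7% pairwise,
  chosen to make alignment non-trivial yet anchorable) applied to
  ancestral material only — recently transposed sequence is young and is
  left unmutated; background indels of 1-10 bp at 1e-4/bp, kept 150 bp
  clear of event footprints so truth labels stay unambiguous;
* events: 150 insertions, 50 excisions, 5 precise excisions, 10 internal
  deletions, split between species at random;
* excision footprints: perfect with probability 8/94; the remaining mass
  split 43:58:9 across deletion-only / filler-only / both (the published
  counts double-report the combined cases, and this renormalisation is
  the one under which the printed means reconcile: 926/51 ≈ 18 bp,
  880/67 ≈ 13 bp). Deletion lengths are geometric with mean 18 bp on one
  side (a config switch enables two-sided), with a 2% "extreme" component
  uniform on 1000-3000 bp reproducing the single multi-kb observation.
  Filler lengths are geometric with mean 13 truncated to [1, 123]
  (a uniform law on that range could not have mean 13); filler sequence
  is copied from a random locus of the same genome (SDSA semantics);
* assembly gaps: 20 N runs of 60-500 bp in species B, 25% centred on TE
  copies, kept 1 kb clear of polymorphic events.

Every mutation is logged with final coordinates in both genomes; length
bookkeeping is asserted exactly per seed, and a fixed seed gives
byte-identical fixtures. All randomness flows from one seeded generator.

**What passing tests do not show about real data**: the simulator plants
well-separated, non-nested, full-length elements with clean TSDs on a
near-uniform backdrop. Real genomes have nested and fragmented elements,
tandem repeats, segmental duplications and assembly errors, all of which
the published analysis handled by manual inspection. Recovery rates on
synthetic data are therefore an upper bound.

## Problem sizes and tolerances

Scores are float64 and compared at 1e-6 (the 0.1 gap extension is not
binary-exact). The exactness contract of the window aligner is verified
against a brute-force quadratic DP on 500 seeded pairs up to 100 bp; long
windows run a banded DP whose band comes from seed diagonals and is
widened until the optimal traceback clears it. End-to-end validation uses
a 2-Mb genome pair (about three minutes on one core) — genome-scale runs
against real assemblies work through the same CLI but are not part of the
test suite. The transmission-ratio check uses 200 events x 1000
replicates; footprint calibration uses 10^4 draws.

## Known limitations

* Excisions whose TSD was hit by a lineage substitution (fixed short
  motifs carry no mismatch slack) are reported `unclear`; at default
  divergence this affects a few percent of DTC/DTT events.
* A `both` footprint whose small filler fully chance-matches the deleted
  flank is reported as `deletion` (see junction details above).
* Internal deletions leaving less than ~50 bp of element, and excisions
  whose TE-derived filler exceeds 160 bp, sit in a genuinely ambiguous
  zone between `internal-deletion` and `excision-filler`; thresholds are
  documented in `classify_polymorphism`.
* Inversions and translocations are filtered out by design (orientation /
  collinearity rules), mirroring the scope of the comparative method.
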