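# Methods

## Coordinates and coverage

External coordinates are 1-based inclusive browser spans
(`chrN:start-end(strand)`); lengths are `end − start + 1`. This is the only
convention under which the packaged chr20 precursor (48664580–48664729) has
length 150 and its union coverage — 140 bp from the underlying MER53 plus a
disjoint 9 bp from the adjacent AluSx1 — rounds (half-up, two decimals) to
99.33%. Coverage is always computed over the union of repeat overlaps so
that abutting repeats are summed but never double-counted, and strand is
ignored in all overlap arithmetic: repeat annotations routinely lie on the
opposite strand of the miRNA they spawned. The repeat-derived call fires at
≥ 50% precursor coverage or exactly 100% mature coverage. Intersection with
segmental duplications requires full containment of the precursor in either
side of a pair (every positive case in the packaged tables is full
containment); a relaxed ≥ 1 bp mode is available. Conservation is the
arithmetic mean of a per-base score track in [0, 1]; computing the scores
themselves (a phylogenetic HMM over a multiple alignment) is out of scope.

## Hairpin folding and the precursor filter

Candidates are folded by Nussinov base-pair maximization over Watson–Crick
and (by default) G·U wobble pairs, minimum hairpin loop 3 nt, N never
paired. The traceback prefers pairing the outer bases over bifurcation and
takes the leftmost split on ties, so every sequence folds to one
deterministic dot-bracket string. Exact dynamic programming was chosen over
free-energy minimization because it is oracle-testable (the pair count is
verified against exhaustive enumeration for short sequences) and adequate
for the long near-perfect palindromes of MER53-like elements; an energy
backend could be substituted without touching the rule filter.

The filter replaces a trained random-forest precursor classifier with an
explicit, auditable rule set over the fold: exactly one hairpin loop and no
multiloops (the operative rejection mode for repeat arrays is
multi-branching), longest contiguous helix ≥ 18 bp, paired fraction ≥ 0.55,
terminal loop within [3, 20] nt, length within [70, 160] nt. All thresholds
live in `HairpinThresholds` and are exposed on the CLI. These defaults are
not claimed to reproduce any trained classifier decision-for-decision; they
encode the same qualitative geometry.

Two caveats worth knowing. First, reverse-complementing a sequence preserves
the maximum pair count only without wobble pairs (the reverse complement of
a G·U pair is the unpairable A·C); the invariance property is therefore
stated and tested for the Watson–Crick-only mode. Second, pure pair-count
maximization will happily add an isolated 2-bp helix wherever point
mutations create one, which can split an otherwise clean stem-loop into a
"two-hairpin" fold; energy models suppress such lonely helices. In practice
this makes the filter conservative on mutated copies — relevant when
interpreting scan sensitivity on diverged elements (see below).

## Paralog scanning

The scan is exact string search for the seed (mature positions 2–8,
U/T-insensitive) within annotated element instances, on both strands by
default (restrictable by flag). BLAST is unnecessary here because the
element instances are already delimited by the repeat annotation and the
operative filter is the exact seed match. Each hit yields two 110-nt
windows: the left-arm window places the 21-nt mature (seed at positions
2–8) starting 10 nt from the window's 5' end; the right-arm window mirrors
this at the 3' end. The 10-nt flank and 110-nt window are configuration
values; windows truncated by a contig end are dropped with a warning.
Transcription evidence is ≥ 1 bp overlap with any EST; exon exclusion is
≥ 1 bp overlap with any annotated exon. With no EST track, strict mode
(default) treats candidates as untranscribed; a permissive mode passes
them. The final call is hairpin ∧ transcribed ∧ ¬exonic, and the full
candidate list with per-rule failure reasons is retained as an audit trail.

## Distances, trees, gain/loss

p-distances use pairwise deletion (sites gapped or ambiguous in either
member of the pair are excluded; compared-site counts are reported) or
complete deletion. K2P is d = −½ ln((1−2P−Q)√(1−2Q)); a non-positive
logarithm argument is reported as NaN ("saturated") rather than an
exception. Neighbor joining is the standard Saitou–Nei agglomeration; ties
in the Q criterion are broken by the lexicographic order of each node's
sorted descendant-leaf labels, making the output invariant to input row
order; negative branch lengths are clamped to zero with the length
transferred to the sibling edge (the behavior of the common desktop
implementations). Bootstrap resamples alignment columns with replacement,
rebuilds the p-distance NJ tree per replicate, and reports per-internal-edge
bipartition frequencies; it is seeded and reproducible.

Gene gain/loss on the rooted species tree is reconstructed under Dollo
parsimony — the natural model for transposon insertions, which are
effectively single-origin characters: the gain sits on the branch above the
most recent common ancestor of the present species, and losses are the
minimal set of branches explaining the absent leaves below it; unknown
leaves never force events. A consequence of working from presence/absence
alone: when a single loss removes an entire child clade of the true gain
node, the reconstructed gain necessarily slides down to the surviving
child, so perfect gain-branch recovery is only achievable in low-loss
regimes. An "ortholog present but not validated as a miRNA" state is mapped
to absent by default for the miRNA-gene character (configurable to
present). Fitch unordered parsimony is provided both as an alternative
event count and as the birth-and-death diagnostic: on a tagged gene tree,
a type-label parsimony score strictly below the species-label score means
the family clusters by type — the birth-and-death signature — and the
reverse means concerted-evolution-like clustering; equality or a degenerate
tagging is "undetermined".

## Junction-Alu recombination test

Junction windows are the duplication terminus ± 5 bp (11 bp total,
truncated at position 1); an Alu is a junction Alu if it overlaps any such
window of its region by ≥ 1 bp, internal if fully inside and clear of every
window. Copies are matched across the two regions of a pair by family name
and rank order along the region (5'→3' on the region's strand; surplus
copies are dropped), aligned globally (match +1 / mismatch −1 / gap −2)
only when their lengths differ, and compared by K2P with pairwise gap
deletion. The Kruskal–Wallis H uses mid-ranks and the standard tie
correction, H := 0 when all values coincide, and an upper-tail chi-square
p-value with df = groups − 1; the implementation is cross-checked against
an independent statistics library to 1e-10 on random instances. The
internal-only test groups divergences by the five internal families
(df = 4); the combined test adds all junction divergences as one group
(df = 5). The genome-scale statistics printed for the human duplications
are functions of the reference sequence and are not recomputable at desk
scale; what is validated instead is the machinery: exact df structure, null
calibration, and power under a simulated junction effect.

## Synthetic data: what it emulates, and what it does not

**Genome simulator.** Background sequence is i.i.d. with GC 0.41
(human-like). The element consensus is TA + random arm + poly-A loop +
reverse-complemented arm + TA (default 193 bp, 9-nt loop), a caricature of
a terminal-inverted-repeat transposon that folds into one long hairpin; the
poly-A loop cannot self-pair even under wobble rules. Carriers embed the
mature 21-mer in the 5' arm (offset 49, which centers the left-arm excision
window on the hairpin); its reverse complement lands on the 3' arm
automatically, so both strands of a carrier yield seed hits — recovery is
therefore scored per implant, not per candidate. Implant copies mutate at a
per-base rate (default 0.02 per copy) under a K2P substitution scheme
(transition:transversion 2:1) with the mature protected, emulating
selection on the mature product. Decoys are Altschul–Erickson
doublet-preserving shuffles of the element: same mono- and dinucleotide
composition, no palindrome. ESTs cover a configurable fraction of carriers
(default all); exons none by default. The simulator does not model indels,
nested insertions, tandem arrays, or regional mutation-rate variation —
passing tests show the scan logic is correct under point substitution, not
that it would recover heavily diverged or rearranged elements.

**Duplication simulator.** Each pair's two copies are independent mutants
of a common ancestor region laid out as mosaic Alu | AluSp | miRNA element
| AluJo | AluYc | AluJr | AluSx | mosaic Alu, with one half-and-half mosaic
of two family consensus sequences at each boundary (the two recombination
junctions), positioned so the mosaics overlap the ± 5 bp terminus windows
and the internal array does not. The Alu "consensus" sequences are random
synthetic 300-mers (GC 0.55) regenerated per simulation, not real
subfamily consensus sequences. Internal copies mutate at 0.01 per copy;
junction copies at a configurable multiple (default 5), the simulated
recombination signature. With two junction observations per pair and six
pairs, the combined rank test carries 12 junction values against 5×6
internal values — enough rank mass for the chi-square test to be decisive
at α = 0.01; with a single junction value per pair the H statistic cannot
reliably clear the df = 5 critical value even under complete separation,
which is why two mosaics (one per boundary) is the default design.

**Family-history simulator.** On an 8-taxon primate-like rooted tree
(branch lengths in substitutions/site), each gene gains once — the first
branch in preorder to fire at gain_rate 0.15 — and is lost independently
at loss_rate 0.02 on each live branch below, a loss silencing its subtree.
Present leaves receive sequences mutated from a per-gene ancestor along the
path length. The default loss rate is deliberately in the regime where the
Dollo gain branch is identifiable (see the reconstruction caveat above);
raising it demonstrates, rather than contradicts, the identifiability
limit.

All three simulators are bit-reproducible from their seeds, and every
emitted annotation is checked against the emitted sequences at generation
time.

## Problem sizes used by the shipped checks

The packaged verification suite runs the coordinate-table reproduction
exactly as printed (11 loci, 10 duplication pairs); scan recovery on a 2-Mb
genome with 20 intact carriers and 30 decoys; Kruskal–Wallis null
calibration on 2,000 seeded simulations and power on 200; NJ exactness over
every unrooted 4- and 5-taxon topology; Dollo against exhaustive minima on
an 8-leaf tree; and gain-branch recovery on 200 simulated genes. These
sizes keep the whole suite in the low minutes while leaving every check at
full strength.
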