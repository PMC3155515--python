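# Methods

## Setting and scope

`isopipe` re-implements, as a library, the bespoke computational procedures
used to annotate a de-novo transcriptome of a species without a reference
genome: isotig (transcript-level consensus) sequences are annotated by
projection onto diverged reference species (pseudo-mouse/rat/human),
variants are called from the assembly's own read stacks, non-conserved
segments are screened against reference introns, and differential expression
is inferred from per-library read counts. Assembly itself, phylogenetics,
protein 3D modelling and wet-lab validation are out of scope; hit tables are
inputs (from an external aligner or from the synthetic generator).

All internal coordinates are 0-based half-open; conversion to the 1-based
inclusive conventions of BLAST tabular and GFF3 happens only at the file
boundary. Minus-strand hits are stored with ascending coordinates plus a
strand flag; chaining treats them as query-ascending/target-descending.

## Homology annotation

**Chaining.** For one query–target pair, the chained hit is the subset of
HSPs that is colinear (order-consistent in query and target) and pairwise
disjoint on both sequences, maximizing total query coverage. "Coverage" is
query bases covered, not alignment columns — annotation is query-centric.
The optimum is found by weighted DP over HSPs sorted by query start
(score tuple: coverage, then total bit score, then fewer members; adding a
fixed vector preserves lexicographic order, so prefix optimality holds).
Chained HSPs may not overlap at all; trimming overlaps is a non-goal.
A property test checks the DP against exhaustive subset search on random
instances of ≤ 12 HSPs.

**Unique rule.** Chains to the same gene are merged first (max coverage and
max bits per gene) — the same-locus exemption, implemented as same-`gene_id`
grouping since chains are gene-resolved before screening. The best gene is
*unique* iff its coverage **and** its summed bit score are each ≥ 2× the
runner-up's (the rule is conjunctive; summed rather than per-HSP bit scores
are compared). A lone gene is unique; no chains is a no-hit.

**Clusters and categories.** Unique isotigs are grouped per target gene;
the representative is the largest-coverage member; a non-overlapping subset
is built greedily by descending coverage on genomic footprints (target
intervals projected through the transcript's exon map), accepting an isotig
only if its footprint shares zero bases with all accepted ones. Greedy
selection is not guaranteed optimal in general; the regression fixture is
one where it is. Orthology categories: 3 — all three species' unique genes
share one ortholog group; 2 — exactly one pair shares; 1 — otherwise.
Species with no call or an ambiguous call count as non-matching. Coding
portion (coding bp over coding+UTR bp) and aligned totals are histogrammed
per category with size bins <400, 400–800, 800–1600, ≥1600 bp.

## ORF projection

The isotig is aligned to its best-mapped reference transcript with a
semi-global affine-gap alignment: match +2, mismatch −3, gap open 12, gap
extend 2 (a length-L gap costs 12 + 2(L−1)), free end gaps on the isotig
row so reference overhangs are unpenalized. These scores are configuration,
not truth claims. The alignment is computed by `Bio.Align.PairwiseAligner`;
the first-listed alignment is used, which fixes the traceback
deterministically. The aligner was checked against an exhaustive alignment
enumerator on tiny instances.

The reference CDS columns are mapped through the alignment;
`aligned_cds_fraction` counts CDS columns aligned to a base (not a gap) over
the CDS length, and `complete75` is strict (> 0.75). Translation starts at
the isotig base aligned to the first aligned CDS column, shifted back to the
reference codon boundary, and runs to the first stop or the end of the
isotig (predicted ORFs may exceed the alignment). A stop strictly before the
isotig position aligned to the reference stop codon is a PTC. Indels within
the CDS whose lengths are not multiples of three set a frameshift warning;
translation still proceeds in the projected frame, so downstream stops are
reported as PTCs with that warning. Multi-reference consensus alignment is
deliberately reduced to pairwise alignment against the single best-mapped
reference: the projection contract is unchanged and no external multiple
aligner is needed.

## SNP calling

Read stacks come from ACE files; minus-strand reads in the minimal dialect
are stored in read orientation and reverse-complemented into consensus
orientation when stacking (true-ACE reads are already complemented). The
pipeline order is fixed: candidates → flanking filter → per-gene dedupe.

- **Candidates**: column depth ≥ 6 (inclusive, at the column itself — the
  windowed-"region" reading is a non-goal) and minor allele ≥ 30% of non-N
  reads. N is absence of evidence, never an allele. A third allele reaching
  the threshold invalidates the column (not biallelic). Ties break
  alphabetically.
- **Flanking filter**: a candidate is removed when either immediate
  neighbour has ambiguous identity — consensus N, zero coverage, or > 20%
  of covering reads carrying N. The 20% operationalizes "ambiguous
  identity" (no numeric rule is given by the procedure this implements) and
  is configurable. Consensus ends are judged on the existing side only.
- **Dedupe**: per gene, only the isotig with the most surviving calls is
  kept (ties: larger chained coverage, then lexicographic id); unmapped
  isotigs are their own units.

Substitution classes: {A,G}/{C,T} → transition; {A,C}/{G,T}, {A,T}, {C,G} →
transversions. The summary reports per-class counts and the transition
percentage (rounded to integer, NA when empty) for the full set and the
depth ≥ 31 subset (inclusive).

## Novel-region detection

Candidates are query gaps between consecutive chained HSPs — conserved
flanks on both sides by construction; uncovered isotig termini are never
candidates. "More than 50 bp" is strict: a 50 bp gap is rejected-short.
Each candidate, with up to 50 bp of each flank (clipped to the flank HSP so
its genomic image lies inside the extracted span), is aligned to the
intervening genomic span of *every* reference species with the gap-open
penalty multiplied by 3 (higher penalties prevent fragmentation of the
anchor into many blocks). The flanks must anchor at ≥ 90% identity,
otherwise the candidate is left unresolved rather than called novel. The
candidate alone is then locally aligned to the intervening intron: identity
≥ 70% over ≥ 80% of its length in any species rejects it as intronic
(conservative multi-species rejection lowers false-positive novel calls).
The 70%/80%/10 bp/×3 thresholds are configurable defaults chosen here; the
procedure defines them only qualitatively. Surviving regions are
insertion-in-exon when the flanks are contiguous on the target genome
(gap ≤ 10 bp) and novel-exon when they map across an annotated intron.
ORF status: ORF iff the region lies inside the projected CDS, its length is
divisible by 3 and its translation in the projected frame has no stop;
PTC+ when a stop is introduced; untested without a projection.

## Differential expression

Counts n1..n4 per gene are compared with library totals N1..N4. The
pairwise test conditions on the pooled count: under the random-sampling
null, k1 | (k1+k2) ~ Binomial(k1+k2, N1/(N1+N2)); the p-value is the exact
two-sided binomial probability (sum of outcomes no more probable than the
observed one, via `scipy.stats.binomtest`). The exact conditional test is
used deliberately instead of a normal approximation on the MA plane: it
shares the same null and is more defensible at the count scales involved.
M = log₂k1 − log₂k2 and A = (log₂k1+log₂k2)/2 use a 0.5 pseudo-count for
zero counts (display only; the test uses raw counts). The four-library χ²
test uses expected_i = Σn·N_i/ΣN with 3 df; cells with expected < 1 set a
low-count warning. BH adjustment comes from statsmodels; Storey q-values
use a single fixed λ (default 0.5): π₀ = #{p>λ}/(m(1−λ)) clipped to (0,1],
q = π₀·BH — deterministic and desk-checkable, in place of spline smoothing.
Which adjustment a given downstream table should use is left to the caller;
both are emitted. Enrichment is hypergeometric upper-tail per term against
a caller-supplied background, BH across terms.

## Synthetic data: what it emulates and what it does not

The generator defines the study conditions for all tests. Each gene has one
transcript per species, diverged from a common ancestor at half the
configured divergence per branch (default 0.05 total, giving ~95% pairwise
identity); start/stop codons are kept intact and premature stops arising
from mutation are reverted, so every reference CDS translates cleanly.
Exon/intron coordinates are shared across species, which makes transcript
coordinates directly comparable — a simplification real orthologs do not
satisfy. Isotigs copy the first species' transcript (full or with an exon
skipped for splice variants); novel inserts are uniform-random sequence
(GC 50%), guaranteeing no homology to the references by construction;
intron-retention controls copy a slice of the real intervening intron.
Reads are error-free apart from planted alleles and optional injected Ns
(no quality scores, no homopolymer artefacts — sequencing-error modelling is
a non-goal, so passing tests demonstrate filter logic, not robustness to
base errors). At each planted site the alternative allele is written into
round(fraction × covering reads) reads, and the realized depth/fraction are
recorded back into the truth set. Decoy paralog hits take coverage
⌊r × true⌋ and bit score exactly r × true, so the 2× rule's decision at
r = 0.49/0.51 is exact for any fixture size. Counts are multinomial over
library weights with Poisson gene totals; planted DE genes multiply one
contrast library's weight by 2^lfc.

Defaults (free choices where the emulated study states none): exons
120–400 bp, 2–6 exons, introns 100–400 bp, UTRs 60/120 bp, reads 100 bp,
depth 6–40 (straddling the 6 and 31 thresholds), 2 planted SNPs/kb at minor
fractions 0.30–0.50, inserts 60–300 bp, equal library weights, mean gene
total 50 reads. Per-library depth distributions are free parameters, not
calibrated to any dataset.

## Problem sizes and numerical choices

The acceptance script and test suite run at desk scale by design: panels of
3–40 genes for recovery suites, 200 random chaining instances (≤ 12 HSPs,
matched against exhaustive search), 100 seeded unique-rule fixtures per
decoy ratio, 1000 null genes for type-I calibration, and 50 replicates with
2 planted 4-fold genes each (≈ 50 reads per library under the null, so the
planted genes do not distort the totals they are tested against) for power.
A single master seed derives every stage's generator stream, and `run_all`
output is byte-identical across runs with the same seed. Headline tallies
of genome-scale studies (tens of thousands of isotigs) are not reproducible
at this scale and are not targets; the suites verify the decision rules and
their boundaries instead.

Known limitations: novel-region filtering assumes comparable transcript
coordinates across the supplied species models (true for the generator;
approximate for real orthologs — supply per-species flank coordinates from
per-species chains to lift it); genomic footprints assume plus-strand gene
models; the greedy non-overlapping selection is not globally optimal; the
exact binomial DE test is conservative at very low counts.
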