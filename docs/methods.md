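# Methods

This note records the models, rules and numerical choices behind each
stage, the design decisions that were genuinely open, and what the
simulator does and does not capture.

## Coordinates, alphabets, missing data

All user-facing coordinates are 1-based inclusive (the convention of
alignment editors and published region tables); internal storage is
0-based. The sequence alphabet is `{A,C,G,T,N,-,?}`, case-insensitive on
input. For site classification and distances, `-`, `N` and `?` are
treated as missing data by default, matching the convention of the
classic phylogenetics packages this workflow interoperates with; a
`fifth-state` mode that counts `-` as an ordinary state is provided for
sensitivity analysis only.

Region maps declare exon/intron/excluded intervals plus a `frame_offset`
(number of exon columns preceding the first complete codon). Validation
enforces non-overlapping exons and a coding length divisible by 3 after
the offset.

## Site classification

Per column, over non-missing cells: *invariant* (≤1 distinct base),
*parsimony-informative* (≥2 bases each in ≥2 sequences), *singleton*
(exactly one sequence deviates from an otherwise represented majority),
*other-variable* (e.g. two distinct rare bases in single sequences). A
column that is entirely missing counts as invariant — it carries no
signal and must never raise. Classification is invariant under row
permutation (property-tested) and the four counts always sum to the
alignment length.

## Clone sorting

**Singleton masking.** A cell is masked when its base occurs in exactly
one clone at a column where some other base is carried by ≥2 clones. The
replacement is `?`, not the column majority: at a column that is
polymorphic *between* homoeolog groups, substituting the global majority
would imprint another group's base onto the clone and split or merge
groups spuriously. Private gaps are never masked — the polymerase error
process being modelled is substitutional, and a private deletion is
legitimate variant signal. With <3 clones the notion is undefined
(warning, no-op).

**Grouping.** Clones identical after masking form groups; rows containing
`?` join the largest group whose consensus matches all their unmasked
positions, and cluster among themselves by wildcard identity otherwise
(unknown cells filled in from cluster mates). A one-clone group whose
consensus is a single step from exactly one larger group is absorbed into
it: after masking, the only way a pure clone remains solitary is a
polymerase error that collided with a group-diagnostic site, which leaves
it exactly one step away. The absorption is skipped when masking found no
singletons anywhere — in that case there is no evidence of an error
process, and a one-step neighbour is better read as a real variant.

**Recombinant screening.** For every pair of donor groups (≥2 members
each), the columns where the two donor consensi differ are diagnostic;
adjacent diagnostic columns inside a gap run collapse into one *unit*,
because an indel is one mutational event, not one per column. A clone is
flagged for a pair when a single changepoint splits the units into a
prefix matching donor A (≥ `min_run` units, default 3) and a suffix
matching donor B (≥ `min_run`), **and** the stitched two-donor model
reproduces the clone's entire sequence up to `max_mismatch` columns
(default 3). The whole-sequence fit is the discriminating condition: a
true template switch matches its donors almost everywhere, while a clone
from a third, phylogenetically intermediate lineage matches the donor
pair only in an interleaved pattern at their mutual differences and
deviates at its own derived sites. Clones in groups of ≥3 identical
members are exempt — independent PCR events essentially never produce
three identical chimeric molecules, whereas three identical clones of a
real variant are routine.

`min_run = 3` tolerates isolated homoplasies that a single diagnostic
site would misread as recombination; a chimera with fewer than `min_run`
diagnostic units on one side of its breakpoint is a *documented false
negative* (with uniform breakpoints this is the dominant miss mode).
Breakpoints are placed midway between the flanking diagnostic units.

**Representatives.** Per group, the clone minimising
(singleton count + residual distance to the group consensus), ties broken
by lexicographically smallest id — deterministic, and an error-free clone
wins whenever one exists.

## Indel coding (MCIC)

Internal gap extents (identical start/end) are events; terminal gap runs
are incomplete sequence and coded as missing. Non-overlapping extents
become binary presence/absence characters. Mutually overlapping extents —
chained transitively into connected components, since positional homology
cannot be split — become one multistate character whose states are the
distinct extents plus "no gap". Step costs: `unit` (all 1) or `mcic`
(default: gap↔no-gap 1, nested extents 1, straddling extents 2,
reflecting the minimum number of indel events separating the states).
Both dialects are retained because legacy programs' character totals depend on
the coding program's dialect and downstream tree lengths depend on the
cost table. Combined matrices are written as a MrBayes-style
`DATATYPE=MIXED(DNA,STANDARD)` NEXUS block with `ASSUMPTIONS` step
matrices; the bundled reader round-trips this dialect exactly (neither
dendropy nor Biopython parses mixed blocks with user step matrices).

## Distances

K2P with pairwise deletion: sites with a gap/`N`/`?` in either sequence
of a pair are dropped for that pair only; `d = −½·ln((1−2P−Q)·√(1−2Q))`
with P, Q the transition and transversion proportions. A non-positive
log argument marks the pair saturated/undefined rather than raising or
returning a number. Full precision is kept internally; 3-decimal rounding
is display-only. Difference accounting counts substitutions where both
sequences have bases, and indel events as maximal runs gapped in exactly
one of the two (a shared gap is not a difference).

## Coding analyses

**Pseudogene screen.** The exon concatenation of a sequence is translated
with the standard genetic code (plant nuclear locus; no alternative
codes). Codons containing gaps or ambiguity are skipped. A sequence is a
*putative pseudogene* iff it carries an internal stop or an exonic gap
run with length ≢ 0 (mod 3). A coding length not divisible by 3 is
reported as a frame anomaly, never an exception.

**Ka/Ks** is pairwise Nei–Gojobori (1986): per-codon synonymous site
fractions averaged over the two sequences; differences averaged over all
minimal mutational pathways, excluding pathways through stop codons
unless all are blocked; mutations *to* stops counted non-synonymous;
Jukes–Cantor correction of pS and pN. The ratio is undefined when
Ks = 0. Pairwise NG86 was chosen over branch-based server methods because
it is fully specified, deterministic and oracle-testable; a branch-wise
extension is future work.

**Tajima's relative rate test** uses complete deletion over the triple
(a, b, outgroup): m₁ = sites where only a deviates, m₂ = sites where only
b deviates (sites where all three differ count for neither);
χ² = (m₁−m₂)²/(m₁+m₂) with 1 df, significance fixed at α = 0.05
(critical value 3.841). m₁+m₂ = 0 yields `computable = False` — the
expected outcome for identical ingroup sequences. Under clock-like
simulation the rejection rate is ≈5% (calibration-tested at 1000
replicates).

## Trees

Unrooted binary trees over labelled leaves; every tie-break (NJ pair
choice, canonical newick ordering) is lexicographic by taxon label, so
all routines are deterministic given their seed.

* **NJ**: classical agglomeration with exact branch lengths; recovers any
  additive metric (property-tested; cross-checked against an independent
  implementation).
* **Parsimony length**: vectorised Fitch for nucleotide and unordered
  coded characters (bitmask folding), Sankoff DP for step-matrix
  characters; `?` never adds steps. Scores are rooting-invariant
  (property-tested) and equal brute-force minima on ≤6-taxon matrices
  (200 random cases).
* **MP search**: random-addition starting trees (seeded) + NNI/SPR/TBR
  swapping to a local optimum; equally-best trees deduplicated by
  canonical newick into a buffer capped at `keep`. TBR additionally
  reroots the pruned subtree at each of its internal edges.
* **CI/RI**: ensemble sums, with `m` = minimum conceivable steps
  (observed states − 1 for unordered; minimum-spanning-tree cost over the
  shortest-path closure of the step matrix for Sankoff characters),
  `g` = star-tree maximum. RI undefined (NaN) when Σg = Σm.
* **Bootstrap**: multinomial character resampling expressed as integer
  column weights, reduced per-replicate search (default 1 addition, NNI),
  bipartition counting, majority-rule consensus at a threshold (default
  85%).

Bayesian inference is deliberately out of scope; the NEXUS export is the
hand-off point to external samplers.

## Simulator

Progenitor haplotypes evolve along a tree (given newick, or random with
every root-to-tip path equal to `depth`) under a K2P process with
transition/transversion rate ratio `kappa` (default 2), using the exact
closed-form transition probabilities — so simulated data match the K2P
estimator's assumptions and bias checks are clean. Random trees cap
internal-edge fractions so terminal branches keep within-library variants
≥ ~0.5·depth apart, matching the divergences observed between homoeolog
variants of a single accession (~0.01–0.05). Exon codons that mutate into
internal stops are reverted to the parental codon (selection against
nonsense changes); deletions are intron-only (lengths default 2–10 bp),
so the injected pseudogene — premature stop plus a 10 bp frame-breaking
deletion in the last exon — is the only source of frame disruption.
Clone libraries copy one haplotype per clone (multinomial, or exact
per-lineage counts when a composition table is the input), convert a
configured fraction into two-donor chimeras with a uniform breakpoint
(single-switch template model; multi-switch chimeras are not modelled),
and then apply per-site errors at base positions. Defaults: 4 lineages,
depth 0.02, 30 clones, error 10⁻³/site, 15% chimeras; the
reference-study emulation fixes a 12-haplotype tree (two haplotypes
shared between accessions, one rate-accelerated lineage, K2P span
~0.003–0.06) and ~19% chimeras over four accessions of 40/26/34/32
clones.

**What the simulator does not capture**: primer bias and length-dependent
amplification, multi-switch chimeras, heterozygosity/allelic variation,
alignment error (clones are born aligned), insertion events (deletions
only), and rate variation across sites. Passing recovery tests therefore
demonstrate correctness of the sorting logic under the stated error
model, not robustness to misalignment or primer artefacts.

**Recovery scoring** compares the pipeline output to ground truth:
adjusted Rand index over truly-pure, unflagged clones; chimera
sensitivity overall and restricted to *detectable* chimeras (≥ `min_run`
diagnostic units on both sides of the breakpoint and both donors
represented by ≥2 pure clones — the precondition of the detection rule);
precision; representative error-freeness; and Robinson–Foulds distance of
the NJ tree of representatives to the generating tree. At default
settings over 200 replicates: mean ARI ≈ 0.999 (median 1.0), detectable
sensitivity ≈ 0.99, precision ≈ 1.0. Extra groups relative to the lineage
count are almost always undetectable chimeras and are scored through
sensitivity, not clustering accuracy.

## Problem sizes

The bundled checks run at the study's own dimensions: a 718-column,
5-region nuclear locus with 14 representatives (+outgroup), accessions of
26–40 clones, and a 1179-column, 50-sequence chloroplast-scale panel.
Calibration experiments use 200 recovery replicates and 1000
relative-rate replicates at 400 coding sites — sizes chosen to make
binomial error bars small relative to the thresholds being checked.

## Known limitations

* Identity-based grouping resolves variants down to one diagnostic
  difference, but two *chimeric* molecules with the same donors and
  breakpoints falling in the same inter-diagnostic interval are
  genuinely identical and, at three or more copies, indistinguishable
  from a real variant by the replication rule.
* The recombinant screen models single switches only; a double-switch
  chimera fitting neither donor pair within `max_mismatch` escapes.
* The relative rate test loses power at small divergences; at the
  emulated accelerated-lineage contrast (~0.016 excess substitutions per
  site over ~400 coding sites) significance at the 5% level is expected
  but not guaranteed in every realisation.
* MCIC character counts depend on the coding dialect; both provided cost
  modes are internally consistent but neither is claimed to reproduce a
  particular legacy program's totals.
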