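# Methods

## Locus model

The locus is modelled as alternating conserved segments (identical in both
parents) and diagnostic elements (markers or repeat motifs) in 5′→3′
order. Every element is addressed by its two *anchors* — the k-mers of
conserved sequence immediately flanking it (default k = 20 nt, long enough
to be unique in a ~2.6 kb locus with high probability and to survive one
sequencing error under fuzzy matching). Validation checks that each anchor
occurs exactly once in each parental sequence, that element intervals are
strictly increasing, and that every segment needed for crossover typing
(upstream of motif 1, motif 1–motif 2, motif 2–motif 3, downstream of
motif 3) carries at least one marker.

Coordinates are 0-based half-open. Breakpoints are reported in the
*element frame* (element *i* at integer position *i*, the conserved gap
before it as gap *i*), so parent-specific indel length differences do not
shift interval semantics.

The default locus emulates a goldfish *ntl*-promoter-like structure:

| element | default | notes |
|---|---|---|
| 39-bp indel | insertion on the paternal haplotype | polarity not knowable from the published description; configurable |
| motif 1 | GT × 84 paternal / 36 maternal (168 / 72 nt), one interruption per parent | the long, HR-active imperfect tract |
| 2 SNPs + 3-bp indel | between motifs 1 and 2 | downstream flank of motif 1 |
| motif 2 | GT × 12, reverse-oriented, both parents | measured on its own strand |
| 3 SNPs | between motifs 2 and 3 | give crossover II multiple resolvable sites |
| motif 3 | GT × 10, both parents | short downstream tract |
| 1 SNP + 8-bp indel | downstream of motif 3 | close the last segment |

Motif 2/3 unit counts are not published ("two downstream short motifs");
12 and 10 units are package defaults and configurable. Conserved segments
are fixed pseudo-random sequence generated from a constant seed (GT/AC
runs ≥ 3 units rejected so conserved sequence cannot extend a tract), so
the default locus is deterministic: paternal 2630 nt, maternal 2500 nt.

## Marker calling

Anchor location tries, in order: exact `str.find`; fuzzy infix alignment of
the anchor against the clone (edlib, ≤ 2 edits, refused when multiple best
placements exist); and, as a last resort, mapping the anchor's parent
coordinates through a global affine-gap clone-vs-parent alignment
(Biopython `PairwiseAligner`; match +1, mismatch −2, gap open −6, extend
−0.2; the first co-optimal alignment is taken, which places gaps leftmost
and makes output deterministic). Clones sequenced in reverse orientation
are detected by counting exact anchor hits on both strands.

The substring between anchors is compared to the two parental alleles:
SNPs must match exactly; indel alleles match at equal length with ≤ 1
substitution, so a sequencing error cannot flip an indel call. Repeat
counts are maximal whole units of the enclosed tract (trailing odd base
ignored; reverse-oriented motifs counted on the reverse complement);
length-preserving interruptions do not change the count. Failures surface
as `missing`/`ambiguous` calls, never exceptions.

## Classification

Minimal-switch parsimony over the informative (P/M) calls in locus order:
the observed number of parental switches is provably the minimum over all
mosaics consistent with the calls, so the class follows directly:

* 0 switches → PD or MD, unless the motif-1 unit count contradicts that
  haplotype, in which case the clone is an intra-allelic PCR artifact
  (uniparental markers + off-size tract: the signature of within-tract
  template switching) — retained in outputs, excluded from HR statistics;
* 1 switch → crossover I when the breakpoint interval contains motif 1
  and no other motif; crossover II when it lies between motifs 2 and 3
  (it may cover motif 2, whose tracts are identical in both parents, but
  not motif 1 or 3); anything else — e.g. a switch in the motif-free
  region or across motif 3 — is AMBIGUOUS, never guessed;
* 2 switches → crossover I+II when the first interval is a crossover-I
  site and the second a crossover-II site (a short exchanged segment);
* more than 2 switches, or more than ⌈n/3⌉ unusable markers, → AMBIGUOUS.

The breakpoint interval is the half-open element-frame span between the
last marker before and the first marker after the switch. For crossover-I
clones the DSB-bearing homolog is inferred from the repeat length: the
maternal unit count implies a paternal break repaired off the maternal
template and vice versa; counts matching neither parent are indeterminate
(contracted below both counts, expanded otherwise).

## Statistics

Per-sample class counts; HR fraction = (CO I + CO II + CO I+II) / retained,
where retained excludes intra-allelic and ambiguous clones from numerator
and denominator (both reported). Wilson score 95% intervals are used for
all proportions — the experiments report no uncertainty, and Wilson
behaves well at the 20–150-clone sample sizes involved; no hypothesis
tests are added. Percentages are rounded to two decimals.

Half-tetrad genotyping: a gynogenetic diploid's clones are reduced to
haplotype patterns (grandfather / grandmother / crossover); one pattern →
homozygous for that grandparental haplotype, two or more → heterozygous,
which directly evidences a meiotic crossover in the mother. Individuals
with fewer than 2 usable clones are withheld, as is the real-data corner
case of a single all-crossover pattern, which the three-way genotype
cannot express. The meiotic HR frequency is the heterozygote proportion
among genotyped individuals.

Instability flags: motif-1 unit counts absent from both parental tracts
are "novel"; contrasting a test sample against a control spectrum reports
the lengths unique to the test sample (the heterozygote-only bands of a
mixed-parent control design).

## Synthetic-data generator

The generator inverts the classifier's class definitions and adds the
artifact processes cloned PCR products actually carry:

* **Breakpoints** are placed uniformly over candidate gaps: the two gaps
  flanking motif 1 for crossover I (the published data localize crossover
  I only to the motif-1 region), and the gaps from motif 2 to the last
  inter-motif marker for crossover II (the gap adjacent to motif 3 is
  excluded because markers cannot separate it from the far side of the
  motif). For crossover-I clones the tract copies the repair template's
  unit count, which fixes the breakpoint side relative to motif 1.
* **Slippage** (default probability 0.15/clone): the tract gains or loses
  a signed-geometric number of whole units (never below 1 unit).
* **Template-switch chimeras** (default 0.1/clone): re-annealing at a
  random register of a same-allele template molecule — uniparental
  markers with an off-register repeat length, the mechanism treated as
  the source of intra-allelic artifact clones.
* **Sequencing errors** (default 0.001/base substitutions), applied last.

Artifact magnitudes are not published; the defaults are plausible for
cloned Ex-Taq products and fully configurable. Simulated crossover-I DSBs
sit on the long paternal tract with default probability 0.8, reflecting
the strong observed asymmetry without being a published parameter. The
embryo series draws each clone recombinant with probability
1 − (1 − p)^d after d divisions (accumulation with cell divisions); the
gynogenote simulator draws clones evenly from an individual's two template
chromosomes, so a heterozygote always exposes both haplotypes given ≥ 2
clones. What the generator does **not** emulate: chromatogram noise,
read-level error models, PCR cycle chemistry, recombination outside the
candidate regions, gene-conversion tract lengths. Tests passing on this
generator therefore demonstrate the pipeline's correctness given the
marker/linkage abstraction, not robustness to every failure mode of real
Sanger data.

## Problem sizes and numerical choices

Count fixtures (146-, 93-, 138-, 63-, 24-clone sets and the 9-individual
cohort) are exact reconstructions of published per-class counts and run
artifact-free; robustness and coverage properties use 500–1000 simulated
clones and 200 replicate estimates, sizes at which binomial standard
errors make the assertions sharp while the whole suite stays fast.
Percentage comparisons in tests use ±0.02 percentage points to absorb
printed rounding. The CI-coverage property is evaluated at the
classification level after a separate end-to-end test establishes that
sequence-level simulation is class-preserving at zero error, so the
sequence path is exercised once and the coverage statistics 200 times.

## Known limitations

* Marker calls are independent per element; a structural rearrangement
  that duplicates an anchor is refused (missing call) rather than
  resolved.
* The classifier caps explanation at two switches; triple crossovers in
  one amplicon — never observed in the source data — are AMBIGUOUS.
* DSB-origin inference assumes repair copies the template tract exactly;
  repair accompanied by slippage is deliberately left indeterminate.
* The intra-allelic exclusion rule removes real HR clones only if an HR
  product also slipped to a uniparental-looking pattern, which the
  two-sided marker layout makes unlikely but not impossible.
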