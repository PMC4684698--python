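# Methods

This note documents the models, estimators, numerical choices and known
limitations of `mdsweave`, in the spirit of a statistical methods appendix.

## 1. Rearrangement model

Coordinates are 0-based half-open everywhere in memory; GFF3 I/O converts to
1-based inclusive at the boundary. A germline MDS stores one MIC interval,
one orientation, and one somatic target per MAC chromosome it contributes to;
a *shared* (constitutive) MDS has ≥ 2 targets and must be single-copy in the
germline. Pointer repeats are represented implicitly: the MIC interval of an
MDS includes the pointer at both flanks, so consecutive targets of a
chromosome overlap by the pointer length in MAC coordinates and assembly
counts each pointer once. Inversion is applied at assembly time (the reverse
complement is never stored twice). Telomeres are boolean flags, excluded from
all coordinate arithmetic. Zero-length pointers are permitted (the field has
no evidence they cannot occur).

Assembly is deterministic and order-invariant (targets are sorted by their
1..k somatic order positions); a disagreement between the two annotated
copies of a pointer is a hard error naming the junction. `validate_map`
checks, for a whole dataset, byte-exact reassembly of every chromosome,
single-copy status of shared MDSs, target-length consistency, and IES
placement strictly between flanking MDSs.

Junction-offset comparison between paralogs matches MDS boundaries greedily
by nearest alignment column (ties toward 5′ — the literature states no
matching rule) and reports offsets in nucleotides of the ungapped consensus;
an offset interval crossing gap columns is flagged rather than silently
trusted.

## 2. Codon evolution simulator

The generator's substitution model is deliberately minimal: equal codon
frequencies, an HKY-style transition/transversion multiplier κ at the
nucleotide level, a per-codon ω multiplier on nonsynonymous changes, zero
rate into stop codons. Each codon evolves as an independent continuous-time
Markov chain, simulated exactly by repeated exponential waiting times and
vectorized over whole sequence batches.

**Time units.** Branch lengths are expressed in expected synonymous
substitutions per synonymous site: the rate matrix is rescaled per
(code, κ) so that at a uniform sense-codon composition the expected dS per
unit time is 1. A strain pair separated by total path length 0.15 therefore
has planted dS ≈ 0.15 by construction, and dS is directly comparable across
ω values.

**Default κ = 1.** The source data provide no transition-bias estimate, and
the downstream counting estimator (NG86) assumes none; the matched choice
keeps parameter-recovery checks about ω rather than about κ-misspecification
bias. κ is exposed in `SimulationConfig` for sensitivity analyses.

## 3. Synthetic world

Defaults are the study system's published structure, fixed once and not
revisited: 69 sharing cases with topology weights 32/31/6 (5′/3′/both), gene
counts per locus 2..5 weighted 59/6/3/1, scrambled fraction 38/69, mechanism
weights 54/69 duplication vs 15/69 noncoding capture, ~11/69 duplication
cases with a planted ancestral-copy loss, 36 decoy loci (12 per filter rule,
105 loci total before filtering), strain divergence dS 0.15, alternative /
constitutive ω = 0.4 / 0.05, genic GC ≈ 0.33 ± 0.03 vs noncoding GC 0.28,
pointers 2–20 nt, IESs 20–100 nt, six expression time points. The species
panel is the fixed nine-genome ladder (seven stichotrichs incl. two focal
strains, plus the *Euplotes* outgroup); a custom newick can be supplied but
there is no separate "number of species" knob.

Construction guarantees worth knowing:

- Region lengths are multiples of 3 and region boundaries codon-aligned, so
  shared blocks are translated in the same frame in every member gene.
  Mid-codon region boundaries therefore never occur in generator output; the
  majority-base rule for them is exercised by unit tests directly.
- At shared↔unique junctions the pointer always penetrates the *shared*
  block from the unique side, because a shared MDS's targets must all have
  equal length while per-gene pointers may differ.
- Duplications are planted at the **midpoint of the stem branch** above the
  origin node. A duplication exactly at a speciation node would create a
  zero-length internal branch in the gene tree that no reconstruction method
  can resolve; mid-stem placement makes the planted history identifiable
  while still mapping to the intended origin node.
- Losses (the gene-tree-correction scenario) are planted only in 2-gene
  cases, as the lineage that loses the ancestral copy keeps exactly one gene
  — which the observable ortholog table then labels as "A's ortholog", the
  ambiguity the correction is designed to resolve.
- UTRs do not evolve across species (only CDSs go through the codon model);
  cross-species operations only use coding and alternative-region sequence.
- Background genes (the stand-in for the genome-wide gene set) have *flat*
  expression profiles with mild lognormal variation; only sharing-case genes
  get developmental peaks. Median-of-ratios normalization assumes most genes
  are not differentially expressed — a reference set consisting entirely of
  strongly peaked genes would make size factors unidentifiable, which is a
  property of the estimator, not of the implementation.
- The ancestral gene A is present in every species (including the outgroup),
  so the "neither ortholog present" phyletic state does not arise in
  generator output; it is exercised by constructed inputs in tests.
- NB dispersion 0 is the deterministic limit: counts are rounded means.

What a green test on this world does **not** establish: robustness to
annotation error, assembly gaps, indels (the codon model has none — codon
alignments of generator output are trivially ungapped), rate variation
among sites or lineages, ortholog-assignment noise, or 3′-biased read
coverage. These are real-data phenomena outside the generator's scope.

## 4. Detection and filters

A case is keyed by MIC locus; chromosomes are grouped by connected sharing.
The three removal rules run in fixed order (1 noncoding chromosome, 2
multigene chromosomes sharing exactly one complete 100%-identical gene, 3
shared region reaching < 20 nt into every CDS), and a case removable by
several rules is logged under the first — the source describes the rules but
not an order, so a fixed order was chosen for reproducible logs. Rule 2's
"100% overlap and sequence similarity" is implemented as exact string
equality of the spliced CDS. Rule 3's threshold is applied per case (any
gene reached ≥ 20 nt keeps the case). Topology classification uses
coding-strand orientation per gene; a shared region touching neither
terminus of some gene yields a majority call flagged ambiguous (impossible
on clean data). Shared-coding fractions use the *shortest* shared portion
across genes as the numerator for every member.

The summary table counts loci, chromosomes and MDSs split by topology and by
scrambled status. "Scrambled" is a per-chromosome property (its MDSs
permuted or inverted); a locus is scrambled when any of its chromosomes is.
The topology columns of the MDS row count shared MDSs only, while the MDS
total and its scrambled split count all MDSs of the case loci — the only
reading under which the published table's margins are arithmetically
consistent.

## 5. Origin inference

Presence-based dating is pure parsimony: no losses assumed, origin at the
stem of the MRCA of novel-gene-bearing species (verified against exhaustive
smallest-superset-clade search in tests). Gene trees are neighbor-joining on
Poisson-corrected protein p-distances of the alternative regions, after
dropping columns with > 50% gaps (a deliberate, desk-scale replacement for
ML/Bayesian trees with automated trimming; the substitution is recorded, and
an external tree can be substituted at the API boundary). p ≥ 1 − 1/20 is
capped and flagged saturated. Rooting is on the outgroup's pendant edge.

The correction rule: the B clade is the largest gene-tree clade containing
the focal novel-gene leaf but not the focal ancestral-gene leaf; its species
set, mapped to the species tree, gives the implied duplication node. If that
node is a proper ancestor of the presence-based origin, the origin moves
there and each clade species without an observed novel gene is recorded as a
loss. No bootstrap support is required (none is computed) — on finite
sequences of 60–180 codons, NJ misplaces single branches in a minority of
cases, so sequence-level correction recovers the exact planted node in
roughly two-thirds of planted-loss cases with errors one node off; on
truth-topology gene trees (the zero-noise limit) recovery is exact, which is
what the acceptance property asserts.

Mechanism classification mirrors a BLASTP screen at desk scale: local
alignment (BLOSUM62, gap open −11 / extend −1), identity > 40% over > 80% of
the shorter unique region, and — replacing the e-value — an empirical floor:
the observed score must exceed all of 200 shuffles of one sequence
(p < 1/201). "40% similar" is read as identity; a switch to matrix-positive
fraction exists. Old duplications genuinely fall below the identity
threshold (a pair diverged > 1 dS at ω 0.4 carries ≳ 1.2 nonsynonymous
substitutions per codon, ≈ 25–35% identity) and are classified
no-similarity — the same depth limitation the original analysis reports for
its no-similarity class. Unassigned-by-similarity segments are flagged as
candidate noncoding captures when their GC falls strictly below the lower
quartile (linear-interpolation quantile) of the somatic gene set.

## 6. Rate analysis

CDSs are handled without the terminal stop codon throughout. Region
partition assigns each codon by the majority of its three bases (≥ 2 shared
bases ⇒ constitutive). Protein pairs are aligned globally (BLOSUM62,
−11/−1), back-translated to codon alignments, and split by the focal gene's
codon classes; gapped columns are dropped.

dN/dS uses the Nei–Gojobori (1986) counting method — the one intentional
methodological substitution for ML codon models, adequate at strain-scale
divergence (dS ≈ 0.15) and exactly reproducible: per-position synonymous
site fractions exclude stop-producing changes from the denominator (each
position contributes one site, so S + N = 3 per codon); multi-difference
codons average differences over all shortest pathways that avoid stops
(falling back to all pathways in the rare fully-blocked case); both
proportions get the Jukes–Cantor correction d = −(3/4)ln(1 − 4p/3), with
4p/3 ≥ 1 a saturation error. Genetic codes 1, 6 (ciliate: TAA/TAG = Gln;
the default) and 10 (Euplotes: TGA = Cys) are supported; an ML estimator can
be swapped in behind `ng86_dnds`.

Amino-acid divergence is reported primarily as p-distance (the bounded
quantity), with the Poisson correction −ln(1 − p) as a companion column —
the source leaves the choice ambiguous, so both are emitted. Gene-level
filters: both regions longer than 150 nt (strict) and dS within [0.01, 5];
dS = 0 leaves ω undefined and fails the lower bound automatically. The
paired Wilcoxon signed-rank test drops zero differences, uses the exact
distribution for n ≤ 25 without ties and the normal approximation with
continuity correction otherwise.

## 7. Expression analysis

Size factors are the median-of-ratios estimator (geometric-mean reference
over regions with no zero count; those regions are excluded from the
reference only), cross-checked against an independent DESeq implementation
in tests. Quantification is reads per kb on the alternative/unique region of
each gene — for shared-3′ groups this is the 5′ end, which sidesteps the
poly(A)-driven 3′ bias of the original libraries. Groups with any member
totalling < 10 normalized reads/kb (strict) are excluded, tallied per
topology; the per-gene reading of "total normalized expression" is the
default, switchable in config. Peaks are argmax with ties broken toward the
earliest time point (an arbitrary fixed rule); percentages are rounded
half-up. Copy-number folds (max/min per group) are tallied against the 2×
and 3× guide lines on all detected groups.

## 8. Thresholds

Every numeric constant of the analysis (20 nt penetration, 40%/80%
similarity gates, 200 shuffles, 150 nt and dS ∈ [0.01, 5] rate filters,
10 reads/kb, 50 bp / 10% length conservation, 2×/3× fold lines, 50% gap
column filter, 0.25 GC quantile) lives in `Thresholds` with the published
value as default and is overridable from YAML; tests verify that changing a
threshold changes the corresponding output.

## 9. Known limitations

- No indel model; real alternative regions align with gaps, and the gene
  tree distance machinery sees its mafft-aligned path only in tests.
- The e-value surrogate calibrates significance empirically per comparison;
  its false-positive rate is bounded by the shuffle count (p < 1/201), which
  is weaker than BLAST's 1e-10.
- Gene-tree correction without bootstrap support will occasionally move an
  origin one node too deep on noisy trees (see §5).
- The parsimony origin is a lower bound by construction: novel-gene losses
  in whole subclades are invisible to both the presence pattern and the
  gene tree.
- Expression "profiles" are six-point vectors; no attempt is made to model
  library-level covariance between time points.
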