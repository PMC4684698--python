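# mdsweave

Analysis of **alternative DNA processing** in ciliate genomes — how the
programmed rearrangement that builds a somatic macronucleus (MAC) from a
germline micronucleus (MIC) lets a single germline DNA segment contribute to
more than one somatic gene, and how that process creates new genes.

In stichotrich ciliates such as *Oxytricha trifallax*, each somatic gene is
stitched together during development from short germline segments
(macronuclear-destined sequences, MDSs) separated by eliminated sequences
(IESs), joined at short repeats (pointers), sometimes after reordering or
inversion (scrambling). Occasionally one single-copy germline MDS is spliced
into several distinct somatic nanochromosomes: the resulting genes share
*constitutive* segments and differ in *alternative* segments — DNA-level
alternative splicing. `mdsweave` implements the comparative-genomic analysis
of this phenomenon for researchers studying genome rearrangement and new-gene
origination:

1. **Detection** — find groups of MAC chromosomes that share single-copy
   germline MDSs; remove groups that do not involve new genes (noncoding
   chromosomes; multigene chromosomes sharing exactly one identical gene;
   sharing that reaches < 20 nt into any coding sequence); classify each case
   by sharing topology (5′, 3′, or both ends) and scrambled status.
2. **Origin inference** — from ortholog presence/sharing across related
   species, place each novel gene's origin on the species tree by parsimony
   (the stem of the smallest clade containing every species with the novel
   gene); correct with neighbor-joining gene trees of the alternative regions
   when they reveal an earlier duplication followed by loss; classify the
   alternative segment's mechanism: segmental duplication (>40% protein
   identity over >80% of the shorter unique region, with an empirical
   shuffle-based significance floor) versus no similarity, flagging low-GC
   segments as candidate captures of germline-limited noncoding DNA.
3. **Rate analysis** — per gene, partition the CDS into alternative and
   constitutive regions, align strain orthologs at the protein level,
   back-translate to codons, and estimate dN/dS per region with the
   Nei–Gojobori (1986) counting method under the ciliate nuclear genetic code
   (TAA/TAG = Gln); compare regions with Wilcoxon signed-rank tests after the
   length (>150 nt) and dS (0.01–5) filters.
4. **Expression analysis** — median-of-ratios normalization of RNA-seq counts
   across the six developmental time points (vegetative; 0, 10, 20, 40, 60 h
   post mixing), reads/kb on alternative regions, a 10 reads/kb filter, and
   within-group comparison of expression peak times and DNA copy numbers.

Because the original sequenced genomes are not bundled, a first-class
**synthetic-data generator** produces complete ground-truth datasets (MIC/MAC
genomes with pointers, IESs, scrambling, planted sharing cases of every
topology, duplication histories with losses on an eight-ciliate species tree
plus outgroup, two strains at dS ≈ 0.15, region-specific dN/dS, and
negative-binomial expression counts). All statistical machinery is validated
against this generator.

## The core quantities

For a codon alignment of strain orthologs, synonymous (S) and nonsynonymous
(N) sites are counted per codon, differences are averaged over all shortest
substitution pathways, and both proportions are Jukes–Cantor corrected:

    pS = Sd / S,  pN = Nd / N,  d = -(3/4) ln(1 - 4p/3),  ω = dN / dS

The origin of gene B (novel, sharing segments with ancestral gene A) is the
stem branch of `MRCA{species : B present}`; a gene tree of the alternative
regions moves the origin deeper when the clade containing the focal B (and
excluding the focal A) spans species outside that MRCA — each such species
implies one loss of the ancestral copy.

## Worked example

```bash
mdsweave all --seed 1 --out run1        # simulate the default world + analyze
```

prints (abridged; `run1/report.md` holds the full report):

```
| row             | total | share5 | share3 | both | nonscrambled | scrambled |
| MIC loci        | 69    | 29     | 32     | 8    | 33           | 36        |
| MAC chromosomes | 154   | 69     | 69     | 16   | 100          | 54        |

Origins per species-tree node (raw / corrected):  NOxy: 47 / 44, NSte: 3 / 5, ...
mechanisms: {'duplication': 47, 'no_similarity': 8, 'low_gc_noncoding': 14}

Substitution rates (paired signed-rank, n = 154 genes):
  aa:    median alt 0.130  vs const 0.0172   P = 5.1e-27
  ds:    median alt 0.148  vs const 0.149    P = 0.104
  dn:    median alt 0.0610 vs const 0.00751  P = 5.1e-27
  omega: median alt 0.432  vs const 0.0490   P = 5.1e-27

Expression: share5 21 groups, 6 same-peak, 71% different; ...
```

Reading this: the generator planted 69 sharing cases (36 decoy loci were
correctly removed by the three filters); most origins date to the youngest
node (the strain pair), and gene-tree corrections move a few deeper (raw vs
corrected counts). The alternative regions were planted with ω = 0.4 and the
constitutive with ω = 0.05 at strain divergence dS = 0.15 — the medians
recover all three values, synonymous rates do not differ between regions
(P = 0.10), and nonsynonymous rates and ω differ strongly, the signature of
faster evolution of alternative segments. Peak-time divergence percentages
are computed per topology after the 10 reads/kb filter.

Each stage is also available separately (`mdsweave simulate / detect /
infer-origin / rates / expression / report`); thresholds and simulation
parameters live in a YAML config (`mdsweave all --config config.yaml`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the full analysis from scratch on the default simulated world —
generation, detection, filtering, origin dating with gene-tree correction,
region-wise dN/dS with the paired tests, and the expression summaries — and
writes its results JSON to `--out` (the run report goes to stderr).
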