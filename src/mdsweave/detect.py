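"""Detection, filtering and classification of alternative-MDS-processing cases.

A sharing case is a group of somatic chromosomes that receive at least one
common single-copy germline MDS.  Three filters remove groups that do not
involve new genes: (1) any involved chromosome lacks gene predictions;
(2) multigene chromosomes that share exactly one complete, 100%-identical
gene (the same gene on two chromosomes, not alternative processing);
(3) the shared region extends less than 20 nt into every coding sequence.
Retained cases are classified by sharing topology (5' / 3' / both ends, in
coding-strand orientation) and by scrambled status, and summarized in the
shape of the study's Table 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rearrangement import (GeneModel, MACChromosome, MDSMap, MICLocus,
                            is_scrambled)

__all__ = [
    "SharingCase", "CaseSummary", "RemovalRecord",
    "find_sharing_groups", "apply_filters", "classify_topology",
    "shared_coding_fraction", "summarize_cases",
]

Interval = tuple[int, int]


def _merge(intervals: list[Interval]) -> list[Interval]:
    out: list[Interval] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _overlap_nt(a: list[Interval], b: list[Interval]) -> int:
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


@dataclass
class SharingCase:
    """A group of MAC chromosomes sharing germline MDSs from one MIC locus."""

    case_id: str
    locus_id: str
    chrom_ids: list[str]
    shared_mds_indices: list[int]
    shared_intervals: dict[str, list[Interval]]  # chrom -> merged MAC intervals
    scrambled_chroms: dict[str, bool] = field(default_factory=dict)
    topology: str | None = None           # share5 | share3 | both
    topology_ambiguous: bool = False
    shared_coding_fraction: dict[str, float] = field(default_factory=dict)
    n_mds: int = 0          # all MDSs of the locus
    n_shared_mds: int = 0
    n_scrambled_mds: int = 0

    @property
    def scrambled(self) -> bool:
        return any(self.scrambled_chroms.values())


def _mds_scrambled_flags(mds_map: MDSMap, locus: MICLocus) -> dict[int, bool]:
    """Per-MDS scrambled status: inverted, or order-breaking in any chromosome."""
    flags = {m.index: m.orientation == "-" for m in locus.mds_list}
    chroms = {t.chrom_id for m in locus.mds_list for t in m.targets}
    for chrom in chroms:
        pairs = mds_map.targets_for(chrom)  # sorted by MAC order
        starts = [m.start for m, _ in pairs]
        ranks = np.argsort(np.argsort(starts))
        for i, (m, _) in enumerate(pairs):
            if ranks[i] != i:
                flags[m.index] = True
    return flags


def find_sharing_groups(loci: dict[str, MICLocus],
                        chromosomes: dict[str, MACChromosome]) -> list[SharingCase]:
    """One unfiltered case per MIC locus with >= 1 multi-target MDS.

    Chromosomes are grouped by connected sharing; a locus whose shared MDSs
    split into disjoint chromosome components yields one case per component
    (suffixing the case id), though clean data never does.
    """
    mds_map = MDSMap(loci)
    cases: list[SharingCase] = []
    for locus_id in sorted(loci):
        locus = loci[locus_id]
        shared = [m for m in locus.mds_list if m.is_shared]
        if not shared:
            continue
        # connected components over chromosomes linked by a common shared MDS
        parent: dict[str, str] = {}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for m in shared:
            ids = sorted({t.chrom_id for t in m.targets})
            for c in ids:
                parent.setdefault(c, c)
            for c in ids[1:]:
                parent[find(ids[0])] = find(c)
        components: dict[str, list[str]] = {}
        for c in parent:
            components.setdefault(find(c), []).append(c)
        scramble_flags = _mds_scrambled_flags(mds_map, locus)
        for k, (_, members) in enumerate(sorted(components.items())):
            members = sorted(members)
            case_id = locus_id if len(components) == 1 else f"{locus_id}.{k + 1}"
            comp_shared = [m for m in shared
                           if {t.chrom_id for t in m.targets} <= set(members)]
            intervals = {
                c: _merge([(t.start, t.end) for m in comp_shared
                           for t in m.targets if t.chrom_id == c])
                for c in members}
            scrambled_chroms = {c: is_scrambled(mds_map.targets_for(c))
                                for c in members}
            cases.append(SharingCase(
                case_id=case_id, locus_id=locus_id, chrom_ids=members,
                shared_mds_indices=sorted(m.index for m in comp_shared),
                shared_intervals=intervals,
                scrambled_chroms=scrambled_chroms,
                n_mds=len(locus.mds_list),
                n_shared_mds=len(comp_shared),
                n_scrambled_mds=sum(scramble_flags.values()),
            ))
    return cases


@dataclass
class RemovalRecord:
    case_id: str
    rule: int
    detail: str


def apply_filters(cases: list[SharingCase],
                  chromosomes: dict[str, MACChromosome],
                  min_cds_penetration: int = 20
                  ) -> tuple[list[SharingCase], list[RemovalRecord]]:
    """Apply the three case filters in fixed order 1 -> 2 -> 3.

    A case removable under several rules is logged under the first that fires.
    Chromosomes without a gene-model record at all (as opposed to an empty
    one) are a missing-annotation error.
    """
    retained: list[SharingCase] = []
    removed: list[RemovalRecord] = []
    for case in cases:
        for c in case.chrom_ids:
            if c not in chromosomes:
                raise KeyError(f"{case.case_id}: no gene-model record for {c}")

        noncoding = [c for c in case.chrom_ids if not chromosomes[c].genes]
        if noncoding:
            removed.append(RemovalRecord(case.case_id, 1,
                                         f"noncoding chromosomes: {','.join(noncoding)}"))
            continue

        if _rule2_identical_single_gene(case, chromosomes):
            removed.append(RemovalRecord(case.case_id, 2,
                                         "multigene chromosomes share exactly one "
                                         "identical gene"))
            continue

        max_pen = 0
        for c in case.chrom_ids:
            for gene in chromosomes[c].genes:
                max_pen = max(max_pen, _overlap_nt(case.shared_intervals[c],
                                                   gene.cds_intervals))
        if max_pen < min_cds_penetration:
            removed.append(RemovalRecord(
                case.case_id, 3,
                f"shared region reaches only {max_pen} nt into coding sequence"))
            continue
        retained.append(case)
    return retained, removed


def _rule2_identical_single_gene(case: SharingCase,
                                 chromosomes: dict[str, MACChromosome]) -> bool:
    if any(len(chromosomes[c].genes) < 2 for c in case.chrom_ids):
        return False
    shared_cds: list[str] = []
    for c in case.chrom_ids:
        chrom = chromosomes[c]
        touching = [g for g in chrom.genes
                    if _overlap_nt(case.shared_intervals[c], g.cds_intervals) > 0]
        if len(touching) != 1:
            return False
        gene = touching[0]
        # 100% overlap: the gene's CDS lies entirely within the shared region
        if _overlap_nt(case.shared_intervals[c], gene.cds_intervals) != gene.cds_length:
            return False
        shared_cds.append(gene.cds_sequence(chrom.sequence))
    return len(set(shared_cds)) == 1


def _gene_5p_3p_in_shared(case: SharingCase, chrom: MACChromosome,
                          gene: GeneModel) -> tuple[bool, bool]:
    """Does the shared region include the gene's coding 5' / 3' terminal base?"""
    lo = min(s for s, _ in gene.cds_intervals)
    hi = max(e for _, e in gene.cds_intervals) - 1
    start_base, end_base = (lo, hi) if gene.strand == "+" else (hi, lo)
    shared = case.shared_intervals[chrom.chrom_id]

    def inside(pos: int) -> bool:
        return any(s <= pos < e for s, e in shared)

    return inside(start_base), inside(end_base)


def _case_genes(case: SharingCase,
                chromosomes: dict[str, MACChromosome]
                ) -> list[tuple[MACChromosome, GeneModel]]:
    out = []
    for c in case.chrom_ids:
        chrom = chromosomes[c]
        for gene in chrom.genes:
            if _overlap_nt(case.shared_intervals[c], gene.cds_intervals) > 0:
                out.append((chrom, gene))
    return out


def classify_topology(case: SharingCase,
                      chromosomes: dict[str, MACChromosome]) -> SharingCase:
    """Assign share5 / share3 / both, in coding-strand orientation per gene.

    A gene whose shared region touches neither CDS terminus makes the case
    ambiguous; it is then classified by the terminus touched in the majority
    of genes and flagged.
    """
    genes = _case_genes(case, chromosomes)
    if not genes:
        raise ValueError(f"{case.case_id}: no genes touching the shared region")
    hits5, hits3 = [], []
    for chrom, gene in genes:
        h5, h3 = _gene_5p_3p_in_shared(case, chrom, gene)
        hits5.append(h5)
        hits3.append(h3)
    if all(hits5) and all(hits3):
        case.topology = "both"
    elif all(hits5):
        case.topology = "share5"
    elif all(hits3):
        case.topology = "share3"
    else:
        case.topology_ambiguous = True
        n5, n3 = sum(hits5), sum(hits3)
        case.topology = "share5" if n5 >= n3 else "share3"
    return case


def shared_coding_fraction(case: SharingCase,
                           chromosomes: dict[str, MACChromosome]) -> SharingCase:
    """Shared-coding fraction per gene, using the shortest shared portion.

    When genes share an MDS run to unequal coding extents, the shortest shared
    coding length is used as the numerator for every gene; the denominator is
    each gene's own total CDS length.
    """
    for c in case.chrom_ids:
        for gene in chromosomes[c].genes:
            if gene.cds_length == 0:
                raise ValueError(
                    f"{case.case_id}: zero-length CDS for {gene.gene_id}")
    genes = _case_genes(case, chromosomes)
    shared_nt = []
    for chrom, gene in genes:
        shared_nt.append(_overlap_nt(case.shared_intervals[chrom.chrom_id],
                                     gene.cds_intervals))
    shortest = min(shared_nt)
    case.shared_coding_fraction = {
        gene.gene_id: shortest / gene.cds_length for _, gene in genes}
    return case


@dataclass
class CaseSummary:
    """Counts in the shape of the study's Table 1.

    Topology columns of the MDS row count shared MDSs only; the MDS total and
    its scrambled split count all MDSs of the case loci (the published table
    is only consistent under that reading).
    """

    loci: dict[str, int]
    chromosomes: dict[str, int]
    mds: dict[str, int]

    def to_dict(self) -> dict:
        return {"loci": self.loci, "chromosomes": self.chromosomes, "mds": self.mds}


def summarize_cases(cases: list[SharingCase]) -> CaseSummary:
    keys = ["total", "share5", "share3", "both", "nonscrambled", "scrambled"]
    loci = dict.fromkeys(keys, 0)
    chroms = dict.fromkeys(keys, 0)
    mds = dict.fromkeys(keys, 0)
    for case in cases:
        topo = case.topology or "share5"
        loci["total"] += 1
        loci[topo] += 1
        loci["scrambled" if case.scrambled else "nonscrambled"] += 1
        nc = len(case.chrom_ids)
        chroms["total"] += nc
        chroms[topo] += nc
        for c in case.chrom_ids:
            chroms["scrambled" if case.scrambled_chroms.get(c) else "nonscrambled"] += 1
        mds["total"] += case.n_mds
        mds[topo] += case.n_shared_mds
        mds["scrambled"] += case.n_scrambled_mds
        mds["nonscrambled"] += case.n_mds - case.n_scrambled_mds
    return CaseSummary(loci, chroms, mds)
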