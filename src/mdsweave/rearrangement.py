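"""Data model for germline (MIC) / somatic (MAC) genome architecture.

Ciliate somatic "nanochromosomes" are stitched together during development
from germline segments (MDSs, macronuclear-destined sequences) separated by
eliminated sequences (IESs).  Consecutive MDSs overlap by a short identical
repeat, the pointer, which appears once in the somatic product.  MDSs may be
stored in permuted order or inverted orientation ("scrambled").  A single
germline MDS may target more than one somatic chromosome (alternative MDS
processing), which is the phenomenon this package analyzes.

Coordinates are 0-based half-open throughout; GFF3 I/O converts at the edge.
MIC MDS intervals include the pointer at both flanks: consecutive targets of
one chromosome overlap by the pointer length in MAC coordinates, and assembly
counts each pointer once.  Telomeres are flags, never sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._codes import revcomp

Interval = tuple[int, int]


class JunctionMismatchError(ValueError):
    """The two annotated copies of a pointer disagree."""


@dataclass(frozen=True)
class MDSTarget:
    """One somatic placement of an MDS."""

    chrom_id: str
    order: int  # 1-based position in the chromosome's assembly order
    start: int  # MAC chromosome coordinates, 0-based half-open
    end: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty MAC interval on {self.chrom_id}")


@dataclass
class MDS:
    """A macronuclear-destined sequence in its germline context."""

    locus_id: str
    index: int  # 1-based ordinal by germline position within the locus
    start: int  # MIC contig coordinates, 0-based half-open
    end: int
    orientation: str = "+"  # '-' means the somatic copy is the reverse complement
    targets: list[MDSTarget] = field(default_factory=list)

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty MIC interval for MDS {self.locus_id}:{self.index}")
        if self.orientation not in "+-":
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_shared(self) -> bool:
        """A constitutive MDS contributes to more than one MAC chromosome."""
        return len({t.chrom_id for t in self.targets}) >= 2


@dataclass
class IES:
    """An internal eliminated sequence, strictly between two MDSs."""

    locus_id: str
    start: int
    end: int
    flanking: tuple[int, int]  # (left MDS index, right MDS index) on the MIC contig


@dataclass(frozen=True)
class Pointer:
    """Microhomology repeat at the junction of two consecutive MDSs."""

    junction: tuple[int, int]  # (left MDS index, right MDS index)
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class GeneModel:
    gene_id: str
    strand: str
    cds_intervals: list[Interval]  # sorted, non-overlapping, chromosome coords

    def __post_init__(self):
        ivs = sorted(self.cds_intervals)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping CDS intervals in {self.gene_id}")
        self.cds_intervals = ivs

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    def cds_sequence(self, chrom_seq: str) -> str:
        """Spliced CDS in coding orientation."""
        s = "".join(chrom_seq[a:b] for a, b in self.cds_intervals)
        return revcomp(s) if self.strand == "-" else s


@dataclass
class MACChromosome:
    chrom_id: str
    sequence: str
    telomere_5: bool = True
    telomere_3: bool = True
    genes: list[GeneModel] = field(default_factory=list)


@dataclass
class MICLocus:
    locus_id: str
    contig_id: str
    sequence: str
    mds_list: list[MDS] = field(default_factory=list)
    ies_list: list[IES] = field(default_factory=list)

    def mds_by_index(self, index: int) -> MDS:
        for m in self.mds_list:
            if m.index == index:
                return m
        raise KeyError(f"no MDS {index} in {self.locus_id}")


def mds_mac_sequence(locus: MICLocus, mds: MDS) -> str:
    """The MDS sequence in somatic (MAC) orientation."""
    seq = locus.sequence[mds.start:mds.end]
    return revcomp(seq) if mds.orientation == "-" else seq


class MDSMap:
    """All MDS records of a dataset, indexable by locus, chromosome and status."""

    def __init__(self, loci: dict[str, MICLocus]):
        self.loci = loci
        self._by_chrom: dict[str, list[tuple[MDS, MDSTarget]]] = {}
        for locus in loci.values():
            for mds in locus.mds_list:
                for t in mds.targets:
                    self._by_chrom.setdefault(t.chrom_id, []).append((mds, t))
        for pairs in self._by_chrom.values():
            pairs.sort(key=lambda p: p[1].order)

    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def targets_for(self, chrom_id: str) -> list[tuple[MDS, MDSTarget]]:
        return self._by_chrom[chrom_id]

    def locus_of(self, chrom_id: str) -> str:
        loci = {m.locus_id for m, _ in self._by_chrom[chrom_id]}
        if len(loci) != 1:
            raise ValueError(f"{chrom_id} maps to {len(loci)} loci")
        return loci.pop()

    def shared_mds(self) -> list[MDS]:
        out = []
        for locus in self.loci.values():
            out.extend(m for m in locus.mds_list if m.is_shared)
        return out


def assemble_mac(loci: dict[str, MICLocus],
                 targets: list[tuple[MDS, MDSTarget]]) -> str:
    """Assemble the somatic sequence from ordered MDS targets.

    Each MDS is extracted from the MIC (reverse-complemented when inverted) and
    consecutive segments are merged with their pointer overlap counted once.
    The result is invariant to input order: targets are sorted by their MAC
    order position first.

    Raises
    ------
    JunctionMismatchError
        If the two copies of an annotated overlap differ, naming the junction.
    """
    if not targets:
        return ""
    ordered = sorted(targets, key=lambda p: p[1].order)
    orders = [t.order for _, t in ordered]
    if orders != list(range(1, len(orders) + 1)):
        raise ValueError(f"MAC order positions not 1..k: {orders}")
    pieces = []
    prev_seq = prev_t = prev_m = None
    for mds, t in ordered:
        seq = mds_mac_sequence(loci[mds.locus_id], mds)
        if len(seq) != t.end - t.start:
            raise ValueError(
                f"MDS {mds.locus_id}:{mds.index} length {len(seq)} != "
                f"target interval {t.end - t.start} on {t.chrom_id}")
        if prev_seq is None:
            pieces.append(seq)
        else:
            overlap = prev_t.end - t.start
            if overlap < 0:
                raise ValueError(
                    f"gap between MDS {prev_m.index} and {mds.index} on {t.chrom_id}")
            if overlap > min(len(seq), len(prev_seq)):
                raise ValueError(
                    f"overlap {overlap} longer than a segment at junction "
                    f"({prev_m.index},{mds.index})")
            if overlap and prev_seq[-overlap:] != seq[:overlap]:
                raise JunctionMismatchError(
                    f"pointer mismatch at junction ({prev_m.index},{mds.index}) "
                    f"on {t.chrom_id}")
            pieces.append(seq[overlap:])
        prev_seq, prev_t, prev_m = seq, t, mds
    return "".join(pieces)


def is_scrambled(targets: list[tuple[MDS, MDSTarget]]) -> bool:
    """True iff the germline order of a chromosome's MDSs differs from the
    somatic order, or any MDS is inverted."""
    ordered = sorted(targets, key=lambda p: p[1].order)
    if any(m.orientation == "-" for m, _ in ordered):
        return True
    starts = [m.start for m, _ in ordered]
    return starts != sorted(starts)


def pointer_at_junction(left_seq: str, right_seq: str, overlap: int,
                        junction: tuple[int, int] = (0, 0)) -> Pointer:
    """The pointer implied by an annotated coordinate overlap.

    Both segments must be in MAC orientation.  Zero-length pointers are
    permitted (abutting segments).
    """
    if overlap < 0 or overlap > min(len(left_seq), len(right_seq)):
        raise ValueError(f"overlap {overlap} out of range")
    if overlap == 0:
        return Pointer(junction, "")
    left = left_seq[-overlap:]
    right = right_seq[:overlap]
    if left != right:
        raise JunctionMismatchError(
            f"annotated {overlap}-nt overlap differs between copies at {junction}")
    return Pointer(junction, left)


@dataclass
class JunctionMatch:
    junction_a: int  # index into boundaries_a
    junction_b: int
    offset_nt: int   # in ungapped-consensus nucleotides
    in_gap: bool     # offset interval spans gap columns


@dataclass
class JunctionOffsets:
    matches: list[JunctionMatch]
    unmatched_a: list[int]
    unmatched_b: list[int]


def _pos_to_column(aligned: str) -> list[int]:
    """Map each ungapped position (plus the end sentinel) to its alignment column."""
    cols = [i for i, c in enumerate(aligned) if c != "-"]
    cols.append(len(aligned))
    return cols


def junction_offsets(boundaries_a: list[int], boundaries_b: list[int],
                     aligned_a: str, aligned_b: str) -> JunctionOffsets:
    """Compare MDS junction positions between two aligned paralogous regions.

    ``boundaries_*`` are junction coordinates in each sequence's own ungapped
    coordinates.  Junctions are matched greedily by nearest alignment column
    (ties broken toward 5'); the offset is reported in nucleotides of the
    ungapped consensus (columns without a gap in either sequence).  A match
    whose offset interval spans gap columns is flagged.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("alignment rows differ in length")
    map_a = _pos_to_column(aligned_a)
    map_b = _pos_to_column(aligned_b)
    cols_a = [map_a[p] for p in boundaries_a]
    cols_b = [map_b[p] for p in boundaries_b]
    consensus = [a != "-" and b != "-" for a, b in zip(aligned_a, aligned_b)]
    csum = [0]
    for flag in consensus:
        csum.append(csum[-1] + flag)

    candidates = sorted(
        (abs(ca - cb), ca, ia, ib)
        for ia, ca in enumerate(cols_a) for ib, cb in enumerate(cols_b))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matches = []
    for _, _, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        lo, hi = sorted((cols_a[ia], cols_b[ib]))
        offset = csum[min(hi, len(consensus))] - csum[min(lo, len(consensus))]
        gap = any(not consensus[c] for c in range(lo, min(hi, len(consensus))))
        matches.append(JunctionMatch(ia, ib, offset, gap))
    matches.sort(key=lambda m: m.junction_a)
    return JunctionOffsets(
        matches=matches,
        unmatched_a=[i for i in range(len(cols_a)) if i not in used_a],
        unmatched_b=[i for i in range(len(cols_b)) if i not in used_b],
    )


@dataclass
class Violation:
    kind: str
    where: str
    detail: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, kind: str, where: str, detail: str):
        self.violations.append(Violation(kind, where, detail))


def validate_map(loci: dict[str, MICLocus],
                 chromosomes: dict[str, MACChromosome]) -> ValidationReport:
    """Check structural invariants of a full MIC/MAC dataset.

    Every MAC chromosome must reassemble exactly from its targets, shared MDSs
    must be single-copy in the germline, order positions must be gapless, and
    IESs must lie strictly between their flanking MDSs.
    """
    report = ValidationReport()
    for locus in loci.values():
        n = len(locus.sequence)
        indices = [m.index for m in locus.mds_list]
        if len(indices) != len(set(indices)):
            report.add("duplicate_mds_index", locus.locus_id, str(sorted(indices)))
        for m in locus.mds_list:
            if not (0 <= m.start < m.end <= n):
                report.add("mds_out_of_bounds", f"{locus.locus_id}:{m.index}",
                           f"[{m.start},{m.end}) vs {n}")
            for t in m.targets:
                if t.end - t.start != m.length:
                    report.add("target_length_mismatch",
                               f"{locus.locus_id}:{m.index}", t.chrom_id)
            if m.is_shared:
                seq = locus.sequence[m.start:m.end]
                count = locus.sequence.count(seq) + locus.sequence.count(revcomp(seq))
                if count > 1:
                    report.add("shared_mds_multicopy",
                               f"{locus.locus_id}:{m.index}", f"{count} germline copies")
        for ies in locus.ies_list:
            if not (0 <= ies.start < ies.end <= n):
                report.add("ies_out_of_bounds", locus.locus_id,
                           f"[{ies.start},{ies.end})")
            try:
                left = locus.mds_by_index(ies.flanking[0])
                right = locus.mds_by_index(ies.flanking[1])
            except KeyError as exc:
                report.add("ies_flank_missing", locus.locus_id, str(exc))
                continue
            lo = min(left.end, right.end)
            hi = max(left.start, right.start)
            if not (lo <= ies.start and ies.end <= hi):
                report.add("ies_not_between_flanks", locus.locus_id,
                           f"[{ies.start},{ies.end}) not within [{lo},{hi})")

    mds_map = MDSMap(loci)
    for chrom_id, chrom in chromosomes.items():
        try:
            targets = mds_map.targets_for(chrom_id)
        except KeyError:
            continue  # chromosome without a germline map: nothing to check
        try:
            assembled = assemble_mac(loci, targets)
        except (ValueError, JunctionMismatchError) as exc:
            report.add("assembly_error", chrom_id, str(exc))
            continue
        if assembled != chrom.sequence:
            report.add("reassembly_mismatch", chrom_id,
                       f"assembled {len(assembled)} nt != stored {len(chrom.sequence)} nt"
                       if len(assembled) != len(chrom.sequence)
                       else "sequence differs")
    return report
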