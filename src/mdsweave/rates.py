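"""Substitution-rate analysis of alternative versus constitutive gene segments.

Each gene in a sharing group is partitioned into alternative (unique-MDS) and
constitutive (shared-MDS) coding regions.  Orthologous strain pairs are
aligned at the protein level, the alignment is back-translated to codons, and
dN/dS is estimated per region with the Nei–Gojobori (1986) counting method:
synonymous/nonsynonymous sites are counted per codon, all shortest
substitution pathways are averaged for multi-difference codon pairs, and the
Jukes–Cantor correction d = -(3/4) ln(1 - 4p/3) is applied to both proportions.
Counting replaces maximum-likelihood estimation deliberately: at the low
strain divergence involved (dS ~ 0.15) the two agree closely, and counting is
deterministic and dependency-free.  A hook for an external ML estimator can be
added by swapping :func:`ng86_dnds`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from Bio.Align import PairwiseAligner, substitution_matrices

from ._codes import CodeTables, encode_codons, get_tables

__all__ = [
    "RegionPartition", "RateRecord", "NG86Result", "SaturationError",
    "partition_regions", "codon_align_from_protein", "aa_distance",
    "ng86_counts", "ng86_dnds", "ng86_batch", "filter_rate_records",
    "paired_signed_rank", "split_codon_alignment_by_region",
]


class SaturationError(ValueError):
    """Jukes–Cantor correction undefined: 4p/3 >= 1 for a substitution class."""


# ---------------------------------------------------------------------------
# region partition

@dataclass
class RegionPartition:
    """Codon-resolved split of a CDS into alternative and constitutive parts.

    Intervals are in spliced-CDS coordinates (0-based half-open, coding
    orientation).  Partial codons at a region boundary are assigned to the
    region holding at least 2 of the 3 bases.
    """

    gene_id: str
    alternative: list[tuple[int, int]]
    constitutive: list[tuple[int, int]]

    @property
    def alternative_nt(self) -> int:
        return sum(e - s for s, e in self.alternative)

    @property
    def constitutive_nt(self) -> int:
        return sum(e - s for s, e in self.constitutive)

    def codon_classes(self) -> np.ndarray:
        """Per-codon region class: True = alternative."""
        n = (self.alternative_nt + self.constitutive_nt) // 3
        cls = np.zeros(n, dtype=bool)
        for s, e in self.alternative:
            cls[s // 3:e // 3] = True
        return cls


def partition_regions(gene_id: str, cds_length: int,
                      shared_cds_positions: np.ndarray) -> RegionPartition:
    """Partition a CDS by the shared/unique status of its underlying MDSs.

    Parameters
    ----------
    shared_cds_positions : bool array of length ``cds_length``
        True where the CDS base derives from a shared (constitutive) MDS.
        Every base must derive from some MDS; coverage gaps are the caller's
        error and should be caught upstream.
    """
    if cds_length % 3:
        raise ValueError(f"{gene_id}: CDS length {cds_length} not divisible by 3")
    if len(shared_cds_positions) != cds_length:
        raise ValueError(f"{gene_id}: status vector length mismatch")
    per_codon = shared_cds_positions.reshape(-1, 3).sum(axis=1)
    constit = per_codon >= 2  # majority-base rule for boundary codons
    alternative, constitutive = [], []
    i = 0
    n = len(constit)
    while i < n:
        j = i
        while j < n and constit[j] == constit[i]:
            j += 1
        iv = (3 * i, 3 * j)
        (constitutive if constit[i] else alternative).append(iv)
        i = j
    return RegionPartition(gene_id, alternative, constitutive)


# ---------------------------------------------------------------------------
# alignment

def default_protein_aligner(mode: str = "global") -> PairwiseAligner:
    aligner = PairwiseAligner(mode=mode)
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def align_proteins(prot_a: str, prot_b: str,
                   aligner: PairwiseAligner | None = None) -> tuple[str, str]:
    """Global protein alignment (affine gaps, BLOSUM62) as two gapped strings."""
    aligner = aligner or default_protein_aligner()
    aln = aligner.align(prot_a, prot_b)[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b


def codon_align_from_protein(prot_a: str, prot_b: str, cds_a: str, cds_b: str,
                             code_id: int = 6,
                             aligner: PairwiseAligner | None = None
                             ) -> tuple[str, str]:
    """Back-translate a protein alignment into a codon alignment.

    Each protein alignment column maps to one codon column; protein gaps
    expand to 3-nt gaps.  The proteins must be the translations of the CDSs
    under ``code_id`` (internal stops are an error).
    """
    tables = get_tables(code_id)
    for prot, cds, name in ((prot_a, cds_a, "A"), (prot_b, cds_b, "B")):
        if len(cds) != 3 * len(prot):
            raise ValueError(f"sequence {name}: CDS length {len(cds)} != 3 x {len(prot)}")
        trans = tables.translate(cds)
        if "*" in trans:
            raise ValueError(f"sequence {name}: internal stop codon under code {code_id}")
        if trans != prot:
            raise ValueError(f"sequence {name}: protein does not match CDS translation")
    pa, pb = align_proteins(prot_a, prot_b, aligner)
    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(pa, pb):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia:3 * ia + 3])
            ia += 1
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib:3 * ib + 3])
            ib += 1
    return "".join(out_a), "".join(out_b)


def split_codon_alignment_by_region(aligned_a: str, aligned_b: str,
                                    codon_classes: np.ndarray
                                    ) -> dict[str, tuple[str, str]]:
    """Split a codon alignment into gap-free alternative/constitutive parts.

    ``codon_classes`` flags each codon of (ungapped) sequence A as alternative
    (True) or constitutive (False); columns where either row is gapped are
    dropped.  Returns per-region (sub_a, sub_b) concatenated codon strings.
    """
    if len(aligned_a) != len(aligned_b) or len(aligned_a) % 3:
        raise ValueError("malformed codon alignment")
    parts = {"alternative": ([], []), "constitutive": ([], [])}
    ia = 0
    for k in range(0, len(aligned_a), 3):
        ca, cb = aligned_a[k:k + 3], aligned_b[k:k + 3]
        if ca != "---":
            cls = bool(codon_classes[ia])
            ia += 1
            if cb != "---":
                key = "alternative" if cls else "constitutive"
                parts[key][0].append(ca)
                parts[key][1].append(cb)
    if ia != len(codon_classes):
        raise ValueError("codon class vector does not match sequence A")
    return {k: ("".join(a), "".join(b)) for k, (a, b) in parts.items()}


@dataclass
class AaDistance:
    p_distance: float
    poisson: float
    n_compared: int
    saturated: bool


def aa_distance(aligned_a: str, aligned_b: str) -> AaDistance:
    """Amino-acid distance from a gapped pairwise protein alignment.

    Gap columns are excluded.  The p-distance (mismatches / compared columns)
    is the primary quantity; the Poisson correction -ln(1 - p) is reported
    alongside and flagged saturated (infinite) at p = 1.
    """
    pairs = [(a, b) for a, b in zip(aligned_a, aligned_b) if a != "-" and b != "-"]
    if not pairs:
        raise ValueError("no comparable (gap-free) columns")
    mism = sum(a != b for a, b in pairs)
    p = mism / len(pairs)
    if p >= 1.0:
        return AaDistance(p, math.inf, len(pairs), True)
    return AaDistance(p, -math.log(1.0 - p), len(pairs), False)


# ---------------------------------------------------------------------------
# Nei–Gojobori 1986

@dataclass
class NG86Result:
    dn: float
    ds: float
    omega: float | None  # None when dS == 0
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    n_codons: int


def _jc_correct(p: float, what: str) -> float:
    x = 1.0 - 4.0 * p / 3.0
    if x <= 0.0:
        raise SaturationError(f"{what}: 4p/3 >= 1 (p = {p:.4f})")
    return -0.75 * math.log(x)


def ng86_counts(cds_a: str, cds_b: str, code_id: int = 6
                ) -> tuple[float, float, float, float, int]:
    """NG86 site and difference counts: (S, N, sd, nd, n_codons).

    Sites are averaged between the two sequences; multi-difference codon pairs
    average synonymous/nonsynonymous differences over all shortest substitution
    pathways that avoid stop codons.
    """
    tables = get_tables(code_id)
    a = encode_codons(cds_a)
    b = encode_codons(cds_b)
    if len(a) != len(b):
        raise ValueError("aligned sequences differ in codon length")
    if len(a) == 0:
        raise ValueError("empty alignment")
    if tables.is_stop[a].any() or tables.is_stop[b].any():
        raise ValueError(f"stop codon in sequence under code {code_id}")
    S = 0.5 * (tables.syn_sites[a].sum() + tables.syn_sites[b].sum())
    N = 0.5 * (tables.nonsyn_sites[a].sum() + tables.nonsyn_sites[b].sum())
    sd = tables.sd[a, b].sum()
    nd = tables.nd[a, b].sum()
    return float(S), float(N), float(sd), float(nd), len(a)


def ng86_dnds(cds_a: str, cds_b: str, code_id: int = 6) -> NG86Result:
    """Pairwise dN/dS by the Nei–Gojobori (1986) counting method.

    The input must be a gap-free codon alignment (equal lengths, divisible by
    3, no stop codons).  Raises :class:`SaturationError` when the Jukes–Cantor
    correction is undefined for either substitution class.
    """
    S, N, sd, nd, n = ng86_counts(cds_a, cds_b, code_id)
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    ds = _jc_correct(ps, "dS") if sd else 0.0
    dn = _jc_correct(pn, "dN") if nd else 0.0
    omega = dn / ds if ds > 0 else None
    return NG86Result(dn, ds, omega, S, N, sd, nd, n)


def ng86_batch(codons_a: np.ndarray, codons_b: np.ndarray,
               segment_ids: np.ndarray, n_segments: int,
               code_id: int = 6) -> dict[str, np.ndarray]:
    """Vectorized NG86 over many concatenated gap-free codon alignments.

    ``codons_a``/``codons_b`` are int codon arrays, ``segment_ids`` assigns
    each codon column to one of ``n_segments`` alignments.  Returns per-segment
    arrays (dn, ds, omega with NaN where undefined or saturated).
    """
    tables: CodeTables = get_tables(code_id)
    S = 0.5 * np.bincount(segment_ids, tables.syn_sites[codons_a]
                          + tables.syn_sites[codons_b], minlength=n_segments)
    N = 0.5 * np.bincount(segment_ids, tables.nonsyn_sites[codons_a]
                          + tables.nonsyn_sites[codons_b], minlength=n_segments)
    sd = np.bincount(segment_ids, tables.sd[codons_a, codons_b], minlength=n_segments)
    nd = np.bincount(segment_ids, tables.nd[codons_a, codons_b], minlength=n_segments)
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(S > 0, sd / S, 0.0)
        pn = np.where(N > 0, nd / N, 0.0)
        ds = np.where(1 - 4 * ps / 3 > 0, -0.75 * np.log(1 - 4 * ps / 3), np.nan)
        dn = np.where(1 - 4 * pn / 3 > 0, -0.75 * np.log(1 - 4 * pn / 3), np.nan)
        omega = np.where(ds > 0, dn / ds, np.nan)
    return {"dn": dn, "ds": ds, "omega": omega, "S": S, "N": N, "sd": sd, "nd": nd}


# ---------------------------------------------------------------------------
# record filtering and the paired test

@dataclass
class RateRecord:
    case_id: str
    gene_id: str
    region_class: str  # 'alternative' | 'constitutive'
    region_nt: int
    aligned_codons: int
    aa_p: float
    aa_poisson: float
    dn: float
    ds: float
    omega: float | None

    def __post_init__(self):
        if self.region_class not in ("alternative", "constitutive"):
            raise ValueError(self.region_class)


def filter_rate_records(records: list[RateRecord],
                        min_region_nt: int = 150,
                        ds_min: float = 0.01,
                        ds_max: float = 5.0) -> list[RateRecord]:
    """Keep genes whose alternative AND constitutive regions both pass.

    A region passes when it is longer than ``min_region_nt`` (strict) and its
    dS lies in [ds_min, ds_max].  Genes with an undefined omega (dS = 0) fail
    the lower dS bound automatically.
    """
    by_gene: dict[str, dict[str, RateRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, {})[r.region_class] = r

    def ok(r: RateRecord) -> bool:
        return (r.region_nt > min_region_nt
                and not math.isnan(r.ds)
                and ds_min <= r.ds <= ds_max)

    kept = []
    for parts in by_gene.values():
        if {"alternative", "constitutive"} <= parts.keys() and all(map(ok, parts.values())):
            kept.extend(parts[c] for c in ("alternative", "constitutive"))
    return kept


def paired_signed_rank(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired vectors.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 without ties, otherwise the normal approximation with continuity
    correction (ties get average ranks).  Returns (statistic, p).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors differ in length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    ranks = stats.rankdata(np.abs(d))
    has_ties = len(np.unique(np.abs(d))) < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method,
                         correction=(method == "approx"))
    del ranks
    return float(res.statistic), float(res.pvalue)
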