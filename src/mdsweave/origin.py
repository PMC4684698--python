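"""Phylogenetic dating and mechanistic classification of new-gene origins.

For each sharing case the focal species carries an ancestral gene A and one or
more novel genes (B, C, ...) assembled from a mix of shared and unique
germline segments.  Orthologs of A and B are queried across related species;
per-species phyletic states (both present and sharing / only A / neither) are
mapped onto a rooted species tree, and the origin of the novel gene is placed
on the stem branch of the smallest clade containing every species where B is
present — a parsimonious estimate that assumes no losses.  Gene trees built
from the alternative (unique) regions can reveal that the duplication predates
the presence-based estimate (one copy having been lost in some lineages); in
that conflict the origin is moved to the deeper node implied by the gene tree.

The mechanism of the alternative segment's origin is classified as segmental
duplication when the unique regions of A and B are similar at the protein
level (>40% identity over >80% of the shorter region, with an empirical
shuffle-based significance floor standing in for a BLAST e-value), and
otherwise as no-similarity; unassignable-by-similarity segments whose GC falls
below the lower quartile of the somatic gene set are flagged as candidate
captures of germline-limited noncoding sequence.
"""

from __future__ import annotations

import subprocess
import tempfile
import math
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj
from Bio.Align import PairwiseAligner, substitution_matrices

from ._codes import gc_content

__all__ = [
    "PhyleticStates", "OriginCall", "GCBaseline",
    "read_species_tree", "species_presence_state", "infer_origin_node",
    "build_gene_tree", "correct_origin_with_gene_tree",
    "classify_alternative_origin", "gc_baseline", "flag_low_gc",
    "check_shared_length_conservation",
]

#: p-distances at or above this bound are capped and flagged saturated
P_SATURATION = 1.0 - 1.0 / 20.0


# ---------------------------------------------------------------------------
# species tree handling

def read_species_tree(newick: str) -> TreeNode:
    """Parse a rooted species tree and give unnamed internal nodes stable ids.

    Internal nodes are labeled N1, N2, ... in preorder; existing labels are
    kept.  The root keeps/gets the name 'root'.
    """
    tree = TreeNode.read(StringIO(newick), convert_underscores=False)
    counter = 1
    for node in tree.preorder():
        if node.is_tip():
            continue
        if node.is_root():
            if not node.name:
                node.name = "root"
            continue
        if not node.name:
            node.name = f"N{counter}"
            counter += 1
    return tree


def _lca(tree: TreeNode, names: list[str]) -> TreeNode:
    tips = [tree.find(n) for n in set(names)]
    if len(tips) == 1:
        return tips[0]
    return tree.lca(tips)


def _is_proper_ancestor(anc: TreeNode, node: TreeNode) -> bool:
    cur = node.parent
    while cur is not None:
        if cur is anc:
            return True
        cur = cur.parent
    return False


# ---------------------------------------------------------------------------
# phyletic states

@dataclass
class PhyleticStates:
    """Per-species ortholog presence/sharing pattern for one case."""

    case_id: str
    states: dict[str, str]  # species -> both_present_sharing|only_A_present|neither_present
    contradictions: list[str] = field(default_factory=list)  # both present, NOT sharing


def species_presence_state(case_id: str, species_records: dict[str, dict],
                           focal_species: str) -> PhyleticStates:
    """Map per-species ortholog records to phyletic states.

    ``species_records[species]`` needs keys ``a_present``, ``b_present`` and
    ``sharing`` (bool or None).  Both orthologs present without sharing has
    never been observed in real data; such species are recorded as
    contradictions rather than assigned a state.
    """
    states: dict[str, str] = {}
    contradictions: list[str] = []
    for sp, rec in species_records.items():
        a, b = bool(rec["a_present"]), bool(rec["b_present"])
        if a and b:
            if rec.get("sharing") is False:
                contradictions.append(sp)
                continue
            states[sp] = "both_present_sharing"
        elif a:
            states[sp] = "only_A_present"
        else:
            states[sp] = "neither_present"
    if states.get(focal_species) != "both_present_sharing":
        raise ValueError(
            f"{case_id}: focal species {focal_species} must be both_present_sharing")
    return PhyleticStates(case_id, states, contradictions)


def infer_origin_node(species_tree: TreeNode, states: PhyleticStates) -> TreeNode:
    """Most-recent-common-ancestor origin estimate (no losses assumed).

    The origin is the stem branch of the smallest clade containing every
    species where the novel gene is present, returned as that clade's node.
    """
    present = [sp for sp, st in states.states.items() if st == "both_present_sharing"]
    if not present:
        raise ValueError(f"{states.case_id}: novel gene present nowhere")
    return _lca(species_tree, present)


# ---------------------------------------------------------------------------
# gene trees

def _run_mafft(seqs: dict[str, str]) -> dict[str, str]:
    """Align protein sequences with the MAFFT CLI (--auto)."""
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fasta"
        fin.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        proc = subprocess.run(["mafft", "--quiet", "--auto", str(fin)],
                              capture_output=True, text=True, check=True)
    out: dict[str, str] = {}
    name = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].strip()
            out[name] = ""
        elif name is not None:
            out[name] += line.strip()
    return out


@dataclass
class GeneTreeResult:
    tree: TreeNode
    saturated_pairs: list[tuple[str, str]]
    n_columns_used: int


def build_gene_tree(sequences: dict[str, str], outgroup: str,
                    aligned: bool = False,
                    max_gap_frac: float = 0.5) -> GeneTreeResult:
    """Neighbor-joining tree on Poisson-corrected protein distances.

    Columns with more than ``max_gap_frac`` gaps are dropped (stand-in for
    automated alignment trimming); saturated p-distances (p >= 1 - 1/20) are
    capped and flagged.  The tree is rooted on the outgroup's pendant edge.
    """
    if len(sequences) < 3:
        raise ValueError("need at least 3 sequences for a gene tree")
    if outgroup not in sequences:
        raise KeyError(f"outgroup {outgroup!r} not among sequences")
    if not aligned:
        lens = {len(s) for s in sequences.values()}
        sequences = sequences if len(lens) == 1 else _run_mafft(sequences)
    names = sorted(sequences)
    mat = np.array([list(sequences[n]) for n in names])
    gaps = (mat == "-")
    keep = gaps.mean(axis=0) <= max_gap_frac
    mat = mat[:, keep]
    n = len(names)
    dist = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~gaps[i, keep] & ~gaps[j, keep]
            if not ok.any():
                raise ValueError(f"no comparable columns between "
                                 f"{names[i]} and {names[j]}")
            p = (mat[i, ok] != mat[j, ok]).mean()
            if p >= P_SATURATION:
                p = P_SATURATION
                saturated.append((names[i], names[j]))
            dist[i, j] = dist[j, i] = -math.log(1.0 - p)
    tree = nj(DistanceMatrix(dist, names))
    out_tip = tree.find(outgroup)
    rooted = tree.root_at(out_tip.parent if out_tip.parent is not None else out_tip,
                          above=True)
    return GeneTreeResult(rooted, saturated, int(keep.sum()))


# ---------------------------------------------------------------------------
# origin calls and correction

@dataclass
class OriginCall:
    case_id: str
    origin_node: str
    corrected: bool = False
    corrected_node: str | None = None
    implied_losses: list[str] = field(default_factory=list)
    mechanism: str = "unassigned"  # duplication|no_similarity|low_gc_noncoding|unassigned
    shared_length_conserved: dict[str, bool] = field(default_factory=dict)
    contradictions: list[str] = field(default_factory=list)

    @property
    def final_node(self) -> str:
        return self.corrected_node if self.corrected else self.origin_node


def correct_origin_with_gene_tree(call: OriginCall, gene_tree: TreeNode,
                                  species_tree: TreeNode,
                                  focal_a_leaf: str, focal_b_leaf: str,
                                  observed_b_species: list[str],
                                  species_of=lambda leaf: leaf.split("|")[0]
                                  ) -> OriginCall:
    """Move the origin deeper when the gene tree implies an earlier duplication.

    The B clade is the largest clade of the gene tree that contains the focal
    novel-gene leaf but not the focal ancestral-gene leaf.  Its species set,
    mapped to the species tree, gives the implied duplication node; when that
    node is a proper ancestor of the presence-based origin, the origin moves
    there and one loss is recorded for each species in the implied clade where
    the novel gene was not observed.
    """
    b_tip = gene_tree.find(focal_b_leaf)
    gene_tree.find(focal_a_leaf)  # raises if the gene tree lacks the A leaf
    node = b_tip
    while node.parent is not None:
        parent_tips = set(t.name for t in node.parent.tips())
        if focal_a_leaf in parent_tips:
            break
        node = node.parent
    b_species = sorted({species_of(t.name) for t in ([node] if node.is_tip()
                                                     else node.tips())})
    implied = _lca(species_tree, b_species)
    origin = species_tree.find(call.origin_node)
    if _is_proper_ancestor(implied, origin):
        clade_species = {t.name for t in implied.tips()}
        losses = sorted(clade_species - set(observed_b_species))
        call.corrected = True
        call.corrected_node = implied.name
        call.implied_losses = losses
    return call


# ---------------------------------------------------------------------------
# mechanism classification

def _local_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def classify_alternative_origin(alt_prot_a: str, alt_prot_b: str,
                                rng: np.random.Generator | None = None,
                                identity_threshold: float = 0.40,
                                coverage_threshold: float = 0.80,
                                n_shuffles: int = 200,
                                use_similarity: bool = False) -> str:
    """Classify the origin of an alternative segment: duplication or not.

    Duplication requires identity > ``identity_threshold`` over an aligned
    length > ``coverage_threshold`` of the shorter unique region, and a local
    alignment score exceeding that of every one of ``n_shuffles`` shuffles of
    one sequence (empirical p < 1/(n_shuffles+1); e-value surrogate).  With
    ``use_similarity`` the matrix-positive fraction replaces strict identity.
    """
    if not alt_prot_a or not alt_prot_b:
        raise ValueError("empty alternative region")
    rng = rng or np.random.default_rng(0)
    aligner = _local_aligner()
    aln = aligner.align(alt_prot_a, alt_prot_b)
    if len(aln) == 0:
        return "no_similarity"
    best = aln[0]
    a_row, b_row = str(best[0]), str(best[1])
    matrix = aligner.substitution_matrix
    pairs = [(x, y) for x, y in zip(a_row, b_row) if x != "-" and y != "-"]
    if not pairs:
        return "no_similarity"
    if use_similarity:
        matches = sum(matrix[x, y] > 0 for x, y in pairs)
    else:
        matches = sum(x == y for x, y in pairs)
    identity = matches / len(pairs)
    shorter = min(len(alt_prot_a), len(alt_prot_b))
    coverage = len(pairs) / shorter
    if identity <= identity_threshold or coverage <= coverage_threshold:
        return "no_similarity"
    score = best.score
    shuffled = list(alt_prot_b)
    for _ in range(n_shuffles):
        rng.shuffle(shuffled)
        s_aln = aligner.align(alt_prot_a, "".join(shuffled))
        if len(s_aln) and s_aln.score >= score:
            return "no_similarity"
    return "duplication"


@dataclass
class GCBaseline:
    values: np.ndarray
    lower_quartile: float


def gc_baseline(gene_cds_seqs: list[str]) -> GCBaseline:
    """Lower-quartile GC baseline over the somatic gene set.

    The quartile uses the linear-interpolation quantile definition so the
    strict-inequality flag is well defined.
    """
    if not gene_cds_seqs:
        raise ValueError("no genes for GC baseline")
    values = np.array([gc_content(s) for s in gene_cds_seqs])
    return GCBaseline(values, float(np.quantile(values, 0.25, method="linear")))


def flag_low_gc(alt_region_seq: str, baseline: GCBaseline) -> bool:
    """True iff the alternative region's GC is strictly below the quartile."""
    return gc_content(alt_region_seq) < baseline.lower_quartile


def check_shared_length_conservation(len_focal: int, len_ortholog: int,
                                     abs_tol: int = 50,
                                     rel_tol: float = 0.10) -> bool:
    """Shared-segment lengths conserved within 50 bp or 10%, whichever larger."""
    if len_focal <= 0 or len_ortholog <= 0:
        raise ValueError("lengths must be positive")
    return abs(len_focal - len_ortholog) <= max(abs_tol, rel_tol * len_focal)
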