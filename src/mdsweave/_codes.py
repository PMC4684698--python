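"""Genetic-code tables and codon bookkeeping shared across the package.

Codons are encoded as integers 0..63 with A=0, C=1, G=2, T=3 and the first
base most significant, so ``code = 16*b1 + 4*b2 + b3``.  All per-code lookup
tables (amino acids, synonymous/nonsynonymous site counts, single-step
neighbor lists, pathway-averaged difference counts) are built once per
genetic code id and cached.

Supported codes: 1 (universal), 6 (ciliate nuclear: TAA/TAG = Gln),
10 (Euplotes: TGA = Cys).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

NT = "ACGT"
NT_INDEX = {c: i for i, c in enumerate(NT)}
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: purine/pyrimidine class per nucleotide index; equal class => transition
_PURINE = np.array([1, 0, 1, 0])  # A, G purines


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


def codon_index(codon: str) -> int:
    return 16 * NT_INDEX[codon[0]] + 4 * NT_INDEX[codon[1]] + NT_INDEX[codon[2]]


def index_codon(i: int) -> str:
    return NT[(i >> 4) & 3] + NT[(i >> 2) & 3] + NT[i & 3]


def encode_codons(seq: str) -> np.ndarray:
    """Encode a gap-free CDS (length divisible by 3) as an int8 codon array."""
    if len(seq) % 3:
        raise ValueError(f"sequence length {len(seq)} not divisible by 3")
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    lut = np.full(128, -1, dtype=np.int8)
    for c, i in NT_INDEX.items():
        lut[ord(c)] = i
    nt = lut[arr]
    if (nt < 0).any():
        bad = seq[int(np.argmax(nt < 0))]
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    nt = nt.reshape(-1, 3).astype(np.int16)
    return (16 * nt[:, 0] + 4 * nt[:, 1] + nt[:, 2]).astype(np.int8)


def decode_codons(codons: np.ndarray) -> str:
    return "".join(index_codon(int(c)) for c in codons)


@dataclass
class CodeTables:
    """Precomputed per-genetic-code lookup tables (all indexed by codon int)."""

    code_id: int
    aa: np.ndarray              # (64,) unicode amino acid, '*' for stop
    is_stop: np.ndarray         # (64,) bool
    syn_sites: np.ndarray       # (64,) float, NG86 synonymous sites (stops: 0)
    nonsyn_sites: np.ndarray    # (64,) float, 3 - syn_sites for sense codons
    sd: np.ndarray              # (64,64) pathway-averaged synonymous differences
    nd: np.ndarray              # (64,64) pathway-averaged nonsynonymous differences
    # neighbor tables for the substitution simulator: up to 9 single-nt neighbors
    nb_codon: np.ndarray = field(repr=False, default=None)   # (64,9) int
    nb_syn: np.ndarray = field(repr=False, default=None)     # (64,9) bool
    nb_ts: np.ndarray = field(repr=False, default=None)      # (64,9) bool
    nb_valid: np.ndarray = field(repr=False, default=None)   # (64,9) bool (sense->sense)

    def translate(self, seq: str) -> str:
        codons = encode_codons(seq)
        aas = self.aa[codons]
        return "".join(aas)


def _neighbors(i: int) -> list[tuple[int, int, int]]:
    """All 9 single-nucleotide neighbors of codon i as (j, position, new_nt)."""
    out = []
    nts = [(i >> 4) & 3, (i >> 2) & 3, i & 3]
    for pos in range(3):
        for new in range(4):
            if new == nts[pos]:
                continue
            trip = list(nts)
            trip[pos] = new
            out.append((16 * trip[0] + 4 * trip[1] + trip[2], pos, new))
    return out


def _pathway_counts(a: int, b: int, aa: np.ndarray, is_stop: np.ndarray) -> tuple[float, float]:
    """NG86 pathway-averaged (syn, nonsyn) differences between codons a and b.

    All shortest substitution pathways are enumerated; pathways passing through
    a stop codon are discarded.  If every pathway is blocked by stops, the
    average falls back to all pathways (rare; keeps the estimator total = #diffs).
    """
    diffs = [pos for pos in range(3)
             if ((a >> (2 * (2 - pos))) & 3) != ((b >> (2 * (2 - pos))) & 3)]
    if not diffs:
        return 0.0, 0.0

    def step(codon: int, pos: int) -> int:
        shift = 2 * (2 - pos)
        target_nt = (b >> shift) & 3
        return (codon & ~(3 << shift)) | (target_nt << shift)

    paths = []
    for order in itertools.permutations(diffs):
        cur = a
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = step(cur, pos)
            if is_stop[nxt] and nxt != b:
                blocked = True
            if aa[cur] == aa[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        paths.append((blocked, syn, nonsyn))
    valid = [(s, n) for blocked, s, n in paths if not blocked]
    if not valid:
        valid = [(s, n) for _, s, n in paths]
    syn = sum(s for s, _ in valid) / len(valid)
    nonsyn = sum(n for _, n in valid) / len(valid)
    return syn, nonsyn


@lru_cache(maxsize=None)
def get_tables(code_id: int = 6) -> CodeTables:
    """Build (and cache) lookup tables for a genetic code id."""
    table = CodonTable.unambiguous_dna_by_id[code_id]
    aa = np.empty(64, dtype="<U1")
    is_stop = np.zeros(64, dtype=bool)
    for i in range(64):
        codon = index_codon(i)
        if codon in table.stop_codons:
            aa[i] = "*"
            is_stop[i] = True
        else:
            aa[i] = table.forward_table[codon]

    syn_sites = np.zeros(64)
    for i in range(64):
        if is_stop[i]:
            continue
        s = 0.0
        for pos in range(3):
            changes = [(j) for j, p, _ in _neighbors(i) if p == pos]
            non_stop = [j for j in changes if not is_stop[j]]
            if not non_stop:
                continue
            syn = sum(1 for j in non_stop if aa[j] == aa[i])
            s += syn / len(non_stop)
        syn_sites[i] = s
    nonsyn_sites = np.where(is_stop, 0.0, 3.0 - syn_sites)

    sd = np.zeros((64, 64))
    nd = np.zeros((64, 64))
    for i in range(64):
        if is_stop[i]:
            continue
        for j in range(64):
            if is_stop[j]:
                continue
            sd[i, j], nd[i, j] = _pathway_counts(i, j, aa, is_stop)

    nb_codon = np.zeros((64, 9), dtype=np.int64)
    nb_syn = np.zeros((64, 9), dtype=bool)
    nb_ts = np.zeros((64, 9), dtype=bool)
    nb_valid = np.zeros((64, 9), dtype=bool)
    for i in range(64):
        if is_stop[i]:
            continue
        for k, (j, pos, new) in enumerate(_neighbors(i)):
            old = [(i >> 4) & 3, (i >> 2) & 3, i & 3][pos]
            nb_codon[i, k] = j
            nb_ts[i, k] = _PURINE[old] == _PURINE[new]
            nb_syn[i, k] = aa[i] == aa[j]
            nb_valid[i, k] = not is_stop[j]

    return CodeTables(
        code_id=code_id, aa=aa, is_stop=is_stop,
        syn_sites=syn_sites, nonsyn_sites=nonsyn_sites, sd=sd, nd=nd,
        nb_codon=nb_codon, nb_syn=nb_syn, nb_ts=nb_ts, nb_valid=nb_valid,
    )


def gc_content(seq: str) -> float:
    """G+C fraction of a sequence."""
    if not seq:
        raise ValueError("empty sequence")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)
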