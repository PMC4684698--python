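"""Continuous-time codon substitution simulator.

The model is deliberately minimal: equal codon frequencies, an HKY-style
transition/transversion multiplier kappa at the nucleotide level, and a
per-codon omega multiplier on nonsynonymous changes.  Stop codons are never
introduced (rates into stops are zero).  Time is measured in expected
synonymous substitutions per synonymous site, so a branch of length t
accumulates dS ~ t regardless of omega; the rate matrix is rescaled per
(code, kappa) to make that hold at a uniform sense-codon composition.

The simulator is vectorized over codons: each codon is an independent CTMC,
simulated by repeated rounds of exponential waiting times, so whole batches
of sequences can be evolved in one call by concatenation.
"""

from __future__ import annotations

from io import StringIO

import numpy as np
from skbio import TreeNode

from ._codes import decode_codons, encode_codons, get_tables

__all__ = ["CodonModel", "evolve_codon_sequences", "random_coding_sequence"]


class CodonModel:
    """Precomputed substitution machinery for one (genetic code, kappa)."""

    def __init__(self, code_id: int = 6, kappa: float = 1.0):
        if kappa <= 0:
            raise ValueError("kappa must be positive")
        self.code_id = code_id
        self.kappa = float(kappa)
        t = get_tables(code_id)
        self.tables = t
        base = np.where(t.nb_ts, self.kappa, 1.0) * t.nb_valid  # (64, 9)
        self.nb_codon = t.nb_codon
        self.nb_rate_syn = base * t.nb_syn
        self.nb_rate_nonsyn = base * ~t.nb_syn
        self.rate_syn = self.nb_rate_syn.sum(axis=1)      # (64,)
        self.rate_nonsyn = self.nb_rate_nonsyn.sum(axis=1)
        sense = ~t.is_stop
        # time scaling: expected dS per unit time = 1 at uniform sense codons
        mean_syn_rate = self.rate_syn[sense].mean()
        mean_syn_sites = t.syn_sites[sense].mean()
        self.mu = mean_syn_sites / mean_syn_rate
        self.sense_codons = np.flatnonzero(sense)

    def evolve(self, codons: np.ndarray, t: float, omega,
               rng: np.random.Generator) -> np.ndarray:
        """Evolve an int codon array for time t (dS units). Returns a copy.

        ``omega`` may be a scalar or a per-codon array (region-specific rates).
        """
        if t < 0:
            raise ValueError("negative branch length")
        cur = np.array(codons, dtype=np.int64)
        if self.tables.is_stop[cur].any():
            raise ValueError(f"stop codon in input under code {self.code_id}")
        omega = np.broadcast_to(np.asarray(omega, dtype=float), cur.shape).copy()
        if (omega < 0).any():
            raise ValueError("omega must be >= 0")
        if t == 0:
            return cur
        remaining = np.full(cur.shape, float(t))
        active = np.arange(cur.size)
        while active.size:
            c = cur[active]
            rate = self.mu * (self.rate_syn[c] + omega[active] * self.rate_nonsyn[c])
            with np.errstate(divide="ignore"):
                wait = rng.exponential(size=c.size) / rate
            jump = wait < remaining[active]
            idx = active[jump]
            if idx.size:
                remaining[idx] -= wait[jump]
                cj = cur[idx]
                w = self.nb_rate_syn[cj] + omega[idx, None] * self.nb_rate_nonsyn[cj]
                cum = np.cumsum(w, axis=1)
                u = rng.random(idx.size) * cum[:, -1]
                pick = (cum < u[:, None]).sum(axis=1)
                cur[idx] = self.nb_codon[cj, pick]
            active = idx
        return cur


def random_coding_sequence(n_codons: int, rng: np.random.Generator,
                           code_id: int = 6, gc: float = 0.33) -> str:
    """A random stop-free CDS with codons drawn by per-base GC bias."""
    t = get_tables(code_id)
    sense = np.flatnonzero(~t.is_stop)
    p_base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])  # A C G T
    w = np.array([p_base[(c >> 4) & 3] * p_base[(c >> 2) & 3] * p_base[c & 3]
                  for c in sense])
    w /= w.sum()
    codons = rng.choice(sense, size=n_codons, p=w)
    return decode_codons(codons)


def _read_tree(tree) -> TreeNode:
    if isinstance(tree, TreeNode):
        return tree
    return TreeNode.read(StringIO(str(tree)), convert_underscores=False)


def evolve_codon_sequences(tree, root_cds: str, omega_by_region,
                           kappa: float = 1.0, code_id: int = 6,
                           rng: np.random.Generator | None = None,
                           internal: bool = False) -> dict[str, str]:
    """Evolve a root CDS down a tree; returns per-leaf (optionally per-node) CDS.

    Parameters
    ----------
    tree : newick string or skbio TreeNode with branch lengths in dS units
    omega_by_region : scalar, per-codon array, or list of ((start, end), omega)
        intervals in nucleotide CDS coordinates.
    """
    rng = rng or np.random.default_rng()
    model = CodonModel(code_id=code_id, kappa=kappa)
    root = encode_codons(root_cds)
    if model.tables.is_stop[root].any():
        raise ValueError(f"root contains a stop codon under code {code_id}")
    omega = np.empty(root.size)
    if np.isscalar(omega_by_region):
        omega[:] = omega_by_region
    elif (isinstance(omega_by_region, (list, tuple)) and omega_by_region
          and isinstance(omega_by_region[0], (list, tuple))
          and len(omega_by_region[0]) == 2
          and isinstance(omega_by_region[0][0], (list, tuple))):
        omega[:] = np.nan
        for (s, e), w in omega_by_region:
            if s % 3 or e % 3:
                raise ValueError("region bounds must be codon-aligned")
            omega[s // 3:e // 3] = w
        if np.isnan(omega).any():
            raise ValueError("omega regions do not cover the CDS")
    else:
        omega[:] = np.asarray(omega_by_region, dtype=float)

    t = _read_tree(tree)
    out: dict[str, str] = {}
    stack = [(t, root)]
    while stack:
        node, seq = stack.pop()
        for child in node.children:
            bl = child.length or 0.0
            child_seq = model.evolve(seq, bl, omega, rng)
            if child.is_tip():
                out[child.name] = decode_codons(child_seq)
            else:
                if internal and child.name:
                    out[child.name] = decode_codons(child_seq)
                stack.append((child, child_seq))
    if internal and t.name:
        out[t.name] = root_cds
    return out
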