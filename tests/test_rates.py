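"""NG86 dN/dS, codon alignment, region partition and the paired test."""

import itertools
import math

import numpy as np
import pytest
from Bio.Data import CodonTable

from mdsweave.rates import (RateRecord, SaturationError, aa_distance,
                            codon_align_from_protein, filter_rate_records,
                            ng86_counts, ng86_dnds, paired_signed_rank,
                            partition_regions, split_codon_alignment_by_region)

# ---------------------------------------------------------------------------
# an independent brute-force oracle for NG86 site/difference counting

NT = "ACGT"


def _oracle_code(code_id):
    table = CodonTable.unambiguous_dna_by_id[code_id]

    def aa(codon):
        return "*" if codon in table.stop_codons else table.forward_table[codon]

    return aa


def oracle_sites(codon, aa):
    """Synonymous sites: per position, the synonymous fraction of the
    non-stop single-nucleotide changes."""
    s = 0.0
    for pos in range(3):
        changes = [codon[:pos] + nt + codon[pos + 1:]
                   for nt in NT if nt != codon[pos]]
        non_stop = [c for c in changes if aa(c) != "*"]
        if non_stop:
            s += sum(aa(c) == aa(codon) for c in non_stop) / len(non_stop)
    return s, 3.0 - s


def oracle_diffs(a, b, aa):
    """Pathway-averaged (syn, nonsyn) differences, stop pathways excluded."""
    diffs = [i for i in range(3) if a[i] != b[i]]
    if not diffs:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diffs):
        cur, syn, nonsyn, blocked = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1:]
            if aa(nxt) == "*" and nxt != b:
                blocked = True
            syn += aa(cur) == aa(nxt)
            nonsyn += aa(cur) != aa(nxt)
            cur = nxt
        results.append((blocked, syn, nonsyn))
    valid = [(s, n) for bl, s, n in results if not bl] or \
        [(s, n) for _, s, n in results]
    return (sum(s for s, _ in valid) / len(valid),
            sum(n for _, n in valid) / len(valid))


def _random_sense_codons(rng, n, aa):
    out = []
    while len(out) < n:
        c = "".join(rng.choice(list(NT), size=3))
        if aa(c) != "*":
            out.append(c)
    return out


@pytest.mark.parametrize("code_id", [1, 6, 10])
def test_ng86_matches_bruteforce_oracle(code_id, rng):
    aa = _oracle_code(code_id)
    for _ in range(120):
        n = int(rng.integers(1, 6))
        ca = _random_sense_codons(rng, n, aa)
        cb = _random_sense_codons(rng, n, aa)
        S, N, sd, nd, _ = ng86_counts("".join(ca), "".join(cb), code_id)
        eS = eN = esd = end_ = 0.0
        for x, y in zip(ca, cb):
            sx, nx = oracle_sites(x, aa)
            sy, ny = oracle_sites(y, aa)
            eS += (sx + sy) / 2
            eN += (nx + ny) / 2
            s, n_ = oracle_diffs(x, y, aa)
            esd += s
            end_ += n_
        assert S == pytest.approx(eS) and N == pytest.approx(eN)
        assert sd == pytest.approx(esd) and nd == pytest.approx(end_)


class TestNG86:
    def test_hand_counted_example(self):
        # one synonymous 3rd-position Gly change over 3 codons
        r = ng86_dnds("ATGGGTGCT", "ATGGGCGCT", code_id=1)
        assert (r.syn_sites, r.nonsyn_sites) == (2.0, 7.0)
        assert (r.syn_diffs, r.nonsyn_diffs) == (1.0, 0.0)
        assert r.dn == 0.0
        assert r.ds == pytest.approx(-0.75 * math.log(1 / 3), rel=1e-9)

    def test_identical_sequences(self):
        r = ng86_dnds("ATGGGT", "ATGGGT")
        assert r.dn == r.ds == 0.0 and r.omega is None

    def test_ciliate_code_makes_caa_taa_synonymous(self):
        # TAA is Gln under the ciliate nuclear code: a synonymous difference
        S, N, sd, nd, _ = ng86_counts("CAA", "TAA", code_id=6)
        assert (sd, nd) == (1.0, 0.0)
        # under the universal code the same pair is invalid (stop codon)
        with pytest.raises(ValueError, match="stop"):
            ng86_counts("CAA", "TAA", code_id=1)
        # ... and the Euplotes code reads TGA as Cys
        S, N, sd, nd, _ = ng86_counts("TGT", "TGA", code_id=10)
        assert (sd, nd) == (1.0, 0.0)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            ng86_dnds("CAA", "TAA", code_id=6)  # pS = 1.5 on a single codon


class TestCodonAlignment:
    def test_identical_proteins_ungapped(self, tables6):
        cds = "ATGGGTGCTCAA"
        prot = tables6.translate(cds)
        a, b = codon_align_from_protein(prot, prot, cds, cds)
        assert a == b == cds

    def test_one_residue_gap_becomes_3nt_gap(self, tables6):
        cds_a = "ATGAAAGAAGATCTTTGGTGGCCA"
        cds_b = "ATGAAAGATCTTTGGTGGCCA"  # GAA codon deleted
        pa, pb = tables6.translate(cds_a), tables6.translate(cds_b)
        a, b = codon_align_from_protein(pa, pb, cds_a, cds_b)
        assert a == cds_a
        assert b.count("-") == 3 and b.replace("---", "") == cds_b
        assert b.index("---") % 3 == 0

    def test_length_mismatch_raises(self, tables6):
        with pytest.raises(ValueError, match="3 x"):
            codon_align_from_protein("MK", "MK", "ATGAAAA", "ATGAAA")


class TestRegionPartition:
    def test_all_shared_gives_empty_alternative(self):
        part = partition_regions("g", 300, np.ones(300, dtype=bool))
        assert part.alternative == [] and part.constitutive == [(0, 300)]

    def test_partition_conserves_length(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 50)) * 3
            mask = rng.random(n) < 0.5
            part = partition_regions("g", n, mask)
            assert part.alternative_nt + part.constitutive_nt == n

    def test_midcodon_boundary_majority_rule(self):
        # boundary after 4 nt: codon 2 has 1 shared + 2 unique bases
        mask = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0], dtype=bool)
        part = partition_regions("g", 9, mask)
        assert part.constitutive == [(0, 3)]
        assert part.alternative == [(3, 9)]
        # 2 shared of 3 -> the boundary codon goes constitutive
        mask = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0], dtype=bool)
        part = partition_regions("g", 9, mask)
        assert part.constitutive == [(0, 6)]


def test_split_codon_alignment_routes_columns():
    cls = np.array([False, True, True])
    a = "AAA---CCCGGG"
    b = "AAATTTCCC---"
    out = split_codon_alignment_by_region(a, b, cls)
    assert out["constitutive"] == ("AAA", "AAA")
    assert out["alternative"] == ("CCC", "CCC")  # the gapped columns drop


class TestFilterRateRecords:
    def _rec(self, gene, region, nt, ds):
        return RateRecord("c", gene, region, nt, nt // 3, 0.0, 0.0, 0.01, ds,
                          0.1 if ds else None)

    def test_low_ds_excludes_gene(self):
        recs = [self._rec("g", "alternative", 300, 0.2),
                self._rec("g", "constitutive", 300, 0.005)]
        assert filter_rate_records(recs) == []

    def test_short_region_excludes_gene(self):
        recs = [self._rec("g", "alternative", 149, 0.2),
                self._rec("g", "constitutive", 300, 0.3)]
        assert filter_rate_records(recs) == []
        # 150 is not "longer than 150 nt" either: strict inequality
        recs[0].region_nt = 150
        assert filter_rate_records(recs) == []

    def test_passing_gene_retained(self):
        recs = [self._rec("g", "alternative", 300, 0.2),
                self._rec("g", "constitutive", 300, 0.3)]
        assert len(filter_rate_records(recs)) == 2


class TestPairedSignedRank:
    def test_all_positive_n6_exact(self):
        _, p = paired_signed_rank([1, 2, 3, 4, 5, 6], [0] * 6)
        assert p == pytest.approx(2 / 64)

    def test_all_zero_differences(self):
        with pytest.warns(UserWarning):
            _, p = paired_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0

    def test_symmetric_pattern_p_one(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        b = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]  # differences +-1 symmetric
        _, p = paired_signed_rank(a, b)
        assert p == pytest.approx(1.0)


class TestAaDistance:
    def test_identical(self):
        d = aa_distance("MKV", "MKV")
        assert d.p_distance == 0.0 and d.poisson == 0.0

    def test_closed_form_one_mismatch(self):
        d = aa_distance("A" * 99 + "K", "A" * 99 + "R")
        assert d.p_distance == pytest.approx(0.01)
        assert d.poisson == pytest.approx(-math.log(0.99))

    def test_saturated_flagged(self):
        d = aa_distance("AAAA", "KKKK")
        assert d.saturated and math.isinf(d.poisson)

    def test_gaps_excluded(self):
        d = aa_distance("MK-V", "MKAV")
        assert d.n_compared == 3 and d.p_distance == 0.0

    def test_no_comparable_columns_raises(self):
        with pytest.raises(ValueError):
            aa_distance("--", "AA")
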