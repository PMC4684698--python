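"""Sharing-case detection, the three filters, topology, Table-1 summary."""

import pytest

from mdsweave.detect import (SharingCase, apply_filters, classify_topology,
                             find_sharing_groups, shared_coding_fraction,
                             summarize_cases)
from mdsweave.rearrangement import (MDS, GeneModel, MACChromosome, MDSTarget,
                                    MICLocus)
from mdsweave._codes import revcomp


def _locus_with_shared(chrom_ids, length=60):
    """One locus whose single MDS targets every listed chromosome."""
    mds = MDS("L1", 1, 0, length, "+",
              [MDSTarget(c, 1, 0, length) for c in chrom_ids])
    return {"L1": MICLocus("L1", "c1", "A" * length, [mds])}


class TestFindSharingGroups:
    def test_one_mds_two_chromosomes_one_case(self):
        loci = _locus_with_shared(["X", "Y"])
        cases = find_sharing_groups(loci, {})
        assert len(cases) == 1 and cases[0].chrom_ids == ["X", "Y"]

    def test_no_multitarget_mds_empty(self):
        loci = _locus_with_shared(["X"])
        assert find_sharing_groups(loci, {}) == []

    def test_five_target_mds_case_of_five(self):
        loci = _locus_with_shared(list("VWXYZ"))
        (case,) = find_sharing_groups(loci, {})
        assert len(case.chrom_ids) == 5


def _simple_case(shared_end, cds_start, cds_end, seqs=None, n_genes=2,
                 multi=False):
    """Two (or more) single-gene chromosomes sharing a 5' block [0, shared_end)."""
    ids = [f"G{i}" for i in range(n_genes)]
    seqs = seqs or {c: "ACGT" * 75 for c in ids}
    chroms = {c: MACChromosome(c, seqs[c],
                               genes=[GeneModel(c, "+", [(cds_start, cds_end)])])
              for c in ids}
    case = SharingCase("case", "L", ids, [1],
                       {c: [(0, shared_end)] for c in ids},
                       scrambled_chroms={c: False for c in ids})
    return case, chroms


class TestApplyFilters:
    def test_noncoding_chromosome_rule1(self):
        case, chroms = _simple_case(60, 40, 220)
        chroms["G1"].genes = []
        kept, removed = apply_filters([case], chroms)
        assert kept == [] and removed[0].rule == 1

    def test_identical_single_shared_gene_rule2(self, small_dataset):
        from mdsweave.detect import find_sharing_groups
        cases = find_sharing_groups(small_dataset.loci,
                                    small_dataset.chromosomes)
        kept, removed = apply_filters(cases, small_dataset.chromosomes)
        by_rule = {}
        for r in removed:
            by_rule.setdefault(r.rule, []).append(r.case_id)
        decoys = small_dataset.truth.decoys
        assert sorted(by_rule.get(1, [])) == sorted(decoys["noncoding"])
        assert sorted(by_rule.get(2, [])) == sorted(decoys["identical_gene"])
        assert sorted(by_rule.get(3, [])) == sorted(decoys["low_penetration"])
        assert {c.case_id for c in kept} == \
            {c.case_id for c in small_dataset.truth.cases}

    def test_19nt_penetration_removed_20_retained(self):
        # shared region [0, 59) reaches 19 nt into a CDS starting at 40
        case, chroms = _simple_case(59, 40, 220)
        kept, removed = apply_filters([case], chroms)
        assert kept == [] and removed[0].rule == 3
        # exactly 20 nt: the rule is strict "< 20", so the case stays
        case, chroms = _simple_case(60, 40, 220)
        kept, removed = apply_filters([case], chroms)
        assert len(kept) == 1 and removed == []

    def test_missing_gene_model_record_is_an_error(self):
        case, chroms = _simple_case(60, 40, 220)
        del chroms["G1"]
        with pytest.raises(KeyError, match="G1"):
            apply_filters([case], chroms)


class TestClassifyTopology:
    def test_shared_prefix_is_share5(self):
        case, chroms = _simple_case(100, 40, 220)
        assert classify_topology(case, chroms).topology == "share5"
        assert not case.topology_ambiguous

    def test_blocks_at_both_ends_is_both(self):
        ids = ["G0", "G1"]
        chroms = {c: MACChromosome(c, "ACGT" * 75,
                                   genes=[GeneModel(c, "+", [(40, 220)])])
                  for c in ids}
        case = SharingCase("case", "L", ids, [1, 2],
                           {c: [(0, 70), (200, 300)] for c in ids},
                           scrambled_chroms={c: False for c in ids})
        assert classify_topology(case, chroms).topology == "both"

    def test_opposite_strand_share3(self):
        """Shared block at each gene's coding 3' end despite opposite
        chromosome strands."""
        fwd_seq = "ACGT" * 75
        rev_seq = revcomp(fwd_seq)
        chroms = {
            "F": MACChromosome("F", fwd_seq,
                               genes=[GeneModel("F", "+", [(40, 220)])]),
            "R": MACChromosome("R", rev_seq,
                               genes=[GeneModel("R", "-", [(80, 260)])]),
        }
        # F: 3' end at 219 -> shared [150, 300); R ('-'): 3' end at base 80
        case = SharingCase("case", "L", ["F", "R"], [1],
                           {"F": [(150, 300)], "R": [(0, 150)]},
                           scrambled_chroms={"F": False, "R": False})
        assert classify_topology(case, chroms).topology == "share3"

    def test_mixed_termini_flagged_ambiguous(self):
        chroms = {
            "G0": MACChromosome("G0", "ACGT" * 75,
                                genes=[GeneModel("G0", "+", [(40, 220)])]),
            "G1": MACChromosome("G1", "ACGT" * 75,
                                genes=[GeneModel("G1", "+", [(40, 220)])]),
        }
        case = SharingCase("case", "L", ["G0", "G1"], [1],
                           {"G0": [(0, 100)], "G1": [(100, 180)]},  # internal in G1
                           scrambled_chroms={"G0": False, "G1": False})
        classify_topology(case, chroms)
        assert case.topology_ambiguous and case.topology == "share5"


class TestSharedCodingFraction:
    def test_entire_cds_shared(self):
        case, chroms = _simple_case(300, 40, 220)
        fr = shared_coding_fraction(case, chroms).shared_coding_fraction
        assert fr == {"G0": 1.0, "G1": 1.0}

    def test_simple_arithmetic(self):
        seqs = {"G0": "A" * 1100, "G1": "A" * 1100}
        case, chroms = _simple_case(400, 100, 1100, seqs=seqs)
        fr = shared_coding_fraction(case, chroms).shared_coding_fraction
        assert fr["G0"] == pytest.approx(300 / 1000)

    def test_shortest_shared_portion_used_for_all(self):
        """Genes sharing 400/450/500 nt of one MDS run all use 400 nt."""
        ids = ["G0", "G1", "G2"]
        chroms = {c: MACChromosome(c, "A" * 1200,
                                   genes=[GeneModel(c, "+", [(100, 1100)])])
                  for c in ids}
        shared = {"G0": [(100, 500)], "G1": [(100, 550)], "G2": [(100, 600)]}
        case = SharingCase("case", "L", ids, [1], shared,
                           scrambled_chroms={c: False for c in ids})
        fr = shared_coding_fraction(case, chroms).shared_coding_fraction
        assert all(v == pytest.approx(400 / 1000) for v in fr.values())

    def test_zero_length_cds_raises(self):
        case, chroms = _simple_case(60, 40, 220)
        chroms["G0"].genes[0].cds_intervals = [(40, 40)]
        with pytest.raises(ValueError, match="zero-length"):
            shared_coding_fraction(case, chroms)


class TestSummary:
    def test_empty_input_all_zero(self):
        s = summarize_cases([])
        assert all(v == 0 for row in (s.loci, s.chromosomes, s.mds)
                   for v in row.values())

    def test_column_sums_match_totals(self, small_dataset):
        cases = find_sharing_groups(small_dataset.loci,
                                    small_dataset.chromosomes)
        kept, _ = apply_filters(cases, small_dataset.chromosomes)
        for c in kept:
            classify_topology(c, small_dataset.chromosomes)
        s = summarize_cases(kept)
        for row in (s.loci, s.chromosomes):
            assert row["share5"] + row["share3"] + row["both"] == row["total"]
            assert row["nonscrambled"] + row["scrambled"] == row["total"]
        assert s.mds["nonscrambled"] + s.mds["scrambled"] == s.mds["total"]


def test_detection_recovers_planted_truth(small_dataset):
    """Zero-noise recovery: cases, topology and scrambled flags equal truth."""
    cases = find_sharing_groups(small_dataset.loci, small_dataset.chromosomes)
    kept, _ = apply_filters(cases, small_dataset.chromosomes)
    truth = {c.case_id: c for c in small_dataset.truth.cases}
    assert {c.case_id for c in kept} == set(truth)
    for c in kept:
        classify_topology(c, small_dataset.chromosomes)
        t = truth[c.case_id]
        assert c.topology == t.topology and not c.topology_ambiguous
        assert c.scrambled == t.scrambled
        assert c.scrambled_chroms == t.scrambled_chroms
        assert sorted(c.chrom_ids) == sorted(t.chrom_ids.values())


def test_no_false_positives_without_sharing():
    from mdsweave.simulate import SimulationConfig, simulate_dataset
    cfg = SimulationConfig(seed=9, n_loci=0, n_background_genes=40,
                           n_decoy_noncoding=0, n_decoy_identical=0,
                           n_decoy_low_penetration=0)
    ds = simulate_dataset(cfg)
    assert find_sharing_groups(ds.loci, ds.chromosomes) == []
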