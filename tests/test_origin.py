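"""Origin dating, gene-tree correction, mechanism and GC classification."""

import numpy as np
import pytest

from mdsweave.origin import (OriginCall, PhyleticStates, build_gene_tree,
                             check_shared_length_conservation,
                             classify_alternative_origin,
                             correct_origin_with_gene_tree, flag_low_gc,
                             gc_baseline, infer_origin_node,
                             read_species_tree, species_presence_state)
from mdsweave.simulate import DEFAULT_TREE, FOCAL

TREE = DEFAULT_TREE.format(d=0.075)


def _states(case_id, present_b, tree):
    """States where the novel gene is present exactly in ``present_b``."""
    species = [t.name for t in read_species_tree(tree).tips()]
    return PhyleticStates(case_id, {
        sp: ("both_present_sharing" if sp in present_b else "only_A_present")
        for sp in species})


class TestSpeciesPresenceState:
    RECS = {
        "X": {"a_present": True, "b_present": True, "sharing": True},
        "Y": {"a_present": True, "b_present": False, "sharing": None},
        "Z": {"a_present": False, "b_present": False, "sharing": None},
        FOCAL: {"a_present": True, "b_present": True, "sharing": True},
    }

    def test_three_scenarios(self):
        st = species_presence_state("c", self.RECS, FOCAL)
        assert st.states["X"] == "both_present_sharing"
        assert st.states["Y"] == "only_A_present"
        assert st.states["Z"] == "neither_present"

    def test_both_present_not_sharing_is_contradiction(self):
        recs = dict(self.RECS)
        recs["X"] = {"a_present": True, "b_present": True, "sharing": False}
        st = species_presence_state("c", recs, FOCAL)
        assert st.contradictions == ["X"] and "X" not in st.states

    def test_focal_must_share(self):
        recs = {FOCAL: {"a_present": True, "b_present": False, "sharing": None}}
        with pytest.raises(ValueError):
            species_presence_state("c", recs, FOCAL)

    def test_generator_output_never_contradicts(self, small_dataset):
        for ct in small_dataset.truth.cases:
            st = species_presence_state(ct.case_id, ct.presence, FOCAL)
            assert st.contradictions == []


class TestInferOriginNode:
    def test_focal_strains_only(self):
        tree = read_species_tree(TREE)
        st = _states("c", {"Oxytricha_JRB310", "Oxytricha_JRB510"}, TREE)
        assert infer_origin_node(tree, st).name == "NOxy"

    def test_present_everywhere_is_root(self):
        tree = read_species_tree(TREE)
        st = _states("c", {t.name for t in tree.tips()}, TREE)
        assert infer_origin_node(tree, st).name == "root"

    def test_absent_everywhere_errors(self):
        tree = read_species_tree(TREE)
        st = PhyleticStates("c", {t.name: "only_A_present" for t in tree.tips()})
        with pytest.raises(ValueError):
            infer_origin_node(tree, st)

    def test_matches_bruteforce_minimal_clade(self, rng):
        """MRCA rule == exhaustive smallest-superset-clade search."""
        tree = read_species_tree(TREE)
        leaves = [t.name for t in tree.tips()]
        nodes = [n for n in tree.traverse(include_self=True) if not n.is_tip()]
        for _ in range(50):
            k = int(rng.integers(1, len(leaves) + 1))
            present = set(rng.choice(leaves, size=k, replace=False).tolist())
            got = infer_origin_node(tree, PhyleticStates("c", {
                sp: ("both_present_sharing" if sp in present
                     else "only_A_present") for sp in leaves}))
            best = None
            for n in nodes + [tree.find(x) for x in leaves]:
                clade = {t.name for t in n.tips()} or {n.name}
                if present <= clade:
                    if best is None or len(clade) < len(best[1]):
                        best = (n, clade)
            assert got.name == best[0].name


class TestGeneTree:
    def test_identical_sequences_zero_branches(self):
        seqs = {"a": "MKVLAW" * 20, "b": "MKVLAW" * 20,
                "c": "MKVLAW" * 20, "out": "MKVLAW" * 20}
        res = build_gene_tree(seqs, "out", aligned=True)
        assert all((n.length or 0) == pytest.approx(0, abs=1e-9)
                   for n in res.tree.traverse())

    def test_fewer_than_three_sequences_rejected(self):
        with pytest.raises(ValueError):
            build_gene_tree({"a": "MK", "b": "MK"}, "a")

    def test_outgroup_on_root_pendant_edge(self, rng):
        base = list("ACDEFGHIKLMNPQRSTVWY" * 10)
        def mutate(s, n):
            s = list(s)
            pos = rng.choice(len(s), size=n, replace=False)
            for p in pos:
                s[p] = "W" if s[p] != "W" else "Y"
            return "".join(s)
        seqs = {"a": "".join(base), "b": mutate(base, 6),
                "c": mutate(base, 60), "out": mutate(base, 120)}
        res = build_gene_tree(seqs, "out")
        children = res.tree.children
        sides = [{t.name for t in (c.tips() or [c])} or {c.name}
                 for c in children]
        assert {"out"} in sides

    def test_nj_recovers_additive_topology(self, rng):
        """Four sequences with ((a,b),(c,d)) additive distances."""
        n = 400
        base = rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n)

        def mutate(s, positions):
            s = np.array(s)
            for p in positions:
                s[p] = "W" if s[p] != "W" else "Y"
            return s

        blocks = {"ab": range(0, 30), "cd": range(30, 90),
                  "a": range(90, 100), "b": range(100, 110),
                  "c": range(110, 120), "d": range(120, 130)}
        seqs = {
            "a": "".join(mutate(base, list(blocks["ab"]) + list(blocks["a"]))),
            "b": "".join(mutate(base, list(blocks["ab"]) + list(blocks["b"]))),
            "c": "".join(mutate(base, list(blocks["cd"]) + list(blocks["c"]))),
            "d": "".join(mutate(base, list(blocks["cd"]) + list(blocks["d"]))),
        }
        res = build_gene_tree(seqs, "d", aligned=True)
        # with the root on d's edge, (a,b) must form a clade
        clades = [{t.name for t in c.tips()} for c in res.tree.traverse()
                  if not c.is_tip()]
        assert {"a", "b"} in clades

    def test_mafft_alignment_path(self):
        """Unequal-length inputs go through the external aligner."""
        seqs = {"a": "MKVLAWEDKHNP" * 6, "b": "MKVLAWEDKHNP" * 6,
                "c": ("MKVLAWEDKHNP" * 6)[3:], "out": "MKVLAWEDKHNP" * 6}
        res = build_gene_tree(seqs, "out")
        assert {t.name for t in res.tree.tips()} == {"a", "b", "c", "out"}


class TestCorrection:
    def _gene_tree(self, newick):
        from io import StringIO
        from skbio import TreeNode
        return TreeNode.read(StringIO(newick), convert_underscores=False)

    def test_congruent_tree_no_correction(self):
        sp_tree = read_species_tree(TREE)
        gt = self._gene_tree(
            "((Oxytricha_JRB310|A,Oxytricha_JRB510|A),"
            "(Oxytricha_JRB310|B,Oxytricha_JRB510|B),(Euplotes|A));")
        call = OriginCall("c", "NOxy")
        out = correct_origin_with_gene_tree(
            call, gt, sp_tree, "Oxytricha_JRB310|A", "Oxytricha_JRB310|B",
            ["Oxytricha_JRB310", "Oxytricha_JRB510"])
        assert not out.corrected

    def test_discordant_tree_moves_origin_and_records_loss(self):
        # Sterkiella's only copy clusters with the B clade: the duplication
        # must predate the Sterkiella split and the A copy was lost there
        sp_tree = read_species_tree(TREE)
        gt = self._gene_tree(
            "((Oxytricha_JRB310|A,Oxytricha_JRB510|A),"
            "((Oxytricha_JRB310|B,Oxytricha_JRB510|B),Sterkiella|A),"
            "(Euplotes|A));")
        call = OriginCall("c", "NOxy")
        out = correct_origin_with_gene_tree(
            call, gt, sp_tree, "Oxytricha_JRB310|A", "Oxytricha_JRB310|B",
            ["Oxytricha_JRB310", "Oxytricha_JRB510"])
        assert out.corrected and out.corrected_node == "NSte"
        assert out.implied_losses == ["Sterkiella"]

    def test_leaf_label_mismatch_errors(self):
        sp_tree = read_species_tree(TREE)
        gt = self._gene_tree("((x|A,y|A),(x|B));")
        with pytest.raises(Exception):
            correct_origin_with_gene_tree(OriginCall("c", "NOxy"), gt, sp_tree,
                                          "Oxytricha_JRB310|A",
                                          "Oxytricha_JRB310|B", [])


class TestClassifyAlternativeOrigin:
    def test_identical_proteins_duplication(self, rng):
        p = "MKVEDLLHAWNPQRSTIKER" * 6
        assert classify_alternative_origin(p, p, rng) == "duplication"

    def test_unrelated_random_proteins_no_similarity(self, rng):
        aas = list("ACDEFGHIKLMNPQRSTVWY")
        a = "".join(rng.choice(aas, size=120))
        b = "".join(rng.choice(aas, size=120))
        assert classify_alternative_origin(a, b, rng) == "no_similarity"

    def test_moderate_identity_full_coverage_duplication(self, rng):
        """~45% identity spread over the full length still passes >40%/>80%."""
        conservative = {"D": "E", "K": "R", "I": "V", "S": "T", "F": "Y",
                        "Q": "E", "N": "D", "L": "M", "A": "S", "H": "Y"}
        a = ("DKISFQNLAH" * 11)
        b_chars = []
        for i, ch in enumerate(a):
            # replace slightly more than half the residues conservatively
            b_chars.append(conservative[ch] if i % 9 < 5 else ch)
        b = "".join(b_chars)
        ident = sum(x == y for x, y in zip(a, b)) / len(a)
        assert 0.40 < ident < 0.50
        assert classify_alternative_origin(a, b, rng) == "duplication"

    def test_empty_region_errors(self, rng):
        with pytest.raises(ValueError):
            classify_alternative_origin("", "MKV", rng)


class TestGCFlag:
    def _baseline(self):
        def seq(gc_count, n=1000):
            return "G" * gc_count + "A" * (n - gc_count)
        return gc_baseline([seq(313), seq(313), seq(400), seq(450)])

    def test_values_below_quartile_flagged(self):
        base = self._baseline()
        assert base.lower_quartile == pytest.approx(0.313)
        assert flag_low_gc("G" * 261 + "A" * 739, base)       # 0.261
        assert flag_low_gc("G" * 310 + "A" * 690, base)       # 0.310

    def test_exactly_at_quartile_not_flagged(self):
        base = self._baseline()
        assert not flag_low_gc("G" * 313 + "A" * 687, base)

    def test_empty_sequence_errors(self):
        with pytest.raises(ValueError):
            flag_low_gc("", self._baseline())


class TestSharedLengthConservation:
    @pytest.mark.parametrize("focal,orth,expected", [
        (400, 430, True),    # 30 <= max(50, 40)
        (400, 460, False),   # 60 > 50
        (1000, 1090, True),  # 90 <= max(50, 100)
        (500, 500, True),
    ])
    def test_rule(self, focal, orth, expected):
        assert check_shared_length_conservation(focal, orth) is expected

    def test_nonpositive_lengths_error(self):
        with pytest.raises(ValueError):
            check_shared_length_conservation(0, 10)
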