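"""Synthetic-data generator: determinism, structure, planted truth."""

import numpy as np
import pytest

from mdsweave.expression import TIMEPOINTS, median_ratio_size_factors
from mdsweave.rearrangement import MDSMap
from mdsweave.simulate import (FOCAL, GENE_LABELS, STRAIN, SimulationConfig,
                               assign_orthologs_rbh, nb_counts,
                               plant_alternative_case, simulate_dataset)


def _tiny_cfg(**kw):
    base = dict(seed=1, n_loci=6, n_background_genes=5, n_decoy_noncoding=1,
                n_decoy_identical=1, n_decoy_low_penetration=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateDataset:
    def test_counts_by_construction(self):
        ds = simulate_dataset(_tiny_cfg())
        assert len(ds.truth.cases) == 6
        assert len([k for k in ds.loci if k.startswith("case")]) == 6
        # one MAC record set per species with any genes
        assert FOCAL in ds.mac_by_species and STRAIN in ds.mac_by_species
        for ct in ds.truth.cases:
            assert len(ct.chrom_ids) == ct.n_genes
            assert set(ct.gene_labels) == set(GENE_LABELS[:ct.n_genes])

    def test_same_seed_identical_output(self):
        ds1 = simulate_dataset(_tiny_cfg())
        ds2 = simulate_dataset(_tiny_cfg())
        assert {k: l.sequence for k, l in ds1.loci.items()} == \
               {k: l.sequence for k, l in ds2.loci.items()}
        assert ds1.expression.equals(ds2.expression)
        assert ds1.orthologs.equals(ds2.orthologs)
        assert ds1.truth.size_factors == ds2.truth.size_factors

    def test_scrambling_probability_zero_and_one(self):
        ds0 = simulate_dataset(_tiny_cfg(scrambled_prob=0.0))
        assert all(not c.scrambled for c in ds0.truth.cases)
        ds1 = simulate_dataset(_tiny_cfg(scrambled_prob=1.0))
        assert all(c.scrambled for c in ds1.truth.cases)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(scrambled_prob=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(omega_alternative=-1)

    def test_truth_traceability(self, small_dataset):
        """Every emitted case annotation refers back to one truth record."""
        truth_ids = {c.case_id for c in small_dataset.truth.cases}
        assert set(small_dataset.regions) == truth_ids
        assert set(small_dataset.orthologs.case_id) == truth_ids
        assert set(small_dataset.sharing.case_id) == truth_ids
        for ct in small_dataset.truth.cases:
            for chrom_id in ct.chrom_ids.values():
                assert chrom_id in small_dataset.chromosomes


class TestPlantAlternativeCase:
    def _plant(self, topology, n_genes, rng):
        cfg = SimulationConfig(seed=0)
        from mdsweave.evolution import random_coding_sequence

        def parts():
            return {
                "utr5": "ACGT" * 10, "utr3": "TTGCA" * 8,
                "alt": random_coding_sequence(80, rng),
                "shared5": random_coding_sequence(90, rng)
                if topology in ("share5", "both") else "",
                "shared3": random_coding_sequence(70, rng)
                if topology in ("share3", "both") else "",
            }

        shared = parts()
        gene_parts = {}
        for g in GENE_LABELS[:n_genes]:
            p = dict(shared)
            p["alt"] = random_coding_sequence(80, rng)
            gene_parts[g] = p
        return plant_alternative_case("caseX", topology, n_genes, gene_parts,
                                      rng, cfg, scrambled=False)

    def test_share5_two_genes_structure(self, rng):
        locus, chroms, flags = self._plant("share5", 2, rng)
        mds_map = MDSMap({"caseX": locus})
        shared = [m for m in locus.mds_list if m.is_shared]
        assert shared, "constitutive MDSs must exist"
        for m in shared:
            assert len({t.chrom_id for t in m.targets}) == 2
        # shared block occupies the 5' end: every shared target starts in the
        # first half of its chromosome
        for m in shared:
            for t in m.targets:
                assert t.start < len(chroms[t.chrom_id].sequence) / 2

    def test_five_genes_single_copy_shared(self, rng):
        locus, chroms, _ = self._plant("share5", 5, rng)
        shared = [m for m in locus.mds_list if m.is_shared]
        for m in shared:
            assert len({t.chrom_id for t in m.targets}) == 5

    def test_both_topology_unique_region_internal(self, rng):
        locus, chroms, _ = self._plant("both", 2, rng)
        for chrom_id, chrom in chroms.items():
            pairs = MDSMap({"caseX": locus}).targets_for(chrom_id)
            unique = [t for m, t in pairs if not m.is_shared]
            shared = [t for m, t in pairs if m.is_shared]
            assert min(t.start for t in shared) < min(t.start for t in unique)
            assert max(t.end for t in shared) > max(t.end for t in unique)

    def test_fewer_than_two_genes_rejected(self, rng):
        with pytest.raises(ValueError):
            self._plant("share5", 1, rng)


class TestExpressionSimulation:
    def test_dispersion_zero_counts_are_rounded_means(self, rng):
        means = np.array([1.2, 7.5, 100.4])
        assert (nb_counts(means, 0.0, rng) == np.array([1, 8, 100])).all()

    def test_size_factor_recovery(self):
        ds = simulate_dataset(_tiny_cfg(n_background_genes=400, dispersion=0.0))
        counts = ds.expression.set_index("region_id")[list(TIMEPOINTS)]
        est = median_ratio_size_factors(counts)
        planted = np.array([ds.truth.size_factors[t] for t in TIMEPOINTS])
        # factors are identifiable up to a constant scale
        ratio = est.to_numpy() / planted
        ratio /= np.exp(np.log(ratio).mean())
        assert np.abs(ratio - 1).max() < 0.05

    def test_planted_peaks_recorded(self, small_dataset):
        for ct in small_dataset.truth.cases:
            assert set(ct.peaks) == set(ct.gene_labels)
            assert all(0 <= p < len(TIMEPOINTS) for p in ct.peaks.values())


def test_assign_orthologs_rbh_identical_proteomes():
    prots = {"sp1": {"g1": "MKVLAWWK", "g2": "MEDEDLLH"},
             "sp2": {"g1x": "MKVLAWWK", "g2x": "MEDEDLLH"}}
    groups = assign_orthologs_rbh(prots)
    as_sets = [g for g in groups if len(g) > 1]
    assert {frozenset(g) for g in as_sets} == {
        frozenset({("sp1", "g1"), ("sp2", "g1x")}),
        frozenset({("sp1", "g2"), ("sp2", "g2x")})}


def test_assign_orthologs_rbh_missing_gene_leaves_gap():
    prots = {"sp1": {"g1": "MKVLAWWK", "g2": "MEDEDLLH"},
             "sp2": {"g1x": "MKVLAWWK"}}
    groups = assign_orthologs_rbh(prots)
    g2_group = next(g for g in groups if ("sp1", "g2") in g)
    assert {s for s, _ in g2_group} == {"sp1"}


def test_rbh_recovers_simulated_truth_groups(small_dataset, tables6):
    """RBH on the focal+strain proteomes reproduces the emitted pairing."""
    df = small_dataset.orthologs
    hits = total = 0
    for ct in small_dataset.truth.cases[:6]:
        sub = df[df.case_id == ct.case_id]
        prots = {}
        for sp in (FOCAL, STRAIN):
            rows = sub[sub.species == sp]
            prots[sp] = {}
            for r in rows.itertuples():
                chrom = small_dataset.mac_by_species[sp][r.gene_id]
                cds = chrom.genes[0].cds_sequence(chrom.sequence)
                prots[sp][r.gene_id] = tables6.translate(cds)
        groups = assign_orthologs_rbh(prots)
        want = {frozenset({(FOCAL, fa.gene_id), (STRAIN, sa.gene_id)})
                for g in sub.group.unique()
                for fa in sub[(sub.group == g) & (sub.species == FOCAL)].itertuples()
                for sa in sub[(sub.group == g) & (sub.species == STRAIN)].itertuples()}
        got = {frozenset(g) for g in groups if len(g) == 2}
        hits += len(want & got)
        total += len(want)
    assert hits / total >= 0.95
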