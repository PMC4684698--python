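"""End-to-end orchestration: detection -> origins -> rates -> expression.

Each stage is a pure function from a :class:`~mdsweave.io.DataBundle` (plus
earlier stage results) to a result object; :func:`run_pipeline` wires them
together, writes machine-readable outputs (TSV + JSON) and a human-readable
markdown report, and is fully deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import detect, expression as expr_mod, origin as origin_mod, rates as rates_mod
from .config import PipelineConfig, Thresholds
from .detect import CaseSummary, RemovalRecord, SharingCase
from .expression import TIMEPOINTS, ExpressionGroupProfile
from .io import DataBundle, bundle_from_simulation, load_dataset, write_dataset
from .origin import OriginCall
from .rearrangement import GeneModel, MACChromosome, validate_map
from .simulate import simulate_dataset

log = logging.getLogger("mdsweave")

__all__ = ["run_detection", "run_origin", "run_rates", "run_expression",
           "run_pipeline", "render_summary", "shared_cds_mask"]


def shared_cds_mask(case: SharingCase, chrom: MACChromosome,
                    gene: GeneModel) -> np.ndarray:
    """Per-CDS-position flag (coding orientation): derived from a shared MDS?"""
    chrom_positions = []
    for s, e in gene.cds_intervals:
        chrom_positions.extend(range(s, e))
    if gene.strand == "-":
        chrom_positions.reverse()
    shared = case.shared_intervals[chrom.chrom_id]
    mask = np.zeros(len(chrom_positions), dtype=bool)
    for i, p in enumerate(chrom_positions):
        mask[i] = any(s <= p < e for s, e in shared)
    return mask


# ---------------------------------------------------------------------------
# stage 1: detection

@dataclass
class DetectionResult:
    cases: list[SharingCase]
    removed: list[RemovalRecord]
    summary: CaseSummary
    validation_violations: int = 0


def run_detection(bundle: DataBundle, thr: Thresholds) -> DetectionResult:
    report = validate_map(bundle.loci, bundle.chromosomes)
    if not report.ok:
        log.warning("map validation: %d violations", len(report.violations))
    raw = detect.find_sharing_groups(bundle.loci, bundle.chromosomes)
    kept, removed = detect.apply_filters(raw, bundle.chromosomes,
                                         thr.min_cds_penetration)
    for case in kept:
        detect.classify_topology(case, bundle.chromosomes)
        detect.shared_coding_fraction(case, bundle.chromosomes)
    summary = detect.summarize_cases(kept)
    log.info("detection: %d raw, %d kept, %d removed",
             len(raw), len(kept), len(removed))
    return DetectionResult(kept, removed, summary, len(report.violations))


# ---------------------------------------------------------------------------
# stage 2: origins

@dataclass
class OriginResult:
    calls: list[OriginCall]
    node_counts_raw: dict[str, int]
    node_counts_corrected: dict[str, int]
    skipped: list[str] = field(default_factory=list)


def _focal_groups(bundle: DataBundle, case_id: str) -> dict[str, str]:
    """Focal chromosome id -> ortholog group label for one case."""
    df = bundle.orthologs
    rows = df[(df.case_id == case_id) & (df.species == bundle.focal_species)]
    return dict(zip(rows.gene_id, rows.group))


def _alt_region_cds(case: SharingCase, chrom: MACChromosome) -> str:
    gene = chrom.genes[0]
    mask = shared_cds_mask(case, chrom, gene)
    part = rates_mod.partition_regions(gene.gene_id, gene.cds_length, mask)
    cds = gene.cds_sequence(chrom.sequence)
    return "".join(cds[s:e] for s, e in part.alternative)


def run_origin(bundle: DataBundle, detection: DetectionResult,
               thr: Thresholds, rng: np.random.Generator) -> OriginResult:
    from ._codes import get_tables
    tables = get_tables(6)
    tree = origin_mod.read_species_tree(bundle.species_tree)
    baseline = origin_mod.gc_baseline(
        [g.cds_sequence(c.sequence)
         for c in bundle.chromosomes.values() for g in c.genes],
    ) if any(c.genes for c in bundle.chromosomes.values()) else None

    calls: list[OriginCall] = []
    skipped: list[str] = []
    for case in detection.cases:
        groups = _focal_groups(bundle, case.case_id)
        if not groups:
            skipped.append(case.case_id)
            continue
        by_label = {lab: cid for cid, lab in groups.items()}
        if "A" not in by_label:
            skipped.append(case.case_id)
            continue

        sh = bundle.sharing[bundle.sharing.case_id == case.case_id]
        records = {r.species: {"a_present": bool(r.a_present),
                               "b_present": bool(r.b_present),
                               "sharing": None if pd.isna(r.sharing)
                               else bool(r.sharing),
                               "shared_len": r.shared_len}
                   for r in sh.itertuples()}
        states = origin_mod.species_presence_state(
            case.case_id, records, bundle.focal_species)
        node = origin_mod.infer_origin_node(tree, states)
        call = OriginCall(case.case_id, node.name,
                          contradictions=states.contradictions)

        # mechanism of the alternative segment
        alt_nt = {lab: _alt_region_cds(case, bundle.chromosomes[cid])
                  for lab, cid in by_label.items()}
        alt_prot = {lab: tables.translate(seq) if seq else ""
                    for lab, seq in alt_nt.items()}
        novel = sorted(lab for lab in by_label if lab != "A")
        verdicts = []
        for lab in novel:
            if not alt_prot["A"] or not alt_prot[lab]:
                verdicts.append("no_similarity")
                continue
            verdicts.append(origin_mod.classify_alternative_origin(
                alt_prot["A"], alt_prot[lab], rng,
                identity_threshold=thr.dup_identity,
                coverage_threshold=thr.dup_coverage,
                n_shuffles=thr.dup_shuffles,
                use_similarity=thr.dup_use_similarity))
        if verdicts and all(v == "duplication" for v in verdicts):
            call.mechanism = "duplication"
        elif verdicts:
            low = [lab for lab, v in zip(novel, verdicts)
                   if v == "no_similarity" and baseline is not None
                   and alt_nt[lab]
                   and origin_mod.flag_low_gc(alt_nt[lab], baseline)]
            call.mechanism = "low_gc_noncoding" if low else "no_similarity"

        # gene-tree correction (duplication cases with region sequences)
        seqs = bundle.regions.get(case.case_id, {})
        og_leaf = f"{bundle.outgroup}|A"
        b_leaf = f"{bundle.focal_species}|B"
        a_leaf = f"{bundle.focal_species}|A"
        if (call.mechanism == "duplication" and len(seqs) >= 3
                and {og_leaf, a_leaf, b_leaf} <= seqs.keys()):
            prots = {k: tables.translate(v) for k, v in seqs.items()}
            gt = origin_mod.build_gene_tree(prots, og_leaf,
                                            max_gap_frac=thr.max_gap_frac)
            observed_b = [sp for sp, r in records.items() if r["b_present"]]
            call = origin_mod.correct_origin_with_gene_tree(
                call, gt.tree, tree, a_leaf, b_leaf, observed_b)

        # shared-length conservation vs the focal species
        focal_len = records.get(bundle.focal_species, {}).get("shared_len")
        if focal_len and not pd.isna(focal_len):
            for sp, r in records.items():
                if sp == bundle.focal_species or not r["b_present"]:
                    continue
                if r["shared_len"] is None or pd.isna(r["shared_len"]):
                    continue
                call.shared_length_conserved[sp] = (
                    origin_mod.check_shared_length_conservation(
                        int(focal_len), int(r["shared_len"]),
                        thr.len_cons_bp, thr.len_cons_frac))
        calls.append(call)

    raw_counts: dict[str, int] = {}
    corr_counts: dict[str, int] = {}
    for call in calls:
        raw_counts[call.origin_node] = raw_counts.get(call.origin_node, 0) + 1
        corr_counts[call.final_node] = corr_counts.get(call.final_node, 0) + 1
    log.info("origins: %d calls, %d corrected, %d skipped",
             len(calls), sum(c.corrected for c in calls), len(skipped))
    return OriginResult(calls, raw_counts, corr_counts, skipped)


# ---------------------------------------------------------------------------
# stage 3: rates

@dataclass
class RateResult:
    records: list[rates_mod.RateRecord]
    filtered: list[rates_mod.RateRecord]
    tests: dict[str, dict]


def run_rates(bundle: DataBundle, detection: DetectionResult,
              thr: Thresholds, code_id: int = 6) -> RateResult:
    from ._codes import get_tables
    tables = get_tables(code_id)
    df = bundle.orthologs
    strain_rows = df[df.species == bundle.strain_species]
    records: list[rates_mod.RateRecord] = []
    for case in detection.cases:
        groups = _focal_groups(bundle, case.case_id)
        for cid, lab in sorted(groups.items()):
            srow = strain_rows[(strain_rows.case_id == case.case_id)
                               & (strain_rows.group == lab)]
            if srow.empty:
                continue
            strain_chrom = bundle.mac_by_species.get(
                bundle.strain_species, {}).get(srow.gene_id.iloc[0])
            if strain_chrom is None:
                continue
            chrom = bundle.chromosomes[cid]
            gene = chrom.genes[0]
            cds_f = gene.cds_sequence(chrom.sequence)
            cds_s = strain_chrom.genes[0].cds_sequence(strain_chrom.sequence)
            mask = shared_cds_mask(case, chrom, gene)
            part = rates_mod.partition_regions(cid, len(cds_f), mask)
            prot_f = tables.translate(cds_f)
            prot_s = tables.translate(cds_s)
            ca, cb = rates_mod.codon_align_from_protein(
                prot_f, prot_s, cds_f, cds_s, code_id=code_id)
            split = rates_mod.split_codon_alignment_by_region(
                ca, cb, part.codon_classes())
            region_nt = {"alternative": part.alternative_nt,
                         "constitutive": part.constitutive_nt}
            for region, (sa, sb) in split.items():
                if not sa:
                    continue
                aa = rates_mod.aa_distance(tables.translate(sa),
                                           tables.translate(sb))
                try:
                    ng = rates_mod.ng86_dnds(sa, sb, code_id)
                    dn, ds, omega = ng.dn, ng.ds, ng.omega
                except rates_mod.SaturationError:
                    dn = ds = float("nan")
                    omega = None
                records.append(rates_mod.RateRecord(
                    case.case_id, cid, region, region_nt[region],
                    len(sa) // 3, aa.p_distance, aa.poisson, dn, ds, omega))
    filtered = rates_mod.filter_rate_records(
        records, thr.min_region_nt, thr.ds_min, thr.ds_max)

    tests: dict[str, dict] = {}
    by_gene: dict[str, dict[str, rates_mod.RateRecord]] = {}
    for r in filtered:
        by_gene.setdefault(r.gene_id, {})[r.region_class] = r
    pairs = [v for v in by_gene.values()
             if {"alternative", "constitutive"} <= v.keys()]
    for metric, getter in (("aa", lambda r: r.aa_p), ("ds", lambda r: r.ds),
                           ("dn", lambda r: r.dn),
                           ("omega", lambda r: r.omega)):
        vals = [(getter(v["alternative"]), getter(v["constitutive"]))
                for v in pairs
                if getter(v["alternative"]) is not None
                and getter(v["constitutive"]) is not None]
        if not vals:
            tests[metric] = {"n": 0, "statistic": None, "p": None}
            continue
        a, c = zip(*vals)
        stat, p = rates_mod.paired_signed_rank(a, c)
        tests[metric] = {"n": len(vals), "statistic": stat, "p": p,
                         "median_alternative": float(np.median(a)),
                         "median_constitutive": float(np.median(c))}
    log.info("rates: %d records, %d genes after filters",
             len(records), len(pairs))
    return RateResult(records, filtered, tests)


# ---------------------------------------------------------------------------
# stage 4: expression

@dataclass
class ExpressionResult:
    size_factors: dict[str, float]
    groups: list[ExpressionGroupProfile]
    retained: list[ExpressionGroupProfile]
    excluded_by_topology: dict[str, int]
    peak_summary: dict
    fold_summary: dict


def run_expression(bundle: DataBundle, detection: DetectionResult,
                   thr: Thresholds) -> ExpressionResult:
    counts = bundle.expression.set_index("region_id")
    lengths = counts["length"]
    mat = counts[list(TIMEPOINTS)]
    sf = expr_mod.median_ratio_size_factors(mat)
    norm = mat.div(sf, axis=1)
    coverage = dict(zip(bundle.coverage.gene_id, bundle.coverage.coverage))

    groups = []
    for case in detection.cases:
        genes = [c for c in case.chrom_ids
                 if c in norm.index and bundle.chromosomes[c].genes]
        if len(genes) < 2:
            continue
        per_kb = {g: expr_mod.reads_per_kb(norm.loc[g].to_numpy(),
                                           int(lengths[g]))
                  for g in genes}
        groups.append(ExpressionGroupProfile(
            case_id=case.case_id, topology=case.topology or "share5",
            genes=genes, per_kb=per_kb,
            copy_number={g: coverage[g] for g in genes if g in coverage}))
    retained, excluded = expr_mod.filter_low_expression_groups(
        groups, thr.expr_threshold)
    peak_summary = expr_mod.peak_divergence_summary(retained)
    fold_summary = expr_mod.copy_number_fold_summary(groups)
    log.info("expression: %d groups, %d retained", len(groups), len(retained))
    return ExpressionResult(dict(sf), groups, retained, excluded,
                            peak_summary, fold_summary)


# ---------------------------------------------------------------------------
# reporting and the full run

def render_summary(summary: CaseSummary, origin_result: OriginResult | None,
                   rate_tests: dict | None,
                   expr_result: ExpressionResult | None) -> str:
    lines = ["# mdsweave report", ""]
    lines += ["## Sharing cases (Table-1 shape)", "",
              "| row | total | share5 | share3 | both | nonscrambled | scrambled |",
              "|---|---|---|---|---|---|---|"]
    for name, row in (("MIC loci", summary.loci),
                      ("MAC chromosomes", summary.chromosomes),
                      ("MDSs", summary.mds)):
        lines.append("| {} | {total} | {share5} | {share3} | {both} | "
                     "{nonscrambled} | {scrambled} |".format(name, **row))
    if origin_result is not None:
        lines += ["", "## Origins per species-tree node (raw / corrected)", ""]
        nodes = sorted(set(origin_result.node_counts_raw)
                       | set(origin_result.node_counts_corrected))
        for n in nodes:
            lines.append(f"- {n}: {origin_result.node_counts_raw.get(n, 0)} / "
                         f"{origin_result.node_counts_corrected.get(n, 0)}")
        mechs = {}
        for c in origin_result.calls:
            mechs[c.mechanism] = mechs.get(c.mechanism, 0) + 1
        lines.append(f"- mechanisms: {mechs}")
    if rate_tests:
        lines += ["", "## Substitution rates: alternative vs constitutive "
                  "(paired signed-rank)", ""]
        for metric, t in rate_tests.items():
            if t.get("p") is None:
                continue
            lines.append(
                f"- {metric}: n = {t['n']}, median alt = "
                f"{t['median_alternative']:.4g}, const = "
                f"{t['median_constitutive']:.4g}, P = {t['p']:.3g}")
    if expr_result is not None:
        lines += ["", "## Expression divergence", ""]
        for topo, d in sorted(expr_result.peak_summary.items()):
            lines.append(f"- {topo}: {d['n_groups']} groups, "
                         f"{d['same_peak']} same-peak, "
                         f"{d['pct_different']}% different")
        lines.append(f"- excluded (low expression): "
                     f"{expr_result.excluded_by_topology}")
        fs = expr_result.fold_summary
        lines.append(f"- copy-number folds: {fs['n_above_2fold']} above "
                     f"2-fold, {fs['n_above_3fold']} above 3-fold "
                     f"of {len(fs['groups'])} groups")
    return "\n".join(lines) + "\n"


def _cases_frame(cases: list[SharingCase]) -> pd.DataFrame:
    rows = []
    for c in cases:
        rows.append({
            "case_id": c.case_id, "locus_id": c.locus_id,
            "n_chromosomes": len(c.chrom_ids),
            "chromosomes": ",".join(c.chrom_ids),
            "topology": c.topology, "ambiguous": c.topology_ambiguous,
            "scrambled": c.scrambled,
            "n_shared_mds": c.n_shared_mds, "n_mds": c.n_mds,
            "shared_coding_fraction": ",".join(
                f"{g}:{f:.4f}" for g, f in sorted(c.shared_coding_fraction.items())),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run everything; returns a dict of output paths and key results."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    try:
        if config.input_dir:
            bundle = load_dataset(config.input_dir)
        else:
            dataset = simulate_dataset(config.simulate)
            write_dataset(dataset, out / "dataset")
            bundle = bundle_from_simulation(dataset)
        rng = np.random.default_rng(config.seed)
        thr = config.thresholds

        detection = run_detection(bundle, thr)
        origin_result = run_origin(bundle, detection, thr, rng)
        rate_result = run_rates(bundle, detection, thr)
        expr_result = run_expression(bundle, detection, thr)

        _cases_frame(detection.cases).to_csv(out / "cases.tsv", sep="\t",
                                             index=False)
        pd.DataFrame([dataclasses.asdict(r) for r in detection.removed]
                     ).to_csv(out / "removal_log.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(
            json.dumps(detection.summary.to_dict(), indent=1))
        pd.DataFrame([dataclasses.asdict(c) for c in origin_result.calls]
                     ).to_csv(out / "origin_calls.tsv", sep="\t", index=False)
        (out / "origin_nodes.json").write_text(json.dumps(
            {"raw": origin_result.node_counts_raw,
             "corrected": origin_result.node_counts_corrected}, indent=1))
        pd.DataFrame([dataclasses.asdict(r) for r in rate_result.records]
                     ).to_csv(out / "rates.tsv", sep="\t", index=False)
        (out / "rate_tests.json").write_text(
            json.dumps(rate_result.tests, indent=1))
        (out / "expression_summary.json").write_text(json.dumps(
            {"size_factors": expr_result.size_factors,
             "excluded_by_topology": expr_result.excluded_by_topology,
             "peaks": expr_result.peak_summary,
             "copy_number": {k: v for k, v in expr_result.fold_summary.items()
                             if k != "groups"}}, indent=1))
        report = render_summary(detection.summary, origin_result,
                                rate_result.tests, expr_result)
        (out / "report.md").write_text(report)
        log.info("pipeline finished in %.1f s", time.time() - t0)
        return {"out_dir": str(out), "detection": detection,
                "origin": origin_result, "rates": rate_result,
                "expression": expr_result, "report": report}
    finally:
        log.removeHandler(handler)
        handler.close()
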