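"""On-disk dataset layout and format conversions.

A dataset directory contains::

    species_tree.newick
    mic/contigs.fasta          germline contigs of the focal species
    mic/annotation.gff3        MDS and IES features with somatic targets
    mac/<species>.fasta        somatic chromosomes per species
    mac/<species>.gff3         chromosome + gene (CDS) features
    orthologs.tsv              case_id, group, species, gene_id
    sharing.tsv                per-species presence/sharing records per case
    regions/<case>.fasta       alternative-region CDS per species|gene
    expression.tsv             region_id, length, raw counts per time point
    coverage.tsv               gene_id, DNA coverage
    truth.json, config.yaml    (simulated datasets only)

Coordinates are 0-based half-open in memory and 1-based inclusive in GFF3.
FASTA goes through Biopython; the GFF3 dialect here is small and fixed, so
feature lines are written and parsed directly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .rearrangement import (IES, MDS, GeneModel, MACChromosome, MDSTarget,
                            MICLocus)

__all__ = ["write_fasta", "read_fasta", "write_dataset", "load_dataset",
           "DataBundle"]


def write_fasta(path, sequences: dict[str, str]):
    records = [SeqRecord(Seq(s), id=name, description="")
               for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _attrs(pairs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in pairs.items() if v is not None)


def _parse_attrs(s: str) -> dict:
    out = {}
    for part in s.strip().split(";"):
        if part:
            k, _, v = part.partition("=")
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# MIC annotation (MDS / IES features)

def _targets_attr(mds: MDS) -> str:
    # chrom:order:start-end, 1-based inclusive
    return ",".join(f"{t.chrom_id}:{t.order}:{t.start + 1}-{t.end}"
                    for t in mds.targets)


def _parse_targets(s: str) -> list[MDSTarget]:
    out = []
    for part in s.split(","):
        chrom, order, span = part.rsplit(":", 2)
        a, b = span.split("-")
        out.append(MDSTarget(chrom, int(order), int(a) - 1, int(b)))
    return out


def write_mic_gff3(path, loci: dict[str, MICLocus]):
    lines = ["##gff-version 3"]
    for locus_id in sorted(loci):
        locus = loci[locus_id]
        for m in locus.mds_list:
            lines.append("\t".join([
                locus.contig_id, "mdsweave", "MDS",
                str(m.start + 1), str(m.end), ".", m.orientation, ".",
                _attrs({"ID": f"{locus_id}.MDS{m.index}",
                        "locus_id": locus_id, "mds_index": m.index,
                        "targets": _targets_attr(m)})]))
        for k, ies in enumerate(locus.ies_list, 1):
            lines.append("\t".join([
                locus.contig_id, "mdsweave", "IES",
                str(ies.start + 1), str(ies.end), ".", "+", ".",
                _attrs({"ID": f"{locus_id}.IES{k}", "locus_id": locus_id,
                        "flanking": f"{ies.flanking[0]}-{ies.flanking[1]}"})]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_mic_gff3(path, contigs: dict[str, str]) -> dict[str, MICLocus]:
    loci: dict[str, MICLocus] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        seqid, _, ftype, start, end, _, strand, _, attrs = line.split("\t")
        a = _parse_attrs(attrs)
        locus_id = a["locus_id"]
        if locus_id not in loci:
            loci[locus_id] = MICLocus(locus_id, seqid, contigs[seqid])
        locus = loci[locus_id]
        if ftype == "MDS":
            locus.mds_list.append(MDS(
                locus_id, int(a["mds_index"]), int(start) - 1, int(end),
                strand, targets=_parse_targets(a["targets"])))
        elif ftype == "IES":
            left, _, right = a["flanking"].partition("-")
            locus.ies_list.append(IES(locus_id, int(start) - 1, int(end),
                                      (int(left), int(right))))
    return loci


# ---------------------------------------------------------------------------
# MAC annotation (chromosome / gene features)

def write_mac_gff3(path, chromosomes: dict[str, MACChromosome]):
    lines = ["##gff-version 3"]
    for chrom_id in sorted(chromosomes):
        chrom = chromosomes[chrom_id]
        lines.append("\t".join([
            chrom_id, "mdsweave", "chromosome", "1", str(len(chrom.sequence)),
            ".", "+", ".",
            _attrs({"ID": chrom_id,
                    "telomere_5": str(chrom.telomere_5).lower(),
                    "telomere_3": str(chrom.telomere_3).lower()})]))
        for gene in chrom.genes:
            lo = min(s for s, _ in gene.cds_intervals)
            hi = max(e for _, e in gene.cds_intervals)
            lines.append("\t".join([
                chrom_id, "mdsweave", "gene", str(lo + 1), str(hi), ".",
                gene.strand, ".", _attrs({"ID": gene.gene_id})]))
            for s, e in gene.cds_intervals:
                lines.append("\t".join([
                    chrom_id, "mdsweave", "CDS", str(s + 1), str(e), ".",
                    gene.strand, "0", _attrs({"Parent": gene.gene_id})]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_mac_gff3(path, sequences: dict[str, str]) -> dict[str, MACChromosome]:
    chroms: dict[str, MACChromosome] = {}
    cds_by_gene: dict[str, tuple[str, str, list]] = {}
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        seqid, _, ftype, start, end, _, strand, _, attrs = line.split("\t")
        a = _parse_attrs(attrs)
        if ftype == "chromosome":
            chroms[seqid] = MACChromosome(
                seqid, sequences[seqid],
                telomere_5=a.get("telomere_5", "true") == "true",
                telomere_3=a.get("telomere_3", "true") == "true")
        elif ftype == "gene":
            cds_by_gene.setdefault(a["ID"], (seqid, strand, []))
        elif ftype == "CDS":
            cds_by_gene.setdefault(a["Parent"], (seqid, strand, []))
            cds_by_gene[a["Parent"]][2].append((int(start) - 1, int(end)))
    for gene_id, (seqid, strand, intervals) in cds_by_gene.items():
        if seqid not in chroms:
            chroms[seqid] = MACChromosome(seqid, sequences[seqid])
        chroms[seqid].genes.append(GeneModel(gene_id, strand, intervals))
    for chrom in chroms.values():
        chrom.genes.sort(key=lambda g: g.gene_id)
    return chroms


# ---------------------------------------------------------------------------
# whole datasets

@dataclasses.dataclass
class DataBundle:
    """Everything the pipeline needs, as loaded from a dataset directory."""

    species_tree: str
    focal_species: str
    strain_species: str
    outgroup: str
    loci: dict[str, MICLocus]
    mac_by_species: dict[str, dict[str, MACChromosome]]
    orthologs: pd.DataFrame
    sharing: pd.DataFrame
    regions: dict[str, dict[str, str]]
    expression: pd.DataFrame
    coverage: pd.DataFrame
    truth: dict | None = None
    config: dict | None = None

    @property
    def chromosomes(self) -> dict[str, MACChromosome]:
        return self.mac_by_species[self.focal_species]


def write_dataset(dataset, outdir) -> Path:
    """Write a SimulatedDataset (or equivalent) to a dataset directory."""
    out = Path(outdir)
    (out / "mic").mkdir(parents=True, exist_ok=True)
    (out / "mac").mkdir(exist_ok=True)
    (out / "regions").mkdir(exist_ok=True)
    (out / "species_tree.newick").write_text(dataset.species_tree + "\n")

    contigs = {locus.contig_id: locus.sequence
               for locus in dataset.loci.values()}
    write_fasta(out / "mic" / "contigs.fasta", contigs)
    write_mic_gff3(out / "mic" / "annotation.gff3", dataset.loci)

    for species, chroms in dataset.mac_by_species.items():
        if not chroms:
            continue
        write_fasta(out / "mac" / f"{species}.fasta",
                    {c: ch.sequence for c, ch in chroms.items()})
        write_mac_gff3(out / "mac" / f"{species}.gff3", chroms)

    dataset.orthologs.to_csv(out / "orthologs.tsv", sep="\t", index=False)
    dataset.sharing.to_csv(out / "sharing.tsv", sep="\t", index=False)
    dataset.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
    dataset.coverage.to_csv(out / "coverage.tsv", sep="\t", index=False)
    for case_id, seqs in dataset.regions.items():
        if seqs:
            write_fasta(out / "regions" / f"{case_id}.fasta", seqs)
    (out / "truth.json").write_text(
        json.dumps(dataset.truth.to_dict(), indent=1, default=str))
    (out / "config.yaml").write_text(
        yaml.safe_dump(dataset.config.to_dict(), sort_keys=False))
    return out


def load_dataset(indir) -> DataBundle:
    """Load a dataset directory back into memory."""
    d = Path(indir)
    if not d.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {d}")
    for required in ("species_tree.newick", "mic/contigs.fasta",
                     "mic/annotation.gff3", "orthologs.tsv", "sharing.tsv",
                     "expression.tsv", "coverage.tsv"):
        if not (d / required).exists():
            raise FileNotFoundError(f"missing dataset file: {d / required}")
    truth = config = None
    if (d / "truth.json").exists():
        truth = json.loads((d / "truth.json").read_text())
    if (d / "config.yaml").exists():
        config = yaml.safe_load((d / "config.yaml").read_text())

    contigs = read_fasta(d / "mic" / "contigs.fasta")
    loci = read_mic_gff3(d / "mic" / "annotation.gff3", contigs)
    mac_by_species = {}
    for fasta in sorted((d / "mac").glob("*.fasta")):
        species = fasta.stem
        seqs = read_fasta(fasta)
        mac_by_species[species] = read_mac_gff3(d / "mac" / f"{species}.gff3",
                                                seqs)
    regions = {}
    for fasta in sorted((d / "regions").glob("*.fasta")):
        regions[fasta.stem] = read_fasta(fasta)

    meta = truth or {}
    from .simulate import FOCAL, OUTGROUP, STRAIN
    return DataBundle(
        species_tree=(d / "species_tree.newick").read_text().strip(),
        focal_species=meta.get("focal_species", FOCAL),
        strain_species=meta.get("strain_species", STRAIN),
        outgroup=meta.get("outgroup", OUTGROUP),
        loci=loci,
        mac_by_species=mac_by_species,
        orthologs=pd.read_csv(d / "orthologs.tsv", sep="\t"),
        sharing=pd.read_csv(d / "sharing.tsv", sep="\t"),
        regions=regions,
        expression=pd.read_csv(d / "expression.tsv", sep="\t"),
        coverage=pd.read_csv(d / "coverage.tsv", sep="\t"),
        truth=truth, config=config)


def bundle_from_simulation(dataset) -> DataBundle:
    """Wrap an in-memory SimulatedDataset as a DataBundle (no disk round trip)."""
    from .simulate import FOCAL, OUTGROUP, STRAIN
    return DataBundle(
        species_tree=dataset.species_tree,
        focal_species=FOCAL, strain_species=STRAIN, outgroup=OUTGROUP,
        loci=dataset.loci, mac_by_species=dataset.mac_by_species,
        orthologs=dataset.orthologs, sharing=dataset.sharing,
        regions=dataset.regions, expression=dataset.expression,
        coverage=dataset.coverage,
        truth=dataset.truth.to_dict(), config=dataset.config.to_dict())
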