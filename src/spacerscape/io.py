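"""Readers and writers for the standard formats the pipeline consumes.

Conventions: FASTA via Biopython; GFF3 is 1-based closed on disk and
converted to 0-based half-open in memory at this boundary only; BED is
0-based half-open; tables are TSV via pandas.  All writers emit
deterministically ordered records (strain_id, contig, start).
"""

from __future__ import annotations

import json
import os
from glob import glob
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (AnnotatedGene, CrisprLocus, GenomeRecord, Region,
                     RegionSet, SpacerRecord, StrainMetadata)

_METADATA_OPTIONAL = ("phylotype", "location", "biome", "latitude",
                      "longitude", "depth", "date")


def read_metadata(path: str) -> dict[str, StrainMetadata]:
    """Strain metadata TSV: columns strain_id and species are required;
    phylotype/location/biome/latitude/longitude/depth/date are optional."""
    df = pd.read_csv(path, sep="\t", dtype={"strain_id": str})
    for col in ("strain_id", "species"):
        if col not in df.columns:
            raise ValueError(f"metadata missing required column {col!r}")
    out: dict[str, StrainMetadata] = {}
    for _, row in df.iterrows():
        sid = str(row["strain_id"])
        if sid in out:
            raise ValueError(f"duplicate strain_id {sid} in metadata")
        kwargs = {}
        for col in _METADATA_OPTIONAL:
            if col in df.columns and pd.notna(row[col]):
                if col in ("latitude", "longitude", "depth"):
                    kwargs[col] = float(row[col])
                else:
                    kwargs[col] = str(row[col])
        out[sid] = StrainMetadata(strain_id=sid, species=str(row["species"]),
                                  **kwargs)
    return out


def read_genomes(fasta: str | Iterable[str],
                 metadata: dict[str, StrainMetadata]
                 ) -> dict[str, GenomeRecord]:
    """Load one FASTA per strain (``<strain_id>.fasta``/``.fa`` under a
    directory, or explicit paths).

    Every strain in the metadata must have a genome (hard error naming the
    missing strain); lowercase bases are uppercased; non-ACGTN symbols and
    duplicate contig ids are hard errors.
    """
    if isinstance(fasta, str):
        paths = sorted(glob(os.path.join(fasta, "*.fasta"))
                       + glob(os.path.join(fasta, "*.fa")))
    else:
        paths = sorted(fasta)
    by_strain = {os.path.splitext(os.path.basename(p))[0]: p for p in paths}
    genomes: dict[str, GenomeRecord] = {}
    for strain_id in sorted(metadata):
        if strain_id not in by_strain:
            raise FileNotFoundError(f"no genome FASTA found for strain {strain_id}")
        contigs: dict[str, str] = {}
        for rec in SeqIO.parse(by_strain[strain_id], "fasta"):
            if rec.id in contigs:
                raise ValueError(
                    f"duplicate contig id {rec.id} in strain {strain_id}")
            contigs[rec.id] = str(rec.seq).upper()
        g = GenomeRecord(strain_id=strain_id, contigs=contigs)
        g.validate()
        genomes[strain_id] = g
    return genomes


def _gff_attributes(attr: str) -> dict[str, str]:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotations(path: str) -> tuple[list[AnnotatedGene], int]:
    """Gene annotations from GFF3 (1-based closed on disk) or a TSV with
    columns contig_id/start/end/strand/name[/product] already in 0-based
    half-open coordinates.

    Returns (genes, n_rejected); records with end < start are rejected and
    counted rather than aborting the run.
    """
    genes: list[AnnotatedGene] = []
    rejected = 0
    if path.endswith((".gff", ".gff3")):
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 9:
                    continue
                contig, _, ftype, start, end, _, strand, _, attrs = fields[:9]
                if ftype not in ("gene", "CDS"):
                    continue
                s, e = int(start), int(end)
                if e < s:
                    rejected += 1
                    continue
                a = _gff_attributes(attrs)
                name = a.get("Name") or a.get("gene") or a.get("ID") or ""
                genes.append(AnnotatedGene(
                    contig_id=contig, start=s - 1, end=e,
                    strand=strand if strand in "+-" else "+",
                    name=name, product=a.get("product", "")))
    else:
        df = pd.read_csv(path, sep="\t")
        for _, row in df.iterrows():
            s, e = int(row["start"]), int(row["end"])
            if e <= s:
                rejected += 1
                continue
            genes.append(AnnotatedGene(
                contig_id=str(row["contig_id"]), start=s, end=e,
                strand=str(row["strand"]), name=str(row["name"]),
                product=str(row.get("product", "") or "")))
    genes.sort(key=lambda g: (g.contig_id, g.start, g.end))
    return genes, rejected


def read_annotation_dir(dirpath: str) -> dict[str, list[AnnotatedGene]]:
    """One annotation file per strain (``<strain_id>.gff3``/``.gff``/``.tsv``)."""
    out: dict[str, list[AnnotatedGene]] = {}
    for path in sorted(glob(os.path.join(dirpath, "*"))):
        base, ext = os.path.splitext(os.path.basename(path))
        if ext in (".gff", ".gff3", ".tsv"):
            out[base], _ = read_annotations(path)
    return out


def read_bed_regions(bed_path: str, fasta_path: str,
                     region_class: str = "prophage") -> RegionSet:
    """Prophage/island regions: BED (0-based half-open; columns contig,
    start, end, region_id, strain_id) plus a FASTA keyed by region_id.
    FASTA headers may carry ``family=`` and ``intact=`` tags."""
    seqs: dict[str, str] = {}
    meta: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(fasta_path, "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
        meta[rec.id] = _gff_attributes(rec.description.replace(" ", ";"))
    entries = []
    with open(bed_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            contig, start, end, region_id = fields[:4]
            strain_id = fields[4] if len(fields) > 4 else region_id.split("_")[0]
            if region_id not in seqs:
                raise ValueError(f"region {region_id} missing from {fasta_path}")
            m = meta[region_id]
            entries.append(Region(
                region_id=region_id, source_id=strain_id,
                region_class=region_class, sequence=seqs[region_id],
                contig_id=contig, start=int(start), end=int(end),
                family=m.get("family", ""),
                intact=m.get("intact", "true").lower() != "false"))
    entries.sort(key=lambda r: (r.source_id, r.contig_id or "", r.start or 0))
    return RegionSet(entries=entries)


def read_mge_fasta(path: str) -> list[Region]:
    """Known-MGE database FASTA; headers may carry ``class=`` and
    ``family=`` tags (default class known_MGE)."""
    out = []
    for rec in SeqIO.parse(path, "fasta"):
        tags = _gff_attributes(rec.description.replace(" ", ";"))
        out.append(Region(
            region_id=rec.id, source_id=tags.get("source", "db"),
            region_class=tags.get("class", "known_MGE"),
            sequence=str(rec.seq).upper(), family=tags.get("family", "")))
    out.sort(key=lambda r: r.region_id)
    return out


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_loci_gff(loci: list[CrisprLocus], path: str) -> None:
    """Loci as GFF3: a repeat_region parent with direct_repeat and spacer
    children; coordinates converted to 1-based closed; sequences kept in
    attributes so the file round-trips losslessly."""
    loci = sorted(loci, key=lambda l: (l.strain_id, l.contig_id, l.start))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for loc in loci:
            attrs = (f"ID={loc.locus_id};strain={loc.strain_id};"
                     f"consensus={loc.consensus_repeat};"
                     f"orientation={loc.orientation};confidence={loc.confidence}")
            if loc.merged_from:
                attrs += f";merged_from={','.join(loc.merged_from)}"
            fh.write("\t".join([
                loc.contig_id, "spacerscape", "repeat_region",
                str(loc.start + 1), str(loc.end), ".", "+", ".", attrs]) + "\n")
            for i, (s, e) in enumerate(loc.repeat_occurrences):
                fh.write("\t".join([
                    loc.contig_id, "spacerscape", "direct_repeat",
                    str(s + 1), str(e), ".", "+", ".",
                    f"ID={loc.locus_id}.r{i};Parent={loc.locus_id}"]) + "\n")
            for i, ((s, e), seq) in enumerate(zip(loc.spacer_intervals, loc.spacers)):
                fh.write("\t".join([
                    loc.contig_id, "spacerscape", "spacer",
                    str(s + 1), str(e), ".", "+", ".",
                    f"ID={loc.locus_id}.s{i};Parent={loc.locus_id};seq={seq}"])
                    + "\n")


def read_loci_gff(path: str) -> list[CrisprLocus]:
    """Inverse of :func:`write_loci_gff` (coordinates and sequences)."""
    parents: dict[str, CrisprLocus] = {}
    children: dict[str, list[tuple[str, int, int, dict]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            contig, _, ftype, start, end, _, _, _, attr_s = \
                line.rstrip("\n").split("\t")
            attrs = _gff_attributes(attr_s)
            s, e = int(start) - 1, int(end)
            if ftype == "repeat_region":
                loc = CrisprLocus(
                    locus_id=attrs["ID"], strain_id=attrs["strain"],
                    contig_id=contig, start=s, end=e,
                    repeat_occurrences=[], spacer_intervals=[],
                    consensus_repeat=attrs["consensus"], spacers=[],
                    orientation=attrs["orientation"],
                    confidence=attrs["confidence"],
                    merged_from=attrs.get("merged_from", "").split(",")
                    if attrs.get("merged_from") else [])
                parents[loc.locus_id] = loc
            elif ftype in ("direct_repeat", "spacer"):
                children.setdefault(attrs["Parent"], []).append(
                    (ftype, s, e, attrs))
    for locus_id, loc in parents.items():
        for ftype, s, e, attrs in sorted(children.get(locus_id, []),
                                         key=lambda c: c[1]):
            if ftype == "direct_repeat":
                loc.repeat_occurrences.append((s, e))
            else:
                loc.spacer_intervals.append((s, e))
                loc.spacers.append(attrs.get("seq", ""))
    return sorted(parents.values(),
                  key=lambda l: (l.strain_id, l.contig_id, l.start))


def write_spacers_fasta(records: list[SpacerRecord], path: str) -> None:
    recs = [SeqRecord(Seq(r.sequence), id=r.spacer_id, description="")
            for r in sorted(records, key=lambda r: r.spacer_id)]
    SeqIO.write(recs, path, "fasta")


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")
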