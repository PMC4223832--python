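"""Cas operon discovery, subtype classification and CRISPR association.

Type I systems are defined by the cas3 signature gene; clusters lacking
cas3 are never assigned a named subtype.  Subtype signatures are set-based
(gene order is recorded for reporting but never used for classification)
and ship as editable YAML so the default table can be adjusted against a
reference operon diagram.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import yaml

from .models import AnnotatedGene, CasCluster, CrisprLocus, GenomeRecord, gc_fraction

# canonical cas vocabulary recognized when building clusters
CAS_VOCABULARY = frozenset(
    [f"cas{i}" for i in range(1, 11)]
    + ["cse1", "cse2", "cas8c", "cst1", "csb1", "csb2", "csb3", "csx17"]
    + [f"csy{i}" for i in range(1, 5)]
    + [f"cmr{i}" for i in range(1, 7)]
)


@dataclass
class SubtypeSignature:
    subtype: str
    required: frozenset[str]
    optional: frozenset[str] = frozenset()
    forbidden: frozenset[str] = frozenset()
    priority: int = 0

    def __post_init__(self) -> None:
        if self.required & self.forbidden:
            raise ValueError(f"{self.subtype}: required and forbidden overlap")

    def matches(self, genes: set[str]) -> bool:
        return self.required <= genes and not (self.forbidden & genes)


def _load_yaml(name: str) -> dict:
    ref = importlib.resources.files("spacerscape.data").joinpath(name)
    return yaml.safe_load(ref.read_text())


def load_aliases(path: str | None = None) -> dict[str, str]:
    data = yaml.safe_load(open(path)) if path else _load_yaml("aliases.yaml")
    return {k.lower(): v.lower() for k, v in data["aliases"].items()}


def load_signatures(path: str | None = None) -> list[SubtypeSignature]:
    """Load the subtype signature table (shipped default or a user YAML),
    sorted by descending priority.  Priorities must be unique."""
    data = yaml.safe_load(open(path)) if path else _load_yaml("signatures.yaml")
    sigs = [
        SubtypeSignature(
            subtype=e["subtype"],
            required=frozenset(g.lower() for g in e.get("required", [])),
            optional=frozenset(g.lower() for g in e.get("optional", [])),
            forbidden=frozenset(g.lower() for g in e.get("forbidden", [])),
            priority=int(e["priority"]),
        )
        for e in data["signatures"]
    ]
    prios = [s.priority for s in sigs]
    if len(set(prios)) != len(prios):
        raise ValueError("signature priorities must be unique")
    return sorted(sigs, key=lambda s: -s.priority)


def normalize_gene_name(name: str, aliases: dict[str, str] | None = None) -> str:
    aliases = aliases if aliases is not None else load_aliases()
    n = name.strip().lower()
    return aliases.get(n, n)


def is_cas_gene(name: str, aliases: dict[str, str] | None = None) -> bool:
    return normalize_gene_name(name, aliases) in CAS_VOCABULARY


def find_cas_clusters(genes: list[AnnotatedGene], strain_id: str,
                      max_intergenic_gap: int = 500,
                      aliases: dict[str, str] | None = None) -> list[CasCluster]:
    """Group cas-vocabulary genes into maximal contiguous clusters.

    A run breaks where the intergenic gap exceeds ``max_intergenic_gap`` or
    where a non-cas gene intervenes.
    """
    aliases = aliases if aliases is not None else load_aliases()
    clusters: list[CasCluster] = []
    current: list[AnnotatedGene] = []

    def flush() -> None:
        nonlocal current
        if current:
            names = {normalize_gene_name(g.name, aliases) for g in current}
            clusters.append(CasCluster(
                cluster_id="",
                strain_id=strain_id,
                contig_id=current[0].contig_id,
                start=current[0].start,
                end=max(g.end for g in current),
                genes=list(current),
                has_cas1="cas1" in names,
                has_cas3="cas3" in names,
            ))
        current = []

    for gene in sorted(genes, key=lambda g: (g.contig_id, g.start, g.end)):
        if not is_cas_gene(gene.name, aliases):
            flush()  # a non-cas gene inside a run splits it
            continue
        if current and (gene.contig_id != current[-1].contig_id
                        or gene.start - current[-1].end > max_intergenic_gap):
            flush()
        current.append(gene)
    flush()
    for i, cl in enumerate(clusters, 1):
        cl.cluster_id = f"{strain_id}_C{i:03d}"
    return clusters


def classify_subtype(cluster: CasCluster,
                     signatures: list[SubtypeSignature] | None = None,
                     aliases: dict[str, str] | None = None) -> str:
    """Assign the highest-priority matching subtype signature.

    Clusters lacking cas3 are 'unclassified' regardless of other content.
    Also sets the cluster's subtype/complete flags in place.
    """
    signatures = signatures if signatures is not None else load_signatures()
    aliases = aliases if aliases is not None else load_aliases()
    names = {normalize_gene_name(g.name, aliases) for g in cluster.genes}
    cluster.has_cas1 = "cas1" in names
    cluster.has_cas3 = "cas3" in names
    label = "unclassified"
    if cluster.has_cas3:
        for sig in sorted(signatures, key=lambda s: -s.priority):
            if sig.matches(names):
                label = sig.subtype
                # completeness: cas1+cas2 adaptation module on top of the
                # required set, waived for subtypes whose definition
                # forbids cas1 (they cannot carry it by construction)
                if "cas1" in sig.forbidden:
                    cluster.complete = True
                else:
                    cluster.complete = {"cas1", "cas2"} <= names
                break
    cluster.subtype = label
    if label == "unclassified":
        cluster.complete = False
    return label


def associate_crispr_cas(loci: list[CrisprLocus], clusters: list[CasCluster],
                         max_distance: int = 1000) -> dict[str, str | None]:
    """Map each locus to its nearest cas cluster on the same contig within
    ``max_distance`` (edge-to-edge), or None.  Paired loci flanking an
    internal cluster both map to it by this rule."""
    mapping: dict[str, str | None] = {}
    for loc in loci:
        best: tuple[int, str] | None = None
        for cl in clusters:
            if cl.contig_id != loc.contig_id:
                continue
            gap = max(cl.start - loc.end, loc.start - cl.end, 0)
            if gap <= max_distance and (best is None or gap < best[0]):
                best = (gap, cl.cluster_id)
        mapping[loc.locus_id] = best[1] if best else None
    return mapping


def gc_contrast(start: int, end: int, contig_seq: str,
                genome: GenomeRecord) -> tuple[float, float, float]:
    """GC% of a region vs the whole genome, and their difference, to 0.1.

    N bases are excluded from denominators.  A lower region GC than the
    genomic background is a hallmark of horizontally acquired elements.
    """
    if end <= start:
        raise ValueError("empty region")
    region = contig_seq[start:end]
    if not region:
        raise ValueError("empty region")
    region_gc = round(100 * gc_fraction(region), 1)
    genome_gc = round(
        100 * gc_fraction("".join(genome.contigs[c] for c in sorted(genome.contigs))),
        1,
    )
    return region_gc, genome_gc, round(region_gc - genome_gc, 1)
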