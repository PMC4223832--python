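"""Shared domain types for the CRISPR-Cas comparative pipeline.

All genomic coordinates are 0-based half-open intervals on the forward
strand of a single contig; features never span contigs.  GFF3 emission
converts to 1-based closed coordinates at the boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide sequence (A/C/G/T/N)."""
    return seq.translate(COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Strand-folded representative: lexicographic min of seq and its
    reverse complement.  Idempotent and strand-invariant by construction."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def gc_fraction(seq: str) -> float:
    """GC fraction over unambiguous bases; N is excluded from the denominator."""
    g = seq.count("G") + seq.count("C")
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("region contains no unambiguous bases")
    return g / denom


@dataclass
class GenomeRecord:
    """One strain's genome as an ordered set of contigs."""

    strain_id: str
    contigs: dict[str, str]  # contig_id -> uppercase A/C/G/T/N sequence
    gene_count: int = 0

    @property
    def genome_size(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def validate(self) -> None:
        if len(set(self.contigs)) != len(self.contigs):
            raise ValueError(f"duplicate contig ids in strain {self.strain_id}")
        for cid, seq in self.contigs.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {cid} of strain {self.strain_id} contains "
                    f"non-ACGTN symbols: {sorted(bad)}"
                )


@dataclass
class StrainMetadata:
    strain_id: str
    species: str
    phylotype: str = ""
    location: str = ""
    biome: str = ""
    latitude: Optional[float] = None
    longitude: Optional[float] = None
    depth: Optional[float] = None
    date: Optional[str] = None


@dataclass
class AnnotatedGene:
    """A gene annotation; interval is 0-based half-open."""

    contig_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    name: str
    product: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid gene interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class Region:
    """A prophage / genomic island / known-MGE record.

    `interval` is present iff the region lies on a strain contig; database
    records (class ``known_MGE``) carry only a sequence.
    """

    region_id: str
    source_id: str  # strain_id for on-genome regions, database id otherwise
    region_class: str  # prophage | known_MGE | island
    sequence: str
    contig_id: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    family: str = ""
    intact: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"region {self.region_id} has empty sequence")
        has_interval = self.start is not None and self.end is not None
        if has_interval != (self.contig_id is not None):
            raise ValueError(
                f"region {self.region_id}: interval present iff contig_id present"
            )


@dataclass
class RegionSet:
    entries: list[Region] = field(default_factory=list)

    def by_class(self, region_class: str) -> list[Region]:
        return [r for r in self.entries if r.region_class == region_class]

    def for_strain(self, strain_id: str) -> list[Region]:
        return [r for r in self.entries if r.source_id == strain_id]


@dataclass
class CrisprLocus:
    """A detected repeat-spacer array.

    ``repeat_occurrences`` and ``spacer_intervals`` alternate and tile
    [start, end); len(spacers) == len(repeats) - 1.
    """

    locus_id: str
    strain_id: str
    contig_id: str
    start: int
    end: int
    repeat_occurrences: list[tuple[int, int]]
    spacer_intervals: list[tuple[int, int]]
    consensus_repeat: str
    spacers: list[str]
    orientation: str = "unknown"  # leader_left | leader_right | unknown
    confidence: str = "questionable"  # confirmed | questionable
    merged_from: list[str] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_occurrences)

    @property
    def n_spacers(self) -> int:
        return len(self.spacer_intervals)

    @property
    def repeat_length_mean(self) -> float:
        if not self.repeat_occurrences:
            return 0.0
        return sum(e - s for s, e in self.repeat_occurrences) / self.n_repeats

    @property
    def size(self) -> int:
        return self.end - self.start

    def validate(self) -> None:
        if self.n_spacers != self.n_repeats - 1:
            raise ValueError(
                f"{self.locus_id}: {self.n_spacers} spacers for {self.n_repeats} repeats"
            )
        tiles = []
        for i, rep in enumerate(self.repeat_occurrences):
            tiles.append(rep)
            if i < len(self.spacer_intervals):
                tiles.append(self.spacer_intervals[i])
        pos = self.start
        for s, e in tiles:
            if s != pos or e < s:
                raise ValueError(f"{self.locus_id}: repeats/spacers do not tile interval")
            pos = e
        if pos != self.end:
            raise ValueError(f"{self.locus_id}: interval end mismatch")


@dataclass
class CasCluster:
    """A contiguous run of cas-vocabulary genes with a subtype call."""

    cluster_id: str
    strain_id: str
    contig_id: str
    start: int
    end: int
    genes: list[AnnotatedGene]
    subtype: str = "unclassified"
    complete: bool = False
    has_cas1: bool = False
    has_cas3: bool = False

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]


@dataclass
class SpacerRecord:
    spacer_id: str
    strain_id: str
    locus_id: str
    sequence: str
    canonical: str
    index_from_trailer: int
    index_from_leader: Optional[int] = None
    cas_associated: bool = False
    subtype_context: Optional[str] = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SpacerCatalog:
    """Strain-folded spacer catalogue.

    A canonical sequence is *shared* iff carried by >=2 distinct strains;
    same-strain repeats count once toward sharing.
    """

    records: list[SpacerRecord]
    clusters: dict[str, list[SpacerRecord]]
    raw_clusters: dict[str, list[SpacerRecord]]  # raw-strand (unfolded) grouping

    @property
    def strains_by_canonical(self) -> dict[str, set[str]]:
        return {c: {r.strain_id for r in recs} for c, recs in self.clusters.items()}

    @property
    def shared_canonicals(self) -> list[str]:
        return sorted(
            c for c, strains in self.strains_by_canonical.items() if len(strains) >= 2
        )

    @property
    def unique_count(self) -> int:
        return len(self.clusters) - self.shared_count

    @property
    def shared_count(self) -> int:
        return len(self.shared_canonicals)


@dataclass
class MatchHit:
    """A 100%-identity hit of a spacer against a target sequence.

    category ``perfect`` covers the entire spacer; ``partial`` is a maximal
    exact common substring with 18 <= length < spacer length.
    """

    spacer_id: str
    target_id: str
    target_class: str  # prophage | known_MGE | self
    strand: str  # '+' or '-'
    target_offset: int
    match_length: int
    category: str  # perfect | partial
    overlaps_prophage: bool = False
    in_crispr_locus: bool = False
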