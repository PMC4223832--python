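"""Spacer extraction, canonicalization and cross-strain cataloguing.

Spacers are indexed from the trailer end (index 0 = most ancestral spacer)
because new spacers are integrated at the leader.  When a locus has no
orientation call, the forward-strand order stands in for trailer order (a
deterministic convention) and the leader index is undefined.

Sharing is computed on canonical (strand-folded) sequences so that the
same spacer read off opposite strands in two strains is not split; the
raw-strand grouping is also kept for comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cas import CasCluster
from .models import CrisprLocus, GenomeRecord, SpacerCatalog, SpacerRecord, canonical


def extract_spacers(loci: list[CrisprLocus],
                    cas_association: dict[str, str | None] | None = None,
                    cluster_subtypes: dict[str, str] | None = None
                    ) -> list[SpacerRecord]:
    """One SpacerRecord per spacer interval of each locus.

    ``cas_association`` maps locus_id -> cluster_id|None and
    ``cluster_subtypes`` maps cluster_id -> subtype label; both optional.
    """
    cas_association = cas_association or {}
    cluster_subtypes = cluster_subtypes or {}
    records: list[SpacerRecord] = []
    for locus in loci:
        n = locus.n_spacers
        cluster = cas_association.get(locus.locus_id)
        subtype = cluster_subtypes.get(cluster) if cluster else None
        for i, seq in enumerate(locus.spacers):
            if locus.orientation == "leader_left":
                from_trailer, from_leader = n - 1 - i, i
            elif locus.orientation == "leader_right":
                from_trailer, from_leader = i, n - 1 - i
            else:
                from_trailer, from_leader = i, None
            records.append(SpacerRecord(
                spacer_id=f"{locus.strain_id}|{locus.locus_id}|{from_trailer}",
                strain_id=locus.strain_id,
                locus_id=locus.locus_id,
                sequence=seq,
                canonical=canonical(seq),
                index_from_trailer=from_trailer,
                index_from_leader=from_leader,
                cas_associated=cluster is not None,
                subtype_context=subtype,
            ))
    return records


def build_catalog(records: list[SpacerRecord]) -> SpacerCatalog:
    """Cluster spacer records by exact canonical identity.

    A canonical sequence is shared iff present in >=2 distinct strains;
    multiple copies within one strain count once toward sharing.
    """
    clusters: dict[str, list[SpacerRecord]] = {}
    raw: dict[str, list[SpacerRecord]] = {}
    for rec in records:
        clusters.setdefault(rec.canonical, []).append(rec)
        raw.setdefault(rec.sequence, []).append(rec)
    return SpacerCatalog(records=list(records), clusters=clusters, raw_clusters=raw)


def per_strain_summary(catalog: SpacerCatalog,
                       loci: list[CrisprLocus],
                       clusters: list[CasCluster],
                       genomes: dict[str, GenomeRecord],
                       cas_association: dict[str, str | None] | None = None
                       ) -> pd.DataFrame:
    """Per-strain summary table: locus counts (raw and per Mb), locus sizes,
    spacer counts, cas-association fraction and subtype inventory."""
    cas_association = cas_association or {}
    subtype_by_cluster = {c.cluster_id: c.subtype for c in clusters}
    rows = []
    for strain_id in sorted(genomes):
        g = genomes[strain_id]
        s_loci = [l for l in loci if l.strain_id == strain_id]
        n_loci = len(s_loci)
        spacer_counts = [l.n_spacers for l in s_loci]
        sizes = [l.size for l in s_loci]
        assoc = [l for l in s_loci if cas_association.get(l.locus_id)]
        subtypes = sorted({
            subtype_by_cluster.get(cas_association[l.locus_id], "unclassified")
            for l in assoc
        })
        rows.append({
            "strain_id": strain_id,
            "genome_size": g.genome_size,
            "n_loci": n_loci,
            "loci_per_mb": round(n_loci / (g.genome_size / 1e6), 1),
            "locus_size_mean": round(float(np.mean(sizes)), 1) if sizes else 0.0,
            "locus_size_sd": round(float(np.std(sizes, ddof=1)), 1)
            if len(sizes) > 1 else 0.0,
            "n_spacers": int(sum(spacer_counts)),
            "spacers_per_locus_mean": round(float(np.mean(spacer_counts)), 1)
            if spacer_counts else 0.0,
            "spacers_per_locus_sd": round(float(np.std(spacer_counts, ddof=1)), 1)
            if len(spacer_counts) > 1 else 0.0,
            "pct_loci_cas_associated": round(100 * len(assoc) / n_loci, 1)
            if n_loci else 0.0,
            "subtypes": ",".join(subtypes),
        })
    return pd.DataFrame(rows)
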