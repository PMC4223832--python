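"""End-to-end orchestration: detection → cas typing → cataloguing →
matching → comparison → biogeography, with deterministic report output.

Only *confirmed* arrays enter downstream analysis; questionable ones are
retained in the locus table for inspection but contribute no spacers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import cas as casmod
from . import catalog as catmod
from . import compare as cmpmod
from . import detect as detmod
from . import io as iomod
from . import matching as matmod
from . import stats as statmod
from .models import (AnnotatedGene, CrisprLocus, GenomeRecord, Region,
                     RegionSet, SpacerCatalog, SpacerRecord, StrainMetadata)


@dataclass
class PipelineResult:
    genomes: dict[str, GenomeRecord]
    metadata: dict[str, StrainMetadata]
    loci: list[CrisprLocus]
    confirmed_loci: list[CrisprLocus]
    clusters: list
    association: dict[str, Optional[str]]
    paired: list[tuple[str, str, str]]
    records: list[SpacerRecord]
    catalog: SpacerCatalog
    hits: list
    self_hits: list
    per_strain: pd.DataFrame
    species_summary: pd.DataFrame
    match_summaries: dict[str, pd.DataFrame]
    sharing_fraction: Optional[float]
    sharing_table: Optional[pd.DataFrame]
    stat_results: list
    homolog_groups: list[list[str]]
    blocks_by_group: dict[str, list]
    variant_groups: list
    summary: dict = field(default_factory=dict)


def run_pipeline(genomes: dict[str, GenomeRecord],
                 metadata: dict[str, StrainMetadata],
                 genes: dict[str, list[AnnotatedGene]] | None = None,
                 prophages: RegionSet | None = None,
                 mge_db: list[Region] | None = None,
                 det_cfg: detmod.DetectionConfig | None = None,
                 signatures=None,
                 clade_group_of: dict[str, str] | None = None,
                 include_partial_prophage: bool = True) -> PipelineResult:
    """Run every stage on an in-memory dataset.

    ``clade_group_of`` (strain -> group) drives group-specific block
    calling on homologous loci; when absent, the metadata phylotype is
    used.  Missing inputs (annotations, prophages, MGE database) skip the
    dependent stages gracefully.
    """
    det_cfg = det_cfg or detmod.DetectionConfig()
    genes = genes or {}
    prophages = prophages or RegionSet()
    mge_db = mge_db or []
    signatures = signatures if signatures is not None else casmod.load_signatures()
    aliases = casmod.load_aliases()

    all_loci: list[CrisprLocus] = []
    clusters = []
    association: dict[str, Optional[str]] = {}
    paired: list[tuple[str, str, str]] = []
    for sid in sorted(genomes):
        genome = genomes[sid]
        loci = detmod.find_candidate_arrays(genome, det_cfg)
        merged: list[CrisprLocus] = []
        for cid in sorted(genome.contigs):
            on_contig = [l for l in loci if l.contig_id == cid]
            merged.extend(detmod.merge_adjacent_loci(
                on_contig, genome.contigs[cid], det_cfg))
        s_clusters = casmod.find_cas_clusters(genes.get(sid, []), sid,
                                              aliases=aliases)
        for cl in s_clusters:
            casmod.classify_subtype(cl, signatures, aliases)
        assoc = casmod.associate_crispr_cas(merged, s_clusters)
        cluster_by_id = {c.cluster_id: c for c in s_clusters}
        for loc in merged:
            side = None
            cl_id = assoc.get(loc.locus_id)
            if cl_id:
                cl = cluster_by_id[cl_id]
                if cl.end <= loc.start:
                    side = "left"
                elif cl.start >= loc.end:
                    side = "right"
            loc.orientation = detmod.orient_locus(
                loc, genome.contigs[loc.contig_id], cas_side=side)
        paired.extend(detmod.detect_paired_loci(merged, s_clusters))
        all_loci.extend(merged)
        clusters.extend(s_clusters)
        association.update(assoc)

    confirmed = [l for l in all_loci if l.confidence == "confirmed"]
    subtype_of = {c.cluster_id: c.subtype for c in clusters}
    records = catmod.extract_spacers(confirmed, association, subtype_of)
    catalog = catmod.build_catalog(records)

    prophage_targets = [(r.region_id, r.sequence, "prophage")
                        for r in prophages.by_class("prophage")]
    mge_targets = [(r.region_id, r.sequence, "known_MGE") for r in mge_db]
    hits = matmod.match_spacers(records, prophage_targets,
                                include_partial=include_partial_prophage)
    # the partial (>=18 nt) rule is headline only for the known-MGE search
    hits += matmod.match_spacers(records, mge_targets, include_partial=True)
    hits.sort(key=lambda h: (h.spacer_id, h.target_id, h.target_offset,
                             h.strand, h.category))
    self_hits = []
    rec_by_strain: dict[str, list[SpacerRecord]] = {}
    for r in records:
        rec_by_strain.setdefault(r.strain_id, []).append(r)
    for sid in sorted(genomes):
        self_hits.extend(matmod.self_targeting_scan(
            genomes[sid],
            [l for l in all_loci if l.strain_id == sid],
            rec_by_strain.get(sid, []),
            prophages.for_strain(sid)))

    per_strain = catmod.per_strain_summary(catalog, confirmed, clusters,
                                           genomes, association)
    species_summary = _species_summary(per_strain, metadata, confirmed,
                                       clusters, association, records, hits,
                                       prophages)

    match_summaries = {}
    group_defs = {
        "strain": {r.spacer_id: r.strain_id for r in records},
        "species": {r.spacer_id: metadata[r.strain_id].species
                    for r in records if r.strain_id in metadata},
        "cas": {r.spacer_id:
                "cas_associated" if r.cas_associated else "cas_devoid"
                for r in records},
        "subtype_family": {
            r.spacer_id: ("known" if r.subtype_context in ("I-E", "I-C", "I-B")
                          else "I-U")
            for r in records if r.subtype_context},
    }
    for name, grouping in group_defs.items():
        match_summaries[name] = matmod.match_summary(
            records, hits + self_hits, grouping, grouping_name=name)

    sharing_fraction = None
    sharing_table = None
    have_geo = metadata and all(m.location and m.biome
                                for m in metadata.values())
    if have_geo:
        sharing_fraction, sharing_table = statmod.location_restricted_fraction(
            catalog, metadata)

    stat_results = _run_stats(per_strain, metadata, prophages, records, hits)

    arrays = {l.locus_id: cmpmod.token_array(l, records) for l in confirmed}
    homolog_groups = cmpmod.find_homologous_loci(confirmed, arrays)
    group_of = clade_group_of or {
        sid: (metadata[sid].phylotype or "all") for sid in metadata}
    blocks_by_group: dict[str, list] = {}
    loci_by_id = {l.locus_id: l for l in confirmed}
    for grp in homolog_groups:
        if len(grp) < 2:
            continue
        strains = {loci_by_id[lid].strain_id for lid in grp}
        if len(strains) < 2:
            continue
        aln = cmpmod.align_token_arrays([arrays[lid] for lid in grp])
        sub_groups = {s: group_of.get(s, "all") for s in aln.strain_ids}
        blocks_by_group["+".join(grp)] = cmpmod.group_specific_blocks(
            aln, sub_groups)
    location_of = {sid: m.location for sid, m in metadata.items()}
    variant_groups = cmpmod.find_spacer_variants(catalog, location_of)

    summary = {
        "n_strains": len(genomes),
        "n_loci_total": len(all_loci),
        "n_loci_confirmed": len(confirmed),
        "n_spacers": len(records),
        "n_distinct_canonical": len(catalog.clusters),
        "n_unique": catalog.unique_count,
        "n_shared": catalog.shared_count,
        "pct_unique": round(100 * catalog.unique_count
                            / max(1, len(catalog.clusters)), 1),
        "n_cas_clusters": len(clusters),
        "n_paired_loci": len(paired),
        "n_self_hits": len(self_hits),
        "pct_shared_location_restricted": sharing_fraction,
    }
    return PipelineResult(
        genomes=genomes, metadata=metadata, loci=all_loci,
        confirmed_loci=confirmed, clusters=clusters, association=association,
        paired=paired, records=records, catalog=catalog, hits=hits,
        self_hits=self_hits, per_strain=per_strain,
        species_summary=species_summary, match_summaries=match_summaries,
        sharing_fraction=sharing_fraction, sharing_table=sharing_table,
        stat_results=stat_results, homolog_groups=homolog_groups,
        blocks_by_group=blocks_by_group, variant_groups=variant_groups,
        summary=summary)


def _species_summary(per_strain: pd.DataFrame,
                     metadata: dict[str, StrainMetadata],
                     confirmed, clusters, association, records, hits,
                     prophages: RegionSet) -> pd.DataFrame:
    """Per-species corpus table: loci/strain (per Mb), locus sizes, cas
    association, spacers/strain, prophages/strain, and the fraction of
    spacers with perfect matches to prophages / known MGEs."""
    if per_strain.empty:
        return pd.DataFrame()
    hit_class: dict[str, set[str]] = {}
    for h in hits:
        if h.category == "perfect":
            hit_class.setdefault(h.spacer_id, set()).add(h.target_class)
    rows = []
    species_of = {sid: m.species for sid, m in metadata.items()}
    for species in sorted(set(species_of.values())):
        strains = sorted(s for s, sp in species_of.items() if sp == species)
        sub = per_strain[per_strain["strain_id"].isin(strains)]
        sp_loci = [l for l in confirmed if l.strain_id in strains]
        assoc = [l for l in sp_loci if association.get(l.locus_id)]
        sp_recs = [r for r in records if r.strain_id in strains]
        n_phage = sum(1 for r in sp_recs
                      if "prophage" in hit_class.get(r.spacer_id, ()))
        n_mge = sum(1 for r in sp_recs
                    if "known_MGE" in hit_class.get(r.spacer_id, ()))
        sizes = [l.size for l in sp_loci]
        n_prophage_regions = len(
            [r for r in prophages.entries if r.source_id in strains])
        rows.append({
            "species": species,
            "genomes": len(strains),
            "total_crisprs": len(sp_loci),
            "avg_loci_per_strain": round(len(sp_loci) / len(strains), 1),
            "avg_loci_per_mb": round(float(sub["loci_per_mb"].mean()), 1),
            "locus_size_mean": round(float(np.mean(sizes)), 0) if sizes else 0,
            "locus_size_sd": round(float(np.std(sizes, ddof=1)), 0)
            if len(sizes) > 1 else 0,
            "loci_with_cas_pct": round(100 * len(assoc) / len(sp_loci), 1)
            if sp_loci else 0.0,
            "total_spacers": len(sp_recs),
            "avg_spacers_per_strain": round(len(sp_recs) / len(strains), 1),
            "avg_prophages_per_strain": round(
                n_prophage_regions / len(strains), 1),
            "pct_spacers_matching_prophages": round(
                100 * n_phage / len(sp_recs), 1) if sp_recs else 0.0,
            "pct_spacers_matching_known_mges": round(
                100 * n_mge / len(sp_recs), 1) if sp_recs else 0.0,
        })
    return pd.DataFrame(rows)


def _run_stats(per_strain: pd.DataFrame,
               metadata: dict[str, StrainMetadata],
               prophages: RegionSet, records, hits) -> list:
    """The statistical battery, each test skipped (not failed) when its
    preconditions cannot be met on the given dataset."""
    results = []
    if per_strain.empty or not metadata:
        return results
    df = per_strain.copy()
    df["species"] = df["strain_id"].map(
        {s: m.species for s, m in metadata.items()})
    df["n_prophages"] = df["strain_id"].map(
        lambda s: len(prophages.for_strain(s)))
    # omnibus + gated pairwise on normalized locus counts across species
    groups = {sp: g["loci_per_mb"].tolist()
              for sp, g in df.groupby("species") if len(g) >= 1}
    if len(groups) >= 2:
        try:
            omnibus, pairwise = statmod.gated_pairwise(groups)
            omnibus.normalization = "per_mb"
            results.append(("loci_per_mb_by_species", omnibus))
            for a, b, res in pairwise:
                res.normalization = "per_mb"
                results.append((f"loci_per_mb:{a}_vs_{b}", res))
        except ValueError:
            pass
    # prophage-presence contrast on fraction of spacers matching prophages
    phage_hit = {h.spacer_id for h in hits
                 if h.category == "perfect" and h.target_class == "prophage"}
    frac = {}
    for sid in df["strain_id"]:
        recs = [r for r in records if r.strain_id == sid]
        frac[sid] = (100 * sum(1 for r in recs if r.spacer_id in phage_hit)
                     / len(recs)) if recs else 0.0
    with_p = [frac[s] for s in df["strain_id"]
              if len(prophages.for_strain(s)) > 0]
    without_p = [frac[s] for s in df["strain_id"]
                 if len(prophages.for_strain(s)) == 0]
    if len(with_p) >= 2 and len(without_p) >= 2:
        try:
            results.append(("prophage_presence_ttest",
                            statmod.two_sample_t(with_p, without_p)))
        except ValueError:
            pass
    # correlations of CRISPR content with prophage content
    for col in ("n_loci", "n_spacers"):
        try:
            results.append((f"{col}_vs_prophages",
                            statmod.least_squares_r2(
                                df["n_prophages"], df[col])))
        except ValueError:
            pass
    return results


def write_outputs(result: PipelineResult, out_dir: str) -> None:
    """Write every stage's tables plus the JSON summary, deterministically
    ordered so identical runs are byte-identical."""
    os.makedirs(out_dir, exist_ok=True)
    iomod.write_loci_gff(result.loci, os.path.join(out_dir, "loci.gff3"))
    loci_rows = [{
        "locus_id": l.locus_id, "strain_id": l.strain_id,
        "contig_id": l.contig_id, "start": l.start, "end": l.end,
        "n_repeats": l.n_repeats, "n_spacers": l.n_spacers,
        "repeat_length_mean": round(l.repeat_length_mean, 1),
        "consensus_repeat": l.consensus_repeat,
        "orientation": l.orientation, "confidence": l.confidence,
        "merged_from": ",".join(l.merged_from),
        "cas_cluster": result.association.get(l.locus_id) or "",
    } for l in sorted(result.loci,
                      key=lambda l: (l.strain_id, l.contig_id, l.start))]
    loci_cols = ["locus_id", "strain_id", "contig_id", "start", "end",
                 "n_repeats", "n_spacers", "repeat_length_mean",
                 "consensus_repeat", "orientation", "confidence",
                 "merged_from", "cas_cluster"]
    iomod.write_table(pd.DataFrame(loci_rows, columns=loci_cols),
                      os.path.join(out_dir, "loci.tsv"))
    cl_rows = [{
        "cluster_id": c.cluster_id, "strain_id": c.strain_id,
        "contig_id": c.contig_id, "start": c.start, "end": c.end,
        "subtype": c.subtype, "complete": c.complete,
        "has_cas1": c.has_cas1, "has_cas3": c.has_cas3,
        "genes": ",".join(c.gene_names),
    } for c in sorted(result.clusters,
                      key=lambda c: (c.strain_id, c.contig_id, c.start))]
    cl_cols = ["cluster_id", "strain_id", "contig_id", "start", "end",
               "subtype", "complete", "has_cas1", "has_cas3", "genes"]
    iomod.write_table(pd.DataFrame(cl_rows, columns=cl_cols),
                      os.path.join(out_dir, "clusters.tsv"))
    iomod.write_spacers_fasta(result.records,
                              os.path.join(out_dir, "spacers.fasta"))
    cat_rows = [{
        "canonical": c,
        "n_strains": len({r.strain_id for r in recs}),
        "n_records": len(recs),
        "strains": ",".join(sorted({r.strain_id for r in recs})),
    } for c, recs in sorted(result.catalog.clusters.items())]
    iomod.write_table(pd.DataFrame(
        cat_rows, columns=["canonical", "n_strains", "n_records", "strains"]),
        os.path.join(out_dir, "catalog.tsv"))
    hit_rows = [{
        "spacer_id": h.spacer_id, "target_id": h.target_id,
        "target_class": h.target_class, "strand": h.strand,
        "target_offset": h.target_offset, "match_length": h.match_length,
        "category": h.category, "overlaps_prophage": h.overlaps_prophage,
    } for h in result.hits + result.self_hits]
    hit_cols = ["spacer_id", "target_id", "target_class", "strand",
                "target_offset", "match_length", "category",
                "overlaps_prophage"]
    iomod.write_table(pd.DataFrame(hit_rows, columns=hit_cols),
                      os.path.join(out_dir, "hits.tsv"))
    iomod.write_table(result.per_strain,
                      os.path.join(out_dir, "per_strain.tsv"))
    iomod.write_table(result.species_summary,
                      os.path.join(out_dir, "species_summary.tsv"))
    for name, df in sorted(result.match_summaries.items()):
        iomod.write_table(df, os.path.join(out_dir, f"match_by_{name}.tsv"))
    if result.sharing_table is not None:
        iomod.write_table(result.sharing_table,
                          os.path.join(out_dir, "sharing.tsv"))
    stat_rows = [{
        "analysis": name, "test": r.test,
        "statistic": round(r.statistic, 6), "p_value": round(r.p_value, 6),
        "group_sizes": ",".join(map(str, r.group_sizes)),
        "normalization": r.normalization,
    } for name, r in result.stat_results]
    stat_cols = ["analysis", "test", "statistic", "p_value", "group_sizes",
                 "normalization"]
    iomod.write_table(pd.DataFrame(stat_rows, columns=stat_cols),
                      os.path.join(out_dir, "stats.tsv"))
    iomod.write_json(result.summary, os.path.join(out_dir, "summary.json"))
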