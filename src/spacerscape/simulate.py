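"""Synthetic multi-strain genome sets with planted CRISPR-Cas features.

The generator emulates the statistical structure the analysis assumes:
strain-variable array counts, subtype-specific conserved repeats beside
cas operons, shared vs unique spacer pools with location structure,
prophages carrying protospacers, self-targeting spacers, clade-specific
spacer blocks and SNP spacer variants — each recorded in a ground-truth
manifest sufficient to score every pipeline stage.

Background sequence is i.i.d. at the configured GC; repeats and spacers
are drawn uniform-random and then frozen in the manifest, so at the
simulated scale (<= ~1 Mb per genome) no unintended repeat structure
arises.  Everything is driven by one numpy Generator: identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .models import (AnnotatedGene, GenomeRecord, Region, RegionSet,
                     StrainMetadata, canonical)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

SUBTYPE_GENE_ORDER = {
    "I-E": ["cas3", "cse1", "cse2", "cas7", "cas5", "cas6", "cas1", "cas2"],
    "I-C": ["cas3", "cas5", "cas8c", "cas7", "cas4", "cas1", "cas2"],
    "I-B": ["cas3", "cst1", "cas7", "cas5", "cas6", "cas4", "cas1", "cas2"],
    "I-U_csb3": ["cas3", "csb3", "csb2", "csb1", "cas1", "cas2"],
    "I-U_csx17": ["cas3", "csx17", "csb2"],
    "I-U_Sa": ["cas3", "csb1", "csb2", "cas2"],
}

DEFAULT_LOCATIONS = ("Sea of Cortez", "Hawaii", "Fiji", "Palmyra",
                     "Bahamas", "Palau")
DEFAULT_BIOMES = {
    "Sea of Cortez": "Coastal",
    "Hawaii": "Tropical Pacific",
    "Fiji": "Tropical Pacific",
    "Palmyra": "Tropical Pacific",
    "Bahamas": "Tropical Atlantic",
    "Palau": "Tropical Pacific",
}


@dataclass
class HomologousLocusSpec:
    """One homologous locus shared by several strains, with clade-specific
    spacer blocks.

    ``strain_groups`` maps a group name to member strain indices; blocks
    are (group_name, n_spacers) runs present only in that group, planted by
    omitting the run from every other strain (so the alignment cannot tell
    deletion from insertion, as in real subclade comparisons).
    """

    strain_groups: dict[str, list[int]]
    n_core_spacers: int = 10
    blocks: list[tuple[str, int]] = field(default_factory=list)


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    Defaults mirror the observed corpus structure: ~4.4 arrays per strain,
    subtype repeats of 29 nt (I-E, I-B) and 37 nt (I-C, I-U), ~60% of loci
    cas-associated, ~1.3 prophages per strain, ~12% of spacers with a
    planted protospacer (≈0.9 of those in prophages, the rest in the
    known-MGE database), and 40% of planted shared spacers restricted to a
    single location.
    """

    seed: int
    n_strains: int = 10
    genome_length: int = 1_000_000
    background_gc: float = 0.70
    arrays_per_strain_mean: float = 4.4
    spacers_per_array: tuple[int, int] = (8, 24)
    spacer_len_range: tuple[int, int] = (34, 41)
    repeat_len_by_subtype: dict[str, int] = field(default_factory=lambda: {
        "I-E": 29, "I-B": 29, "I-C": 37, "I-U_csb3": 37,
        "I-U_csx17": 37, "I-U_Sa": 37})
    repeat_mutation_rate: float = 0.0
    cas_associated_fraction: float = 0.6
    subtype_cycle: tuple[str, ...] = ("I-E", "I-C", "I-B", "I-U_csb3",
                                      "I-U_csx17", "I-U_Sa")
    prophages_per_strain_mean: float = 1.3
    prophage_length: int = 12_000
    n_mge_records: int = 20
    mge_length: int = 5_000
    protospacer_rate: float = 0.12
    protospacer_partial_fraction: float = 0.2
    protospacer_mge_fraction: float = 0.1
    self_target_rate: float = 0.01
    self_target_prophage_fraction: float = 0.3
    shared_spacer_count: int = 20
    location_restricted_rate: float = 0.4
    locations: tuple[str, ...] = DEFAULT_LOCATIONS
    biome_of: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_BIOMES))
    species_cycle: tuple[str, ...] = ("S. arenicola", "S. pacifica", "S. tropica")
    homologous_group: Optional[HomologousLocusSpec] = None
    variant_spec: Optional[list[tuple[str, int, int]]] = None
    variant_length: int = 41
    variant_max_snps: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("repeat_mutation_rate", "cas_associated_fraction",
                     "protospacer_rate", "protospacer_partial_fraction",
                     "protospacer_mge_fraction", "self_target_rate",
                     "self_target_prophage_fraction",
                     "location_restricted_rate", "background_gc"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0,1]")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    genomes: dict[str, GenomeRecord]
    metadata: dict[str, StrainMetadata]
    genes: dict[str, list[AnnotatedGene]]
    prophages: RegionSet
    mge_db: list[Region]
    truth: dict


@dataclass
class Score:
    precision: float
    recall: float

    @property
    def f1(self) -> float:
        if self.precision + self.recall == 0:
            return 0.0
        return 2 * self.precision * self.recall / (self.precision + self.recall)


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=length, p=p)
    return _BASES[idx].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hit:
        others = [b for b in b"ACGT" if bytes([b]) != arr[i]]
        arr[i] = bytes([others[rng.integers(0, 3)]])
    return arr.tobytes().decode()


class _UniquePool:
    """Draws globally unique random sequences."""

    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.seen: set[str] = set()

    def draw(self, length: int, gc: float = 0.5,
             first_last: str | None = None) -> str:
        while True:
            s = _random_seq(self.rng, length, gc)
            if first_last:
                s = first_last + s[1:-1] + first_last
            if s not in self.seen and canonical(s) not in self.seen:
                self.seen.add(s)
                self.seen.add(canonical(s))
                return s


# ---------------------------------------------------------------------------
# planning structures (internal)
# ---------------------------------------------------------------------------

@dataclass
class _ArrayPlan:
    strain: str
    repeat: str
    spacers: list[str]
    subtype: Optional[str]  # None => cas-devoid
    homolog_label: Optional[str] = None


@dataclass
class _Placement:  # a protospacer planted in a target
    spacer: str
    target_id: str
    target_class: str
    offset: int
    length: int
    category: str


def simulate_dataset(cfg: SimulationConfig,
                     out_dir: str | None = None) -> SyntheticDataset:
    """Generate the full dataset (and optionally write it to ``out_dir``).

    Deterministic given ``cfg.seed``; planted features never overlap; the
    truth manifest is complete enough to score every stage.
    """
    rng = np.random.default_rng(cfg.seed)
    pool = _UniquePool(rng)
    lo_sp, hi_sp = cfg.spacers_per_array
    lo_len, hi_len = cfg.spacer_len_range

    # --- strains & metadata ------------------------------------------------
    strain_ids = [f"S{i + 1:02d}" for i in range(cfg.n_strains)]
    metadata: dict[str, StrainMetadata] = {}
    for i, sid in enumerate(strain_ids):
        loc = cfg.locations[i % len(cfg.locations)]
        metadata[sid] = StrainMetadata(
            strain_id=sid,
            species=cfg.species_cycle[i % len(cfg.species_cycle)],
            phylotype="ABC"[i % 3],
            location=loc,
            biome=cfg.biome_of.get(loc, "Oceanic"),
            latitude=round(float(rng.uniform(-25, 25)), 4),
            longitude=round(float(rng.uniform(-180, 180)), 4),
            depth=round(float(rng.uniform(1, 50)), 1),
            date="2004-06-15",
        )

    # --- subtype repeats (dataset-wide, conserved) -------------------------
    subtype_repeat = {
        st: pool.draw(cfg.repeat_len_by_subtype[st])
        for st in cfg.subtype_cycle
    }
    homolog_repeat = pool.draw(37)

    # --- per-strain array plans -------------------------------------------
    plans: dict[str, list[_ArrayPlan]] = {s: [] for s in strain_ids}
    subtype_ptr = 0
    for sid in strain_ids:
        n_arrays = max(1, int(rng.poisson(cfg.arrays_per_strain_mean)))
        n_cas = round(cfg.cas_associated_fraction * n_arrays)
        for j in range(n_arrays):
            if j < n_cas:
                st = cfg.subtype_cycle[subtype_ptr % len(cfg.subtype_cycle)]
                subtype_ptr += 1
                repeat = subtype_repeat[st]
            else:
                st = None
                repeat = pool.draw(int(rng.choice([29, 37])))
            n_sp = int(rng.integers(lo_sp, hi_sp + 1))
            spacers = [pool.draw(int(rng.integers(lo_len, hi_len + 1)))
                       for _ in range(n_sp)]
            plans[sid].append(_ArrayPlan(sid, repeat, spacers, st))

    # --- homologous locus with clade-specific blocks -----------------------
    clade_blocks_truth: list[dict] = []
    if cfg.homologous_group is not None:
        spec = cfg.homologous_group
        core = [pool.draw(int(rng.integers(lo_len, hi_len + 1)))
                for _ in range(spec.n_core_spacers)]
        block_tokens = {}
        for grp, blen in spec.blocks:
            key = f"{grp}:{len(block_tokens)}"
            block_tokens[key] = (grp, [
                pool.draw(int(rng.integers(lo_len, hi_len + 1)))
                for _ in range(blen)])
        # interleave: core chunks alternating with blocks
        n_slots = len(spec.blocks) + 1
        chunk = max(1, len(core) // n_slots)
        chunks = [core[i * chunk:(i + 1) * chunk] for i in range(n_slots - 1)]
        chunks.append(core[(n_slots - 1) * chunk:])
        block_items = list(block_tokens.values())
        for grp, members in sorted(spec.strain_groups.items()):
            for idx in members:
                sid = strain_ids[idx]
                tokens: list[str] = []
                for ci, ch in enumerate(chunks):
                    tokens.extend(ch)
                    if ci < len(block_items):
                        bgrp, btoks = block_items[ci]
                        if bgrp == grp:
                            tokens.extend(btoks)
                plans[sid].append(_ArrayPlan(
                    sid, homolog_repeat, list(tokens), None,
                    homolog_label="homolog"))
        for bgrp, btoks in block_items:
            clade_blocks_truth.append({"group": bgrp, "tokens": btoks})

    # --- shared spacer pool with location structure ------------------------
    # free slots: (strain, plan_idx, spacer_idx) in non-homolog arrays
    free_slots: dict[str, list[tuple[int, int]]] = {
        sid: [(pi, si)
              for pi, p in enumerate(plans[sid]) if p.homolog_label is None
              for si in range(len(p.spacers))]
        for sid in strain_ids
    }
    used: set[tuple[str, int, int]] = set()

    def take_slot(sid: str) -> tuple[int, int]:
        avail = [s for s in free_slots[sid] if (sid,) + s not in used]
        if not avail:
            raise ValueError(f"no free spacer slots left in strain {sid}")
        pick = avail[int(rng.integers(0, len(avail)))]
        used.add((sid,) + pick)
        return pick

    by_location: dict[str, list[str]] = {}
    for sid in strain_ids:
        by_location.setdefault(metadata[sid].location, []).append(sid)
    shared_truth: list[dict] = []
    if cfg.shared_spacer_count:
        n_restricted = round(cfg.location_restricted_rate
                             * cfg.shared_spacer_count)
        multi_locs = sorted(l for l, ss in by_location.items() if len(ss) >= 2)
        coastal = sorted(s for s in strain_ids
                         if metadata[s].biome == "Coastal")
        non_coastal = sorted(s for s in strain_ids
                             if metadata[s].biome != "Coastal")
        if n_restricted and not multi_locs:
            raise ValueError("restricted sharing needs a location with >=2 strains")
        if cfg.shared_spacer_count > n_restricted and (
                not coastal or not non_coastal):
            raise ValueError("unrestricted sharing needs >=2 biomes among strains")
        for k in range(cfg.shared_spacer_count):
            seq = pool.draw(int(rng.integers(lo_len, hi_len + 1)))
            if k < n_restricted:
                loc = multi_locs[k % len(multi_locs)]
                members = by_location[loc][:2]
                restricted = True
            else:
                members = [coastal[k % len(coastal)],
                           non_coastal[k % len(non_coastal)]]
                restricted = False
            for sid in members:
                pi, si = take_slot(sid)
                plans[sid][pi].spacers[si] = seq
            shared_truth.append({
                "sequence": seq, "strains": sorted(members),
                "restricted": restricted,
                "locations": sorted({metadata[s].location for s in members}),
            })

    # --- SNP spacer variants ------------------------------------------------
    variant_truth: list[dict] = []
    if cfg.variant_spec:
        base = pool.draw(cfg.variant_length, first_last="A")
        snp_pos = sorted(rng.choice(
            np.arange(1, cfg.variant_length - 1),
            size=cfg.variant_max_snps, replace=False).tolist())
        variants_made: list[str] = []

        def make_variant(v: int) -> str:
            s = list(base)
            for bit in range(cfg.variant_max_snps):
                if v >> bit & 1:
                    p = snp_pos[bit]
                    s[p] = "ACGT"[("ACGT".index(s[p]) + 1) % 4]
            return "".join(s)

        group_members: list[dict] = []
        v_counter = 0
        for loc, n_strains_here, n_variants in cfg.variant_spec:
            candidates = by_location.get(loc, [])
            if len(candidates) < n_strains_here:
                raise ValueError(
                    f"variant spec needs {n_strains_here} strains at {loc}, "
                    f"found {len(candidates)}")
            chosen = candidates[:n_strains_here]
            these = [make_variant(v_counter + i) for i in range(n_variants)]
            v_counter += n_variants
            variants_made.extend(these)
            carriers: dict[str, list[str]] = {v: [] for v in these}
            for j, sid in enumerate(chosen):
                v = these[j % n_variants]
                pi, si = take_slot(sid)
                plans[sid][pi].spacers[si] = v
                carriers[v].append(sid)
            for v in these:
                group_members.append({"sequence": v, "location": loc,
                                      "strains": sorted(carriers[v])})
        variant_truth.append({
            "base": base, "length": cfg.variant_length,
            "snp_positions": snp_pos, "variants": group_members})

    # --- prophage / MGE content and protospacer planting --------------------
    prophage_plan: dict[str, list[dict]] = {}  # strain -> [{'id','seq','used'}]
    all_prophages: list[tuple[str, dict]] = []
    for sid in strain_ids:
        n_p = int(rng.poisson(cfg.prophages_per_strain_mean))
        prophage_plan[sid] = []
        for j in range(n_p):
            entry = {
                "id": f"{sid}_P{j + 1}",
                "seq": bytearray(
                    _random_seq(rng, cfg.prophage_length,
                                cfg.background_gc).encode()),
                "used": [],
                "family": f"phage_fam{int(rng.integers(1, 4))}",
            }
            prophage_plan[sid].append(entry)
            all_prophages.append((sid, entry))
    mge_records = []
    for j in range(cfg.n_mge_records):
        mge_records.append({
            "id": f"MGE{j + 1:03d}",
            "seq": bytearray(_random_seq(rng, cfg.mge_length, 0.5).encode()),
            "used": [],
            "family": "plasmid" if j % 2 == 0 else "phage",
        })

    def plant_into(entry: dict, spacer: str, category: str) -> Optional[_Placement]:
        L = len(spacer)
        if category == "partial":
            k = int(rng.integers(18, max(19, L - 5)))
            frag = spacer[(L - k) // 2:(L - k) // 2 + k]
        else:
            k, frag = L, spacer
        for _ in range(50):
            off = int(rng.integers(100, len(entry["seq"]) - 100 - k))
            if all(off + k <= s or off >= e for s, e in entry["used"]):
                entry["seq"][off:off + k] = frag.encode()
                entry["used"].append((off, off + k))
                return _Placement(spacer, entry["id"], "", off, k, category)
        return None

    all_slots = [(sid, pi, si)
                 for sid in strain_ids
                 for pi, p in enumerate(plans[sid])
                 for si in range(len(p.spacers))]
    total_spacers = len(all_slots)
    n_plant = round(cfg.protospacer_rate * total_spacers)
    chosen_idx = rng.choice(total_spacers, size=min(n_plant, total_spacers),
                            replace=False)
    chosen_idx = [int(i) for i in chosen_idx]
    n_mge = round(cfg.protospacer_mge_fraction * len(chosen_idx))
    n_partial = round(cfg.protospacer_partial_fraction * len(chosen_idx))
    partial_set = set(chosen_idx[:n_partial])  # rng.choice order is random
    placements: list[_Placement] = []
    for rank, idx in enumerate(chosen_idx):
        sid, pi, si = all_slots[idx]
        spacer = plans[sid][pi].spacers[si]
        category = "partial" if idx in partial_set else "perfect"
        if rank < n_mge or not all_prophages:
            if not mge_records:
                continue
            entry = mge_records[int(rng.integers(0, len(mge_records)))]
            target_class = "known_MGE"
        else:
            _, entry = all_prophages[int(rng.integers(0, len(all_prophages)))]
            target_class = "prophage"
        pl = plant_into(entry, spacer, category)
        if pl is not None:
            pl.target_class = target_class
            placements.append(pl)

    # --- self-targeting plantings -------------------------------------------
    remaining = [i for i in range(total_spacers) if i not in set(chosen_idx)]
    n_self = round(cfg.self_target_rate * total_spacers)
    self_idx = [int(i) for i in rng.choice(len(remaining),
                                           size=min(n_self, len(remaining)),
                                           replace=False)]
    self_plan: dict[str, list[dict]] = {s: [] for s in strain_ids}
    n_self_phage = round(cfg.self_target_prophage_fraction * len(self_idx))
    self_truth: list[dict] = []
    for rank, ridx in enumerate(self_idx):
        sid, pi, si = all_slots[remaining[ridx]]
        spacer = plans[sid][pi].spacers[si]
        if rank < n_self_phage and prophage_plan[sid]:
            entry = prophage_plan[sid][0]
            pl = plant_into(entry, spacer, "perfect")
            if pl is not None:
                self_truth.append({"strain": sid, "sequence": spacer,
                                   "in_prophage": True,
                                   "region_id": entry["id"]})
        else:
            self_plan[sid].append({"spacer": spacer})
            self_truth.append({"strain": sid, "sequence": spacer,
                               "in_prophage": False, "region_id": None})

    # --- genome assembly ----------------------------------------------------
    genomes: dict[str, GenomeRecord] = {}
    genes: dict[str, list[AnnotatedGene]] = {}
    prophage_regions: list[Region] = []
    loci_truth: list[dict] = []
    cas_truth: list[dict] = []
    contig = "chr"
    min_gap = 2500
    for sid in strain_ids:
        blocks: list[dict] = []  # {'kind', 'seq', 'meta'}
        for plan in plans[sid]:
            parts = []
            rep_offsets = []
            pos = 0
            for si, sp in enumerate(plan.spacers + [None]):
                rep = _mutate(rng, plan.repeat, cfg.repeat_mutation_rate)
                rep_offsets.append(pos)
                parts.append(rep)
                pos += len(rep)
                if sp is not None:
                    parts.append(sp)
                    pos += len(sp)
            array_seq = "".join(parts)
            meta = {"plan": plan, "rep_offsets": rep_offsets,
                    "array_len": len(array_seq)}
            if plan.subtype is not None:
                gene_names = SUBTYPE_GENE_ORDER[plan.subtype]
                gseqs, gene_iv, gpos = [], [], 0
                for gn in gene_names:
                    glen = int(rng.integers(600, 1500))
                    gene_iv.append((gn, gpos, gpos + glen))
                    gseqs.append(_random_seq(rng, glen, cfg.background_gc))
                    gpos += glen + int(rng.integers(20, 200))
                cluster_seq = "".join(
                    s + _random_seq(rng, iv_next[1] - iv[2], cfg.background_gc)
                    for s, iv, iv_next in zip(
                        gseqs, gene_iv, gene_iv[1:] + [(None, gpos, None)]))
                gap = _random_seq(rng, int(rng.integers(120, 350)),
                                  cfg.background_gc)
                if rng.random() < 0.5:
                    meta["cas_local"] = (0, gene_iv)
                    meta["array_offset"] = len(cluster_seq) + len(gap)
                    seq = cluster_seq + gap + array_seq
                else:
                    meta["array_offset"] = 0
                    meta["cas_local"] = (len(array_seq) + len(gap), gene_iv)
                    seq = array_seq + gap + cluster_seq
            else:
                meta["array_offset"] = 0
                seq = array_seq
            blocks.append({"kind": "array", "seq": seq, "meta": meta})
        for entry in prophage_plan[sid]:
            blocks.append({"kind": "prophage",
                           "seq": entry["seq"].decode(),
                           "meta": {"entry": entry}})
        for sp in self_plan[sid]:
            flank_l = _random_seq(rng, 20, cfg.background_gc)
            flank_r = _random_seq(rng, 20, cfg.background_gc)
            blocks.append({"kind": "selfsite",
                           "seq": flank_l + sp["spacer"] + flank_r,
                           "meta": {"spacer": sp["spacer"]}})
        order = rng.permutation(len(blocks))
        blocks = [blocks[i] for i in order]
        total_block = sum(len(b["seq"]) for b in blocks)
        budget = cfg.genome_length - total_block - min_gap * (len(blocks) + 1)
        if budget < 0:
            raise ValueError("genome_length too small for planted features")
        extra = rng.multinomial(budget, [1 / (len(blocks) + 1)] * (len(blocks) + 1))
        genome = bytearray(
            _random_seq(rng, cfg.genome_length, cfg.background_gc).encode())
        strain_genes: list[AnnotatedGene] = []
        pos = 0
        hk = 0
        for bi, b in enumerate(blocks):
            pos += min_gap + int(extra[bi])
            genome[pos:pos + len(b["seq"])] = b["seq"].encode()
            m = b["meta"]
            if b["kind"] == "array":
                plan = m["plan"]
                a0 = pos + m["array_offset"]
                loci_truth.append({
                    "strain": sid, "contig": contig,
                    "start": a0, "end": a0 + m["array_len"],
                    "repeat": plan.repeat,
                    "repeat_starts": [a0 + o for o in m["rep_offsets"]],
                    "spacers": list(plan.spacers),
                    "subtype": plan.subtype,
                    "homolog_label": plan.homolog_label,
                })
                if "cas_local" in m:
                    c0, gene_iv = m["cas_local"]
                    for gn, gs, ge in gene_iv:
                        strain_genes.append(AnnotatedGene(
                            contig_id=contig, start=pos + c0 + gs,
                            end=pos + c0 + ge, strand="+", name=gn,
                            product=f"CRISPR-associated protein {gn}"))
                    cas_truth.append({
                        "strain": sid, "contig": contig,
                        "start": pos + c0 + gene_iv[0][1],
                        "end": pos + c0 + gene_iv[-1][2],
                        "genes": [g for g, _, _ in gene_iv],
                        "subtype": plan.subtype,
                    })
            elif b["kind"] == "prophage":
                entry = m["entry"]
                prophage_regions.append(Region(
                    region_id=entry["id"], source_id=sid,
                    region_class="prophage", sequence=b["seq"],
                    contig_id=contig, start=pos, end=pos + len(b["seq"]),
                    family=entry["family"], intact=True))
            else:  # selfsite: annotate as a housekeeping gene
                hk += 1
                strain_genes.append(AnnotatedGene(
                    contig_id=contig, start=pos, end=pos + len(b["seq"]),
                    strand="+", name=f"hk{hk}",
                    product="housekeeping gene"))
            pos += len(b["seq"])
        g = GenomeRecord(strain_id=sid, contigs={contig: genome.decode()},
                         gene_count=cfg.genome_length // 1100)
        genomes[sid] = g
        genes[sid] = sorted(strain_genes, key=lambda x: (x.contig_id, x.start))

    mge_db = [Region(region_id=m["id"], source_id="db",
                     region_class="known_MGE", sequence=m["seq"].decode(),
                     family=m["family"]) for m in mge_records]

    truth = {
        "seed": int(cfg.seed),
        "n_strains": cfg.n_strains,
        "loci": sorted(loci_truth, key=lambda l: (l["strain"], l["start"])),
        "cas_clusters": sorted(cas_truth, key=lambda c: (c["strain"], c["start"])),
        "prophages": [{"region_id": r.region_id, "strain": r.source_id,
                       "contig": r.contig_id, "start": r.start, "end": r.end}
                      for r in prophage_regions],
        "protospacers": [{"sequence": p.spacer, "target_id": p.target_id,
                          "target_class": p.target_class, "offset": p.offset,
                          "length": p.length, "category": p.category}
                         for p in placements],
        "self_targets": self_truth,
        "shared_pool": shared_truth,
        "clade_blocks": clade_blocks_truth,
        "variant_groups": variant_truth,
        "subtype_repeats": dict(sorted(subtype_repeat.items())),
    }
    dataset = SyntheticDataset(
        config=cfg, genomes=genomes, metadata=metadata, genes=genes,
        prophages=RegionSet(entries=sorted(
            prophage_regions, key=lambda r: (r.source_id, r.start))),
        mge_db=mge_db, truth=truth)
    if out_dir is not None:
        write_dataset(dataset, out_dir)
    return dataset


def write_dataset(ds: SyntheticDataset, out_dir: str) -> None:
    """Emit the dataset as FASTA/GFF3/TSV/BED/JSON under ``out_dir``."""
    from . import io as sio  # local import to avoid cycle at module load
    import pandas as pd

    os.makedirs(os.path.join(out_dir, "genomes"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "annotations"), exist_ok=True)
    for sid in sorted(ds.genomes):
        g = ds.genomes[sid]
        with open(os.path.join(out_dir, "genomes", f"{sid}.fasta"), "w") as fh:
            for cid in sorted(g.contigs):
                fh.write(f">{cid}\n")
                seq = g.contigs[cid]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        with open(os.path.join(out_dir, "annotations", f"{sid}.gff3"), "w") as fh:
            fh.write("##gff-version 3\n")
            for k, gene in enumerate(ds.genes[sid], 1):
                fh.write("\t".join([
                    gene.contig_id, "spacerscape_sim", "gene",
                    str(gene.start + 1), str(gene.end), ".", gene.strand, ".",
                    f"ID=g{k};Name={gene.name};product={gene.product}"]) + "\n")
    rows = []
    for sid in sorted(ds.metadata):
        m = ds.metadata[sid]
        rows.append({"strain_id": m.strain_id, "species": m.species,
                     "phylotype": m.phylotype, "location": m.location,
                     "biome": m.biome, "latitude": m.latitude,
                     "longitude": m.longitude, "depth": m.depth,
                     "date": m.date})
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "metadata.tsv"),
                              sep="\t", index=False)
    with open(os.path.join(out_dir, "prophages.bed"), "w") as bed, \
            open(os.path.join(out_dir, "prophages.fasta"), "w") as fa:
        for r in ds.prophages.entries:
            bed.write(f"{r.contig_id}\t{r.start}\t{r.end}\t{r.region_id}"
                      f"\t{r.source_id}\n")
            fa.write(f">{r.region_id} class=prophage family={r.family}\n")
            for i in range(0, len(r.sequence), 80):
                fa.write(r.sequence[i:i + 80] + "\n")
    with open(os.path.join(out_dir, "mge_db.fasta"), "w") as fa:
        for r in ds.mge_db:
            fa.write(f">{r.region_id} class=known_MGE family={r.family}\n")
            for i in range(0, len(r.sequence), 80):
                fa.write(r.sequence[i:i + 80] + "\n")
    sio.write_json(ds.truth, os.path.join(out_dir, "truth.json"))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = min(a[1], b[1]) - max(a[0], b[0])
    if inter <= 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def _prf(n_true: int, n_pred: int, n_match: int) -> Score:
    p = n_match / n_pred if n_pred else (1.0 if n_true == 0 else 0.0)
    r = n_match / n_true if n_true else 1.0
    return Score(precision=p, recall=r)


def score_loci(detected, truth: dict, min_overlap: float = 0.5) -> Score:
    """Locus recovery by >=50% reciprocal overlap (same strain & contig)."""
    preds = [(l.strain_id, l.contig_id, (l.start, l.end)) for l in detected]
    trues = [(t["strain"], t["contig"], (t["start"], t["end"]))
             for t in truth["loci"]]
    matched_pred = set()
    n_match = 0
    for ts, tc, tiv in trues:
        for i, (ps, pc, piv) in enumerate(preds):
            if i in matched_pred or ps != ts or pc != tc:
                continue
            if _reciprocal_overlap(tiv, piv) >= min_overlap:
                matched_pred.add(i)
                n_match += 1
                break
    return _prf(len(trues), len(preds), n_match)


def score_spacers(records, truth: dict) -> Score:
    pred = {(r.strain_id, r.sequence) for r in records}
    true = {(t["strain"], s) for t in truth["loci"] for s in t["spacers"]}
    return _prf(len(true), len(pred), len(pred & true))


def score_subtypes(clusters, truth: dict, min_overlap: float = 0.5) -> Score:
    """Subtype label accuracy on clusters matched by reciprocal overlap."""
    n_match = 0
    for t in truth["cas_clusters"]:
        for cl in clusters:
            if cl.strain_id != t["strain"] or cl.contig_id != t["contig"]:
                continue
            if _reciprocal_overlap((t["start"], t["end"]),
                                   (cl.start, cl.end)) >= min_overlap:
                if cl.subtype == t["subtype"]:
                    n_match += 1
                break
    return _prf(len(truth["cas_clusters"]), len(clusters), n_match)


def score_hits(hits, records, truth: dict) -> Score:
    """Recovery of planted protospacer placements (sequence, target,
    category)."""
    seq_of = {r.spacer_id: r.sequence for r in records}
    pred = {(seq_of.get(h.spacer_id), h.target_id, h.category)
            for h in hits if h.target_class in ("prophage", "known_MGE")}
    true = {(t["sequence"], t["target_id"], t["category"])
            for t in truth["protospacers"]}
    return _prf(len(true), len(pred), len(pred & true))


def score_blocks(blocks, truth: dict) -> Score:
    pred = {tuple(canonical(t) for t in b.tokens) for b in blocks}
    true = {tuple(canonical(t) for t in b["tokens"])
            for b in truth["clade_blocks"]}
    return _prf(len(true), len(pred), len(pred & true))


def score_variants(variant_groups, truth: dict) -> Score:
    pred = {frozenset(m["sequence"] for m in g.members)
            for g in variant_groups}
    true = {frozenset(canonical(v["sequence"]) for v in g["variants"])
            for g in truth["variant_groups"]}
    return _prf(len(true), len(pred), len(pred & true))


def score_against_truth(truth: dict, loci=None, spacer_records=None,
                        clusters=None, hits=None, blocks=None,
                        variant_groups=None) -> dict[str, Score]:
    """Precision/recall per feature class for whichever outputs are given."""
    out: dict[str, Score] = {}
    if loci is not None:
        out["loci"] = score_loci(loci, truth)
    if spacer_records is not None:
        out["spacers"] = score_spacers(spacer_records, truth)
    if clusters is not None:
        out["subtypes"] = score_subtypes(clusters, truth)
    if hits is not None and spacer_records is not None:
        out["hits"] = score_hits(hits, spacer_records, truth)
    if blocks is not None:
        out["blocks"] = score_blocks(blocks, truth)
    if variant_groups is not None:
        out["variants"] = score_variants(variant_groups, truth)
    return out
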