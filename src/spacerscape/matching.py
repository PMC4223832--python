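"""Spacer-protospacer matching against prophages, MGE databases and the
host chromosome.

Only 100%-identity spans are biologically meaningful here: a *perfect*
match covers the entire spacer, a *partial* match is a maximal exact common
substring of at least ``min_len`` (default 18 nt, two-thirds of the average
repeat length, the suggested minimum for a functioning spacer).

Equivalence with seeded local alignment (documented as a theorem): a
short-query BLAST with word size 7 post-filtered to ungapped, 100%-identity
hits of length >= L reports exactly the maximal exact common substrings of
length >= L, because every exact span of length >= 18 > 7 necessarily
contains a 7-word seed and cannot be extended by a scorer beyond a
mismatch without breaking 100% identity.  Exact substring search is
therefore the faithful (and dependency-free) equivalent used here.
"""

from __future__ import annotations

import pandas as pd

from .models import (CrisprLocus, GenomeRecord, MatchHit, Region, SpacerRecord,
                     revcomp)

MIN_PARTIAL_LEN = 18


def _find_all(needle: str, haystack: str) -> list[int]:
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def perfect_match(spacer_id: str, spacer_seq: str,
                  targets: list[tuple[str, str, str]]) -> list[MatchHit]:
    """All full-length, 100%-identity occurrences of a spacer (either
    strand) in a set of targets.

    ``targets`` are (target_id, sequence, target_class) triples.  A hit on
    the minus strand means the spacer's reverse complement occurs at the
    reported forward-strand offset.  Palindromic double-counts collapse to
    the plus strand.  Output is ordered by (target_id, offset).
    """
    hits: list[MatchHit] = []
    rc = revcomp(spacer_seq)
    for target_id, tseq, tclass in sorted(targets, key=lambda t: t[0]):
        seen: set[int] = set()
        for strand, query in (("+", spacer_seq), ("-", rc)):
            for off in _find_all(query, tseq):
                if off in seen:
                    continue
                seen.add(off)
                hits.append(MatchHit(
                    spacer_id=spacer_id, target_id=target_id,
                    target_class=tclass, strand=strand, target_offset=off,
                    match_length=len(spacer_seq), category="perfect",
                ))
    hits.sort(key=lambda h: (h.target_id, h.target_offset, h.strand))
    return hits


def _maximal_common_substrings(query: str, target: str, min_len: int
                               ) -> list[tuple[int, int, int]]:
    """Maximal exact common substrings >= min_len as (q_start, t_start, length).

    Seeds every min_len-window of the query, extends maximally both ways,
    and deduplicates: each maximal span is reported once.
    """
    spans: set[tuple[int, int, int]] = set()
    for qi in range(len(query) - min_len + 1):
        seed = query[qi:qi + min_len]
        for ti in _find_all(seed, target):
            qs, ts = qi, ti
            while qs > 0 and ts > 0 and query[qs - 1] == target[ts - 1]:
                qs -= 1
                ts -= 1
            qe, te = qi + min_len, ti + min_len
            while (qe < len(query) and te < len(target)
                   and query[qe] == target[te]):
                qe += 1
                te += 1
            spans.add((qs, ts, qe - qs))
    return sorted(spans)


def partial_match(spacer_id: str, spacer_seq: str,
                  targets: list[tuple[str, str, str]],
                  min_len: int = MIN_PARTIAL_LEN) -> list[MatchHit]:
    """Maximal exact common substrings >= min_len between a spacer (either
    strand) and targets, excluding spans that are perfect (full-coverage)
    hits — those belong to :func:`perfect_match`."""
    hits: list[MatchHit] = []
    rc = revcomp(spacer_seq)
    for target_id, tseq, tclass in sorted(targets, key=lambda t: t[0]):
        seen: set[tuple[str, int, int]] = set()
        for strand, query in (("+", spacer_seq), ("-", rc)):
            for qs, ts, length in _maximal_common_substrings(query, tseq, min_len):
                if length >= len(spacer_seq):
                    continue  # perfect, not partial
                key = (strand, ts, length)
                if key in seen:
                    continue
                seen.add(key)
                hits.append(MatchHit(
                    spacer_id=spacer_id, target_id=target_id,
                    target_class=tclass, strand=strand, target_offset=ts,
                    match_length=length, category="partial",
                ))
    hits.sort(key=lambda h: (h.target_id, h.target_offset, h.strand,
                             h.match_length))
    return hits


def match_spacers(records: list[SpacerRecord],
                  targets: list[tuple[str, str, str]],
                  include_partial: bool = False,
                  min_len: int = MIN_PARTIAL_LEN) -> list[MatchHit]:
    """Run perfect (and optionally partial) matching for many spacers.

    Identical spacer sequences are scanned once and the hits fanned out to
    every record carrying that sequence.
    """
    hits: list[MatchHit] = []
    by_seq: dict[str, list[SpacerRecord]] = {}
    for r in records:
        by_seq.setdefault(r.sequence, []).append(r)
    for seq in sorted(by_seq):
        found = perfect_match("", seq, targets)
        if include_partial:
            found += partial_match("", seq, targets, min_len)
        for rec in by_seq[seq]:
            for h in found:
                hits.append(MatchHit(
                    spacer_id=rec.spacer_id, target_id=h.target_id,
                    target_class=h.target_class, strand=h.strand,
                    target_offset=h.target_offset,
                    match_length=h.match_length, category=h.category,
                ))
    hits.sort(key=lambda h: (h.spacer_id, h.target_id, h.target_offset,
                             h.strand, h.category))
    return hits


def self_targeting_scan(genome: GenomeRecord,
                        loci: list[CrisprLocus],
                        records: list[SpacerRecord],
                        prophage_regions: list[Region],
                        include_partial: bool = False,
                        locus_margin: int = 100) -> list[MatchHit]:
    """Hits of a strain's own spacers against its chromosome, excluding the
    CRISPR loci themselves (± ``locus_margin`` nt).

    Hits falling inside an annotated prophage region are flagged
    ``overlaps_prophage`` — self-targeting of a resident prophage is a
    different biological situation than targeting a housekeeping gene.
    """
    loci_by_contig: dict[str, list[tuple[int, int]]] = {}
    for loc in loci:
        loci_by_contig.setdefault(loc.contig_id, []).append(
            (max(0, loc.start - locus_margin), loc.end + locus_margin))
    phage_by_contig: dict[str, list[tuple[int, int]]] = {}
    for reg in prophage_regions:
        if reg.contig_id is not None and reg.source_id == genome.strain_id:
            phage_by_contig.setdefault(reg.contig_id, []).append(
                (reg.start, reg.end))

    targets = [(cid, genome.contigs[cid], "self") for cid in sorted(genome.contigs)]
    out: list[MatchHit] = []
    for rec in records:
        found = perfect_match(rec.spacer_id, rec.sequence, targets)
        if include_partial:
            found += partial_match(rec.spacer_id, rec.sequence, targets)
        for h in found:
            s, e = h.target_offset, h.target_offset + h.match_length
            if any(s < ge and e > gs
                   for gs, ge in loci_by_contig.get(h.target_id, [])):
                continue  # the spacer's own (or any) CRISPR locus
            h.overlaps_prophage = any(
                s < pe and e > ps
                for ps, pe in phage_by_contig.get(h.target_id, []))
            out.append(h)
    out.sort(key=lambda h: (h.spacer_id, h.target_id, h.target_offset, h.strand))
    return out


def match_summary(records: list[SpacerRecord],
                  hits: list[MatchHit],
                  group_of: dict[str, str],
                  grouping_name: str = "group",
                  categories: tuple[str, ...] = ("perfect",)) -> pd.DataFrame:
    """Fraction of distinct spacers (canonical) with >=1 hit per target
    class, within groups.

    ``group_of`` maps spacer_id -> group label; spacers without a label are
    skipped.  A spacer counts once per target class however many targets it
    hits.
    """
    hit_classes: dict[str, set[str]] = {}
    for h in hits:
        if h.category in categories:
            hit_classes.setdefault(h.spacer_id, set()).add(h.target_class)
    groups: dict[str, dict[str, set[str]]] = {}
    for rec in records:
        grp = group_of.get(rec.spacer_id)
        if grp is None:
            continue
        g = groups.setdefault(grp, {"spacers": set(), "prophage": set(),
                                    "known_MGE": set(), "self": set()})
        g["spacers"].add(rec.canonical)
        for cls in hit_classes.get(rec.spacer_id, ()):
            g[cls].add(rec.canonical)
    rows = []
    for grp in sorted(groups):
        g = groups[grp]
        n = len(g["spacers"])
        row = {grouping_name: grp, "n_spacers": n}
        for cls in ("prophage", "known_MGE", "self"):
            k = len(g[cls])
            row[f"n_matching_{cls}"] = k
            row[f"pct_matching_{cls}"] = round(100 * k / n, 1) if n else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def encounter_history(records: list[SpacerRecord],
                      hits: list[MatchHit],
                      family_targets: set[str]) -> dict[str, dict]:
    """Positions of matching spacers within each array, trailer to leader.

    For every locus with >=1 spacer hitting a target in ``family_targets``,
    reports the matched (index_from_trailer, index_from_leader, category)
    positions, the trailer-index span (max - min) expressing how much of
    the array's history involves this family, and a ``recent_only`` flag
    when all matches sit in the leader-proximal quarter of the array.
    """
    rec_by_id = {r.spacer_id: r for r in records}
    n_by_locus: dict[str, int] = {}
    for r in records:
        n_by_locus[r.locus_id] = n_by_locus.get(r.locus_id, 0) + 1
    per_locus: dict[str, list[tuple[int, int | None, str]]] = {}
    for h in hits:
        if h.target_id not in family_targets:
            continue
        rec = rec_by_id.get(h.spacer_id)
        if rec is None:
            continue
        entry = (rec.index_from_trailer, rec.index_from_leader, h.category)
        per_locus.setdefault(rec.locus_id, []).append(entry)
    out: dict[str, dict] = {}
    for locus_id in sorted(per_locus):
        entries = sorted(set(per_locus[locus_id]))
        idx = [e[0] for e in entries]
        n = n_by_locus[locus_id]
        out[locus_id] = {
            "positions": entries,
            "span": max(idx) - min(idx),
            "n_spacers": n,
            "recent_only": min(idx) >= 0.75 * n,
        }
    return out
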