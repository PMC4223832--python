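"""Cross-strain comparison of homologous spacer arrays.

Arrays are compared as *token* sequences — ordered lists of canonical
spacer identifiers, trailer end first — rather than as concatenated
nucleotides.  Identical spacers align in one column; token longest-common-
subsequence is exact for such columns and avoids aligner heuristics, while
a concatenated-nucleotide export is available for external replication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import dendropy

from .models import CrisprLocus, SpacerCatalog, SpacerRecord, canonical, revcomp


@dataclass
class TokenArray:
    """One locus's spacers as canonical tokens, trailer end first."""

    strain_id: str
    locus_id: str
    tokens: list[str]


@dataclass
class Block:
    block_id: str
    group: str
    col_start: int  # column range, half-open
    col_end: int
    tokens: list[str]


@dataclass
class Alignment:
    strain_ids: list[str]
    columns: list[dict]  # {'token': str, 'members': {strain_id: token|None}}

    @property
    def shared_columns(self) -> int:
        return sum(
            1 for c in self.columns
            if all(c["members"][s] is not None for s in self.strain_ids)
        )


@dataclass
class VariantGroup:
    length: int
    members: list[dict]  # {'sequence', 'strains', 'locations', 'location_exclusive'}
    polymorphic_positions: list[int]

    @property
    def n_variants(self) -> int:
        return len(self.members)


def token_array(locus: CrisprLocus, records: list[SpacerRecord]) -> TokenArray:
    """Build the trailer-first token sequence for one locus."""
    recs = sorted((r for r in records if r.locus_id == locus.locus_id),
                  key=lambda r: r.index_from_trailer)
    return TokenArray(strain_id=locus.strain_id, locus_id=locus.locus_id,
                      tokens=[r.canonical for r in recs])


def find_homologous_loci(loci: list[CrisprLocus],
                         arrays: dict[str, TokenArray]) -> list[list[str]]:
    """Group loci that carry the same repeat (identical consensus or exact
    reverse complements) *and* share at least one canonical spacer.

    Singleton groups are allowed.  Deterministic: groups and members sorted
    by locus_id.
    """
    ids = sorted(l.locus_id for l in loci)
    by_id = {l.locus_id: l for l in loci}
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    for i, a in enumerate(ids):
        la = by_id[a]
        ta = set(arrays[a].tokens) if a in arrays else set()
        for b in ids[i + 1:]:
            lb = by_id[b]
            same_repeat = (la.consensus_repeat == lb.consensus_repeat
                           or la.consensus_repeat == revcomp(lb.consensus_repeat))
            if not same_repeat:
                continue
            tb = set(arrays[b].tokens) if b in arrays else set()
            if ta & tb:
                union(a, b)
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    return [sorted(g) for _, g in sorted(groups.items())]


def _lcs_table(a: list[str], b: list[str]):
    n, m = len(a), len(b)
    L = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a[i] == b[j]:
                L[i][j] = L[i + 1][j + 1] + 1
            else:
                L[i][j] = max(L[i + 1][j], L[i][j + 1])
    return L

def lcs_tokens(a: list[str], b: list[str]) -> list[tuple[int, int]]:
    """Longest common subsequence of two token lists as matched index
    pairs.  Tie-break: prefer matching, then advancing in ``a`` — fully
    deterministic."""
    L = _lcs_table(a, b)
    out = []
    i = j = 0
    while i < len(a) and j < len(b):
        if a[i] == b[j]:
            out.append((i, j))
            i += 1
            j += 1
        elif L[i + 1][j] >= L[i][j + 1]:
            i += 1
        else:
            j += 1
    return out


def align_token_arrays(arrays: list[TokenArray]) -> Alignment:
    """Progressive token alignment of >=2 arrays.

    Guide order: descending array length, ties by strain_id.  Each new
    array is aligned to the running column profile by token LCS; matched
    tokens join the column, the rest open gap columns.  Deterministic.
    """
    if len(arrays) < 2:
        raise ValueError("alignment needs >=2 arrays")
    order = sorted(arrays, key=lambda a: (-len(a.tokens), a.strain_id))
    strain_ids = [a.strain_id for a in order]
    columns: list[dict] = [
        {"token": t, "members": {order[0].strain_id: t}}
        for t in order[0].tokens
    ]
    for arr in order[1:]:
        profile = [c["token"] for c in columns]
        matched = lcs_tokens(profile, arr.tokens)
        new_columns: list[dict] = []
        pi = ti = 0
        for ci, tj in matched:
            while pi < ci:
                new_columns.append(columns[pi])
                pi += 1
            while ti < tj:
                new_columns.append(
                    {"token": arr.tokens[ti], "members": {arr.strain_id: arr.tokens[ti]}})
                ti += 1
            col = columns[pi]
            col["members"][arr.strain_id] = arr.tokens[ti]
            new_columns.append(col)
            pi += 1
            ti += 1
        new_columns.extend(columns[pi:])
        for t in arr.tokens[ti:]:
            new_columns.append({"token": t, "members": {arr.strain_id: t}})
        columns = new_columns
    for c in columns:
        for s in strain_ids:
            c["members"].setdefault(s, None)
    return Alignment(strain_ids=strain_ids, columns=columns)


def group_specific_blocks(alignment: Alignment,
                          group_of: dict[str, str]) -> list[Block]:
    """Maximal runs of consecutive columns occupied by *all* members of one
    group and by *no* member of any other.

    Such runs are reported as subclade-specific deletion-or-insertion
    blocks; the polarity (which lineage gained or lost them) is not
    inferable from the alignment alone and is never asserted.
    """
    members_of: dict[str, set[str]] = {}
    for strain, grp in group_of.items():
        members_of.setdefault(grp, set()).add(strain)

    def column_group(col: dict) -> Optional[str]:
        occupied = {s for s, t in col["members"].items() if t is not None}
        for grp, members in members_of.items():
            if occupied == members and len(members) < len(alignment.strain_ids):
                return grp
        return None

    blocks: list[Block] = []
    i = 0
    cols = alignment.columns
    while i < len(cols):
        grp = column_group(cols[i])
        if grp is None:
            i += 1
            continue
        j = i
        while j < len(cols) and column_group(cols[j]) == grp:
            j += 1
        blocks.append(Block(
            block_id=f"B{len(blocks) + 1}",
            group=grp,
            col_start=i,
            col_end=j,
            tokens=[cols[k]["token"] for k in range(i, j)],
        ))
        i = j
    return blocks


def groups_from_newick(newick_path: str, cut_depth: float | None = None,
                       clade_names: list[str] | None = None
                       ) -> dict[str, str]:
    """Strain -> group assignment from a strain tree.

    Either named internal nodes (``clade_names``) define the groups, or the
    tree is cut at ``cut_depth`` from the root and each resulting subtree
    becomes a group.
    """
    tree = dendropy.Tree.get(path=newick_path, schema="newick")
    group_of: dict[str, str] = {}
    if clade_names:
        for node in tree.preorder_node_iter():
            if node.label in clade_names:
                for leaf in node.leaf_iter():
                    group_of[leaf.taxon.label] = node.label
        return group_of
    if cut_depth is None:
        raise ValueError("provide clade_names or cut_depth")
    tree.calc_node_root_distances()
    counter = 0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if node.root_distance >= cut_depth and (
                parent is None or parent.root_distance < cut_depth):
            counter += 1
            for leaf in node.leaf_iter():
                group_of[leaf.taxon.label] = f"clade_{counter}"
    return group_of


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_spacer_variants(catalog: SpacerCatalog,
                         location_of: dict[str, str],
                         max_snps: int = 3) -> list[VariantGroup]:
    """Groups of equal-length canonical spacers related by <= max_snps
    substitutions (single linkage), with >=2 distinct variants.

    Each variant reports its strains and locations; a variant is
    location-exclusive when it occurs at exactly one location.  Processing
    is over sorted sequences, so grouping is input-order invariant.
    """
    by_len: dict[int, list[str]] = {}
    for c in sorted(catalog.clusters):
        by_len.setdefault(len(c), []).append(c)
    groups: list[VariantGroup] = []
    for length in sorted(by_len):
        seqs = by_len[length]
        parent = {s: s for s in seqs}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i, a in enumerate(seqs):
            for b in seqs[i + 1:]:
                if _hamming(a, b) <= max_snps:
                    ra, rb = find(a), find(b)
                    if ra != rb:
                        parent[max(ra, rb)] = min(ra, rb)
        clusters: dict[str, list[str]] = {}
        for s in seqs:
            clusters.setdefault(find(s), []).append(s)
        for _, variants in sorted(clusters.items()):
            if len(variants) < 2:
                continue
            members = []
            for v in sorted(variants):
                strains = sorted({r.strain_id for r in catalog.clusters[v]})
                locations = sorted({location_of.get(s, "") for s in strains} - {""})
                members.append({
                    "sequence": v,
                    "strains": strains,
                    "locations": locations,
                    "location_exclusive": len(locations) == 1,
                })
            poly = [i for i in range(length)
                    if len({m["sequence"][i] for m in members}) > 1]
            groups.append(VariantGroup(length=length, members=members,
                                       polymorphic_positions=poly))
    return groups


def concatenated_export(arrays: list[TokenArray]) -> dict[str, str]:
    """Concatenated spacer nucleotides (trailer to leader) per array, for
    replication with an external nucleotide aligner.  Tokens are canonical
    spacer sequences, so concatenation is direct."""
    return {a.locus_id: "".join(a.tokens) for a in arrays}
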