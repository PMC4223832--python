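import numpy as np
import pytest

import spacerscape as ss
from spacerscape.compare import (align_token_arrays,
                                 find_homologous_loci, find_spacer_variants,
                                 group_specific_blocks, lcs_tokens,
                                 token_array)
from spacerscape.models import CrisprLocus, canonical, revcomp


def _locus(locus_id, strain, consensus, spacers):
    pos = 0
    occ, iv = [], []
    for i in range(len(spacers) + 1):
        occ.append((pos, pos + len(consensus)))
        pos += len(consensus)
        if i < len(spacers):
            iv.append((pos, pos + len(spacers[i])))
            pos += len(spacers[i])
    return CrisprLocus(locus_id, strain, "c", 0, pos, occ, iv, consensus,
                       list(spacers), confidence="confirmed")


def _arrays(loci):
    from spacerscape.catalog import extract_spacers
    recs = extract_spacers(loci)
    return {l.locus_id: token_array(l, recs) for l in loci}, recs


REP = "GACCTTACGGTAGGTCAACGATTGAAACAGTC"
TOK = {c: c * 36 for c in "ABCDEFXYZW"}  # readable spacer tokens


def test_homologous_grouping_rules():
    l1 = _locus("L1", "s1", REP, [TOK["A"], TOK["B"]])
    l2 = _locus("L2", "s2", REP, [TOK["B"], TOK["C"]])
    l3 = _locus("L3", "s3", revcomp(REP), [TOK["B"]])
    l4 = _locus("L4", "s4", REP, [TOK["W"]])          # no shared spacer
    l5 = _locus("L5", "s5", "A" + REP[1:], [TOK["A"]])  # 1-nt different repeat
    arrays, _ = _arrays([l1, l2, l3, l4, l5])
    groups = find_homologous_loci([l1, l2, l3, l4, l5], arrays)
    assert ["L1", "L2", "L3"] in groups
    assert ["L4"] in groups and ["L5"] in groups


def test_alignment_identical_arrays():
    l1 = _locus("L1", "s1", REP, [TOK["A"], TOK["B"], TOK["C"]])
    l2 = _locus("L2", "s2", REP, [TOK["A"], TOK["B"], TOK["C"]])
    arrays, _ = _arrays([l1, l2])
    aln = align_token_arrays([arrays["L1"], arrays["L2"]])
    assert len(aln.columns) == 3 and aln.shared_columns == 3
    assert group_specific_blocks(aln, {"s1": "g1", "s2": "g2"}) == []


def test_alignment_with_group_specific_runs():
    """g1 = A B C D E F vs g2 = A B X Y E F gives the hand-derived column
    layout and exactly one group-specific block per lineage."""
    g1 = _locus("L1", "s1", REP,
                [TOK[c] for c in "ABCDEF"])
    g2 = _locus("L2", "s2", REP,
                [TOK[c] for c in "ABXYEF"])
    arrays, _ = _arrays([g1, g2])
    aln = align_token_arrays([arrays["L1"], arrays["L2"]])
    assert len(aln.columns) == 8
    assert aln.shared_columns == 4  # A B E F
    blocks = group_specific_blocks(aln, {"s1": "g1", "s2": "g2"})
    assert len(blocks) == 2
    by_group = {b.group: {t[:1] for t in b.tokens} for b in blocks}
    assert by_group == {"g1": {"C", "D"}, "g2": {"X", "Y"}}


def test_alignment_disjoint_arrays():
    l1 = _locus("L1", "s1", REP, [TOK["A"], TOK["B"]])
    l2 = _locus("L2", "s2", REP, [TOK["X"], TOK["Y"]])
    arrays, _ = _arrays([l1, l2])
    aln = align_token_arrays([arrays["L1"], arrays["L2"]])
    assert aln.shared_columns == 0


def test_alignment_score_bounds():
    l1 = _locus("L1", "s1", REP, [TOK[c] for c in "ABCDE"])
    l2 = _locus("L2", "s2", REP, [TOK[c] for c in "CDE"])
    arrays, _ = _arrays([l1, l2])
    a12 = align_token_arrays([arrays["L1"], arrays["L2"]]).shared_columns
    a21 = align_token_arrays([arrays["L2"], arrays["L1"]]).shared_columns
    assert a12 == a21 <= 3


def _brute_lcs_len(a, b):
    """Plain recursive-with-memo LCS length, independent of the aligner."""
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == len(a) or j == len(b):
            return 0
        if a[i] == b[j]:
            return 1 + rec(i + 1, j + 1)
        return max(rec(i + 1, j), rec(i, j + 1))
    return rec(0, 0)


def test_token_lcs_equals_brute_force():
    rng = np.random.default_rng(5)
    for _ in range(60):
        n, m = rng.integers(0, 30, size=2)
        a = [f"t{v}" for v in rng.integers(0, 12, size=n)]
        b = [f"t{v}" for v in rng.integers(0, 12, size=m)]
        assert len(lcs_tokens(a, b)) == _brute_lcs_len(tuple(a), tuple(b))


def test_variant_groups_basic():
    base = "A" + "CGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"[:39] + "A"
    var = base[:10] + ("C" if base[10] != "C" else "G") + base[11:]
    loci = [_locus("L1", "s1", REP, [base]), _locus("L2", "s2", REP, [var])]
    _, recs = _arrays(loci)
    cat = ss.build_catalog(recs)
    groups = find_spacer_variants(cat, {"s1": "Hawaii", "s2": "Fiji"})
    assert len(groups) == 1
    g = groups[0]
    assert g.n_variants == 2 and g.length == 41
    assert all(m["location_exclusive"] for m in g.members)
    assert len(g.polymorphic_positions) == 1

    # identical spacers only: no variant group
    loci = [_locus("L1", "s1", REP, [base]), _locus("L2", "s2", REP, [base])]
    _, recs = _arrays(loci)
    assert find_spacer_variants(ss.build_catalog(recs),
                                {"s1": "x", "s2": "y"}) == []


def test_variant_grouping_input_order_invariant():
    base = "A" + "CGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"[:39] + "A"
    v2 = base[:5] + "G" + base[6:]
    v3 = base[:7] + "T" + base[8:]
    loci = [_locus(f"L{i}", f"s{i}", REP, [v])
            for i, v in enumerate([base, v2, v3])]
    _, recs = _arrays(loci)
    locs = {f"s{i}": "loc" for i in range(3)}
    g_fwd = find_spacer_variants(ss.build_catalog(recs), locs)
    _, recs_rev = _arrays(loci[::-1])
    g_rev = find_spacer_variants(ss.build_catalog(recs_rev), locs)
    assert ([m["sequence"] for m in g_fwd[0].members]
            == [m["sequence"] for m in g_rev[0].members])


@pytest.fixture(scope="module")
def variant_ds():
    """Eight strains at three locations with a planted 41-nt conserved
    spacer carrying 3+1+1 location-specific variants."""
    cfg = ss.SimulationConfig(
        seed=19, n_strains=8, genome_length=150_000,
        shared_spacer_count=0,
        locations=("Hawaii", "Hawaii", "Hawaii", "Fiji", "Fiji", "Fiji",
                   "Fiji", "Palau"),
        biome_of={"Hawaii": "Tropical Pacific", "Fiji": "Tropical Pacific",
                  "Palau": "Tropical Pacific"},
        variant_spec=[("Hawaii", 3, 3), ("Fiji", 4, 1), ("Palau", 1, 1)])
    return ss.simulate_dataset(cfg)


def test_planted_variant_structure_recovered(variant_ds):
    res = ss.run_pipeline(variant_ds.genomes, variant_ds.metadata,
                          variant_ds.genes, variant_ds.prophages,
                          variant_ds.mge_db)
    truth_variants = {canonical(v["sequence"])
                      for g in variant_ds.truth["variant_groups"]
                      for v in g["variants"]}
    matching = [g for g in res.variant_groups
                if {m["sequence"] for m in g.members} == truth_variants]
    assert len(matching) == 1
    g = matching[0]
    assert g.n_variants == 5
    for m in g.members:
        if m["locations"] == ["Hawaii"]:
            assert m["location_exclusive"]
    hawaii = [m for m in g.members if m["locations"] == ["Hawaii"]]
    assert len(hawaii) == 3
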