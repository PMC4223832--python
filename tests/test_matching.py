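import numpy as np

from spacerscape.examples import self_targeting_examples
from spacerscape.matching import (encounter_history, match_summary,
                                  partial_match, perfect_match,
                                  self_targeting_scan)
from spacerscape.models import (CrisprLocus, GenomeRecord, Region,
                                SpacerRecord, canonical, revcomp)

EX = self_targeting_examples().set_index("gene")


def test_adenylosuccinate_lyase_example_perfect_hit():
    """The documented adenylosuccinate-lyase self-targeting spacer has
    exactly one full-coverage 100%-identity hit at offset 7 of its
    chromosomal region."""
    row = EX.loc["Adenylosuccinate lyase"]
    hits = perfect_match("sp", row["spacer"],
                         [("chrom", row["chromosomal_region"], "self")])
    assert len(hits) == 1
    h = hits[0]
    assert (h.strand, h.target_offset) == ("+", 7)
    assert h.match_length == len(row["spacer"])


def test_methyltransferase_example_perfect_hit():
    row = EX.loc["23S rRNA methyltransferase"]
    hits = perfect_match("sp", row["spacer"],
                         [("chrom", row["chromosomal_region"], "self")])
    assert len(hits) == 1 and hits[0].match_length == len(row["spacer"])


def test_cytochrome_p450_example_partial_only():
    """The CNX-481 cytochrome-P450 spacer diverges from its chromosomal
    region after 32 nt: no perfect hit, one 32-nt partial hit."""
    row = EX.loc["Cytochrome P450"]
    targets = [("chrom", row["chromosomal_region"], "self")]
    assert perfect_match("sp", row["spacer"], targets) == []
    partial = partial_match("sp", row["spacer"], targets)
    assert len(partial) == 1
    assert partial[0].match_length == 32
    assert partial[0].match_length >= 18


def test_perfect_match_minus_strand():
    spacer = "ACGGATTACCAGGATCACGGT"
    target = "TTTT" + revcomp(spacer) + "GGGG"
    hits = perfect_match("sp", spacer, [("t", target, "prophage")])
    assert len(hits) == 1 and hits[0].strand == "-"
    assert hits[0].target_offset == 4


def test_perfect_match_negative_control(make_seq):
    spacer = make_seq(36, seed=21)
    target = make_seq(2000, seed=22)
    assert perfect_match("sp", spacer, [("t", target, "prophage")]) == []


def test_partial_below_threshold_ignored(make_seq):
    spacer = make_seq(36, seed=23)
    target = make_seq(500, seed=24) + spacer[10:20] + make_seq(500, seed=25)
    assert partial_match("sp", spacer, [("t", target, "known_MGE")]) == []


def test_full_length_span_is_perfect_not_partial():
    spacer = "ACGGATTACCAGGATCACGGT"
    targets = [("t", spacer, "known_MGE")]
    assert partial_match("sp", spacer, targets) == []
    assert len(perfect_match("sp", spacer, targets)) == 1


def _np_oracle_spans(query: str, target: str, min_len: int):
    """Independent oracle: boolean match matrix, run lengths along
    diagonals via a rolling numpy recurrence; maximal runs >= min_len."""
    q = np.frombuffer(query.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    M = (q[:, None] == t[None, :])
    C = np.zeros_like(M, dtype=np.int32)
    C[0] = M[0]
    for i in range(1, len(q)):
        C[i, 0] = M[i, 0]
        C[i, 1:] = (C[i - 1, :-1] + 1) * M[i, 1:]
    spans = set()
    for i in range(len(q)):
        for j in range(len(t)):
            if C[i, j] >= min_len:
                ended = (i == len(q) - 1 or j == len(t) - 1
                         or not M[i + 1, j + 1])
                if ended:
                    L = int(C[i, j])
                    spans.add((i - L + 1, j - L + 1, L))
    return spans


def test_matching_agrees_with_numpy_oracle(make_seq):
    """perfect/partial matching equals a sliding-comparison oracle on
    seeded spacer/target pairs, including reverse-complement planting."""
    rng = np.random.default_rng(77)
    for trial in range(40):
        spacer = make_seq(int(rng.integers(20, 45)), seed=1000 + trial)
        target = make_seq(int(rng.integers(200, 1500)), seed=2000 + trial)
        # plant something half the time, sometimes reverse-complemented
        if trial % 2 == 0:
            frag = spacer if trial % 4 == 0 else revcomp(spacer)
            cut = frag[:int(rng.integers(18, len(frag) + 1))]
            pos = int(rng.integers(0, len(target) - len(cut)))
            target = target[:pos] + cut + target[pos + len(cut):]
        got = set()
        for h in perfect_match("s", spacer, [("t", target, "x")]):
            got.add((h.strand, h.target_offset, h.match_length))
        for h in partial_match("s", spacer, [("t", target, "x")]):
            got.add((h.strand, h.target_offset, h.match_length))
        expected = set()
        for strand, q in (("+", spacer), ("-", revcomp(spacer))):
            for qs, ts, L in _np_oracle_spans(q, target, 18):
                expected.add((strand, ts, L))
        # collapse palindromic duplicates the same way the scanner does
        plus_full = {(o, L) for s_, o, L in expected if s_ == "+"}
        expected = {(s_, o, L) for s_, o, L in expected
                    if s_ == "+" or (o, L) not in plus_full}
        assert got == expected, f"trial {trial}"


def _locus_stub(strain, start, end):
    return CrisprLocus("L1", strain, "chr", start, end,
                       repeat_occurrences=[(start, start + 30),
                                           (end - 30, end)],
                       spacer_intervals=[(start + 30, end - 30)],
                       consensus_repeat="G" * 30,
                       spacers=["X"], confidence="confirmed")


def test_self_scan_excludes_own_locus(make_seq):
    spacer = make_seq(36, seed=30)
    bg = make_seq(5000, seed=31)
    seq = bg[:2000] + "G" * 30 + spacer + "G" * 30 + bg[2100:]
    locus = _locus_stub("s", 2000, 2000 + 30 + 36 + 30)
    g = GenomeRecord("s", {"chr": seq})
    rec = SpacerRecord("s|L1|0", "s", "L1", spacer, canonical(spacer), 0)
    assert self_targeting_scan(g, [locus], [rec], []) == []


def test_self_scan_finds_planted_chromosomal_copy(make_seq):
    spacer = make_seq(36, seed=32)
    bg = make_seq(6000, seed=33)
    seq = (bg[:1000] + "G" * 30 + spacer + "G" * 30  # the CRISPR locus
           + bg[1100:4000] + spacer + bg[4000 + 36:])
    locus = _locus_stub("s", 1000, 1096)
    g = GenomeRecord("s", {"chr": seq})
    rec = SpacerRecord("s|L1|0", "s", "L1", spacer, canonical(spacer), 0)
    hits = self_targeting_scan(g, [locus], [rec], [])
    assert len(hits) == 1
    assert not hits[0].overlaps_prophage

    phage = Region("P1", "s", "prophage", seq[3900:4200],
                   contig_id="chr", start=3900, end=4200)
    hits = self_targeting_scan(g, [locus], [rec], [phage])
    assert len(hits) == 1 and hits[0].overlaps_prophage


def test_match_summary_fractions():
    recs = [SpacerRecord(f"sp{i}", "s", "L", f"ACGT{i:02d}" * 4,
                         canonical(f"ACGT{i:02d}" * 4), i)
            for i in range(10)]
    group = {r.spacer_id: "all" for r in recs}
    df = match_summary(recs, [], group)
    assert df.iloc[0]["pct_matching_prophage"] == 0.0
    from spacerscape.models import MatchHit
    hits = [MatchHit(f"sp{i}", "P1", "prophage", "+", 0, 24, "perfect")
            for i in range(4)]
    df = match_summary(recs, hits, group)
    assert df.iloc[0]["pct_matching_prophage"] == 40.0
    assert df.iloc[0]["n_spacers"] == 10


def test_match_summary_equals_planted_rate(small_ds, small_result):
    """The detected fraction of spacers with planted protospacers matches
    the manifest exactly (exact matching is lossless)."""
    truth_seqs = {canonical(p["sequence"])
                  for p in small_ds.truth["protospacers"]}
    hit_ids = {h.spacer_id for h in small_result.hits}
    matched = {r.canonical for r in small_result.records
               if r.spacer_id in hit_ids}
    assert truth_seqs <= matched


def test_encounter_history_positions_and_span():
    n = 10
    recs = [SpacerRecord(f"s|L|{i}", "s", "L", "A" * 30, "A" * 30,
                         index_from_trailer=i, index_from_leader=n - 1 - i)
            for i in range(n)]
    from spacerscape.models import MatchHit

    def hits_at(indices):
        return [MatchHit(f"s|L|{i}", "SV1", "prophage", "+", 0, 30, "perfect")
                for i in indices]

    out = encounter_history(recs, hits_at([1, 4, 8]), {"SV1"})
    assert out["L"]["span"] == 7
    assert [p[0] for p in out["L"]["positions"]] == [1, 4, 8]
    assert not out["L"]["recent_only"]

    out = encounter_history(recs, hits_at([8, 9]), {"SV1"})
    assert out["L"]["span"] == 1 and out["L"]["recent_only"]

    assert encounter_history(recs, [], {"SV1"}) == {}
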