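import pytest

from spacerscape.detect import (DetectionConfig, classify_confidence,
                                detect_paired_loci, find_candidate_arrays,
                                merge_adjacent_loci, orient_locus,
                                repeat_consensus, ungapped_identity)
from spacerscape.models import CasCluster, CrisprLocus, GenomeRecord, revcomp

# A fixed 32-nt repeat and 35-nt spacers whose first/last bases are all
# distinct, so the true repeat boundary is unambiguous for any detector.
REPEAT = "GTCGCACCTTACGGTAGGTCAACGATTGAAAC"
SPACERS = [
    "A" + "TCACGGATCAGTTCGAATGCCTGATCAGGATCA"[:33] + "A",
    "C" + "GGTATTCAGCAACTTCGGAGTCCATAGGTTCAA"[:33] + "C",
    "G" + "ATCCTGAGTTACGCATTCGGTACAATCGTTAGG"[:33] + "G",
]


def build_array(repeat=REPEAT, spacers=SPACERS) -> str:
    parts = [repeat]
    for s in spacers:
        parts += [s, repeat]
    return "".join(parts)


def plant(bg: str, pos: int, insert: str) -> str:
    return bg[:pos] + insert + bg[pos + len(insert):]


def mklocus(seq_parts, start=0, **kw):
    """Assemble a CrisprLocus from alternating repeat/spacer strings."""
    occ, sp_iv, spacers = [], [], []
    pos = start
    for i, part in enumerate(seq_parts):
        iv = (pos, pos + len(part))
        if i % 2 == 0:
            occ.append(iv)
        else:
            sp_iv.append(iv)
            spacers.append(part)
        pos += len(part)
    defaults = dict(locus_id="L1", strain_id="s", contig_id="c",
                    start=start, end=pos, repeat_occurrences=occ,
                    spacer_intervals=sp_iv,
                    consensus_repeat=seq_parts[0], spacers=spacers)
    defaults.update(kw)
    return CrisprLocus(**defaults)


def test_negative_control_random_sequence(make_seq):
    """A uniform-random 10 kb sequence contains no confirmed array."""
    g = GenomeRecord("s", {"c": make_seq(10_000, seed=5)})
    loci = [l for l in find_candidate_arrays(g) if l.confidence == "confirmed"]
    assert loci == []


def test_planted_array_recovered_exactly(make_seq):
    bg = make_seq(10_000, seed=6)
    arr = build_array()
    g = GenomeRecord("s", {"c": plant(bg, 4000, arr)})
    loci = find_candidate_arrays(g)
    confirmed = [l for l in loci if l.confidence == "confirmed"]
    assert len(confirmed) == 1
    loc = confirmed[0]
    assert (loc.start, loc.end) == (4000, 4000 + len(arr))
    assert loc.n_repeats == 4 and loc.n_spacers == 3
    assert loc.consensus_repeat == REPEAT
    assert loc.spacers == SPACERS
    loc.validate()


def test_pure_tandem_repeat_rejected(make_seq):
    """RRRR with zero-length spacers falls outside the spacer-length window."""
    bg = make_seq(8_000, seed=7)
    g = GenomeRecord("s", {"c": plant(bg, 3000, REPEAT * 4)})
    assert all(l.confidence != "confirmed"
               for l in find_candidate_arrays(g))


def test_contig_shorter_than_two_repeats_skipped():
    g = GenomeRecord("s", {"c": "ACGT" * 10})
    assert find_candidate_arrays(g) == []


def test_classify_confidence_rules():
    cfg = DetectionConfig()
    ok = mklocus([REPEAT, SPACERS[0], REPEAT, SPACERS[1], REPEAT,
                  SPACERS[2], REPEAT])
    assert classify_confidence(ok, cfg) == "confirmed"
    two = mklocus([REPEAT, SPACERS[0], REPEAT])
    assert classify_confidence(two, cfg) == "questionable"
    same = mklocus([REPEAT, SPACERS[0]] * 4 + [REPEAT])
    assert classify_confidence(same, cfg) == "questionable"  # identical spacers


def test_merge_only_across_n_gap_with_same_repeat(make_seq):
    cfg = DetectionConfig()
    arr_a = build_array()
    other = [x + s[1:-1] + x for x, s in zip("TAC", SPACERS)]
    arr_b = build_array(spacers=other)
    bg = make_seq(6000, seed=8)

    def detect_on(gapseq):
        seq = (bg[:1000] + arr_a + gapseq + arr_b
               + bg[1000 + len(arr_a) + len(gapseq) + len(arr_b):])
        g = GenomeRecord("s", {"c": seq})
        loci = find_candidate_arrays(g)
        return seq, [l for l in loci if l.confidence == "confirmed"]

    seq, loci = detect_on("N" * 500)
    assert len(loci) == 2
    merged = merge_adjacent_loci(loci, seq, cfg)
    assert len(merged) == 1
    assert sorted(merged[0].merged_from) == sorted(
        [l.locus_id for l in loci])
    merged[0].validate()

    # same geometry, random ACGT gap: not an N-run, no merge
    seq, loci = detect_on(make_seq(500, seed=9))
    assert len(merge_adjacent_loci(loci, seq, cfg)) == 2

    # N-gap but repeats differing at 3 positions: no merge
    rep_b = "AAA" + REPEAT[3:]
    arr_b2 = build_array(repeat=rep_b)
    seq = bg[:1000] + arr_a + "N" * 500 + arr_b2 + bg[1000:]
    g = GenomeRecord("s", {"c": seq})
    loci = [l for l in find_candidate_arrays(g) if l.confidence == "confirmed"]
    assert len(loci) == 2
    assert len(merge_adjacent_loci(loci, seq, cfg)) == 2


def test_orientation_rules():
    parts = [REPEAT, SPACERS[0], REPEAT, SPACERS[1], REPEAT, SPACERS[2],
             REPEAT]
    seq = "".join(parts)
    loc = mklocus(parts)
    assert orient_locus(loc, seq, cas_side="left") == "leader_left"
    assert orient_locus(loc, seq, cas_side="right") == "leader_right"
    # all repeats identical: no degeneracy signal
    assert orient_locus(loc, seq) == "unknown"
    # degenerate last repeat (75% identity) marks the trailer on the right
    degen = "CAGCGTGG" + REPEAT[8:]  # first 8 bases flipped (25% divergence)
    parts2 = [REPEAT, SPACERS[0], REPEAT, SPACERS[1], degen]
    loc2 = mklocus(parts2)
    assert ungapped_identity(degen, REPEAT) == pytest.approx(0.75)
    assert orient_locus(loc2, "".join(parts2)) == "leader_left"


def test_paired_locus_requires_inverted_repeat():
    left = mklocus([REPEAT, SPACERS[0], REPEAT, SPACERS[1], REPEAT],
                   start=0, locus_id="L", confidence="confirmed")
    gap = left.end
    cluster = CasCluster("C1", "s", "c", gap + 100, gap + 600, genes=[])
    rc = revcomp(REPEAT)
    right_parts = [rc, SPACERS[2], rc, "T" + SPACERS[0][1:-1] + "T", rc]
    right = mklocus(right_parts, start=gap + 700, locus_id="R",
                    confidence="confirmed", consensus_repeat=rc)
    assert detect_paired_loci([left, right], [cluster]) == [("L", "C1", "R")]
    # same-orientation repeats: no pair
    right_same = mklocus([REPEAT, SPACERS[2], REPEAT, SPACERS[1], REPEAT],
                         start=gap + 700, locus_id="R2",
                         confidence="confirmed")
    assert detect_paired_loci([left, right_same], [cluster]) == []
    # single locus beside cas: no pair
    assert detect_paired_loci([left], [cluster]) == []


def test_repeat_consensus_majority_and_ties():
    cons, table = repeat_consensus(["ACGT", "ACGT", "ACGT"])
    assert cons == "ACGT"
    cons, _ = repeat_consensus(["AA", "AA", "GA"])
    assert cons == "AA"  # majority 2A/1G
    cons, _ = repeat_consensus(["AT", "AT", "GT", "GT"])
    assert cons == "AT"  # 2A/2G tie broken in A<C<G<T order
    _, table = repeat_consensus(["ACGT", "ACGA", "ACGT"])
    assert (table.sum(axis=1) == 3).all()


def test_reverse_complement_symmetry(make_seq):
    """Detection on the reverse complement yields mirrored coordinates."""
    bg = make_seq(8_000, seed=10)
    seq = plant(bg, 2500, build_array())
    n = len(seq)
    fwd = find_candidate_arrays(GenomeRecord("s", {"c": seq}))
    rev = find_candidate_arrays(GenomeRecord("s", {"c": revcomp(seq)}))
    fwd_iv = sorted((l.start, l.end) for l in fwd)
    rev_iv = sorted((n - e, n - s) for s, e in
                    ((l.start, l.end) for l in rev))
    assert fwd_iv == rev_iv
    assert sorted(l.n_repeats for l in fwd) == sorted(l.n_repeats for l in rev)


def test_spacer_count_invariant_on_simulated_loci(small_result):
    assert small_result.loci
    for loc in small_result.loci:
        assert loc.n_spacers == loc.n_repeats - 1
        loc.validate()


# ---------------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------------

def brute_force_scan(seq: str, cfg: DetectionConfig):
    """Exhaustive (start, repeat-length, period) scanner for regular arrays
    (constant spacer length, exact repeat copies), applying the same
    acceptance rules as the detector.  Independent of the seed-and-extend
    implementation; feasible only on short sequences."""
    candidates = []
    for replen in range(cfg.repeat_len_min, cfg.repeat_len_max + 1):
        smin, smax = cfg.spacer_bounds(replen)
        for period in range(replen + smin, replen + smax + 1):
            for start in range(len(seq) - replen + 1):
                rep = seq[start:start + replen]
                if "N" in rep:
                    continue
                prev = start - period
                if prev >= 0 and seq[prev:prev + replen] == rep:
                    continue  # not the leftmost occurrence of this chain
                n = 1
                while True:
                    nxt = start + n * period
                    if (nxt + replen <= len(seq)
                            and seq[nxt:nxt + replen] == rep):
                        n += 1
                    else:
                        break
                if n < cfg.min_repeats_confirmed:
                    continue
                spacers = [seq[start + i * period + replen:
                               start + (i + 1) * period]
                           for i in range(n - 1)]
                pairs = [(a, b) for i, a in enumerate(spacers)
                         for b in spacers[i + 1:]]
                mean_id = (sum(ungapped_identity(a, b) for a, b in pairs)
                           / len(pairs))
                if mean_id > cfg.max_spacer_self_identity:
                    continue
                span = (n - 1) * period + replen
                candidates.append((start, start + span, n,
                                   [(start + i * period,
                                     start + i * period + replen)
                                    for i in range(n)]))
    candidates.sort(key=lambda c: (-c[2], -(c[1] - c[0]), c[0]))
    accepted = []
    for c in candidates:
        if all(c[1] <= a[0] or c[0] >= a[1] for a in accepted):
            accepted.append(c)
    return sorted(occ for _, _, _, occs in accepted for occ in [occs])


def test_detector_matches_brute_force_oracle(make_seq):
    """On short sequences with a planted regular array, the detector's
    repeat occurrence sets equal those of the exhaustive scanner."""
    cfg = DetectionConfig()
    bg = make_seq(1500, seed=12)
    seq = plant(bg, 400, build_array())
    det = find_candidate_arrays(GenomeRecord("s", {"c": seq}), cfg)
    det_occ = sorted(l.repeat_occurrences for l in det
                     if l.confidence == "confirmed")
    assert det_occ == brute_force_scan(seq, cfg)

    # and both agree on the empty case
    empty = make_seq(1000, seed=13)
    det = [l for l in find_candidate_arrays(GenomeRecord("s", {"c": empty}), cfg)
           if l.confidence == "confirmed"]
    assert det == [] and brute_force_scan(empty, cfg) == []
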