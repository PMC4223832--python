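import numpy as np
import pytest
from scipy import stats as sps

import spacerscape as ss
from spacerscape.stats import (gated_pairwise, kruskal_wallis,
                               least_squares_r2, location_restricted_fraction,
                               normalize_counts, two_sample_t,
                               wilcoxon_ranksum)


def test_kruskal_wallis_closed_form():
    """H for [1,2,3] vs [4,5,6]: ranks 1..6, R1=6, R2=15,
    H = 12/42*(12+75) - 21 = 27/7 = 3.857."""
    res = kruskal_wallis([1, 2, 3], [4, 5, 6])
    assert res.statistic == pytest.approx(3.857, abs=5e-4)
    assert 0 <= res.p_value <= 1


def test_kruskal_wallis_constant_groups():
    res = kruskal_wallis([5, 5, 5], [5, 5, 5])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_kruskal_wallis_label_permutation_invariant():
    a, b = [1.0, 2.0, 7.0], [3.0, 4.0, 5.0]
    assert (kruskal_wallis(a, b).statistic
            == pytest.approx(kruskal_wallis(b, a).statistic))


def test_wilcoxon_exact_enumeration():
    """a=[1,2] vs b=[3,4]: W=3 in 1 of C(4,2)=6 assignments; two-sided
    exact p = 2/6 = 0.333."""
    res = wilcoxon_ranksum([1, 2], [3, 4])
    assert res.statistic == 3.0
    assert res.p_value == pytest.approx(1 / 3, abs=1e-9)
    assert res.extra["method"] == "exact"


def test_wilcoxon_identical_samples():
    res = wilcoxon_ranksum([2, 2, 2], [2, 2, 2])
    assert res.p_value == 1.0


def test_wilcoxon_swap_symmetry():
    a, b = [1, 2, 5], [3, 4, 9]
    ra, rb = wilcoxon_ranksum(a, b), wilcoxon_ranksum(b, a)
    assert ra.p_value == pytest.approx(rb.p_value)
    # rank sums mirror: W_a + W_b = N(N+1)/2
    assert ra.statistic + rb.statistic == 21


def test_wilcoxon_normal_approx_against_scipy():
    """Above the exact-enumeration size, the continuity-corrected normal
    approximation agrees with scipy's Mann-Whitney asymptotic p."""
    rng = np.random.default_rng(3)
    a = rng.normal(0, 1, 9).tolist()
    b = rng.normal(1, 1, 9).tolist()
    res = wilcoxon_ranksum(a, b)
    assert res.extra["method"] == "normal_approx"
    ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                           method="asymptotic", use_continuity=True)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)


def test_t_test_closed_form():
    """[1,2,3] vs [4,5,6]: pooled SD 1, SE sqrt(2/3), t = -3/0.8165 = -3.674."""
    res = two_sample_t([1, 2, 3], [4, 5, 6])
    assert res.statistic == pytest.approx(-3.674, abs=5e-4)


def test_t_test_invariances():
    res0 = two_sample_t([1.0, 2.0, 4.0], [1.0, 2.0, 4.0])
    assert res0.statistic == pytest.approx(0.0)
    a, b = [1, 2, 3], [4, 5, 6]
    t1 = two_sample_t(a, b).statistic
    t2 = two_sample_t([3 * x for x in a], [3 * x for x in b]).statistic
    assert t1 == pytest.approx(t2)
    with pytest.raises(ValueError):
        two_sample_t([1, 1], [1, 1])


def test_least_squares_r2():
    x = [0.0, 1.0, 2.0, 3.0]
    assert least_squares_r2(x, [2 * v + 1 for v in x]).statistic == 1.0
    assert least_squares_r2(x, [5, 5, 5, 5]).statistic == 0.0
    rng = np.random.default_rng(9)
    xr, yr = rng.normal(size=30), rng.normal(size=30)
    res = least_squares_r2(xr, yr)
    assert res.statistic == pytest.approx(np.corrcoef(xr, yr)[0, 1] ** 2)


def test_normalize_counts():
    assert normalize_counts(9, 5_500_000) == pytest.approx(1.63636, abs=1e-5)
    assert normalize_counts(0, 5_500_000) == 0.0
    vec = normalize_counts([9, 18], [5_500_000, 5_500_000])
    assert vec[0] == pytest.approx(normalize_counts(9, 5_500_000))
    assert normalize_counts(4400, 4000, mode="per_gene") == pytest.approx(1.1)
    with pytest.raises(ValueError):
        normalize_counts(1, 0)


def test_omnibus_gating():
    groups = {"a": [1.0, 2.0, 3.0], "b": [1.1, 2.1, 2.9]}
    omnibus, pairwise = gated_pairwise(groups)
    assert omnibus.p_value >= 0.05 and pairwise == []
    groups = {"a": [1, 2, 3, 2, 1], "b": [10, 11, 12, 11, 10]}
    omnibus, pairwise = gated_pairwise(groups)
    assert omnibus.p_value < 0.05 and len(pairwise) == 1
    # both routes agree on the significance call for a clear separation
    assert pairwise[0][2].p_value < 0.05


def _cat(assignments):
    """Build a catalog where each sequence is carried by the given strains."""
    from spacerscape.catalog import build_catalog
    from spacerscape.models import SpacerRecord, canonical
    recs = []
    for i, (seq, strains) in enumerate(assignments.items()):
        for s in strains:
            recs.append(SpacerRecord(f"{s}|{i}", s, f"L{s}{i}", seq,
                                     canonical(seq), 0))
    return build_catalog(recs)


def _meta(location_biome):
    from spacerscape.models import StrainMetadata
    return {s: StrainMetadata(s, "sp", location=l, biome=b)
            for s, (l, b) in location_biome.items()}


def test_location_restricted_fraction_extremes():
    meta = _meta({"s1": ("A", "Coastal"), "s2": ("B", "Oceanic"),
                  "s3": ("A", "Coastal")})
    # every shared spacer spans two locations and two biomes: 0%
    cat = _cat({"ACGTACGTAACCA": ["s1", "s2"], "TTGGCCAATTGGA": ["s2", "s1"]})
    frac, table = location_restricted_fraction(cat, meta)
    assert frac == 0.0 and not table["restricted"].any()
    # every shared spacer confined to one location: 100%
    cat = _cat({"ACGTACGTAACCA": ["s1", "s3"]})
    frac, _ = location_restricted_fraction(cat, meta)
    assert frac == 100.0


def test_location_restricted_fraction_matches_planting(small_ds, small_result):
    assert small_result.sharing_fraction == pytest.approx(
        100 * small_ds.config.location_restricted_rate)


def test_merging_locations_cannot_raise_restriction():
    meta = _meta({"s1": ("A", "X"), "s2": ("B", "Y"), "s3": ("A", "X")})
    cat = _cat({"ACGTACGTAACCA": ["s1", "s2"], "TTGGCCAATTGGA": ["s1", "s3"]})
    before, _ = location_restricted_fraction(cat, meta)
    merged = _meta({"s1": ("AB", "XY"), "s2": ("AB", "XY"),
                    "s3": ("A", "X")})
    after, _ = location_restricted_fraction(cat, merged)
    assert after >= before  # merging can only merge sets toward cardinality 1
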