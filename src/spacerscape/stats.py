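"""Biogeographic sharing analysis and the statistical battery.

The pipeline's testing scheme: counts are normalized per Mb of genome (or
per gene), groups are screened with the Kruskal-Wallis omnibus test, and
specific pairs are compared with the Wilcoxon rank-sum test only after a
significant omnibus result (p < 0.05).  Prophage-presence contrasts use a
pooled-variance t-test and count correlations use ordinary least squares.
All tests are two-sided; no multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import SpacerCatalog, StrainMetadata

EXACT_WILCOXON_MAX_N = 10


@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    group_sizes: list[int]
    normalization: str = "none"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValueError(f"p_value {self.p_value} outside [0,1]")


def normalize_counts(counts, denominators, mode: str = "per_mb"):
    """Normalize per-strain counts by genome size (per Mb) or gene count.

    Accepts scalars or array-likes; vector behaviour equals elementwise
    scalar behaviour.
    """
    c = np.asarray(counts, dtype=float)
    d = np.asarray(denominators, dtype=float)
    if np.any(d <= 0):
        raise ValueError("denominators must be positive")
    if mode == "per_mb":
        out = c / (d / 1e6)
    elif mode == "per_gene":
        out = c / d
    else:
        raise ValueError(f"unknown normalization mode {mode!r}")
    return float(out) if out.ndim == 0 else out


def kruskal_wallis(*groups) -> StatResult:
    """Kruskal-Wallis one-way analysis of variance on ranks.

    H is tie-corrected; p comes from the chi-square distribution with
    k-1 degrees of freedom.  Identical constant groups give H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >=2 non-empty groups")
    pooled = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.all(pooled == pooled[0]):
        # scipy raises on all-identical input; H is 0 by definition
        return StatResult("kruskal_wallis", 0.0, 1.0,
                          [len(g) for g in groups])
    h, p = sps.kruskal(*groups)
    return StatResult("kruskal_wallis", float(h), float(p),
                      [len(g) for g in groups])


def _exact_ranksum_p(ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Two-sided exact p by enumeration of all rank assignments, using the
    observed (possibly tied) ranks."""
    n = len(ranks)
    total = comb(n, n_a)
    le = ge = 0
    eps = 1e-9
    for idx in combinations(range(n), n_a):
        w = ranks[list(idx)].sum()
        if w <= w_obs + eps:
            le += 1
        if w >= w_obs - eps:
            ge += 1
    return min(1.0, 2 * min(le, ge) / total)


def wilcoxon_ranksum(a, b) -> StatResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration of all rank assignments when n_a + n_b <= 10
    (reproducible small-sample behaviour); otherwise a tie-corrected
    normal approximation with continuity correction.  The statistic is the
    rank sum W of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    n = n_a + n_b
    ranks = sps.rankdata(np.concatenate([a, b]))
    w = float(ranks[:n_a].sum())
    if n <= EXACT_WILCOXON_MAX_N:
        p = _exact_ranksum_p(ranks, n_a, w)
        method = "exact"
    else:
        mu = n_a * (n + 1) / 2
        _, tie_counts = np.unique(np.concatenate([a, b]), return_counts=True)
        tie_term = float(((tie_counts ** 3 - tie_counts)).sum()) / (n * (n - 1))
        var = n_a * n_b / 12 * ((n + 1) - tie_term)
        if var == 0:
            p = 1.0
        else:
            # continuity correction toward the mean
            z = (w - mu - 0.5 * np.sign(w - mu)) / sqrt(var)
            p = float(min(1.0, 2 * sps.norm.sf(abs(z))))
        method = "normal_approx"
    return StatResult("wilcoxon_ranksum", w, p, [n_a, n_b],
                      extra={"method": method})


def two_sample_t(a, b) -> StatResult:
    """Two-sided pooled-variance (Student) t-test, df = n_a + n_b - 2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >=2 values")
    t, p = sps.ttest_ind(a, b, equal_var=True)
    if np.isnan(t):
        raise ValueError("zero pooled variance")
    return StatResult("two_sample_t", float(t), float(p), [len(a), len(b)])


def least_squares_r2(x, y) -> StatResult:
    """Ordinary least squares of y on x; the statistic is R² (squared
    Pearson correlation).  p is the slope's two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need >=3 paired points")
    if np.var(x) == 0:
        raise ValueError("x has zero variance")
    if np.var(y) == 0:
        # constant response: regression explains nothing by definition
        return StatResult("least_squares_r2", 0.0, 1.0, [len(x)],
                          extra={"slope": 0.0, "intercept": float(y[0])})
    res = sps.linregress(x, y)
    r2 = float(res.rvalue ** 2)
    p = 1.0 if np.isnan(res.pvalue) else float(res.pvalue)
    return StatResult("least_squares_r2", r2, p, [len(x)],
                      extra={"slope": float(res.slope),
                             "intercept": float(res.intercept)})


def location_restricted_fraction(catalog: SpacerCatalog,
                                 metadata: dict[str, StrainMetadata]
                                 ) -> tuple[float, pd.DataFrame]:
    """Fraction (%) of shared spacers confined to one location and/or one
    biome, with the underlying sharing table.

    Only canonical spacers present in >=2 strains enter; a spacer is
    restricted when its locations *or* its biomes collapse to a single
    value.  Merging locations can only lower (never raise) the fraction.
    """
    strains_by_canonical = catalog.strains_by_canonical
    rows = []
    for c in catalog.shared_canonicals:
        strains = sorted(strains_by_canonical[c])
        missing = [s for s in strains if s not in metadata]
        if missing:
            raise ValueError(f"no metadata for strains {missing}")
        locations = sorted({metadata[s].location for s in strains})
        biomes = sorted({metadata[s].biome for s in strains})
        if any(not v for v in locations + biomes):
            raise ValueError(f"empty location/biome among strains of spacer {c}")
        rows.append({
            "canonical": c,
            "n_strains": len(strains),
            "strains": ",".join(strains),
            "locations": ",".join(locations),
            "biomes": ",".join(biomes),
            "restricted_to_location": len(locations) == 1,
            "restricted_to_biome": len(biomes) == 1,
            "restricted": len(locations) == 1 or len(biomes) == 1,
        })
    table = pd.DataFrame(rows, columns=[
        "canonical", "n_strains", "strains", "locations", "biomes",
        "restricted_to_location", "restricted_to_biome", "restricted"])
    if len(table) == 0:
        return 0.0, table
    fraction = round(100 * float(table["restricted"].mean()), 1)
    return fraction, table


def gated_pairwise(groups: dict[str, list[float]], alpha: float = 0.05
                   ) -> tuple[StatResult, list[tuple[str, str, StatResult]]]:
    """Omnibus Kruskal-Wallis, then pairwise Wilcoxon rank-sum tests only
    when the omnibus p is below ``alpha`` (the pipeline's gating)."""
    names = sorted(groups)
    omnibus = kruskal_wallis(*[groups[n] for n in names])
    pairwise: list[tuple[str, str, StatResult]] = []
    if omnibus.p_value < alpha:
        for a, b in combinations(names, 2):
            pairwise.append((a, b, wilcoxon_ranksum(groups[a], groups[b])))
    return omnibus, pairwise
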