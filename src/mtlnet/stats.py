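"""Directionality statistics over region pairs.

Contact-level directed metrics (connectivity band matrices or CCEP z
scores) are pooled into one group per unordered region pair, with a forward
(A->B) and a reverse (B->A) value list drawn from the same contact pairs.
Direction is then tested two ways:

* a one-way two-level ANOVA (forward vs reverse) per region pair, with
  Bonferroni correction over the test family — for two levels the F
  statistic equals the square of the pooled two-sample t statistic;
* element-wise asymmetry differences M[i, j] - M[j, i], tested against a
  zero mean by a two-sided one-sample t-test.

A side-by-side contrast of runs with and without seizure-onset-zone
channels reports direction flips and significance changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import ConnectivityResult

__all__ = [
    "RegionPairGroup",
    "DirectionalityTest",
    "pool_region_pairs",
    "pool_ccep_pairs",
    "asymmetry_differences",
    "ttest_zero_mean",
    "anova_direction",
    "directionality_table",
    "soz_contrast",
    "significance_stars",
]


@dataclass
class RegionPairGroup:
    """Forward/reverse metric values for one unordered region pair."""

    pair: tuple  # (regionA, regionB); forward means A -> B
    forward: np.ndarray
    reverse: np.ndarray
    metric: str = ""
    band: str = ""

    def __post_init__(self):
        self.forward = np.asarray(self.forward, dtype=float)
        self.reverse = np.asarray(self.reverse, dtype=float)
        if not (np.all(np.isfinite(self.forward))
                and np.all(np.isfinite(self.reverse))):
            raise ValueError("non-finite metric values")


@dataclass
class DirectionalityTest:
    """Result of one directed-asymmetry test for a region pair."""

    pair: tuple
    band: str
    metric: str
    n_fwd: int
    n_rev: int
    diff_mean: float
    t: float = float("nan")
    F: float = float("nan")
    df1: int = 0
    df2: int = 0
    p: float = float("nan")
    p_corrected: float = float("nan")
    favored: str = ""
    stars: str = ""


def significance_stars(p):
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _region_channels(labels, region_of):
    by_region = {}
    for i, l in enumerate(labels):
        r = region_of.get(l)
        if r is not None:
            by_region.setdefault(r, []).append(i)
    return by_region


def pool_region_pairs(band_matrix, channel_labels, region_of, metric="",
                      band="") -> list:
    """Pool a contact-level [source, target] matrix into region-pair groups.

    One group per unordered region pair (R regions -> R(R-1)/2 groups);
    each ordered contact pair contributes one value per direction. Diagonal
    and within-region elements are excluded. Regions without contacts are
    omitted with a warning.
    """
    band_matrix = np.asarray(band_matrix, dtype=float)
    if band_matrix.ndim != 2 or band_matrix.shape[0] != band_matrix.shape[1]:
        raise ValueError("band matrix must be square")
    by_region = _region_channels(channel_labels, region_of)
    declared = set(region_of.values())
    empty = declared - set(by_region)
    for r in sorted(empty):
        warnings.warn(f"region {r} has no contacts; its pairs are omitted",
                      RuntimeWarning)
    if len(by_region) < 2:
        raise ValueError("need contacts in at least 2 regions")
    groups = []
    for ra, rb in combinations(sorted(by_region), 2):
        fwd = [band_matrix[i, j] for i in by_region[ra] for j in by_region[rb]]
        rev = [band_matrix[j, i] for i in by_region[ra] for j in by_region[rb]]
        groups.append(
            RegionPairGroup(pair=(ra, rb), forward=fwd, reverse=rev,
                            metric=metric, band=band)
        )
    return groups


def pool_ccep_pairs(table: pd.DataFrame) -> list:
    """Region-pair groups from a long-format CCEP z table.

    Forward values for pair (A, B) are the z scores of responses recorded
    in B while stimulating in A, and vice versa. Pairs missing either
    direction are omitted with a warning.
    """
    t = table[(table["source_region"] != "") & (table["target_region"] != "")]
    t = t[t["source_region"] != t["target_region"]]
    regions = sorted(set(t["source_region"]) | set(t["target_region"]))
    groups = []
    for ra, rb in combinations(regions, 2):
        fwd = t[(t.source_region == ra) & (t.target_region == rb)]["z"].values
        rev = t[(t.source_region == rb) & (t.target_region == ra)]["z"].values
        if len(fwd) == 0 or len(rev) == 0:
            warnings.warn(
                f"pair ({ra}, {rb}) lacks one direction; omitted",
                RuntimeWarning,
            )
            continue
        groups.append(
            RegionPairGroup(pair=(ra, rb), forward=fwd, reverse=rev,
                            metric="CCEP", band="CCEP")
        )
    return groups


def asymmetry_differences(band_matrix, channel_labels, region_of):
    """Element-wise asymmetries M[i, j] - M[j, i], grouped by region pair.

    Returns ``{(regionA, regionB): differences}`` over cross-region
    unordered contact pairs, oriented A->B minus B->A.
    """
    band_matrix = np.asarray(band_matrix, dtype=float)
    if band_matrix.ndim != 2 or band_matrix.shape[0] != band_matrix.shape[1]:
        raise ValueError("band matrix must be square")
    by_region = _region_channels(channel_labels, region_of)
    out = {}
    for ra, rb in combinations(sorted(by_region), 2):
        diffs = [
            band_matrix[i, j] - band_matrix[j, i]
            for i in by_region[ra]
            for j in by_region[rb]
        ]
        out[(ra, rb)] = np.asarray(diffs)
    return out


def ttest_zero_mean(differences, pair=("", ""), band="", metric="") -> DirectionalityTest:
    """Two-sided one-sample t-test of asymmetry differences against 0."""
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 differences")
    if np.var(d, ddof=1) == 0:
        raise ValueError("zero variance in differences")
    t, p = sps.ttest_1samp(d, 0.0)
    mean = float(d.mean())
    return DirectionalityTest(
        pair=tuple(pair),
        band=band,
        metric=metric,
        n_fwd=d.size,
        n_rev=d.size,
        diff_mean=mean,
        t=float(t),
        df1=1,
        df2=d.size - 1,
        p=float(p),
        favored=(f"{pair[0]}->{pair[1]}" if mean > 0 else
                 f"{pair[1]}->{pair[0]}" if mean < 0 else "none"),
    )


def anova_direction(group: RegionPairGroup, alpha=0.05, n_comparisons=1) -> DirectionalityTest:
    """One-way two-level ANOVA (forward vs reverse) with Bonferroni.

    F has df (1, n_fwd + n_rev - 2); the corrected p is
    ``min(1, p * n_comparisons)`` and stars are assigned on the corrected
    value at 0.05 / 0.01 / 0.001.
    """
    fwd, rev = group.forward, group.reverse
    if fwd.size == 0 or rev.size == 0:
        raise ValueError(f"pair {group.pair}: a direction list is empty")
    if fwd.size + rev.size < 3:
        raise ValueError(
            f"pair {group.pair}: need at least 3 observations for the ANOVA"
        )
    F, p = sps.f_oneway(fwd, rev)
    diff = float(fwd.mean() - rev.mean())
    p_corr = min(1.0, float(p) * n_comparisons)
    ra, rb = group.pair
    return DirectionalityTest(
        pair=group.pair,
        band=group.band,
        metric=group.metric,
        n_fwd=fwd.size,
        n_rev=rev.size,
        diff_mean=diff,
        F=float(F),
        df1=1,
        df2=fwd.size + rev.size - 2,
        p=float(p),
        p_corrected=p_corr,
        favored=(f"{ra}->{rb}" if diff > 0 else
                 f"{rb}->{ra}" if diff < 0 else "none"),
        stars=significance_stars(p_corr),
    )


def directionality_table(
    result: ConnectivityResult,
    region_of,
    bands=None,
    alpha=0.05,
    n_comparisons=None,
) -> pd.DataFrame:
    """ANOVA directionality tests for every region pair and band.

    `result` must carry band-aggregated matrices. The Bonferroni family
    defaults to (number of pairs) x (number of bands tested).
    """
    if not result.band_values:
        raise ValueError("result has no band aggregates; run band_aggregate")
    bands = list(bands) if bands is not None else list(result.band_values)
    sample = pool_region_pairs(
        result.band_values[bands[0]], result.channel_labels, region_of
    )
    if n_comparisons is None:
        n_comparisons = len(sample) * len(bands)
    rows = []
    for band in bands:
        groups = pool_region_pairs(
            result.band_values[band], result.channel_labels, region_of,
            metric=result.metric, band=band,
        )
        for g in groups:
            r = anova_direction(g, alpha=alpha, n_comparisons=n_comparisons)
            rows.append(
                {
                    "pair": f"{r.pair[0]}-{r.pair[1]}",
                    "direction": r.favored,
                    "band": r.band,
                    "metric": r.metric,
                    "n_fwd": r.n_fwd,
                    "n_rev": r.n_rev,
                    "diff_mean": r.diff_mean,
                    "F": r.F,
                    "df1": r.df1,
                    "df2": r.df2,
                    "p_raw": r.p,
                    "p_corrected": r.p_corrected,
                    "stars": r.stars,
                }
            )
    return pd.DataFrame(rows)


def soz_contrast(full: pd.DataFrame, reduced: pd.DataFrame) -> pd.DataFrame:
    """Side-by-side comparison of directionality tables with/without SOZ.

    Both inputs must come from identical pipeline configurations differing
    only in channel exclusion. Raises if the reduced table tests pairs the
    full table lacks; pairs dropped by the exclusion are reported as such.
    """
    key = ["pair", "band", "metric"]
    extra = set(map(tuple, reduced[key].values)) - set(map(tuple, full[key].values))
    if extra:
        raise ValueError(f"reduced results test unknown pairs: {sorted(extra)}")
    merged = full.merge(
        reduced, on=key, how="left", suffixes=("_full", "_reduced"),
        indicator=True,
    )
    sig_full = merged["p_corrected_full"] < 0.05
    sig_red = merged["p_corrected_reduced"] < 0.05
    present = merged["_merge"] == "both"
    return pd.DataFrame(
        {
            "pair": merged["pair"],
            "band": merged["band"],
            "metric": merged["metric"],
            "direction_full": merged["direction_full"],
            "direction_reduced": merged["direction_reduced"].fillna("dropped"),
            "significant_full": sig_full,
            "significant_reduced": sig_red.fillna(False),
            "direction_flip": present
            & (merged["direction_full"] != merged["direction_reduced"])
            & sig_full
            & sig_red,
            "significance_change": present & (sig_full != sig_red.fillna(False)),
            "pair_dropped": ~present,
        }
    )
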