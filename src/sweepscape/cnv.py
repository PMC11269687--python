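"""Copy-number inference from read-depth ratios at target gene regions.

Copy-number variation at a tandem gene cluster shows up as a deviation of
read depth inside the cluster's coding regions relative to the flanking
sequence of the same individual.  The statistic is, per sample, the mean
depth over coding-region sites divided by the mean depth over sites within
10 Mb upstream and downstream of the cluster span; the per-sample
sequencing effort cancels in the ratio.  Sites below 1X depth are excluded
per sample, and samples with fewer than 500 retained coding sites are
omitted.  Region-level differences are assessed with a one-way fixed-effects
ANOVA on the ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genodata import ConfigurationError, DepthMatrix, IntervalSet

__all__ = ["DepthRatioResult", "depth_ratio", "flank_consistency", "group_anova"]


@dataclass
class DepthRatioResult:
    """Per-sample depth ratios and the filters that produced them."""

    records: pd.DataFrame  # sample, n_coding_sites, mean_coding_depth,
    #                        mean_flank_depth, ratio, flank_up_mean,
    #                        flank_down_mean, included
    params: dict = field(default_factory=dict)

    def included(self) -> pd.DataFrame:
        return self.records[self.records["included"]]

    def group_summary(self, grouping: dict) -> pd.DataFrame:
        df = self.included().copy()
        df["group"] = df["sample"].map(grouping)
        return (
            df.groupby("group")["ratio"]
            .agg(mean_ratio="mean", n="count")
            .reset_index()
        )


def depth_ratio(
    depths: DepthMatrix,
    coding: IntervalSet,
    flank_bp: float = 1e7,
    min_sites: int = 500,
    min_depth: int = 1,
    equal_flank_weight: bool = False,
) -> DepthRatioResult:
    """Per-sample ratio of coding-region depth to flanking depth.

    The flanks are the two ``flank_bp`` windows abutting the outermost
    coding-interval span (the span interior is excluded).  By default sites
    from both flanks pool into one mean (site-count weighting);
    ``equal_flank_weight=True`` averages the two flank means instead.
    Samples with fewer than ``min_sites`` retained coding sites, or with an
    empty flank site set, are excluded with ``included=False``.
    """
    if len(coding) == 0:
        raise ConfigurationError("empty coding interval set")
    chrom, span_start, span_end = coding.span()
    on = depths.chrom == chrom
    pos0 = depths.pos - 1

    in_coding = np.zeros(len(depths.pos), dtype=bool)
    for c, start, end, _name in coding:
        in_coding |= on & (pos0 >= start) & (pos0 < end)
    up = on & (pos0 >= span_start - flank_bp) & (pos0 < span_start)
    down = on & (pos0 >= span_end) & (pos0 < span_end + flank_bp)

    recs = []
    for i, sample in enumerate(depths.samples):
        d = depths.depth[i]
        retained = d >= min_depth
        cod = d[in_coding & retained]
        dup = d[up & retained]
        ddn = d[down & retained]
        n_coding = len(cod)
        mean_coding = float(cod.mean()) if n_coding else np.nan
        up_mean = float(dup.mean()) if len(dup) else np.nan
        dn_mean = float(ddn.mean()) if len(ddn) else np.nan
        if equal_flank_weight:
            flank_vals = [v for v in (up_mean, dn_mean) if np.isfinite(v)]
            mean_flank = float(np.mean(flank_vals)) if flank_vals else np.nan
        else:
            pooled = np.concatenate([dup, ddn])
            mean_flank = float(pooled.mean()) if len(pooled) else np.nan
        included = (
            n_coding >= min_sites
            and np.isfinite(mean_flank)
            and mean_flank > 0
        )
        ratio = mean_coding / mean_flank if included else np.nan
        recs.append(
            (sample, n_coding, mean_coding, mean_flank, ratio, up_mean, dn_mean, included)
        )
    records = pd.DataFrame(
        recs,
        columns=[
            "sample", "n_coding_sites", "mean_coding_depth", "mean_flank_depth",
            "ratio", "flank_up_mean", "flank_down_mean", "included",
        ],
    )
    return DepthRatioResult(
        records,
        params={
            "flank_bp": flank_bp,
            "min_sites": min_sites,
            "min_depth": min_depth,
            "region": (chrom, span_start, span_end),
            "equal_flank_weight": equal_flank_weight,
        },
    )


def flank_consistency(result: DepthRatioResult) -> float:
    """Squared Pearson correlation of upstream vs downstream flank means.

    Computed across included samples; returns NaN (undefined) with fewer
    than 3 usable samples.
    """
    df = result.included().dropna(subset=["flank_up_mean", "flank_down_mean"])
    if len(df) < 3:
        return float("nan")
    r = np.corrcoef(df["flank_up_mean"], df["flank_down_mean"])[0, 1]
    return float(r**2)


def group_anova(result: DepthRatioResult, grouping: dict):
    """One-way fixed-effects ANOVA of depth ratios across groups.

    ``grouping`` maps sample id to a group label (e.g. geographic region).
    Returns ``(F, df_between, df_within, p)``.  With zero within-group
    variance and differing means, F is infinite and p = 0.
    """
    df = result.included().copy()
    df["group"] = df["sample"].map(grouping)
    df = df.dropna(subset=["group", "ratio"])
    groups = [grp["ratio"].to_numpy() for _, grp in df.groupby("group")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ConfigurationError("need >= 2 groups with >= 2 included samples each")
    k = len(groups)
    n = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = k - 1, n - k
    if ss_within <= 0:
        if ss_between > 0:
            return float("inf"), df_b, df_w, 0.0
        return float("nan"), df_b, df_w, float("nan")
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), df_b, df_w, p
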