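"""Channel-sensitivity ratios and nuclear vs cytoplasmic classification.

The Rrp41-channel mutant impedes RNA entry into the exosome's central
channel; Rrp44 binding to transcripts degraded via the channel in the
cytoplasm collapses in that strain, while nuclear substrates are
unaffected. Because RPKM is relative to total mapped reads, global
depletion of cytoplasmic mRNAs inflates the channel-strain RPKM of
unaffected transcripts, so nuclear substrates show WT/channel ratio
below 1 — hence the ratio < 0.8 rule for the nuclear call. The
orientation is switchable for readers who prefer channel/WT.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

NUCLEAR_THRESHOLD = 0.8
CYTOPLASMIC_THRESHOLD = 1.25


def channel_ratio(rpkm_wt: pd.Series, rpkm_channel: pd.Series,
                  orientation: str = "wt_over_channel") -> pd.Series:
    """Per-transcript ratio of replicate-averaged Rrp44 RPKM between
    strains; missing where the denominator is zero."""
    if (rpkm_wt < 0).any() or (rpkm_channel < 0).any():
        raise ValueError("negative RPKM input")
    idx = rpkm_wt.index.intersection(rpkm_channel.index)
    num, den = rpkm_wt.loc[idx], rpkm_channel.loc[idx]
    if orientation == "channel_over_wt":
        num, den = den, num
    elif orientation != "wt_over_channel":
        raise ValueError(f"unknown orientation {orientation!r}")
    ratio = num / den.replace(0, np.nan)
    ratio[num == 0] = np.nan  # ratio defined only when both means > 0
    return ratio


def classify_localization(ratio: pd.Series,
                          threshold: float = NUCLEAR_THRESHOLD,
                          upper_threshold: float = CYTOPLASMIC_THRESHOLD
                          ) -> pd.Series:
    """nuclear (< threshold) / cytoplasmic (> upper) / intermediate.

    Boundary values are intermediate (strict inequalities); undefined
    ratios get no call (missing).
    """
    calls = pd.Series("intermediate", index=ratio.index, dtype=object)
    calls[ratio < threshold] = "nuclear"
    calls[ratio > upper_threshold] = "cytoplasmic"
    calls[ratio.isna()] = pd.NA
    return calls


def pathway_table(rpkm_wt: pd.Series, rpkm_channel: pd.Series,
                  mtr4_rpkm: pd.Series | None = None,
                  classes: pd.Series | None = None,
                  threshold: float = NUCLEAR_THRESHOLD,
                  upper_threshold: float = CYTOPLASMIC_THRESHOLD
                  ) -> pd.DataFrame:
    """Per-transcript channel-sensitivity table, ratio-ascending
    (most-nuclear transcripts at the top)."""
    ratio = channel_ratio(rpkm_wt, rpkm_channel)
    table = pd.DataFrame({
        "rpkm_wt": rpkm_wt.loc[ratio.index],
        "rpkm_channel": rpkm_channel.loc[ratio.index],
        "ratio": ratio,
        "localization": classify_localization(ratio, threshold,
                                              upper_threshold),
    })
    if mtr4_rpkm is not None:
        table.insert(3, "mtr4_rpkm", mtr4_rpkm.reindex(ratio.index))
    if classes is not None:
        table.insert(0, "gene_class", classes.reindex(ratio.index))
    table.attrs["threshold"] = threshold
    table.attrs["upper_threshold"] = upper_threshold
    return table.sort_values("ratio", na_position="last")


def mtr4_association(ratios: pd.Series, mtr4_rpkm: pd.Series,
                     n_bins: int = 10) -> pd.DataFrame:
    """Median (and IQR) Mtr4 RPKM per ratio-quantile bin, plus a
    Spearman monotonicity statistic in ``.attrs``."""
    both = pd.DataFrame({"ratio": ratios, "mtr4": mtr4_rpkm}).dropna()
    if len(both) < n_bins:
        raise ValueError(f"need >= {n_bins} transcripts with defined ratio")
    if both["ratio"].nunique() == 1:
        logger.warning("all ratios equal; single bin")
        bins = pd.Series(0, index=both.index)
    else:
        bins = pd.qcut(both["ratio"], q=min(n_bins, both["ratio"].nunique()),
                       labels=False, duplicates="drop")
    grouped = both.groupby(bins)["mtr4"]
    out = pd.DataFrame({
        "median_mtr4": grouped.median(),
        "q25": grouped.quantile(0.25),
        "q75": grouped.quantile(0.75),
        "n": grouped.size(),
        "mean_ratio": both.groupby(bins)["ratio"].mean(),
    })
    if both["mtr4"].nunique() == 1 or both["ratio"].nunique() == 1:
        rho = 0.0
    else:
        rho = float(stats.spearmanr(both["ratio"], both["mtr4"]).statistic)
    out.attrs["spearman"] = rho
    return out
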