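"""Normalized-coverage rank screen for cellular-DNA contamination.

Each contig's share of the sample-wide normalized coverage
(mean coverage / sum of mean coverages) is ranked within the
whole-community and the VLP sample separately, rank 1 being the highest
share.  DNA genuinely carried in VLPs keeps the same or a better (lower)
rank in the VLP sample, because the purification enriches it; reads from
residual cellular DNA are depleted, so such contigs drop to a worse
(numerically higher) rank.  The screen is advisory: flags annotate
pattern calls, they do not delete them.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .tracks import PairedCoverage, normalize_track

__all__ = ["build_rank_table", "flag_contamination"]


def build_rank_table(pairs: Sequence[PairedCoverage]) -> pd.DataFrame:
    """Per-contig coverage shares and ranks in both samples.

    Ranks within each sample are a permutation of ``1..n_contigs``
    (ordinal ranking on share, ties broken lexicographically by contig
    id, so zero-coverage contigs deterministically take the worst ranks).
    Requires at least two contigs and nonzero total coverage per sample.
    """
    if len(pairs) < 2:
        raise ValueError("rank screen needs >= 2 contigs")
    rows = []
    for p in pairs:
        rows.append({
            "contig": p.contig_id,
            "mean_cov_wgs": normalize_track(p.wgs).mean_norm_depth(),
            "mean_cov_vlp": normalize_track(p.vlp).mean_norm_depth(),
        })
    df = pd.DataFrame(rows)
    for sample in ("wgs", "vlp"):
        total = df[f"mean_cov_{sample}"].sum()
        if total <= 0:
            raise ValueError(f"{sample} sample has zero total coverage")
        df[f"share_{sample}"] = df[f"mean_cov_{sample}"] / total
        order = df.sort_values(
            [f"share_{sample}", "contig"], ascending=[False, True]
        ).index
        ranks = pd.Series(np.arange(1, len(df) + 1), index=order)
        df[f"rank_{sample}"] = ranks
    df["rank_delta"] = df["rank_vlp"] - df["rank_wgs"]
    df["flag"] = "consistent"
    return df.set_index("contig")


def flag_contamination(table: pd.DataFrame, candidates: Iterable[str]) -> pd.DataFrame:
    """Flag candidate contigs whose VLP rank is worse than their WGS rank.

    A candidate is ``contamination_suspect`` iff ``rank_vlp > rank_wgs``
    (numerically higher rank = less abundant in the VLP fraction than
    cellular abundance predicts); equal rank is consistent with carriage.
    """
    candidates = list(candidates)
    unknown = sorted(set(candidates) - set(table.index))
    if unknown:
        raise KeyError(f"unknown candidate contigs: {unknown}")
    out = table.copy()
    suspect = out.loc[candidates, "rank_delta"] > 0
    out.loc[candidates, "flag"] = np.where(
        suspect, "contamination_suspect", "consistent"
    )
    return out
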