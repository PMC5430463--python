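"""Aggregating scores across alignments and aligners.

A score table has one row per alignment (aligner, alpha, network pair)
and one column per quality measure.  The benchmark proceeds in three
steps, mirroring how aligners with a topology/sequence balancing
parameter are usually compared:

1. for each aligner and measure, average over network pairs at each
   alpha and keep the best average over the alpha sweep;
2. rank the aligners per measure with competition ranking (tied
   aligners share the minimal rank; the next distinct value's rank is
   1 + the number of strictly better aligners) and sort by the average
   of the nine ranks — the average of the S3 and KP ranks alone is also
   reported, since S3 subsumes the topological measures and KP the
   biological ones;
3. optionally, correlate measures across all alignments (Pearson,
   pairwise-complete) to see which measures agree.

A per-alignment topology/biology trade-off is the geometric mean of the
S3 and KP scores.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import UndefinedScoreError

#: The nine quality measures, in conventional column order.
SCORE_COLUMNS = ("NC", "EC", "ICS", "S3", "LCC", "KP", "GO-BP", "GO-MF", "GO-CC")

#: Identifier columns of a score table.
ID_COLUMNS = ("aligner", "alpha", "pair")


def make_score_table(rows: Sequence[Mapping]) -> pd.DataFrame:
    """Build a score table from row dicts; absent scores become NaN."""
    df = pd.DataFrame(list(rows))
    for col in ID_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"score table needs a {col!r} column")
    for col in SCORE_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if df.duplicated(subset=list(ID_COLUMNS)).any():
        raise ValueError("duplicate (aligner, alpha, pair) rows")
    present = df[list(SCORE_COLUMNS)].to_numpy(dtype=float)
    valid = np.isnan(present) | ((present >= 0) & (present <= 1))
    if not valid.all():
        raise ValueError("scores must lie in [0, 1]")
    return df[list(ID_COLUMNS) + list(SCORE_COLUMNS)]


def best_mean_score(
    table: pd.DataFrame, aligner: str, metric: str
) -> tuple[float, float]:
    """Best over the alpha sweep of the across-pair mean of one metric.

    Missing values are excluded from each mean; alphas with no
    non-missing value are skipped.  Ties go to the smallest alpha.
    Returns (alpha, mean score).
    """
    sub = table[table["aligner"] == aligner]
    if sub.empty:
        raise UndefinedScoreError(f"no rows for aligner {aligner!r}")
    means = sub.groupby("alpha")[metric].mean().dropna()
    if means.empty:
        raise UndefinedScoreError(
            f"aligner {aligner!r} has no defined {metric!r} value"
        )
    best = means.max()
    alpha = min(a for a, v in means.items() if v == best)
    return float(alpha), float(best)


def best_score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Aligner x metric table of best sweep-averaged scores (NaN if undefined)."""
    aligners = sorted(table["aligner"].unique())
    out = pd.DataFrame(index=aligners, columns=list(SCORE_COLUMNS), dtype=float)
    for a in aligners:
        for m in SCORE_COLUMNS:
            try:
                _, out.loc[a, m] = best_mean_score(table, a, m)
            except UndefinedScoreError:
                out.loc[a, m] = np.nan
    out.index.name = "aligner"
    return out


def tradeoff_score(s3: float | None, kp: float | None) -> float:
    """Geometric mean of the S3 and KP scores; NaN when either is missing."""
    if s3 is None or kp is None or (isinstance(s3, float) and math.isnan(s3)) or (
        isinstance(kp, float) and math.isnan(kp)
    ):
        return float("nan")
    if not (0 <= s3 <= 1 and 0 <= kp <= 1):
        raise ValueError(f"scores must lie in [0, 1], got s3={s3}, kp={kp}")
    return math.sqrt(s3 * kp)


def competition_ranks(values: pd.Series, descending: bool = True) -> pd.Series:
    """Competition ("1, 1, 1, 4") ranks: 1 + the number of strictly better values.

    Missing values stay missing and do not consume a rank.
    """
    return values.rank(method="min", ascending=not descending)


def average_ranks(ranks: pd.DataFrame) -> pd.DataFrame:
    """Append avg_s3_kp and avg_all to a per-metric rank table and sort.

    ``ranks`` has one row per aligner and one column per metric (as in a
    published rank table); averages skip missing metrics.
    """
    out = ranks.copy().astype(float)
    metric_cols = [c for c in SCORE_COLUMNS if c in out.columns]
    s3_kp = [c for c in ("S3", "KP") if c in out.columns]
    out["avg_s3_kp"] = out[s3_kp].mean(axis=1) if s3_kp else np.nan
    out["avg_all"] = out[metric_cols].mean(axis=1)
    return out.sort_values("avg_all", kind="stable")


def rank_aligners(best: pd.DataFrame) -> pd.DataFrame:
    """Rank aligners per metric and sort by the average of all ranks.

    ``best`` is the aligner x metric output of :func:`best_score_table`
    (higher is better for every metric).  An aligner missing a metric is
    excluded from that metric's ranking and its averages skip it.
    """
    if len(best) < 2:
        raise ValueError("need at least two aligners to rank")
    ranks = pd.DataFrame(index=best.index, dtype=float)
    for m in SCORE_COLUMNS:
        if m in best.columns:
            ranks[m] = competition_ranks(best[m])
    return average_ranks(ranks)


def score_correlation(table: pd.DataFrame, min_periods: int = 3) -> pd.DataFrame:
    """Pearson correlations between measures over all alignments.

    Uses pairwise-complete observations so one missing score does not
    discard an alignment entirely; cells with fewer than ``min_periods``
    complete rows, and rows/columns of zero-variance measures, are NaN.
    """
    cols = [c for c in SCORE_COLUMNS if c in table.columns]
    return table[cols].corr(method="pearson", min_periods=min_periods)
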