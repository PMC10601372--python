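"""Normalized encoding-performance ranks and rank-stability statistics.

Within a session of N neurons, the neuron ranked R (1 = best cross-validated
encoding accuracy) gets the normalized rank (N - R + 1)/N, so the best
neuron scores 1 and the worst 1/N.  Elusive neurons (full model no better
than the intercept-only null) have their accuracy forced to 0 before
ranking, placing them collectively at the bottom.  Group-level rank
stability in later sessions is assessed against a resampling null: the mean
normalized rank of the group is compared with the 97.5th percentile of the
mean over many randomly drawn populations of the same size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def normalized_rank(
    accuracies: np.ndarray,
    elusive: np.ndarray,
    neuron_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Rank all neurons of a session and attach normalized ranks.

    Elusive accuracies are set to 0 before ranking.  Ties are broken
    deterministically by neuron index; elusive neurons are placed strictly
    below every non-elusive neuron (in index order among themselves), so the
    elusive set occupies the smallest normalized ranks.
    """
    acc = np.asarray(accuracies, dtype=float).copy()
    elusive = np.asarray(elusive, dtype=bool)
    n = len(acc)
    if n < 1:
        raise ValueError("need at least one neuron")
    if neuron_ids is None:
        neuron_ids = np.arange(n)
    acc[elusive] = 0.0
    order = sorted(range(n), key=lambda i: (elusive[i], -acc[i], i))
    rank = np.empty(n, dtype=int)
    rank[order] = np.arange(1, n + 1)
    table = pd.DataFrame(
        {
            "neuron": np.asarray(neuron_ids),
            "accuracy": acc,
            "rank": rank,
            "normalized_rank": (n - rank + 1) / n,
            "elusive": elusive,
        }
    )
    return table


def select_top_group(
    rank_table: pd.DataFrame,
    pursued_mask: np.ndarray,
    band: tuple[float, float] = (0.8, 1.0),
) -> np.ndarray:
    """Pursued neurons whose normalized rank lies in ``(low, high]``.

    The half-open convention makes adjacent bands such as (0.8, 0.9] and
    (0.9, 1.0] partition (0.8, 1.0]; the top-20% group is band (0.8, 1.0].
    """
    low, high = band
    if not (0.0 <= low < high <= 1.0):
        raise ValueError("band must satisfy 0 <= low < high <= 1")
    pursued_mask = np.asarray(pursued_mask, dtype=bool)
    nr = rank_table["normalized_rank"].to_numpy()
    ids = rank_table["neuron"].to_numpy()
    pursued = pursued_mask[ids]
    sel = pursued & (nr > low) & (nr <= high)
    return ids[sel]


@dataclass
class RankStability:
    """Outcome of the resampled-population rank-stability test."""

    mean_rank: float
    null_mean: float
    percentile_2_5: float
    percentile_97_5: float
    significant: bool
    n_draws: int
    seed: int


def rank_stability_test(
    group: np.ndarray,
    rank_table: pd.DataFrame,
    pool: np.ndarray,
    n_draws: int = 10_000,
    seed: int = 0,
) -> RankStability:
    """Compare a group's mean normalized rank with resampled populations.

    ``pool`` is the neuron-id population the null draws from (all neurons of
    the session, or all pursued neurons, depending on the analysis).  Each of
    ``n_draws`` null samples draws ``len(group)`` neurons from the pool
    without replacement; the group is significant iff its mean normalized
    rank exceeds the 97.5th percentile of the null means.
    """
    group = np.asarray(group)
    pool = np.asarray(pool)
    if len(group) == 0:
        raise ValueError("group is empty")
    if len(group) > len(pool):
        raise ValueError("group larger than the sampling pool")
    nr = rank_table.set_index("neuron")["normalized_rank"]
    pool_vals = nr.loc[pool].to_numpy()
    if np.ptp(pool_vals) == 0:
        raise ValueError("degenerate pool: all normalized ranks equal")
    mean_rank = float(nr.loc[group].mean())

    rng = np.random.default_rng(seed)
    g = len(group)
    keys = rng.random((n_draws, len(pool)))
    idx = np.argpartition(keys, g - 1, axis=1)[:, :g]
    null_means = pool_vals[idx].mean(axis=1)
    p025, p975 = np.percentile(null_means, [2.5, 97.5])
    return RankStability(
        mean_rank=mean_rank,
        null_mean=float(null_means.mean()),
        percentile_2_5=float(p025),
        percentile_97_5=float(p975),
        significant=bool(mean_rank > p975),
        n_draws=n_draws,
        seed=seed,
    )
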