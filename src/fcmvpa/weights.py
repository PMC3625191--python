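"""Fold-aggregated discriminative-weight maps.

The LOOCV selects a slightly different connectivity feature set in every
fold.  A connection's discriminative weight is its mean Kendall tau over
the folds where it was selected, multiplied by its occurrence rate
(folds selected / total folds); connections selected in at least
``retention_min`` folds are retained as the stable signature.  Retained
weights roll up to regions (half of |weight| to each endpoint) and to
resting-state networks (half of |weight| to each endpoint's network,
full |weight| to the network pair), so the total weight is conserved at
every level.  Signed mean taus are preserved in the connection report: a
positive mean tau marks a connection weakened in the -1 (patient) group.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AtlasTable, FeatureIndex

__all__ = [
    "ConnectionWeight",
    "aggregate_connections",
    "connection_table",
    "region_weights",
    "network_weights",
]


@dataclass(frozen=True)
class ConnectionWeight:
    feature_position: int
    mean_tau: float
    occurrence: int
    n_folds: int
    retained: bool

    @property
    def weight(self) -> float:
        return self.mean_tau * self.occurrence / self.n_folds


def aggregate_connections(
    folds, retention_min: int, n_folds: int | None = None
) -> list[ConnectionWeight]:
    """Union of per-fold selections with mean tau, occurrence counts and
    retention flags.

    ``folds`` is the fold list of a completed LOOCV (:class:`FoldRecord`
    objects, or (selected_positions, taus) pairs).  The occurrence-rate
    denominator is the total number of folds.
    """
    folds = list(folds)
    if not folds:
        raise ValueError("no folds to aggregate")
    if n_folds is None:
        n_folds = len(folds)
    tau_sum: dict[int, float] = {}
    count: dict[int, int] = {}
    for f in folds:
        sel = f.selected_positions if hasattr(f, "selected_positions") else f[0]
        taus = f.taus if hasattr(f, "taus") else f[1]
        for pos, tau in zip(np.asarray(sel).tolist(), np.asarray(taus).tolist()):
            tau_sum[pos] = tau_sum.get(pos, 0.0) + tau
            count[pos] = count.get(pos, 0) + 1
    conns = [
        ConnectionWeight(
            feature_position=int(pos),
            mean_tau=tau_sum[pos] / count[pos],
            occurrence=count[pos],
            n_folds=int(n_folds),
            retained=count[pos] >= retention_min,
        )
        for pos in sorted(tau_sum)
    ]
    conns.sort(key=lambda c: (-abs(c.weight), c.feature_position))
    return conns


def connection_table(
    conns: list[ConnectionWeight],
    idx: FeatureIndex | None = None,
    atlas: AtlasTable | None = None,
) -> pd.DataFrame:
    """Connection report sorted by |weight| (region pair names and the
    network-pair category when an atlas is supplied)."""
    rows = []
    for c in conns:
        row = {
            "feature_position": c.feature_position,
            "mean_tau": c.mean_tau,
            "occurrence": c.occurrence,
            "n_folds": c.n_folds,
            "weight": c.weight,
            "retained": c.retained,
        }
        if idx is not None:
            i, j = idx.pair(c.feature_position)
            row["region_pair"] = idx.pair_name(c.feature_position, atlas)
            if atlas is not None:
                ni, nj = sorted((atlas.network_of(i), atlas.network_of(j)))
                row["network_pair"] = (
                    f"{atlas.network_name_of(ni)}/{atlas.network_name_of(nj)}"
                )
        rows.append(row)
    return pd.DataFrame(rows)


def _retained(conns) -> list[ConnectionWeight]:
    return [c for c in conns if c.retained]


def region_weights(
    conns: list[ConnectionWeight], idx: FeatureIndex, atlas: AtlasTable
) -> pd.DataFrame:
    """Half of each retained connection's |weight| to each endpoint region,
    summed per region and sorted descending."""
    acc: dict[int, float] = {}
    for c in _retained(conns):
        i, j = idx.pair(c.feature_position)
        for r in (i, j):
            if not (1 <= r <= atlas.n_regions):
                raise KeyError(f"region index {r} not in atlas")
            acc[r] = acc.get(r, 0.0) + abs(c.weight) / 2.0
    rows = [
        {"region_index": r, "region": atlas.name_of(r), "weight": w}
        for r, w in acc.items()
    ]
    df = pd.DataFrame(rows, columns=["region_index", "region", "weight"])
    return df.sort_values(
        ["weight", "region_index"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def network_weights(
    conns: list[ConnectionWeight], idx: FeatureIndex, atlas: AtlasTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-network weight sums and the symmetric network-pair weight matrix.

    Each retained connection contributes half of |weight| to each
    endpoint's network (both halves to the same network for a
    within-network connection) and its full |weight| to the network pair.
    """
    K = atlas.n_networks
    per_net = np.zeros(K)
    pair = np.zeros((K, K))
    for c in _retained(conns):
        i, j = idx.pair(c.feature_position)
        ni, nj = atlas.network_of(i), atlas.network_of(j)
        w = abs(c.weight)
        per_net[ni - 1] += w / 2.0
        per_net[nj - 1] += w / 2.0
        pair[ni - 1, nj - 1] += w
        if ni != nj:
            pair[nj - 1, ni - 1] += w
    nets = pd.DataFrame(
        {
            "network_id": np.arange(1, K + 1),
            "network": list(atlas.network_names),
            "weight": per_net,
        }
    ).sort_values(["weight", "network_id"], ascending=[False, True], kind="stable")
    pair_df = pd.DataFrame(
        pair, index=list(atlas.network_names), columns=list(atlas.network_names)
    )
    return nets.reset_index(drop=True), pair_df
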