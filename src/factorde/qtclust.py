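"""Quality-threshold (QT) partitional clustering of response profiles.

The classic QT procedure over the 1 - Pearson correlation distance: every
profile in turn seeds a candidate cluster, grown greedily by repeatedly
adding the profile that minimises the resulting cluster diameter (the
maximum pairwise distance among members), stopping when no addition keeps
the diameter within threshold. The largest candidate is extracted (ties go
to the candidate with the lowest-index seed), its members are removed, and
the procedure repeats until the largest candidate falls below the minimum
cluster size; leftovers are reported unclustered.

Defaults (minimum correlation 0.9, minimum cluster size 14) target the
8-point two-tissue log2 fold-change profiles this package produces, where
a tight correlation floor groups genes by response shape rather than
magnitude — Pearson distance is invariant to scaling and offset of a
profile.

The growth criterion is configurable: ``diameter`` (default, the original
QT criterion) or ``seed`` linkage, where candidates only need to stay
within threshold of the seed profile. ``jackknife`` correlation (the
minimum of leave-one-timepoint-out Pearson values, robust to single
outlier cells) is available in place of plain Pearson.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class ClusterParams:
    min_correlation: float = 0.9
    min_cluster_size: int = 14
    criterion: str = "diameter"  # or "seed"
    correlation: str = "pearson"  # or "jackknife"

    def validate(self) -> None:
        if not -1.0 < self.min_correlation <= 1.0:
            raise ValueError("min_correlation must be in (-1, 1]")
        if self.min_cluster_size < 2:
            raise ValueError("min_cluster_size must be >= 2")
        if self.criterion not in ("diameter", "seed"):
            raise ValueError(f"unknown criterion {self.criterion!r}")
        if self.correlation not in ("pearson", "jackknife"):
            raise ValueError(f"unknown correlation {self.correlation!r}")

    @property
    def threshold(self) -> float:
        return 1.0 - self.min_correlation


@dataclass
class Cluster:
    cluster_id: int
    seed: str
    members: list
    diameter: float


@dataclass
class ClusterSet:
    clusters: list = field(default_factory=list)
    unclustered: list = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cluster_id": c.cluster_id,
                    "size": len(c.members),
                    "seed": c.seed,
                    "diameter": c.diameter,
                }
                for c in self.clusters
            ],
            columns=["cluster_id", "size", "seed", "diameter"],
        )

    def membership(self) -> pd.DataFrame:
        rows = [
            {
                "cluster_id": c.cluster_id,
                "probe_id": m,
                "seed_flag": m == c.seed,
            }
            for c in self.clusters
            for m in c.members
        ]
        rows += [
            {"cluster_id": -1, "probe_id": m, "seed_flag": False}
            for m in self.unclustered
        ]
        return pd.DataFrame(rows, columns=["cluster_id", "probe_id", "seed_flag"])


def _jackknife_corr(X: np.ndarray) -> np.ndarray:
    """Min over leave-one-column-out Pearson correlation matrices."""
    n_feat = X.shape[1]
    out = np.full((X.shape[0], X.shape[0]), np.inf)
    for j in range(n_feat):
        sub = np.delete(X, j, axis=1)
        out = np.minimum(out, np.corrcoef(sub))
    return out


def distance_matrix(profiles: pd.DataFrame, correlation: str = "pearson") -> np.ndarray:
    """1 - correlation over profile rows; zero-variance rows are rejected."""
    X = profiles.to_numpy(dtype=float)
    if np.any(X.std(axis=1) == 0):
        bad = profiles.index[X.std(axis=1) == 0]
        raise ValueError(
            f"zero-variance profiles (Pearson undefined): {list(bad[:5])}"
        )
    if correlation == "jackknife":
        corr = _jackknife_corr(X)
    else:
        corr = np.corrcoef(X)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    return d


def cluster_diameter(profiles: pd.DataFrame, member_ids) -> float:
    """Maximum pairwise 1 - Pearson distance among the given members."""
    member_ids = list(member_ids)
    if len(member_ids) < 2:
        raise ValueError("diameter needs at least 2 members")
    d = distance_matrix(profiles.loc[member_ids])
    iu = np.triu_indices(len(member_ids), k=1)
    return float(d[iu].max())


def _grow_candidate(d: np.ndarray, seed: int, alive: np.ndarray, threshold: float,
                    criterion: str) -> list[int]:
    """Greedy candidate cluster from one seed; returns member indices in
    addition order. Ties in the diameter-minimising addition go to the
    lowest index."""
    if criterion == "seed":
        members = np.nonzero(alive & (d[seed] <= threshold))[0]
        # keep seed first, rest in index order
        rest = [int(i) for i in members if i != seed]
        return [seed] + rest
    members = [seed]
    in_cluster = np.zeros(len(d), dtype=bool)
    in_cluster[seed] = True
    # max distance from each point to current members
    maxd = d[seed].copy()
    maxd[~alive | in_cluster] = np.inf
    while True:
        j = int(np.argmin(maxd))
        if maxd[j] > threshold:
            break
        members.append(j)
        in_cluster[j] = True
        maxd = np.maximum(maxd, d[j])
        maxd[j] = np.inf
    return members


def qt_cluster(profiles: pd.DataFrame, params: ClusterParams | None = None) -> ClusterSet:
    """QT-cluster profile rows; see module docstring for the procedure."""
    params = params or ClusterParams()
    params.validate()
    ids = list(profiles.index)
    n = len(ids)
    result = ClusterSet()
    if n < params.min_cluster_size:
        result.unclustered = ids
        return result

    d = distance_matrix(profiles, params.correlation)
    alive = np.ones(n, dtype=bool)
    threshold = params.threshold
    cluster_id = 1
    while alive.sum() >= params.min_cluster_size:
        best_members: list[int] | None = None
        best_seed = -1
        for seed in np.nonzero(alive)[0]:
            cand = _grow_candidate(d, int(seed), alive, threshold, params.criterion)
            if best_members is None or len(cand) > len(best_members):
                best_members = cand
                best_seed = int(seed)
        assert best_members is not None
        if len(best_members) < params.min_cluster_size:
            break
        member_idx = sorted(best_members)
        sub = d[np.ix_(member_idx, member_idx)]
        diam = float(sub.max()) if len(member_idx) > 1 else 0.0
        result.clusters.append(
            Cluster(
                cluster_id=cluster_id,
                seed=ids[best_seed],
                members=[ids[i] for i in member_idx],
                diameter=diam,
            )
        )
        alive[member_idx] = False
        cluster_id += 1
    result.unclustered = [ids[i] for i in np.nonzero(alive)[0]]
    return result
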