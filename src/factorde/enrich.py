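"""Gene-set enrichment: hypergeometric over-representation and preranked ES.

Two screens over GMT gene-set collections:

* over-representation analysis (ORA): upper-tail hypergeometric test of a
  selected gene list against an explicit background universe, BH-corrected
  across sets;
* preranked enrichment: the weighted Kolmogorov–Smirnov-like running-sum
  enrichment score (ES) over a score-ranked gene list, with a gene-label
  permutation null, sign-matched normalised ES (NES) and tail-ratio q-values.

The background universe is always an explicit argument: enrichment p-values
are meaningless without a stated background, and annotation-database-version
effects make externally computed p-values non-portable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT-compatible)."""

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def add(self, name: str, members, description: str = "") -> None:
        members = list(dict.fromkeys(members))  # dedupe, keep order
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
        if name in self.sets:
            raise ValueError(f"duplicate gene set name {name!r}")
        self.sets[name] = members
        self.descriptions[name] = description

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    @classmethod
    def from_gmt(cls, path) -> "GeneSetCollection":
        coll = cls()
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                members = [m for m in parts[2:] if m]
                coll.add(parts[0], members, description=parts[1])
        return coll

    def to_gmt(self, path) -> None:
        with open(path, "w") as fh:
            for name, members in self.sets.items():
                fh.write(
                    "\t".join([name, self.descriptions.get(name, "")] + list(members))
                    + "\n"
                )


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeometric(N, K, n).

    N: universe size; K: annotated genes in the universe; n: selected genes;
    k: overlap. Summed in log space for stability at extreme tails.
    """
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"require 0 <= k <= min(K, n); got k={k}, K={K}, n={n}")
    if K > N or n > N:
        raise ValueError(f"require K <= N and n <= N; got K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    return float(np.exp(logsumexp(hypergeom.logpmf(support, N, K, n))))


def ora_table(
    selected,
    universe,
    sets: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``selected`` in each gene set.

    ``selected`` must be a subset of ``universe`` (the post-filter
    background). Sets with no member in the universe are omitted with a
    logged warning. Returns one row per set, BH-adjusted across sets, sorted
    by raw p.
    """
    selected = set(selected)
    universe = set(universe)
    extra = selected - universe
    if extra:
        raise ValueError(
            f"{len(extra)} selected genes are not in the universe "
            f"(e.g. {sorted(extra)[:3]}); pass the background actually screened"
        )
    N = len(universe)
    n = len(selected)
    rows = []
    for name, members in sets.sets.items():
        in_universe = universe.intersection(members)
        if not in_universe:
            logger.warning("gene set %s is disjoint from the universe; omitted", name)
            continue
        K = len(in_universe)
        k = len(selected.intersection(in_universe))
        rows.append(
            {
                "set": name,
                "description": sets.descriptions.get(name, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_raw": hypergeom_tail(k, K, n, N),
            }
        )
    table = pd.DataFrame(
        rows, columns=["set", "description", "k", "K", "n", "N", "p_raw"]
    )
    if len(table):
        table["p_adj"] = multipletests(table["p_raw"], method="fdr_bh")[1]
        table = table.sort_values("p_raw", kind="mergesort").reset_index(drop=True)
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return table


def _running_sum(in_set: np.ndarray, scores: np.ndarray, weight: float) -> np.ndarray:
    """Cumulative hit/miss running sum over a ranked list (internal)."""
    n = len(in_set)
    n_hits = int(in_set.sum())
    w = np.abs(scores) ** weight
    hit_w = np.where(in_set, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:
        # all hit scores are zero (possible at weight > 0): fall back to ranks
        hit_w = in_set.astype(float)
        denom = float(n_hits)
    steps = hit_w / denom - (~in_set) / (n - n_hits)
    return np.cumsum(steps)


def preranked_es(ranked: pd.Series, gene_set, weight_exponent: float = 1.0) -> float:
    """Enrichment score of ``gene_set`` in a score-ranked gene list.

    ``ranked`` maps gene -> score, ordered from best to worst (descending
    score). Hits advance the running sum proportionally to
    |score|**weight_exponent (normalised over hits); misses retreat by
    1/(N - K). The ES is the running sum's maximum deviation from zero,
    signed. At ``weight_exponent`` 0 the statistic depends on ranks only.
    """
    genes = np.asarray(ranked.index)
    scores = np.asarray(ranked, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranking scores must be finite")
    in_set = np.isin(genes, list(gene_set))
    n_hits = int(in_set.sum())
    if n_hits == 0:
        raise ValueError("gene set has no member in the ranked list")
    if n_hits == len(genes):
        raise ValueError("gene set covers the whole ranked list (degenerate)")
    rs = _running_sum(in_set, scores, weight_exponent)
    return float(rs[np.argmax(np.abs(rs))])


def es_permutation_fdr(
    ranked: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_exponent: float = 1.0,
) -> pd.DataFrame:
    """Preranked enrichment with a gene-label permutation null.

    For each set the null ES distribution is obtained by permuting which
    ranked positions are hits (equivalent to shuffling gene labels), keeping
    the scores fixed. NES divides ES by the mean |null ES| of matching sign;
    q follows the positive/negative tail-ratio convention: for a set with
    NES >= 0, q = (fraction of all positive null NES >= NES) / (fraction of
    observed positive NES >= NES), capped at 1, and symmetrically for
    negative NES. Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100 (got {n_perm})")
    genes = np.asarray(ranked.index)
    scores = np.asarray(ranked, dtype=float)
    n = len(genes)
    rng = np.random.default_rng(seed)

    names, es_obs, null_nes_pos, null_nes_neg, nes_obs = [], [], [], [], []
    p_raw = []
    for name, members in sets.sets.items():
        in_set = np.isin(genes, members)
        k = int(in_set.sum())
        if k == 0 or k == n:
            logger.warning("gene set %s degenerate in ranked list; omitted", name)
            continue
        es = preranked_es(ranked, members, weight_exponent)
        null = np.empty(n_perm)
        for b in range(n_perm):
            perm = np.zeros(n, dtype=bool)
            perm[rng.choice(n, size=k, replace=False)] = True
            rs = _running_sum(perm, scores, weight_exponent)
            null[b] = rs[np.argmax(np.abs(rs))]
        pos = null[null >= 0]
        neg = null[null < 0]
        if es >= 0:
            denom = pos.mean() if len(pos) else np.nan
            same = pos
            p = (1 + np.sum(same >= es)) / (1 + len(same))
        else:
            denom = np.abs(neg).mean() if len(neg) else np.nan
            same = neg
            p = (1 + np.sum(same <= es)) / (1 + len(same))
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        null_nes_pos.append(pos / pos.mean() if len(pos) else np.array([]))
        null_nes_neg.append(
            neg / np.abs(neg).mean() if len(neg) else np.array([])
        )
        names.append(name)
        es_obs.append(es)
        nes_obs.append(nes)
        p_raw.append(p)

    nes_obs = np.asarray(nes_obs, dtype=float)
    all_pos = np.concatenate(null_nes_pos) if null_nes_pos else np.array([])
    all_neg = np.concatenate(null_nes_neg) if null_nes_neg else np.array([])
    q = np.full(len(names), np.nan)
    for i, nes in enumerate(nes_obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            null_frac = np.mean(all_pos >= nes) if len(all_pos) else 1.0
            obs = nes_obs[np.isfinite(nes_obs) & (nes_obs >= 0)]
            obs_frac = np.mean(obs >= nes)
        else:
            null_frac = np.mean(all_neg <= nes) if len(all_neg) else 1.0
            obs = nes_obs[np.isfinite(nes_obs) & (nes_obs < 0)]
            obs_frac = np.mean(obs <= nes)
        q[i] = min(1.0, null_frac / obs_frac) if obs_frac > 0 else np.nan

    return pd.DataFrame(
        {
            "set": names,
            "ES": es_obs,
            "NES": nes_obs,
            "p_raw": p_raw,
            "q": q,
        }
    ).sort_values("p_raw", kind="mergesort").reset_index(drop=True)
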