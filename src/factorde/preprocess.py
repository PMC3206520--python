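"""Probe filtering, vehicle-normalised fold-change profiles, gene collapse.

The pipeline starts from an already-normalised probe x sample log2 matrix.
Filtering removes control probe sets and "non-responsive" probes, defined
here by an unsupervised variance-and-level floor (across-sample sd and mean
log2 value); the thresholds are configurable and the filter is independent
of the treatment labels, so it cannot bias the downstream contrasts.

Fold change is computed cell-wise: within every (tissue, time) cell the
treated replicate mean is divided by the vehicle replicate mean (a
difference on the log2 scale), yielding the 8-cell treated/vehicle response
profile each probe carries into the screens and clustering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .design import TISSUES, TIMES_H

logger = logging.getLogger(__name__)


def validate_matrix(matrix: pd.DataFrame, design: pd.DataFrame) -> None:
    missing = set(design["sample_id"]) - set(matrix.columns)
    if missing:
        raise ValueError(f"matrix missing sample columns: {sorted(missing)[:5]}")
    if matrix.index.duplicated().any():
        raise ValueError("duplicate probe_ids in matrix")
    if not np.isfinite(matrix.to_numpy()).all():
        raise ValueError("matrix contains non-finite values")


def filter_probes(
    matrix: pd.DataFrame,
    annotation: pd.DataFrame,
    min_sd: float = 0.1,
    min_mean: float = 4.0,
) -> pd.DataFrame:
    """Remove control probes and low-variance / low-level probes.

    A probe survives iff it is not flagged ``is_control``, its across-sample
    standard deviation is >= ``min_sd`` and its mean log2 value is
    >= ``min_mean``. Thresholds must be >= 0. Logs the surviving count; an
    empty result is a warning, not an error.
    """
    if min_sd < 0 or min_mean < 0:
        raise ValueError("thresholds must be >= 0")
    ann = annotation.set_index("probe_id")
    missing = matrix.index.difference(ann.index)
    if len(missing):
        raise ValueError(f"probes without annotation: {list(missing[:5])}")
    is_control = ann.loc[matrix.index, "is_control"].astype(bool).to_numpy()
    values = matrix.to_numpy()
    sd = values.std(axis=1, ddof=1)
    mean = values.mean(axis=1)
    keep = (~is_control) & (sd >= min_sd) & (mean >= min_mean)
    out = matrix.loc[keep]
    n_ctrl = int(is_control.sum())
    n_nonresp = int((~is_control).sum() - keep.sum())
    logger.info(
        "filter_probes: %d of %d probes survive (removed %d control, %d non-responsive)",
        int(keep.sum()),
        len(matrix),
        n_ctrl,
        n_nonresp,
    )
    if keep.sum() == 0:
        logger.warning("filter_probes: no probes survive filtering")
    return out


def fold_change_profiles(matrix: pd.DataFrame, design: pd.DataFrame) -> pd.DataFrame:
    """Per-probe treated/vehicle log2 fold change in each (tissue, time) cell.

    Returns a DataFrame indexed by probe with MultiIndex columns
    ``(tissue, time_h)`` holding log2_fc = mean(log2 treated) - mean(log2
    vehicle). Linear fold change is 2**log2_fc (see ``profiles_long``).
    """
    validate_matrix(matrix, design)
    cols = {}
    for tissue in TISSUES:
        for t in TIMES_H:
            cell = design[(design["tissue"] == tissue) & (design["time_h"] == t)]
            treated = cell.loc[cell["treatment"] == "treated", "sample_id"]
            vehicle = cell.loc[cell["treatment"] == "vehicle", "sample_id"]
            if len(treated) == 0 or len(vehicle) == 0:
                raise ValueError(
                    f"cell (tissue={tissue}, time_h={t}) is missing a treatment arm"
                )
            cols[(tissue, t)] = (
                matrix[treated].mean(axis=1) - matrix[vehicle].mean(axis=1)
            )
    out = pd.DataFrame(cols)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["tissue", "time_h"])
    out.index.name = "probe_id"
    return out


def profiles_long(profiles: pd.DataFrame) -> pd.DataFrame:
    """Tidy long form of a fold-change profile table, with linear fold change."""
    long = (
        profiles.stack(["tissue", "time_h"], future_stack=True)
        .rename("log2_fc")
        .reset_index()
    )
    long["fold_change"] = np.exp2(long["log2_fc"])
    return long[["probe_id", "tissue", "time_h", "log2_fc", "fold_change"]]


def collapse_to_genes(
    probe_results: pd.DataFrame,
    annotation: pd.DataFrame,
    rule: str = "best_p",
    p_col: str = "p_raw",
    hit_col: str = "significant",
) -> pd.DataFrame:
    """Collapse a per-probe table to one row per mapped gene symbol.

    rule ``best_p``: keep, per gene, the probe with the smallest ``p_col``.
    rule ``any_hit``: a gene is a hit iff any of its probes has ``hit_col``
    true; the returned table carries the per-gene OR plus the probe count.
    Unmapped probes (no gene symbol) are dropped with a logged count.
    """
    if rule not in ("best_p", "any_hit"):
        raise ValueError(f"unknown rule {rule!r}")
    ann = annotation[["probe_id", "gene_symbol"]]
    merged = probe_results.merge(ann, on="probe_id", how="left")
    unmapped = merged["gene_symbol"].isna()
    if unmapped.any():
        logger.info("collapse_to_genes: dropping %d unmapped probes", unmapped.sum())
    merged = merged[~unmapped]
    if merged.empty:
        out = merged.drop(columns=["probe_id"]).iloc[0:0]
        return out
    if rule == "best_p":
        idx = merged.groupby("gene_symbol")[p_col].idxmin()
        out = merged.loc[idx].sort_values("gene_symbol").reset_index(drop=True)
    else:
        out = (
            merged.groupby("gene_symbol")
            .agg(**{hit_col: (hit_col, "any"), "n_probes": ("probe_id", "size")})
            .reset_index()
        )
    return out
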