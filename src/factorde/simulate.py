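"""Synthetic expression data with planted factorial effect classes.

Generates probe x sample log2 expression matrices over the balanced
two-tissue time-course design, with each probe assigned one of five effect
classes:

``null``
    no treatment effect anywhere.
``treatment_only``
    a constant treated-vs-vehicle shift in both tissues at every time.
``treatment_x_tissue``
    the shift appears in one (randomly chosen) tissue only.
``treatment_x_time``
    late-onset shift: applied only at times >= ``time_onset_h`` (default
    16 h), in both tissues.
``threeway``
    late-onset shift in one tissue only.

On top of the class-determined mean structure the generator adds a
per-(probe, batch) random offset, a linear RNA-quality term and i.i.d.
Gaussian noise, all on the log2 scale — the nuisance structure the factorial
model's covariates are meant to absorb. Extra "flat" probes (near-zero
variance, emulating non-responsive probe sets) and "control" probes (flagged
in the annotation) exercise the probe filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import TISSUES, TIMES_H, validate_design
from .enrich import GeneSetCollection

GENE_CLASSES = (
    "null",
    "treatment_only",
    "treatment_x_tissue",
    "treatment_x_time",
    "threeway",
)

#: (tissue, time) cell order used for truth-table shift columns and profiles
CELLS = [(tissue, t) for tissue in TISSUES for t in TIMES_H]


def _default_proportions() -> dict:
    return {
        "null": 0.6,
        "treatment_only": 0.1,
        "treatment_x_tissue": 0.1,
        "treatment_x_time": 0.1,
        "threeway": 0.1,
    }


@dataclass
class SimulationConfig:
    """Generative parameters, all on the log2 scale unless noted.

    ``effect_size`` defaults to 1.5 log2 units (~2.8-fold) with
    ``noise_sd`` 0.25 so that a 2-fold screen is well powered at three
    replicates per arm.
    """

    n_probes: int = 2000
    class_proportions: dict = field(default_factory=_default_proportions)
    effect_size: float = 1.5
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    noise_sd: float = 0.25
    batch_sd: float = 0.1
    quality_slope: float = 0.1
    n_control_probes: int = 0
    n_flat_probes: int = 0
    time_onset_h: int = 16
    flat_noise_sd: float = 1e-8
    seed: int = 0

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if set(self.class_proportions) != set(GENE_CLASSES):
            raise ValueError(f"class_proportions must have keys {GENE_CLASSES}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1 (got {total})")
        for name in ("baseline_sd", "noise_sd", "batch_sd", "flat_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_control_probes < 0 or self.n_flat_probes < 0:
            raise ValueError("probe counts must be >= 0")
        if self.time_onset_h not in TIMES_H:
            raise ValueError(f"time_onset_h must be one of {TIMES_H}")


def simulate_expression(
    design: pd.DataFrame, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a log2 expression matrix and its ground-truth table.

    Returns
    -------
    matrix
        DataFrame, probes x samples, log2 intensities; column order matches
        ``design["sample_id"]``.
    truth
        One row per probe: ``true_class``, per-cell treated-arm mean shifts
        (columns ``shift_<tissue>_<time>h``), ``is_control``, ``is_flat``.

    Reproducible bit-for-bit given ``config.seed``.
    """
    config.validate()
    validate_design(design)
    rng = np.random.default_rng(config.seed)

    n_sig = config.n_probes
    n_flat = config.n_flat_probes
    n_ctrl = config.n_control_probes
    n_total = n_sig + n_flat + n_ctrl

    classes = rng.choice(
        GENE_CLASSES,
        size=n_sig,
        p=[config.class_proportions[c] for c in GENE_CLASSES],
    )
    probe_ids = (
        [f"probe_{i:05d}" for i in range(n_sig)]
        + [f"flat_{i:05d}" for i in range(n_flat)]
        + [f"ctrl_{i:05d}" for i in range(n_ctrl)]
    )
    all_classes = np.concatenate([classes, np.full(n_flat + n_ctrl, "null")])
    is_flat = np.array([False] * n_sig + [True] * n_flat + [False] * n_ctrl)
    is_control = np.array([False] * (n_sig + n_flat) + [True] * n_ctrl)

    signs = rng.choice([-1.0, 1.0], size=n_total)
    target_tissue = rng.choice(TISSUES, size=n_total)

    # per-cell treated-arm shift for every probe: (n_total, 8)
    shifts = np.zeros((n_total, len(CELLS)))
    late = np.array([t >= config.time_onset_h for _, t in CELLS])
    for ci, (tissue, _t) in enumerate(CELLS):
        in_tissue = target_tissue == tissue
        cls = all_classes
        shifts[cls == "treatment_only", ci] = 1.0
        shifts[(cls == "treatment_x_tissue") & in_tissue, ci] = 1.0
        if late[ci]:
            shifts[cls == "treatment_x_time", ci] = 1.0
            shifts[(cls == "threeway") & in_tissue, ci] = 1.0
    shifts *= (signs * config.effect_size)[:, None]

    baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=n_total)

    batches = pd.unique(design["batch"])
    batch_offsets = rng.normal(0.0, config.batch_sd, size=(n_total, len(batches)))
    batch_col = {b: j for j, b in enumerate(batches)}

    q = design["rna_quality"].to_numpy()
    q_centered = q - q.mean()

    cell_index = {cell: ci for ci, cell in enumerate(CELLS)}
    n_samples = len(design)
    values = np.empty((n_total, n_samples))
    noise = rng.normal(0.0, 1.0, size=(n_total, n_samples))
    noise_scale = np.where(is_flat, config.flat_noise_sd, config.noise_sd)

    for si, row in enumerate(design.itertuples(index=False)):
        ci = cell_index[(row.tissue, row.time_h)]
        mean = baselines.copy()
        if row.treatment == "treated":
            mean = mean + shifts[:, ci]
        # flat probes emulate dead probe sets: no batch/quality structure
        nuisance = (
            batch_offsets[:, batch_col[row.batch]]
            + config.quality_slope * q_centered[si]
        )
        mean = mean + np.where(is_flat, 0.0, nuisance)
        values[:, si] = mean + noise_scale * noise[:, si]

    matrix = pd.DataFrame(
        values, index=pd.Index(probe_ids, name="probe_id"), columns=design["sample_id"]
    )
    truth = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "true_class": all_classes,
            "sign": signs,
            "target_tissue": target_tissue,
            "is_control": is_control,
            "is_flat": is_flat,
        }
    )
    for ci, (tissue, t) in enumerate(CELLS):
        truth[f"shift_{tissue}_{t}h"] = shifts[:, ci]
    truth.loc[truth["true_class"] == "null", "sign"] = 0.0
    return matrix, truth


def make_probe_annotation(
    truth: pd.DataFrame,
    seed: int = 0,
    duplicate_fraction: float = 0.1,
    unmapped_fraction: float = 0.02,
) -> pd.DataFrame:
    """Build a probe -> gene-symbol annotation for a simulated truth table.

    A fraction of probes share a symbol with another probe (probe-to-gene
    multiplicity, so gene-level counts are below probe-level counts), a small
    fraction are left unmapped, and control probes carry no symbol.
    """
    rng = np.random.default_rng(seed)
    probe_ids = truth["probe_id"].to_numpy()
    is_control = truth["is_control"].to_numpy()
    symbols: list = []
    gene_counter = 0
    last_symbol = None
    for i in range(len(probe_ids)):
        if is_control[i]:
            symbols.append(pd.NA)
            continue
        u = rng.random()
        if u < unmapped_fraction:
            symbols.append(pd.NA)
        elif u < unmapped_fraction + duplicate_fraction and last_symbol is not None:
            symbols.append(last_symbol)
        else:
            last_symbol = f"GENE{gene_counter:05d}"
            gene_counter += 1
            symbols.append(last_symbol)
    return pd.DataFrame(
        {"probe_id": probe_ids, "gene_symbol": symbols, "is_control": is_control}
    )


def plant_gene_sets(
    truth: pd.DataFrame,
    n_sets: int,
    set_size: int,
    enrichment_fraction: float,
    seed: int = 0,
) -> GeneSetCollection:
    """Generate gene sets with planted enrichment for non-null probes.

    The first ``ceil(n_sets / 2)`` sets are "planted": ``enrichment_fraction``
    of their members are drawn from non-null probes, the remainder uniformly
    from all probes. The remaining sets are drawn uniformly. Planted status is
    recorded in each set's description.
    """
    if not 0.0 <= enrichment_fraction <= 1.0:
        raise ValueError("enrichment_fraction must be in [0, 1]")
    if n_sets > 0 and set_size < 2:
        raise ValueError("set_size must be >= 2")
    pool = truth["probe_id"].to_numpy()
    if n_sets > 0 and set_size > len(pool):
        raise ValueError(
            f"set_size {set_size} exceeds number of probes {len(pool)}"
        )
    nonnull = truth.loc[truth["true_class"] != "null", "probe_id"].to_numpy()

    rng = np.random.default_rng(seed)
    collection = GeneSetCollection()
    n_planted = (n_sets + 1) // 2
    for i in range(n_sets):
        planted = i < n_planted
        if planted and len(nonnull) > 0:
            k_enriched = int(round(enrichment_fraction * set_size))
            k_enriched = min(k_enriched, len(nonnull))
            enriched = rng.choice(nonnull, size=k_enriched, replace=False)
            rest_pool = np.setdiff1d(pool, enriched, assume_unique=False)
            rest = rng.choice(rest_pool, size=set_size - k_enriched, replace=False)
            members = np.concatenate([enriched, rest])
        else:
            members = rng.choice(pool, size=set_size, replace=False)
        name = f"set_{'planted' if planted else 'background'}_{i:03d}"
        desc = "planted" if planted else "background"
        collection.add(name, list(members), description=desc)
    return collection


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
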