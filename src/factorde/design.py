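"""Balanced two-tissue, two-treatment, four-time-point study designs.

The design emulated throughout this package is a switchable-oncogene time
course: two tissues (pancreatic islet beta-cells and skin keratinocytes),
each sampled at 4, 8, 16 and 32 hours after administration of either the
activating ligand (4OHT, the "treated" arm) or vehicle, with replicate
animals per cell. Nuisance structure consists of a categorical batch and a
continuous RNA-quality score (RIN-like).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TISSUES = ("pancreas", "skin")
TREATMENTS = ("treated", "vehicle")
TIMES_H = (4, 8, 16, 32)

DESIGN_COLUMNS = [
    "sample_id",
    "tissue",
    "treatment",
    "time_h",
    "replicate",
    "batch",
    "rna_quality",
]


class InvalidDesignError(ValueError):
    """Raised when a design cannot support the factorial analysis."""


def generate_design(
    replicates: int = 3,
    batches: int = 2,
    seed: int = 0,
    rna_quality_mean: float = 8.0,
    rna_quality_sd: float = 0.5,
) -> pd.DataFrame:
    """Generate a balanced design table.

    Parameters
    ----------
    replicates
        Samples per (tissue, treatment, time) cell; at least 2 so that
        within-cell contrasts have positive degrees of freedom.
    batches
        Number of processing batches, assigned round-robin over samples
        (samples are ordered cell-major with replicate innermost, so for
        R == batches every cell contains one sample per batch).
    seed
        Seed for the RNA-quality draws.
    rna_quality_mean, rna_quality_sd
        RNA quality is Normal(mean, sd) truncated to be positive.

    Returns
    -------
    pandas.DataFrame with columns ``sample_id, tissue, treatment, time_h,
    replicate, batch, rna_quality`` — 2 * 2 * 4 * replicates rows.
    """
    if replicates < 2:
        raise InvalidDesignError(
            f"replicates must be >= 2 (got {replicates}): within-cell "
            "contrasts need at least two samples per arm"
        )
    if batches < 1:
        raise InvalidDesignError(f"batches must be >= 1 (got {batches})")

    rng = np.random.default_rng(seed)
    rows = []
    idx = 0
    for tissue in TISSUES:
        for treatment in TREATMENTS:
            for time_h in TIMES_H:
                for rep in range(1, replicates + 1):
                    rows.append(
                        {
                            "sample_id": f"{tissue[:4]}_{treatment[:3]}_{time_h:02d}h_r{rep}",
                            "tissue": tissue,
                            "treatment": treatment,
                            "time_h": time_h,
                            "replicate": rep,
                            "batch": f"b{idx % batches + 1}",
                            "rna_quality": 0.0,
                        }
                    )
                    idx += 1
    design = pd.DataFrame(rows, columns=DESIGN_COLUMNS)

    # truncated-normal RNA quality: redraw until positive
    q = rng.normal(rna_quality_mean, rna_quality_sd, size=len(design))
    while (q <= 0).any():
        bad = q <= 0
        q[bad] = rng.normal(rna_quality_mean, rna_quality_sd, size=int(bad.sum()))
    design["rna_quality"] = q
    return design


def validate_design(design: pd.DataFrame) -> None:
    """Check balance, level sets and uniqueness; raise InvalidDesignError."""
    missing = set(DESIGN_COLUMNS) - set(design.columns)
    if missing:
        raise InvalidDesignError(f"design missing columns: {sorted(missing)}")
    if design["sample_id"].duplicated().any():
        raise InvalidDesignError("duplicate sample_ids in design")
    if not set(design["tissue"]) <= set(TISSUES):
        raise InvalidDesignError(f"tissue levels must be in {TISSUES}")
    if not set(design["treatment"]) <= set(TREATMENTS):
        raise InvalidDesignError(f"treatment levels must be in {TREATMENTS}")
    if not set(design["time_h"]) <= set(TIMES_H):
        raise InvalidDesignError(f"time_h levels must be in {TIMES_H}")
    counts = design.groupby(["tissue", "treatment", "time_h"], observed=True).size()
    if counts.nunique() != 1 or len(counts) != len(TISSUES) * len(TREATMENTS) * len(TIMES_H):
        raise InvalidDesignError(
            "design is not balanced over 2 tissues x 2 treatments x 4 times"
        )
    if counts.iloc[0] < 2:
        raise InvalidDesignError("fewer than 2 replicates per cell")


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t")
    validate_design(design)
    return design


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)
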