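"""Per-probe factorial ANOVA, FDR, gene classification and group contrasts.

The model for each probe's log2 values is the full factorial in treatment
(T: 4OHT vs vehicle), tissue (S: pancreas vs skin) and time (H: 4/8/16/32 h,
categorical), with all interactions, plus nuisance covariates: a categorical
batch and a linear RNA-quality score. Each term is tested with a Type-II
F statistic — the reduction in residual sum of squares from adding the term
to the model containing every term except it and any term containing it,
scaled by the full-model mean squared error. Type-II respects marginality
and, in a balanced design, coincides with the sequential decomposition
regardless of term order.

Covariates can be screened per probe (``screen_then_include``): each
covariate is kept only if its own Type-II test in the full model has
p <= 0.05, and the factorial terms are then retested in the reduced model.

Per-term p-values are Benjamini–Hochberg adjusted across probes within each
term family, and every probe is assigned to the highest-order significant
treatment-involving term: three-way interaction first, then the two-way
interactions (smaller adjusted p wins a double hit, tie to treatment x
tissue), then the treatment main effect. Terms not involving treatment
never confer significance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import TISSUES, TIMES_H

#: factorial terms in marginality order, with their factor content
FACTORIAL_TERMS: dict[str, frozenset] = {
    "treatment": frozenset({"T"}),
    "tissue": frozenset({"S"}),
    "time": frozenset({"H"}),
    "treatment:tissue": frozenset({"T", "S"}),
    "treatment:time": frozenset({"T", "H"}),
    "tissue:time": frozenset({"S", "H"}),
    "treatment:tissue:time": frozenset({"T", "S", "H"}),
}

#: the treatment-involving ("MYC-responsive") term families
T_TERMS = ("treatment", "treatment:tissue", "treatment:time", "treatment:tissue:time")

CLASS_BY_TERM = {
    "treatment:tissue:time": "threeway",
    "treatment:tissue": "treatment_x_tissue",
    "treatment:time": "treatment_x_time",
    "treatment": "treatment_only",
}


@dataclass
class ModelSpec:
    """Which covariates enter the per-probe model and how.

    covariate_policy ``always_include`` (default) keeps batch and RNA quality
    in every probe's model; ``screen_then_include`` keeps a covariate for a
    probe only if its own Type-II p-value in the full model is <=
    ``screen_alpha``, then refits. Screening is provided for comparison but
    distorts the extreme tail of the null F distribution (the pre-test makes
    the selected model data-dependent), which measurably inflates the
    family-wise error of BH at stringent thresholds; ``always_include``
    keeps the per-term null exact.
    """

    use_batch: bool = True
    use_quality: bool = True
    covariate_policy: str = "always_include"
    screen_alpha: float = 0.05

    def validate(self) -> None:
        if self.covariate_policy not in ("always_include", "screen_then_include"):
            raise ValueError(f"unknown covariate_policy {self.covariate_policy!r}")


def _dummies(values: pd.Series) -> np.ndarray:
    """Treatment-coded (drop-first) dummy columns; empty for one level."""
    d = pd.get_dummies(values.astype("category"), drop_first=True, dtype=float)
    return d.to_numpy()


def _interaction(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Columnwise product block (Khatri–Rao over columns)."""
    if a.shape[1] == 0 or b.shape[1] == 0:
        return np.empty((a.shape[0], 0))
    return (a[:, :, None] * b[:, None, :]).reshape(a.shape[0], -1)


def _term_blocks(design: pd.DataFrame, spec: ModelSpec) -> tuple[dict, list[str]]:
    """Build design-matrix column blocks per term, dropping empty terms."""
    t = _dummies(design["treatment"])
    s = _dummies(design["tissue"])
    h = _dummies(design["time_h"])
    blocks = {
        "treatment": t,
        "tissue": s,
        "time": h,
        "treatment:tissue": _interaction(t, s),
        "treatment:time": _interaction(t, h),
        "tissue:time": _interaction(s, h),
        "treatment:tissue:time": _interaction(_interaction(t, s), h),
    }
    blocks = {k: v for k, v in blocks.items() if v.shape[1] > 0}
    covariates = []
    if spec.use_batch and design["batch"].nunique() > 1:
        blocks["batch"] = _dummies(design["batch"])
        covariates.append("batch")
    if spec.use_quality and "rna_quality" in design:
        q = design["rna_quality"].to_numpy(dtype=float)
        blocks["rna_quality"] = (q - q.mean())[:, None]
        covariates.append("rna_quality")
    return blocks, covariates


def _rss(Y: np.ndarray, blocks: dict, terms) -> np.ndarray:
    """Residual sum of squares of each probe under the model with ``terms``."""
    n = Y.shape[0]
    cols = [np.ones((n, 1))] + [blocks[t] for t in terms]
    X = np.hstack(cols)
    Q, _ = np.linalg.qr(X)
    resid = Y - Q @ (Q.T @ Y)
    return np.einsum("ij,ij->j", resid, resid)


def _type2_f(
    Y: np.ndarray,
    blocks: dict,
    test_terms: list[str],
    model_terms: list[str],
    rss_cache: dict,
) -> dict:
    """Type-II F, df and p for each term in ``test_terms``.

    ``model_terms`` is the probe's full model (factorial terms present plus
    retained covariates); the error term is its residual mean square.
    """

    def cached_rss(terms) -> np.ndarray:
        key = frozenset(terms)
        if key not in rss_cache:
            rss_cache[key] = _rss(Y, blocks, sorted(key))
        return rss_cache[key]

    n = Y.shape[0]
    p_full = 1 + sum(blocks[t].shape[1] for t in model_terms)
    df_den = n - p_full
    if df_den <= 0:
        raise ValueError(
            f"zero residual degrees of freedom (n={n}, model columns={p_full})"
        )
    rss_full = cached_rss(model_terms)
    mse = rss_full / df_den

    out = {}
    for tau in test_terms:
        factors = FACTORIAL_TERMS.get(tau)
        if factors is None:  # covariate: nothing contains it
            containers: set = set()
        else:
            containers = {
                other
                for other, of in FACTORIAL_TERMS.items()
                if of > factors and other in model_terms
            }
        base = [t for t in model_terms if t != tau and t not in containers]
        rss0 = cached_rss(base)
        rss1 = cached_rss(base + [tau])
        df_num = blocks[tau].shape[1]
        ss = np.maximum(rss0 - rss1, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = np.where(mse > 0, (ss / df_num) / mse, np.inf)
        F = np.where((mse <= 0) & (ss <= 0), 0.0, F)
        p = stats.f.sf(F, df_num, df_den)
        out[tau] = (F, df_num, df_den, p)
    return out


def term_anova(
    matrix: pd.DataFrame, design: pd.DataFrame, spec: ModelSpec | None = None
) -> pd.DataFrame:
    """Per-term Type-II ANOVA for every probe in the matrix.

    Returns a long DataFrame with columns ``probe_id, term, F, df_num,
    df_den, p_raw`` covering the factorial terms present in the design
    (terms whose factors have a single level are dropped). Probes that are
    constant across samples get p_raw = 1.0 for every term by convention.
    """
    spec = spec or ModelSpec()
    spec.validate()
    design = design.reset_index(drop=True)
    Y = matrix[design["sample_id"]].to_numpy(dtype=float).T  # samples x probes
    blocks, covariates = _term_blocks(design, spec)
    factorial = [t for t in FACTORIAL_TERMS if t in blocks]

    n_probes = Y.shape[1]
    constant = np.ptp(Y, axis=0) < 1e-12

    # decide the per-probe covariate set
    if spec.covariate_policy == "always_include" or not covariates:
        groups = {frozenset(covariates): np.arange(n_probes)}
    else:
        rss_cache: dict = {}
        full = factorial + covariates
        cov_stats = _type2_f(Y, blocks, covariates, full, rss_cache)
        keep_masks = {
            cov: cov_stats[cov][3] <= spec.screen_alpha for cov in covariates
        }
        pattern = np.zeros(n_probes, dtype=int)
        for j, cov in enumerate(covariates):
            pattern |= keep_masks[cov].astype(int) << j
        groups = {}
        for code in np.unique(pattern):
            kept = frozenset(
                cov for j, cov in enumerate(covariates) if code >> j & 1
            )
            groups[kept] = np.nonzero(pattern == code)[0]

    F = np.zeros((n_probes, len(factorial)))
    P = np.ones((n_probes, len(factorial)))
    DFN = np.zeros(len(factorial), dtype=int)
    DFD = np.zeros(n_probes, dtype=int)
    for kept, idx in groups.items():
        model_terms = factorial + sorted(kept)
        res = _type2_f(Y[:, idx], blocks, factorial, model_terms, {})
        for k, tau in enumerate(factorial):
            f, dfn, dfd, p = res[tau]
            F[idx, k] = f
            P[idx, k] = p
            DFN[k] = dfn
            DFD[idx] = dfd

    F[constant, :] = 0.0
    P[constant, :] = 1.0

    rows = pd.DataFrame(
        {
            "probe_id": np.repeat(matrix.index.to_numpy(), len(factorial)),
            "term": np.tile(factorial, n_probes),
            "F": F.ravel(),
            "df_num": np.tile(DFN, n_probes),
            "df_den": np.repeat(DFD, len(factorial)),
            "p_raw": P.ravel(),
        }
    )
    return rows


def fit_term_anova(
    y: np.ndarray, design: pd.DataFrame, spec: ModelSpec | None = None
) -> pd.DataFrame:
    """Per-term ANOVA for a single probe; returns a term-indexed DataFrame."""
    y = np.asarray(y, dtype=float)
    if len(y) != len(design):
        raise ValueError("y must have one value per design sample")
    matrix = pd.DataFrame(
        [y], index=pd.Index(["_probe"], name="probe_id"), columns=design["sample_id"]
    )
    out = term_anova(matrix, design, spec)
    return out.set_index("term")[["F", "df_num", "df_den", "p_raw"]]


def adjust_fdr(term_stats: pd.DataFrame) -> pd.DataFrame:
    """Benjamini–Hochberg step-up across probes, separately per term family."""
    out = term_stats.copy()
    out["p_adj"] = np.nan
    for _term, idx in out.groupby("term").groups.items():
        out.loc[idx, "p_adj"] = multipletests(
            out.loc[idx, "p_raw"].to_numpy(), method="fdr_bh"
        )[1]
    return out


def classify_probes(term_stats: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Assign each probe to its highest-order significant treatment term.

    Precedence: treatment:tissue:time, then the better of treatment:tissue /
    treatment:time (smaller adjusted p; tie goes to treatment:tissue), then
    treatment alone; otherwise ``not_significant``. Non-treatment terms never
    confer significance. Requires a ``p_adj`` column (see ``adjust_fdr``).
    """
    if "p_adj" not in term_stats:
        raise ValueError("term_stats must carry p_adj (run adjust_fdr first)")
    wide = term_stats.pivot(index="probe_id", columns="term", values="p_adj")
    missing = [t for t in T_TERMS if t not in wide.columns]
    if missing:
        raise ValueError(f"missing term columns: {missing}")

    p3 = wide["treatment:tissue:time"].to_numpy()
    pts = wide["treatment:tissue"].to_numpy()
    pth = wide["treatment:time"].to_numpy()
    pt = wide["treatment"].to_numpy()

    cls = np.full(len(wide), "not_significant", dtype=object)
    class_p = np.ones(len(wide))

    sig3 = p3 <= alpha
    sig_ts = pts <= alpha
    sig_th = pth <= alpha
    sig_t = pt <= alpha

    cls[sig_t] = "treatment_only"
    class_p[sig_t] = pt[sig_t]

    two = ~sig3 & (sig_ts | sig_th)
    pick_ts = two & (sig_ts & ~sig_th | (sig_ts & sig_th & (pts <= pth)))
    pick_th = two & ~pick_ts
    cls[pick_ts] = "treatment_x_tissue"
    class_p[pick_ts] = pts[pick_ts]
    cls[pick_th] = "treatment_x_time"
    class_p[pick_th] = pth[pick_th]

    cls[sig3] = "threeway"
    class_p[sig3] = p3[sig3]

    return pd.DataFrame(
        {"probe_id": wide.index, "assigned_class": cls, "class_p": class_p}
    ).reset_index(drop=True)


def contrast_tests(
    matrix: pd.DataFrame, design: pd.DataFrame, t_variant: str = "pooled"
) -> pd.DataFrame:
    """Treated-vs-vehicle t-test per probe in each of the 8 (tissue, time) groups.

    ``pooled`` (default) is the Student two-sample t with df = n1 + n2 - 2;
    ``welch`` uses the Welch–Satterthwaite approximation. Star flags follow
    the convention ** p <= 0.01, * p <= 0.05. Zero pooled variance yields
    t = 0, p = 1 for equal means, and p = 0 with a ``degenerate`` flag for
    unequal means.
    """
    if t_variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t_variant {t_variant!r}")
    frames = []
    for tissue in TISSUES:
        for time_h in TIMES_H:
            cell = design[(design["tissue"] == tissue) & (design["time_h"] == time_h)]
            s1 = cell.loc[cell["treatment"] == "treated", "sample_id"]
            s0 = cell.loc[cell["treatment"] == "vehicle", "sample_id"]
            if len(s1) < 2 or len(s0) < 2:
                raise ValueError(
                    f"group (tissue={tissue}, time_h={time_h}) needs >= 2 "
                    "replicates per arm"
                )
            x1 = matrix[s1].to_numpy(dtype=float)
            x0 = matrix[s0].to_numpy(dtype=float)
            n1, n0 = x1.shape[1], x0.shape[1]
            m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
            v1, v0 = x1.var(axis=1, ddof=1), x0.var(axis=1, ddof=1)
            diff = m1 - m0
            if t_variant == "pooled":
                sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
                se2 = sp2 * (1 / n1 + 1 / n0)
                df = np.full(len(diff), float(n1 + n0 - 2))
            else:
                se2 = v1 / n1 + v0 / n0
                with np.errstate(divide="ignore", invalid="ignore"):
                    df = se2**2 / (
                        (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
                    )
                df = np.where(np.isfinite(df), df, n1 + n0 - 2)
            degenerate = se2 <= 0
            with np.errstate(divide="ignore", invalid="ignore"):
                t = diff / np.sqrt(se2)
            t = np.where(degenerate & (diff == 0), 0.0, t)
            p = 2 * stats.t.sf(np.abs(t), df)
            p = np.where(degenerate, np.where(diff == 0, 1.0, 0.0), p)
            stars = np.where(p <= 0.01, 2, np.where(p <= 0.05, 1, 0))
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": matrix.index,
                        "tissue": tissue,
                        "time_h": time_h,
                        "log2_fc": diff,
                        "t": t,
                        "df": df,
                        "p": p,
                        "stars": stars,
                        "degenerate": degenerate & (diff != 0),
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def flag_early_responders(
    profiles: pd.DataFrame,
    contrasts: pd.DataFrame,
    fold_threshold: float = 2.0,
    window_h: int = 8,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Probes changing >= fold_threshold with contrast p <= alpha early on.

    A probe qualifies in a tissue if, at any time <= ``window_h``, its
    |log2 fold change| >= log2(fold_threshold) and the group contrast has
    p <= alpha (both thresholds inclusive). Direction is the fold-change
    sign at the earliest qualifying time.
    """
    if fold_threshold < 1:
        raise ValueError("fold_threshold must be >= 1")
    if window_h not in TIMES_H:
        raise ValueError(f"window_h must be one of {TIMES_H}")
    long = profiles.stack(["tissue", "time_h"], future_stack=True).rename("log2_fc")
    long = long.reset_index()
    merged = long.merge(
        contrasts[["probe_id", "tissue", "time_h", "p"]],
        on=["probe_id", "tissue", "time_h"],
    )
    lfc_cut = np.log2(fold_threshold)
    hits = merged[
        (merged["time_h"] <= window_h)
        & (merged["log2_fc"].abs() >= lfc_cut)
        & (merged["p"] <= alpha)
    ]
    first = (
        hits.sort_values(["probe_id", "tissue", "time_h"])
        .groupby(["probe_id", "tissue"], as_index=False)
        .first()
    )
    first["direction"] = np.where(first["log2_fc"] > 0, "up", "down")
    return first.rename(columns={"time_h": "first_time_h"})[
        ["probe_id", "tissue", "direction", "first_time_h", "log2_fc", "p"]
    ].reset_index(drop=True)
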