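"""Per-probeset two-way ANOVA, FDR control, and four-category response calls.

A balanced 2x2 factorial design (factor 1 = knock-down vs control, factor 2 =
stimulus vs control, r replicates per cell) is decomposed on the log2 scale
into the classical fixed-effects sums of squares

    SS_total = SS_1 + SS_2 + SS_12 + SS_error,

each effect on 1 degree of freedom and the error on 4(r-1).  F statistics are
MS_effect / MS_error and p-values come from the F(1, 4(r-1)) distribution.
Benjamini-Hochberg q-values are computed separately within each of the three
effect families across all probesets, and each probeset is assigned one of
four response categories (or none):

    D "interactive"  q_interaction < alpha
    C "additive"     both main-effect q < alpha, interaction not significant
    A "factor1 only" only the factor-1 main effect significant
    B "factor2 only" only the factor-2 main effect significant

Interaction dominates: a significant interaction always yields D regardless
of the main effects, because additivity is defined by its absence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CELL_ORDER, ExpressionBundle

__all__ = [
    "ClassifyConfig",
    "anova_two_way",
    "anova_table",
    "fdr_adjust",
    "classify",
    "summarize_categories",
    "overlap_shares",
]

CATEGORIES = ("A", "B", "C", "D", "none")


@dataclass(frozen=True)
class ClassifyConfig:
    """Significance and fold-change cut-offs for category assignment."""

    alpha_fdr: float = 0.01
    fold_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_fdr < 1:
            raise ValueError("alpha_fdr must be in (0, 1)")
        if self.fold_threshold < 1:
            raise ValueError("fold threshold must be >= 1")


def _cells_to_array(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim == 3:
        arr = arr[np.newaxis]
    if arr.ndim != 4 or arr.shape[1:3] != (2, 2):
        raise ValueError("expected a (n, 2, 2, r) array of log2 intensities")
    if arr.shape[3] < 2:
        raise ValueError("need >= 2 replicates per cell")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite log2 intensity")
    return arr


def _anova_core(arr: np.ndarray) -> pd.DataFrame:
    """Vectorized balanced 2x2 ANOVA over an (n, 2, 2, r) array."""
    n, _, _, r = arr.shape
    cell_means = arr.mean(axis=3)  # (n, 2, 2)
    # marginal contrasts on the log2 scale
    d1 = cell_means[:, 1, :].mean(axis=1) - cell_means[:, 0, :].mean(axis=1)
    d2 = cell_means[:, :, 1].mean(axis=1) - cell_means[:, :, 0].mean(axis=1)
    c12 = cell_means[:, 1, 1] - cell_means[:, 1, 0] - cell_means[:, 0, 1] + cell_means[:, 0, 0]
    ss1 = r * d1**2
    ss2 = r * d2**2
    ss12 = r * c12**2 / 4.0
    sse = ((arr - cell_means[..., np.newaxis]) ** 2).sum(axis=(1, 2, 3))
    df_resid = 4 * (r - 1)
    mse = sse / df_resid

    def f_and_p(ss_eff: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(mse > 0, ss_eff / mse, np.nan)
        p = np.empty(n)
        ok = mse > 0
        p[ok] = stats.f.sf(f[ok], 1, df_resid)
        # degenerate zero-residual-variance convention: no effect -> F=0, p=1;
        # a nonzero effect with zero noise -> p=0
        zero = ~ok
        f[zero & (ss_eff <= 0)] = 0.0
        p[zero & (ss_eff <= 0)] = 1.0
        f[zero & (ss_eff > 0)] = np.inf
        p[zero & (ss_eff > 0)] = 0.0
        return f, p

    f1, p1 = f_and_p(ss1)
    f2, p2 = f_and_p(ss2)
    f12, p12 = f_and_p(ss12)
    return pd.DataFrame(
        {
            "F_factor1": f1,
            "p_factor1": p1,
            "F_factor2": f2,
            "p_factor2": p2,
            "F_interaction": f12,
            "p_interaction": p12,
            "df_resid": df_resid,
            "ms_resid": mse,
            "delta1_log2": d1,
            "delta2_log2": d2,
            "interaction_log2": c12,
        }
    )


def anova_two_way(values) -> pd.Series:
    """Two-way fixed-effects ANOVA of one probeset.

    Parameters
    ----------
    values
        (2, 2, r) array of log2 intensities; axis 0 is factor 1
        (control, treated), axis 1 is factor 2.

    Returns
    -------
    pandas.Series with F, p per effect, residual df and mean square, and
    the marginal/interaction log2 contrasts.
    """
    arr = _cells_to_array(values)
    if arr.shape[0] != 1:
        raise ValueError("anova_two_way takes a single probeset; use anova_table")
    return _anova_core(arr).iloc[0]


def _bundle_log2(bundle: ExpressionBundle) -> tuple[np.ndarray, list[str]]:
    """Stack the bundle into an (n, 2, 2, r) array of log2(x + 1) values."""
    cells = bundle.cell_samples()
    reps = {cell: len(s) for cell, s in cells.items()}
    if len(set(reps.values())) != 1:
        raise ValueError(
            f"unbalanced design not supported: replicates per cell {reps}"
        )
    r = next(iter(reps.values()))
    n = len(bundle.probeset_ids)
    arr = np.empty((n, 2, 2, r))
    log2v = np.log2(bundle.values.to_numpy(dtype=float) + 1.0)
    col_pos = {s: k for k, s in enumerate(bundle.sample_ids)}
    for (f1, f2), samples in cells.items():
        i = 0 if f1 == "control" else 1
        j = 0 if f2 == "control" else 1
        idx = [col_pos[s] for s in samples]
        arr[:, i, j, :] = log2v[:, idx]
    return arr, bundle.probeset_ids


def anova_table(bundle: ExpressionBundle) -> pd.DataFrame:
    """ANOVA records for every probeset of a bundle (log2(x+1) scale),
    with BH q-values added per effect family."""
    arr, probesets = _bundle_log2(bundle)
    table = _anova_core(arr)
    table.insert(0, "probeset_id", probesets)
    for eff in ("factor1", "factor2", "interaction"):
        table[f"q_{eff}"] = fdr_adjust(table[f"p_{eff}"].to_numpy())
    return table


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.empty(0)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction(delta: np.ndarray, significant: np.ndarray) -> np.ndarray:
    out = np.where(delta > 0, "up", "down")
    out = np.where(delta == 0, "n/a", out)
    return np.where(significant, out, "n/a")


def classify(anova: pd.DataFrame, config: ClassifyConfig = ClassifyConfig()) -> pd.DataFrame:
    """Assign each probeset to category A/B/C/D/none with direction and fold.

    The fold change is the largest absolute linear ratio over the contrasts
    belonging to the category (the significant marginal contrasts for A/B/C;
    all three treatment-vs-control cell contrasts for D).
    """
    a = config.alpha_fdr
    q1 = anova["q_factor1"].to_numpy()
    q2 = anova["q_factor2"].to_numpy()
    q12 = anova["q_interaction"].to_numpy()
    sig1, sig2, sig12 = q1 < a, q2 < a, q12 < a

    category = np.full(len(anova), "none", dtype=object)
    category[sig12] = "D"
    category[~sig12 & sig1 & sig2] = "C"
    category[~sig12 & sig1 & ~sig2] = "A"
    category[~sig12 & ~sig1 & sig2] = "B"

    d1 = anova["delta1_log2"].to_numpy()
    d2 = anova["delta2_log2"].to_numpy()
    # treatment-vs-control log2 contrasts of the three treated cells, from the
    # marginal/interaction parametrization of the 2x2 cell means
    c12 = anova["interaction_log2"].to_numpy()
    lfc_f2 = d2 - c12 / 2.0  # (ctl, treated) - (ctl, ctl)
    lfc_f1 = d1 - c12 / 2.0  # (treated, ctl) - (ctl, ctl)
    lfc_both = d1 + d2  # (treated, treated) - (ctl, ctl)

    max_lfc = np.zeros(len(anova))
    is_a, is_b = category == "A", category == "B"
    is_c, is_d = category == "C", category == "D"
    max_lfc[is_a] = np.abs(d1[is_a])
    max_lfc[is_b] = np.abs(d2[is_b])
    max_lfc[is_c] = np.maximum(np.abs(d1[is_c]), np.abs(d2[is_c]))
    max_lfc[is_d] = np.max(
        np.abs(np.column_stack([lfc_f1, lfc_f2, lfc_both]))[is_d], axis=1
    )
    fold = 2.0**max_lfc

    return pd.DataFrame(
        {
            "probeset_id": anova["probeset_id"].to_numpy()
            if "probeset_id" in anova
            else np.arange(len(anova)),
            "category": category,
            "direction_factor1": _direction(d1, sig1),
            "direction_factor2": _direction(d2, sig2),
            "max_fold_change": fold,
            "passes_2fold": fold >= config.fold_threshold,
            "q_factor1": q1,
            "q_factor2": q2,
            "q_interaction": q12,
        }
    )


def summarize_categories(calls: pd.DataFrame) -> pd.DataFrame:
    """Count table per category at the FDR-only and FDR + fold cut-offs,
    split by direction of the category's driving factor.

    Direction for A and C uses factor 1, for B factor 2; D profiles mix
    directions and are counted as a whole.
    """
    rows = []
    for cutoff in ("fdr", "fdr+fold"):
        sub = calls if cutoff == "fdr" else calls[calls["passes_2fold"]]
        counts = {c: int((sub["category"] == c).sum()) for c in CATEGORIES}
        up = {
            "A": int(((sub["category"] == "A") & (sub["direction_factor1"] == "up")).sum()),
            "B": int(((sub["category"] == "B") & (sub["direction_factor2"] == "up")).sum()),
            "C": int(((sub["category"] == "C") & (sub["direction_factor1"] == "up")).sum()),
        }
        rows.append(
            {
                "cutoff": cutoff,
                **{f"n_{c}": counts[c] for c in CATEGORIES},
                "n_up_A": up["A"],
                "n_up_B": up["B"],
                "n_up_C": up["C"],
                "factor1_responsive": counts["A"] + counts["C"] + counts["D"],
                "factor2_responsive": counts["B"] + counts["C"] + counts["D"],
                "both_responsive": counts["C"] + counts["D"],
            }
        )
    return pd.DataFrame(rows)


def overlap_shares(n_B: int, n_C: int, n_D: int, n_A: int | None = None) -> dict:
    """Overlap ratios between the two response axes.

    ``factor2_overlap`` is the share of factor-2-responsive probesets
    (B + C + D) that also respond to factor 1 (C + D); ``factor1_overlap``
    is the analogue for factor 1 when ``n_A`` is given.  Zero denominators
    yield NaN rather than an error.
    """
    both = n_C + n_D
    denom2 = n_B + both
    out = {
        "both_responsive": both,
        "factor2_responsive": denom2,
        "factor2_overlap": both / denom2 if denom2 else float("nan"),
    }
    if n_A is not None:
        denom1 = n_A + both
        out["factor1_responsive"] = denom1
        out["factor1_overlap"] = both / denom1 if denom1 else float("nan")
    return out
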