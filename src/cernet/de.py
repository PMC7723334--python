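"""Differential expression calling.

Features are tested per species and comparison group with an unpaired
two-sample t-test on log2 intensities (pooled variance by default, Welch
optional), gated by a signed fold-change threshold plus a multiplicity-
corrected (or raw, for circRNA) p-value, then merged across comparisons
by direction-consistent intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import SPECIES, ExpressionMatrix

COMPARISONS = ("AvsCtrl", "BvsCtrl", "merged")

CALL_COLUMNS = [
    "feature_id", "species", "comparison", "log2fc", "fold_change",
    "p_raw", "p_adj", "direction",
]


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (q-values).

    q_(i) = min_{j >= i} min(1, p_(j) * n / j) in rank order, mapped back
    to the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * n / np.arange(1, n + 1)
    q = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(n)
    out[order] = q
    return out


def adjust_holm(p_values) -> np.ndarray:
    """Holm step-down adjustment with enforced monotonicity, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * (n - np.arange(n))
    adj = np.minimum(1.0, np.maximum.accumulate(scaled))
    out = np.empty(n)
    out[order] = adj
    return out


def signed_fold_change(log2fc: np.ndarray) -> np.ndarray:
    """Map log2 fold change to the signed-ratio convention.

    2^|lfc| with the sign of lfc, so values never fall in (-1, 1); a
    doubling is +2.0 and a halving is -2.0.
    """
    lfc = np.asarray(log2fc, dtype=float)
    return np.where(lfc >= 0, 2.0 ** lfc, -(2.0 ** (-lfc)))


def differential_test(
    matrix: ExpressionMatrix,
    condition_a: str,
    condition_b: str,
    welch: bool = False,
) -> pd.DataFrame:
    """Per-feature two-sided t-test of condition_b vs condition_a.

    Returns columns feature_id, log2fc (mean(b) - mean(a)), fold_change,
    p_raw, degenerate.  Zero pooled variance yields p = 1 for equal means
    and p = 0 (flagged degenerate) otherwise.
    """
    samples_a = matrix.samples_of(condition_a)
    samples_b = matrix.samples_of(condition_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each condition needs >= 2 replicates")
    a = matrix.values[samples_a].to_numpy(dtype=float)
    b = matrix.values[samples_b].to_numpy(dtype=float)
    na, nb = a.shape[1], b.shape[1]
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = mean_b - mean_a

    var_a = a.var(axis=1, ddof=1)
    var_b = b.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        if welch:
            se2 = var_a / na + var_b / nb
            t = log2fc / np.sqrt(se2)
            df = se2 ** 2 / (
                (var_a / na) ** 2 / (na - 1) + (var_b / nb) ** 2 / (nb - 1)
            )
        else:
            pooled = ((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2)
            t = log2fc / np.sqrt(pooled * (1 / na + 1 / nb))
            df = np.full_like(t, float(na + nb - 2))
        p = 2.0 * stats.t.sf(np.abs(t), df)

    degenerate = ~np.isfinite(t)
    equal_means = np.isclose(log2fc, 0.0)
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, 0.0, p)
    degenerate = degenerate & ~equal_means

    return pd.DataFrame(
        {
            "feature_id": matrix.feature_ids,
            "log2fc": log2fc,
            "fold_change": signed_fold_change(log2fc),
            "p_raw": p,
            "degenerate": degenerate,
        }
    )


@dataclass
class ThresholdPolicy:
    """Per-species DE gates.

    ``min_abs_fc`` is the minimum |signed fold change| (ratio scale);
    ``p_mode`` selects the gated p-value per species (``adjusted`` or
    ``raw``); calls pass when |FC| meets the species threshold and the
    selected p is below ``alpha``.
    """

    min_abs_fc: dict[str, float] = field(
        default_factory=lambda: {"lncRNA": 2.0, "circRNA": 2.0, "miRNA": 1.5, "mRNA": 2.0}
    )
    p_mode: dict[str, str] = field(
        default_factory=lambda: {
            "lncRNA": "adjusted", "circRNA": "raw", "miRNA": "adjusted", "mRNA": "adjusted",
        }
    )
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        for sp, fc in self.min_abs_fc.items():
            if fc < 1.0:
                raise ValueError(f"{sp}: |FC| threshold must be >= 1")
        for sp, mode in self.p_mode.items():
            if mode not in ("adjusted", "raw"):
                raise ValueError(f"{sp}: p_mode must be 'adjusted' or 'raw'")


def call_de(
    stats_df: pd.DataFrame,
    policy: ThresholdPolicy,
    species: str,
    comparison: str,
) -> pd.DataFrame:
    """Apply the threshold policy to one species x comparison family.

    BH adjustment is computed within this family regardless of which p the
    policy gates on, so ``p_adj`` is always reported.
    """
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    df = stats_df.copy()
    df["p_adj"] = adjust_bh(df["p_raw"].to_numpy())
    gate_p = df["p_adj"] if policy.p_mode[species] == "adjusted" else df["p_raw"]
    fc_min = policy.min_abs_fc[species]
    passes = (df["fold_change"].abs() >= fc_min) & (gate_p < policy.alpha)
    df["direction"] = np.where(
        passes & (df["fold_change"] > 0), "up", np.where(passes, "down", "not_de")
    )
    df["species"] = species
    df["comparison"] = comparison
    return df[CALL_COLUMNS]


def merge_comparisons(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Direction-consistent intersection of two comparison groups.

    A feature is merged iff it is DE in both inputs with the same
    direction; conflicting directions are excluded.  Reported statistics
    take the per-feature maximum p and minimum |fold change| (the
    conservative envelope of the two comparisons).
    """
    species = set(calls_a["species"]) | set(calls_b["species"])
    if len(species) > 1:
        raise ValueError(f"species mismatch in merge: {sorted(species)}")
    de_a = calls_a[calls_a["direction"] != "not_de"]
    de_b = calls_b[calls_b["direction"] != "not_de"]
    merged = de_a.merge(de_b, on=["feature_id", "species", "direction"], suffixes=("_a", "_b"))
    weaker = merged["fold_change_a"].abs() <= merged["fold_change_b"].abs()
    out = pd.DataFrame(
        {
            "feature_id": merged["feature_id"],
            "species": merged["species"],
            "comparison": "merged",
            "log2fc": np.where(weaker, merged["log2fc_a"], merged["log2fc_b"]),
            "fold_change": np.where(weaker, merged["fold_change_a"], merged["fold_change_b"]),
            "p_raw": merged[["p_raw_a", "p_raw_b"]].max(axis=1),
            "p_adj": merged[["p_adj_a", "p_adj_b"]].max(axis=1),
            "direction": merged["direction"],
        }
    )
    return out[CALL_COLUMNS].sort_values("feature_id", ignore_index=True)


def de_feature_set(calls: pd.DataFrame) -> set[str]:
    """Feature ids called DE (direction != not_de)."""
    return set(calls.loc[calls["direction"] != "not_de", "feature_id"])
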