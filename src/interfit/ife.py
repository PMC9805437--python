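"""Interaction fitness effects: per-gene difference statistics against growth alone.

The interaction fitness effect (IFE) of a gene in an interactive condition is
the difference between its gene fitness there and its gene fitness in growth
alone.  A nonzero IFE marks an interaction-associated mutant: positive when
the partners improve the mutant's relative growth, negative when they hurt it.

Per-gene testing follows the classical recipe: an F-test first checks
equality of the replicate variances; if not rejected the two groups are
compared with a pooled-variance two-sample t-test, otherwise with Welch's
unequal-variance t-test.  P-values are corrected per interactive condition
with the Benjamini-Hochberg step-up, and IFEs with adjusted p at or below
``alpha_ife`` (default 0.1) are called significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pool_io import ALONE, ConditionCode


def compute_ife(interactive_values, alone_values) -> float:
    """Difference of condition means: mean(interactive) - mean(alone)."""
    return float(np.mean(interactive_values) - np.mean(alone_values))


def test_ife(
    alone_reps, inter_reps, var_alpha: float = 0.05
) -> tuple[float, float, float]:
    """Two-sided two-sample t-test with an F-test pre-check of variance equality.

    Returns ``(t_stat, df, p_raw)``.  The statistic is oriented so that a
    positive value means the interactive mean exceeds the alone mean.  If the
    F-test rejects equality of variances at ``var_alpha`` the Welch form with
    Welch-Satterthwaite degrees of freedom is used instead of the pooled form.

    Degenerate inputs (both groups with zero variance) return p = 1 when the
    means agree and p = 0 when they differ.
    """
    a = np.asarray(alone_reps, dtype=float)
    b = np.asarray(inter_reps, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two replicates per group")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("replicate values must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        same = np.mean(a) == np.mean(b)
        return (0.0 if same else np.inf * np.sign(np.mean(b) - np.mean(a))), float(
            len(a) + len(b) - 2
        ), (1.0 if same else 0.0)

    # F-test of variance equality (two-sided)
    if va > 0 and vb > 0:
        f = va / vb
        p_f = 2.0 * min(
            stats.f.cdf(f, len(a) - 1, len(b) - 1),
            stats.f.sf(f, len(a) - 1, len(b) - 1),
        )
        equal_var = p_f > var_alpha
    else:
        equal_var = False

    res = stats.ttest_ind(b, a, equal_var=equal_var)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class IFEParams:
    alpha_ife: float = 0.1
    var_alpha: float = 0.05
    bh_family: str = "per_condition"  # or "global"

    def __post_init__(self) -> None:
        if not (0 < self.alpha_ife < 1 and 0 < self.var_alpha < 1):
            raise ValueError("thresholds must lie in (0, 1)")
        if self.bh_family not in ("per_condition", "global"):
            raise ValueError("bh_family must be per_condition or global")


def ife_table(per_rep: pd.DataFrame, params: IFEParams | None = None) -> pd.DataFrame:
    """Full IFE table over genes x interactive conditions.

    ``per_rep`` is the per-replicate gene-fitness table (locus_id, condition,
    replicate, value).  Genes lacking fitness in the alone condition or in an
    interactive condition are skipped for that comparison, never imputed.

    Returns columns: locus_id, condition, ife, t_stat, df, p_raw, p_adj,
    significant, sign.
    """
    params = params or IFEParams()
    alone_label = ALONE.label
    wide = {
        (locus, cond): grp["value"].to_numpy()
        for (locus, cond), grp in per_rep.groupby(["locus_id", "condition"])
    }
    alone = {
        locus: v for (locus, cond), v in wide.items() if cond == alone_label
    }
    rows = []
    for (locus, cond), vals in sorted(wide.items()):
        if cond == alone_label or locus not in alone:
            continue
        a = alone[locus]
        if len(a) < 2 or len(vals) < 2:
            continue
        t, df, p = test_ife(a, vals, params.var_alpha)
        rows.append(
            {
                "locus_id": locus,
                "condition": cond,
                "ife": compute_ife(vals, a),
                "t_stat": t,
                "df": df,
                "p_raw": p,
            }
        )
    tab = pd.DataFrame(
        rows, columns=["locus_id", "condition", "ife", "t_stat", "df", "p_raw"]
    )
    if tab.empty:
        tab["p_adj"] = tab["significant"] = tab["sign"] = []
        return tab
    if params.bh_family == "global":
        tab["p_adj"] = bh_adjust(tab["p_raw"].to_numpy())
    else:
        tab["p_adj"] = np.nan
        for cond, idx in tab.groupby("condition").groups.items():
            tab.loc[idx, "p_adj"] = bh_adjust(tab.loc[idx, "p_raw"].to_numpy())
    return call_interactions(tab, params.alpha_ife)


def call_interactions(tab: pd.DataFrame, alpha_ife: float = 0.1) -> pd.DataFrame:
    """Attach significance and sign calls at the adjusted-p threshold."""
    tab = tab.copy()
    tab["significant"] = tab["p_adj"] <= alpha_ife
    sign = np.where(tab["ife"] > 0, "positive", np.where(tab["ife"] < 0, "negative", "none"))
    tab["sign"] = np.where(tab["significant"], sign, "none")
    return tab


def condition_counts(tab: pd.DataFrame) -> pd.DataFrame:
    """Per-condition counts of significant positive/negative IFEs (volcano totals)."""
    sig = tab[tab["significant"]]
    rows = []
    for cond in sorted(tab["condition"].unique()):
        sub = sig[sig["condition"] == cond]
        rows.append(
            {
                "condition": cond,
                "n_positive": int((sub["sign"] == "positive").sum()),
                "n_negative": int((sub["sign"] == "negative").sum()),
                "n_tested": int((tab["condition"] == cond).sum()),
            }
        )
    return pd.DataFrame(rows, columns=["condition", "n_positive", "n_negative", "n_tested"])
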