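"""Exact local epistasis decomposition of gene fitness over community compositions.

The eight community compositions form a three-bit genotype space over the
presence/absence of the partners (Gc, Ha, Pc).  Any real-valued phenotype on
that space — per-gene fitness, or the community's final CFU count — has a
unique exact expansion

    f(x) = f0 + sum_i beta_i x_i + sum_{i<j} eps_ij x_i x_j + eps_123 x1 x2 x3

whose coefficients follow by inclusion-exclusion from the corner phenotypes:
beta_i is the single-partner effect (the 2-species interaction fitness
effect), eps_ij the deviation of the two-partner composition from the sum of
its single-partner effects (3-species epistasis), and eps_123 the residual of
the full community beyond all lower-order terms (4-species epistasis).
Because the system is square (8 phenotypes, 8 coefficients) the
reconstruction is exact, not a regression.

Coefficient significance is assessed with parametric pseudoreplicates: each
composition's phenotype is redrawn from a normal law centred on its observed
mean with the standard error of that mean, the decomposition is recomputed,
and a two-sided empirical p-value per coefficient is read off the resampled
distribution (add-one corrected so p is never zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ife import bh_adjust
from .pool_io import ALL_CONDITIONS, ConditionCode

#: Genotype order used throughout: by complexity level, then bitstring.
GENOTYPE_ORDER: tuple[ConditionCode, ...] = ALL_CONDITIONS

COEF_NAMES = (
    "f0",
    "beta_Gc",
    "beta_Ha",
    "beta_Pc",
    "eps_GcHa",
    "eps_GcPc",
    "eps_HaPc",
    "eps_GcHaPc",
)

EPS_NAMES = COEF_NAMES[4:]

#: Which bits each coefficient multiplies, in (Gc, Ha, Pc) bit order.
_COEF_BITS = (
    (0, 0, 0),
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, 0, 1),
    (0, 1, 1),
    (1, 1, 1),
)


def design_matrix() -> np.ndarray:
    """8x8 binary design: rows = genotypes in GENOTYPE_ORDER, cols = COEF_NAMES."""
    X = np.empty((8, 8))
    for r, g in enumerate(GENOTYPE_ORDER):
        for c, bits in enumerate(_COEF_BITS):
            X[r, c] = np.prod([g.bits[k] for k in range(3) if bits[k]] or [1.0])
    return X


_X = design_matrix()
_XINV = np.linalg.inv(_X)


@dataclass
class GenotypePhenotypeMap:
    """Phenotype mean/sd/replication for each of the 8 compositions (GENOTYPE_ORDER)."""

    means: np.ndarray
    sds: np.ndarray
    ns: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        self.ns = np.asarray(self.ns, dtype=int)
        if not (self.means.shape == self.sds.shape == (8,) and self.ns.shape == (8,)):
            raise ValueError("a genotype-phenotype map needs exactly 8 compositions")
        if np.any(self.sds < 0):
            raise ValueError("phenotype sds must be non-negative")

    def phenotype(self, cond: ConditionCode) -> float:
        return float(self.means[GENOTYPE_ORDER.index(cond)])


def build_gpmap(summary: pd.DataFrame, locus_id: str) -> GenotypePhenotypeMap:
    """Assemble a gene's 8-composition map from the gene-fitness summary table.

    Raises ``KeyError`` when the gene lacks fitness in any composition; callers
    skip (and log) such genes rather than imputing.
    """
    sub = summary[summary["locus_id"] == locus_id].set_index("condition")
    means, sds, ns = [], [], []
    for g in GENOTYPE_ORDER:
        if g.label not in sub.index:
            raise KeyError(f"gene {locus_id}: no fitness for composition {g.label}")
        row = sub.loc[g.label]
        means.append(row["mean"])
        sds.append(0.0 if pd.isna(row["sd"]) else row["sd"])
        ns.append(row["n_replicates"])
    return GenotypePhenotypeMap(np.array(means), np.array(sds), np.array(ns))


def decompose_local(gpmap: GenotypePhenotypeMap | np.ndarray) -> dict[str, float]:
    """Closed-form inclusion-exclusion decomposition of the 8 phenotype means.

    Returns the coefficient dict keyed by COEF_NAMES.  Exact: reconstructing
    the phenotypes from the full-order coefficients reproduces the inputs to
    machine precision.
    """
    y = gpmap.means if isinstance(gpmap, GenotypePhenotypeMap) else np.asarray(gpmap, float)
    f = {g.code: y[i] for i, g in enumerate(GENOTYPE_ORDER)}
    coef = {
        "f0": f["000"],
        "beta_Gc": f["100"] - f["000"],
        "beta_Ha": f["010"] - f["000"],
        "beta_Pc": f["001"] - f["000"],
        "eps_GcHa": f["110"] - f["100"] - f["010"] + f["000"],
        "eps_GcPc": f["101"] - f["100"] - f["001"] + f["000"],
        "eps_HaPc": f["011"] - f["010"] - f["001"] + f["000"],
        "eps_GcHaPc": f["111"]
        - (f["110"] + f["101"] + f["011"])
        + (f["100"] + f["010"] + f["001"])
        - f["000"],
    }
    return {k: float(v) for k, v in coef.items()}


def coef_vector(coef: dict[str, float]) -> np.ndarray:
    return np.array([coef[k] for k in COEF_NAMES])


def predict_truncated(coef: dict[str, float], max_order: int) -> dict[str, float]:
    """Phenotype predictions keeping terms up to ``max_order`` (1 = additive, 2 = +pairwise).

    At the full community genotype 111, the observed phenotype minus the
    order-2 prediction equals the third-order coefficient exactly.
    """
    if max_order not in (1, 2):
        raise ValueError("max_order must be 1 or 2")
    n_terms = 4 if max_order == 1 else 7
    c = coef_vector(coef).copy()
    c[n_terms:] = 0.0
    pred = _X @ c
    return {g.code: float(pred[i]) for i, g in enumerate(GENOTYPE_ORDER)}


def reconstruct(coef: dict[str, float]) -> dict[str, float]:
    """Full-order reconstruction of all 8 phenotypes from the coefficients."""
    pred = _X @ coef_vector(coef)
    return {g.code: float(pred[i]) for i, g in enumerate(GENOTYPE_ORDER)}


def pseudoreplicate_significance(
    gpmap: GenotypePhenotypeMap,
    B: int = 7000,
    seed: int | np.random.Generator = 0,
    scale: str = "sem",
) -> dict[str, float]:
    """Empirical two-sided p-value per coefficient from parametric pseudoreplicates.

    Each pseudoreplicate redraws every composition's phenotype from
    N(mean, spread^2) with spread = sd/sqrt(n) ("sem", default — the model
    consumes condition means) or spread = sd ("sd"), then recomputes the
    decomposition.  p = (2 * min(#{c <= 0}, #{c >= 0}) + 1) / (B + 1), capped
    at 1, so the smallest attainable p is 1/(B+1).  Deterministic given seed.
    """
    if B < 100:
        raise ValueError("need at least 100 pseudoreplicates")
    if scale not in ("sem", "sd"):
        raise ValueError("scale must be 'sem' or 'sd'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spread = gpmap.sds / np.sqrt(gpmap.ns) if scale == "sem" else gpmap.sds
    draws = gpmap.means + rng.standard_normal((B, 8)) * spread
    coefs = draws @ _XINV.T  # (B, 8) coefficient pseudoreplicates
    n_le = (coefs <= 0).sum(axis=0)
    n_ge = (coefs >= 0).sum(axis=0)
    p = np.minimum(1.0, (2.0 * np.minimum(n_le, n_ge) + 1.0) / (B + 1.0))
    return dict(zip(COEF_NAMES, p.astype(float)))


def classify_additivity(
    significant: dict[str, bool] | pd.Series,
) -> str:
    """Additivity category from the significance flags of the 4 epistatic terms.

    additive: no pairwise nor third-order epistasis; eps3_only: only the
    third-order term; eps2_only: pairwise epistasis without a third-order
    term; eps2_and_eps3: both.
    """
    missing = [k for k in EPS_NAMES if k not in significant]
    if missing:
        raise ValueError(f"missing significance flag(s) for {missing}")
    e2 = any(bool(significant[k]) for k in EPS_NAMES[:3])
    e3 = bool(significant["eps_GcHaPc"])
    if not e2 and not e3:
        return "additive"
    if e3 and not e2:
        return "eps3_only"
    if e2 and not e3:
        return "eps2_only"
    return "eps2_and_eps3"


def epistasis_table(
    summary: pd.DataFrame,
    genes: list[str] | None = None,
    B: int = 7000,
    seed: int = 0,
    alpha_eps: float = 0.01,
    scale: str = "sem",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Decompose every eligible gene and test its coefficients.

    BH correction pools all coefficients across all genes in the run into a
    single family.  Returns ``(results, skipped)``; skipped lists genes
    lacking any composition.
    """
    if genes is None:
        genes = sorted(summary["locus_id"].unique())
    rng = np.random.default_rng(seed)
    rows, skipped = [], []
    for locus in genes:
        try:
            gpm = build_gpmap(summary, locus)
        except KeyError as exc:
            skipped.append({"locus_id": locus, "reason": str(exc)})
            continue
        coef = decompose_local(gpm)
        p_emp = pseudoreplicate_significance(gpm, B=B, seed=rng, scale=scale)
        row = {"locus_id": locus}
        row.update(coef)
        row.update({f"p_emp_{k}": p_emp[k] for k in COEF_NAMES})
        rows.append(row)
    res = pd.DataFrame(rows)
    skip = pd.DataFrame(skipped, columns=["locus_id", "reason"])
    if res.empty:
        return res, skip
    pcols = [f"p_emp_{k}" for k in COEF_NAMES]
    flat = res[pcols].to_numpy().ravel()
    res[[f"p_adj_{k}" for k in COEF_NAMES]] = bh_adjust(flat).reshape(-1, len(COEF_NAMES))
    res["category"] = [
        classify_additivity(
            {k: res.loc[i, f"p_adj_{k}"] <= alpha_eps for k in EPS_NAMES}
        )
        for i in res.index
    ]
    return res, skip


def nonlinearity_check(
    observed,
    predicted,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Quadratic scale diagnostic: fit observed = a + b*pred + c*pred^2.

    Reports the curvature coefficient c with a bootstrap percentile interval;
    the data are flagged nonlinear iff the interval excludes zero.  A
    degenerate predictor (no variance) yields a null diagnostic.
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape or obs.size < 10:
        raise ValueError("need >= 10 paired (observed, predicted) values")
    if np.std(pred) == 0:
        return {"c": None, "ci_low": None, "ci_high": None, "nonlinear": None}
    coeffs = np.polyfit(pred, obs, 2)
    c = float(coeffs[0])
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, obs.size, size=(n_boot, obs.size))
    cs = []
    for ii in idx:
        if np.std(pred[ii]) == 0:
            continue
        cs.append(np.polyfit(pred[ii], obs[ii], 2)[0])
    lo, hi = np.quantile(cs, [(1 - level) / 2, 1 - (1 - level) / 2])
    # guard against numerically-zero curvature on exact linear data
    tol = 1e-9 * max(1.0, float(np.std(obs)))
    return {
        "c": c,
        "ci_low": float(lo),
        "ci_high": float(hi),
        "nonlinear": bool(lo > tol or hi < -tol),
    }


def growth_epistasis(
    cfu: pd.DataFrame,
    B: int = 7000,
    seed: int = 0,
    alpha_eps: float = 0.01,
    log_scale: bool = False,
    scale: str = "sem",
) -> dict:
    """Epistasis decomposition of community-level growth (final CFU counts).

    ``cfu`` is a long table (condition, replicate, cfu) covering all 8
    compositions with at least two replicates each.  The identical machinery
    used for per-gene fitness runs on the condition means (raw CFU scale by
    default; ``log_scale`` switches to log10 CFUs).  The result says whether
    3- and 4-species growth is predictable from the 2-species growths.
    """
    df = cfu.copy()
    df["condition"] = [ConditionCode.from_string(c).label for c in df["condition"]]
    if log_scale:
        df["cfu"] = np.log10(df["cfu"])
    g = df.groupby("condition")["cfu"]
    summary = pd.DataFrame(
        {
            "locus_id": "community_growth",
            "condition": g.mean().index,
            "mean": g.mean().to_numpy(),
            "sd": g.std(ddof=1).to_numpy(),
            "n_replicates": g.size().to_numpy(),
        }
    )
    missing = [c.label for c in GENOTYPE_ORDER if c.label not in set(summary["condition"])]
    if missing:
        raise ValueError(f"CFU table missing composition(s): {missing}")
    if (summary["n_replicates"] < 2).any():
        raise ValueError("every composition needs >= 2 CFU replicates")
    gpm = build_gpmap(summary, "community_growth")
    coef = decompose_local(gpm)
    p_emp = pseudoreplicate_significance(gpm, B=B, seed=seed, scale=scale)
    p_adj = dict(zip(COEF_NAMES, bh_adjust([p_emp[k] for k in COEF_NAMES])))
    category = classify_additivity({k: p_adj[k] <= alpha_eps for k in EPS_NAMES})
    pred2 = predict_truncated(coef, max_order=2)
    return {
        "coefficients": coef,
        "p_emp": p_emp,
        "p_adj": p_adj,
        "category": category,
        "predicted_order2": pred2,
        "observed": {g.code: gpm.phenotype(g) for g in GENOTYPE_ORDER},
        "additive_growth": category == "additive",
    }
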