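"""Forward simulator for pooled barcoded-transposon interaction assays.

Generates poolcount-style inputs with a known ground truth so that every
downstream stage (fitness, interaction fitness effects, transition set logic,
epistasis) can be validated by parameter recovery:

1. a pool of insertion strains (Poisson strains per gene, uniform within-gene
   insertion positions so a predictable share falls outside the central
   10-90% window, plus intergenic strains and neutral reference-gene strains);
2. a per-gene interaction surface over the 8 community compositions, planted
   as local-epistasis coefficients drawn class-by-class (null, additive
   pairwise, pairwise epistasis, third-order epistasis, both, or a fully
   conserved additive chain);
3. sequencing counts: T0 abundances are log-normal around equal shares;
   endpoint strain weights multiply the T0 share by 2^(surface + strain noise
   + replicate noise) and reads are drawn multinomially at fixed depth, so
   the planted log2 surface equals, in expectation, the fitness statistic the
   pipeline computes (identity-calibrated recovery).

The truth table records the planted coefficients plus analytic expectations
(noncentral-t power at the configured noise) for which interaction calls the
pipeline should make, and ``score_recovery`` turns a pipeline run into
confusion matrices, precision/recall and coefficient RMSE.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import epistasis as ep
from . import hoi
from .fitness import DEFAULT_REFERENCE_GENES
from .pool_io import (
    ALONE,
    ALL_CONDITIONS,
    INTERACTIVE_CONDITIONS,
    ConditionCode,
    InsertionStrain,
    SampleMeta,
)

DEFAULT_CLASS_MIX = {
    "null": 0.30,
    "pairwise_only": 0.25,
    "eps2": 0.15,
    "eps3": 0.10,
    "eps2_and_eps3": 0.10,
    "conserved_chain": 0.10,
}

_INTER_LABELS = tuple(c.label for c in INTERACTIVE_CONDITIONS)


@dataclass
class SimConfig:
    """Study conditions of the simulated assay.

    Defaults mirror the real experiment at desk scale: 200 genes with a
    Poisson average of 16 insertion strains each, 3 biological replicates of
    8 community compositions sharing one T0 sample, and 2e6 reads per sample.
    Noise has two additive log2-scale layers: a per-strain offset
    (``strain_noise_sd``) and a per-gene-per-replicate offset
    (``replicate_noise_sd``).
    """

    n_genes: int = 200
    mean_strains_per_gene: float = 16.0
    intergenic_fraction: float = 0.15
    n_replicates: int = 3
    read_depth: int = 2_000_000
    strain_noise_sd: float = 0.25
    replicate_noise_sd: float = 0.05
    t0_spread_log2: float = 1.0
    f0_sd: float = 0.3
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    effect_size_grid: tuple = (0.5, 1.0, 1.5)
    reference_genes: tuple = DEFAULT_REFERENCE_GENES
    alpha_power: float = 0.05
    power_threshold: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        if not (0 <= self.intergenic_fraction < 1):
            raise ValueError("intergenic_fraction must lie in [0, 1)")
        if self.read_depth <= 0 or self.n_replicates < 2:
            raise ValueError("read_depth must be positive and n_replicates >= 2")
        if min(self.strain_noise_sd, self.replicate_noise_sd) < 0:
            raise ValueError("noise sds must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic substream per stage."""
        return np.random.default_rng([self.seed, stream])


def gene_ids(config: SimConfig) -> list[str]:
    return [f"g{i:04d}" for i in range(1, config.n_genes + 1)]


def generate_pool(config: SimConfig) -> list[InsertionStrain]:
    """Insertion pool: planted genes, neutral reference genes, intergenic strains."""
    rng = config.rng(1)
    pool: list[InsertionStrain] = []
    pos = 100
    genes = gene_ids(config) + list(config.reference_genes if config.n_genes else ())
    for locus in genes:
        k = max(1, rng.poisson(config.mean_strains_per_gene))
        for j in range(k):
            pool.append(
                InsertionStrain(
                    barcode=f"{locus}_bc{j:02d}",
                    rcbarcode=f"rc_{locus}_{j:02d}",
                    scaffold="chr1",
                    position=pos,
                    strand=rng.choice(["+", "-"]),
                    locus_id=locus,
                    gene_fraction=float(rng.uniform(0.0, 1.0)),
                )
            )
            pos += 7
    n_genic = len(pool)
    f = config.intergenic_fraction
    n_inter = int(round(n_genic * f / (1.0 - f))) if n_genic else 0
    for j in range(n_inter):
        pool.append(
            InsertionStrain(
                barcode=f"ig_bc{j:04d}",
                rcbarcode=f"rc_ig_{j:04d}",
                scaffold="chr1",
                position=pos,
                strand=rng.choice(["+", "-"]),
                locus_id=None,
                gene_fraction=None,
            )
        )
        pos += 7
    return pool


def _draw_class(rng: np.random.Generator, mix: dict) -> str:
    names = sorted(mix)
    return str(rng.choice(names, p=[mix[n] for n in names]))


def _draw_effect(rng: np.random.Generator, grid) -> float:
    return float(rng.choice(grid)) * float(rng.choice([-1.0, 1.0]))


def _plant_coefficients(rng: np.random.Generator, label: str, grid) -> dict[str, float]:
    """Coefficients (local-epistasis parameterisation) for one gene of a class."""
    coef = {k: 0.0 for k in ep.COEF_NAMES}
    betas = ["beta_Gc", "beta_Ha", "beta_Pc"]
    pair_of = {("beta_Gc", "beta_Ha"): "eps_GcHa",
               ("beta_Gc", "beta_Pc"): "eps_GcPc",
               ("beta_Ha", "beta_Pc"): "eps_HaPc"}
    if label == "null":
        pass
    elif label == "pairwise_only":
        k = int(rng.choice([1, 2, 3], p=[0.5, 0.3, 0.2]))
        for b in rng.choice(betas, size=k, replace=False):
            coef[b] = _draw_effect(rng, grid)
    elif label == "eps2":
        i, j = sorted(rng.choice(3, size=2, replace=False))
        coef[betas[i]] = _draw_effect(rng, grid)
        coef[betas[j]] = _draw_effect(rng, grid)
        coef[pair_of[(betas[i], betas[j])]] = _draw_effect(rng, grid)
    elif label == "eps3":
        for b in betas:
            coef[b] = _draw_effect(rng, grid)
        coef["eps_GcHaPc"] = _draw_effect(rng, grid)
    elif label == "eps2_and_eps3":
        i, j = sorted(rng.choice(3, size=2, replace=False))
        coef[betas[i]] = _draw_effect(rng, grid)
        coef[betas[j]] = _draw_effect(rng, grid)
        coef[pair_of[(betas[i], betas[j])]] = _draw_effect(rng, grid)
        coef["eps_GcHaPc"] = _draw_effect(rng, grid)
    elif label == "conserved_chain":
        e = float(rng.choice(grid)) * float(rng.choice([-1.0, 1.0]))
        for b in betas:
            coef[b] = e
    else:
        raise ValueError(f"unknown gene class {label!r}")
    return coef


def analytic_replicate_sd(config: SimConfig) -> float:
    """Approximate per-replicate sd of an estimated gene fitness value.

    Combines the replicate offset, the strain offset averaged over the
    expected number of centrally inserted strains, and endpoint counting
    noise at the expected reads per strain (delta method on the log2 count).
    """
    k_eff = max(1.0, 0.8 * config.mean_strains_per_gene)  # central 10-90% window
    n_strains = (
        config.n_genes * config.mean_strains_per_gene
        + len(config.reference_genes) * config.mean_strains_per_gene
    )
    n_strains = n_strains / (1.0 - config.intergenic_fraction) if n_strains else 1.0
    reads_per_strain = max(1.0, config.read_depth / n_strains)
    count_var = 1.0 / (math.log(2) ** 2 * reads_per_strain) / k_eff
    return math.sqrt(
        config.replicate_noise_sd**2 + config.strain_noise_sd**2 / k_eff + count_var
    )


def ife_power(delta: float, se: float, df: float, alpha: float) -> float:
    """Two-sided noncentral-t power of detecting a mean difference ``delta``."""
    if se == 0:
        return 1.0 if delta != 0 else 0.0
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    ncp = delta / se
    return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))


def generate_truth(config: SimConfig) -> pd.DataFrame:
    """Planted coefficients per gene plus analytic expected downstream calls.

    One row per gene: class label, the 8 local coefficients, the implied
    planted interaction fitness effect per interactive composition
    (``ife_<label>``), the analytic expected significance call per composition
    (``exp_sig_<label>``, noncentral-t power at the configured noise compared
    against ``power_threshold``), the per-gene analytic standard errors, and
    the expected additivity category and provenance origin.
    """
    rng = config.rng(2)
    sd_rep = analytic_replicate_sd(config)
    se_ife = sd_rep * math.sqrt(2.0 / config.n_replicates)
    df = 2.0 * (config.n_replicates - 1)
    sem = sd_rep / math.sqrt(config.n_replicates)

    rows = []
    loci = [(g, None) for g in gene_ids(config)]
    if config.n_genes:
        loci += [(g, "reference") for g in config.reference_genes]
    for locus, forced in loci:
        label = forced or _draw_class(rng, config.class_mix)
        if label == "reference":
            coef = {k: 0.0 for k in ep.COEF_NAMES}
        else:
            coef = _plant_coefficients(rng, label, config.effect_size_grid)
            coef["f0"] = float(rng.normal(0.0, config.f0_sd))
        surface = ep.reconstruct(coef)
        row: dict = {"locus_id": locus, "class_label": label}
        row.update(coef)
        exp_sets: dict[str, bool] = {}
        for cond in INTERACTIVE_CONDITIONS:
            ife = surface[cond.code] - coef["f0"]
            power = ife_power(ife, se_ife, df, config.alpha_power)
            sig = power >= config.power_threshold
            row[f"ife_{cond.label}"] = ife
            row[f"exp_sig_{cond.label}"] = sig
            exp_sets[cond.label] = sig
        row["se_ife"] = se_ife
        row["sem_phenotype"] = sem
        row["expected_category"] = ep.classify_additivity(
            {k: coef[k] != 0.0 for k in ep.EPS_NAMES}
        )
        rows.append(row)
    truth = pd.DataFrame(rows)
    if truth.empty:
        return truth
    truth["expected_origin"] = _expected_origins(truth)
    return truth


def _expected_sets(truth: pd.DataFrame) -> dict[str, set[str]]:
    return {
        lbl: set(truth.loc[truth[f"exp_sig_{lbl}"], "locus_id"]) for lbl in _INTER_LABELS
    }


def _expected_origins(truth: pd.DataFrame) -> list[str | None]:
    sets = _expected_sets(truth)
    prov, _ = hoi.trace_provenance(sets)
    origin = dict(zip(prov["locus_id"], prov["origin"]))
    return [origin.get(g) for g in truth["locus_id"]]


def expected_transitions(truth: pd.DataFrame) -> pd.DataFrame:
    """Expected transition statuses implied by the analytic significance calls."""
    sets = _expected_sets(truth)
    return pd.concat(
        [hoi.classify_2to3(sets), hoi.classify_3to4(sets)], ignore_index=True
    )


def simulate_counts(
    pool: list[InsertionStrain], truth: pd.DataFrame, config: SimConfig
) -> tuple[pd.DataFrame, list[SampleMeta]]:
    """Multinomial sequencing counts for one shared T0 plus all endpoint samples.

    Endpoint strain weight = T0 share x 2^(gene surface + strain offset +
    replicate offset); intergenic and reference strains sit at surface zero.
    Column sums equal ``read_depth`` exactly.
    """
    known = set(truth["locus_id"]) | set(config.reference_genes)
    bad = {s.locus_id for s in pool if s.locus_id is not None} - known
    if bad:
        raise ValueError(f"pool contains genes without planted truth: {sorted(bad)[:5]}")
    rng = config.rng(3)
    barcodes = [s.barcode for s in pool]
    n = len(pool)

    # planted log2 surface per gene x condition (reference/intergenic = 0)
    coef_mat = truth.set_index("locus_id")[list(ep.COEF_NAMES)]
    surf = pd.DataFrame(
        coef_mat.to_numpy() @ ep.design_matrix().T,
        index=coef_mat.index,
        columns=[g.code for g in ep.GENOTYPE_ORDER],
    )
    # the full surface (f0 included) drives endpoint growth, so recovered
    # fitness in growth alone estimates f0 and IFEs estimate f(x) - f0
    locus_idx = np.array(
        [
            surf.index.get_loc(s.locus_id)
            if (s.locus_id in surf.index)
            else -1
            for s in pool
        ]
    )

    t0_w = np.power(2.0, rng.normal(0.0, config.t0_spread_log2, size=n))
    t0_w /= t0_w.sum()

    samples = [SampleMeta("T0", ALONE, 1, "T0")]
    counts: dict[str, np.ndarray] = {
        "T0": rng.multinomial(config.read_depth, t0_w)
    }
    for cond in ALL_CONDITIONS:
        f_gene = np.zeros(n)
        has_gene = locus_idx >= 0
        f_gene[has_gene] = surf[cond.code].to_numpy()[locus_idx[has_gene]]
        for rep in range(1, config.n_replicates + 1):
            rep_off_gene = rng.normal(0.0, config.replicate_noise_sd, size=len(surf))
            strain_off = rng.normal(0.0, config.strain_noise_sd, size=n)
            f = f_gene + strain_off
            f[has_gene] += rep_off_gene[locus_idx[has_gene]]
            w = t0_w * np.power(2.0, f)
            w /= w.sum()
            sid = f"{cond.label}_r{rep}"
            counts[sid] = rng.multinomial(config.read_depth, w)
            samples.append(SampleMeta(sid, cond, rep, "endpoint"))
    mat = pd.DataFrame(counts, index=barcodes).astype(int)
    mat.index.name = "barcode"
    return mat, samples


def simulate_cfu(
    config: SimConfig,
    coef: dict[str, float] | None = None,
    cfu_sd: float = 3e7,
) -> pd.DataFrame:
    """Replicate final CFU counts per composition from a planted growth surface.

    The default surface is additive: growing with any partner costs the focal
    species a fixed CFU decrement and no epistasis is planted.  Pass ``coef``
    (local-epistasis parameterisation, raw CFU scale) to plant synergy.
    """
    if coef is None:
        coef = {k: 0.0 for k in ep.COEF_NAMES}
        coef["f0"] = 5e8
        coef.update({f"beta_{p}": -4e7 for p in ("Gc", "Ha", "Pc")})
    rng = config.rng(4)
    surface = ep.reconstruct(coef)
    rows = []
    for cond in ALL_CONDITIONS:
        for rep in range(1, config.n_replicates + 1):
            rows.append(
                {
                    "condition": cond.label,
                    "replicate": rep,
                    "cfu": max(1.0, surface[cond.code] + rng.normal(0.0, cfu_sd)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recovery scoring


def _confusion(true_labels, called_labels, classes) -> dict:
    mat = {t: {c: 0 for c in classes} for t in classes}
    for t, c in zip(true_labels, called_labels):
        mat[t][c] += 1
    return mat


def score_recovery(
    truth: pd.DataFrame,
    ife_tab: pd.DataFrame | None = None,
    eps_res: pd.DataFrame | None = None,
    transitions: pd.DataFrame | None = None,
    se_mult: float = 5.0,
    alpha_eps: float = 0.01,
) -> dict:
    """Score a pipeline run against the planted truth.

    Returns a JSON-serialisable dict with, per stage: a significance/sign
    confusion matrix and precision/recall for interaction calls (recall
    restricted to planted effects at least ``se_mult`` analytic standard
    errors strong), epistatic-coefficient RMSE and detection recall, and a
    transition-status confusion matrix.
    """
    out: dict = {}
    if ife_tab is not None:
        merged = ife_tab.merge(truth, on="locus_id", how="inner", validate="m:1")
        if len(merged) != len(ife_tab):
            raise ValueError("IFE table contains loci absent from the truth table")
        planted = np.array(
            [r[f"ife_{r['condition']}"] for _, r in merged.iterrows()]
        )
        called = merged["significant"].to_numpy(bool)
        nonzero = planted != 0.0
        strong = np.abs(planted) >= se_mult * merged["se_ife"].to_numpy()
        tp_strong = int((called & strong).sum())
        out["ife"] = {
            "n_tests": int(len(merged)),
            "n_called": int(called.sum()),
            "recall_strong": tp_strong / int(strong.sum()) if strong.any() else None,
            "precision": (
                int((called & nonzero).sum()) / int(called.sum())
                if called.any()
                else None
            ),
            "sign_confusion": _confusion(
                np.where(nonzero, np.where(planted > 0, "positive", "negative"), "none"),
                merged["sign"],
                ("positive", "negative", "none"),
            ),
        }
    if eps_res is not None:
        merged = eps_res.merge(
            truth, on="locus_id", how="inner", suffixes=("", "_true"), validate="1:1"
        )
        if len(merged) == 0:
            raise ValueError("no shared loci between epistasis results and truth")
        errs, strong_det, strong_tot = [], 0, 0
        for _, r in merged.iterrows():
            sem = r["sem_phenotype"]
            for k in ep.COEF_NAMES:
                errs.append(r[k] - r[f"{k}_true"])
            for k in ep.EPS_NAMES:
                n_cond = 8 if k == "eps_GcHaPc" else 4
                se_k = sem * math.sqrt(n_cond)
                if abs(r[f"{k}_true"]) >= se_mult * se_k:
                    strong_tot += 1
                    if r[f"p_adj_{k}"] <= alpha_eps:
                        strong_det += 1
        out["epistasis"] = {
            "n_genes": int(len(merged)),
            "coefficient_rmse": float(np.sqrt(np.mean(np.square(errs)))),
            "eps_recall_strong": strong_det / strong_tot if strong_tot else None,
            "n_strong_eps": strong_tot,
        }
    if transitions is not None:
        expected = expected_transitions(truth)
        classes = ("maintained", "dropped", "emerging", "unclassified", "absent")
        conf: dict = {}
        for tr in ("2to3", "3to4"):
            e = expected[expected["transition"] == tr].set_index("locus_id")["status"]
            o = transitions[transitions["transition"] == tr].set_index("locus_id")[
                "status"
            ]
            genes = sorted(set(e.index) | set(o.index))
            conf[tr] = _confusion(
                [e.get(g, "absent") for g in genes],
                [o.get(g, "absent") for g in genes],
                classes,
            )
            conf[f"{tr}_agreement"] = (
                float(np.mean([e.get(g, "absent") == o.get(g, "absent") for g in genes]))
                if genes
                else None
            )
        out["transitions"] = conf
    return out
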