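"""End-to-end orchestration: run the staged analysis and write auditable artifacts.

Stage order is fitness -> interaction fitness effects -> transition set logic
-> epistasis (-> growth epistasis when a CFU table is supplied).  Every run
writes a manifest (config echo + hash, seed, package version, row counts per
output) and is deterministic: identical inputs and seed reproduce
byte-identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import epistasis as ep
from . import hoi, ife, simulate
from .fitness import (
    FitnessError,
    FitnessParams,
    drop_log,
    gene_fitness,
    replicate_qc,
    strain_fitness_table,
)
from .pool_io import PoolFormatError, read_poolcount, read_sample_meta

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    poolcount: str = "poolcount.tsv"
    metadata: str = "samples.tsv"
    cfu: str | None = None
    outdir: str = "interfit_out"
    fitness: FitnessParams = field(default_factory=FitnessParams)
    alpha_ife: float = 0.1
    var_alpha: float = 0.05
    alpha_eps: float = 0.01
    B: int = 7000
    seed: int = 0
    sign_aware_sets: bool = False
    chain_free_provenance: bool = False
    weighted_gene_fitness: bool = False
    log_cfu: bool = False
    conserved_only_epistasis: bool = False

    def __post_init__(self) -> None:
        for a in ("alpha_ife", "var_alpha", "alpha_eps"):
            if not (0 < getattr(self, a) < 1):
                raise ValueError(f"{a} must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "fitness" in d and isinstance(d["fitness"], dict):
            fp = dict(d["fitness"])
            if "reference_genes" in fp:
                fp["reference_genes"] = tuple(fp["reference_genes"])
            d["fitness"] = FitnessParams(**fp)
        return cls(**d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["fitness"]["reference_genes"] = list(d["fitness"]["reference_genes"])
        return d


def _write_tsv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, sep="\t", index=False, lineterminator="\n", float_format=_FLOAT_FMT)
    return len(df)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the artifact directory.

    On stage failure the partial outputs are retained next to a ``FAILED``
    marker naming the stage, and the exception propagates.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "row_counts": {},
        "stages": [],
    }
    stage = "fitness"
    try:
        pool, counts = read_poolcount(config.poolcount)
        samples = read_sample_meta(config.metadata)
        fp = config.fitness
        if config.weighted_gene_fitness:
            fp = FitnessParams(**{**asdict(fp), "weighted": True})
        strain_fit = strain_fitness_table(pool, counts, samples, fp)
        per_rep, summary = gene_fitness(strain_fit, pool, fp, counts, samples)
        qc = replicate_qc(per_rep)
        dropped = drop_log(pool, per_rep)
        manifest["row_counts"]["gene_fitness.tsv"] = _write_tsv(
            per_rep, out / "gene_fitness.tsv"
        )
        manifest["row_counts"]["gene_fitness_summary.tsv"] = _write_tsv(
            summary, out / "gene_fitness_summary.tsv"
        )
        manifest["row_counts"]["gene_drop_log.tsv"] = _write_tsv(
            dropped, out / "gene_drop_log.tsv"
        )
        _write_json(
            {
                "replicate_pearson": qc.to_dict("records"),
                "strains_retained": int(strain_fit["barcode"].nunique()),
            },
            out / "fitness_qc.json",
        )
        manifest["stages"].append(stage)

        stage = "ife"
        ife_params = ife.IFEParams(alpha_ife=config.alpha_ife, var_alpha=config.var_alpha)
        ife_tab = ife.ife_table(per_rep, ife_params)
        manifest["row_counts"]["ife.tsv"] = _write_tsv(ife_tab, out / "ife.tsv")
        _write_json(
            {
                "alpha_ife": config.alpha_ife,
                "var_alpha": config.var_alpha,
                "per_condition": ife.condition_counts(ife_tab).to_dict("records"),
            },
            out / "ife_summary.json",
        )
        manifest["stages"].append(stage)

        stage = "hoi"
        sets = hoi.build_sets(ife_tab)
        if config.sign_aware_sets:
            sets = {
                c: hoi.build_sets(ife_tab, "positive")[c]
                | hoi.build_sets(ife_tab, "negative")[c]
                for c in sets
            }
        t23 = hoi.classify_2to3(sets)
        t34 = hoi.classify_3to4(sets)
        transitions = pd.concat([t23, t34], ignore_index=True)
        prov, alluvial = hoi.trace_provenance(
            sets, chain=not config.chain_free_provenance
        )
        manifest["row_counts"]["transitions.tsv"] = _write_tsv(
            transitions, out / "transitions.tsv"
        )
        manifest["row_counts"]["provenance.tsv"] = _write_tsv(
            prov, out / "provenance.tsv"
        )
        manifest["row_counts"]["alluvial_counts.tsv"] = _write_tsv(
            alluvial, out / "alluvial_counts.tsv"
        )
        _write_json(
            {
                "set_cardinalities": hoi.set_cardinalities(sets),
                "fractions_2to3": hoi.condition_fractions(sets, "2to3").to_dict("records"),
                "fractions_3to4": hoi.condition_fractions(sets, "3to4").to_dict("records"),
                "provenance": hoi.provenance_percentages(prov),
            },
            out / "venn_counts.json",
        )
        manifest["stages"].append(stage)

        stage = "epistasis"
        genes = None
        if config.conserved_only_epistasis:
            genes = sorted(prov.loc[prov["origin"] == "from_2_species", "locus_id"])
        eps_res, eps_skip = ep.epistasis_table(
            summary,
            genes=genes,
            B=config.B,
            seed=config.seed,
            alpha_eps=config.alpha_eps,
        )
        manifest["row_counts"]["epistasis.tsv"] = _write_tsv(
            eps_res, out / "epistasis.tsv"
        )
        manifest["row_counts"]["epistasis_skipped.tsv"] = _write_tsv(
            eps_skip, out / "epistasis_skipped.tsv"
        )
        _write_json(
            {
                "B": config.B,
                "seed": config.seed,
                "scale": "sem",
                "alpha_eps": config.alpha_eps,
                "categories": {}
                if eps_res.empty
                else eps_res["category"].value_counts().to_dict(),
            },
            out / "epistasis_summary.json",
        )
        manifest["stages"].append(stage)

        if config.cfu:
            stage = "growth"
            cfu = pd.read_csv(config.cfu, sep="\t")
            growth = ep.growth_epistasis(
                cfu,
                B=config.B,
                seed=config.seed,
                alpha_eps=config.alpha_eps,
                log_scale=config.log_cfu,
            )
            _write_json(growth, out / "growth_epistasis.json")
            manifest["stages"].append(stage)
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise
    _write_json(manifest, out / "manifest.json")
    return out


def report(artifact_dir: str | Path) -> str:
    """Human-readable summary of a completed run; pure function of the directory."""
    out = Path(artifact_dir)
    lines = ["interfit run summary", "====================", ""]
    for name in ("ife_summary.json", "venn_counts.json", "epistasis_summary.json"):
        if not (out / name).exists():
            raise FileNotFoundError(f"missing stage output: {name}")

    ife_sum = json.loads((out / "ife_summary.json").read_text())
    lines.append(f"significant IFE counts (alpha={ife_sum['alpha_ife']}):")
    total_sig = 0
    for row in ife_sum["per_condition"]:
        n = row["n_positive"] + row["n_negative"]
        total_sig += n
        lines.append(
            f"  {row['condition']:<8} +{row['n_positive']:<4} -{row['n_negative']:<4} "
            f"(of {row['n_tested']} tested)"
        )
    lines.append(f"  total significant IFEs: {total_sig}")
    lines.append("")

    venn = json.loads((out / "venn_counts.json").read_text())
    trans = pd.read_csv(out / "transitions.tsv", sep="\t") if (
        out / "transitions.tsv"
    ).exists() else pd.DataFrame(columns=["transition", "status"])
    for tr in ("2to3", "3to4"):
        sub = trans[trans["transition"] == tr]
        cnt = sub["status"].value_counts().to_dict()
        lines.append(
            f"transition {tr}: "
            + ", ".join(f"{k}={cnt.get(k, 0)}" for k in ("maintained", "dropped", "emerging", "unclassified"))
        )
    lines.append("")
    lines.append("4-species provenance:")
    for origin, rec in venn["provenance"].items():
        if rec["fraction"] is None:
            lines.append(f"  {origin}: 0/0")
        else:
            lines.append(
                f"  {origin}: {rec['count']}/{rec['total']} "
                f"({rec['percent']}%, exact {rec['fraction']:.4f})"
            )
    lines.append("")

    eps_sum = json.loads((out / "epistasis_summary.json").read_text())
    lines.append(
        f"epistasis categories (B={eps_sum['B']}, alpha={eps_sum['alpha_eps']}):"
    )
    for cat in ("additive", "eps3_only", "eps2_only", "eps2_and_eps3"):
        lines.append(f"  {cat}: {eps_sum['categories'].get(cat, 0)}")
    if (out / "growth_epistasis.json").exists():
        growth = json.loads((out / "growth_epistasis.json").read_text())
        lines.append("")
        lines.append(
            "community growth: "
            + ("additive (predictable from 2-species growth)" if growth["additive_growth"] else f"non-additive ({growth['category']})")
        )
    return "\n".join(lines) + "\n"
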