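"""Strain filtering, fitness computation and replicate QC for pooled insertion libraries.

Per-strain fitness is the log2 change in a strain's relative abundance between
the pre-growth library aliquot (T0) and the endpoint sample, with a small
pseudocount guarding zero counts:

    fitness = log2((n_end + pc) / N_end) - log2((n_T0 + pc) / N_T0)

where N_* are the total read counts of the full pool in each sample, so the
statistic is compositional (invariant under sequencing-depth changes).  Raw
values are then re-centred per sample on a set of reference genes whose
mutants are expected to be neutral in every condition; after normalisation
the reference strains' mean fitness is exactly zero in every sample.

Gene fitness per condition and replicate is the unweighted mean of the gene's
retained strains.  Strains enter a condition only if they are gene-assigned,
centrally inserted (10-90% of the gene body by default) and sufficiently
covered in every T0 sample relevant to that condition.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pool_io import ALONE, ConditionCode, InsertionStrain, SampleMeta

DEFAULT_REFERENCE_GENES = ("glgP", "acnA", "modE", "leuA")


@dataclass
class FitnessParams:
    """Tunable knobs of the fitness stage.

    t0_min: minimum T0 reads per strain in every relevant T0 sample.
    central_low/high: retained window of within-gene insertion position.
    pseudocount: additive count guard in the log-ratio.
    reference_genes: loci whose strains define the per-sample zero point.
    weighted: weight strains by T0 counts in the gene mean (off by default;
        the plain average is the documented behaviour).
    """

    t0_min: int = 3
    central_low: float = 0.10
    central_high: float = 0.90
    pseudocount: float = 0.5
    reference_genes: tuple[str, ...] = DEFAULT_REFERENCE_GENES
    weighted: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.central_low < self.central_high <= 1):
            raise ValueError("require 0 <= central_low < central_high <= 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.t0_min < 0:
            raise ValueError("t0_min must be non-negative")


class FitnessError(RuntimeError):
    """Raised when an assay is uninformative (no usable strains or references)."""


def t0_samples_for(
    condition: ConditionCode, samples: Sequence[SampleMeta]
) -> list[SampleMeta]:
    """T0 samples relevant to a condition: condition-specific T0s when present,
    otherwise every T0 in the experiment (shared-T0 convention)."""
    t0 = [s for s in samples if s.role == "T0"]
    if not t0:
        raise FitnessError("no T0 sample in metadata")
    matched = [s for s in t0 if s.condition == condition]
    return matched or t0


def filter_strains(
    pool: Sequence[InsertionStrain],
    counts: pd.DataFrame,
    samples: Sequence[SampleMeta],
    params: FitnessParams,
) -> dict[ConditionCode, set[str]]:
    """Retained gene-assigned strains per condition.

    A strain is retained for a condition iff it is gene-assigned, centrally
    inserted, and its T0 count reaches ``t0_min`` in every T0 sample relevant
    to that condition.  Intergenic strains are never retained here (they have
    no gene) but still contribute to per-sample totals elsewhere.
    """
    conditions = sorted({s.condition for s in samples if s.role == "endpoint"})
    central = {
        s.barcode
        for s in pool
        if s.locus_id is not None
        and params.central_low <= s.gene_fraction <= params.central_high
    }
    out: dict[ConditionCode, set[str]] = {}
    for cond in conditions:
        t0s = t0_samples_for(cond, samples)
        ok = counts[[s.sample_id for s in t0s]].ge(params.t0_min).all(axis=1)
        retained = central & set(ok.index[ok])
        if not retained:
            raise FitnessError(
                f"condition {cond.label}: no strain passes the T0/centrality filters"
            )
        out[cond] = retained
    return out


def strain_fitness_raw(
    t0_count: float,
    end_count: float,
    t0_total: float,
    end_total: float,
    pseudocount: float = 0.5,
) -> float:
    """Raw log2 relative-abundance change of one strain between T0 and endpoint."""
    if t0_count < 0 or end_count < 0:
        raise ValueError("counts must be non-negative")
    if t0_total <= 0 or end_total <= 0:
        raise ValueError("totals must be positive")
    return float(
        np.log2((end_count + pseudocount) / end_total)
        - np.log2((t0_count + pseudocount) / t0_total)
    )


def normalize_fitness(values: pd.Series, reference_barcodes: set[str]) -> pd.Series:
    """Subtract the mean raw fitness of the reference strains from every strain.

    Location-only: differences between strains within a sample are untouched.
    """
    refs = values.index.intersection(list(reference_barcodes))
    if len(refs) == 0:
        raise FitnessError(
            "all reference strains were filtered out; configure a different "
            "reference gene set"
        )
    return values - values.loc[refs].mean()


def strain_fitness_table(
    pool: Sequence[InsertionStrain],
    counts: pd.DataFrame,
    samples: Sequence[SampleMeta],
    params: FitnessParams | None = None,
) -> pd.DataFrame:
    """Normalized per-strain fitness for every retained strain and endpoint sample.

    Returns a long table (barcode, locus_id, condition, replicate, value).
    Totals are the full-pool column sums (intergenic strains included), taken
    before filtering.
    """
    params = params or FitnessParams()
    retained = filter_strains(pool, counts, samples, params)
    locus_of = {s.barcode: s.locus_id for s in pool}
    ref_barcodes = {
        s.barcode for s in pool if s.locus_id in set(params.reference_genes)
    }
    totals = counts.sum(axis=0)

    rows: list[pd.DataFrame] = []
    for smp in samples:
        if smp.role != "endpoint":
            continue
        keep = sorted(retained[smp.condition])
        t0s = t0_samples_for(smp.condition, samples)
        # prefer the replicate-matched T0 when per-replicate T0s exist
        rep_match = [s for s in t0s if s.replicate == smp.replicate]
        t0s = rep_match or t0s
        t0_ids = [s.sample_id for s in t0s]
        t0_counts = counts[t0_ids].sum(axis=1)
        t0_total = float(totals[t0_ids].sum())
        end_total = float(totals[smp.sample_id])
        raw = np.log2(
            (counts[smp.sample_id] + params.pseudocount) / end_total
        ) - np.log2((t0_counts + params.pseudocount) / t0_total)
        refs_here = ref_barcodes & retained[smp.condition]
        norm = normalize_fitness(raw, refs_here)
        sub = norm.loc[keep]
        rows.append(
            pd.DataFrame(
                {
                    "barcode": sub.index,
                    "locus_id": [locus_of[b] for b in sub.index],
                    "condition": smp.condition.label,
                    "replicate": smp.replicate,
                    "value": sub.to_numpy(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def gene_fitness(
    strain_fit: pd.DataFrame,
    pool: Sequence[InsertionStrain] | None = None,
    params: FitnessParams | None = None,
    counts: pd.DataFrame | None = None,
    samples: Sequence[SampleMeta] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate strain fitness to genes.

    Returns ``(per_replicate, summary)``:
      * per_replicate — locus_id, condition, replicate, value, n_strains
        (value = unweighted mean over the gene's retained strains);
      * summary — locus_id, condition, mean, sd (n-1 denominator across
        replicates), n_replicates, n_strains.
    """
    params = params or FitnessParams()
    if params.weighted and counts is not None and samples is not None:
        t0_ids = [s.sample_id for s in samples if s.role == "T0"]
        w = counts[t0_ids].sum(axis=1).astype(float)
        sf = strain_fit.assign(_w=strain_fit["barcode"].map(w))
        per_rep = (
            sf.groupby(["locus_id", "condition", "replicate"])
            .apply(
                lambda g: pd.Series(
                    {
                        "value": np.average(g["value"], weights=g["_w"]),
                        "n_strains": len(g),
                    }
                ),
                include_groups=False,
            )
            .reset_index()
        )
    else:
        per_rep = (
            strain_fit.groupby(["locus_id", "condition", "replicate"])["value"]
            .agg(value="mean", n_strains="size")
            .reset_index()
        )
    per_rep["n_strains"] = per_rep["n_strains"].astype(int)

    summary = (
        per_rep.groupby(["locus_id", "condition"])
        .agg(
            mean=("value", "mean"),
            sd=("value", lambda v: v.std(ddof=1)),
            n_replicates=("value", "size"),
            n_strains=("n_strains", "min"),
        )
        .reset_index()
    )
    return per_rep, summary


def drop_log(
    pool: Sequence[InsertionStrain], per_rep: pd.DataFrame
) -> pd.DataFrame:
    """Genes absent from a condition's fitness table (zero retained strains)."""
    genes = sorted({s.locus_id for s in pool if s.locus_id is not None})
    conds = sorted(per_rep["condition"].unique())
    present = set(zip(per_rep["locus_id"], per_rep["condition"]))
    rows = [
        {"locus_id": g, "condition": c, "reason": "no retained strain"}
        for g in genes
        for c in conds
        if (g, c) not in present
    ]
    return pd.DataFrame(rows, columns=["locus_id", "condition", "reason"])


def replicate_qc(per_rep: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation of gene fitness between replicates, per condition.

    Purely diagnostic; never used to drop data.  Pairs with fewer than two
    shared genes report a null correlation.
    """
    rows = []
    for cond, sub in per_rep.groupby("condition"):
        wide = sub.pivot(index="locus_id", columns="replicate", values="value")
        for r1, r2 in itertools.combinations(sorted(wide.columns), 2):
            pair = wide[[r1, r2]].dropna()
            if len(pair) < 2 or pair[r1].std() == 0 or pair[r2].std() == 0:
                r = np.nan
            else:
                r = float(stats.pearsonr(pair[r1], pair[r2]).statistic)
            rows.append(
                {
                    "condition": cond,
                    "replicate_a": r1,
                    "replicate_b": r2,
                    "pearson_r": r,
                    "n_genes": len(pair),
                }
            )
    return pd.DataFrame(rows, columns=["condition", "replicate_a", "replicate_b", "pearson_r", "n_genes"])
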