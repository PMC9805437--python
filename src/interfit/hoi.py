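"""Set algebra over per-condition interaction calls across community complexity.

Starting from the per-condition sets of genes with significant interaction
fitness effects, this module classifies how interaction-associated mutants
behave as community complexity grows:

* 2 -> 3 species: a 2-species interaction gene is *maintained* if it is also
  significant in at least one 3-species condition that contains one of its
  2-species partners, *dropped* if it appears in no 3-species condition, and
  *unclassified* if it reappears only in unrelated 3-species conditions (the
  two published definitions leave this gap; it is reported, not hidden).
  Genes significant only at the 3-species level are *emerging*.
* 3 -> 4 species: maintained iff also significant in the single 4-species
  condition, else dropped; genes significant only at the 4-species level are
  emerging.  A 4-species gene whose only other occurrence is at the 2-species
  level (skipping 3-species entirely) fits neither published definition and
  is reported as unclassified.
* Provenance of the 4-species set: *from_2_species* requires a full
  conservation chain (significant at 2-, 3- and 4-species levels),
  *from_3_species* a 3-species occurrence without such a chain, and
  *four_species_specific* otherwise.

Dropped and emerging genes at any transition are the mechanistic face of
higher-order interactions: the extra species removes an interaction or brings
about a new one.
"""

from __future__ import annotations

import pandas as pd

from .pool_io import ConditionCode, INTERACTIVE_CONDITIONS

TWO_SPECIES = tuple(c.label for c in INTERACTIVE_CONDITIONS if c.level == 2)
THREE_SPECIES = tuple(c.label for c in INTERACTIVE_CONDITIONS if c.level == 3)
FOUR_SPECIES = next(c.label for c in INTERACTIVE_CONDITIONS if c.level == 4)


def build_sets(
    ife_tab: pd.DataFrame, sign: str | None = None
) -> dict[str, set[str]]:
    """Per-condition sets of significant interaction genes.

    ``sign`` optionally restricts membership to "positive" or "negative"
    calls; by default a gene is in a set regardless of the sign of its IFE.
    """
    sets: dict[str, set[str]] = {c.label: set() for c in INTERACTIVE_CONDITIONS}
    if ife_tab.empty:
        return sets
    sig = ife_tab[ife_tab["significant"].astype(bool)]
    if sign is not None:
        sig = sig[sig["sign"] == sign]
    for cond, grp in sig.groupby("condition"):
        if cond in sets:
            sets[cond] |= set(grp["locus_id"])
    return sets


def set_cardinalities(sets: dict[str, set[str]]) -> dict[str, int]:
    return {cond: len(genes) for cond, genes in sets.items()}


def _partners(label: str) -> frozenset[str]:
    return ConditionCode.from_string(label).partners


def _conditions_of(gene: str, sets: dict[str, set[str]], labels) -> list[str]:
    return [c for c in labels if gene in sets[c]]


def classify_2to3(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Transition statuses of interaction genes between 2- and 3-species levels."""
    rows = []
    genes2 = set().union(*(sets[c] for c in TWO_SPECIES))
    genes3 = set().union(*(sets[c] for c in THREE_SPECIES))
    for gene in sorted(genes2):
        src = _conditions_of(gene, sets, TWO_SPECIES)
        tgt = _conditions_of(gene, sets, THREE_SPECIES)
        src_partners = set().union(*(_partners(c) for c in src))
        associated = [c for c in tgt if _partners(c) & src_partners]
        if associated:
            status = "maintained"
        elif not tgt:
            status = "dropped"
        else:
            status = "unclassified"  # reappears only in unrelated 3-species conditions
        rows.append(
            {
                "locus_id": gene,
                "transition": "2to3",
                "status": status,
                "source_conditions": ",".join(src),
                "target_conditions": ",".join(tgt),
            }
        )
    for gene in sorted(genes3 - genes2):
        rows.append(
            {
                "locus_id": gene,
                "transition": "2to3",
                "status": "emerging",
                "source_conditions": "",
                "target_conditions": ",".join(_conditions_of(gene, sets, THREE_SPECIES)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["locus_id", "transition", "status", "source_conditions", "target_conditions"],
    )


def classify_3to4(sets: dict[str, set[str]]) -> pd.DataFrame:
    """Transition statuses of interaction genes between the 3- and 4-species levels."""
    rows = []
    genes2 = set().union(*(sets[c] for c in TWO_SPECIES))
    genes3 = set().union(*(sets[c] for c in THREE_SPECIES))
    genes4 = sets[FOUR_SPECIES]
    for gene in sorted(genes3):
        status = "maintained" if gene in genes4 else "dropped"
        rows.append(
            {
                "locus_id": gene,
                "transition": "3to4",
                "status": status,
                "source_conditions": ",".join(_conditions_of(gene, sets, THREE_SPECIES)),
                "target_conditions": FOUR_SPECIES if gene in genes4 else "",
            }
        )
    for gene in sorted(genes4 - genes3):
        # a 2-species occurrence without any 3-species link fits neither
        # definition: not emerging (seen before), not maintained (no 3-species)
        status = "unclassified" if gene in genes2 else "emerging"
        rows.append(
            {
                "locus_id": gene,
                "transition": "3to4",
                "status": status,
                "source_conditions": ",".join(_conditions_of(gene, sets, TWO_SPECIES)),
                "target_conditions": FOUR_SPECIES,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["locus_id", "transition", "status", "source_conditions", "target_conditions"],
    )


def condition_fractions(sets: dict[str, set[str]], transition: str) -> pd.DataFrame:
    """Per-condition maintained/dropped/emerging fractions.

    For ``2to3``: per 2-species condition, the fraction of its genes maintained
    in at least one associated 3-species condition; per 3-species condition,
    the fraction of its genes conserved from at least one associated 2-species
    condition versus emerging.  For ``3to4``: per 3-species condition, the
    fraction of its genes present in the 4-species set.  Empty denominators
    yield a null fraction.
    """
    rows = []
    if transition == "2to3":
        for c2 in TWO_SPECIES:
            members = sets[c2]
            assoc = [c3 for c3 in THREE_SPECIES if _partners(c2) <= _partners(c3)]
            kept = {g for g in members if any(g in sets[c3] for c3 in assoc)}
            n = len(members)
            rows.append(
                {
                    "condition": c2,
                    "metric": "maintained_in_associated_3species",
                    "numerator": len(kept),
                    "denominator": n,
                    "fraction": len(kept) / n if n else None,
                }
            )
        for c3 in THREE_SPECIES:
            members = sets[c3]
            assoc = [c2 for c2 in TWO_SPECIES if _partners(c2) <= _partners(c3)]
            kept = {g for g in members if any(g in sets[c2] for c2 in assoc)}
            n = len(members)
            rows.append(
                {
                    "condition": c3,
                    "metric": "maintained_from_associated_2species",
                    "numerator": len(kept),
                    "denominator": n,
                    "fraction": len(kept) / n if n else None,
                }
            )
    elif transition == "3to4":
        for c3 in THREE_SPECIES:
            members = sets[c3]
            kept = members & sets[FOUR_SPECIES]
            n = len(members)
            rows.append(
                {
                    "condition": c3,
                    "metric": "maintained_in_4species",
                    "numerator": len(kept),
                    "denominator": n,
                    "fraction": len(kept) / n if n else None,
                }
            )
    else:
        raise ValueError("transition must be '2to3' or '3to4'")
    return pd.DataFrame(
        rows, columns=["condition", "metric", "numerator", "denominator", "fraction"]
    )


def trace_provenance(
    sets: dict[str, set[str]], chain: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Origin of each 4-species interaction gene, plus level-by-level flow counts.

    With ``chain=True`` (default) the *from_2_species* label requires the full
    2 -> 3 -> 4 conservation chain; with ``chain=False`` any 2-species
    occurrence suffices.  The three origins partition the 4-species set.
    """
    genes2 = set().union(*(sets[c] for c in TWO_SPECIES))
    genes3 = set().union(*(sets[c] for c in THREE_SPECIES))
    genes4 = sets[FOUR_SPECIES]
    rows = []
    for gene in sorted(genes4):
        in2, in3 = gene in genes2, gene in genes3
        if chain:
            from2 = in2 and in3
        else:
            from2 = in2
        if from2:
            origin = "from_2_species"
        elif in3:
            origin = "from_3_species"
        else:
            origin = "four_species_specific"
        rows.append({"locus_id": gene, "origin": origin})
    prov = pd.DataFrame(rows, columns=["locus_id", "origin"])

    all_genes = genes2 | genes3 | genes4
    flow_rows = [
        {"level": "2_species", "category": "total", "count": len(genes2)},
        {"level": "3_species", "category": "total", "count": len(genes3)},
        {"level": "4_species", "category": "total", "count": len(genes4)},
        {"level": "any", "category": "total_unique", "count": len(all_genes)},
        {
            "level": "2to3",
            "category": "maintained",
            "count": len(genes2 & genes3),
        },
        {
            "level": "3to4",
            "category": "maintained",
            "count": len(genes3 & genes4),
        },
        {
            "level": "all_levels",
            "category": "conserved_chain",
            "count": len(genes2 & genes3 & genes4),
        },
    ]
    for origin in ("from_2_species", "from_3_species", "four_species_specific"):
        flow_rows.append(
            {
                "level": "4_species",
                "category": origin,
                "count": int((prov["origin"] == origin).sum()),
            }
        )
    return prov, pd.DataFrame(flow_rows, columns=["level", "category", "count"])


def provenance_percentages(prov: pd.DataFrame) -> dict[str, dict]:
    """Exact fractions and half-away-from-zero integer percentages per origin."""
    n = len(prov)
    out = {}
    for origin in ("from_2_species", "from_3_species", "four_species_specific"):
        k = int((prov["origin"] == origin).sum())
        frac = k / n if n else None
        out[origin] = {
            "count": k,
            "total": n,
            "fraction": frac,
            "percent": None if frac is None else int(frac * 100 + 0.5),
        }
    return out
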