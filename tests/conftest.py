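import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from interfit import fitness as fit
from interfit import ife
from interfit import simulate as sim

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_run():
    """A 40-gene simulated assay pushed through fitness and IFE stages.

    Session-scoped: several test modules read from it without mutating it.
    """
    cfg = sim.SimConfig(n_genes=40, read_depth=200_000, seed=7)
    pool = sim.generate_pool(cfg)
    truth = sim.generate_truth(cfg)
    counts, samples = sim.simulate_counts(pool, truth, cfg)
    strain_fit = fit.strain_fitness_table(pool, counts, samples)
    per_rep, summary = fit.gene_fitness(strain_fit)
    ife_tab = ife.ife_table(per_rep)
    return {
        "cfg": cfg,
        "pool": pool,
        "truth": truth,
        "counts": counts,
        "samples": samples,
        "strain_fit": strain_fit,
        "per_rep": per_rep,
        "summary": summary,
        "ife_tab": ife_tab,
    }


@pytest.fixture(scope="session")
def hoi_fixture():
    """Hand-built significance sets for 12 genes covering every transition pattern.

    Expected statuses were enumerated by hand from the classification rules.
    """
    sets = {
        "Gc": {"gE", "gH", "gI", "gJ", "gL"},
        "Ha": {"gA", "gB", "gH", "gL"},
        "Pc": {"gG", "gH"},
        "GcHa": {"gA", "gG", "gI", "gL"},
        "GcPc": {"gE", "gI", "gK"},
        "HaPc": {"gC", "gF", "gL"},
        "GcHaPc": {"gD", "gE", "gF", "gI", "gJ", "gL"},
    }
    expected_2to3 = {
        "gA": "maintained",
        "gB": "dropped",
        "gC": "emerging",
        "gE": "maintained",
        "gF": "emerging",
        "gG": "unclassified",  # reappears only in a 3-species condition without Pc
        "gH": "dropped",
        "gI": "maintained",
        "gJ": "dropped",
        "gK": "emerging",
        "gL": "maintained",
    }
    expected_3to4 = {
        "gA": "dropped",
        "gC": "dropped",
        "gD": "emerging",
        "gE": "maintained",
        "gF": "maintained",
        "gG": "dropped",
        "gI": "maintained",
        "gJ": "unclassified",  # 2-species hit reappearing only at 4-species
        "gK": "dropped",
        "gL": "maintained",
    }
    expected_origin = {
        "gD": "four_species_specific",
        "gE": "from_2_species",
        "gF": "from_3_species",
        "gI": "from_2_species",
        "gJ": "four_species_specific",  # 2-species hit but no 3-species link
        "gL": "from_2_species",
    }
    return sets, expected_2to3, expected_3to4, expected_origin
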