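"""Shared fixtures: one small synthetic cohort and a model trained on it.

The small cohort (3 entities x 40 samples, 2,000 probes, 100 planted
informative) is the workhorse of the unit tests; the full-size reference
cohorts live in the acceptance tests that need them.
"""

import numpy as np
import pandas as pd
import pytest

import purityforest as pf

SMALL_CFG = pf.SimulationConfig(
    n_probes=2000,
    n_informative=100,
    n_entity_probes=50,
    lump_panel_size=20,
    samples_per_entity=40,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    return pf.simulate_cohort(SMALL_CFG)


@pytest.fixture(scope="session")
def small_model(small_cohort):
    return pf.train_purity_model(
        small_cohort.betas, small_cohort.truth, pf.TrainConfig(seed=11)
    )


@pytest.fixture()
def tiny_betas():
    """2 probes x 2 samples, the minimal valid beta matrix."""
    return pf.BetaMatrix(
        pd.DataFrame(
            [[0.1, 0.9], [0.5, 0.3]],
            index=["cg001", "cg002"],
            columns=["s1", "s2"],
        )
    )


@pytest.fixture()
def toy_annotation():
    """10 hand-written probes: 4 Body, 3 promoter (TSS200/TSS1500), 5 Island."""
    rows = {
        "cg00": (frozenset({"TP53"}), frozenset({"Body"}), "Island"),
        "cg01": (frozenset({"RB1"}), frozenset({"Body"}), "OpenSea"),
        "cg02": (frozenset({"MYC"}), frozenset({"Body"}), "Island"),
        "cg03": (frozenset({"GENE1"}), frozenset({"Body", "TSS200"}), "N_Shore"),
        "cg04": (frozenset({"GENE2"}), frozenset({"TSS200"}), "Island"),
        "cg05": (frozenset({"GENE3"}), frozenset({"TSS1500"}), "Island"),
        "cg06": (frozenset(), frozenset(), "Island"),
        "cg07": (frozenset({"GENE4"}), frozenset({"5'UTR"}), "S_Shelf"),
        "cg08": (frozenset({"GENE5"}), frozenset({"3'UTR"}), "OpenSea"),
        "cg09": (frozenset(), frozenset(), "OpenSea"),
    }
    table = pd.DataFrame(
        {
            "gene_symbols": [v[0] for v in rows.values()],
            "gene_region": [v[1] for v in rows.values()],
            "island_relation": [v[2] for v in rows.values()],
        },
        index=pd.Index(rows.keys(), name="probe_id"),
    )
    return pf.ProbeAnnotation(table)


def make_purity(values, source="SYNTHETIC_TRUTH", ids=None, group=None):
    ids = ids or [f"s{i}" for i in range(len(values))]
    g = None if group is None else pd.Series(group, index=ids)
    return pf.PurityTable(purity=pd.Series(values, index=ids, dtype=float), source=source, group=g)
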