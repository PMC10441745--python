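import numpy as np
import pytest

from exocerna import cerna, diffexpr
from exocerna import synthetic_data as sd


@pytest.fixture(scope="session")
def small_config() -> sd.SimulationConfig:
    return sd.SimulationConfig(
        n_lncrna=30, n_mirna=20, n_mrna=50, n_triplets=3, seed=7
    )


@pytest.fixture(scope="session")
def small_data(small_config) -> sd.SimulatedData:
    return sd.generate_bundle(small_config)


@pytest.fixture(scope="session")
def small_de_sets(small_data):
    return diffexpr.de_sets(diffexpr.compute_de(small_data.bundle))


@pytest.fixture()
def toy_instance():
    """Hand-traceable ceRNA instance.

    Up-miRNAs {m1,m2,m3}; down-lncRNAs {L1,L2}; down-mRNAs {G1,G2,G3};
    expected final network: nodes {m1,L1,G1,G2}, edges (L1,m1),(m1,G1),(m1,G2).
    """
    de_sets = {
        "lncRNA": {"up": set(), "down": {"L1", "L2"}},
        "miRNA": {"up": {"m1", "m2", "m3"}, "down": set()},
        "mRNA": {"up": set(), "down": {"G1", "G2", "G3"}},
    }
    tables = sd.TargetTables(
        mir_to_lnc=frozenset({("m1", "L1"), ("m2", "L2"), ("m3", "Lx")}),
        mir_to_mrna=frozenset(
            {("m1", "G1"), ("m1", "G2"), ("m2", "G9"), ("m3", "G3")}
        ),
    )
    return de_sets, tables


def random_cerna_instance(rng: np.random.Generator, max_features: int = 30):
    """Random DE sets and target tables for oracle-equivalence trials."""
    n_l = rng.integers(2, max_features + 1)
    n_m = rng.integers(2, max_features + 1)
    n_g = rng.integers(2, max_features + 1)
    lncs = [f"L{i}" for i in range(n_l)]
    mirs = [f"m{i}" for i in range(n_m)]
    genes = [f"G{i}" for i in range(n_g)]

    def pick(items):
        mask = rng.random(len(items)) < rng.uniform(0.2, 0.8)
        chosen = [x for x, keep in zip(items, mask) if keep]
        split = rng.random(len(chosen)) < 0.5
        up = {x for x, u in zip(chosen, split) if u}
        return up, set(chosen) - up

    l_up, l_down = pick(lncs)
    m_up, m_down = pick(mirs)
    g_up, g_down = pick(genes)
    de_sets = {
        "lncRNA": {"up": l_up, "down": l_down},
        "miRNA": {"up": m_up, "down": m_down},
        "mRNA": {"up": g_up, "down": g_down},
    }
    density = rng.uniform(0.05, 0.4)
    t_lnc = {
        (m, l) for m in mirs for l in lncs if rng.random() < density
    }
    t_mrna = {
        (m, g) for m in mirs for g in genes if rng.random() < density
    }
    return de_sets, sd.TargetTables(frozenset(t_lnc), frozenset(t_mrna))


def brute_force_network(de_sets, tables: sd.TargetTables, polarity: str):
    """Oracle: enumerate all candidate (lncRNA, miRNA, mRNA) triples directly."""
    mir_dir = "up" if polarity == cerna.UP_MIR else "down"
    partner_dir = "down" if polarity == cerna.UP_MIR else "up"
    mirs = de_sets["miRNA"][mir_dir]
    lncs = de_sets["lncRNA"][partner_dir]
    genes = de_sets["mRNA"][partner_dir]
    t_lnc = set(tables.mir_to_lnc)
    t_mrna = set(tables.mir_to_mrna)
    triples = {
        (l, m, g)
        for m in mirs
        for l in lncs
        for g in genes
        if (m, l) in t_lnc and (m, g) in t_mrna
    }
    nodes = {x for t in triples for x in t}
    edges = {frozenset((l, m)) for l, m, _ in triples} | {
        frozenset((m, g)) for _, m, g in triples
    }
    return triples, nodes, edges
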