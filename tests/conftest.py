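import numpy as np
import pandas as pd
import pytest

import phylospectra as ps


@pytest.fixture(scope="session")
def small_community():
    return ps.simulate_community(10, 8, log_sd=1.0, seed=11)


@pytest.fixture(scope="session")
def small_probes(small_community):
    return ps.simulate_probe_table(small_community, probes_per_taxon=8, seed=12)


@pytest.fixture(scope="session")
def small_eotus(small_community, small_probes):
    return ps.discover_eotus(small_probes, reference=small_community.reference(), seed=13)


def make_eotu_table(n_eotus, samples, hybscore, n_families=None, present=None, rng=None):
    """Hand-assembled EOTUTable for statistics tests (no discovery involved)."""
    ids = [f"e{i:03d}" for i in range(n_eotus)]
    members = {e: [f"{e}_p{j}" for j in range(3)] for e in ids}
    if n_families is None:
        n_families = n_eotus
    lineages = {}
    for i, e in enumerate(ids):
        f = i % n_families
        lineages[e] = [
            (name, 1.0)
            for name in ("Dom", f"Phy{f}", f"Cls{f}", f"Ord{f}", f"Fam{f}", f"Gen{i}", f"Sp{i}")
        ]
    hyb = pd.DataFrame(np.asarray(hybscore, float), index=ids, columns=samples)
    if present is None:
        pres = pd.DataFrame(True, index=ids, columns=samples)
    else:
        pres = pd.DataFrame(np.asarray(present, bool), index=ids, columns=samples)
    return ps.EOTUTable(members, lineages, hyb, pres)
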