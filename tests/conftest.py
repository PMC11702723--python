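import numpy as np
import pandas as pd
import pytest

from phgap import pre_forward as pf
from phgap import synthetic_data as sd
from phgap.structures import Structure


def make_structure(rows, n_models=1):
    """rows: (chain, resnum, resname, atom, element, (x, y, z))."""
    records = []
    for m in range(n_models):
        for chain, resnum, resname, atom, element, xyz in rows:
            records.append((m, chain, resnum, resname, atom, element, *xyz))
    return Structure(pd.DataFrame(
        records, columns=["model", "chain", "resnum", "resname", "atom",
                          "element", "x", "y", "z"]))


@pytest.fixture(scope="session")
def two_pose_bundle():
    """Two-pose probe/reporter ensembles plus exact forward profiles.

    Session-scoped: the forward computation (label placement + rate
    averaging over 10 models x 200 candidates) is the expensive part and is
    reused by the PRE, synthetic-data and acceptance tests.
    """
    pose_a, pose_b, site = sd.make_two_pose_ensemble(seed=42, n_models=10)
    observed, prof_a, prof_b = sd.synth_pre_dataset(
        pose_a, pose_b, site, rho_major=0.9, noise_sd=0.0, seed=42,
        n_label_candidates=200)
    return {
        "pose_a": pose_a, "pose_b": pose_b, "site": site,
        "observed": observed, "prof_a": prof_a, "prof_b": prof_b,
        "params": pf.RelaxationParams(), "r2": 100.0,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
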