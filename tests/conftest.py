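import numpy as np
import pandas as pd
import pytest

import jointfactor as jf


@pytest.fixture(scope="session")
def catalog():
    return jf.default_catalog()


@pytest.fixture(scope="session")
def toy_catalog():
    """Six bilateral joint types, no midline: 12 joints."""
    joints = []
    for rank, jt in enumerate(["tmj", "elbow", "wrist", "hip", "knee", "ankle"]):
        joints.append(jf.Joint(f"{jt}_l", f"Left {jt}", "left", jt, rank))
        joints.append(jf.Joint(f"{jt}_r", f"Right {jt}", "right", jt, rank))
    return jf.JointCatalog(joints)


@pytest.fixture(scope="session")
def toy_sim():
    """Planted toy cohort (k1=6, k2=3) with follow-up and ground truth."""
    return jf.simulate_cohort("toy", 300, seed=11, noise_rate=0.02)


@pytest.fixture(scope="session")
def toy_fit(toy_sim):
    cohort, truth, planted = toy_sim
    res = jf.MultilayerNMF.from_cohort(cohort, k1=6, k2=3).fit(seed=0)
    return cohort, truth, planted, res


@pytest.fixture(scope="session")
def homunculus_sim():
    """One homunculus synthetic cohort (71 joints, k1=19, k2=7, n=600)."""
    return jf.simulate_cohort("homunculus", 600, seed=7, noise_rate=0.02)


@pytest.fixture(scope="session")
def homunculus_fit(homunculus_sim):
    cohort, truth, planted = homunculus_sim
    res = jf.MultilayerNMF.from_cohort(cohort).fit(seed=0)
    return cohort, truth, planted, res


def small_matrix(active: dict[str, list[str]], joints: list[str]) -> pd.DataFrame:
    """Binary joints × patients matrix from {patient: active joint list}."""
    X = pd.DataFrame(0, index=joints, columns=list(active), dtype=np.int8)
    for p, js in active.items():
        X.loc[js, p] = 1
    return X
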