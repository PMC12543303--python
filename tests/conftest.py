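import numpy as np
import pytest

from fixelcouple.connectome_model import (
    AtlasDefinition,
    ConnectomeMatrix,
    SubjectRecord,
)
from fixelcouple.synthetic_cohort import CohortGenerator, GeneratorConfig


def make_atlas(n_nodes: int, dmn_nodes) -> AtlasDefinition:
    """Small hand-built atlas with an explicit DMN subset."""
    dmn = set(dmn_nodes)
    return AtlasDefinition(
        labels=tuple(f"n{i}" for i in range(n_nodes)),
        network=tuple(
            "Default" if i in dmn else "Vis" for i in range(n_nodes)
        ),
        is_dmn=tuple(i in dmn for i in range(n_nodes)),
    )


def random_sc_matrix(rng, n_nodes, density=0.8, modality="FD"):
    """Random sparse symmetric SC matrix with a valid mask."""
    iu, ju = np.triu_indices(n_nodes, k=1)
    present = rng.random(iu.size) < density
    w = np.full((n_nodes, n_nodes), np.nan)
    p = np.zeros((n_nodes, n_nodes), dtype=bool)
    vals = rng.lognormal(0.0, 0.5, size=iu.size)
    if modality == "logFbC":
        vals = np.log(vals)
    w[iu, ju] = np.where(present, vals, np.nan)
    w[ju, iu] = w[iu, ju]
    p[iu, ju] = present
    p[ju, iu] = present
    return ConnectomeMatrix(modality=modality, weights=w, present=p)


def random_fc_matrix(rng, n_nodes):
    iu, ju = np.triu_indices(n_nodes, k=1)
    w = np.full((n_nodes, n_nodes), np.nan)
    vals = rng.normal(0.0, 0.5, size=iu.size)
    w[iu, ju] = vals
    w[ju, iu] = vals
    p = ~np.eye(n_nodes, dtype=bool)
    return ConnectomeMatrix(modality="FC", weights=w, present=p)


def make_subject(rng, atlas, subject_id="sub-1", group="CN", density=0.8):
    n = atlas.n_nodes
    matrices = {
        m: random_sc_matrix(rng, n, density, m)
        for m in ("FD", "logFbC", "FDC", "streamline")
    }
    matrices["FC"] = random_fc_matrix(rng, n)
    return SubjectRecord(
        subject_id=subject_id,
        group=group,
        age=float(rng.uniform(60, 85)),
        sex="F" if rng.random() < 0.5 else "M",
        icv=float(rng.normal(1.5e6, 1e5)),
        matrices=matrices,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Synthetic cohort small enough for fast whole-suite reuse."""
    cfg = GeneratorConfig(
        n_per_group={"CN": 30, "MCI": 25, "AD": 20},
        n_nodes=20,
        dmn_size=5,
        seed=7,
    )
    return CohortGenerator(cfg).generate()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def atlas10():
    return make_atlas(10, dmn_nodes=(0, 1, 2))
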