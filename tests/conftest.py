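import numpy as np
import pandas as pd
import pytest

import exprsearch as es


@pytest.fixture(scope="session")
def demo_bundle(tmp_path_factory):
    """The worked-example fixture bundle, generated once per session."""
    outdir = tmp_path_factory.mktemp("demo")
    return es.make_demo_fixtures(outdir, seed=1)


@pytest.fixture(scope="session")
def demo_db(demo_bundle):
    return es.load_database(demo_bundle["db"])


@pytest.fixture(scope="session")
def demo_signature(demo_bundle):
    return es.load_signature(demo_bundle["signature"])


@pytest.fixture
def small_matrix():
    """2 control + 2 treated log2 matrix with a clear shift on probe B."""
    values = np.array(
        [
            [8.0, 8.2, 8.1, 7.9],
            [6.0, 6.1, 9.0, 9.2],
            [10.0, 10.3, 10.1, 9.8],
        ]
    )
    return es.ExpressionMatrix(
        probe_ids=["A_at", "B_at", "C_at"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=values,
        experiment_id="TEST1",
        scale="log2",
    )


@pytest.fixture
def small_groups():
    return es.GroupDefinition(
        contrast_id="TEST1_1",
        control_samples=["s1", "s2"],
        treated_samples=["s3", "s4"],
        description="toy control versus treated",
    )


def make_db(folds: np.ndarray, probe_ids=None, contrast_ids=None) -> es.ContrastDatabase:
    """Build an in-memory database straight from a probe x contrast fold matrix."""
    folds = np.asarray(folds, dtype=float)
    n_probes, n_contrasts = folds.shape
    probe_ids = probe_ids or [f"P{i:04d}_at" for i in range(n_probes)]
    contrast_ids = contrast_ids or [f"C{j:04d}_1" for j in range(n_contrasts)]
    index = pd.Index(probe_ids, name="probe_id")
    db = es.ContrastDatabase()
    for j, cid in enumerate(contrast_ids):
        db.add_contrast(
            es.ContrastRecord(
                contrast_id=cid,
                study_title=f"study {cid}",
                n_control=2,
                n_treated=2,
                design="crafted",
                fold=pd.Series(folds[:, j], index=index),
                pvalue=pd.Series(np.full(n_probes, 0.5), index=index),
            )
        )
    return db
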