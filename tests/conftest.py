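import numpy as np
import pandas as pd
import pytest

import evsig as ev


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort without missingness: fast to preprocess, with the
    default spiked markers."""
    cfg = ev.CohortConfig(
        n_proteins=60, n_metabolites=30, n_immunoglobulin_decoys=5,
        mcar_rate=0.0, mnar_slope=0.0, seed=42,
    )
    return ev.generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_normalised(small_cohort):
    proteins, metabolites, sheet, truth = small_cohort
    prot_n, _ = ev.preprocess(proteins, seed=1)
    met_n, _ = ev.preprocess(metabolites, seed=1)
    return prot_n, met_n, sheet, truth


@pytest.fixture(scope="session")
def subject_level(small_normalised):
    prot_n, met_n, sheet, truth = small_normalised
    prot_s, sheet_s = ev.average_replicates(prot_n, sheet)
    met_s, _ = ev.average_replicates(met_n, sheet)
    return prot_s, met_s, sheet_s, truth


def make_matrix(values, obs=None, features=None, kind="protein", layer="normalised_log"):
    """Small OmicsMatrix literal for targeted tests."""
    values = np.asarray(values, dtype=float)
    obs = obs or [f"o{i}" for i in range(values.shape[0])]
    features = features or [f"f{j}" for j in range(values.shape[1])]
    return ev.OmicsMatrix(
        values=pd.DataFrame(values, index=obs, columns=features),
        feature_kind=pd.Series(kind, index=features),
        layer=layer,
    )


def make_sheet(groups, subjects=None, obs=None, replicate_index=None):
    n = len(groups)
    obs = obs or [f"o{i}" for i in range(n)]
    subjects = subjects or obs
    replicate_index = replicate_index or [1] * n
    return ev.SampleSheet(pd.DataFrame({
        "observation_id": obs,
        "subject_id": subjects,
        "group": groups,
        "replicate_index": replicate_index,
    }))
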