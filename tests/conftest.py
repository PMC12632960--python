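"""Shared fixtures: one small synthetic study reused across the suite."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from reactage import features as feat
from reactage import react
from reactage import synthetic as syn


@pytest.fixture(scope="session")
def sim_cfg() -> syn.SimulationConfig:
    return syn.SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def templates(sim_cfg):
    return syn.make_templates(sim_cfg)


@pytest.fixture(scope="session")
def atlas(sim_cfg):
    return syn.make_atlas(sim_cfg)


@pytest.fixture(scope="session")
def fixture_subjects() -> pd.Index:
    return pd.Index([f"sub-{i:04d}" for i in range(5)], name="subject")


@pytest.fixture(scope="session")
def fixture_covariates(fixture_subjects) -> pd.DataFrame:
    rng = np.random.default_rng(5)
    return pd.DataFrame(
        {
            "age": rng.uniform(18, 90, len(fixture_subjects)),
            "sex": rng.integers(0, 2, len(fixture_subjects)).astype(float),
            "site": "site0",
        },
        index=fixture_subjects,
    )


@pytest.fixture(scope="session")
def regional_frames(sim_cfg, templates, atlas, fixture_subjects):
    """Per-transporter subjects x ROI regional means from the full REACT chain."""
    rows: dict[str, list[np.ndarray]] = {t: [] for t in templates.target_names}
    for i in range(len(fixture_subjects)):
        cfg_i = replace(sim_cfg, seed=100 + i, noise_sd=0.5, n_timepoints=40)
        ts = syn.make_weight_timeseries(cfg_i)
        bold, _ = syn.make_bold_run(cfg_i, templates, ts)
        _, maps = react.run_react(bold, templates, templates.mask)
        regional = feat.parcellate(maps, atlas)
        for k, t in enumerate(templates.target_names):
            rows[t].append(regional[:, k])
    return {
        t: pd.DataFrame(np.vstack(v), index=fixture_subjects)
        for t, v in rows.items()
    }


@pytest.fixture(scope="session")
def structural_table(fixture_subjects, fixture_covariates):
    return syn.make_structural_block(
        len(fixture_subjects), seed=3, covariates=fixture_covariates
    )
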