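"""Shared fixtures: small simulated tables and reusable MCMC fits.

Expensive fits are session-scoped so several test modules can share them.
All randomness is seeded; every dataset is generated in-process by the
package's own simulator.
"""

from __future__ import annotations

import numpy as np
import pytest

import mdnrm as m


@pytest.fixture(scope="session")
def tiny_table() -> m.ResponseTable:
    """3 raters x 12 cases x 3 classes, original-MDNRM generated."""
    spec = m.ModelSpec(variant="mdnrm_orig", n_classes=3, alpha_prior="none")
    table, _ = m.generate_dataset(
        m.SimulationConfig(spec=spec, n_raters=3, n_cases=12, seed=41)
    )
    return table


@pytest.fixture(scope="session")
def study_table() -> m.ResponseTable:
    """A table with the real study's geometry: 6 raters x 150 cases x 3
    classes, generated from the full MDNRM (per-case discrimination and
    easiness). Truth discriminations are drawn Gamma(2, 2) — mean 1, the
    conventional scale — so simulated raters err at realistic rates."""
    spec = m.ModelSpec(variant="mdnrm_r", n_classes=3, alpha_prior="gamma")
    table, _ = m.generate_dataset(m.SimulationConfig(spec=spec, seed=2026))
    return table


@pytest.fixture(scope="session")
def small_fit_orig() -> tuple[m.PosteriorDraws, m.ResponseTable]:
    """Original-MDNRM fit on a 3x15x3 table: cheap but long enough for
    distributional checks on the marginals."""
    spec = m.ModelSpec(variant="mdnrm_orig", n_classes=3, alpha_prior="none")
    table, _ = m.generate_dataset(
        m.SimulationConfig(spec=spec, n_raters=3, n_cases=15, seed=7)
    )
    config = m.McmcConfig(n_chains=4, n_warmup=300, n_samples=700, seed=19)
    return m.fit(spec, table, config), table


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
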