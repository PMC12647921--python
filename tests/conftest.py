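"""Shared fixtures: tiny simulated contractions and hand-built data objects."""

from __future__ import annotations

import numpy as np
import pytest

from mnexcite.discharge import SmoothedDischarge, UnitEvents
from mnexcite.io import AnalysisConfig, ContractionTrial
from mnexcite.simulate import DEFAULT_PROFILES, PoolParams, draw_pool, simulate_trial


def triangular_trial(
    intensity: float = 0.2, mvt_nm: float = 25.0, fs: float = 100.0,
    participant_id: str = "p1", trial: int = 1,
) -> ContractionTrial:
    """Noise-free triangular torque ramp (10 s up, 10 s down)."""
    t = np.arange(0.0, 20.0 + 0.5 / fs, 1.0 / fs)
    peak = intensity * 100.0
    pct = np.where(t <= 10.0, peak / 10.0 * t, np.maximum(peak - peak / 10.0 * (t - 10.0), 0))
    return ContractionTrial(
        participant_id=participant_id, intensity=intensity, trial=trial,
        mvt_nm=mvt_nm, time_s=t, torque_nm=pct / 100.0 * mvt_nm,
    )


from mnexcite.simulate import trial_dataset as dataset_from_trial  # noqa: F401


def constant_curve(lo: float, hi: float, rate: float) -> SmoothedDischarge:
    grid = np.linspace(lo, hi, int((hi - lo) * 100) + 1)
    return SmoothedDischarge(grid, np.full_like(grid, rate), np.inf)


def linear_curve(lo: float, hi: float, r_lo: float, r_hi: float) -> SmoothedDischarge:
    grid = np.linspace(lo, hi, int((hi - lo) * 100) + 1)
    return SmoothedDischarge(grid, np.interp(grid, [lo, hi], [r_lo, r_hi]), np.inf)


def events(
    rec: float, derec: float, rt: float = 10.0, derec_pct: float = 5.0,
    peak: float = 12.0,
) -> UnitEvents:
    return UnitEvents(
        recruitment_time_s=rec, derecruitment_time_s=derec,
        recruitment_threshold_pct=rt, derecruitment_torque_pct=derec_pct,
        peak_discharge_pps=peak,
    )


@pytest.fixture(scope="session")
def noisefree_pool():
    """Noise-free 25-unit control-profile pool at i20 with its trial simulation."""
    params = PoolParams(isi_cv=0.0, n_units=25)
    rng = np.random.default_rng(3)
    pool = draw_pool(params, DEFAULT_PROFILES["control"], 0.2, rng)
    sim = simulate_trial(pool, params, 0.2, rng, participant_id="p1", trial=1)
    return params, pool, sim


@pytest.fixture(scope="session")
def noisefree_analysis(noisefree_pool):
    """Full per-contraction analysis of the noise-free pool."""
    from mnexcite.pipeline import analyze_contraction

    params, pool, sim = noisefree_pool
    ds = dataset_from_trial(sim)
    ca = analyze_contraction(ds, sim.trial.key, AnalysisConfig())
    return params, pool, sim, ds, ca
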