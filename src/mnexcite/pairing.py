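"""Paired motor-unit ΔF analysis.

A lower-threshold "control" unit is paired with a higher-threshold "test"
unit recorded in the same contraction. ΔF is the smoothed discharge rate of
the control unit at the moment the test unit is recruited minus at the
moment it is derecruited; under recruitment–derecruitment hysteresis
(persistent-inward-current amplification) this difference is positive.
Each test unit's ΔF values over all eligible controls are averaged to one
value per test unit per contraction.

Eligibility criteria (all thresholds configurable, conventional values for
this literature):

a. the control's recruitment threshold is below the test unit's;
b. the control is recruited at least ``sep_min_s`` before the test unit;
c. the control is derecruited after the test unit;
d. the control's smoothed rate modulates by at least ``mod_min_pps`` within
   the test unit's activity window;
e. the control and test smoothed curves correlate at ``r >= r_min`` over
   their common active interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discharge import SmoothedDischarge, UnitEvents
from .io import PairingConfig


@dataclass
class UnitRecord:
    """One unit's smoothed curve and events inside one contraction."""

    unit_id: str
    smoothed: SmoothedDischarge
    events: UnitEvents


@dataclass
class PairResult:
    """One candidate control/test pairing with eligibility diagnostics."""

    control_id: str
    test_id: str
    criteria: dict[str, bool]
    separation_s: float
    control_modulation_pps: float
    rate_correlation: float
    delta_f_pps: float | None = None

    @property
    def eligible(self) -> bool:
        return all(self.criteria.values())

    def failing(self) -> list[str]:
        return [k for k, ok in self.criteria.items() if not ok]


@dataclass
class UnitDeltaF:
    """Per-test-unit ΔF: the mean over all eligible control pairings."""

    test_id: str
    delta_f_pps: float
    n_controls: int


def pair_deltaf(control: SmoothedDischarge, test_events: UnitEvents) -> float | None:
    """ΔF of one pair: control rate at test recruitment minus at derecruitment.

    Returns ``None`` when the control curve is undefined at either time.
    Negative values are retained (no clipping).
    """
    r_rec = control.rate_at(test_events.recruitment_time_s)
    r_derec = control.rate_at(test_events.derecruitment_time_s)
    if np.isnan(r_rec) or np.isnan(r_derec):
        return None
    return float(r_rec - r_derec)


def _rate_correlation(
    a: SmoothedDischarge, b: SmoothedDischarge, grid_hz: float = 100.0
) -> float:
    """Pearson correlation of two smoothed curves over their overlap."""
    lo = max(a.active_interval[0], b.active_interval[0])
    hi = min(a.active_interval[1], b.active_interval[1])
    if hi - lo < 2.0 / grid_hz:
        return np.nan
    grid = np.linspace(lo, hi, max(int((hi - lo) * grid_hz) + 1, 3))
    ra, rb = a.rate_at(grid), b.rate_at(grid)
    if np.std(ra) < 1e-12 or np.std(rb) < 1e-12:
        return np.nan
    return float(np.corrcoef(ra, rb)[0, 1])


def evaluate_pair(
    control: UnitRecord, test: UnitRecord, criteria: PairingConfig
) -> PairResult:
    """Evaluate all eligibility criteria for one ordered (control, test) pair."""
    ce, te = control.events, test.events
    separation = te.recruitment_time_s - ce.recruitment_time_s
    window = (te.recruitment_time_s, te.derecruitment_time_s)
    grid = control.smoothed.grid_s
    in_window = (grid >= window[0]) & (grid <= window[1])
    if in_window.sum() >= 2:
        seg = control.smoothed.rate_pps[in_window]
        modulation = float(np.ptp(seg))
    else:
        modulation = 0.0
    r = _rate_correlation(control.smoothed, test.smoothed)
    crit = {
        "rank": ce.recruitment_threshold_pct < te.recruitment_threshold_pct,
        "separation": separation >= criteria.sep_min_s,
        "derecruit": ce.derecruitment_time_s > te.derecruitment_time_s,
        "modulation": modulation >= criteria.mod_min_pps,
        "correlation": bool(np.isfinite(r) and r >= criteria.r_min),
    }
    result = PairResult(
        control_id=control.unit_id,
        test_id=test.unit_id,
        criteria=crit,
        separation_s=separation,
        control_modulation_pps=modulation,
        rate_correlation=r,
    )
    if result.eligible:
        df = pair_deltaf(control.smoothed, te)
        if df is None:
            result.criteria["derecruit"] = False  # curve did not cover the window
        else:
            result.delta_f_pps = df
    return result


def eligible_pairs(
    units: list[UnitRecord], criteria: PairingConfig | None = None
) -> list[PairResult]:
    """Evaluate every ordered (control, test) pair within one contraction.

    All candidate pairs are returned with their per-criterion diagnostics;
    ``delta_f_pps`` is populated only for eligible pairs. Eligibility is
    antisymmetric through the rank criterion.
    """
    criteria = criteria or PairingConfig()
    out = []
    for control in units:
        for test in units:
            if control.unit_id == test.unit_id:
                continue
            out.append(evaluate_pair(control, test, criteria))
    return out


def unit_deltaf(pairs: list[PairResult]) -> list[UnitDeltaF]:
    """Average pair ΔF values per test unit over its eligible controls.

    Test units with no eligible pairing carry no ΔF (they are kept for the
    other discharge metrics but excluded from ΔF analyses).
    """
    by_test: dict[str, list[float]] = {}
    for p in pairs:
        if p.eligible and p.delta_f_pps is not None:
            by_test.setdefault(p.test_id, []).append(p.delta_f_pps)
    return [
        UnitDeltaF(test_id=t, delta_f_pps=float(np.mean(v)), n_controls=len(v))
        for t, v in sorted(by_test.items())
    ]
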