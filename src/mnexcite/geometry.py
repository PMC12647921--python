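"""Brace height: nonlinearity of the ascending discharge-rate trajectory.

The ascending phase of a unit's smoothed discharge rate is re-parameterised
against torque (%MVT), from the recruitment point to the peak-discharge
point. A straight reference segment joins those two endpoints; brace height
is the maximal perpendicular deviation of the trajectory above that line,
normalised to the hypotenuse of the right triangle formed by the endpoint
legs and expressed in %rTri.

Torque and rate are first rescaled so the endpoint span of each axis maps
to [0, 1]. In that frame the reference segment is the diagonal of the unit
square and the right-triangle hypotenuse has length √2, making the metric
scale-free (invariant to affine rescaling of either axis) and "orthogonal"
well defined despite the mixed units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .discharge import SmoothedDischarge, UnitEvents
from .io import ContractionTrial


@dataclass
class AscendingTrajectory:
    """Smoothed rate versus torque on the ascending ramp phase."""

    torque_pct: np.ndarray
    rate_pps: np.ndarray
    truncated_at_torque_peak: bool = False
    nonmonotone_torque: bool = False

    @property
    def n(self) -> int:
        return len(self.torque_pct)


@dataclass
class BraceHeightResult:
    """Brace height of one unit with its exclusion status."""

    brace_pct_rtri: float | None
    apex_torque_pct: float | None
    apex_rate_pps: float | None
    recruitment_slope: float | None   # normalised-frame slope, recruitment -> apex
    excluded: bool
    reason: str | None = None


def ascending_trajectory(
    smoothed: SmoothedDischarge,
    trial: ContractionTrial,
    events: UnitEvents,
    monotone_tol_pct: float = 0.5,
) -> AscendingTrajectory:
    """Re-parameterise the smoothed rate against torque on the ascent.

    The phase runs from recruitment to the time of peak smoothed discharge;
    if the peak discharge falls beyond the torque peak of the ramp the
    trajectory is truncated there and flagged. Non-monotone torque within
    tolerance is projected onto its running-maximum envelope and flagged.
    """
    t_peak_rate = smoothed.peak_time
    torque_pct_full = trial.torque_pct_mvt()
    t_torque_peak = float(trial.time_s[int(np.argmax(torque_pct_full))])
    truncated = t_peak_rate > t_torque_peak
    t_hi = min(t_peak_rate, t_torque_peak)

    mask = (smoothed.grid_s >= events.recruitment_time_s) & (smoothed.grid_s <= t_hi)
    grid = smoothed.grid_s[mask]
    rate = smoothed.rate_pps[mask]
    torque = np.interp(grid, trial.time_s, torque_pct_full)

    nonmono = False
    if len(torque) >= 2:
        drops = np.maximum.accumulate(torque) - torque
        if np.any(drops > monotone_tol_pct):
            nonmono = True
        torque = np.maximum.accumulate(torque)  # monotone envelope
    return AscendingTrajectory(
        torque_pct=torque, rate_pps=rate,
        truncated_at_torque_peak=truncated, nonmonotone_torque=nonmono,
    )


def brace_height(traj: AscendingTrajectory) -> BraceHeightResult:
    """Maximal above-line deviation of the trajectory, in %rTri.

    Both axes are normalised to the endpoint span, the reference line is the
    segment joining the (0,0) recruitment point to the (1,1) peak-discharge
    point, and the perpendicular deviation at the apex is expressed as a
    percentage of the √2 hypotenuse. Only deviations above the line compete
    for the maximum; a trajectory lying entirely below the line is sent down
    the negative-slope exclusion path.
    """
    if traj.n < 3:
        return BraceHeightResult(None, None, None, None, True, "degenerate trajectory")
    x_span = traj.torque_pct[-1] - traj.torque_pct[0]
    y_span = traj.rate_pps[-1] - traj.rate_pps[0]
    if abs(x_span) < 1e-9 or abs(y_span) < 1e-9:
        return BraceHeightResult(None, None, None, None, True, "degenerate endpoints")

    x = (traj.torque_pct - traj.torque_pct[0]) / x_span
    y = (traj.rate_pps - traj.rate_pps[0]) / y_span
    # signed perpendicular distance to the unit-square diagonal, as % of the
    # sqrt(2) hypotenuse: dist/sqrt(2) = (y - x)/2
    signed_pct = (y - x) / 2.0 * 100.0

    above = signed_pct > 0
    if not np.any(above):
        k = int(np.argmax(np.abs(signed_pct)))
        slope = _safe_slope(x[k], y[k])
        return BraceHeightResult(
            brace_pct_rtri=float(np.abs(signed_pct[k])),
            apex_torque_pct=float(traj.torque_pct[k]),
            apex_rate_pps=float(traj.rate_pps[k]),
            recruitment_slope=slope,
            excluded=True,
            reason="trajectory below reference line (negative slope path)",
        )
    k = int(np.argmax(signed_pct))
    slope = _safe_slope(x[k], y[k])
    return BraceHeightResult(
        brace_pct_rtri=float(signed_pct[k]),
        apex_torque_pct=float(traj.torque_pct[k]),
        apex_rate_pps=float(traj.rate_pps[k]),
        recruitment_slope=slope,
        excluded=False,
    )


def _safe_slope(x: float, y: float) -> float:
    return float(y / x) if abs(x) > 1e-12 else float(np.inf * np.sign(y) if y else 0.0)


def brace_exclusions(results: list[BraceHeightResult]) -> list[BraceHeightResult]:
    """Apply the automated exclusion rules in place and return the list.

    Units whose normalised brace height exceeds 100 %rTri, or whose
    recruitment-point-to-brace-point slope (normalised frame) is negative,
    are flagged as excluded with the reason recorded. This is a hard
    deterministic filter; there is no manual review step.
    """
    for r in results:
        if r.excluded or r.brace_pct_rtri is None:
            continue
        if r.brace_pct_rtri > 100.0:
            r.excluded = True
            r.reason = "brace height > 100 %rTri"
        elif r.recruitment_slope is not None and r.recruitment_slope < 0:
            r.excluded = True
            r.reason = "negative recruitment-to-brace-height slope"
    return results
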