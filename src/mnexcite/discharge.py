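"""Per-unit discharge metrics.

Instantaneous discharge rates from spike times, continuous smoothed
discharge-rate curves by support vector regression (SVR), recruitment and
derecruitment events referenced to the torque trace, peak discharge rate,
and recruitment-threshold binning.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.svm import SVR

from .io import ContractionTrial, SVRConfig, ValidationError

#: Recruitment-threshold bins in %MVT: label -> (lo, hi], units above the
#: last edge are excluded from binned analyses.
RT_BINS = {"rt0-20": (0.0, 20.0), "rt20-40": (20.0, 40.0), "rt40-60": (40.0, 60.0)}


@dataclass
class SmoothedDischarge:
    """A continuous discharge-rate curve over a unit's active interval.

    The curve is evaluated on a uniform grid spanning [first spike, last
    spike]; it is never extrapolated beyond that interval.
    """

    grid_s: np.ndarray
    rate_pps: np.ndarray
    length_scale_s: float

    @property
    def active_interval(self) -> tuple[float, float]:
        return float(self.grid_s[0]), float(self.grid_s[-1])

    def rate_at(self, t: float | np.ndarray) -> np.ndarray | float:
        """Rate at time(s) ``t``; NaN outside the active interval."""
        t = np.asarray(t, dtype=float)
        out = np.interp(t, self.grid_s, self.rate_pps)
        lo, hi = self.active_interval
        out = np.where((t < lo - 1e-9) | (t > hi + 1e-9), np.nan, out)
        return float(out) if out.ndim == 0 else out

    @property
    def peak_rate(self) -> float:
        return float(np.max(self.rate_pps))

    @property
    def peak_time(self) -> float:
        return float(self.grid_s[int(np.argmax(self.rate_pps))])


@dataclass
class UnitEvents:
    """Recruitment/derecruitment events and peak discharge of one unit."""

    recruitment_time_s: float
    derecruitment_time_s: float
    recruitment_threshold_pct: float
    derecruitment_torque_pct: float
    peak_discharge_pps: float


class UnsmoothableUnit(Exception):
    """Raised when a unit has too few rate points to smooth."""


def instantaneous_rates(spike_times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Instantaneous discharge rates from spike times.

    The rate for each closed inter-spike interval is ``1 / ISI`` and is
    placed at the midpoint of the interval — ``1/ISI`` measures the mean
    rate over the interval, which a drifting discharge attains mid-interval;
    end-aligned placement would lag the rising phase and lead the falling
    phase, deflating hysteresis estimates by roughly the rate slope times
    half an ISI at each end. ``n`` spikes give ``n - 1`` rate points.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if len(spike_times) < 2:
        raise ValidationError("at least 2 spikes are needed to define a rate")
    isi = np.diff(spike_times)
    return 0.5 * (spike_times[1:] + spike_times[:-1]), 1.0 / isi


def smooth_discharge(
    times: np.ndarray,
    rates: np.ndarray,
    svr: SVRConfig | None = None,
    grid_hz: float = 100.0,
    min_points: int = 4,
    first_spike: float | None = None,
    last_spike: float | None = None,
) -> SmoothedDischarge:
    """Smooth instantaneous rates into a continuous curve with RBF-kernel SVR.

    The kernel length scale adapts per unit: ``length_scale_factor`` times
    the median pairwise distance between rate-point times, clipped to the
    configured bounds — wide enough to bridge inter-spike gaps, narrow
    enough to follow the ramp-driven rate modulation.

    The curve is evaluated on a uniform grid spanning the unit's active
    interval, [first spike, last spike] when those are given (the rate-point
    abscissae are interval midpoints, so the model is evaluated over half a
    leading/trailing ISI, never extrapolated further).
    """
    svr = svr or SVRConfig()
    times = np.asarray(times, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if len(times) < min_points:
        raise UnsmoothableUnit(
            f"{len(times)} rate points < required minimum {min_points}"
        )
    start = times[0] if first_spike is None else first_spike
    stop = times[-1] if last_spike is None else last_spike
    if np.ptp(rates) < 1e-12:
        # degenerate: constant input produces a constant curve
        grid = _grid(start, stop, grid_hz)
        return SmoothedDischarge(grid, np.full_like(grid, rates[0]), np.inf)

    pairwise_med = np.median(np.abs(times[:, None] - times[None, :]))
    ell = float(
        np.clip(svr.length_scale_factor * pairwise_med,
                svr.length_scale_min, svr.length_scale_max)
    )
    model = SVR(kernel="rbf", C=svr.C, epsilon=svr.epsilon, gamma=1.0 / (2 * ell**2))
    # centre the time axis so the fit is invariant to the trial's time origin
    t0 = times.mean()
    model.fit((times - t0)[:, None], rates)
    grid = _grid(start, stop, grid_hz)
    pred = model.predict((grid - t0)[:, None])
    return SmoothedDischarge(grid, pred, ell)


def _grid(lo: float, hi: float, grid_hz: float) -> np.ndarray:
    n = max(int(np.ceil((hi - lo) * grid_hz)) + 1, 2)
    return np.linspace(lo, hi, n)


def unit_events(
    spike_times: np.ndarray,
    smoothed: SmoothedDischarge,
    trial: ContractionTrial,
) -> UnitEvents:
    """Recruitment/derecruitment thresholds and peak discharge rate.

    The recruitment threshold is the torque (as %MVT, from the filtered
    trace) at the first discharge; the derecruitment torque is defined
    analogously at the last discharge; the peak discharge rate is the
    maximum of the smoothed curve.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    t_rec, t_derec = float(spike_times[0]), float(spike_times[-1])
    rec_pct = float(trial.torque_at(t_rec)) / trial.mvt_nm * 100.0
    derec_pct = float(trial.torque_at(t_derec)) / trial.mvt_nm * 100.0
    return UnitEvents(
        recruitment_time_s=t_rec,
        derecruitment_time_s=t_derec,
        recruitment_threshold_pct=rec_pct,
        derecruitment_torque_pct=derec_pct,
        peak_discharge_pps=smoothed.peak_rate,
    )


def assign_bin(
    rt_pct: float, edges: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0)
) -> str | None:
    """Assign a recruitment threshold (%MVT) to its bin.

    Bins are left-open/right-closed: (0, 20] -> ``rt0-20``, (20, 40] ->
    ``rt20-40``, (40, 60] -> ``rt40-60``. Thresholds above the last edge
    return ``None`` (excluded from binned analyses); negative thresholds are
    invalid.
    """
    if rt_pct < 0:
        raise ValidationError(f"negative recruitment threshold: {rt_pct}")
    for lo, hi in zip(edges[:-1], edges[1:]):
        if lo < rt_pct <= hi:
            return f"rt{lo:g}-{hi:g}"
    if rt_pct <= edges[0]:  # exactly zero: attach to the first bin
        return f"rt{edges[0]:g}-{edges[1]:g}"
    return None
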