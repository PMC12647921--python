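"""Data model and tidy-table I/O for decomposed motor-unit contraction experiments.

The pipeline consumes three long-format CSV tables:

``spikes.csv``
    one row per motor-unit discharge:
    ``participant_id, group, sex, intensity, trial, unit_id, spike_time_s, pnr_db``
``torque.csv``
    one row per torque sample:
    ``participant_id, intensity, trial, time_s, torque_nm, mvt_nm``
``participants.csv``
    one row per participant with group, sex, body mass and the optional
    strength/power/function covariates.

Intensities are stored as fractions of maximal voluntary torque (MVT):
0.20, 0.40, 0.60 for ramps peaking at 20/40/60 %MVT. Spike times are
trial-relative seconds (0 at ramp onset).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

logger = logging.getLogger(__name__)

VALID_INTENSITIES = (0.2, 0.4, 0.6)
VALID_GROUPS = ("sarcopenic", "control", "athlete")
VALID_SEXES = ("female", "male")

SPIKES_COLUMNS = [
    "participant_id", "group", "sex", "intensity", "trial",
    "unit_id", "spike_time_s", "pnr_db",
]
TORQUE_COLUMNS = [
    "participant_id", "intensity", "trial", "time_s", "torque_nm", "mvt_nm",
]
PARTICIPANTS_COLUMNS = [
    "participant_id", "group", "sex", "body_mass_kg", "handgrip_kg",
    "ugs_ms", "fgs_ms", "tug_s", "fsst_s", "ststs_s", "ststs_w_kg",
    "peak_torque_nm",
]


class DatasetError(Exception):
    """Base class for dataset problems."""


class SchemaError(DatasetError):
    """A required column is missing or a table cannot be parsed."""


class IntegrityError(DatasetError):
    """Cross-references between tables do not resolve."""


class ValidationError(DatasetError):
    """A record violates a per-record invariant (e.g. spike out of bounds)."""


def intensity_label(intensity: float) -> str:
    """0.2 -> 'i20' etc."""
    return f"i{round(intensity * 100):d}"


@dataclass
class Participant:
    """One study participant with group/sex factors and functional covariates.

    Function measures are optional (``None`` when not collected); all times,
    speeds and masses must be positive when present.
    """

    id: str
    sex: str
    group: str
    body_mass_kg: float
    handgrip_kg: float | None = None
    ugs_ms: float | None = None
    fgs_ms: float | None = None
    tug_s: float | None = None
    fsst_s: float | None = None
    ststs_s: float | None = None
    ststs_w_kg: float | None = None
    peak_torque_nm: float | None = None

    def __post_init__(self) -> None:
        if self.sex not in VALID_SEXES:
            raise ValidationError(f"participant {self.id}: unknown sex {self.sex!r}")
        if self.group not in VALID_GROUPS:
            raise ValidationError(f"participant {self.id}: unknown group {self.group!r}")
        if not self.body_mass_kg > 0:
            raise ValidationError(f"participant {self.id}: body mass must be > 0")
        for f in fields(self):
            if f.name in ("id", "sex", "group", "body_mass_kg"):
                continue
            v = getattr(self, f.name)
            if v is not None and not v > 0:
                raise ValidationError(
                    f"participant {self.id}: {f.name} must be > 0, got {v}"
                )


@dataclass
class ContractionTrial:
    """One triangular ramped contraction with its sampled torque trace."""

    participant_id: str
    intensity: float
    trial: int
    mvt_nm: float
    time_s: np.ndarray
    torque_nm: np.ndarray
    ramp_up_s: float = 10.0
    ramp_down_s: float = 10.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.torque_nm = np.asarray(self.torque_nm, dtype=float)
        if not any(np.isclose(self.intensity, v) for v in VALID_INTENSITIES):
            raise ValidationError(
                f"trial {self.key}: intensity must be one of {VALID_INTENSITIES}"
            )
        if not self.mvt_nm > 0:
            raise ValidationError(f"trial {self.key}: mvt must be > 0")
        if self.time_s.shape != self.torque_nm.shape:
            raise ValidationError(f"trial {self.key}: time/torque length mismatch")
        if not np.all(np.isfinite(self.torque_nm)):
            raise ValidationError(f"trial {self.key}: non-finite torque samples")
        if len(self.time_s) >= 2 and np.any(np.diff(self.time_s) <= 0):
            raise ValidationError(f"trial {self.key}: time samples not increasing")

    @property
    def key(self) -> tuple[str, float, int]:
        return (self.participant_id, round(self.intensity, 2), self.trial)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1])

    @property
    def fs(self) -> float:
        """Sampling rate in Hz (uniform sampling assumed)."""
        return 1.0 / float(np.median(np.diff(self.time_s)))

    def torque_pct_mvt(self) -> np.ndarray:
        return self.torque_nm / self.mvt_nm * 100.0

    def torque_at(self, t: float | np.ndarray) -> np.ndarray:
        """Linear interpolation of torque (N·m) at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.time_s[0] - 1e-9) or np.any(t > self.time_s[-1] + 1e-9):
            raise IntegrityError(
                f"trial {self.key}: torque undefined at requested time"
            )
        return np.interp(t, self.time_s, self.torque_nm)


@dataclass
class SpikeTrain:
    """Discharge times of one decomposed motor unit in one contraction trial."""

    unit_id: str
    participant_id: str
    intensity: float
    trial: int
    spike_times_s: np.ndarray
    pnr_db: float

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=float)
        if self.pnr_db is None or not np.isfinite(self.pnr_db):
            raise ValidationError(f"unit {self.unit_id}: missing PNR")
        if len(self.spike_times_s) >= 2 and np.any(np.diff(self.spike_times_s) <= 0):
            raise ValidationError(
                f"unit {self.unit_id} ({self.participant_id}, "
                f"{intensity_label(self.intensity)}, trial {self.trial}): "
                "spike times not strictly increasing"
            )

    @property
    def trial_key(self) -> tuple[str, float, int]:
        return (self.participant_id, round(self.intensity, 2), self.trial)

    @property
    def n_spikes(self) -> int:
        return len(self.spike_times_s)


@dataclass
class Dataset:
    """A validated collection of participants, trials and spike trains."""

    participants: dict[str, Participant]
    trials: dict[tuple[str, float, int], ContractionTrial]
    spike_trains: list[SpikeTrain]

    def validate(self) -> None:
        """Check cross-references and per-record invariants; raise on failure."""
        for trial in self.trials.values():
            if trial.participant_id not in self.participants:
                raise IntegrityError(
                    f"trial {trial.key}: unknown participant {trial.participant_id}"
                )
        problems = []
        for st in self.spike_trains:
            if st.trial_key not in self.trials:
                raise IntegrityError(
                    f"unit {st.unit_id}: no torque trial {st.trial_key}"
                )
            trial = self.trials[st.trial_key]
            if st.n_spikes and (
                st.spike_times_s[0] < trial.time_s[0] - 1e-9
                or st.spike_times_s[-1] > trial.duration_s + 1e-9
            ):
                problems.append(
                    f"unit {st.unit_id} ({st.trial_key}): spike times outside "
                    f"trial bounds [0, {trial.duration_s:.2f}] s"
                )
        if problems:
            raise ValidationError("; ".join(problems))

    @property
    def n_units(self) -> int:
        return len(self.spike_trains)

    def counts(self) -> dict[str, int]:
        return {
            "participants": len(self.participants),
            "trials": len(self.trials),
            "spike_trains": len(self.spike_trains),
        }


@dataclass
class SVRConfig:
    """Support-vector-regression smoothing hyperparameters.

    ``length_scale_factor`` multiplies the per-unit median pairwise
    spike-time distance to obtain the RBF length scale, which is then
    clipped to [``length_scale_min``, ``length_scale_max``] seconds.
    """

    C: float = 50.0
    epsilon: float = 0.01
    length_scale_factor: float = 0.25
    length_scale_min: float = 0.35
    length_scale_max: float = 1.2


@dataclass
class PairingConfig:
    """Eligibility thresholds for control/test motor-unit pairing."""

    sep_min_s: float = 1.0
    mod_min_pps: float = 0.5
    r_min: float = 0.7


@dataclass
class AnalysisConfig:
    """All tunable analysis parameters with their defaults."""

    pnr_min_db: float = 30.0
    torque_lowpass_hz: float = 15.0
    svr: SVRConfig = field(default_factory=SVRConfig)
    pairing: PairingConfig = field(default_factory=PairingConfig)
    grid_hz: float = 100.0
    min_rate_points: int = 4
    bin_edges_pct: tuple[float, ...] = (0.0, 20.0, 40.0, 60.0)
    bootstrap_B: int = 2000
    huber_c: float = 1.345
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pnr_min_db < 0:
            raise ValueError("pnr_min_db must be >= 0")
        if np.any(np.diff(self.bin_edges_pct) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @classmethod
    def from_dict(cls, d: Mapping) -> "AnalysisConfig":
        d = dict(d)
        svr = SVRConfig(**d.pop("svr", {}))
        pairing = PairingConfig(**d.pop("pairing", {}))
        if "bin_edges_pct" in d:
            d["bin_edges_pct"] = tuple(d["bin_edges_pct"])
        return cls(svr=svr, pairing=pairing, **d)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        d["bin_edges_pct"] = list(self.bin_edges_pct)
        return d


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, cols: Iterable[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing columns {missing}")


def _opt(value) -> float | None:
    return None if pd.isna(value) else float(value)


def read_dataset(
    spikes_path: str | Path,
    torque_path: str | Path,
    participants_path: str | Path,
) -> Dataset:
    """Read and cross-validate the three tidy tables into a :class:`Dataset`."""
    spikes = pd.read_csv(spikes_path)
    torque = pd.read_csv(torque_path)
    parts = pd.read_csv(participants_path)
    _require_columns(spikes, SPIKES_COLUMNS, "spikes table")
    _require_columns(torque, TORQUE_COLUMNS, "torque table")
    _require_columns(parts, PARTICIPANTS_COLUMNS, "participants table")

    participants = {}
    for _, row in parts.iterrows():
        p = Participant(
            id=str(row.participant_id),
            sex=str(row.sex),
            group=str(row.group),
            body_mass_kg=float(row.body_mass_kg),
            handgrip_kg=_opt(row.handgrip_kg),
            ugs_ms=_opt(row.ugs_ms),
            fgs_ms=_opt(row.fgs_ms),
            tug_s=_opt(row.tug_s),
            fsst_s=_opt(row.fsst_s),
            ststs_s=_opt(row.ststs_s),
            ststs_w_kg=_opt(row.ststs_w_kg),
            peak_torque_nm=_opt(row.peak_torque_nm),
        )
        participants[p.id] = p

    trials = {}
    for (pid, inten, tr), g in torque.groupby(
        ["participant_id", "intensity", "trial"], sort=True
    ):
        g = g.sort_values("time_s")
        trial = ContractionTrial(
            participant_id=str(pid),
            intensity=float(inten),
            trial=int(tr),
            mvt_nm=float(g.mvt_nm.iloc[0]),
            time_s=g.time_s.to_numpy(),
            torque_nm=g.torque_nm.to_numpy(),
        )
        trials[trial.key] = trial

    spike_trains = []
    for (pid, inten, tr, uid), g in spikes.groupby(
        ["participant_id", "intensity", "trial", "unit_id"], sort=True
    ):
        g = g.sort_values("spike_time_s")
        spike_trains.append(
            SpikeTrain(
                unit_id=str(uid),
                participant_id=str(pid),
                intensity=float(inten),
                trial=int(tr),
                spike_times_s=g.spike_time_s.to_numpy(),
                pnr_db=float(g.pnr_db.iloc[0]),
            )
        )

    ds = Dataset(participants=participants, trials=trials, spike_trains=spike_trains)
    ds.validate()
    return ds


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset back to the three tidy CSV tables; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    spike_rows = []
    for st in ds.spike_trains:
        p = ds.participants[st.participant_id]
        for t in st.spike_times_s:
            spike_rows.append(
                (st.participant_id, p.group, p.sex, st.intensity, st.trial,
                 st.unit_id, t, st.pnr_db)
            )
    spikes = pd.DataFrame(spike_rows, columns=SPIKES_COLUMNS)

    torque_rows = []
    for trial in ds.trials.values():
        torque_rows.append(
            pd.DataFrame(
                {
                    "participant_id": trial.participant_id,
                    "intensity": trial.intensity,
                    "trial": trial.trial,
                    "time_s": trial.time_s,
                    "torque_nm": trial.torque_nm,
                    "mvt_nm": trial.mvt_nm,
                }
            )
        )
    torque = pd.concat(torque_rows, ignore_index=True) if torque_rows else pd.DataFrame(
        columns=TORQUE_COLUMNS
    )

    part_rows = []
    for p in ds.participants.values():
        part_rows.append(
            (p.id, p.group, p.sex, p.body_mass_kg, p.handgrip_kg, p.ugs_ms,
             p.fgs_ms, p.tug_s, p.fsst_s, p.ststs_s, p.ststs_w_kg,
             p.peak_torque_nm)
        )
    parts = pd.DataFrame(part_rows, columns=PARTICIPANTS_COLUMNS)

    paths = {
        "spikes": out / "spikes.csv",
        "torque": out / "torque.csv",
        "participants": out / "participants.csv",
    }
    spikes.to_csv(paths["spikes"], index=False, float_format="%.6f")
    torque.to_csv(paths["torque"], index=False, float_format="%.6f")
    parts.to_csv(paths["participants"], index=False, float_format="%.6f")
    return paths


# ---------------------------------------------------------------------------
# filtering operations


def filter_pnr(ds: Dataset, pnr_min_db: float) -> Dataset:
    """Drop spike trains whose pulse-to-noise ratio falls below the threshold.

    The threshold is inclusive: a unit at exactly ``pnr_min_db`` is retained.
    Idempotent; the number of removed units is logged.
    """
    for st in ds.spike_trains:
        if st.pnr_db is None or not np.isfinite(st.pnr_db):
            raise ValidationError(f"unit {st.unit_id}: missing PNR")
    kept = [st for st in ds.spike_trains if st.pnr_db >= pnr_min_db]
    removed = len(ds.spike_trains) - len(kept)
    logger.info("PNR filter >= %.1f dB: removed %d of %d units",
                pnr_min_db, removed, len(ds.spike_trains))
    return replace(ds, spike_trains=kept)


def lowpass_torque(
    torque: np.ndarray, fs: float, cutoff_hz: float = 15.0, order: int = 2
) -> np.ndarray:
    """Zero-phase Butterworth low-pass of a uniformly sampled torque trace.

    A forward-backward (zero-lag) 2nd-order filter; length is preserved and
    the operation is linear. ``cutoff_hz`` must lie below the Nyquist rate.
    """
    torque = np.asarray(torque, dtype=float)
    if cutoff_hz >= fs / 2:
        raise ValueError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist ({fs / 2:.1f} Hz)"
        )
    sos = butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, torque)


def lowpass_trial(trial: ContractionTrial, cutoff_hz: float = 15.0) -> ContractionTrial:
    """Return a copy of the trial with its torque trace low-pass filtered."""
    return replace(trial, torque_nm=lowpass_torque(trial.torque_nm, trial.fs, cutoff_hz))
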