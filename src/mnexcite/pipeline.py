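"""End-to-end orchestration: validate → filter → metrics → ΔF → brace → stats.

Every stage logs its record counts into a run manifest so that each
decomposed unit is accounted for (analysed or excluded with a reason), and
a fixed master seed makes the whole run deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .discharge import (
    UnsmoothableUnit,
    assign_bin,
    instantaneous_rates,
    smooth_discharge,
    unit_events,
)
from .geometry import ascending_trajectory, brace_exclusions, brace_height
from .io import AnalysisConfig, Dataset, filter_pnr, lowpass_trial, read_dataset
from .pairing import UnitRecord, eligible_pairs, unit_deltaf
from .stats import ConvergenceError, fit_bin_model, fit_association_model

logger = logging.getLogger(__name__)

ASSOCIATION_MEASURES = (
    "ugs_ms", "fgs_ms", "fsst_s", "tug_s", "ststs_w_kg", "peak_torque_nm",
)


@dataclass
class RunManifest:
    """Reproducibility record: config, seeds, digests and per-stage counts."""

    config: dict
    seed: int
    version: str = __version__
    input_digests: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "config": self.config,
                "input_digests": self.input_digests,
                "counts": self.counts,
            },
            indent=2,
            sort_keys=True,
        )


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class ContractionAnalysis:
    """Per-unit smoothed curves/events and pair results for one contraction."""

    records: list[UnitRecord]
    pairs: list
    n_too_few_spikes: int
    n_unsmoothable: int


def analyze_contraction(
    ds: Dataset, trial_key: tuple, config: AnalysisConfig
) -> ContractionAnalysis:
    """Smooth every unit of one contraction and evaluate all pairings."""
    trial = lowpass_trial(ds.trials[trial_key], config.torque_lowpass_hz)
    records = []
    too_few = unsmoothable = 0
    for st in ds.spike_trains:
        if st.trial_key != trial_key:
            continue
        if st.n_spikes < 2:
            too_few += 1
            continue
        times, rates = instantaneous_rates(st.spike_times_s)
        try:
            smoothed = smooth_discharge(
                times, rates, config.svr, config.grid_hz,
                config.min_rate_points,
                first_spike=st.spike_times_s[0], last_spike=st.spike_times_s[-1],
            )
        except UnsmoothableUnit:
            unsmoothable += 1
            continue
        events = unit_events(st.spike_times_s, smoothed, trial)
        records.append(UnitRecord(unit_id=st.unit_id, smoothed=smoothed, events=events))
    pairs = eligible_pairs(records, config.pairing) if len(records) >= 2 else []
    return ContractionAnalysis(records, pairs, too_few, unsmoothable)


def analyze_dataset(
    ds: Dataset, config: AnalysisConfig
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Run the discharge/pairing/geometry stages over every contraction.

    Returns ``(units, pairs, counts)``. ``units`` has one row per unit per
    intensity (metrics averaged over that intensity's trials): recruitment
    threshold and bin, peak discharge rate, ΔF with its control count, brace
    height with exclusion flags. ``pairs`` holds the full per-contraction
    pair diagnostics.
    """
    unit_trial_rows = []
    pair_rows = []
    counts = {
        "spike_trains": ds.n_units,
        "too_few_spikes": 0,
        "unsmoothable": 0,
        "analyzed_unit_trials": 0,
    }
    for trial_key in sorted(ds.trials):
        ca = analyze_contraction(ds, trial_key, config)
        counts["too_few_spikes"] += ca.n_too_few_spikes
        counts["unsmoothable"] += ca.n_unsmoothable
        counts["analyzed_unit_trials"] += len(ca.records)
        pid, intensity, trial = trial_key
        trial_obj = lowpass_trial(ds.trials[trial_key], config.torque_lowpass_hz)
        deltaf = {u.test_id: u for u in unit_deltaf(ca.pairs)}
        for p in ca.pairs:
            pair_rows.append(
                {
                    "participant_id": pid, "intensity": intensity, "trial": trial,
                    "control_id": p.control_id, "test_id": p.test_id,
                    "eligible": p.eligible,
                    "delta_f_pps": p.delta_f_pps,
                    "separation_s": p.separation_s,
                    "control_modulation_pps": p.control_modulation_pps,
                    "rate_correlation": p.rate_correlation,
                    **{f"crit_{k}": v for k, v in p.criteria.items()},
                }
            )
        for rec in ca.records:
            traj = ascending_trajectory(rec.smoothed, trial_obj, rec.events)
            bh = brace_exclusions([brace_height(traj)])[0]
            udf = deltaf.get(rec.unit_id)
            unit_trial_rows.append(
                {
                    "participant_id": pid, "intensity": intensity, "trial": trial,
                    "unit_id": rec.unit_id,
                    "rt_pct": rec.events.recruitment_threshold_pct,
                    "derecruit_pct": rec.events.derecruitment_torque_pct,
                    "peak_dr_pps": rec.events.peak_discharge_pps,
                    "n_spikes": 0,  # filled from the raw trains below
                    "delta_f_pps": None if udf is None else udf.delta_f_pps,
                    "n_controls": 0 if udf is None else udf.n_controls,
                    "brace_pct_rtri": bh.brace_pct_rtri,
                    "brace_excluded": bh.excluded,
                    "brace_reason": bh.reason,
                }
            )
    # n_spikes needs the raw trains
    spikes_by = {(st.trial_key, st.unit_id): st.n_spikes for st in ds.spike_trains}
    for row in unit_trial_rows:
        key = ((row["participant_id"], round(row["intensity"], 2), row["trial"]),
               row["unit_id"])
        row["n_spikes"] = spikes_by.get(key, 0)

    unit_trials = pd.DataFrame(unit_trial_rows)
    pairs = pd.DataFrame(pair_rows)
    if unit_trials.empty:
        return unit_trials, pairs, counts

    units = _aggregate_unit_intensity(unit_trials, config)
    counts["unit_intensities"] = len(units)
    counts["deltaf_units"] = int(units["delta_f_pps"].notna().sum())
    counts["brace_included"] = int((~units["brace_excluded"].astype(bool)).sum())
    counts["brace_excluded"] = int(units["brace_excluded"].astype(bool).sum())
    counts["above_bin_ceiling"] = int(units["bin"].isna().sum())
    counts["eligible_pairs"] = int(pairs["eligible"].sum()) if len(pairs) else 0
    return units, pairs, counts


def _aggregate_unit_intensity(
    unit_trials: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Average per-contraction metrics per unit × intensity (tracked trials)."""
    def agg(sub: pd.DataFrame) -> pd.Series:
        brace_vals = sub.loc[~sub.brace_excluded.astype(bool), "brace_pct_rtri"].dropna()
        rt = float(sub.rt_pct.mean())
        return pd.Series(
            {
                "rt_pct": rt,
                "bin": assign_bin(max(rt, 0.0), config.bin_edges_pct),
                "peak_dr_pps": float(sub.peak_dr_pps.mean()),
                "n_spikes": float(sub.n_spikes.mean()),
                "n_trials": len(sub),
                "delta_f_pps": (
                    float(sub.delta_f_pps.dropna().mean())
                    if sub.delta_f_pps.notna().any() else np.nan
                ),
                "n_controls": int(sub.n_controls.sum()),
                "brace_pct_rtri": float(brace_vals.mean()) if len(brace_vals) else np.nan,
                "brace_excluded": bool(len(brace_vals) == 0),
            }
        )

    units = (
        unit_trials.groupby(["participant_id", "intensity", "unit_id"], sort=True)
        .apply(agg, include_groups=False)
        .reset_index()
    )
    return units


def _join_participants(units: pd.DataFrame, ds: Dataset) -> pd.DataFrame:
    pmeta = pd.DataFrame(
        [
            {
                "participant_id": p.id, "group": p.group, "sex": p.sex,
                "body_mass_kg": p.body_mass_kg, "handgrip_kg": p.handgrip_kg,
                "ugs_ms": p.ugs_ms, "fgs_ms": p.fgs_ms, "tug_s": p.tug_s,
                "fsst_s": p.fsst_s, "ststs_s": p.ststs_s,
                "ststs_w_kg": p.ststs_w_kg, "peak_torque_nm": p.peak_torque_nm,
            }
            for p in ds.participants.values()
        ]
    )
    return units.merge(pmeta, on="participant_id", how="left")


def run_stats_stage(
    units: pd.DataFrame,
    out_dir: Path,
    outcomes: tuple[str, ...] = ("delta_f_pps", "brace_pct_rtri", "peak_dr_pps"),
    bootstrap_B: int = 2000,
    seed: int = 0,
    huber_c: float = 1.345,
) -> dict:
    """Per-bin robust mixed models and association models; writes CSV tables."""
    out_dir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"bin_models": [], "association_models": []}
    for outcome in outcomes:
        for bin_label, sub in units.dropna(subset=["bin"]).groupby("bin"):
            sub = sub.dropna(subset=[outcome])
            try:
                res = fit_bin_model(
                    sub, outcome=outcome, bin_label=str(bin_label),
                    bootstrap_B=bootstrap_B, seed=seed, huber_c=huber_c,
                )
            except ConvergenceError as exc:
                logger.warning("bin model %s/%s skipped: %s", outcome, bin_label, exc)
                continue
            stem = f"{outcome}_{bin_label}".replace("-", "_")
            res.coefficients.to_csv(out_dir / f"coef_{stem}.csv", index=False)
            res.emms.to_csv(out_dir / f"emm_{stem}.csv", index=False)
            pd.DataFrame(
                [
                    {"contrast": c.name, "estimate": c.estimate,
                     "ci_low": c.ci_low, "ci_high": c.ci_high,
                     "excludes_zero": c.excludes_zero}
                    for c in res.contrasts
                ]
            ).to_csv(out_dir / f"contrasts_{stem}.csv", index=False)
            summary["bin_models"].append({"outcome": outcome, "bin": str(bin_label)})
    for measure in ASSOCIATION_MEASURES:
        if measure not in units.columns or units[measure].isna().all():
            continue
        try:
            res = fit_association_model(
                units.dropna(subset=["delta_f_pps"]), measure,
                adjust_body_mass=(measure == "peak_torque_nm"), huber_c=huber_c,
            )
        except (ConvergenceError, ValueError) as exc:
            logger.warning("association model %s skipped: %s", measure, exc)
            continue
        res.slopes.assign(
            predictor=measure, r2m=res.r2_marginal, r2c=res.r2_conditional
        ).to_csv(out_dir / f"association_{measure}.csv", index=False)
        summary["association_models"].append(measure)
    return summary


def run_pipeline(config: dict, out_dir: str | Path) -> RunManifest:
    """Run the full pipeline from a config mapping; returns the manifest.

    Config keys: ``seed``; ``simulate`` (group_sizes, n_trials, intensities,
    pool overrides) OR ``inputs`` (spikes/torque/participants paths);
    ``analysis`` (AnalysisConfig overrides); ``stats`` (bootstrap_B,
    outcomes).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    analysis = AnalysisConfig.from_dict(dict(config.get("analysis", {}), seed=seed))
    manifest = RunManifest(config=dict(config), seed=seed)

    if "inputs" in config:
        paths = {k: Path(v) for k, v in config["inputs"].items()}
        ds = read_dataset(paths["spikes"], paths["torque"], paths["participants"])
        for name, p in paths.items():
            manifest.input_digests[name] = file_digest(p)
    else:
        from .simulate import PoolParams, simulate_cohort, write_ground_truth
        from .io import write_dataset

        sim_cfg = dict(config.get("simulate", {}))
        pool = PoolParams(**sim_cfg.pop("pool", {}))
        ds, truth = simulate_cohort(
            group_sizes=sim_cfg.get("group_sizes"),
            params=pool, seed=seed,
            intensities=tuple(sim_cfg.get("intensities", (0.2, 0.4, 0.6))),
            n_trials=int(sim_cfg.get("n_trials", 3)),
        )
        paths = write_dataset(ds, out / "simulated")
        write_ground_truth(truth, out / "simulated")
        for name, p in paths.items():
            manifest.input_digests[name] = file_digest(p)

    manifest.counts.update({f"input_{k}": v for k, v in ds.counts().items()})
    ds_f = filter_pnr(ds, analysis.pnr_min_db)
    manifest.counts["pnr_excluded"] = ds.n_units - ds_f.n_units

    units, pairs, counts = analyze_dataset(ds_f, analysis)
    manifest.counts.update(counts)
    units = _join_participants(units, ds_f)

    units.to_csv(out / "units.csv", index=False)
    pairs.to_csv(out / "pairs.csv", index=False)
    units[units.delta_f_pps.notna()][
        ["participant_id", "intensity", "unit_id", "rt_pct", "bin",
         "delta_f_pps", "n_controls"]
    ].to_csv(out / "deltaf.csv", index=False)
    units[
        ["participant_id", "intensity", "unit_id", "rt_pct", "bin",
         "brace_pct_rtri", "brace_excluded"]
    ].to_csv(out / "brace.csv", index=False)

    stats_cfg = dict(config.get("stats", {}))
    if stats_cfg.get("enabled", True) and not units.empty:
        run_stats_stage(
            units, out / "stats",
            outcomes=tuple(stats_cfg.get("outcomes",
                                         ("delta_f_pps", "brace_pct_rtri", "peak_dr_pps"))),
            bootstrap_B=int(stats_cfg.get("bootstrap_B", 2000)),
            seed=seed,
        )

    # unit-count conservation check
    c = manifest.counts
    assert c["input_spike_trains"] == (
        c["pnr_excluded"] + c["too_few_spikes"] + c["unsmoothable"]
        + c["analyzed_unit_trials"]
    ), "unit-count conservation violated"

    (out / "manifest.json").write_text(manifest.to_json())
    logger.info("pipeline complete: %s", json.dumps(manifest.counts))
    return manifest
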