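"""Run orchestration: configuration, result bundles and the study grid.

:func:`run_experiment` executes one configured simulation and writes its
time series, beat table, metric summary and PV loops as CSV;
:func:`reproduce_study` runs the full 2 groups x 2 conditions x
(baseline + 4 devices) grid and emits the three reproduction tables:
the baseline hemodynamic panel with validity flags, the pump operating
points, and the pooled percent-change report.

Pump speeds default to the reported operating points (rest-optimized per
group and inflow site); they can be overridden or re-derived with
:func:`hfpefsim.devices.select_pump_speed`.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd

from .analysis import (HemodynamicSummary, beat_metrics, percent_changes,
                       pv_loop, validity_check, PANEL_METRICS)
from .baroreflex import apply_exercise, group_baroreflex
from .calibration import LITERATURE_TARGETS, SIMULATION_REFERENCE
from .devices import DeviceConfig, copulse, iasd, no_device, rbp
from .network import SolverSettings, run_to_steady_state
from .parameters import group_preset

logger = logging.getLogger("hfpefsim")

#: Rest-optimized pump speeds (rpm) per (group, inflow site).
DEFAULT_PUMP_SPEEDS: Dict[Tuple[int, str], float] = {
    (1, "lv"): 5000.0, (1, "la"): 5300.0,
    (2, "lv"): 5700.0, (2, "la"): 5900.0,
}

#: Reported pump flows (l/min) at those speeds, (rest, exercise).
REFERENCE_PUMP_FLOWS: Dict[Tuple[int, str], Tuple[float, float]] = {
    (1, "lv"): (3.5, 4.1), (1, "la"): (2.1, 2.5),
    (2, "lv"): (5.0, 4.9), (2, "la"): (3.0, 2.5),
}

DEVICE_LABELS = ("baseline", "iasd", "rbp_lv", "rbp_la", "copulse")


@dataclass
class RunConfig:
    """Validated description of one simulation run."""

    group: int = 1
    condition: str = "rest"
    device: str = "baseline"
    pump_speed: Optional[float] = None     # rpm; None -> reported default
    outdir: Optional[str] = None
    seed: int = 0                          # reserved for stochastic add-ons
    settings: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self) -> None:
        if self.group not in (1, 2):
            raise ValueError("group must be 1 or 2")
        if self.condition not in ("rest", "exercise"):
            raise ValueError("condition must be 'rest' or 'exercise'")
        if self.device not in DEVICE_LABELS:
            raise ValueError(f"device must be one of {DEVICE_LABELS}")

    def device_config(self) -> DeviceConfig:
        if self.device == "baseline":
            return no_device()
        if self.device == "iasd":
            return iasd()
        if self.device == "copulse":
            return copulse()
        inflow = self.device.split("_")[1]
        speed = self.pump_speed or DEFAULT_PUMP_SPEEDS[(self.group, inflow)]
        return rbp(inflow, speed)

    def provenance(self) -> str:
        # hash the scientific configuration only, not output locations
        payload = {k: v for k, v in asdict(self).items()
                   if k not in ("settings", "outdir")}
        payload["settings"] = asdict(self.settings)
        digest = hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]
        return f"config_sha={digest} {json.dumps(payload, sort_keys=True)}"


def _configure(config: RunConfig):
    params = group_preset(config.group)
    baro = group_baroreflex(config.group)
    if config.condition == "exercise":
        baro, params = apply_exercise(baro, params, config.group)
    return params, baro


def run_experiment(config: RunConfig):
    """Run one configuration; optionally write the result bundle to disk.

    Returns ``(solution, summary)``.  With ``config.outdir`` set, writes
    ``timeseries.csv``, ``beats.csv``, ``summary.csv`` and
    ``pvloops.csv``, each carrying the config hash in a header comment.
    """
    params, baro = _configure(config)
    sol = run_to_steady_state(params, baro, config.device_config(),
                              config.settings)
    summary = beat_metrics(sol)
    summary.group = config.group
    summary.condition = config.condition
    summary.device = config.device
    if not sol.converged:
        logger.warning("run %s/%s/%s did not converge within the beat budget",
                       config.group, config.condition, config.device)

    if config.outdir:
        out = Path(config.outdir)
        out.mkdir(parents=True, exist_ok=True)
        prov = config.provenance()
        sol.to_csv(out / "timeseries.csv", provenance=prov)
        with open(out / "beats.csv", "w") as fh:
            fh.write(f"# {prov}\n")
            sol.beats.to_csv(fh, index=False)
        srow = {"group": config.group, "condition": config.condition,
                "device": config.device, **summary.as_dict(),
                "rvsw": summary.rvsw,
                "mean_device_flow": summary.mean_device_flow,
                "min_device_flow": summary.min_device_flow,
                "converged": summary.converged}
        with open(out / "summary.csv", "w") as fh:
            fh.write(f"# {prov}\n")
            pd.DataFrame([srow]).to_csv(fh, index=False)
        loops = []
        for chamber in ("lv", "rv", "la", "ra"):
            loop = pv_loop(sol, chamber)
            loops.append(pd.DataFrame({"chamber": chamber,
                                       "volume": loop.volume,
                                       "pressure": loop.pressure}))
        with open(out / "pvloops.csv", "w") as fh:
            fh.write(f"# {prov}\n")
            pd.concat(loops).to_csv(fh, index=False)
    return sol, summary


def run_grid(settings: Optional[SolverSettings] = None, devices=DEVICE_LABELS):
    """Run the full study grid; returns summaries keyed by
    (group, condition, device) with baselines under device='baseline'."""
    settings = settings or SolverSettings()
    summaries: Dict[Tuple[int, str, str], HemodynamicSummary] = {}
    failures = []
    for group in (1, 2):
        for condition in ("rest", "exercise"):
            for device in devices:
                cfg = RunConfig(group=group, condition=condition,
                                device=device, settings=settings)
                try:
                    _, summary = run_experiment(cfg)
                    summaries[(group, condition, device)] = summary
                except Exception as exc:  # collect, keep going
                    logger.error("grid cell %s failed: %s",
                                 (group, condition, device), exc)
                    failures.append(((group, condition, device), str(exc)))
    return summaries, failures


def reproduce_study(outdir, settings: Optional[SolverSettings] = None):
    """Run the grid and write the three reproduction tables as CSV.

    ``baseline_panel.csv`` -- simulated baseline panel per group and
    condition beside the literature targets, with validity flags;
    ``pump_operating_points.csv`` -- speeds and mean/min pump flows;
    ``percent_changes.csv`` -- per-run percent changes and pooled
    mean +/- SD rows.  Per-cell failures are collected, not fatal.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summaries, failures = run_grid(settings)

    rows = []
    for (group, condition), ref in SIMULATION_REFERENCE.items():
        summ = summaries.get((group, condition, "baseline"))
        if summ is None:
            continue
        targets = LITERATURE_TARGETS[(group, condition)]
        flags = validity_check(summ, targets)
        for m in PANEL_METRICS:
            lit = targets.metric(m)
            rows.append({
                "group": group, "condition": condition, "metric": m,
                "simulated": round(getattr(summ, m), 2),
                "reference_simulation": ref[m],
                "literature": lit.value if lit else None,
                "within_validity": flags[m],
            })
    pd.DataFrame(rows).to_csv(out / "baseline_panel.csv", index=False)

    rows = []
    for (group, inflow), speed in DEFAULT_PUMP_SPEEDS.items():
        for condition in ("rest", "exercise"):
            summ = summaries.get((group, condition, f"rbp_{inflow}"))
            if summ is None:
                continue
            ref = REFERENCE_PUMP_FLOWS[(group, inflow)][
                0 if condition == "rest" else 1]
            rows.append({
                "group": group, "inflow": inflow, "condition": condition,
                "speed_rpm": speed,
                "mean_flow_lmin": round(summ.mean_device_flow, 2),
                "min_flow_lmin": round(summ.min_device_flow, 2),
                "reference_flow_lmin": ref,
            })
    pd.DataFrame(rows).to_csv(out / "pump_operating_points.csv", index=False)

    device_summaries = {k: v for k, v in summaries.items()
                        if k[2] != "baseline"}
    baselines = {(g, c): v for (g, c, d), v in summaries.items()
                 if d == "baseline"}
    panel = percent_changes(device_summaries, baselines)
    pool_rows = [{"metric": m, "scope": s, "mean": round(mean, 2),
                  "sd": round(sd, 2), "n": n}
                 for (m, s), (mean, sd, n) in sorted(panel.pools.items())]
    with open(out / "percent_changes.csv", "w") as fh:
        panel.table.round(2).to_csv(fh, index=False)
    pd.DataFrame(pool_rows).to_csv(out / "percent_change_pools.csv", index=False)

    if failures:
        pd.DataFrame(failures, columns=["cell", "error"]).to_csv(
            out / "failures.csv", index=False)
    return summaries, panel, failures
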