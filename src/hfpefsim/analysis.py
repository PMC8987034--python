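"""Beat-wise metric extraction, PV loops, stroke work and percent changes.

The converged final beats of a run are condensed into the standard
hemodynamic panel (EDV, ESV, EF, MAP, HR, RAP, PAP, LAP, CO, RVSW plus
device flows).  Cardiac output is reported as *systemic* output -- the
mean flow delivered into the systemic arterial tree -- so recirculation
through an interatrial shunt lowers it while pump output raises it.
PCWP is equated to mean left atrial pressure.

Percent changes against the matched baseline are pooled the way the
study reports them: per device over the four (group x condition) cells,
over the three mechanical support devices (12 values), or over all four
devices (16 values), as mean +/- SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .network import PeriodicSolution

#: Metrics of the standard panel, in reporting order.
PANEL_METRICS = ("edv", "esv", "ef", "map", "hr", "rap", "pap", "lap", "co")


@dataclass
class HemodynamicSummary:
    """Beat-averaged metric panel of one converged run."""

    edv: float           # ml
    esv: float           # ml
    ef: float            # %
    map: float           # mmHg
    hr: float            # bpm
    rap: float           # mmHg
    pap: float           # mmHg
    lap: float           # mmHg
    co: float            # l/min, systemic
    rvsw: float          # mmHg*ml
    mean_device_flow: float = 0.0   # l/min (pump or shunt)
    min_device_flow: float = 0.0    # l/min (pump trough; 0 if no pump)
    group: Optional[int] = None
    condition: Optional[str] = None
    device: Optional[str] = None
    converged: bool = True

    def as_dict(self) -> Dict[str, float]:
        return {m: getattr(self, m) for m in PANEL_METRICS}


@dataclass
class PVLoop:
    """Ordered (volume, pressure) samples of one beat for one chamber."""

    volume: np.ndarray
    pressure: np.ndarray
    chamber: str = "lv"

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.volume.shape != self.pressure.shape or self.volume.ndim != 1:
            raise ValueError("volume and pressure must be 1-D arrays of equal length")
        if len(self.volume) < 4:
            raise ValueError("degenerate loop: need at least 4 samples")

    def is_closed(self, rel_tol: float = 0.10) -> bool:
        vspan = np.ptp(self.volume)
        pspan = np.ptp(self.pressure)
        if vspan == 0 or pspan == 0:
            return False
        dv = abs(self.volume[0] - self.volume[-1]) / vspan
        dp = abs(self.pressure[0] - self.pressure[-1]) / pspan
        return dv < rel_tol and dp < rel_tol


def pv_loop(sol: PeriodicSolution, chamber: str = "rv", beat: int = -1) -> PVLoop:
    """Extract the PV loop of one recorded beat from a solution."""
    cols = {"lv": ("v_lv", "p_lv"), "rv": ("v_rv", "p_rv"),
            "la": ("v_la", "p_la"), "ra": ("v_ra", "p_ra")}
    if chamber not in cols:
        raise ValueError(f"unknown chamber {chamber!r}")
    starts = sol.beat_starts()
    bounds = list(starts) + [len(sol.data)]
    idx = range(bounds[beat], bounds[beat + 1]) if beat != -1 else \
        range(bounds[-2], bounds[-1])
    vcol, pcol = cols[chamber]
    return PVLoop(sol.data[vcol].to_numpy()[list(idx)],
                  sol.data[pcol].to_numpy()[list(idx)], chamber)


def loop_area(loop: PVLoop) -> float:
    """Signed-area magnitude of a closed PV loop via the shoelace formula."""
    if not loop.is_closed():
        raise ValueError("open or degenerate PV loop")
    v = np.append(loop.volume, loop.volume[0])
    p = np.append(loop.pressure, loop.pressure[0])
    area = 0.5 * np.sum(v[:-1] * p[1:] - v[1:] * p[:-1])
    return abs(float(area))


def rv_stroke_work(loop: PVLoop) -> float:
    """Right-ventricular stroke work (mmHg*ml): area of the RV PV loop.

    Orientation-independent; reversing the traversal direction yields the
    same magnitude.
    """
    return loop_area(loop)


def beat_metrics(sol: PeriodicSolution) -> HemodynamicSummary:
    """Condense the recorded final beats into the standard metric panel.

    EDV/ESV are per-beat LV volume extrema averaged over the recorded
    beats; pressures are time means; CO is the mean flow into the
    systemic arterial branches.  An unconverged solution is flagged on
    the summary, never silently averaged away.
    """
    d = sol.data
    if len(d) == 0:
        raise ValueError("solution contains no recorded samples")
    starts = sol.beat_starts()
    bounds = list(starts) + [len(d)]

    edvs, esvs, rvsws = [], [], []
    for i in range(len(bounds) - 1):
        seg = d.iloc[bounds[i]:bounds[i + 1]]
        edvs.append(seg["v_lv"].max())
        esvs.append(seg["v_lv"].min())
        rvloop = PVLoop(seg["v_rv"].to_numpy(), seg["p_rv"].to_numpy(), "rv")
        if rvloop.is_closed():
            rvsws.append(loop_area(rvloop))
    edv = float(np.mean(edvs))
    esv = float(np.mean(esvs))
    period = float(d["period"].mean())

    kind = sol.device.kind
    if kind in ("rbp_lv", "rbp_la"):
        dev_mean = float(d["q_pump_alg"].mean()) * 0.06
        dev_min = float(d["q_pump_alg"].min()) * 0.06
    elif kind == "iasd":
        dev_mean = float(d["q_iasd"].mean()) * 0.06
        dev_min = float(d["q_iasd"].min()) * 0.06
    else:
        dev_mean = 0.0
        dev_min = 0.0

    return HemodynamicSummary(
        edv=edv,
        esv=esv,
        ef=100.0 * (edv - esv) / edv if edv > 0 else 0.0,
        map=float(d["p_ao"].mean()),
        hr=60.0 / period,
        rap=float(d["p_ra"].mean()),
        pap=float(d["p_pa"].mean()),
        lap=float(d["p_la"].mean()),
        co=float(d["q_sys"].mean()) * 0.06,
        rvsw=float(np.mean(rvsws)) if rvsws else float("nan"),
        mean_device_flow=dev_mean,
        min_device_flow=dev_min,
        device=kind,
        converged=sol.converged,
    )


# ---------------------------------------------------------------------------
# percent changes and pooling
# ---------------------------------------------------------------------------

#: Metrics pooled in the percent-change report.
CHANGE_METRICS = ("edv", "esv", "ef", "map", "hr", "rap", "pap", "lap",
                  "co", "rvsw")

MCS_DEVICES = ("rbp_lv", "rbp_la", "copulse")
ALL_DEVICES = ("iasd", "rbp_lv", "rbp_la", "copulse")


@dataclass
class PercentChangePanel:
    """Per-run percent changes vs baseline and their pooled summaries.

    ``table`` holds one row per (group, condition, device) with the
    percent change of every metric; ``pools`` maps a pool label such as
    ``("lap", "all")`` or ``("co", "rbp_lv")`` to (mean, sd, n).
    """

    table: pd.DataFrame
    pools: Dict[Tuple[str, str], Tuple[float, float, int]] = field(default_factory=dict)

    def pool(self, metric: str, scope: str) -> Tuple[float, float, int]:
        return self.pools[(metric, scope)]


def percent_changes(
    device_summaries: Mapping[Tuple[int, str, str], HemodynamicSummary],
    baseline_summaries: Mapping[Tuple[int, str], HemodynamicSummary],
) -> PercentChangePanel:
    """Percent change of each metric vs the matched (group, condition)
    baseline, with the study's pooled mean +/- SD aggregates.

    Raises on a device run whose matching baseline is missing.
    """
    rows = []
    for (group, condition, device), summ in device_summaries.items():
        key = (group, condition)
        if key not in baseline_summaries:
            raise KeyError(f"no baseline for (group={group}, condition={condition})")
        base = baseline_summaries[key]
        row = {"group": group, "condition": condition, "device": device}
        for m in CHANGE_METRICS:
            b = getattr(base, m)
            v = getattr(summ, m)
            row[m] = 100.0 * (v - b) / b if b != 0 else np.nan
        rows.append(row)
    table = pd.DataFrame(rows)

    pools: Dict[Tuple[str, str], Tuple[float, float, int]] = {}
    scopes = {d: (d,) for d in table["device"].unique()}
    scopes["mcs"] = MCS_DEVICES
    scopes["all"] = ALL_DEVICES
    for m in CHANGE_METRICS:
        for label, devs in scopes.items():
            vals = table.loc[table["device"].isin(devs), m].to_numpy(dtype=float)
            if len(vals) == 0:
                continue
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            pools[(m, label)] = (float(np.mean(vals)), sd, len(vals))
    return PercentChangePanel(table=table, pools=pools)


# ---------------------------------------------------------------------------
# validity against literature dispersion
# ---------------------------------------------------------------------------

def validity_check(summary: HemodynamicSummary, targets) -> Dict[str, Optional[bool]]:
    """Flag each metric against the literature dispersion rule.

    A simulated value passes when it lies inside the closed interquartile
    interval (metrics reported as median (IQR)) or within +/- 1.5 SD of
    the mean (metrics reported as mean +/- SD).  Metrics without
    literature data map to ``None``.
    """
    flags: Dict[str, Optional[bool]] = {}
    for m in PANEL_METRICS:
        entry = targets.metric(m)
        if entry is None:
            flags[m] = None
            continue
        lo, hi = entry.validity_interval()
        flags[m] = bool(lo <= getattr(summary, m) <= hi)
    return flags
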