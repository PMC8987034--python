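"""Synthetic literature-style target panels and known-truth phenotypes.

Two generators make the calibration pipeline testable without external
data:

* :func:`sample_target_panel` draws a random but internally consistent
  hemodynamic panel around a literature panel's dispersions (ejection
  fraction is recomputed from the drawn volumes; draws violating the
  panel invariants are rejected and resampled);

* :func:`model_forward_phenotype` builds a virtual patient with *known*
  circulation parameters (a perturbed phenotype preset), simulates it to
  steady state, perturbs the resulting metric panel with multiplicative
  measurement noise, and returns the panel together with the hidden
  truth -- enabling parameter-recovery experiments for the calibration.

Everything is driven by a seeded generator: the same seed reproduces
the same cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

from .baroreflex import BaroreflexParams, group_baroreflex
from .calibration import HemodynamicTargets, MetricTarget, LITERATURE_TARGETS
from .parameters import CirculationParams, group_preset

#: Truncation of the multiplicative noise at +/- 3 SD.
NOISE_TRUNCATION = 3.0


@dataclass
class PhenotypeSpec:
    """Recipe for one synthetic phenotype draw."""

    seed: int
    group: int = 1
    condition: str = "rest"
    noise_sd: float = 0.05          # fractional measurement noise
    panel_spread: float = 1.0       # multiplier on the literature dispersions
    svr_spread: float = 0.15        # fractional spread of the arteriolar scale
    mcfp_spread: float = 1.5        # mmHg spread of the filling pressure

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _truncated_normal(rng: np.random.Generator, sd: float) -> float:
    """One N(0, sd) draw truncated to +/- NOISE_TRUNCATION * sd."""
    if sd == 0.0:
        return 0.0
    while True:
        x = rng.normal(0.0, sd)
        if abs(x) <= NOISE_TRUNCATION * sd:
            return x


def sample_target_panel(spec: PhenotypeSpec,
                        max_rejections: int = 1000) -> HemodynamicTargets:
    """Draw a consistent literature-style panel around the group's
    dispersions.

    Volumes, pressures, HR and CO are drawn from normal distributions
    centred on the literature panel (IQR metrics use a normal with
    sigma = IQR / 1.349); EF is recomputed from the drawn volumes.  The
    draw is rejected and repeated until the panel invariants hold.
    """
    base = LITERATURE_TARGETS[(spec.group, spec.condition)]
    rng = spec.rng()
    for _ in range(max_rejections):
        metrics: Dict[str, MetricTarget] = {}
        ok = True
        for name, t in base.metrics.items():
            if name == "ef":
                continue
            # IQR panels: a normal with matching quartiles (sigma = IQR/1.349)
            sigma = t.sd if t.kind == "sd" else (t.iqr[1] - t.iqr[0]) / 1.349
            sigma *= spec.panel_spread
            value = t.value + _truncated_normal(rng, sigma)
            if value <= 0:
                ok = False
                break
            metrics[name] = MetricTarget(value, "sd", sd=max(sigma, 0.0))
        if not ok:
            continue
        if "edv" in metrics and "esv" in metrics:
            edv, esv = metrics["edv"].value, metrics["esv"].value
            if not (0 < esv < edv):
                continue
            ef_base = base.metric("ef")
            ef_sd = ef_base.sd if ef_base and ef_base.kind == "sd" else \
                ((ef_base.iqr[1] - ef_base.iqr[0]) / 1.349 if ef_base else 10.0)
            metrics["ef"] = MetricTarget(100.0 * (edv - esv) / edv, "sd", sd=ef_sd)
        try:
            return HemodynamicTargets(metrics=metrics, group=spec.group,
                                      condition=spec.condition)
        except ValueError:
            continue
    raise ValueError(f"no consistent panel within {max_rejections} draws")


@dataclass
class TruthRecord:
    """Hidden ground truth of a model-forward phenotype."""

    params: CirculationParams
    baro: BaroreflexParams
    total_svr: float
    mcfp: float
    metrics: Dict[str, float] = field(default_factory=dict)


def perturbed_phenotype(
    group: int, seed: int,
    svr_spread: float = 0.15, mcfp_spread: float = 1.5,
) -> Tuple[CirculationParams, BaroreflexParams]:
    """A virtual patient: the group preset with perturbed vascular tone
    and filling state.

    The arteriolar resistances are scaled by a common log-normal factor
    and the filling pressure is shifted; the chamber relations stay at
    the phenotype preset (the cohort varies vascular properties).  The
    baroreflex set point is then equilibrated to the patient's own
    resting pressure so the reflex effectors are neutral at rest and the
    nominal filling pressure is the operative one.
    """
    from .network import run_to_steady_state  # local import: avoid cycle
    from .analysis import beat_metrics

    rng = np.random.default_rng(seed)
    f_svr = float(np.exp(_truncated_normal(rng, svr_spread)))
    d_mcfp = _truncated_normal(rng, mcfp_spread)
    params = group_preset(group)
    params = replace(params,
                     rart_ub=params.rart_ub * f_svr,
                     rart_lb=params.rart_lb * f_svr,
                     mcfp=max(params.mcfp + d_mcfp, 6.0))
    baro = group_baroreflex(group)
    # fixed-point equilibration: set point = realized resting MAP + dp0
    for _ in range(2):
        sol = run_to_steady_state(params, baro)
        m = beat_metrics(sol)
        baro = replace(baro, map_setpoint=m.map + baro.dp0)
    return params, baro


def model_forward_phenotype(
    true_params: CirculationParams,
    baro: BaroreflexParams,
    noise_sd: float,
    seed: int,
    group: Optional[int] = None,
) -> Tuple[HemodynamicTargets, TruthRecord]:
    """Simulate a known-truth phenotype and return its noisy panel.

    The converged metric panel is perturbed with multiplicative Gaussian
    noise (truncated at 3 SD); with ``noise_sd = 0`` the panel equals
    the simulated metrics exactly.  The hidden truth record carries the
    generating parameters; different seeds produce different panels for
    the same truth.
    """
    from .network import run_to_steady_state  # local import: avoid cycle
    from .analysis import beat_metrics

    sol = run_to_steady_state(true_params, baro)
    if not sol.converged:
        raise RuntimeError("truth simulation did not converge")
    m = beat_metrics(sol)
    rng = np.random.default_rng(seed)
    noisy: Dict[str, MetricTarget] = {}
    for name in ("edv", "esv", "map", "hr", "rap", "pap", "lap", "co"):
        value = getattr(m, name) * (1.0 + _truncated_normal(rng, noise_sd))
        noisy[name] = MetricTarget(value, "sd", sd=max(abs(value) * max(noise_sd, 0.02), 1e-6))
    edv, esv = noisy["edv"].value, noisy["esv"].value
    noisy["ef"] = MetricTarget(100.0 * (edv - esv) / edv, "sd",
                               sd=max(noise_sd * 100.0, 2.0))
    targets = HemodynamicTargets(metrics=noisy, group=group,
                                 condition="rest")
    truth = TruthRecord(params=true_params, baro=baro,
                        total_svr=true_params.total_svr(),
                        mcfp=true_params.mcfp, metrics=m.as_dict())
    return targets, truth


def recovery_experiment(
    n_phenotypes: int = 20,
    group: int = 1,
    noise_sd: float = 0.05,
    seed: int = 7,
    fit_chambers: bool = False,
    fit_compliances: bool = False,
):
    """Calibrate against ``n`` model-forward phenotypes and report errors.

    Returns a list of dicts with the relative total-SVR error and the
    absolute MCFP error of each recovered parameter set.  The chamber
    relations are held at the phenotype preset by default, matching how
    the cohort is generated (vascular variation only).
    """
    from .calibration import calibrate_from_targets, RefineSettings

    results = []
    for i in range(n_phenotypes):
        params, baro = perturbed_phenotype(group, seed + 1000 * i)
        targets, truth = model_forward_phenotype(
            params, baro, noise_sd, seed + 1000 * i + 500, group=group)
        report = calibrate_from_targets(
            targets, group, fit_chambers=fit_chambers,
            fit_compliances=fit_compliances,
            settings=RefineSettings(max_iterations=8))
        rec = report.params
        results.append({
            "svr_rel_error": (rec.total_svr() - truth.total_svr) / truth.total_svr,
            "mcfp_abs_error": rec.mcfp - truth.mcfp,
            "converged": report.converged,
            "iterations": report.iterations,
        })
    return results
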