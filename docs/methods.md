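# Methods

`hfpefsim` is a closed-loop, lumped-parameter (0-D) model of the human
circulation configured for two hemodynamic phenotypes of heart failure
with preserved ejection fraction (HFpEF), with a simplified baroreflex
that produces an autoregulated exercise response, and with models of four
device therapies. This note describes the model, its assumptions, the
parameters that matter, the numerical choices, and what the synthetic
cohort does and does not show.

## Cardiovascular model

**Chambers.** All four heart chambers are time-varying elastance elements.
Instantaneous ventricular pressure interpolates between two bounding
relations,

    P(V, t) = e(t) · P_es(V) + (1 − e(t)) · P_ed(V),

with the end-systolic pressure–volume relation (ESPVR) a downward
parabola with vertex (V_sys, P_sys) crossing the volume axis at V_0 = 0,

    P_es(V) = P_sys · [1 − ((V_sys − V) / V_sys)²],

clipped at zero beyond the far root, and the end-diastolic relation
(EDPVR) the empirical power law P_ed(V) = α·V^β. The HFpEF phenotype
enters through a stiff LV EDPVR (high operating pressures at small
volumes) and a prolonged early-relaxation time constant τ = 54 ms.

**Activation.** e(t) rises as a squared sine over the systolic interval
0.3·√T (T the heart period), holds a 70 ms plateau at 1, and decays
exponentially with τ = 54 ms. The plateau lets ejection ride the ESPVR
down as aortic pressure decays; without it the end-systolic volume stays
~10–15% above the calibration targets. The atria are EDPVR chambers with
a superimposed active elastance ("kick") timed 120 ms before ventricular
onset (rise 60 ms, decay 30 ms). The left atrial kick is strong
(1.0 mmHg/ml peak): it delivers the final ~10 ml of LV filling at an
end-diastolic LV pressure of ~24 mmHg while the mean left atrial pressure
stays near 16 mmHg — the signature "a-wave dependence" of the stiff
HFpEF ventricle. The right atrial kick against the compliant RV is weak
(0.04 mmHg/ml). The right-ventricular EDPVR is not part of the published
parameter set; α = 3.3e−6 / 3.9e−6 (groups 1/2) with β = 3 were
calibrated so that right atrial pressure, pulmonary pressures and output
are mutually consistent with the phenotype targets.

**Network.** Ascending aorta and pulmonary trunk are 3-element
Windkessels (characteristic resistance, compliance, inertance) feeding
parallel upper/lower-body and left/right-lung branches, each a 3-element
arterial plus 2-element venous compartment, closing on the right and
left atrium respectively. Valves are ideal diodes in series with their
R (and L for the ventricular inflow and outflow tracts): the flow state
integrates L·dq/dt = ΔP − R·q while forward-biased and is clamped at
zero otherwise, so closed valves leak nothing and regurgitation is
structurally impossible. Total vascular compliance is 120 ml/mmHg; the
filling state is set by the mean circulatory filling pressure (MCFP),
the uniform zero-flow pressure that fixes the total stressed volume
(12.7 / 14.3 mmHg at rest for groups 1 / 2).

## Baroreflex and exercise

A single afferent signal — the error dP between an arterial set point
and the measured mean arterial pressure — drives three effectors: heart
period through a bounded sigmoid (limits T_min/T_max, gain G_HR per
phenotype), systemic arteriolar resistance (+1% per mmHg), and a shift
of unstressed into stressed venous volume (130 / 75 ml per mmHg for
groups 1 / 2, saturating at ±2 l). Effectors follow first-order dynamics
(τ = 2 s). The afferent pressure is the mean arterial pressure of the
last completed beat, exponentially smoothed across beats with the same
2 s constant: a beat mean is free of pulse-phase bias (a filtered
instantaneous pressure sampled at beat boundaries reads ~1 mmHg low,
biasing HR by ~+4 bpm), and the smoothing damps the discrete HR
feedback, which otherwise limit-cycles under continuous-flow pump
support.

The set point is not printed in the source material; it is taken as the
resting arterial pressure plus the sigmoid offset dP0 that reproduces
the resting heart rate (so the resting operating point sits slightly
below the set point, as a real baroreflex does), with a +2 mmHg
calibration trim for group 1. The resistance and volume effectors are
referenced to that resting offset, making the calibrated resting
parameter set the effector-neutral equilibrium. Exercise is triggered by
dropping the systemic arteriolar resistances 45% and raising the set
point 32% / 30% (groups 1 / 2); the reflex then closes the loop —
tachycardia, partial vasoconstriction, and recruitment of ~1.4–1.9 l of
stressed volume, which drives the exercise rise in filling pressures.

## Device models

* **Interatrial shunt (IASD):** a fixed 0.1 mmHg·s/ml orifice between
  the atria (~8 mm); bidirectional Ohmic flow.
* **Rotary blood pump (LV-VAD / LA-VAD):** HeartMate 3-class centrifugal
  pump from LV apex or left atrium to the ascending aorta. Static head
  H = a·ω² − b·q·|q| (a = 3.6 mmHg/krpm², b = 1.5 mmHg/(l/min)², the
  affinity-law speed scaling) in series with an effective inertance of
  0.05 mmHg·s²/ml lumping fluid and rotor-control dynamics; backflow is
  admitted. The original pump model is published elsewhere and not
  reproduced here; these coefficients are a calibrated stand-in chosen
  within centrifugal-pump physics to reproduce the reported operating
  points. Speed selection (smallest 100-rpm step meeting mean LAP
  < 10 mmHg and no diastolic backflow at rest) reproduces the reported
  5000 rpm (group 1, LV inflow) and 5900 rpm (group 2, LA inflow)
  exactly. A suction guard brakes pump inflow when the source chamber
  falls below 3 ml; it is inactive at all reported operating points.
* **Co-pulsating chamber (CoPulse):** a valveless 30 ml chamber on a
  single LV-apex cannula. The chamber empties into the LV with the
  systolic activation rise, lagging it by a 70 ms drive delay so the
  tail of the ejected volume arrives around aortic valve closure
  (which is what elevates end-systolic volume by a few percent, as
  observed), and refills from the LV along a half-cosine spread over the
  whole diastole, so it never sucks the relaxing ventricle dry. Net
  cannula flow per beat is zero; displaced volume is stroke × HR, hence
  more unloading at higher heart rates.

Devices move blood, never create it: total blood volume (circulation
plus device chamber, minus the reflex volume recruited from the
unstressed reserve) is conserved to < 0.1 ml over hundreds of beats.

## Calibration

Phenotype parametrization follows four steps — (1) vascular resistances
from mean pressures and flows by Ohm's law, allocated to branches in
preset proportions; (2) MCFP initialised from Guyton's venous-return
relation RAP + CO·0.07; (3) chamber PV relations through the reported
volumes (end-systolic pressure ≈ 0.9 × systolic pressure with systolic
pressure 1.35 × MAP; vertex volume 1.4 × EDV; EDPVR through
(EDV, LAP + 5) with the exponent anchored by the Klotz V30
construction); (4) compliances from stroke volume / pulse pressure
within the 120 ml/mmHg budget — followed by an iterative refinement that
simulates the closed loop and applies damped updates until every metric
lies inside the literature validity interval (the IQR, or mean ± 1.5 SD)
and the residuals are below tolerance, retaining a full audit trail.

One identifiability point matters: under the active reflex, cardiac
output is nearly flat in MCFP (measured 0.011 l/min per mmHg — the
volume effector buffers it), while the resting filling pressures respond
strongly (RAP + LAP combined ≈ 1.4 mmHg per mmHg, measured). The
refinement therefore identifies MCFP from the filling-pressure residual
and simultaneously folds any standing reflex volume shift back into the
nominal filling state, so the recovered MCFP is the operative one.

## Synthetic cohort

The cohort module generates (a) literature-style target panels drawn
around the published dispersions (IQR panels mapped to a normal with
matching quartiles; EF recomputed from the drawn volumes;
rejection-resampling enforces panel consistency) and (b) known-truth
virtual patients: the phenotype preset with a log-normal arteriolar
scale (σ = 15%) and a shifted MCFP (σ = 1.5 mmHg), set point
re-equilibrated so the reflex is neutral at the patient's own rest,
simulated forward and reported with multiplicative measurement noise
(truncated at 3σ). Everything is reproducible from a single seed.

What this emulates: measurement spread and vascular/filling heterogeneity
around a fixed chamber phenotype. What it does not: chamber-property
heterogeneity, inter-metric correlation structure of real cohorts, or
measurement bias — so a passing recovery experiment shows the
calibration is consistent and well-conditioned for vascular tone and
filling state, not that it would recover arbitrary patient physiology.

## Numerics

Fixed-step classical RK4 at dt = 0.25 ms (the fastest network time
constant is ~2 ms; halving dt changes beat metrics by < 0.05%), output
recorded at 1 ms. Runs are bit-reproducible. Steady state is declared
when stroke volume, MAP and LAP all change < 0.5% beat-to-beat over 5
consecutive beats (earliest at beat 25, so the slow effectors have
loaded; cap 300 beats, non-convergence flagged, with the final beats
recorded regardless). Metrics are computed over the 5 recorded beats.
The full 20-run study grid takes well under a minute of CPU after JIT
compilation; the 20-phenotype recovery experiment a few minutes.

## Known limitations

* The model understates left-sided congestion during exercise, most
  visibly in group 1: exercise LAP converges ~15–18% below the
  reproduction target (though inside the literature IQR), which
  propagates to the exercise shunt flow, the group 1 LA-VAD exercise
  pump flow, and the pooled IASD effects (CO reduction 4.9% vs 5.6%,
  LAP reduction 19% vs >20%). The missing mechanism is most likely
  exercise inotropy, which the modelled exercise trigger (vasodilation
  plus set-point rise) does not include; notably, the reported exercise
  pulmonary pressures require right-ventricular pressures at the ceiling
  of the printed resting RV ESPVR.
* The atrial contraction model (strength, timing) is a calibration
  construct — no atrial systolic parameters are published for these
  phenotypes.
* The pump coefficients are a calibrated stand-in for the original,
  separately published pump model; instantaneous pump waveforms should
  be read qualitatively (the diastolic backflow of the group 2 LA-VAD at
  exercise is reproduced in sign and order of magnitude, −0.5 vs −0.9
  l/min troughs).
* Long-term volume regulation, respiration, posture, wave propagation
  and ventricular interaction are outside the model class.
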