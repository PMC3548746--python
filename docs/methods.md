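# Methods

## Scope and model overview

`ergokinetics` simulates whole-body energy turnover during exercise as a
chain of four coupled stages driven by a single exogenous input, the virtual
steady-state metabolic power `Q̄vir(t)` — the metabolic power the current work
rate would require if it could be met under purely aerobic conditions.
`Q̄vir` may exceed the maximal aerobic power `Qmax`; everything downstream is
derived from it.

1. **Aerobic kinetics.** The virtual power relaxes toward its target with a
   first-order lag, `dQvir/dt = (Q̄vir − Qvir)/τa`, starting from the resting
   power `Qr`. The aerobic power is the clamped output `Qa = min(Qmax, Qvir)`.
   `Qvir` itself integrates unclamped, so a supramaximal bout leaves a memory
   that delays the fall of `Qa` below `Qmax` during recovery. The clamp-aware
   rate `dQa/dt` is defined as the ODE right-hand side except when both
   `Qvir` and the target sit at or above `Qmax`, where it is zero. Only the
   mono-exponential (phase II/III) response is modeled; the short
   cardiodynamic delay and the slow component are out of scope.

2. **Lactate kinetics.** The concentration `C` averaged over the whole
   lactate space obeys a one-compartment balance,
   `dC/dt = p0·D(Qa) − d0·(tanh(χC)/χ)·D(Qa)·(Qmax − Qa)`, with the drive
   `D(Qa) = Qa − α0·s·tanh(Qa/s)`, `s = 0.6·Qmax` (around peak fat
   metabolism). Removal saturates in `C`, which produces a finite closed-form
   steady state `Cs = artanh(x)/χ`, `x = p0χ/(d0(Qmax − Qa))`, only while
   `x < 1`. The boundary defines the lactate threshold
   `QLT = Qmax − p0χ/d0`; above it the modeled concentration grows without
   bound. With the default parameters `QLT = 1655.1 J/s` and
   `QLT/Qmax = 0.88`.

3. **Lactic power.** `QG = m·λ·dC/dt` with `λ = 60 J/(kg·mmol/L)` (3 ml
   O2/kg per mmol/L at 20 J/ml). Its integral telescopes:
   `EG(t0,t) = m·λ·(C(t) − C(t0))` exactly, so lactic energy is evaluated
   from concentration endpoints, never by quadrature.

4. **Alactic (phosphocreatine) power.** Two closures of the power balance
   `Q − Qr = (Qa − Qr) + QG + QCK` are implemented side by side.
   *Model 1* assumes the total work power always equals the virtual
   steady-state work power, giving
   `QCK1 = (ηa/ηCK)[Q̄vir − Qa − (ηG/ηa)QG]` — a generalization of the
   O2-deficit method, to which it reduces when `ηG = ηCK = ηa`.
   *Model 2* ties the alactic power to the aerobic rate of change,
   `QCK2 = θ·dQa/dt`, so `ECK2(t0,t) = θ·(Qa(t) − Qa(t0))` exactly and is
   path-independent.

Recovery bookkeeping: the O2-deficit `EDF` integrates `Q̄vir − Qa`; the
energy depth is `EDB = −EDF` over a recovery interval; EPOC integrates
`Qa − Q̄a` (`Q̄a = min(Qmax, Q̄vir)`); and `EPOC_Alt = τa·(Qa(t1) − Qa(t2))` is
the endpoint shortcut. All three are defined positive during recovery from
elevated `Qa`, the convention under which their subcritical equality holds.

## Parameters

All defaults are the published values fitted to one elite male cross-country
skier (77.5 kg); they are individual, not population, values.

| name | meaning | default | unit |
|---|---|---|---|
| `Qr` | resting metabolic power | 80 | J/s |
| `Qmax` | maximal aerobic power | 1886 | J/s |
| `tau_a` | aerobic e-folding time | 30 | s |
| `eta` | mechanical efficiency | 0.5 | – |
| `eta_a`, `eta_G` | aerobic / glycolytic coupling efficiency | 0.6 | – |
| `eta_CK` | creatine-kinase coupling efficiency | 0.95 | – |
| `theta` | Model-2 constant | 20 | s |
| `c` | virtual-power slope vs work rate | 6.6 | – |
| `lambda_` | lactate energy equivalent | 60 | J/(kg·mmol/L) |
| `E_G0`, `E_CK0` | initial lactic / alactic stores | 870 / 830 | J/kg |
| `chi` | lactate removal saturation | 2.54 | m³/kg |
| `p0` | production scale | 1e-5 | kg/(m³·s)/(J/s) |
| `d0` | removal scale | 1.1e-7 | 1/((J/s)²·s) |
| `alpha0` | drive offset factor | 0.9 | – |
| `C0` | initial concentration | 0.5 | mmol/L |

`theta` is stored as the printed 20 s even though the defining relation
`θ = (ηa/ηCK)·τa` evaluates to 18.95 s; `with_derived_theta()` switches to
the derived value, and the identities that rely on `θ/τa = ηa/ηCK` (e.g. the
EPOC-based anaerobic-energy decomposition) are exact only under that choice.
Similarly `QLT` evaluates to 1655.1 J/s while 1654 J/s is the printed
figure — a 0.07% difference consistent with parameter rounding in the source
values; the package always reports the computed number.

### Units

Powers are metabolic, in J/s. The lactate rate law is evaluated in its
native units (kg/m³, with `χ`, `p0`, `d0` as printed) and converted at a
single canonical point to the interface unit mmol/L, using a lactate molar
mass of 90.08 g/mol (1 mmol/L = 0.09008 kg/m³), which makes the published
0.045 kg/m³ ↔ 0.5 mmol/L correspondence exact at one decimal. The rate law
is nonlinear in `C`, so the conversion point matters and is unique.

## Numerical choices

- **Integrator.** Fixed-step classical RK4, default `dt = 0.1 s`. The system
  is smooth and non-stiff; a fixed step makes runs bit-for-bit reproducible
  and keeps energy columns deterministic. Against the constant-input
  closed form the aerobic trajectory agrees to ~1e-13 relative at this step.
- **Breakpoint alignment.** Each protocol segment is subdivided into
  `ceil(length/dt)` equal steps, so every protocol jump or kink is a grid
  point and no RK4 step or trapezoid straddles a discontinuity. At an
  interior jump the series stores both one-sided limits of `Q̄vir`
  (`Qbar_vir` right, `Qbar_vir_pre` left), and all O2-deficit quadratures
  use the one-sided limits on either side of the jump.
- **Lactate stage coupling.** The lactate ODE is driven by the aerobic
  series on the same grid; the RK4 midpoint stage uses the endpoint average
  of `Qa` (exact for the piecewise-constant protocols, second-order
  otherwise). Tiny negative concentration excursions (< 1e-9 mmol/L) are
  clipped; larger ones abort the run.
- **Energies.** `EG` and `ECK2` come from their exact endpoint closed forms;
  `EDF` (and hence `ECK1`) uses trapezoid quadrature on the grid. Tests that
  compare quadrature against closed forms at 1e-6 relative run at
  `dt = 0.02–0.05 s`, where the trapezoid truncation error is safely below
  the tolerance.
- **Threshold boundary.** The steady-state solver reports "divergent" (a
  typed marker, not `inf`) when the saturation argument `x ≥ 1 − 1e-12`; the
  slack absorbs float round-off when `Qa` is computed as exactly `QLT`.
- **Clamp edge.** `dQa/dt` at `Qvir ≥ Qmax` with a subcritical target is the
  (negative) relaxation rate, so recovery from a supramaximal state resumes
  smoothly; with a supracritical target it is zero (pinned at the clamp).
- **Time-varying efficiencies.** The alternative aerobic form integrates the
  virtual *work* power `Pvir = s(t)·(Qvir − Qr)` with `s(t) = η·ηa(t)` and
  maps back via `Qvir = Qr + Pvir/s(t)`. Under this mapping `Pvir(0) = 0` is
  the same statement as `Qvir(0) = Qr`, and a constant schedule reproduces
  the standard form exactly — which is why that mapping was chosen over
  carrying a second, inconsistent initial condition.

## Protocols

Built-in generators: constant bout, bout + active recovery, sinusoidal
interval exercise (`Q̄vir = Qmax/2 + (Qmax/2)·sin(2πt/T)`, `T = 360 s`), and
the energy-matched continuous protocol (quarter-period sinusoidal ramp to
`Q5 = 0.87·Qmax`, then a hold). Interval and continuous protocols default to
5 periods; the multi-period figures this emulates never state a count, so
the number is configurable. The speed→power front end is a piecewise-linear
interpolation through the skier's published steady-state points
(v1–v8 plus the 1.67 m/s recovery point), linearly extrapolated outside the
measured range. Where the source's running text and figure captions disagree
on the third test speed (2.58 vs 2.64 m/s), the caption value is used, since
the captions carry the `Q̄vir` fractions used everywhere else. Bouts
described only as "to exhaustion" are capped at 600 s and flagged `capped`
in their label — no exhaustion criterion is modeled.

## What the simulations do and do not show

The protocol fixtures reproduce the published study conditions (parameter
values, speeds, durations) rather than new data, so passing tests establish
internal consistency of the implementation — ODE vs closed forms, energy
identities, cycle closure, threshold location, qualitative store shapes —
not agreement with new physiological measurements. Known model limitations:
one lactate compartment (blood and muscle concentrations are not separated,
which the source itself notes misfits high intensities and recovery); no
VO2 slow component; no prolonged (multi-hour) EPOC component in Model 1; no
exhaustion criterion; parameters are athlete-specific and not rescaled
anthropometrically. Below-resting intensities (`Qa < Qr`) make the lactate
drive negative with the default `α0`; the regime was never fitted and the
integrator only logs a warning there.

## Design notes

- Profiles are parameterized by `Q̄vir/Qmax` fractions, not by speed; the
  speed curve is a separate front end, because every downstream equation
  consumes `Q̄vir` only.
- Supra-threshold steady-state queries return a typed marker so callers must
  branch explicitly.
- Store fractions (`1 − E_used/(E0·m)`) are not clamped at 1 during
  recharge; excursions above `1 + 1e-6` are logged, since the source
  narrative implies restoration *to* the initial store but states no
  clamping rule.
- The exponential-saturation variant of the removal term (superseded in the
  source by the tanh form) is intentionally not implemented, nor is
  least-squares fitting of the lactate parameters.
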