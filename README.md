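# ergokinetics

Coupled kinetic models of whole-body exercise bioenergetics: the lag of
aerobic power behind the work rate, blood-lactate accumulation and removal,
and two competing models of the alactic (phosphocreatine) anaerobic power —
packaged as a deterministic simulator with protocol generators for
steady-state, recovery, interval and continuous exercise.

The package is aimed at exercise physiologists and sports scientists who
want to decompose the metabolic power of an exercise bout into its aerobic,
lactic and alactic components, compute O2-deficit and EPOC measures, and
compare interval against continuous training protocols in simulation.

## The model

A work-intensity protocol is expressed as the *virtual steady-state
metabolic power* Q̄vir(t) — the power the work rate would require under
purely aerobic conditions (it may exceed the maximal aerobic power Qmax).
The stages are:

- **Aerobic power** (first-order VO2 kinetics with a ceiling):

      dQvir/dt = (Q̄vir − Qvir)/τa,   Qvir(0) = Qr,   Qa = min(Qmax, Qvir)

- **Blood lactate** (one compartment, saturating removal):

      dC/dt = p0·D(Qa) − d0·(tanh(χC)/χ)·D(Qa)·(Qmax − Qa),
      D(Qa) = Qa − α0·(0.6·Qmax)·tanh(Qa/(0.6·Qmax))

  with closed-form steady state Cs = artanh(x)/χ, x = p0χ/(d0(Qmax − Qa)),
  finite only below the **lactate threshold** QLT = Qmax − p0χ/d0.

- **Lactic anaerobic power** QG = m·λ·dC/dt, energy EG = m·λ·ΔC.

- **Alactic anaerobic power**, two closures of Q − Qr = (Qa−Qr) + QG + QCK:
  *Model 1* (work power linear in work rate, a generalized O2-deficit
  method): QCK1 = (ηa/ηCK)[Q̄vir − Qa − (ηG/ηa)QG];
  *Model 2* (alactic power proportional to the aerobic rate of change):
  QCK2 = θ·dQa/dt, with the exact energy ECK2 = θ·ΔQa.

Default parameters are the published values fitted to one elite
cross-country skier (m = 77.5 kg, Qr = 80 J/s, Qmax = 1886 J/s, τa = 30 s,
η = 0.5, ηa = ηG = 0.6, ηCK = 0.95, θ = 20 s). See `docs/methods.md` for the
full parameter table, unit conventions and numerical choices.

## Worked example

Simulate the skier's 3.08 m/s bout (Q̄vir = 0.87·Qmax) for 800 s followed by
5 min of active recovery at 1.67 m/s (0.47·Qmax):

```python
import ergokinetics as ek

params, lpar = ek.EnergeticsParameters(), ek.LactateParameters()
profile = ek.bout_with_recovery_profile(0.87, 800, 0.47, 300, Qmax=params.Qmax)
result = ek.run_simulation(profile, params, lpar, dt=0.1)
for key, value in ek.summary_report(result).items():
    print(f"{key}: {value:.6g}")
```

prints

```
QLT_J_per_s: 1655.09
QLT_over_Qmax: 0.877567
peak_C_mmol_per_L: 7.14495
terminal_C_mmol_per_L: 1.04174
EDF_total_J: 24193.6
EG_total_J: 2519.08
ECK1_total_J: 13689.2
ECK2_total_J: 16129.1
terminal_EG_frac: 0.962639
terminal_ECK1_frac: 0.787187
terminal_ECK2_frac: 0.749256
EDB_J: 22631
EPOC_J: 22631
EPOC_Alt_J: 22631
```

Reading this: the bout sits just below the lactate threshold
(0.87 < QLT/Qmax ≈ 0.88), so lactate climbs to a peak of ~7.1 mmol/L at the
end of the work phase and falls back toward ~1 mmol/L during recovery
(EG_total is the *net* lactic energy after partial recovery). The
accumulated O2-deficit is ~24.2 kJ; the three recovery measures — energy
depth, EPOC and the endpoint form τa·ΔQa — agree at ~22.6 kJ because the
recovery stays below the Qmax clamp. The terminal store fractions show the
phosphocreatine store still partly depleted after 5 min: ~79% (Model 1) and
~75% (Model 2) of its initial content.

The same run from the shell:

```sh
ergokin simulate --protocol bout_recovery --fraction 0.87 --duration 800 \
    --recovery-fraction 0.47 --recovery-duration 300 --out run.csv
ergokin threshold            # prints QLT: 1655.1 J/s,  QLT/Qmax: 0.88
ergokin fixtures             # the skier's steady-state points as CSV
```

`result.data` is a pandas DataFrame with the full time series (Q̄vir, Qvir,
Qa, C, QG, QCK1, QCK2, cumulative energies, store fractions) for plotting
or export; `ek.write_timeseries(result, "run.csv")` round-trips it with
metadata.

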