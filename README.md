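# breathmech

Breath-by-breath respiratory mechanics monitoring from ventilator waveforms.

Mechanically ventilated patients with ARDS have stiff (high-elastance)
lungs, and clinicians titrate PEEP by tracking respiratory mechanics.
Conventional metrics use inspiratory data only. This package implements an
*expiratory* alternative — the expiratory time-constant model — together
with the two inspiratory estimators used to validate it, and a
single-compartment ventilation simulator that provides ground truth for
end-to-end checks. It is aimed at researchers in respiratory physiology and
biomedical signal processing who work with airway pressure/flow recordings
from volume-controlled ventilation.

## The model

The single-compartment lung model relates airway pressure to flow and
volume:

```
P_aw(t) = R_rs · Q(t) + E_rs · V(t) + P0
```

with `E_rs` (cmH₂O/L) the respiratory-system elastance, `R_rs` (cmH₂O·s/L)
the resistance, and `P0 ≈ PEEP` the offset pressure. During passive
expiration the airway is held at PEEP, so the model collapses to a
first-order decay of flow:

```
Q(t) = Q0 · e^(−K t),      K = E_rs / R_rs = 1 / τ
```

Fitting `(Q0, K)` to each breath's expiratory flow by nonlinear least
squares gives a breath-by-breath mechanics index **K** that needs no
pause manoeuvre and no inspiratory data. While resistance is constant, K is
proportional to elastance: a rising K means a stiffening lung. The fit
starts at the peak expiratory flow and is truncated where flow has covered
95 % of the distance to its end-expiratory equilibrium, excluding the
near-constant tail caused by the expiratory-valve resistance. Expiratory
*pressure* is never used — downstream of the valve it is uninformative.

Two per-breath validators are computed alongside:

* **Static (EIP) mechanics** — from the end-inspiratory pause:
  `E_static = (Pplat − PEEP) / Vt`, `R_static = (PIP − Pplat) / Q`.
* **Integral-based identification** — linear least squares on the running
  integrals of the model equation,
  `∫P_aw = R_rsIB·∫Q + E_rsIB·∫V + P0·t`, stacked over every inspiratory
  sample.

Trend agreement between K and the elastance estimates is summarised by the
squared Pearson correlation R²; fitting quality by the median [IQR]
absolute percentage error between modelled and measured signal.

## Worked example

Simulate a healthy-state staircase recruitment manoeuvre
(PEEP 5–10–15–20–15–10–5 cmH₂O, 30 breaths per step, 5 % channel noise)
and analyse it:

```python
from breathmech import RunConfig
from breathmech.model import RespiratoryMechanics
from breathmech.simulate import phase1_scenario, simulate_protocol

record, truth = simulate_protocol(phase1_scenario(seed=3))
results = RespiratoryMechanics(record, RunConfig()).fit()
print(results.summary())
```

```
Respiratory mechanics results
================================================================
breaths detected: 210   fully clean: 205   flagged: 5
record: 31510 samples @ 50 Hz (630.2 s)

per-breath medians (unflagged breaths)
----------------------------------------------------------------
          K:      4.232 1/s   (IQR 3.929-4.975, n=210)
        tau:     0.2363 s   (IQR 0.201-0.2545, n=210)
   E_static:      22.35 cmH2O/L   (IQR 19.92-25.52, n=210)
   R_static:      7.498 cmH2O.s/L   (IQR 5.806-8.879, n=210)
     E_rsIB:      22.11 cmH2O/L   (IQR 20.05-25.68, n=210)
     R_rsIB:       5.21 cmH2O.s/L   (IQR 4.141-6.031, n=210)
       peep:      10.19 cmH2O   (IQR 5.346-15.14, n=210)

fitting error, median [IQR] % (Overall)
----------------------------------------------------------------
    time-constant:   9.66 [8.11-11.49]  n=210
              eip:   6.30 [5.18-8.01]  n=210
   integral-based:   4.34 [3.88-5.13]  n=210

trend correlation
----------------------------------------------------------------
    K~E_static: R^2 = 0.4876  (n=210, scale=5.1)
      K~E_rsIB: R^2 = 0.6704  (n=210, scale=5.1)
```

Reading the output: all 210 simulated breaths are detected; the fitted
decay rate K is lowest (τ longest, lung most compliant) around the
15 cmH₂O PEEP steps; the integral-based method reconstructs inspiratory
pressure most faithfully (4.3 % median error); and the displayed `scale`
(≈ 5.1 ≈ R_rs) is the least-squares factor that overlays K on the
elastance axis for plotting — it never enters the statistics. Comparing
against the simulator's truth table,
`results.validate_against(truth.table)`, shows the median relative error of
K against E/R is about 3 % under this noise level.

The same pipeline is available from the shell:

```sh
breathmech simulate --scenario phase1 --seed-override 3 --outdir sim/
breathmech analyze  --input sim/waveform.csv --outdir out/
breathmech validate --input sim/waveform.csv --truth sim/truth.csv --outdir out/
```

`analyze` accepts any delimited waveform file with columns
`time_s, pressure_cmH2O, flow_Lps` (remappable via a YAML config).

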