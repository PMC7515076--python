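# hippogamma

An in-silico experiment on the hippocampal trisynaptic loop: can driving the
perforant path with gamma-band trains (40–130 Hz) restore the activity of a
circuit degraded by Alzheimer-like synaptic deletion?

The package simulates a 21-cell DG–CA3–CA1 microcircuit (granule, pyramidal,
basket, O-LM and mossy cells, each a 16-compartment discrete-time neuron with
NMDA-gated LTP), drives it with theta-nested 100 Hz bursts from entorhinal
layer 2 and rhythmic septal (MS-DB) disinhibition at 8 Hz, applies staged
deactivation of perforant-path synapses in DG–CA3, and superimposes periodic
gamma induction. Outcomes are quantified with:

* **burst metrics** — spike count, spikes/burst, burst duration, inter-burst
  interval per principal cell;
* **nonlinear dynamics** — delay-embedding reconstruction (auto-MI delay,
  false-nearest-neighbour dimension), recurrence quantification
  (determinism, diagonal-line Shannon entropy, maxline), maximal Lyapunov
  exponent λ (Rosenstein divergence and a local-Jacobian/QR estimator) and
  Grassberger–Procaccia correlation dimension D2;
* **information flow** — plug-in mutual information and Schreiber transfer
  entropy between binarised spike trains, DG→CA3 and CA3→CA1;
* **group statistics** — normality-screened ANOVA/Kruskal–Wallis with
  Tukey/Dunn–Holm post-hoc tests at α = 0.05.

It is aimed at computational neuroscientists who want a small, fully
reproducible lesion-and-stimulation testbed with the complete analysis chain
(spike statistics → attractor reconstruction → directed information) in one
place. See `docs/methods.md` for the model equations, estimator settings and
known limitations.

## Worked example

```python
from hippogamma import build_circuit, run_batch
from hippogamma.protocols import standard_conditions
from hippogamma.pipeline import metrics_table, nonlinear_table
from hippogamma.spike_metrics import aggregate_metrics

circuit = build_circuit()
conditions = standard_conditions(n_runs=5, base_seed=42)
for name in ("control", "ad", "ad_stim130"):
    recordings, manifest = run_batch(conditions[name], circuit)
    summary = aggregate_metrics(metrics_table(recordings))
    net = summary[summary.region_group == "DG-CA3-CA1"].iloc[0]
    lam = nonlinear_table(recordings[:2])["lyapunov"].mean()
    print(f"{name:11s} spikes={net['n_spikes_mean']:6.1f}  "
          f"spikes/burst={net['mean_spikes_per_burst_mean']:4.2f}  "
          f"burst={net['mean_burst_duration_ms_mean']:4.1f} ms  "
          f"lambda={lam:+.2f}")
```

prints

```
control     spikes= 526.6  spikes/burst=5.94  burst=46.0 ms  lambda=-0.09
ad          spikes= 319.5  spikes/burst=4.06  burst=29.3 ms  lambda=+0.09
ad_stim130  spikes= 576.7  spikes/burst=6.04  burst=46.8 ms  lambda=-0.14
```

Reading: synaptic deletion (`ad`) cuts the mean spike count of the principal
cells by ~40 % and shortens their theta bursts, and the network's mean
maximal Lyapunov exponent turns positive (loss of dynamical stability);
130 Hz stimulation of the perforant path (`ad_stim130`) restores firing to
slightly above control and re-stabilises the dynamics (λ < 0).

A command-line interface wraps the same pipeline:

```sh
hippogamma simulate --condition control --out out/control --seed 1 --runs 5
hippogamma analyze  --in out/control --out out/control_analysis
hippogamma compare  --in out/control_analysis --in out/ad_analysis --report out/report
hippogamma run-study --out out/study --seed 1 --runs 30   # all five conditions
```

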