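# Methods

## The model

`hippogamma` simulates a 21-cell functional (connectionist) model of the
hippocampal trisynaptic loop. The dentate gyrus (DG) holds four granule
cells (G1–G4), two basket cells (B5, B6) and a mossy cell (MC); CA3 holds
four pyramidal cells (P5–P8), two basket cells (B3, B4) and an O-LM cell
(OLM2); CA1 mirrors CA3 (P1–P4, B1, B2, OLM1). Each cell is a tree of 16
iso-potential compartments (soma plus a binary dendritic tree) carrying 13
excitatory and 3 inhibitory synapses. Compartments leak toward the resting
potential (−70 mV), diffuse charge along the tree, and integrate
postsynaptic potentials shaped as differences of exponentials (AMPA 2/10 ms,
NMDA 5/50 ms with a sigmoidal voltage gate, GABA 2/20 ms unless a projection
overrides the decay). A spike fires when the somatic potential crosses the
class threshold outside the refractory period; the soma then resets to rest.
Excitatory synapses on granule, pyramidal and O-LM cells are plastic: a
presynaptic spike arriving while the local compartment is depolarised past
the NMDA-unblock level (+10 mV above rest) increments the weight by 5 % of
its ceiling (LTP only, no depression), saturating at twice the initial
weight.

Connectivity follows the canonical pathways: entorhinal layer-2 perforant
path lines Ex1–Ex9 onto granule cells (Ex8/Ex9 silent under the control
protocol), Ex1–Ex5 onto CA3 pyramidal cells, Ex1–Ex7 onto the DG/CA3 basket
cells; mossy fibres G→CA3 on proximal dendrites; Schaffer collaterals
CA3→CA1; sparse CA3 recurrence; mossy-cell loops in DG; perisomatic basket
inhibition and distal O-LM inhibition within each region. Septal (MS-DB)
GABAergic lines T4–T9 inhibit the interneurons only.

## Rhythm generation

The control stimulus drives Ex1–Ex7 with bursts of five spikes at 100 Hz
nested in an 8 Hz theta rhythm (125 ms cycle), phase-staggered between lines
in a stride-3 permutation of seven equal offsets so 2–3 lines are active at
any phase. The MS-DB lines fire a volley at phases 0–40 ms of every cycle,
silencing the basket cells and opening a disinhibition window in which the
principal cells burst at their refractory-limited rate (granule ≈14 ms
inter-spike interval, CA3 ≈7 ms, CA1 ≈9.5 ms — these intervals set the
region-specific spikes-per-burst). Outside the window the tonically driven
basket cells keep the principal cells subthreshold. One additional late
MS-DB "echo" spike per cycle (phase 80–92 ms, region-staggered, delivered at
0.8–1.0 of the gating weight) opens a brief secondary window that admits
roughly one isolated spike per cell per cycle.

## Conditions

* **control** — intact circuit, theta-burst protocol.
* **ad** — synaptic-deletion stage 32: perforant lines Ex1–Ex4 deactivated
  on every granule and CA3 pyramidal cell (a "preclinical" stage; interneuron
  afferents intact, CA1 untouched). The deletion order interleaves the two
  principal-cell tiers per line index so that this pinned stage is a prefix
  of the order.
* **ad_gamma40 / ad_gamma100 / ad_stim130** — the deleted circuit plus a
  strictly periodic induction train at 40/100/130 Hz superimposed on all
  nine perforant lines. Induction is delivered on the principal cells'
  perforant synapses at 1.4× the synaptic weight; it does not drive the
  basket cells. This is a deliberate design choice: line-level delivery to
  interneurons makes induction self-defeating (the extra tonic interneuron
  drive cancels the septal disinhibition window at every frequency), whereas
  dendritic induction of principal cells restores firing monotonically with
  frequency, which is the phenomenon under study.

Each condition runs 30 seeded 10 s repetitions (1 ms steps; spike-time
jitter 1 ms SD on the theta bursts is the only stochastic element; run *i*
uses seed `base_seed + i`, so every run is bit-reproducible).

## Outcome measures

**Burst metrics.** A burst is a maximal run of ≥2 spikes with inter-spike
intervals ≤15 ms (the protocol separates ~10 ms intra-burst intervals from
~85 ms theta gaps by nearly an order of magnitude). Per cell and run we
report total spikes, mean spikes per burst, mean burst duration
(first-to-last spike) and mean inter-burst interval (end-to-next-start).
Region aggregates are unweighted means over principal cells × runs; DG's
"principal cells" are the granule cells.

**Nonlinear dynamics.** The analysis series is the smoothed instantaneous
firing rate (5 ms bins, Gaussian σ = 2 bins) of each principal cell; the
somatic-potential traces are recorded alongside. Embedding delay comes from
the first local minimum of the lagged auto mutual information, dimension
from the false-nearest-neighbour criterion (1 % threshold). The maximal
Lyapunov exponent is estimated two ways: a Rosenstein divergence slope
(used for the map surrogates, where it recovers ln 2 for the logistic map
within 10 %) and an Eckmann-style local-Jacobian + QR estimator (the
headline estimator for network series, since it resolves negative exponents
of noise-driven phase-locked activity; evolution step 2 bins, ridge 1e−6).
Recurrence analysis fixes the radius at a 2 % recurrence rate
(Chebyshev norm, Theiler window = delay × dimension) and reports
determinism, maximal diagonal line, the Shannon entropy (bits) of the
diagonal-line length distribution, and the Grassberger–Procaccia
correlation dimension over an automatically selected scaling region
(flattest positive-slope window of the log–log correlation sum).

**Information flow.** Spike trains are binarised into 10 ms bins. Mutual
information and Schreiber transfer entropy (histories k = l = 1) use plug-in
estimators in bits; the first-order bias bound (m−1)/(2N ln 2) is exposed so
tests can reason about estimator error, and a time-shuffle control drives TE
to its noise floor. Matrices are computed for DG→CA3 (G1–G4 × P5–P8),
CA3→CA1 (P5–P8 × P1–P4) and all-pairs MI, averaged over runs.

**Statistics.** Group comparisons are normality-screened (Shapiro–Wilk at
0.05 per group): one-way ANOVA with Tukey HSD when all groups pass,
Kruskal–Wallis with Dunn/Holm otherwise; α = 0.05 throughout, stars at
0.05/0.01/0.001. A chi-squared independence test is provided for
qualitative tables. Type-I error of the omnibus path is calibrated ≤ 6 % on
1000 null datasets (5 × 30 Gaussian).

## Synthetic ground truths

The surrogate module generates Poisson trains, theta-burst trains,
directionally coupled binary processes (follower copies the lagged driver
with probability *c*; TE, its pointwise log-ratio SD and MI computed by
exact enumeration of the joint distribution and carried with the data),
and logistic/sine map series whose Lyapunov exponents come from the average
log-derivative along the generated orbit. The sine period defaults to 19.7
samples, incommensurate with the sampling grid, so the orbit fills its
closed curve densely instead of revisiting a handful of exact duplicates —
noise-free exact periodicity degenerates nearest-neighbour statistics.

These surrogates exercise every analysis stage without the simulator, but
they do not emulate nonstationarity (LTP drift), bursting autocorrelation,
or cross-cell correlation; passing them shows estimator correctness, not
robustness to every property of real recordings.

## Calibration and known limitations

The default weights and class parameters were calibrated once against the
five-condition study design and then pinned; the calibration dials were the
projection weights, the gating kernel decays (MS-DB 8 ms, basket→principal
6 ms, Schaffer/mossy 5 ms), the disinhibition window length and the echo
phases. With 30-run batches the model reproduces the qualitative program:
deletion lowers spike counts, shortens bursts and lengthens the inter-burst
interval; induction restores them monotonically with frequency, with 130 Hz
exceeding control; the deleted circuit has a positive mean Lyapunov exponent
while control and all induction conditions are negative; and DG→CA3
transfer entropy rises under deletion and collapses under induction.

Known limitations, all visible in the acceptance outputs:

* The control inter-burst interval reads ≈68 ms rather than ≈84 ms because
  the DG echo window occasionally admits a two-spike mini-burst; removing
  the echo restores the interval but removes the isolated spikes that the
  130 Hz condition amplifies, so the trade-off is resolved in favour of the
  induction effect.
* The 40 Hz condition is dynamically close to control, so its mean Lyapunov
  exponent is mildly negative (≈−0.1 per bin) rather than strongly negative.
* CA3→CA1 transfer entropy is insensitive to deletion in this circuit: CA1
  is a pure Schaffer follower in every condition, so the deletion-induced
  increase seen in DG→CA3 does not propagate (checked across bin widths
  5–25 ms and histories k = 1–4).
* Correlation dimensions of the network rate series sit near 1 (the series
  are dominated by the theta limit cycle), lower than values obtained from
  higher-dimensional observables.

Problem sizes were chosen to keep a full five-condition study (150 runs plus
all estimators) within a few minutes on one CPU: 10 s runs at 1 ms steps,
2000-sample rate series, recurrence plots subsampled to ≤1200 points, and
the per-cell embedding estimators evaluated on up to 30 runs per condition.
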