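# Model and methods

## The model

`ifnet` simulates a small cortical circuit under closed- and open-loop
conditioning. Three columns (A: recorded, B: stimulated, C: control) each
contain 40 excitatory and 40 inhibitory integrate-and-fire units; each column
drives a pool of 40 motoneurons. A unit's potential is the difference of two
leaky accumulators sharing the same synaptic input,

    V_i(t)     = V_s(t) - V_f(t)
    V_s(t + h) = (1 - h/tau_s) V_s(t) + A_i(t)        (0 after a spike)
    V_f(t + h) = (1 - h/tau_f) V_f(t) + A_i(t)        (0 after a spike)

so that every input event evokes a difference-of-exponentials PSP
`w (e^{-t/tau_s} - e^{-t/tau_f})`. A spike is emitted when `V_i` strictly
exceeds the threshold; both accumulators are reset to zero on the next step.
The forward-Euler step is `h = 0.1 ms` by default (the validated set is
0.1/0.05/0.025/0.02/0.01 ms); `h < tau_f` is enforced for stability. Spikes
propagate with a 3-ms delay between cortical units and 10 ms from cortex to
motoneurons. A *connection strength* is the PSP maximum, `|w| k*` with
`k* = g(t*) ~ 0.47247` from the kernel's closed-form peak; configuration
values quoted in microvolts are converted through the continuous-time `k*`
(not the discretized kernel maximum, which is ~3% higher at h = 0.1 ms) so
that weight bounds do not depend on `h`.

### Plasticity

Each connection weight follows a trace-based, two-lobe STDP rule. Source
units carry a strengthening trace incremented by delayed spike arrivals;
target units carry a weakening trace incremented by their own spikes; both
are twin integrators like the membrane but without reset. At every step

    dw_ij = r sgn(w_ij) (S_j U_i(t) - c T_i U_j(t - d))

with hard clipping to `[w_min, w_max]` for excitatory and
`[-w_max, -w_min]` for inhibitory connections (sign never flips; a graded
squashing hook exists but is disabled). `r` and `c` scale the update only at
weight-change time, so an isolated pre/post pair reproduces the curve
`r (e^{-dt/a_s} - e^{-dt/a_f})` / `-c r (e^{dt/b_s} - e^{dt/b_f})` exactly
(up to Euler error). With the default parameters (r = 100, c = 0.55,
a = 15.4/2 ms, b = 33.3/2 ms) the weakening lobe has the larger area
(1721.5 vs 1340), which keeps unconditioned networks at small steady-state
weights (~40-60 uV mean strength from 100-300 uV initial draws) so that
conditioned strengthening stands out and open-loop (tetanic) effects stay
small. Coincident pre-arrival and post-spike in one step read the traces
*before* that step's increments, so a simultaneous pair contributes nothing,
matching the curve's zero at dt = 0.

### External input

Each cortical unit receives background drive at 1800 events/s with PSP peak
350 uV: 30% arrives as column-wide *correlated* events (each event delivers
once to every unit of the column with Gaussian jitter, SD 3 ms, truncated at
4 SD) and 70% as independent per-unit events. Motoneurons receive
uncorrelated drive; the rate is not stated by the model's sources, and 1000
events/s at the same 350-uV strength was chosen so that pools are nearly
silent at rest but recruit during cortical bursts (mean drive ~1.8 mV
against 5-6-mV thresholds). Episode generators can modulate a column's
event probabilities multiplicatively, e.g. four 6-cycle 20-Hz sine episodes
per 10-s block (depth 0.5, a choice — only the mechanism is prescribed) for
beta-cycle conditioning.

### Signals

The **LFP** of a column is the sum of all PSPs arriving at its cortical
units, integrated by the same kernel without reset. Two provenance modes are
computed each step: the *full* LFP including external-bias PSPs, and the
*spike-sourced* LFP restricted to PSPs evoked by network spikes. Direct
stimulus steps are excluded from both: they are not synaptic events, and
including a 2-3-mV step across 80 units would swamp the synaptic response
that evoked potentials are meant to measure. **EMG** is the sum of
motor-unit potentials (kernel peaks 0.5-1.5 mV, co-sorted with thresholds
per the size principle) band-passed causally at 100-2500 Hz.

An **evoked potential (EP)** is measured from 3-mV test stimuli delivered to
a whole column: the stimulus-locked LFP segments of the recorded column are
averaged first, then the EP is the signed extremum over (3, 18] ms minus the
mean over [-20, 0) ms. Averaging before peak-picking matters: the background
LFP fluctuates with a SD of roughly 27 mV (sum over 80 units), and the
extremum of single noisy trials is biased upward. The windows are package
choices (3 ms skips the conduction delay; 18 ms includes disynaptic
components). Percent EP change between the post- and pre-conditioning
testing periods is `100 (post - pre)/pre`.

### Conditioning protocols

All eight paradigms drive 2-mV (configurable) column-wide stimuli, realized
as a step added to the slow accumulator only (an immediate deflection of V
decaying with tau_s; negative amplitudes model spike-triggered inhibition):

* **spike-triggered** — every spike of Ae1 schedules a stimulus on B at a
  configurable delay (no lockout by default);
* **EMG-triggered** — rising threshold crossings of the causally band-passed
  (100-2500 Hz) EMG of muscle A, 20-ms lockout; the threshold is calibrated
  by bisection on a plasticity-off recording to ~6 triggers/s, matching the
  stimulation rate across protocols;
* **gamma-triggered** — threshold crossings (falling by default) of the
  gamma-band (50-80 Hz) filtered *spike-sourced* LFP of A, calibrated the
  same way. The spike-sourced signal is used because this protocol's premise
  is that gamma reflects coincident multiunit firing; on the full LFP the
  crossings mostly track bias-input noise and the falling/rising asymmetry
  disappears;
* **cycle-triggered** — the *full* LFP of B, band-passed 15-25 Hz with a
  causal second-order Butterworth filter; when it exceeds an episode level
  (2 x the SD of a plasticity-off recording) the next rising zero crossing
  defines 0 deg (falling defines 180 deg) and a stimulus on A is scheduled
  at the phase offset; triggers repeat each cycle while the episode persists
  (75-ms arming window, 30-ms lockout);
* **paired-pulse / triplets** — periodic repetitions at 1.4 Hz (chosen to
  match ~700 pairs per 500-s conditioning period): A-stimulus, then
  B-stimulus at a signed delay; trains deliver 1-3 pulses per column at
  33-ms spacing;
* **tetanic** — open-loop Poisson train (default 10 Hz) with an imposed
  10-ms refractory period, delivered to one column.

The trigger filters are part of the closed loop; their group delay (roughly
the inverse bandwidth) is what places stimulus-evoked spikes after the
presynaptic volley that generated the trigger. Closed-loop causality holds
by construction: the online detectors see only samples up to the current
step, and scheduled stimuli are applied at or after the trigger step.

### Schedule

Runs advance in 10-s blocks through four periods — preconditioning
(plasticity on: the network settles to its unconditioned steady state),
pre-testing (plasticity off, EP measurement), conditioning (plasticity and
protocol on), post-testing (plasticity off). During testing periods test
stimuli rotate over the three columns; cycle-triggered runs instead place
three test pulses before and three after each oscillatory episode,
alternating between columns A and B so both directions are probed.
Induction/decay experiments stimulate only the first 4 s of each
conditioning block and track the mean A->B strength on a 0.1-s grid.

## Implementation notes

The production path is a numba-compiled fixed-step kernel (spike
propagation through ring buffers, trace/weight updates on spike events,
online biquad filtering, delivery queues for jittered correlated events and
pending stimuli). A plain-Python reference engine implements the same
update equations operation by operation; the test suite holds the two paths
to spike-for-spike and near-bit weight agreement on a 0.5-s network
simulation, and to analytic oracles (superposition of discretized PSP
kernels on a passive unit; brute-force pairwise STDP sums). Correlated bias
events are generated with a 4-SD look-ahead so Gaussian jitter never
schedules into the past; uncorrelated events use geometric countdowns,
thinned against the episode envelope where modulation is active.

Determinism: a run is a pure function of (config, seed). Topology, initial
countdowns, the protocol schedule and each block's kernel RNG use separate
seed derivations, so e.g. changing the protocol does not perturb network
construction or bias streams — this is what makes matched comparisons
(conditioning vs none, intact vs lesioned twin, phase sweeps branched from
a common preconditioned snapshot) exact: the background drift is common
mode and cancels in contrasts.

## Problem sizes

Full-scale runs (4 x 500-s periods) are supported but slow for sweeps; the
packaged experiment harnesses default to 60/40/100/40-s periods with test
stimuli every 0.25 s (~53 EP averages per directed pair vs ~83 at full
scale). Conditioning effects induce and decay within seconds to tens of
seconds at r = 100, so 100-200-s conditioning periods express the same
phenomena; the cost is EP measurement noise (a few thousand uV after
averaging), which the multi-seed means and matched contrasts in the tests
absorb. The phase sweep in `scripts/acceptance.py` runs 24 phases x 3 seeds
with the preconditioning shared per seed via state snapshots.

## What the synthetic conditions do and do not show

All inputs are generated by the model itself; there is no external data.
The bias generator emulates stationary background cortical drive with a
controllable synchrony fraction and optional oscillatory episodes; it does
not emulate behavioral nonstationarity, state transitions, or realistic
spectral content beyond the PSP-filtered event streams. Passing tests
therefore show that the conditioning mechanisms (STDP windows interacting
with protocol-imposed spike timing) behave as described under these
idealized conditions, not that effect sizes would transfer to in-vivo
recordings.

## Known limitations

* Disynaptic conditioning (strengthening A->C->B with direct A<->B removed)
  does not emerge at the reduced scales used here: after paired-triplet
  conditioning the relay strengths equal their unconditioned steady state in
  both the intact and lesioned twins, so the lesioned/intact disynaptic EP
  ratio measures ~1.0. The corresponding acceptance test documents this and
  fails; see the test docstring for the measurement design.
* The beta-cycle A->B optimum falls on the -30/-15-deg boundary of the
  15-deg phase grid; adjacent-phase means differ by a few percent, within
  seed noise.
* No conductance-based units, no multispike STDP, no depolarization-based
  plasticity, no per-connection time constants; the optional absolute
  refractory period defaults to 0 (threshold reset is the only
  refractoriness).
* Inhibitory units use the same STDP curve as excitatory ones and play a
  minor role at the default operating point, as the small steady-state
  weights confine recurrent dynamics.
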