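# ifnet — closed-loop conditioning in a spiking cortical-column network

`ifnet` is an integrate-and-fire network simulator for studying how
activity-dependent stimulation protocols reshape synaptic connections
between cortical sites — the computational counterpart of closed-loop
brain-computer-interface conditioning experiments. It is aimed at
computational and systems neuroscientists who want a compact, fully
deterministic model in which spike-triggered, EMG-triggered, beta-cycle-
and gamma-triggered, paired-pulse and tetanic stimulation can be run under
one set of physiological parameters and read out the same way experiments
are: stimulus-evoked LFP potentials, connection matrices and EMG.

## Model

Three columns (A recorded, B stimulated, C control) of 40 excitatory + 40
inhibitory units each, plus three 40-motoneuron pools recruited by the size
principle. Unit *i* integrates its synaptic input twice,

$$V_i = V_i^s - V_i^f,\qquad
V_i^{s,f}(t+h) = (1 - h/\tau_{s,f})\,V_i^{s,f}(t) + A_i(t),$$

firing when $V_i > \theta$ (both accumulators reset to zero), so each input
evokes a PSP $w\,(e^{-t/\tau_s} - e^{-t/\tau_f})$. Synaptic input sums
delayed spikes and external background events,
$A_i(t) = E_i(t) + \sum_j U_j(t-d)\,w_{ij}(t)$. Weights obey a trace-based
asymmetric STDP rule,

$$\Delta w_{ij} = r\,\mathrm{sgn}(w_{ij})\bigl(S_j\,U_i(t) - c\,T_i\,U_j(t-d)\bigr),$$

whose isolated-pair limit is the classic two-lobe curve
$r(e^{-\Delta t/a_s} - e^{-\Delta t/a_f})$ for pre-before-post and
$-c\,r(e^{\Delta t/b_s} - e^{\Delta t/b_f})$ otherwise, with the weakening
lobe larger in area so unconditioned weights settle small. Conditioning
protocols close the loop from spikes, EMG or band-passed LFP back to
column-wide stimulation; evoked potentials (EPs) from 3-mV test stimuli
quantify directed intercolumn strength before and after conditioning. See
`docs/methods.md` for the full account.

## Worked example

```
$ ifnet simulate --preset spike_triggered --seed 1 --out demo
protocol=spike_triggered network=standard seed=1 [preconditioning=60s, pretest=40s, conditioning=100s, posttest=40s]
EP A->B:   +190.9 %
EP A->C:     -3.2 %
EP B->A:    -45.2 %
EP B->C:    -16.6 %
EP C->A:    -30.6 %
EP C->B:    -34.4 %
triggers per period: [0, 0, 991, 0]
```

Every spike of unit Ae1 triggered a 2-mV stimulus on column B 10 ms later
(991 stimuli during the 100-s conditioning period). The A→B evoked
potential nearly tripled (+190.9%), while the untargeted A→C pathway barely
moved (−3.2%) — the signature of spike-timing-dependent strengthening of
the trigger-to-stimulus pathway. Changes of a few tens of percent on the
other pairs are within the run-to-run drift of this reduced-duration
schedule. The mean connection-strength matrix written to
`demo/mean_strengths_uv.csv` shows the same effect at the weight level:
A→B averages 133 µV after conditioning against 32–55 µV for every other
intercolumn pathway.

Other presets: `spike_triggered_inhibition`, `emg_triggered`,
`paired_pulse`, `paired_triplet`, `cycle_triggered` (with `--set
phase=180`), `gamma_triggered`, `tetanic`, `none`. `--full-scale` switches
to 500-s periods. The library interface (`ifnet.conditioning_run`,
`ifnet.cycle_phase_sweep`, `ifnet.disynaptic_comparison`, ...) exposes the
same experiments programmatically.

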