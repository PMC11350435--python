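# mepdsim

Simulation and bifurcation-analysis toolkit for a mean-field model of the
GABA–glutamate circuit in the posterodorsal medial amygdala (MePD) coupled
one-way to an arcuate KNDy pulse-generator model of GnRH pulsatility.

Components:

- **`mepdsim.params` / `mepdsim.models`** — validated parameter sets
  (published default calibration), right-hand sides and analytic Jacobian
  of the 3-D Wilson–Cowan-type MePD circuit, the 3-D KNDy
  (dynorphin / neurokinin B / firing rate) model and the 6-D coupled system.
- **`mepdsim.simulate` / `mepdsim.pulses`** — deterministic adaptive-step
  integration (RK45/DOP853 for the MePD block, LSODA for the stiff coupled
  system) with uniform resampling and transient handling; mean-output
  functionals (time averages of Gl, Ge, Gl−Ge); pulse-peak detection with
  inter-pulse-interval (IPI) statistics and a seeded synthetic-trace
  generator for testing the detector.
- **`mepdsim.continuation`** — a self-contained numerical continuation
  toolkit: pseudo-arclength equilibrium branches with Hopf/saddle-node
  detection and bisection refinement, single-shooting limit-cycle
  continuation (period, amplitude envelope, Floquet multipliers, with an
  arclength fallback towards the homoclinic period asymptote),
  two-parameter Hopf/saddle-node loci via minimally augmented systems,
  Bogdanov–Takens and cusp detection, a large-period homoclinic proxy, and
  torus-bifurcation location for the coupled system.
- **`mepdsim.scenarios`** — drivers for the in-silico experiments:
  kisspeptin-stimulation sweeps, GABA/glutamate receptor-antagonism sweeps
  (beta1/beta2), projection-stimulation presets (`glut_stim`, `gaba_stim`)
  with IPI-versus-stimulation curves, mean-output heat maps, and the
  GABA-efferent gain-switch locator.
- **`mepdsim.cli`** — `mepdsim` command with `simulate`, `continue`,
  `scenario`, `pulses` and `fixtures` subcommands (CSV/JSON/YAML I/O,
  deterministic 12-significant-digit output).

## CLI examples

```bash
# trajectory of the MePD circuit at kisspeptin drive 2.3
mepdsim simulate --model mepd --set Kp=2.3 --out-dir out/

# coupled run under glutamatergic projection stimulation
mepdsim simulate --model coupled --preset glut_stim --set Kp=1.2 --t-end 600 --out-dir out/

# equilibrium continuation in Kp with bifurcation points (Hopf near 1.4)
mepdsim continue --free Kp --range 0 3 --out-dir out/

# two-parameter Hopf/saddle-node loci in (Kp, alpha) with codim-2 points
mepdsim continue --free Kp --range 0 14 --second alpha --second-range 0 1 --out-dir out/

# scenario drivers
mepdsim scenario gain_switch --out-dir out/
mepdsim scenario projection --preset gaba_stim --grid 0 2 11 --out-dir out/

# pulse detection on a 2-column (time,value) CSV
mepdsim fixtures --peaks 15,30,45,60 --noise-sd 1 --seed 1 --out trace.csv
mepdsim pulses trace.csv
```

## Parameter files

All parameters live in one flat namespace keyed by the model symbol names
(`delta, alpha, Kp, c_ll, c_li, c_il, c_le, c_ie, a_l, a_i, a_e, theta_l,
theta_i, theta_e, beta1, beta2` for the MePD block; `d_D, d_N, d_v, k_D,
k_N, p_v, v0, K_D, K_N, K_v1, K_v2, k, m, I0` for the KNDy block; `j_l,
j_e` for the coupling), serialisable to YAML or JSON and overridable per
key with `--set`.
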