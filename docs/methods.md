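# Methods

## The model

`gainnet` studies gain control — intensity-invariant population activity —
in a randomly connected circuit of excitatory projection neurons (PNs) and
inhibitory local interneurons (LNs), patterned on the insect antennal lobe.
A stimulus of intensity `I` drives a fraction `f` (the sparseness
parameter) of both populations; the question is under which connectivity
conditions the mean excitatory activity stays constant as `I` varies.

Three tiers implement the same circuit at increasing realism:

1. **Mean field** (`gainnet.meanfield`).  Four ODEs for the mean rates of
   the stimulated/unstimulated E and I subpopulations, with
   threshold-linear transfer functions `G_X(u) = beta_X (u - theta_X)^+`
   and effective couplings `J_XY = p_XY N_Y g_XY` (probability × presynaptic
   population size × strength).  f-weighting compresses them into a
   two-variable system for the population means `x` (excitatory) and `y`
   (inhibitory), whose 2×2 Jacobian carries the stability analysis.

2. **Firing-rate network** (`gainnet.ratenet`).  One ODE per neuron,
   `tau r_i' = -r_i + G(u_i)`, on realized Bernoulli weight matrices.  The
   mean field is exact for this model as N → ∞.

3. **Conductance-based network** (`gainnet.hhnet`).  Traub–Miles-type
   Hodgkin–Huxley neurons with an M-type adaptation current and
   first-order kinetic synapses, driven by a triangular current ramp.

## Main results the package computes

* **Stability.**  Without lateral excitation (`J_EE = 0`) every fixed point
  of the compressed system is stable: the Jacobian has negative trace and
  positive determinant because both transfer functions are non-decreasing.
  With lateral excitation the fixed point destabilizes at
  `J_EE D_E = min(1 + J_EI J_IE D_E D_I / (1 + J_II D_I),
  1 + (tau_E/tau_I)(1 + J_II D_I))`, where `D_X` are the f-weighted
  transfer slopes at the fixed point.  Which crossing comes first (real
  eigenvalue → divergence, or complex pair → oscillation) depends on
  `tau_E/tau_I`; the divergence cross-check in the tests uses
  `tau_E/tau_I = 4`, where the real crossing is first.  Beyond the real
  crossing the threshold-linear equilibrium escapes to infinity, so "no
  solvable fixed point" and "unstable" coincide there.

* **Strict gain control in intensity.**  Differentiating the equilibrium
  equations in `I` and demanding `dx/dI = 0` gives, in the operating regime
  where inhibition silences the unstimulated groups and the stimulated
  groups are supra-threshold,

      f · beta_I · (J_EI − J_II) = 1.

  Only the connections *leaving the inhibitory population* enter (I→E and
  I→I); couplings from the excitatory side (`p_IE`, `g_IE`, `J_EE`) drop
  out, which the tests assert as exact invariance of the boundary.  With a
  shared inhibitory strength `g_I = g_EI = g_II` the boundary in the
  `(p_EI, g_I)` plane is `g_I (p_EI − p_II) = 1/(f beta_I N_I)` — close
  to a hyperbola `p_EI · g_I ≈ const` when the `p_II` term is subdominant —
  and in the `(f, p_EI)` plane it is `p_EI = p_II + 1/(f beta_I N_I g_I)`,
  flat at large `f` and rising steeply at small `f`.

* **Non-degeneracy requires `theta_I > theta_E`.**  On the gain-control
  manifold the equilibrium mean excitatory rate is proportional to
  `theta_I − theta_E`; equal thresholds would pin the controlled activity
  at exactly zero.  The defaults use `theta_E = 1`, `theta_I = 2` (current
  units; the inhibitory population is the harder to recruit).

* **Inhibitory linear scaling.**  Under the gain-control condition the
  equilibrium inhibitory mean grows exactly linearly, `dy/dI = 1/J_EI`:
  the inhibitory network scales its activity with the input so that the
  extra drive to the excitatory population is cancelled.

* **No static gain control against sparseness.**  The analogous condition
  for `dx/df = 0` involves the stimulated-minus-unstimulated rate gaps,
  which grow with `I`; a parameter set zeroing it at one intensity fails at
  another.  Stimulus encoding by recruiting more neurons therefore admits
  no fixed-connectivity gain control — the package demonstrates this by
  root-finding the condition at `I₁` and evaluating it at `2 I₁`.

* **Beyond the boundary: total silencing.**  Raising `p_EI` roughly 30–40%
  above the boundary (at the default operating point) silences the entire
  excitatory population; there `dx/dI` is identically zero — a degenerate
  second zero of the slope, distinct from balanced gain control.  Tests
  that probe the sharpness of the gain-control zero set therefore probe the
  displacement path rather than only its endpoint.

## Default study conditions and why

All defaults live in `gainnet.defaults` (rate/mean-field tiers) and in the
`HHNeuronParams` / `KineticSynapseParams` tables in `gainnet.hhnet`.

Rate/mean-field tier: `N_E = 1500`, `N_I = 500` (3:1 E:I, total 2000);
`beta = 1`, `theta_E = 1`, `theta_I = 2`, `tau = 10 ms`; `p_EE = 0.01` and
small `g_EE` (weak lateral excitation standing in for excitatory LNs),
`p_IE = 0.5`, `p_II = 0.3`, `g_I = 0.01`.  These place the gain-control
boundary `p_EI(f) = 0.3 + 0.2/f` inside the unit probability range for
`f ≳ 0.3` and keep every scanned operating point well below the
lateral-excitation stability boundary.  The default `p_EI = 0.7` sits
exactly on the boundary at `f = 0.5`, `I_ref = 5` (supra-threshold for both
stimulated groups).

Smaller rate networks used in grids (N = 400) keep the *couplings* `J_XY`
fixed by scaling strengths with the population-size ratio
(`scan.scaled_connectivity`); the mean-field prediction depends on the
network only through `J_XY`.

HH tier: 90 PNs + 30 LNs.  Membrane constants are standard Traub–Miles
values (C = 0.143 nF, g_Na = 7.15 µS/E_Na = 50 mV, g_K = 1.43 µS/E_K =
−95 mV, g_L = 0.02672 µS/E_L = −63.563 mV) plus an M-type adaptation
conductance g_M = 0.0572 µS with τ_max = 200 ms.  Kinetic synapses use
first-order transmitter-pulse kinetics (1 ms release; AMPA-like α = 1.1,
β = 0.19 ms⁻¹, E = 0 mV; GABA_A-like α = 5, β = 0.18 ms⁻¹, E = −80 mV),
10% Gaussian per-synapse conductance jitter, −20 mV spike detection with a
2 ms lockout.  Bias currents put PNs just above rheobase (0.41 ± 0.05 nA,
spontaneously active at a few Hz) and LNs below it (0.25 ± 0.05 nA, driven
by PNs and the stimulus).  The ramp protocol is 200 ms settle, 500 ms up /
500 ms down to 0.9 nA (≈2.5× rheobase), 25 ms count windows, with up- and
down-ramp windows of equal current paired and summed.  The scanned
`(p_EI, g_I)` grid (p ∈ [0.45, 0.9], g ∈ [0.006, 0.03] µS, log-spaced in
g) is the region where the zero-slope contour crosses every grid column
under this protocol; the balanced example pair is `(0.75, 0.016 µS)`.
Desk-scale problem sizes throughout (N = 120 HH neurons, 5×5 / 6×6 grids,
single-digit repetitions) are the package's chosen operating scale; the
mean-field comparisons are size-robust because they are phrased in the
couplings `J_XY`.

## What the synthetic generator emulates — and what it does not

The generator reproduces the structural assumptions of the theory:
independent Bernoulli connectivity per directed population pair,
homogeneous strengths (jittered only in the HH tier), stimulated subsets
drawn independently of the connectivity, and identical input to all
stimulated neurons.  Real antennal lobes violate several of these —
glomerular structure, correlated and odor-specific ORN drive, synaptic
plasticity, heterogeneous cell types.  Passing tests therefore show that
the *theory is internally consistent and robust across model tiers*, not
that a biological circuit satisfies the gain-control condition.

## Numerical choices

* Mean-field fixed points: quasi-Newton root solve (scipy `hybr`) started
  from the uncoupled closed form, residual tolerance 1e-10, with a
  long-time LSODA integration fallback; failures are flagged, never
  silently accepted.  At a transfer-function kink the sub-threshold
  (zero) one-sided slope is used in Jacobians and response systems.
* Response slopes `dx/dI`, `dx/df` by implicit differentiation of the
  equilibrium equations (2×2 linear solve); singular systems raise.
* Boundary root-finding: a 41-point scan in `p_EI` locates the strict
  `+/−` sign change of the slope (skipping the silenced-plateau zeros),
  refined by Brent's method; cells without a bracketed crossing are NaN.
* Rate networks: explicit adaptive RK45 (scipy `solve_ivp`) with a
  terminal "settled" event on ‖dr/dt‖∞ < 1e-7 and a divergence guard at
  1e7; intensity sweeps warm-start each intensity from the previous steady
  state.
* HH networks: adaptive embedded Dormand–Prince 5(4) with PI step control,
  rtol 1e-5, dt_max 0.1 ms, compiled with numba; synaptic activation is
  tracked per presynaptic neuron (all outgoing synapses share kinetics).
  Spike times are linearly interpolated at the −20 mV upward crossing.
  Gating/synaptic variables are bounded by the dynamics; excursions beyond
  1e-3 abort the run rather than being projected back.
* Spike-density functions: Gaussian kernel with per-spike edge
  renormalization, so the time integral equals the spike count exactly.

## Known limitations

* The coupled HH network at balanced inhibition is chaotic: spike counts
  of decorrelated trajectories of the *same* system differ by a few
  percent, so integration-step invariance is verified on an uncoupled
  reference run (which isolates integrator and detection accuracy); the
  coupled run is checked for bit-reproducibility at fixed seed instead.
* The realization-to-realization scatter of the *population-mean* rate
  self-averages close to 1/N (per-neuron quenched fluctuations are largely
  independent); 1/√N is the guaranteed upper envelope and is what the
  tests assert.
* Oscillatory (Hopf-side) instabilities of the mean field are detected via
  eigenvalues but their limit cycles are not analyzed.
* The HH zero-slope contour is extracted from single-realization cells;
  near-boundary cells carry realization noise of a few counts/nA, so the
  contour is interpreted at grid resolution only (the rate-tier grid uses
  5 realizations per cell).
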