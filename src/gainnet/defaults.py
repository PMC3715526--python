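"""Default study conditions for the mean-field and rate tiers.

One place holds the network configuration used throughout the package:
population sizes, threshold-linear gain parameters and Bernoulli
connectivity.  The values define a regime in which (i) lateral excitation is
weak and dominated by inhibition, (ii) the strict gain-control boundary
p_EI = p_II + 1/(f * beta_I * N_I * g_I) lies inside the unit probability
range for the sparseness values scanned, and (iii) the gain-controlled
fixed point is non-degenerate (theta_I > theta_E, see docs/methods.md).

Units are dimensionless model units: rates in units of beta*current,
currents in threshold units, time in ms.
"""

from __future__ import annotations

from .netgen import ConnectivitySpec, PopulationSpec, RampProtocol


#: Rate-tier population sizes (E:I = 3:1, total 2000).
POPS = PopulationSpec(N_E=1500, N_I=500)

#: Default Bernoulli connectivity.  g_EI = g_II = g_I is the shared
#: inhibitory strength scanned in the (p_EI, g_I) planes.
CONN = ConnectivitySpec(
    p_EE=0.01,
    p_EI=0.7,   # on the strict gain-control boundary at f = 0.5
    p_IE=0.5,
    p_II=0.3,
    g_EE=0.005,
    g_EI=0.01,
    g_IE=0.005,
    g_II=0.01,
)

#: Threshold-linear gain parameters: unit slopes, inhibitory threshold above
#: the excitatory one, 10 ms relaxation for both populations.
GAIN = dict(beta_E=1.0, beta_I=1.0, theta_E=1.0, theta_I=2.0, tau_E=10.0, tau_I=10.0)

#: Reference stimulus intensity (supra-threshold for stimulated groups) and
#: sparseness used when a single operating point is needed.
I_REF = 5.0
F_REF = 0.5

#: Supra-threshold intensity range for intensity sweeps.
I_RANGE = (3.0, 10.0)

#: HH-tier (desk-scale) populations: 90 projection neurons, 30 local
#: interneurons, same E:I proportion structure as the rate tier.
HH_POPS = PopulationSpec(N_E=90, N_I=30)

#: HH-tier connectivity.  Probabilities as in the rate tier; strengths are
#: maximal synaptic conductances in uS.  g_EI = g_II = g_I is the shared
#: inhibitory conductance scanned against p_EI; the default pair
#: (p_EI = 0.5, g_I = 0.01) sits near the gain-control contour of the
#: default ramp experiment.
HH_CONN = ConnectivitySpec(
    p_EE=0.01,
    p_EI=0.75,
    p_IE=0.5,
    p_II=0.3,
    g_EE=0.002,
    g_EI=0.016,
    g_IE=0.008,
    g_II=0.016,
)

#: HH ramp protocol: 200 ms settle, 500 ms up / 500 ms down, 0.9 nA peak
#: (about 2.5x the isolated-neuron rheobase, driving LNs well into their
#: responsive range).
HH_PROTOCOL = RampProtocol(t_settle=200.0, t_up=500.0, t_down=500.0, I_peak=0.9)

#: (p_EI, g_I) grid of the HH slope map: the zero-slope contour crosses
#: every column of this grid under the default protocol.
HH_P_EI_GRID = (0.45, 0.5625, 0.675, 0.7875, 0.9)
HH_G_I_GRID = (0.006, 0.009, 0.0135, 0.02, 0.03)
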