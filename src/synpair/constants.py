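"""Unit conventions and fixed model constants.

Internal unit system (the one the published parameter magnitudes are mutually
consistent under): potential mV, time ms, length um, specific axial
resistivity Ohm*cm, specific conductance S/cm^2, specific capacitance
uF/cm^2, point current nA, absolute conductance uS, absolute capacitance nF.
In these units ``uS * mV = nA`` and ``nF * mV / ms = nA``, so the
compartmental ODEs need no further conversion once per-segment absolute
quantities are formed.  All cross-unit factors live here and nowhere else.
"""

import math

# --- conversions --------------------------------------------------------
UM2_TO_CM2 = 1e-8
# c_m [uF/cm^2] * area [um^2] -> capacitance [nF]
CAP_UF_CM2_UM2_TO_NF = UM2_TO_CM2 * 1e3
# g [S/cm^2] * area [um^2] -> absolute conductance [uS]
COND_S_CM2_UM2_TO_US = UM2_TO_CM2 * 1e6
# axial resistance 4*r_a*L/(pi*d^2) with r_a [Ohm*cm], L,d [um] -> Ohm
AXIAL_OHM_FACTOR = 1e4
OHM_TO_US = 1e6  # g [uS] = OHM_TO_US / r [Ohm]
# line-source potential: I [nA] / (4*pi*sigma [S/m] * r [um]) -> uV
LINE_SOURCE_UV = 1e3 / (4.0 * math.pi)

# --- fixed biophysics (published reference values) ----------------------
R_A = 100.0          # Ohm*cm, specific axial resistance
C_M = 1.0            # uF/cm^2, specific membrane capacitance
G_NA = 0.05          # S/cm^2, maximal sodium conductance
G_K = 0.005          # S/cm^2, maximal potassium conductance
G_L = 0.0003         # S/cm^2, leak conductance
E_L = -39.2          # mV, leak reversal potential
E_NA = 70.0          # mV, sodium reversal potential
E_K = -80.0          # mV, potassium reversal potential
V_T = -30.4          # mV, global voltage offset of the gating rate functions
TEMPERATURE_C = 37.0  # deg C

# --- morphology ---------------------------------------------------------
SOMA_DIAMETER = 10.0     # um
SOMA_LENGTH = 10.0       # um
N_AXON_SEGMENTS = 100
AXON_SEGMENT_LENGTH = 19.9   # um
AXON_DIAMETER_RANGE = (0.2, 5.0)  # um, prior box for both neurons
POST_SOMA_Z0 = 1000.0    # um, postsynaptic soma start along the channel axis

# --- synaptic kinetics (tau_decay, tau_rise, reversal) ------------------
AMPA_TAU1 = 0.3      # ms (decay)
AMPA_TAU2 = 0.1      # ms (rise)
NMDA_TAU1 = 30.0     # ms
NMDA_TAU2 = 10.0     # ms
SYN_REVERSAL = 0.0   # mV, AMPA and NMDA
SPONT_TAU1 = 0.2     # ms (as printed; tau1<->tau2 symmetric in the kernel)
SPONT_TAU2 = 0.4     # ms
SPONT_REVERSAL = 0.0  # mV
SPONT_MU_PER_UM = 0.02     # uS per um of target-segment diameter
SPONT_SIGMA_PER_UM = 0.02  # uS per um

# --- electrodes ---------------------------------------------------------
ELECTRODE_1 = (0.0, 0.0, 60.0)     # um
ELECTRODE_2 = (0.0, 0.0, 1060.0)   # um
SIGMA_EXT = 0.3                    # S/m, extracellular conductivity

# --- prior box of the nine variable parameters --------------------------
PRIOR_RANGES = {
    "d_pre": (0.2, 5.0),          # um
    "d_post": (0.2, 5.0),         # um
    "mu_ampa": (0.0, 0.002),      # uS
    "sigma_ampa": (0.0, 0.001),   # uS
    "mu_nmda": (0.0, 0.0002),     # uS
    "sigma_nmda": (0.0, 0.0001),  # uS
    "lambda_pre": (5.0, 100.0),   # Hz
    "lambda_post": (5.0, 100.0),  # Hz
    "z_syn": (1000.0, 2000.0),    # um
}
PARAM_NAMES = tuple(PRIOR_RANGES)
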