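"""Shared physical constants and the base parameters of the molluscan neuron model.

Unit conventions used throughout the package
--------------------------------------------
===============  ======  =====================================================
quantity         unit    note
===============  ======  =====================================================
voltage          mV
time             ms      all rates are per ms, all time constants in ms
current          nA
conductance      uS      1 uS * 1 mV = 1 nA
capacitance      nF      1 nA / 1 nF = 1 mV/ms
concentration    mM      intracellular calcium, transmitter
===============  ======  =====================================================

With these units the membrane equation ``C dV/dt = -sum(I)`` is dimensionally
consistent without conversion factors.  The original Komendantov-Kononenko
(KK) formulation uses seconds and uF; trajectories are identical, only the
time axis and the capacitance figure are rescaled (0.02 uF = 20 nF, a 50 ms
time constant instead of 0.05 s, and so on).

Base (cell-class independent) parameters of the KK molluscan neuron
-------------------------------------------------------------------
=========  ==========  ====================================================
symbol     value       meaning
=========  ==========  ====================================================
V_NA       +40 mV      sodium reversal potential
V_K        -70 mV      potassium reversal potential
V_B        -58 mV      reversal of the slow B-current
V_CA       +150 mV     calcium reversal potential
C_M        20 nF       membrane capacitance (0.02 uF)
V_CELL     0.1 nL      effective volume of the calcium compartment
K_S        0.05 /ms    calcium removal rate (50 per second)
RHO        0.002       calcium buffer dilution factor (dimensionless)
K_BETA     15000 /mM   steepness of the Ca-activated gate
BETA_CA    4e-5 mM     half-activation calcium level of that gate
=========  ==========  ====================================================
"""

import math

# reversal potentials (mV)
V_NA = 40.0
V_K = -70.0
V_B = -58.0
V_CA = 150.0

# membrane capacitance: 0.02 uF expressed in nF
C_M = 20.0

# calcium buffer
RHO = 0.002                # dimensionless buffer factor
K_S = 0.05                 # Ca removal rate, per ms (= 50 per s)
K_BETA = 15000.0           # per mM
BETA_CA = 0.00004          # mM

FARADAY = 96485.33212      # C per mol

#: effective volume (litres) of the intracellular calcium compartment
#: (1 nL; a molluscan soma of ~60 um radius)
CELL_VOLUME_L = 1e-9

#: converts a calcium current in nA into a concentration flux in mM/ms:
#: d[Ca]/dt contribution = -K_CA_FLUX * I_Ca
#: derivation: I[nA] = 1e-12 C/ms; / (2 F v[L]) -> mol/L per ms = M/ms;
#: * 1e3 -> mM/ms.
K_CA_FLUX = 1e-12 / (2.0 * FARADAY * CELL_VOLUME_L) * 1e3

# gating time constants (ms); KK values of 0.05 s etc. rescaled to ms
TAU_MB = 50.0     # B-current activation
TAU_HB = 1500.0   # B-current inactivation
TAU_M = 0.5       # fast (TTX-sensitive) Na activation
TAU_H = 10.0      # fast Na inactivation
TAU_N = 15.0      # delayed-rectifier (TEA-sensitive) K activation
TAU_MCA = 10.0    # Ca-current activation

#: number of dynamical state variables per cell:
#: V, mB, hB, m, h, n, mCa, [Ca]
N_STATE_VARS = 8

#: canonical ordering of the eight maximal conductances
CONDUCTANCE_NAMES = (
    "g_K",        # potassium leak
    "g_Na",       # sodium leak
    "g_NaV",      # slow voltage-dependent Na ("Na(V)")
    "g_B",        # slow chemosensitive B-current
    "g_NaTTX",    # fast TTX-sensitive Na (spike upstroke)
    "g_KTEA",     # TEA-sensitive delayed rectifier (spike downstroke)
    "g_Ca",       # voltage-gated Ca
    "g_CaCa",     # Ca-activated Ca current
)
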