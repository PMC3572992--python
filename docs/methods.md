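# Methods

`clionesim` models the sensory–motor chain that lets the sea angel
*Clione limacina* use one gravity-sensing organ for two behaviors: keeping
a head-up posture during routine swimming, and generating the irregular
wing beating of hunting search.  This note records the model equations,
the parameter choices the package makes where the underlying literature
leaves them open, the numerical methods, and the known limitations.

## The single-cell model

Every neuron is an eight-current Hodgkin–Huxley-type molluscan cell with an
intracellular calcium pool.  The membrane equation is

    C_m dV/dt = I_ext − (I_K + I_Na + I_NaV + I_B + I_NaTTX + I_KTEA + I_Ca + I_CaCa)

with two ohmic leaks (`I_K = g_K (V−V_K)`, `I_Na = g_Na (V−V_Na)`), a slow
voltage-gated sodium current `I_NaV` with instantaneous sigmoidal
activation `1/(1+exp(−0.2(V+45)))`, the slow B-current
`I_B = g_B·mB·hB·(V−V_B)` (activation mB decreasing in V, center −34 mV,
τ = 50 ms; inactivation hB increasing in V, center −43 mV, τ = 1.5 s), fast
spike currents `I_NaTTX = g·m³h(V−V_Na)` (τ_m = 0.5 ms, τ_h = 10 ms) and
`I_KTEA = g·n⁴(V−V_K)` (τ_n = 15 ms), a voltage-gated calcium current
`I_Ca = g·mCa²(V−V_Ca)` (τ = 10 ms, activation centered at 0 mV), and a
calcium-dependent current

    I_CaCa = g_CaCa (V−V_Ca) / (1+exp(0.06(V+45))) / (1+exp(k_β([Ca]−β))).

`I_CaCa` is an inward pacemaker-type current: it is favored at
hyperpolarized potentials and *inhibited* by intracellular calcium.  The
calcium pool obeys `d[Ca]/dt = ρ(−I_Ca/(2Fv) − k_s[Ca])` with ρ = 0.002,
k_s = 50 s⁻¹ and an effective compartment volume v = 1 nL.

The slow dynamics work as a relaxation oscillator: with [Ca] low the
I_CaCa drive depolarizes the cell into a burst; spiking loads calcium
through I_Ca, which closes the gate and ends the burst; calcium then clears
with the ~10 s time constant set by ρ·k_s, and the cycle restarts.  The
interaction of this calcium clock with the B-current wave makes the firing
irregular (weakly chaotic) rather than periodic.

Some orientations of the slow gates are not recoverable from the sources
available to this package; they were fixed by requiring the shipped
parameter rows to reproduce their documented regimes — the statocyst
receptor row must burst irregularly and the hunting-interneuron row must
spike irregularly, in isolation.  The combination above is the only one of
the 32 scanned sign/placement variants that does both.  A consequence is
that the cerebral-interneuron and wing-CPG rows are *quiescent* in
isolation in this transcription (subthreshold oscillators with a rheobase
near 1.5–2 nA) rather than spontaneous spikers; they fire readily under
network drive, which is the role they play.

Four cell classes share every kinetic constant and differ only in the
eight maximal conductances (µS):

| class            | g_K  | g_Na   | g_NaV  | g_B    | g_NaTTX | g_KTEA | g_Ca | g_CaCa |
|------------------|------|--------|--------|--------|---------|--------|------|--------|
| hunting (H)      | 0.25 | 0.0231 | 0.11   | 0.1372 | 400     | 10     | 1.5  | 0.02   |
| receptor (SRC)   | 0.25 | 0.02   | 0.11   | 0.128  | 400     | 10     | 1.0  | 0.01   |
| cerebral (CG)    | 0.25 | 0.0231 | 0.0795 | 0.1372 | 400     | 10     | 1.5  | 0.02   |
| wing CPG         | 0.25 | 0.0231 | 0.0807 | 0.1372 | 400     | 10     | 2.0  | 0.02   |

Shared constants: V_Na = +40 mV, V_K = −70 mV, V_B = −58 mV, V_Ca = +150 mV,
C_m = 20 nF (0.02 µF), k_β = 15000 mM⁻¹, β = 4·10⁻⁵ mM.  Internal units
are mV / ms / nA / µS / nF / mM throughout (note 1 nA into 20 nF gives
50 mV *per second*).

The effective calcium volume merits a remark: with a whole-soma volume
(radius 0.1 mm, ≈ 4 nL) the calcium load per spike is so small that
receptors burst spontaneously every ~7 s, which destroys the
winner-take-all regime (silent receptors must stay silent for tens of
seconds); with 0.1 nL a single spike saturates the gate and activations
collapse to single spikes.  The shipped 1 nL compartment gives ~1 s
bursts recurring every ~16–30 s, matching both regimes.  Initial states
start with the calcium buffer loaded (1.0–1.4·10⁻³ mM), as after recent
activity, so cells do not all burst simultaneously at startup.

## Synapses

Chemical synapses follow a first-order transmitter-binding scheme: the
postsynaptic current is `g·r·(V_post − E_syn)` and the open fraction obeys
`dr/dt = α[T](1−r) − βr` with α, β in the kinetic scheme's native per-ms
units (α per mM·ms, β per ms), per connection class:

| connection       | α   | β    |
|------------------|-----|------|
| H → SRC          | 2.0 | 0.75 |
| SRC → SRC        | 1.0 | 0.1  |
| SRC → CG         | 1.0 | 0.1  |
| CG → CG          | 2.0 | 0.2  |
| CG → CPG         | 1.5 | 0.5  |
| CPG fast         | 2.5 | 1.0  |
| CPG slow         | 2.5 | 0.25 |

The transmitter [T] is a rectangular pulse of amplitude T_max = 1 mM:
each upward crossing of 0 mV by the presynaptic potential starts (or
restarts) a release window of 1 s.  Because the cells fire faster than
1 Hz whenever active, r relaxes to α/(α+β) ≈ 0.7–0.9 during presynaptic
activity and collapses within milliseconds once the last window closes:
the synapse transmits the presynaptic *activity envelope* with a one-second
memory.  This combination — millisecond binding kinetics with a one-second
release window — is what lets millisecond-scale channel kinetics shape the
second-scale competition dynamics of these slow molluscan cells.  Reversal
potentials are −80 mV (inhibition) and 0 mV (excitation), except the
SRC→CG synapses (below).  Gap junctions are ohmic,
`I = g(V_pre − V_post)`.

## Network architecture and tuned conductances

**Statocyst.**  Six receptors on a ring; each inhibits the next two
(indices mod 6), so the twelve edges decompose into two inhibitory
triangles ({1,3,5} and {2,4,6}) coupled by a weak ring.  The shipped
weight vector (µS) is ring (0.012, 0.0165, 0.0135, 0.018, 0.015, 0.0195)
and triangles (0.048, 0.022, 0.040, 0.026, 0.044, 0.024): the odd triangle
is roughly twice as strong as the even one, and every edge differs — the
asymmetry required for winnerless competition.  The hunting interneuron H
excites all six receptors (0.07 µS) and receives nothing.

These values come from a documented grid search accepting vectors that
jointly satisfy (i) winner-take-all for every one of the six pressed
receptors (20 s of sole firing after a 5 s transient at I_statolith = 3 nA),
(ii) a balanced winnerless competition under hunting drive (all six
receptors with ≥ 4 activations per 100 s, none dominating), and (iii) a
stereotyped switching order (recurring multi-receptor word motifs, the
substrate of the phase-lock analysis).  Stimulation currents sit below the
cells' depolarization block (~4.5 nA): I_statolith = 3 nA, I_hunting = 3 nA.

During routine swimming the network is built *without* H: the biological
hunting interneuron is silent in that state, and the model H cell is
spontaneously active in isolation, so including it would corrupt the
winner-take-all regime.

**Cerebral interface.**  SRC1–3 excite CG1 and SRC4–6 excite CG2
(0.18 µS); CG1⇄CG2 inhibit each other (0.12 µS) so the two sides compete;
both excite CG3 (0.10 µS), which relays to the CPG interneurons 7 and 8
symmetrically (0.095 µS).  The SRC→CG synapses use a reversal of −20 mV
instead of 0 mV: with up to three co-active receptors converging on one CG
cell, a 0 mV reversal strong enough for the routine case (one active
receptor) drives the CG into sustained depolarization block during
hunting.  The −20 mV reversal makes group excitation saturating — one
receptor fires the CG, three cannot block it.

**Wing CPG.**  Two half-centers — dorsal (interneuron 7 → motoneurons 1A,
3) and ventral (8 → 2A, 4) — with slow mutual inhibition between the
interneurons (0.08 µS), slow crossing inhibition onto the opposite
motoneurons (0.08 µS), fast excitation of each interneuron's own
motoneurons (0.08 µS), and intra-group gap junctions (0.03 µS) that keep
each group synchronous.  Under the steady CG3 drive of routine swimming
the half-centers alternate on the cells' calcium clock: a regular
antiphase rhythm of ~0.09–0.12 Hz with cycle-period CV below 0.1.  This
frequency is set by the cell model's intrinsic burst timescale
(ρ·k_s ≈ (10 s)⁻¹), about an order of magnitude slower than the animal's
wing beat; the model reproduces the *pattern* (regular antiphase
alternation, synchronous groups, motoneurons firing spikes/doublets per
cycle), not the absolute frequency.

## Numerical methods

The network ODE system (8 states per cell, one open fraction per chemical
synapse) is integrated with an adaptive embedded Dormand–Prince 5(4) pair
(per-step mixed absolute/relative error control, default tolerance 1e-6),
compiled with numba.  Transmitter-pulse offsets and stimulus switches are
step boundaries — no trial step straddles them — so the field is smooth
within every step; pulse onsets are registered at accepted-step boundaries
from sub-step-interpolated spike crossings (the step cap of 0.5 ms bounds
the onset latency).  Output is resampled at 0.5 ms; spike times are
sub-step interpolated upward crossings of 0 mV with a 2 ms refractory
floor.  Runs are bitwise deterministic given (network, protocol, seed,
tolerance).  Halving the tolerance changes a 1 s trajectory by well under
1 mV; beyond a few seconds trajectories decorrelate, as they must in a
chaotic system.

Lyapunov spectra are computed from the model equations: the flow plus k
tangent vectors are propagated together through the same Runge–Kutta
stages, with analytic Jacobian-vector products (verified against central
differences at 1e-8) and QR renormalization every 250 ms.  Because the
rectangular transmitter pulse makes the field non-differentiable, the
variational analysis runs on a smooth counterpart: release is an extra
per-cell state `s` with `ds/dt = k_on σ(V)(1−s) − s/τ_pulse`
(k_on = 0.2 ms⁻¹, σ a sigmoid at the spike threshold), which matches the
pulse's time integral per spike; both the winner-take-all and the
winnerless regimes were verified to persist under this variant before it
was used.  Exponents count as positive when they exceed three standard
errors of the tail of their running estimate.  The machinery is validated
on closed forms (3-D linear flow: −1 exactly) and on the Lorenz system
(leading exponent within 5% of an independent two-trajectory divergence
oracle and of the literature value 0.906).

## Analysis conventions

- **Activation intervals and activity words** use the 0 mV threshold.  At
  the statocyst entry points a morphological closing over 400 ms is applied
  first, because the model's spikes dip below 0 mV between spikes of a
  burst while the analyses concern burst-level activations.  The literal
  per-sample thresholding remains available (`envelope_ms=0`).
- **Words** are 6-bit patterns, SRC1 the most significant bit; compression
  removes consecutive duplicates, making everything downstream invariant
  to activation durations (tested by time-dilating fixtures).
- **Phase locks** are exact recurring motifs of ≥ 3 compressed words
  involving ≥ 4 distinct receptors, counted left-to-right without overlap,
  with maximality (a motif contained in an equally frequent longer one is
  dropped); the ≥ 30-occurrence criterion is applied to counts pooled over
  three 120 s hunting series.  The miner is property-tested against an
  independent brute-force enumerator on random streams.
- **Episodes** are disjoint windows (≤ 30 s) where one recurring motif
  chains ≥ 3 times with bounded gaps; typed by which receptors have long
  (> 1 s) mean activations inside the window.
- **PCA** operates on spike trains smoothed to rates (Gaussian kernel,
  100 ms), concatenated across episode windows; all components are kept so
  the variance fractions sum to 1.
- **PSTH / motor response**: spikes of 1A and 2A are aligned to phase-lock
  onsets over a 0–4 s window (100 ms bins); each occurrence is classified
  by presence and order of 1A/2A firing (`none`, `1A`, `2A`, `1A→2A`,
  `2A→1A`), and a pattern's reliability is the fraction of its occurrences
  matching its modal class.

## What the synthetic fixtures do and do not show

The fixture generators emulate only the temporal/statistical structure the
analyses assume — threshold crossings on known schedules, spikes at known
latencies, word streams with planted motifs — and are bit-reproducible
from their seed.  Tests that pass on fixtures certify the analysis
algorithms (exactness, invariances, statistics), not the biophysics; the
network-level claims are tested on the simulations themselves.

## Known limitations

- **Absolute time scales.**  The wing rhythm (~0.1 Hz) and the sensory
  switching (~0.4 Hz) are an order of magnitude slower than the animal's;
  all regime-level structure (who fires when, what alternates, what is
  chaotic) is reproduced at the model's intrinsic timescale.
- **Chaos counts.**  The receptor row is intrinsically weakly chaotic, so
  the routine state retains small positive exponents (~0.03 s⁻¹ leading,
  still decaying at 300 s) instead of none, and hunting is hyperchaotic
  (≥ 4 positive exponents, leading ~0.25 s⁻¹) instead of exactly two.  The
  hunting/routine contrast (≈ 8× in the leading exponent) is robust.
- **Sensory→motor phase locking.**  The interface funnels both receptor
  groups through the single, symmetrically projecting CG3 cell.  During
  hunting CG3 fires at a nearly constant rate (CV < 6%), so the wing CPG
  cannot entrain to the sensory rotation and the motor response class at a
  phase-lock onset is close to a uniform phase sample (modal-class
  consistency 23–31% instead of the 88–100% reported for the original
  model).  Recovering high per-occurrence consistency would need either a
  motor network an order of magnitude faster than these cells allow, or
  steering projections (CG1/CG2 direct to the half-centers) that the
  modeled circuit does not contain.
- Single statocyst, no tail motor system, no plasticity, no conduction
  delays, no channel noise.
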