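# Methods

## The model

`cholwave` simulates a two-layer cortical sheet in which the level of
acetylcholine (ACh) is represented, inversely, by the maximal conductance of
a slow potassium current. Each cell is a single-compartment
Hodgkin-Huxley-type neuron:

    c_m dV/dt = − m∞(V)³ h ḡ_Na (V − E_Na) − n⁴ ḡ_Kdr (V − E_K)
                − s ḡ_Ks (V − E_K) − ḡ_l (V − E_l) + I_tune − I_syn

Sodium activation m is instantaneous (`m = m∞(V)`; it is not a state
variable). The gates h, n, s relax as `dx/dt = (x∞(V) − x)/τ_x(V)` with the
logistic steady state `x∞(V) = 1/(1 + exp((α_x − V)/β_x))` and, for h and n,
`τ_x(V) = 0.37 + D_x/(1 + exp((γ_x + V)/ε_x))` ms. The slow potassium (M-type)
gate s has a fixed `τ_s = 75` ms; its conductance `ḡ_Ks ∈ [0, 1.5]` mS/cm² is
the cholinergic control parameter. Raising ḡ_Ks produces spike-frequency
adaptation (SFA), flattens the f-I curve near rheobase, and converts the
phase response curve (PRC) from type 1 (advance-only) to type 2 (with an
early-phase delay lobe). All cell constants live in the bundled config
`cholwave/data/pyramidal.yaml` (c_m = 1 µF/cm², ḡ_Na = 24, ḡ_Kdr = 3,
ḡ_l = 0.02 mS/cm², E_Na = 55, E_K = −90, E_l = −60 mV, and the gate
constants); nothing numerical is hard-coded, and alternative parameter files
can be passed everywhere.

`I_tune` is calibrated by bisection, separately for every ḡ_Ks value, so the
isolated cell fires at 10 Hz (tolerance ±0.2 Hz; rates are measured as
`(n−1)/(t_last − t_first)` over the 4 s after a 1 s transient, which is
insensitive to window-edge alignment). More adaptation requires more drive,
so I_tune grows with ḡ_Ks.

## Synapses and network

Synaptic input is conductance-based with a delayed double-exponential
kernel, normalized so each pulse's peak equals the synaptic weight exactly.
Crucially, the kernel is keyed to the *last* presynaptic spike only — a new
spike resets the conductance rather than summing over history. The kernel is
truncated once it falls below ~1e−6 of its peak (15 τ_S past the delay).

Cells sit on a periodic square sheet of side L = 25: 625 excitatory cells on
a unit grid and 121 inhibitory cells on an 11×11 grid (spacing L/11, offset
half a cell). Excitatory cells project to every cell within a radius
`R = sqrt(L²k/(πN))`, where N is the size of the target layer: k_ee = 16
gives exactly 20 excitatory targets per excitatory cell, k_ei = 4 gives 4
inhibitory targets on average. Inhibitory cells are globally connected: each
projects to all 625 excitatory cells and to all 120 other inhibitory cells
(no self-edges). All weights default to 20 µS/cm²; the inhibitory-to-
excitatory weight w_i→e is the E/I-balance control parameter.

The I→I projection deserves a note. With it removed, the 121 interneurons —
each intrinsically firing at 10 Hz — impose a tonic conductance on every
excitatory cell large enough (≈5× leak) to hold the whole excitatory layer
below threshold, and any network-wide volley drives all interneurons at once,
silencing the excitatory layer symmetrically: no localized state can nucleate
at low ḡ_Ks for any tested inhibitory reversal potential. Mutual inhibition
caps interneuron output during volleys and lets partial activity patterns
survive; with it, the full regime repertoire appears immediately. We
therefore read "globally connected" as including the I→I block.

Synaptic kinetics are τ_F = 0.3 ms, τ_S = 3 ms, delay τ_D = 1 ms, with
reversal 0 mV for excitatory and −75 mV for inhibitory synapses —
standard fast AMPA-like and GABA_A-like values adopted as this package's
reconstruction (they are not constrained further by the behaviors the
package reproduces).

## Integration

All cells advance synchronously with classical RK4 at dt = 0.05 ms for 5 s
(standard runs). Within a step the last-spike table is frozen; because
τ_D ≥ dt this clock-driven scheme is exact for the delayed kernel. Spikes
are upward crossings of 0 mV with a 2 ms lockout. Gates are clamped to
[0, 1] against round-off. Initial voltages are drawn per cell from
U[−70, −50] mV (seeded) with gates at steady state; the staggered initial
volley breaks translation symmetry and one pattern wins the ensuing
competition. (An alternative `limit_cycle` initializer places each cell at a
random phase of its intrinsic 10 Hz cycle; it produces a smooth asynchronous
start from which, notably, nothing ignites — the initial volley is what
seeds patterned activity.) The compiled core (numba) is verified step-for-
step against a plain-Python reference integrator.

Halving dt leaves single-cell spike times unchanged to within one step
(<0.1 ms over 2 s). Network trajectories, however, are chaotic: dt-halving
changes 1 s population spike counts by a few percent (1.7–7.8% measured at
full scale) because trajectories decorrelate, not because integration is
inaccurate; count-level agreement under dt-halving holds on horizons before
decorrelation (~250 ms) and is tested there.

## Measurements

- **Bursting measure** B = (CV − 1)/√N, where CV is the coefficient of
  variation of the inter-spike intervals of the merged spike train (all
  cells pooled) and N the number of cells that fired. For N cells spiking
  coincidently over complete periods, B = sqrt(1 − 1/N) − 1/√N exactly
  (≈0.895 at N = 100, → 1 as N grows); Poisson-like asynchrony gives B ≈ 0.
  B > 0.7 defines "synchronized".
- **Upstates**: per-cell maximal runs of spikes with consecutive ISIs below
  100 ms; singletons discarded. The gap separates within-upstate ISIs (tens
  of ms) from ~1 Hz down states.
- **ISI-phase distribution**: for cell pairs with temporally overlapping
  upstates, each spike is matched to the partner's nearest spike; the signed
  difference is normalized by the pair's mean within-upstate period and
  histogrammed over [−π, π]. Synchronous upstates pile mass near 0.
- **Center of activity and wave speed**: activity is binned at 10 ms; per
  bin the excitatory rate distribution's toroidal center of mass is taken by
  per-axis circular means; consecutive minimal-image displacements give the
  speed, averaged over the final 2.5 s. Runs are flagged (never discarded
  silently) when: no excitatory cell is active; more than 300 cells are
  active in a bin of the averaging window; the s.d. of per-bin active counts
  exceeds their mean; two or more clusters of ≥10 active cells (single
  linkage at radius R_ee) persist in ≥50% of bins; or B > 0.7.
- **Heterogeneity preference** φ = (f_in − f_out)/(f_in + f_out), with
  f_in/f_out the mean excitatory rates inside/outside a strengthened 8×8
  region, computed over the last half of the run. Rates are averaged per
  cell (not per spike); the two coincide only for equal populations.
- **Regime classification**: a deterministic decision tree over these
  diagnostics assigns one of eight labels (quiescent, mixed, stationary
  bump, traveling bump, global high-frequency, multiple bumps, planar wave,
  global burst). Stationary vs traveling is decided by the net drift of the
  center of activity, < 2 lattice units per 2.5 s; planar waves span ≥90% of
  one axis while occupying ≤40% of the other; global high-frequency means
  ≥80% of excitatory cells active in ≥80% of bins with B ≤ 0.7; a global
  burst is B > 0.7 with at least half the excitatory layer participating.
  If four equal sub-windows of the run classify into more than one family
  (localized/moving vs quiescent vs global), the run is "mixed". All
  thresholds are arguments.

## Heterogeneity protocol

`apply_heterogeneity` multiplies only excitatory-to-excitatory weights whose
*both* endpoints lie in the 8×8 region (multipliers 1.005–2.5); member cells
receive +0.5 µA/cm² for the first 0.5 s of the run, seeding activity there.
At ḡ_Ks = 0 the bump does not drift, so this seeding alone suffices to keep
activity in the region for the whole run (φ ≈ 0.8 even at multiplier 1.0);
the multiplier threshold for localization measured by an upward scan is
therefore the protocol floor. In traveling regimes (ḡ_Ks ≳ 0.3) the
unreinforced bump visits the whole sheet and φ returns to ~0; φ collapses to
half its ḡ_Ks = 0 value within ≲0.1 mS/cm² of ḡ_Ks.

## Reduced lattice for fast checks

Qualitative tests use L = 10 (100 excitatory / 16 inhibitory cells, 3 s
runs; region scaled to 3×3 to preserve its area fraction). The global
inhibitory weights (w_i→e, w_i→i) are multiplied by a single calibrated
factor 5.0 rather than the naive interneuron-count ratio 121/16: the small
lattice has a proportionally larger bump and larger interneuron shot noise,
and preserving total conductance over-inhibits. The factor was fixed once so
the reduced lattice reproduces the full-scale regime ordering (localized at
ḡ_Ks = 0, traveling at ḡ_Ks = 1) at w_i→e = 20-equivalent. On L = 10 the
ḡ_Ks = 0 bump random-walks a few lattice units per 2.5 s (small-N
fluctuations), so reduced-mode regime checks assert the drift/participation
ordering rather than the binary full-scale label. Synthetic spike fixtures
(`make_fixture`) exercise every measure against constructed ground truth:
the synchronous fixture spans complete burst periods closed by the onset
spike of the next burst, which makes the closed-form bursting measure exact
rather than asymptotic.

## Characterization protocols

- **f-I curve**: a batch of unconnected copies at different current offsets,
  rates measured after a 1 s transient.
- **PRC**: the calibrated cell is run to its limit cycle; a 0.5 ms square
  pulse is injected at 32 uniformly spaced phases of one anchored cycle
  (each phase is one cell of a batch), and the shift (T − T_perturbed)/T is
  measured on the perturbed cycle only. The amplitude is auto-scaled so the
  largest |shift| lies in [1%, 10%] of a period. Type 2 iff the most
  negative shift is below −2% of the largest |shift|. Baselines with ISI
  CV > 1% are rejected.
- **SFA**: ISIs under a step of I_tune + 2 µA/cm² from rest (upstate-like
  drive); at ḡ_Ks = 1.5 the first five ISIs lengthen monotonically, at
  ḡ_Ks = 0 they vary by <5%.

## Known limitations

- The synaptic kinetics and reversal potentials are reconstructions
  constrained only by the qualitative network behaviors; other values in
  their neighborhoods may work equally well.
- The last-spike-only synapse makes conductances non-additive across rapid
  presynaptic bursts; summed-kernel synapses would strengthen high-rate
  inputs relative to this implementation.
- Wave speeds and regime boundaries are reported for the specific lattice
  sizes above; the reduced lattice is a qualitative proxy, and its
  inhibitory scaling is calibrated, not derived.
- Watts-Strogatz rewiring, irregular placement, non-periodic boundaries,
  restricted inhibitory radii, and tonic inhibition are out of scope.
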