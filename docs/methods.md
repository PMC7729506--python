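# Methods

## The two-state (g-e) model

Each hydrocarbon chain of a saturated TAG is reduced to an effective
ground state *g* (pooled low-energy, extended conformers) and an effective
excited state *e* (pooled melted conformers with degeneracy De per chain).
Mapping the two states onto a pseudo-spin σ = +1 (g) / −1 (e) gives an
Ising model in a temperature-dependent field,

    H = −J Σ_<ij> σ_i σ_j − H(T) Σ_i σ_i,    H(T) = H0 − (T/2) ln(De/Dg),

with the sum over distinct nearest-neighbour chain pairs. All energies are
stored divided by kB, i.e. in kelvin; molar quantities are recovered as
(energy in K) × R × (chains per molecule), with R = 8.314 J mol⁻¹ K⁻¹.
The conventions Eg = 0 and Dg = 1 fix the zero of energy and make
ln_deg = ln(De/Dg) the only degeneracy parameter. The field's sign change
defines the melting temperature T\* = 2H0/ln_deg; the mean-field critical
temperature is Tc = zJ. T\* < Tc gives a discontinuous transition with
metastable branches, T\* = Tc a critical point, T\* > Tc a smooth
crossover. A classification tolerance |T\*−Tc|/Tc ≤ 1e−6 defines
"critical" numerically.

The assumptions worth keeping in view: nearest-neighbour (dispersion)
couplings only, a single transition (no α/β′/β polymorph ladder), no
internal stresses, and a mean-field treatment of the thermodynamics, which
is exact for T\* (the field's zero does not move) but shifts Tc and the
latent heat relative to an exact treatment.

## Mean-field solution

The self-consistency equation σ = tanh((zJσ + H(T))/T) is solved by
scanning σ on 2001 uniform points in [−1, 1] and refining every
sign-change bracket with Brent's method (xtol 1e−14); the map has at most
three fixed points, so the scan cannot lose a root except exactly at a
tangency. Saturated roots, where tanh rounds to ±1 in double precision,
are captured by the grid endpoints. Roots are accepted at a fixed-point
residual ≤ 1e−10.

Stability uses the variational free energy per chain

    f(σ) = −(zJ/2)σ² − H(T)σ + T[ (1+σ)/2 ln((1+σ)/2) + (1−σ)/2 ln((1−σ)/2) ],

whose stationary points are exactly the fixed points of the tanh map. With
three roots the middle one is a maximum (unstable); the extremal root with
the lower f is the equilibrium phase and the other is metastable. At T\*
the field vanishes, f is even, and the two extremal roots tie exactly; the
positive (solid) root is then reported stable by convention and the
solution carries a `coexistence` flag, keeping the output deterministic.

The enthalpy per mole of molecule on a branch is

    U(σ) = chains · R · (−(zJ/2)σ² − H0·σ) / 1000   [kJ/mol],

i.e. only the energy terms of the Hamiltonian; the −kBT ln D degeneracy
term is entropic and excluded. The model never fixes this convention
explicitly elsewhere, so it is a documented design choice of this package;
its internal check is that the branch jump at T\* reduces to
chains·R·2H0σ0/1000 (the σ² terms cancel between the ±σ0 roots) and closes
the trilaurin calibration exactly. Spinodals — the temperatures where a
metastable extremal root merges with the unstable root and disappears —
are located by bisection on the 3-root → 1-root change with temperature
resolution 1e−6 K. A supercooled branch that stays locally stable all the
way to T → 0 (which happens whenever H0 < zJ) is reported with a spinodal
at the numerical floor rather than `None`, since the branch genuinely
never terminates at positive temperature.

## Chain-length scaling

J = JC + J0·L (JC the electrostatic glycerol-core contribution), excited
chain energy Ee = E0·L, excited degeneracy De = De0(L)·3^L with the step
convention De0(0) = 1, De0(L>0) = D0, and a core degeneracy DC. The step
is implemented exactly as stated, with no smoothing, and L is real-valued
so the L → 0 and L → ∞ limits can be probed numerically. The map to model
parameters sets H0 = (z/4)J + E0·L/2, which makes T\* = 2H0/ln_deg
reproduce the closed-form T\*(L) identically; Tc/T\* then vanishes ∝ L as
L → 0 (with DC = 1) and grows ∝ L at large L with slope
2zJ0·ln3/(zJ0 + 2E0). The critical length solves Tc/T\* = 1 by Brent
bracketing (residual ≤ 1e−9). Where different printed forms of the
H0/T\*(L) relations disagree by constant factors, the mutually consistent
set (the one whose limits reproduce each other) is the one implemented.

## Trilaurin calibration

Inputs: T\* = 319.4 K (the β melting point of trilaurin — an external
physical constant, configurable, not a fitted quantity) and
ΔU = 86.7 kJ/mol, with L = 12, z = 6, three chains, D0 = DC = 1. The
inversion is closed-form: ln_deg = 12 ln 3; H0 = T\*·ln_deg/2;
σ0 = 1000·ΔU/(3R·2H0); J = T\*·atanh(σ0)/(zσ0). Because atanh(σ0) > σ0 on
(0,1), any valid calibration automatically lands in the discontinuous
regime zJ > T\*. The defaults give J ≈ 75.7 K, Tc ≈ 454 K, σ0 ≈ 0.826,
implied E0 ≈ 332 K per carbon (the scale of a gauche excitation), and a
combined metastable width of ≈ 16 K — all recomputed, not stored.

## Modified VFT lifetime and memory regions

τ(T) = τ0(exp(D\*T\*/(T−T\*)) − 1) for T > T\*; below or at T\* the solid
is (meta)stable and the call is a domain error. The curve is strictly
decreasing and convex, diverging at T\* and vanishing at infinity; its
exact inverse is T = T\* + D\*T\*/ln(1+τ/τ0). A holding pair (T, t) is
"region I" (memory persists) when t < τ(T), "region II" (memory lost)
otherwise, with ties assigned to region II — the conservative choice for a
memory-erasure protocol. D\* is held constant in T; a temperature-dependent
strength parameter would be a model extension, not implemented.

Fitting uses the linearization ln(1 + τ/τ0) = D\*·[T\*/(T−T\*)]: for any
candidate (T\*, τ0), D\* is a one-line least-squares solve through the
origin, and the outer pair is found by Nelder–Mead with τ0 in log-space
(multi-start over T\* below the coldest observation; ln τ0 clamped to
avoid overflow). τ0 and D\* are weakly identified when the data span only
a few kelvin — the usual case for memory studies — so `fix_tau0` pins the
prefactor when needed. Confidence intervals are percentile intervals from
a seeded case-resampling bootstrap (default 1000 resamples; resample fits
warm-start at the full-data solution). Boundary estimates from labelled
data take, per temperature, the geometric mean of the longest persisting
and shortest lost hold (times are log-distributed, so the geometric mean
is the symmetric estimator); temperatures missing one label are dropped
with a warning.

## Monte Carlo

Single-site Metropolis on periodic square (z = 4) and triangular (z = 6)
lattices; the triangular lattice is the physically motivated default for
hexagonally packed chains. One sweep is N attempted flips at uniformly
random sites (cleaner detailed balance than typewriter order); acceptance
min(1, exp(−ΔE/T)). Bond lists are built from directed offsets, so a
side-2 lattice uses the standard doubled-bond convention — applied
identically in the enumerator and the dynamics, which is what the
cross-checks compare. The hot loop is compiled with numba when available.
All randomness flows from a single seed; per-replica streams are spawned
via `SeedSequence`, so replica sets are bit-reproducible.

The exact enumerator sums all 2^N configurations (N ≤ 20) vectorised over
a bit matrix; at T\* the vanishing field makes the energy flip-invariant
and ⟨σ⟩ = 0 exactly, which is used as an exact (non-statistical) oracle.
Hysteresis ramps run the heating branch from all-solid and the cooling
branch from all-melt over the same temperature grid; the loop area is the
trapezoidal integral of (m_heat − m_cool) dT. First-passage lifetimes
start from the all-solid state inside the superheated window
(T\*, spinodal_high) and record the sweep count at which a block-mean
magnetization first drops to ≤ 0 (a robust, parameter-free decay
criterion); runs surviving `max_sweeps` are reported censored. Sweeps are
the only time unit — no attempt is made to map them onto laboratory
minutes.

## Synthetic data generator

The generator emulates a holding time–temperature memory study: a grid of
holding temperatures above T\*, log-spaced candidate holding times (as
such experiments are designed), one effective lifetime per temperature
drawn as τ(T)·exp(σ_noise·N(0,1)) — multiplicative lognormal noise,
preserving positivity and log-scale symmetry over the decades such data
span — and a persists/lost label per candidate time. It is
seed-deterministic, and at zero noise the labels are perfectly separated
by the generating curve.

What it does *not* emulate: the α/β′/β polymorph taxonomy of real memory
data (each memory type would be a separate VFT curve), temperature-ramp
artefacts, or correlated replicate structure. Passing parameter-recovery
tests therefore shows the estimator is consistent under the stated noise
model, not that real DSC/XRD-labelled datasets are this clean.

## Problem sizes and test-study designs

The suite's simulation studies use sizes chosen to probe each claim at
desk scale: Metropolis-versus-enumeration on 2×2 and 3×3 lattices
(12–20k sweeps), hysteresis on 10×10 lattices with 15–300 sweeps per
2.5 K block, lifetimes on 8×8 lattices with 12 replicas, and a VFT
coverage study of 100 replicates × 200 bootstrap resamples (the library
default of 1000 resamples is reserved for one-shot fits). The Monte Carlo
kinetics tests use a toy discontinuous parameter set (J = 50 K, z = 4,
T\* = 150 K < Tc = 200 K) rather than calibrated trilaurin: trilaurin's
field-to-coupling ratio makes the superheated state astronomically
long-lived on any lattice — a correct feature of the model, but useless
for finite tests.

## Known limitations

- Single transition only: no polymorphism, so the model cannot reproduce
  the multi-branch structure of real TAG memory boundaries (β versus
  early-α memory types), only the shape of each branch.
- Mean-field Tc and ΔU carry the usual mean-field bias; T\* does not.
- The VFT strength parameter D\* is temperature-independent here.
- MC lifetimes are in sweeps and qualitative; no cluster updates or
  finite-size scaling are attempted.
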