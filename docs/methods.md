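# Methods

This note documents the models implemented in `rampclamp`, the conventions
and defaults that matter for interpreting its output, what the synthetic-data
generators do and do not emulate, and the numerical choices behind the
pipeline.

## Units and constants

Coordinates are in Å, time in ns, force in pN and energy in kcal/mol
throughout; only the AFM layer uses nm and Pa, with explicit converters in
`rampclamp.units`. The Boltzmann constant is 0.138065 pN·Å/K, so
k_BT = 42.8 pN·Å at the default temperature of 310 K. The Coulomb constant
for charges in units of e, distances in Å and energies in kcal/mol is
332.0636.

## Interfacial chemistry

**Hydrogen bonds.** A cross-group bond exists when the donor-heavy-atom to
acceptor distance is strictly below 3.5 Å and, when a hydrogen can be
attributed to the donor, the deviation angle — measured at the donor between
the D→H and D→A vectors — is strictly below 30°. This deviation reading is
the convention of the common visualisation tools; it is the only reading
under which a "D–H–A angle of 20°" counts as a bond with a 30° cutoff.
Hydrogens are attributed geometrically (element H, same residue and chain,
within 1.2 Å of the donor heavy atom) because the topology sidecar carries no
bond list; donors without an attributable hydrogen are evaluated
distance-only and flagged as such. Bond identity is the
(donor-heavy, acceptor) atom pair, so one residue pair can contribute several
tracked bonds; the heatmap export aggregates atom-level bonds to
residue–saccharide pairs by maximum occupancy.

**Salt bridges.** Any side-chain oxygen of Asp/Glu (OD1/OD2, OE1/OE2) within
strictly 4 Å of a side-chain nitrogen of Lys/Arg (NZ; NE/NH1/NH2), reported
per residue pair. Boundary values (exactly 3.5 Å / 4.0 Å / 30°) are
non-bonds; the boundary behaviour is tested explicitly.

**Occupancy and P_D.** The occupancy o_i of bond i is the fraction of frames
in which it is present. The dissociation probability is

    P_D = Π_i (1 − o_i),

the probability that no interfacial bond is present in a random frame if
bond presence events are independent. This is an approximation — real
interfacial bonds are correlated — but it is exactly the statistic the
telegraph generator realises, and the Monte-Carlo zero-bond frame frequency
agrees with the product within sampling error in the closed-loop tests. An
empty occupancy table gives P_D = 1 by convention; adding a bond with o = 0
leaves P_D unchanged; P_D is non-increasing in every o_i.

**Interaction energy.** E = Σ over cross-group pairs within 12 Å of
Coulomb (ε_r = 1) plus 12-6 Lennard-Jones terms with Lorentz–Berthelot
combination (ε_ij = √(ε_i·ε_j), Rmin_ij = Rmin/2_i + Rmin/2_j), plainly
truncated. This is a per-frame descriptor of interface engagement and is
deliberately *not* an MD-grade energy: no Ewald summation, no switching
function, no polarisation. It should be compared only against itself.

## Conformational descriptors

Superposition is the Kabsch least-squares rigid fit (SVD with a determinant
correction, so the rotation is always proper); it is validated against an
independent quaternion (Horn) oracle to 1e-9 relative. RMSD time courses
superpose each frame on the **first frame** of the analysed trajectory over
the fit selection — the reference frame is a convention, and results with a
different reference differ accordingly. RMSF is √⟨|x−⟨x⟩|²⟩ per atom over
frames (after optional superposition), averaged over each residue's selected
atoms.

SASA uses the Shrake–Rupley construction with a deterministic golden-spiral
point set (default 960 points, ≤1% error on spheres) and a 1.4 Å probe.
Van der Waals radii come from a bundled element table (H 1.10, C 1.70,
N 1.55, O 1.52, S 1.80, P 1.80, F 1.47, Cl 1.75 Å), with the Lennard-Jones
Rmin/2 as fallback for unknown elements. A selection's SASA is computed with
only the selected atoms present, plus an optional occluding `environment`
set. Buried SASA is SASA(A) + SASA(B) − SASA(A∪B), **not halved**: it is the
total interface area over both partners.

The pocket cross angle φ ∈ [0, 180]° is the planar angle at the Tyr46 Cα
vertex between the arms to the Arg155 and Ile100 Cα atoms (all three
selectable). The chain bend angle θ uses a reflex convention: with a the
planar angle at the middle chain marker, θ = a when the middle atom bows
toward a supplied reference point (the receptor side — chain convex toward
the binding site) and θ = 360 − a otherwise; a collinear chain gives exactly
180°. The convention makes concave and convex chain shapes distinguishable
in one scalar and satisfies θ(mirrored frame, mirrored reference) = θ. The
pocket distance *l* is the Arg155–Ile100 Cα distance.

## Ramp-clamp simulator

The simulator is a **protocol analogue, not an MD replica**: overdamped
(inertialess) Langevin dynamics of beads with harmonic bonds,

    x ← x + (F/γ)·dt + √(2·k_BT·dt/γ)·η,

with fixed beads never moving. The steering construction follows the
standard ramp-clamp protocol: a dummy point starts at the steered bead's
position and moves at constant velocity v along the pulling axis; a 1-D
spring of stiffness k (default 13.90 pN/Å, v = 5 Å/ns) acts on the steered
bead along that axis, giving a nominal loading rate k·v = 69.5 pN/ns (the
realised rate is lower by the compliance factor 1/(1 + k/k_anchor); the
stiff-anchor test recovers 69.5 within 1%). At the first step where the
spring force reaches the clamp threshold (default 25 pN) the spring is
replaced by a constant applied force of exactly that magnitude — the clamp is
an applied force, not a servo on the spring, so the dummy/spring columns of
the force log are meaningful only during the ramp.

Interface bonds rupture irreversibly, either deterministically when their
extension exceeds a threshold, or stochastically with a Bell rate
k(F) = k₀·e^(±F·x_b/k_BT) (slip: +, catch pathway: −) applied per step with
probability 1 − e^(−k·dt). Rebinding is not modelled in the simulator; the
analytic lifetime sampler in the synthetic-data module is the place for
richer kinetics. Because the Bell exponent needs k_BT > 0, the configuration
carries a separate `kinetics_temperature` (default: the mechanical
temperature) so deterministic T = 0 mechanics can be combined with 310 K
kinetics; this is how the clamp-lifetime checks obtain bond tension exactly
equal to the setpoint.

Constraint patterns on a chain of odd length: S0 fixes nothing, S1 the
middle bead, S2 both ends, S3 ends and middle.

**Numerical stability.** The explicit Euler–Maruyama update requires
k·dt/γ < 0.1 for every bond and for the pulling spring; configurations
violating this are rejected before integration. The discretised
Ornstein–Uhlenbeck variance is biased by the factor 1/(1 − k·dt/2γ), which
is below 1% at the enforced step sizes. Identical model, configuration and
seed give bit-identical outputs.

## Event extraction

**Rupture peaks.** The force is smoothed with a centred moving average
(default window 0.1 ns); the candidate peak is the smoothed global maximum,
accepted only if the smoothed force later stays below half the peak
(configurable) for at least one window. The reported force and time come
from the raw maximum within one window of the smoothed peak, so noiseless
plants are recovered exactly. Real pulling force–time curves oscillate and
the field rarely states how peaks are read off; window and drop fraction are
therefore explicit parameters.

**Dissociation time** is the first time a contact series (buried SASA or
bond count) falls below 10% of its initial-plateau mean (first 1 ns by
default) and stays below for a dwell of 1 ns. **Named-bond breakage** is the
start of the bond's final absence run of at least 1 ns, with the force read
from the log at that time.

**AFM adhesion events.** Baseline and noise come from the median and
1.4826×MAD of the final 20% of the retract trace (robust to the adhesion
excursions themselves). Samples above baseline + 3σ are clustered (bridging
gaps of up to two samples), and a cluster is an event when it has at least
three samples and ends discontinuously — cluster maximum minus the mean of
the following ≤3 samples exceeds 3σ. The width requirement is what keeps the
false-positive rate below 1% per trace: a bare threshold-plus-step rule
accepts single-sample noise spikes roughly a quarter of the time on a
~400-sample trace. Measured on 1000 synthetic traces each: 0 false positives
and >99% detection power for 5σ plants. The retract force column stores
adhesion tension as a positive excursion above baseline.

**Lifetimes.** A clamp lifetime runs from first entering setpoint ±
tolerance to the force leaving the band downward permanently; records ending
in-band are censored and excluded from binned means (but counted). Lifetime
bins are left-closed, right-open.

**Catch–slip model.** τ(F) = 1/(k_c·e^(−F·x_c/k_BT) + k_s·e^(+F·x_s/k_BT))
is the minimal two-pathway model of a catch–slip bond; its lifetime optimum
is F\* = k_BT/(x_c+x_s)·ln(k_c·x_c/(k_s·x_s)), and the fit is classified
biphasic when F\* is interior to the observed force range. The default
estimator is exponential maximum likelihood over the raw lifetimes
(multi-start L-BFGS-B on (ln k_c, x_c, ln k_s, x_s) with non-negativity
bounds); for per-level means the level mean is the sufficient statistic, so
a least-squares fit of log mean lifetimes (`method="ls"`, the default for
binned input) is the natural alternative and reproduces the analytic F\* to
1e-6 on noiseless input. The two prefactor/width pairs are strongly
correlated: recovering all four parameters to ~15% needs lifetimes at many
force levels spanning well past the optimum. The recovery experiments use
60 levels uniform on 1–100 pN at 200 lifetimes per level, chosen by a Fisher
information analysis so that 15% corresponds to roughly three standard
errors.

## Hertz indentation

The conical (Sneddon) contact law is F = (2/π)·tanα·E/(1−ν²)·δ². Some
sources typeset the prefactor as 2π; the package uses the standard 2/π — the
two differ by π² in fitted E — and provides a `literal_prefactor` switch for
comparison with such sources. ν defaults to 0.5 (incompressible soft
matter); the tip half-opening angle α has no default, since it is a property
of the probe. Indentation depth δ is piezo travel past the contact point,
without cantilever-deflection correction (the bead-level definition of the
protocol this package mirrors); fits with a deflection-corrected δ would
require the cantilever spring constant and are out of scope. The contact
point is the changepoint minimising the total squared error of a flat-then-
quadratic piecewise model over the approach trace; the modulus then comes
from the closed-form least-squares coefficient of F = c·δ² on the
post-contact region, E = c·π·(1−ν²)/(2·tanα). The estimator is unbiased to
within one sample spacing and recovers planted moduli within 1% (noiseless)
and 10% (5% multiplicative noise).

## Synthetic data: what it emulates, and what it does not

The toy complex is a ~17-bead caricature of a receptor binding pocket with a
7-saccharide ligand chain (alternating GlcNAc/GlcUA, resids 1175–1181,
middle 1178): every selection, interface pair, constraint pattern and
descriptor used by the analysis modules resolves on it. Interface bonds
default to Bell-rupture kinetics (k₀ = 0.2/ns, x_b = 1 Å; the internal
Glu52–Tyr166 latch 0.05/ns) because at the toy model's soft spring constants
(30–50 pN/Å) thermal extension fluctuations are ~1.7 Å and would cross any
deterministic threshold reachable by a 25 pN clamp.

The telegraph generator gives each planted bond an independent two-state
Markov chain with stationary presence probability o_i and relaxation time
τ_c, realised as donor–acceptor distances of 3.0 Å (bonded) and 4.5 Å
(unbonded) — both placed well clear of the 3.5 Å cutoff so detector boundary
behaviour is tested separately from occupancy statistics. Occupancies of
exactly 0 or 1 become constant states. Estimator standard errors on
telegraph data carry the autocorrelation inflation factor
(1+ρ)/(1−ρ), ρ = e^(−Δt/τ_c).

What passing the closed loops does **not** show: real interfacial bonds are
correlated and water-mediated, real force curves carry coloured
instrument/solvent noise, real AFM retract traces have tether stretching and
hydrodynamic drag, and the bead model has no sequence-dependent mechanics.
The closed loops demonstrate that the analysis stack measures what the
generators plant, at the stated tolerances — not that the generators
reproduce laboratory data.

## Problem sizes used by the test suite and acceptance script

Telegraph occupancy/P_D runs use 2×10⁴–10⁵ frames; the Monte-Carlo P_D
check compares the product rule with the zero-bond frame frequency over 10⁵
frames (test) / 5×10⁴ frames (script) within three autocorrelation-inflated
standard errors. Bell-lifetime Kolmogorov–Smirnov checks use 1000 replicas
at three clamp forces. AFM detector calibration uses 1000 event-free and
1000 planted traces. Catch–slip recovery uses the 9-point grid described
above. The full test suite runs in about two minutes on one CPU; the
acceptance script in about one.

## Known limitations

- P_D inherits the independence assumption; on correlated interfaces it is a
  lower bound on the true zero-bond probability in typical (positively
  correlated) cases, and the package makes no correction for this.
- The interaction energy is a truncated descriptor; absolute values are not
  comparable across force fields or to Ewald-based MD energies.
- The simulator's clamp applies exactly the setpoint force; compliance of a
  real transducer and servo dynamics are not modelled.
- `bond_breakage` defines breakage by the final absence run; bonds that
  flicker until the very end of a record return no event by design.
- The Hertz fit assumes a half-space; thin-film (bottom-effect) and
  viscoelastic corrections are out of scope.
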