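# Methods

## The problem

Quinol oxidation in the Q_o site of the cytochrome bc1 complex releases two
protons that must travel from the substrate to surface acceptors through
chains of hydrogen-bonded waters and protonable side chains (proton wires),
by Grotthuss hopping: covalent O-H/N-H bonds break and re-form along the
wire rather than any single proton diffusing. `protonwire` implements the
analysis machinery for this problem: a smooth collective coordinate that
tracks the excess proton across many carriers, biased sampling along it,
free-energy reconstruction with uncertainties, wire enumeration from
structures, and a bioenergetic feasibility classification of the resulting
profiles. The quantum-chemical potential that such studies use for real
proteins is out of scope; the sampling engine is potential-agnostic and the
package ships synthetic wire systems whose exact profiles are known, so
every stage of the chain can be validated end to end.

## The mCEC / zeta coordinate

The modified center of excess charge is the 3-D point

    eps = sum_i r_Hi - sum_j w_j r_Xj + sum_i sum_j f_sw(d_ij) (r_Xj - r_Hi)

with i over the mobile protons, j over protonable heavy atoms, and

    f_sw(d) = 1 / (1 + exp((d - r_sw)/d_sw)),   r_sw = 1.20 A, d_sw = 0.04 A.

The weight w_j equals the number of protons the atom holds in its reference
state (water O 2.0, Tyr O-H 1.0, His ring N 0.5, carboxylate / propionate /
quinone O 0.0), so with a single excess proton sum(w) = n_protons - 1 and
eps transforms like a position under rigid motions. The pairwise switching
term snaps eps onto whichever heavy atom currently binds the excess proton
and interpolates smoothly during bond breaking.

For biasing, eps is reduced to the relative transfer coordinate

    zeta = d(eps, donor) / (d(eps, donor) + d(eps, acceptor))  in [0, 1],

0 at the reactant (donor protonated) and 1 at the product. Analytic
gradients of zeta with respect to all atom positions are implemented by the
chain rule through eps, f_sw and the distance ratio; they are validated
against central finite differences to 1e-6 per component, and rows sum to
zero (translation invariance). f_sw is evaluated as (1 - tanh(x/2))/2,
which cannot overflow at any distance.

## Sampling protocol

Langevin dynamics (BAOAB splitting) at 310 K with collision frequency
25 ps^-1 and a 1 fs step; masses in amu, lengths in A, energies kJ/mol
(k_B = 0.0083144621 kJ/mol/K). Umbrella windows divide [0, 1] into centers
0.1 apart with k_umb = 1000 kJ/mol per unit zeta^2 (the force constant is
read per unit of the dimensionless coordinate; the same convention is used
in the WHAM bias energies). Flat-bottom positional restraints (2.0 A wide,
150 kJ/mol/A^2 half-harmonic walls) confine mobile waters.

Two refinement mechanisms extend the base ladder when needed:

* **overlap refinement** - adjacent windows sharing less than 0.10
  normalized histogram area get a midpoint window with k' = 3 k_umb
  (escalating up to 9 k where one level is not enough);
* **gap filling** - interior zeta stretches whose pooled histogram holds
  fewer than a handful of samples receive stiff windows across the run.
  This catches holes that pairwise overlap cannot see: two windows whose
  centers bracket a steep wall may both equilibrate into the same basin.

Refinement decisions are taken on the post-equilibration part of each
window (the samples WHAM will use), not on transient crossing trails.
Windows stiffer than 3000 kJ/mol run with a proportionally smaller time
step (dt ~ sqrt(3000/k) fs) so the biased oscillation stays resolved; the
total simulated time per window is preserved. Each window is seeded from
its own deterministic noise stream (seed = base seed + window index), so
trajectories are bit-reproducible and independent of which windows share a
batch.

For 1-D toy wires all windows propagate as one vectorized batch
(`propagate_windows_1d`), with each window initialized at its own target
zeta via the known coordinate map - this avoids hysteresis when a window
ladder is dragged across sticky stretches of the coordinate.

## WHAM and uncertainties

Profiles are reconstructed by the standard self-consistent WHAM iteration
on binned zeta samples, iterated until the window free-energy shifts move
by less than 1e-8 kJ/mol. Numerical choices:

* **output bins** 0.01 wide in zeta; internally the solve runs on a grid
  oversampled 10x and aggregates afterwards, because stiff refinement
  windows violate the bias-constant-per-bin assumption at 0.01;
* **equilibration discard** - the leading 20% of every window (0.1 ns of a
  0.5 ns window) is dropped;
* **support restriction** - each window's normalization runs over the
  contiguous hull of bins it actually visited (plus one output bin of
  padding). A window kinetically confined to one basin of a bimodal biased
  ensemble then contributes that basin's conditional density, instead of
  being treated as if it had equilibrated across an internal barrier it
  never crossed;
* **connectivity** - windows must form a single overlap component (two
  windows are linked when their visited supports come within half an
  output bin); otherwise the relative offsets of the components are
  undetermined and the fit aborts naming the unsampled gap;
* **anchor** - G = 0 at the sampled global minimum.

95% confidence bands come from a per-window block bootstrap with 30
resampling cycles: time-contiguous blocks of length twice the integrated
autocorrelation time of zeta (Sokal's 5-tau self-consistent window, floor
10 samples), WHAM re-solved per resample, and normal-approximation bands
G_hat +/- 1.96 SD. At 30 cycles raw 2.5/97.5 percentiles are extreme order
statistics and unstable, which is why the SD form is used.

## Profile features and classification

Profiles restricted to sampled bins are smoothed by a Savitzky-Golay local
polynomial (window 11 bins, order 3) and scanned for interior extrema with
prominence above 1 kJ/mol. The reactant (product) basin is the minimum
nearest zeta = 0 (1), dG_R their difference, and the forward barrier the
highest point between them relative to the reactant.

Classification applies ordered rules with configurable thresholds
(defaults in kJ/mol):

1. required ascent or dG_R > 70 -> `infeasible_uphill` (more free energy
   than complete quinol oxidation provides);
2. an interior minimum >= 20 below both flanking maxima ->
   `trapped_intermediate` (deep enough that thermal escape at 310 K stalls
   the transfer; an escape barrier above 70 traps regardless);
3. dG_R < -70 -> `dissipative_downhill` (a "hot proton" would transfer
   indiscriminately and the step could not run in reverse);
4. reverse barrier < 15 -> `unstable_product`;
5. forward barrier <= 45 and |dG_R| < 20 -> `plausible`.

The rule order and the threshold sides (strict where stated above) are
package policy; profiles matching no rule - e.g. a forward barrier in
(45, 70] with small dG_R - resolve to the nearest violated side
(uphill-leaning to `infeasible_uphill`, downhill-leaning to
`dissipative_downhill`), keeping the classification total and
deterministic. Both-direction feasibility checking is available as an
option; the default judges the forward direction.

Trajectory analysis assigns every mobile proton to its nearest protonable
heavy atom; the site exceeding its reference proton count holds the excess
(a water owning three protons is tagged hydronium-like). Hop sequences are
debounced transitions of the holder (minimum residence 10 saved frames),
so sub-residence flicker across a shared proton emits no event.

## Synthetic wires

A toy wire is a donor, 0-5 water-like carriers and an acceptor on a line at
2.7 A spacing, with one excess proton. Each site binds the proton through a
soft-core logistic attraction well: depth = the site's proton affinity
(kJ/mol), radius 1.25 A, wall width 0.08 A. Two properties of this shape
are load-bearing:

* the core is *soft* (finite plateau across the site center, representing
  the hydronium-like protonated state), because in one dimension a
  hard-core bond well would make the carrier nucleus impassable;
* the wall is *aligned with the mCEC switching region*, so the binding
  energy is expressed while zeta responds. A wall much wider than d_sw
  puts most of the affinity change where zeta is saturated, producing
  near-vertical cliffs in G(zeta) that no umbrella window of any stiffness
  can hold at a 1 fs step.

In the default 1-D mode the excess proton is the only mobile degree of
freedom and carriers are bare (w = 0) acceptor-like sites, so the partition
function is a one-dimensional integral: the reference profile is computed
by dense quadrature (trapezoid at dx = 2e-5 A; halving dx changes G by
< 0.01 kJ/mol) and is exact for the sampled system - the package's
independent truth. The 3-D mode carries explicit reference protons (waters
two each, w = 2; donor hydroxyl one, w = 1) plus screened proton-proton
repulsion and heavy-atom tethers, exercising the full vector mCEC/gradient
path without an exact oracle.

Scenario presets emulate the four canonical profile shapes at the
magnitudes typical of quinol-oxidation proton transfers; they are scenario
templates, not physical predictions:

| preset      | affinities (kJ/mol)      | shape                                     |
|-------------|--------------------------|-------------------------------------------|
| `plausible` | 38 / 22 / 32             | forward ~36, dG_R ~ +6                     |
| `trapped`   | 70 / 45(+50 trap) / 62   | mid-wire minimum ~55 below flanking maxima |
| `uphill`    | 170 / 65 / 45            | ascent with dG_R > +100                    |
| `downhill`  | 45 / 30 / 38, redox -90  | dG_R ~ -81                                 |

The redox switch adds an energy to the acceptor-side well bottom (negative
= deeper product well), emulating electron transfer that activates the
acceptor; dG_R tracks it approximately linearly.

### What the toys do and do not show

The toys reproduce the statistical structure the analysis assumes -
multiple carriers, metastable intermediates, redox-shifted wells, windows
that must be refined across steep stretches - with an exact reference. They
do not model real electrostatics, polarization, carrier reorientation
entropy, or multi-proton coupling; passing the recovery tests shows the
*estimation chain* is correct at these conditions, not that any particular
protein profile is right.

## Problem sizes used in the shipped checks

Umbrella recovery runs 11 base windows of 50 ps each (plus refinement) per
preset; the bootstrap-calibration experiment runs 50 replicates at 15 ps
per window on the near-thermoneutral wire; the thermostat checks use a
10-particle harmonic system for 0.3-1 ns. These sizes were chosen so the
whole validation chain runs on a single CPU in minutes while keeping
per-window sampling a large multiple of the zeta autocorrelation time
(~0.1-0.2 ps in the wells).

## Known limitations

* Windows whose biased ensemble is split by an internal barrier much
  larger than k_B T sample one basin only; the support-restricted WHAM
  treats this correctly as conditional sampling, but regions reachable by
  no window stay unsampled and, if they disconnect the ladder, the fit
  honestly refuses rather than guessing the offset.
* The pipeline samples synthetic surfaces only; applying the full chain to
  a protein requires an external energy/force provider satisfying the
  `PotentialSurface` contract.
* Single excess proton per system; no periodic boundaries (cluster models).
* Barrier heights are not converted to rates; classification is purely
  free-energy based.
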