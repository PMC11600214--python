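# Methods

This note documents the models and procedures implemented in `transpath`,
the parameters that matter, and the choices made where the design was
genuinely open. Internal units are nm, kJ/mol, ps and K throughout, with
kB = 0.008314 kJ mol⁻¹ K⁻¹.

## The problem

A two-state (multi-state) protein has two experimentally resolved
conformations A and B. The package generates a physical description of the
transition between them: a free-energy surface over the two collective
variables (RMSD to A, RMSD to B), the lowest-barrier transition pathway and
its transition state on that surface, a distance-matrix representation of
the high-energy state, a neural model trained to predict such matrices
directly from the two endpoint structures, and a restrained-annealing
procedure that turns predicted matrices back into Cα structures.

## Dataset rules and contact statistics (`curation`)

A structure pair qualifies as multi-state iff sequence identity > 90 %,
best-fit Cα RMSD > 0.5 nm and the longest alignment gap < 21 residues, with
sequence length > 50. Terminal loops are trimmed before the RMSD: mapped
positions are dropped from either end while either state's secondary
structure code is `C`. Identity is the match fraction over the columns of a
global alignment with identity scoring and affine gaps (open 10,
extend 0.5); any fixed convention serves the rule, and this one is logged.

Single-state clusters: more than five members with all pairwise RMSD below
0.2 nm yield the shortest-sequence member as representative.

Transitions are classified by the mapped secondary-structure strings:
more than five residues alternating between helix and strand → Category IV;
more than five residues melting from helix/strand to coil (or folding from
coil) → Category III; otherwise a rigid-block heuristic separates
Categories I and II: residues are greedily clustered into blocks whose
internal distance changes between the states stay below 0.2 nm, and the
transition is Category I iff at least two blocks of ≥ 30 residues move
relative to each other (both thresholds overridable). This replaces visual
inspection with a reproducible rule.

Contact-type frequencies F_pq are computed over the 210 unordered
residue-type pairs: per protein, the count of pairs with Cα separation in
(0.3 nm, 1.0 nm) divided by N_p·N_q, averaged over the dataset. Proteins
lacking a type contribute zero for it. For structure pairs both states are
counted and averaged. The multi-state/single-state ratio is
R_pq = 2 F_MS / (F_MS + F_SS) ∈ [0, 2]; types absent from both datasets are
reported missing (NaN), not zero. Changed-contact frequencies count pairs
whose Cα distance shifts by at least 0.5 nm between the states (formed plus
broken pooled), normalized the same way.

## The dual-basin Cα model (`cgsim`)

Bead-per-residue structure-based model with

* bonds V = ½ k_b (r − r₀)², k_b = 20000 kJ mol⁻¹ nm⁻²,
* pseudo-angles V = ½ k_a (θ − θ₀)², k_a = 40 kJ mol⁻¹ rad⁻²,
* pseudo-dihedrals V = k_d[(1 − cos Δφ) + ½(1 − cos 3Δφ)], k_d = 1 kJ/mol,
* native contacts as 12-10 wells V = ε[5(r₀/r)¹² − 6(r₀/r)¹⁰] with uniform
  depth ε = 1 kJ/mol for every contact,
* excluded volume ε(σ/r)¹² with σ = 0.4 nm on all non-contact pairs with
  |i − j| ≥ 3, truncated beyond 2.5 σ.

Contacts are a Cα cutoff map (0.8 nm, |i − j| ≥ 4); a shadow-type all-atom
map is out of scope, and the cutoff is configurable. For a two-state pair
the contact set is partitioned into common contacts (well minimum at the
mean of the two native distances; both per-state distances are recorded)
and contacts unique to either state. Bonded reference geometry comes from
state A; angles and dihedrals whose reference value conflicts between the
states — geometrically (|Δθ₀| > 0.3 rad, |Δφ₀| > 0.5 rad wrapped) or
because the secondary structure differs — are excluded by default
(`conflict_scale = 0`, configurable to partial strengths). Without this,
bonded terms built from one state overwhelm the other basin's unique
contacts; excluding them lets the contact sets decide between the basins,
which is the point of a dual-basin construction.

Forces are analytic (verified against central finite differences to ~1e-10
relative) and compiled with numba; mass is 1 (reduced) per bead.

### Dynamics and biasing

Langevin dynamics uses BAOAB splitting; with zero friction it reduces to
velocity Verlet (energy drift < 1e-3 kJ/mol per 10³ steps at dt = 0.0005 ps
on the test systems). Default dt = 0.0005 ps, friction 0.1 ps⁻¹ (a low
friction limit; annealing uses 1 ps⁻¹).

Well-tempered metadynamics deposits a Gaussian every 500 steps with initial
height 1.0 kJ/mol, width 0.05 (CV units) and bias factor 50; the deposit
height decays as exp(−V_bias/(kB·ΔT)) with ΔT = (γ−1)T. The collective
variables are best-fit RMSD to each endpoint; the CV gradient is the
analytic best-fit-RMSD derivative (envelope theorem through the optimal
rotation and centroids). During a run the accumulated bias lives on a grid
(spacing 0.0125 nm, domain [0, 4] nm per CV) read by bilinear
interpolation; every deposited Gaussian is also logged exactly, and the
free-energy estimate F = −(γ/(γ−1))·ΣGaussians (minimum shifted to zero)
is always computed from the exact hills log, not the grid.

The simulation temperature is not part of the published protocol and is a
model parameter here. The default (110 K) is of order ε/kB; the synthetic
hinge studies run at 75 K, ≈ 0.9 of the toy's folding temperature, where
both endpoint basins are clear free-energy minima — hotter runs let
entropy favor partially detached intermediates.

## Pathway search (`pathfind`)

Two rounds on the estimated surface. Round one: elastic bands of 7 beads,
endpoints fixed at the two basin minima, interior beads initialized
uniformly at random, relaxed for 1000 iterations under the perpendicular
component of the landscape gradient plus a full elastic force (the full
spring also straightens kinked random initializations on flat regions;
the slight corner-cutting this allows is immaterial for barrier scoring on
smooth surfaces). Steps are normalized with a cap decaying from 0.25 to
0.025 grid cells. 100 restarts for each spring constant 0.3/0.6/0.9/1.2
(treated as dimensionless relative weights) give 400 candidates.

Round two: 50 Metropolis grid walks: from the current cell a uniform
4-neighbor proposal is accepted with min(1, e^(−ΔF/kBT)); failed walks
(end not reached within the proposal budget) are reseeded until 50
succeed, so the two-round total is exactly 450. Loops are pruned from the
returned path (on revisiting a cell the detour is discarded). The walk
temperature is a search parameter, not a physical one: on surfaces with
tens of kJ/mol of relief it must be scaled to the landscape (roughly
kB·T_walk ≈ cell-level ΔF) or walks cannot cross within the budget.

Candidate barriers are max F − F(start) along the polyline, densified to
sub-cell resolution and evaluated by bilinear interpolation; the lowest
barrier wins (ties: shorter arc length, then lower mean F) and its peak is
the transition state. The transition-state ensemble averages the pairwise
distance matrices of trajectory frames whose CVs fall within ±0.08 nm of
the transition state in both coordinates.

An exhaustive minimax (widest-path) oracle — binary search over F
thresholds with 4-connected flood fill — provides the independent check.
Note the oracle works on grid nodes: walk candidates (node paths) can
never beat it, while relaxed-band candidates interpolate between nodes and
may score up to about one grid-cell F-range below it.

## Featurization (`featurize`)

D(r) = 1 − (1 + e^(1−r))⁻¹ maps distances (nm) to (0, 1−1/(1+e)];
D = 0.5 exactly at r = 1 nm defines contact formation, and D → 0 at large
separation. For simulated transition states the ensemble-mean distance is
transformed (average first, then sigmoid). Contacts in exactly one state
are *unique*, in both *common*; pairs with |i − j| < 3 are excluded from
both masks (trivially near along the chain), and *non-unique* is the
complement of unique. Per-residue importance sums the negative parts of
D_TS − D_native over partners (sign flipped), so larger scores mean more
contact loss at the transition. The max-fold metric is the pathway maximum
of a property divided by the larger endpoint value.

## Distance-matrix models (`models`)

The two endpoint matrices stack into a 2-channel L×L input for a residual
CNN: a 3×3 stem to 64 channels, eight residual blocks (y = x + conv3×3(relu x)),
then a per-position head of 64 cells (1×1 convolutions 64→64→1). The raw
output is symmetrized as (M + Mᵀ)/2 — averaging rather than summing keeps
the output scale — and clamped to the sigmoid range at prediction time.
The pathway variant shares the backbone with three heads for the anchors
(pre-transition, transition, post-transition); the full series is
elementwise linear interpolation through [A, s2, s3, s4, B].

The engine is a self-contained float32 numpy implementation (im2col GEMM
convolutions with hand-written backward passes). The network output is
parameterized as a deviation from the average of the two endpoint
matrices — common contacts barely change along the pathway, so the
endpoint mean is the natural baseline and the heads only learn the
correction. Optimization is SGD at learning rate 0.001 with momentum 0.9
on the weighted squared error with unique-contact pairs up-weighted 5:1;
the training gradient is that of the raw weighted sum, and two standard
stabilizers compensate for the absence of normalization layers:
residual-block and final-head convolutions are initialized near zero
(N(0, 0.01), so the untrained stack reproduces the baseline) and the
global gradient norm is clipped at 1.0. The loss reported during training
is the weight-normalized mean (weighted sum divided by the sum of
weights), comparable across matrix sizes; the raw 5:1 weighted *sum* is
available as `weighted_loss`. One example per SGD step, shuffled epochs,
best-validation checkpoint; evaluation restricts to unique-contact pairs
in the upper triangle (Pearson r and MAE).

## Structure generation (`reconstruct`)

A single-basin model of the reference state is modified in the declared
changing regions: native contacts there are removed, and every predicted
contact (D ≥ 0.5) becomes a flat-bottom harmonic restraint of strength
2.0 kJ/mol centered at the inverse-sigmoid distance of the predicted value
(tolerance half-width 0.02 nm). Angles and dihedrals touching residues of
removed contacts are softened (×0.5) — their reference geometry is
ambiguous mid-transition, and leaving them at full strength biases the
annealed structures several tenths of a nm away from the target. Ten
simulated-annealing runs (linear 100 K → 10 K over 3×10⁶ steps by default)
each return their final frame; structures whose bond lengths deviate more
than 10 % from reference are rejected. `select_best` picks the minimum
mean-squared restraint violation.

## Synthetic data (`fixtures`)

*Hinge protein*: two ideal Cα helices (0.38 nm bonds) joined at the chain
midpoint. Both states are packed two-helix conformations chosen from a
deterministic grid of arm azimuths, junction elevations and helix phases:
state A maximizes the arm-arm interface at the requested bend angle;
state B is the most distant clash-free packing with a comparable interface
size (so the two basins are similarly stable under uniform contact
strength). Internal bond lengths are identical between states (the arm is
rigidly transformed), so only junction geometry differs. Ground truth
(RMSD, unique/common contacts, the hinge set = pivot region plus all
unique-contact residues) is recorded by independent brute-force scans.
At 40 residues and 90° the two states differ by ≈ 0.9 nm RMSD with ~8-10
unique contacts per side. What this fixture does *not* emulate: real
residue-type contact energetics, side chains, solvent, or rugged
landscapes — passing tests show the machinery is correct on a clean
two-state system, not that predictions transfer to real proteins.

*Landscapes*: closed-form double/triple wells (exact saddle and barrier),
an S-shaped channel with a flat-floored corridor and steep linear walls
(single exact saddle), and Gaussian-filtered random landscapes with two
carved basins. *1D double well*: V = b((x/a)² − 1)², exact barrier b,
run through the same integrator interface as the protein systems.

*Training corpus*: toy hinge proteins with random lengths and bend angles;
inputs are the two state features and the target is a fixed rule
(elementwise min / geometric mean / midpoint) on unique pairs and the
midpoint elsewhere. The rule-recovery experiments test whether training
identifies a known generative rule.

## Problem sizes used by the test suite

Tests run the method at desk scale: metadynamics studies use the
40-residue hinge with 4×10⁶ steps (about 8000 hills) for the end-to-end
pipeline and 10⁶ steps for the 1D free-energy recovery; annealing checks
use 4 runs of 4×10⁵ steps; the search-versus-oracle audit uses twenty
40×40 landscapes; CNN experiments use 20-250 synthetic proteins of L = 32.
These sizes are the package's own reproducibility conditions; the defaults
in the code (e.g. 3×10⁶ annealing steps) remain the published protocol's.

## Known limitations

* The free-energy surface from desk-scale runs is qualitatively converged
  (clear basins, finite barrier) but barrier heights retain a few kJ/mol
  of hysteresis; the published protocol runs two orders of magnitude
  longer.
* The walk round of the search needs a landscape-scaled temperature to
  contribute on high-relief surfaces.
* The Cα sphere SASA is an approximation adequate for max-fold ratios,
  not for absolute areas.
* All-atom reconstruction, shadow contact maps and side-chain modelling
  are out of scope; outputs are Cα-only.
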