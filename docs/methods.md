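# Methods

## Ligand-binding model

IGF1R is modeled as a preformed dimer with two equivalent ligand-binding
pockets.  A pocket is empty, singly bound at site S1 or S2, or crosslinked
(one ligand engaging both sites).  Crosslinking of one pocket sterically
blocks crosslinking of the other, so a dimer has nine admissible
configurations, three of them crosslinked; a dimer is active
(autophosphorylation-competent) iff a pocket is crosslinked.  The
per-pocket cycle

    E  <-a1·L / d1->  S1  <-a2' / d2'->  X
    E  <-a2·L / d2->  S2  <-a1' / d1'->  X

is thermally driven, so the eight rate constants satisfy detailed balance,
(a1/d1)(a2'/d2') = (a1'/d1')(a2/d2), leaving seven free.  The packaged
defaults are the best-fit constants (a1 = 2.8e5 M⁻¹s⁻¹, d1 = 5.0e-2 s⁻¹,
a2 = 1.5e4 M⁻¹s⁻¹, d2 = 1.9e-4 s⁻¹, a1' = 5.6e-3 s⁻¹, d1' = 1.9e-5 s⁻¹,
d2' = 1.3e-2 s⁻¹, a2' = 52 s⁻¹).  Because the reported values
are rounded to two significant figures this set closes the cycle
only to ~4%; `best_fit_params(balanced=True)` recomputes a2' exactly
(≈54 s⁻¹) and is the default for simulations, so that equilibrium is a
true detailed-balance state (zero cycle flux).  The implied single-site
dissociation constants are {13, 180} nM; the assignment to S1/S2 is
arbitrary, and swapping the two paths is unobservable (tested).

Ligand is clamped (dose-controlled) by default; a depleting pool is
available for the washout protocol and for natural-formulation or
single-form networks, where its bookkeeping is exact.  Two kinetically
identical ligand species (tracer/competitor, 25 dimer states) implement
the two parameterization protocols: steady-state competition (normalized
bound tracer vs competitor dose) and washout dissociation (2 h clamped
preincubation, tracer clamp set to zero, 20/60 min chase).  The model
reproduces ligand-accelerated dissociation: competitor occupying the
second pocket blocks re-crosslinking of a partially dissociated tracer.

## Phosphorylation and recruitment rules

All six tyrosines share pseudo-first-order rates kp = 0.5 s⁻¹
(phosphorylation, active dimers only) and kdp = 0.1 s⁻¹
(dephosphorylation, unoccupied phosphosites only) — kinases and
phosphatases are assumed unsaturated.  Partner binding uses a single
association rate ka = 1e6 M⁻¹s⁻¹ with per-edge off-rate ka·K_D; a partner
may bind any phosphorylated cognate site regardless of current receptor
activity and remains bound after de-crosslinking.  A protein with several
SH2/PTB domains reported at one site carries the strongest (minimum) K_D;
IRS1, lacking a direct measurement, gets K_D(Y980) = 20 × SHC1's.
Bivalent (two-point) attachment and receptor trafficking are out of model
scope.

## Exact restructuration

The natural formulation tracks each dimer's joint state: pocket pair plus
all 12 site statuses (unphosphorylated / phospho-free / phospho-bound per
partner), deduplicated under the protomer-swap symmetry.  The package
enumerates it only for small instances (default cap 20,000 species) as an
exactness oracle.  Three transformations give the production network:

1. **Bunching** — the four ligand-contact sites of a dimer are two pocket
   variables (the states of the two sites in one pocket are mutually
   exclusive).
2. **Decoupling** — each tyrosine lives on its own receptor form, since
   site phospho-dynamics are independent given the ligand configuration.
   The six forms still share the free-partner pools, so the system remains
   one coupled ODE; this shared-pool coupling is what preserves
   partner-depletion competition.
3. **Scaling** — receptor and ligand abundances are doubled and a1, a2
   halved, so one single-tyrosine form unit represents one site copy (two
   per dimer) while keeping mass-action fluxes exact.

The result for the full 18-partner, 50-edge, 6-site map is
F + 9·Σᵢ(2+nᵢ) = 19 + 9·62 = 577 species.  Equivalence of the two
formulations along trajectories (bound per partner, phospho per site,
crosslinked fraction, free ligand) is verified to relative 1e-6 on one-
and two-site instances, including a partner shared between sites.  Under
ligand clamping the clamp is doubled together with the halved rates, so
per-receptor kinetics are unchanged; a depleting pool with more than one
decoupled form is refused (each form would deplete the pool
independently).

Symmetry lumping is implemented once for both formulations: microstates
carry an internal order, physical species are orbits of the swap, and a
lumped reaction's rate is the microscopic rate divided by the source-orbit
size with duplicates merged — exact because initial conditions are
symmetric.

## Cell models and numerics

Copy numbers convert to concentrations via copies/(N_A·V) with
V = 2e-12 L by default (configurable); an IGF1R copy number of 2e4 then
corresponds to ≈17 nM receptor.  Doses are nM clamps.  Zero-copy partners
are dropped before network generation; profiles without IGF1R are
rejected.  Relative-abundance profiles are rescaled to a stated IGF1R
anchor, preserving partner/receptor ratios.

Steady states are computed two ways:

* **Algebraic (default).** Given the free-partner concentrations the
  receptor species are linear, so each form's stationary distribution is a
  small linear solve (the per-form generator is affine in the ligand clamp
  and free concentrations; the matrices are precomputed).  Free
  concentrations are closed by partner conservation via an adaptively
  damped fixed point (tolerance 1e-11 relative), with a log-space Powell
  root polish and an ODE fallback.  A warm start from a neighboring cell
  makes population sweeps ~5 ms/cell.
* **ODE.** LSODA integration in doubling time chunks until the maximum
  state derivative falls below 1e-10 of the state scale (default
  t_max = 1e6 s; the slow X→S2 step, d1' = 1.9e-5 s⁻¹, sets an ~5e4 s
  relaxation mode).  The two routes agree to better than 1e-7 relative on
  the bundled fixture; the documented tolerance for comparisons is 1e-6.

Conservation laws (receptor per form, per-partner totals, ligand when
depleting) are carried on the network object and checked against the
right-hand side and along trajectories (drift < 1e-8 relative).

## Analytical approximation

Assuming each active receptor binds one partner at a time,
X_b,i = R·X_tot,i/(K_i+R) with R the unique root of
R(1+Σ X_tot,i/(K_i+R)) = R_tot on [0, R_tot] (bracketed Brent, relative
1e-12, one Newton polish).  Mapping the network model onto these inputs
requires two choices, both recorded in result metadata and swappable:
R_tot = crosslinked IGF1R monomer concentration × kp/(kp+kdp) (the
phospho-availability of an active site), and a harmonic combination
1/K_i = Σ_edges 1/K_edge for multi-site partners (parallel binding routes;
`aggregation="min"` keeps the strongest edge only).  On the bundled
fixture the approximation correlates with the full model at r ≈ 0.99 over
bound molecules while misordering competition-dominated partners.

## Population model

Cell k draws copy number X_k,i = mean_i · exp(σ·N) (σ = 0.2 for all
proteins, seeded).  With μ_i = ln(mean) the lognormal mean is
exp(σ²/2) ≈ 1.02× the stated mean; this stated convention is kept.  The
receptor is *not* varied by default: receptor abundance is a capacity mode
common to every partner, and varying it at the same σ adds ≈ +σ² to every
covariance, which (linearizing ln-bound in the ln-copies) makes
cov/σ² = 1 + Σβ² − β_i − β_j > 0 for all pairs (β = bound share of site
copies) and masks competition entirely.  With the receptor fixed,
cov/σ² = Σβ² − β_i − β_j, negative for direct competitors and positive for
two partners suppressed by a big mutual competitor — the two signatures
the correlation analysis is built to expose.  Pass
`PopulationSpec(varied=...)` to include IGF1R.  Default population size is
5000 cells at 1 nM; correlations are standard sample Pearson coefficients,
with columns whose variance is at the solver-noise floor flagged
undefined.

## Ranking, summaries, clustering

Rank 1 = most recruited; ties break alphabetically.  Metrics: steady-state
bound copies at 1 nM (simulation), analytical bound, copy number, minimum
K_D (ascending), copy/min-K_D.  Unexpressed proteins are excluded from a
line's permutation by default (reported separately); an alternative
assigns them rank m+1.  Rank deviation is simulation rank minus
alternative rank (negative = the alternative predicted less binding).
Cell lines are clustered on the normalized-recruitment matrix
(bound/IGF1R monomers; configurable to dimers; can exceed 1 because a
dimer carries twelve sites) with Ward linkage on Euclidean distances and
deterministic scipy leaf ordering.

## Synthetic data

Generators emulate the statistical shape of the real inputs: copy numbers
log-uniform on 1e2–1e7 per cell (receptor 5e3–5e4, keeping it in the nM
range), K_Ds log-uniform on 0.1–10 μM, bipartite maps with every site
covered, and a 45-line panel built by multiplying a base profile by
exp(1.5·N) per protein with 12% dropout — roughly the order-of-magnitude
spread and patchy expression of real panels.  The HeLa-like fixture
transcribes qualitative facts (site assignments, ITK/ZAP70 absent, SHC1
100× IRS1 in copies and 20× in affinity, ABL2 ~40× stronger than CRKL at
Y973, nine competitors at Y1161, YES1 at 0.9 μM) and chooses the remaining
K_Ds in the sub-μM range so that top-partner recruitment lands at 18–25%
of IGF1R at 1 nM.  It is **not** the measured proteomics/affinity dataset:
fixture-based checks are qualitative (orderings, signs, agreement
strength), and quantities tied to the measured tables (exact correlation
magnitudes, panel top-rank shares) will differ from measured-data values.
What passing tests show is that the machinery reproduces the structure of
the phenomena, not the measured numbers.

## Known limitations

* No receptor trafficking, no bivalent attachment, no downstream
  signaling; recruitment only.
* The depleting-ligand mode is limited to natural/single-form networks.
* Mean-field ODEs: exact for deterministic copy numbers, but intrinsic
  stochasticity of binding within single cells is not represented
  (population variability enters only through copy-number draws).
* The analytical mapping (phospho-availability scaling, harmonic K
  aggregation) is a modeling choice; alternatives change the approximation
  by more than the root-finding tolerance.
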