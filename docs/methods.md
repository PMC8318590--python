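# Methods

## Scope and model

The package reproduces, at desk scale, the analysis stack of a
parallel-tempering well-tempered metadynamics (PTmetaD) study of kinase
activation: contact-map collective variables built from two reference
conformations, a replica-exchange sampler with a well-tempered-ensemble
(WTE) pre-stage, free-energy-surface (FES) reconstruction and
reweighting, conformational clustering, and minimum-energy-path tracing.
All-atom molecular dynamics is out of scope; sampling runs on analytic
toy potentials whose coordinates play the role of the collective
variables, so every statistical claim can be checked against closed-form
or quadrature ground truth.

Units: nm, ps, kJ/mol and K internally; reported free energies in
kcal/mol (1 kcal = 4.184 kJ); k_B = 0.0083144621 kJ/(mol·K). Particle
masses are 1 — the toys carry no physical inertia scale, and the
canonical distribution is independent of mass.

## Collective variables

**CV1** is the distance difference d(K:NZ, E:CD) − d(K:NZ, D:CG) between
the catalytic lysine, the αC-helix glutamate and the DFG aspartate.
Negative values mean the K–E pair is shorter (αC-in, active-like);
positive values mean K–D (αC-out, Src-like inactive). Residue ids follow
the signal-peptide convention (K745/E762/D855); `apply_numbering_offset`
converts mature-protein PDB numbering with a +24 shift. The offset is
applied exactly once, enforced by a convention flag.

**Contact degree.** The degree of formation of a contact at distance r is
the rational switching function

    D(r) = w · (1 − (r/r₀)ⁿ) / (1 − (r/r₀)ᵐ),  n = 6, m = 10,

bounded in (0, w], strictly decreasing, with the removable singularity at
r = r₀ evaluated as its limit w·n/m = 0.6·w. A divergent power-law
variant w·(r/r₀)^(n−m) is retained behind `variant="literal"` for
comparison only; it is not sigmoidal and blows up at r → 0, so it is
never the default. The weight w is 3 when the pair joins a Lys/Arg
side-chain nitrogen to an Asp/Glu carboxylate oxygen (a salt bridge), 1
otherwise.

**Discriminating contacts.** Candidate pairs are heavy atoms of residues
at least 4 apart in sequence. A pair enters the set Γ iff its distance is
≤ 0.45 nm in one reference conformation and ≥ 0.80 nm in the other;
r₀ is taken from the conformation where the contact is formed. The
cutoffs are conventional heavy-atom contact definitions; they are config
parameters, not fitted values. **CV2/CV3** are then

    CV(R) = (1/N) · sqrt( Σ_γ (D_γ(R) − D_γ(R_ref))² ),

with R_ref the inactive (CV2) or active (CV3) reference and N = |Γ|.
Mean-square and unnormalised aggregation forms are selectable; every form
is exactly zero at its own reference, which is the property the tests
pin. Normalising contact-map axes by their maximum sampled value is a
plot-time operation only and is never applied to a biased CV.

## Sampling engine

**Integrator.** BAOAB Langevin (half-kick, half-drift,
Ornstein–Uhlenbeck, half-drift, half-kick), friction 2 ps⁻¹ and
dt = 0.01–0.02 ps by default. BAOAB's configurational sampling error for
these step sizes is well below the statistical tolerances used anywhere
in the suite; the harmonic-well position variance reproduces k_B T/k to
better than 1%.

**Well-tempered hills.** A Gaussian of height
W = W₀·exp(−V(s,t)/((f−1)k_B T)) is deposited every `stride` ps
(defaults: W₀ = 4 kJ/mol, f = 15, stride 1 ps). The bias and its
analytic gradient are accumulated on a regular grid (separable outer
products per hill), so the bias force is O(1) per step and the full
ledger is still written out hill by hill. Hill widths default to one
third of the unbiased CV standard deviation from a short pre-run when
not configured.

**Replica exchange.** The ladder defaults to the 11 rungs
300, 305, 310, 318, 326, 335, 344, 354, 363, 375, 382 K with adjacent
pairs attempted every 2 ps, alternating even/odd parity between rounds.
The acceptance uses the bias-including criterion derived from detailed
balance against the biased stationary densities exp(−β_r(U + V_r)):

    Δ = (β_i − β_j)(U(x_i) − U(x_j))
        + β_i [V_i(s_i) − V_i(s_j)] + β_j [V_j(s_j) − V_j(s_i)],

accept with min(1, e^Δ). On acceptance coordinates swap between rungs
(velocities rescaled by sqrt(T_new/T_old)); bias ledgers stay with their
temperature rung.

**WTE pre-stage.** Only the potential energy is biased: constant-height
hills (1 kJ/mol) of width 100 kJ/mol on the energy CV, tabulated per
replica on a shared energy axis. After each exchange round the moving
average of the last 100 attempted exchanges is compared with the 15%
target; at least 50 attempts are required before the check fires, so the
transient of identically initialised replicas (whose swaps are trivially
accepted) cannot satisfy the target on its own. On success the energy
bias is frozen and handed to production as initial bias; exhausting the
hill budget raises an error that reports the rate actually achieved.

**Steered runs.** A harmonic restraint (default 10⁴ kJ/mol per CV-unit²)
tracks a linear schedule from start to target; the trajectory records the
restraint centre and the distance to the target, the toy analogue of
monitoring the RMSD to the target conformation during steered MD.

## Free-energy surfaces

The well-tempered estimator F = −(f/(f−1))·V is applied to the exact
Gaussian-summed bias on the requested grid, min-shifted to zero and
converted to kcal/mol. Projections onto CV subsets marginalise with
F_proj = −k_B T·ln Σ exp(−F/k_B T). Whether the original figures used
the f/(f−1) rescaling or raw bias inversion is not documented anywhere
authoritative; the rescaled estimator is the standard choice consistent
with a stated bias factor, and the factor is recorded on the grid's
metadata.

**Convergence** is declared when the min-shifted FES changed by at most
2.5 kcal/mol (≤ convention) between t_end − window and t_end; the window
defaults to the production value (100 ns equivalent) and falls back to
the trailing 10% of runs shorter than the window. Diffusivity is proxied
by counting, per CV, crossings between the outer quartiles of the
sampled range within the window — the underlying criterion ("diffusive
behaviour in all CVs") is qualitative, so the proxy is a stated, testable
stand-in.

**Reweighting** uses the static final-bias approximation: frame weights
w_i ∝ exp(V_final(s_i)/k_B T), projected free energy
−k_B T·ln Σ w_i per bin. Empty bins are flagged unsampled (NaN), never
imputed, and unsampled nodes are impassable to the path finder. On
converged toy runs the reweighted projection agrees with the hill-summed
FES within 1 k_B T on every sampled bin (tested).

**ΔF estimation** between basins integrates exp(−F/k_B T) over each
half-space and averages the estimate over seven time slices spanning the
trailing 30% of the ledger — the usual time-averaged estimator, because
the instantaneous well-tempered profile oscillates around the converged
surface. The oracle is trapezoid quadrature of exp(−βU) with each basin
integrated on its own subgrid (the split point is a node, keeping the
error O(h²)), Richardson-checked at half resolution.

**Basins** are found by a persistence sweep: nodes processed in
increasing F with union-find merging; a minimum whose depth below its
lowest escape saddle is at most `min_depth` merges into the neighbour
basin, deeper ones survive. Members are assigned by steepest descent with
lexicographic tie-breaking; the global minimum's persistence is the full
sampled range, so a flat surface has no basins. Basin ΔF is available
min-to-min and Boltzmann-integrated; the two legitimately disagree for a
deep-narrow versus wide-shallow pair, with the integrated value pulled
toward the wide basin.

**Minimum-energy paths** minimise the maximum node energy along 8-
neighbour grid paths (the barrier), with cumulative energy as the
tie-break — a grid-global search in the spirit of node-by-node FES path
tools. The implementation is a modified Dijkstra on (max, sum) keys; an
independent level-set-connectivity oracle checks the barrier in the
tests. Barrier monotonicity under grid coarsening holds when the crest
column is a shared node of the nested grids and is tested in exactly that
setting; it is not a theorem for arbitrary surfaces under 8-neighbour
adjacency.

## Clustering

GROMOS-style greedy clustering: the frame with the most neighbours within
the cutoff (default 0.2 nm; distance equal to the cutoff counts as a
neighbour; ties break to the lowest frame index) founds a cluster with
its neighbours, all are removed, and the scan repeats. The metric is
Kabsch-superposed RMSD over a configurable selection, superposing on the
selection itself. The representative of a cluster is the member with the
smallest summed distance to the others. Both the clustering and the
representative selection are checked against brute-force reference
implementations, exhaustively over all three-level distance matrices for
small frame counts.

## Synthetic data

The toy kinase pair places residues on a 2 nm-pitch backbone so that only
planted atom pairs can satisfy any contact cutoff; each planted contact
moves one residue's atoms next to its partner in exactly one of the two
states, and the K/E/D triad distances are set so CV1 is negative in the
active and positive in the inactive reference (defaults −0.65/+0.80 nm).
Ground truth (contact list, weights, switch labels, analytic ΔF) is
always returned with the data, so downstream tests are closed-loop. What
the toys deliberately do not emulate: real protein geometry, degree
values spread across the (0, w) range at the references (planted contacts
are nearly fully formed or fully broken), correlated noise between atoms,
and partially formed contacts — so passing tests demonstrate the
machinery, not force-field realism.

Hill streams come in three patterns: `converging` (geometrically decaying
heights, passes the convergence criterion by construction), `drifting`
(constant 3 kJ/mol hills marching along one CV — tall enough that the
trailing-window change genuinely exceeds the 2.5 kcal/mol threshold) and
`constant` (identical repeated hill, for superposition checks).

## Problem sizes and defaults

The shipped configurations are sized for a single CPU: free-energy
recovery runs 0.8–1.2 M integrator steps (8–12 ns equivalent, 40 s),
replica-ladder runs use the full 11 rungs for 1–2 ns equivalent, the
exchange-rate protocol measures 10,000 post-tuning attempts per seed, and
the end-to-end toy pipeline completes in about a minute. The recovered
ΔF on the tilted double well lands within a few percent of quadrature;
tolerances in the tests (10% on ΔF, 5% on the harmonic variance, 1 k_B T
on reweighting consistency) reflect the statistics achievable at these
sizes, not instrument precision.

## Known limitations

* Exchange acceptance on few-DOF toys is far higher than for solvated
  proteins at the same temperature spacing, so the WTE stage's target is
  reached almost immediately; the protocol logic (tune → freeze → carry
  into production) is exercised, the difficulty of tuning is not.
* The static final-bias reweighting ignores the time dependence of the
  bias; time-dependent estimators could be swapped in behind the same
  interface.
* `find_minima` ties on perfectly flat plateaus resolve by node index,
  which is deterministic but grid-ordering dependent.
* PDB I/O supports the fixed-column ATOM/HETATM subset (altloc by highest
  occupancy, ties to "A"); mmCIF is out of scope.
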