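# Methods

## Model

An EDS reference state over *N* end-state potentials *V_i* is

    V_R(r; s, E) = -(1/(β s)) · ln Σ_i exp(-β s (V_i(r) - E_i)),

with β = 1/(kB·T), kB = 0.00831446 kJ·mol⁻¹·K⁻¹ and T = 300 K by default.
The temperature and kB are configurable; the kB precision is a package
choice (engines differ in their printed constant and none is canonical).
Forces are the softmax-weighted mixture of end-state forces,
f = Σ_i w_i · (-∇V_i) with w_i ∝ exp(-β s (V_i - E_i)).

Properties relied on throughout:

* soft-min bounds: min_i(V_i - E_i) - ln(N)/(βs) ≤ V_R ≤ min_i(V_i - E_i);
* s → 0: weights → 1/N and V_R approaches the state-average potential —
  the "undersampling" regime with a single unphysical minimum;
* adding a constant C to every offset leaves the weights unchanged and
  shifts V_R by exactly -C (each exponential gains a factor e^{+βsC}).

All mixture arithmetic is in log space with a max shift. This matters:
with s = 10⁻⁵ and end-state gaps of hundreds of kJ/mol the raw
exponentials overflow, while the shifted form is exact to machine
precision (verified against extended-precision summation over 1000 random
instances).

## Toy end states and oracles

End states are analytic potentials, not molecular systems. Separable
harmonic wells have the closed-form pairwise free energy

    ΔG_ji = Δshift + (1/(2β)) Σ_d ln(k_{j,d}/k_{i,d}),

and any 1D potential (e.g. the quartic double well) is handled by adaptive
quadrature of ∫exp(-βV) with the minimum factored out (absolute agreement
with the closed form ≤ 10⁻⁵ kJ/mol on random harmonic pairs). The oracle
matrix is exactly antisymmetric and additive, so cycle-closure and
parameter-recovery statements have an unambiguous ground truth.

Two presets define the study conditions:

* **benchmark** — five 1D wells, minima spread over 1 nm, force constants
  500–5000 kJ·mol⁻¹·nm⁻², shifts in [-80, 20] kJ/mol. The shift spread
  mimics the tens-of-kJ/mol offset gaps of realistic multi-ligand setups,
  so offset estimation is exercised over realistic magnitudes.
* **bottleneck** — two clusters of soft wells (k ≈ 240–360) at ±0.4–0.6 nm
  separated by ~25–31 kJ/mol. On a sparse log ladder the dominant basin
  switches abruptly near s ≈ 0.05–0.1, exchange acceptance collapses there,
  and round trips stall — the situation N-LRTO exists to repair. The
  energy scale was chosen so that the gap is severe on six log-spaced
  replicas yet bridgeable by ~12 inserted replicas; with much stiffer or
  more distant clusters the acceptance width shrinks below any practical
  ladder density.

What the toys do *not* emulate: high-dimensional configuration spaces,
solvent and environment reorganisation, restrained dummy-state geometry,
integrator artefacts. Passing tests demonstrate the correctness of the
estimators and the workflow logic under exact canonical sampling; they do
not certify force-field or sampling adequacy on molecular systems.

## Sampling engine

The default propagator is Metropolis Monte Carlo with isotropic Gaussian
proposals, which samples exp(-βV_R) exactly (no discretisation bias), so
exchange statistics and detailed-balance tests are clean. The proposal
scale defaults to 1.5× the narrowest end-state Boltzmann width (floor
0.02 nm), giving ~50–70% acceptance on the presets. An overdamped-Langevin
(Euler–Maruyama) integrator is provided for MD-likeness; it carries the
usual O(Δt) bias and is not used by the workflow stages.

Replica exchange swaps *configurations* between neighbouring s-levels
(walker identities move with them; the two descriptions are equivalent up
to bookkeeping). Sweeps alternate even/odd neighbour pairs. A round trip
is one walker touching the top (s = 1), then the bottom level, then the
top again; the round-trip clock starts at the last top touch before the
walker heads down. Time is measured in MC steps; ns-denominated criteria
are mapped through a configurable steps-per-ns constant (default 5×10⁵,
i.e. 2 fs per step), so "round trips per ns > 0" and "τ̄/nRT < 0.5 ns"
keep their literal form at any scale.

## Diagnostics and thresholds

Per-state metrics over a trajectory: f_mc (fraction of frames where the
state has the lowest V_i - E_i; ties to the lowest index for determinism),
f_occur (V_i ≤ T_phys; states may co-occur), and the undersampling flag
(every state satisfies V_i - E_i ≤ T_us). The threshold estimator is not
uniquely determined by the protocol descriptions we follow; we use
per-state empirical quantiles (default 0.95) — T_phys from the frames of a
state's own biased run where it is the maximal contributor, T_us from the
lowest-s run — as a robust, reproducible interpretation. The quantile is
configurable.

## Workflow stages and defaults

Exploration uses the canonical constants: 21 initial s-values in
[1, 10⁻⁵]; undersampling when every state's occurrence (against T_us) is
≥ 0.75; lower bound two ladder levels below the highest undersampling
replica, clamped at the ladder end; ±500 kJ/mol biasing offsets and the
last-30% dominance criterion for state optimisation (one retry with
doubled length, then an error naming the state); PEOE membership at
occurrence ≥ 0.9, per-replica offsets averaged unweighted, spread reported
as the standard deviation over replicas. If no replica meets the strict
0.9 criterion (possible in short runs), the driver falls back to the
lowest-s replica with a logged warning rather than aborting.

On stiff, well-separated toys the PEOE estimates are rough (tens of
kJ/mol): the undersampling ensemble concentrates at the unphysical
state-average minimum, which overlaps the distant physical wells poorly.
This is the expected behaviour — the offsets from undersampling replicas
"should provide a first solution" only — and motivates the rebalancing
budget below.

Optimisation: N-LRTO ranks ladder intervals per end state by
1 - (acceptance among attempts where the state was maximal contributor on
either side); zero-attempt intervals count as full bottlenecks (severity 1,
warning logged); ties break to the larger s-gap, then the lower index.
Four insertions per iteration are allocated round-robin over the states'
top intervals and placed by linear interpolation in s (linear, not log-s,
even though the initial ladder is logarithmic — interpolation densifies
exactly the gap interval either way); previous s-values are retained and
near-duplicates (10⁻¹² relative) coalesced. Iteration lengths ramp
3000/6000/9000 steps (mirroring the canonical 0.5/1.0/1.5 ns ramp at toy
scale), cap 6. Rebalancing then runs without adding replicas:
ΔE_i = -(1/β)·ln((f_i + c)/(1/N + c)), c = 1/(N·x), x = 30, stopping at
max|f_mc - 1/N| ≤ 0.12 (chosen to match the observed post-rebalancing
deviation band) or after 20 iterations of 5000 steps. The budget of 20 is
sized for PEOE starts that are tens of kJ/mol off: the per-iteration
correction is capped at (1/β)·ln(x+1) ≈ 8.57 kJ/mol, and shorter budgets
stalled on some seeds. Convergence requires all f_mc > 0 at s = 1, round
trips per ns > 0, and τ̄/nRT < 0.5 ns — the last ratio taken literally
(mean round-trip time over round-trip count), with both quantities logged
because the criterion is sometimes read as a per-iteration improvement
instead.

Two cap quantities coexist deliberately: the literal maximum of the
rebalancing correction, (1/β)·ln(x+1) = 8.566 kJ/mol at x = 30, T = 300 K,
and the commonly quoted kB·T·ln(x) = 8.431 kJ/mol at T = 298.15 K (an
x-fold-reduced-sampling figure without the pseudo count). Both are exposed
(`rebalancing_correction_cap`, `correction_for_fold_reduction`) and
printed in the workflow log; they are not reconciled.

Production runs 40 000 steps at fixed parameters (exchange every 20,
every frame recorded), preceded by stages totalling roughly 2×10⁶
replica-steps — sizes chosen so the statistical error of the final
estimates sits well below 1 kJ/mol on the benchmark.

## Free-energy estimation and uncertainties

All exponential averages are log-mean-exp; the per-state vector
L_i = ln⟨exp(-β(V_i - V_R))⟩ over the s = 1 frames yields every pair as
ΔG_ji = -(L_j - L_i)/β, so cycle closure holds to machine precision and
the estimates are invariant to the offsets used during production (offsets
enter V_i - V_R consistently). The default production discard fraction is
0 — the parameter stages already equilibrate the starting point — and is
configurable.

Uncertainties are Gaussian approximations from blocked standard errors
(10 blocks by default; fewer frames than blocks fall back to per-frame
blocking with a warning). Pairwise σ is the blocked standard error of the
per-block *difference* L_j - L_i rather than a quadrature sum of per-state
variances: the per-frame weights of different states are correlated
(exactly anticorrelated for N = 2), and the quadrature form underestimates
pairwise σ by up to √2 (measured 2σ coverage 85% vs ~90–95% for the
difference form; validated against a nonparametric bootstrap within 30%).
States whose weights all vanish get infinite uncertainty and a warning.

ΔΔG between two environments is the elementwise difference of the
pairwise matrices; comparison statistics (RMSE with 100-fold bootstrap
uncertainty, MAE ± spread of absolute errors, Spearman) are computed over
all N(N-1) ordered pairs. Anchored absolute values average over all anchor
choices and report the population standard deviation over those outcomes
(the anchor set is exhaustive, not a sample).

## Degenerate inputs and tie-breaks

Single-state reference: V_R = V_1 - E_1 exactly, forces reduce to -∇V_1,
exchange between levels is always accepted. Zero propagation steps return
the input configuration. A single-replica ladder has no exchanges and no
round trips; τ̄ is reported as absent when no round trip completed.
Argmin ties in f_mc go to the lowest state index (measure zero for
continuous systems; determinism for tests). SSM seeding assigns replica r
the optimised coordinates of state (r mod N) + 1.

## Known limitations

* PEOE accuracy degrades with the phase-space distance between end states;
  on this package's stiff toys the initial offsets rely on rebalancing for
  recovery, more than in systems whose states share most coordinates.
* The rebalancing f_mc estimates come from finite runs; near the tolerance
  boundary the stop decision is noisy, and the workflow may use up its cap
  without formally converging (the status reasons say so; production still
  runs and the reported σ covers the residual error).
* The Gaussian/blocked uncertainty assumes the block means are
  approximately normal; with very few effective well-switches at s = 1 it
  can still underestimate.
* The global ladder re-distribution variant of round-trip optimisation is
  not implemented; only local insertion (N-LRTO) is.
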