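# Methods

## Model and assumptions

The cell is assumed to be at metabolic steady state: the flux vector
*v* ∈ ℝⁿ satisfies *S v* = 0 for the m × n stoichiometric matrix *S* of a
genome-scale reconstruction. Transcript abundance is treated as a proxy for
enzyme capacity — an upper bound on attainable flux in E-Flux2, a
correlation target in SPOT. Both readings are approximations: they ignore
translation efficiency, post-translational regulation, enzyme kinetics and
metabolite-level control, which is why predictions are validated against
¹³C-measured fluxes by a scale-free statistic rather than interpreted as
absolute rates.

## Template construction

Expression values arrive in arbitrary units (microarray intensities, TPM),
so numeric flux bounds from the source model (mmol·gDW⁻¹·h⁻¹) would either
dominate or be dominated by them. Every bound is therefore relaxed to the
sign information it carries:

    lower: 0 if it was ≥ 0, else −∞;   upper: +∞ if it was > 0, else 0.

This keeps reversibility structure, discards uptake rates and maintenance
floors (e.g. a positive ATPM lower bound becomes 0), and guarantees that
the zero flux vector is feasible. The relaxation is idempotent. Carbon
knowledge enters afterwards: DC opens one named uptake to −∞; AC opens
every exchange whose single boundary metabolite has ≥ 1 carbon atom in its
formula. Fully oxidized one-carbon species (CO2, bicarbonate, carbonate,
carbonic acid) are excluded by default because heterotrophs cannot grow on
them; the exclusion list is configurable and an explicit curated list can
replace formula detection entirely. Exchanges whose metabolite lacks a
formula are skipped with a warning rather than guessed.

Consequence of uniform relaxation: any exchange that was open for uptake in
the source model (oxygen, ions, water) stays open, so DC/AC only ever add
carbon uptake routes.

## Expression mapping

GPR rules are boolean AND/OR trees over genes. AND (complex subunits)
evaluates to the minimum abundance — the scarcest subunit limits the
complex; OR (isozymes) evaluates to the sum — parallel capacities add.
Unmeasured genes are dropped from their node by default (`missing="drop"`);
a rule with no measured gene at all, or a reaction without a GPR, is
*unavailable* and keeps its template bounds so the model is not constrained
by missing data. The stricter alternative (`missing="strict"`: any gap
voids the rule) is selectable; neither choice affects fully measured
profiles. Expression values are used exactly as supplied — no rescaling —
because the template construction already removes the unit problem.

## E-Flux2

Step 1 maximizes *f*′*v* under expression-capped bounds (LP). Step 2
minimizes ‖*v*‖² over the step-1 optimal face; strict convexity makes this
point unique, interpretable as the most "efficient" (shortest) flux vector
achieving maximal growth. The optimum is retained through the inequality
*f*′*v* ≥ *z*\*(1 − ε) with ε = 1e-6 rather than an equality against the
LP-reported *z*\*, which is numerically brittle; the realized objective is
reported in the solve metadata. Scaling all abundances by α > 0 scales the
solution by exactly α (positive homogeneity), so the output unit is as
arbitrary as the input unit.

## SPOT

Reversible reactions are split as *v*ⱼ = *v*ⱼᶠ − *v*ⱼᵇ with both parts ≥ 0
and both carrying weight *g*ⱼ; backward-only reactions (template upper
bound 0) are flipped into forward orientation (column negated) so their
weight stays positive, and their flux is recombined with the original sign.
Maximizing the uncentered correlation *v̄*·*ḡ*/(‖*v̄*‖‖*ḡ*‖) over the
resulting cone K = {*v̄* ≥ 0, *S̄* *v̄* = 0} is equivalent to maximizing
*v̄*·*ḡ* under ‖*v̄*‖ ≤ 1 because the correlation is invariant to the
length of *v̄* and ‖*ḡ*‖ is constant.

Numerically the program is solved through the conic-projection identity

    argmax { g·v : v ∈ K, ‖v‖ ≤ 1 } = P_K(g) / ‖P_K(g)‖,

where P_K is the Euclidean projection onto K — a quadratic program with
identity Hessian. The identity follows from the polar decomposition
g = P_K(g) + (g − P_K(g)) with (g − P_K(g))·v ≤ 0 on K; it also shows the
solution is unique whenever P_K(g) ≠ 0, and that the reported objective
*v̄*·*ḡ* equals ‖P_K(g)‖. If the weights are orthogonal to the cone (or
all zero) the zero flux vector is returned with a warning. A direct
norm-capped formulation (`backend="socp"`) is retained as an independent
route and agrees with the projection to ~1e-6 on the fixtures.

Simultaneous forward/backward activity of a reversible pair is feasible in
this program and is not suppressed; pairs with min(*v*ᶠ, *v*ᵇ) above
tolerance are listed in the solve diagnostics instead.

## Baselines

FBA and E-Flux return a vertex of a generally non-unique optimal face and
are flagged `optimal_possibly_nonunique`; no silent canonicalization is
applied. pFBA minimizes Σ|*v*ⱼ| at the optimum via the standard
split-variable LP (not strictly convex, hence also flagged). FBA+min-l²
runs on the model's own bounds (including measured uptake rates) and is
unique.

## Validation

Measured central-carbon fluxes map onto model reactions through the same
AND/OR grammar: AND chains reactions in series and the matched prediction
is their minimum (rate-limiting step); OR joins parallel reactions and the
matched prediction is their sum. Records whose mapping references a missing
reaction raise an error — silently dropping them would bias the reported
correlation. Agreement is the uncentered Pearson correlation
*x*·*y*/(‖*x*‖‖*y*‖), insensitive to the arbitrary prediction unit; signed
fluxes are used for method validation, absolute measured values for the
expression-versus-flux baseline (abundances have no sign). Per-condition
correlations are summarized by arithmetic mean ± SD.

### Correlation range over an optimal face

For non-unique methods the attainable correlation interval over the face
{*S v* = 0, bounds, *f*′*v* = *z*\*} is computed. The matching map m(*v*)
is concave, piecewise-linear and positively homogeneous (minima and sums of
coordinates), i.e. a minimum of finitely many linear maps M_σ. For each
piece (enumerated with its linearity region; enumeration is refused above
256 combinations) the face is homogenized with a scale variable *t* —
correlation is scale-invariant, so the face is replaced by its cone — the
matched vector is capped at unit norm, and ±*v*ₘ·(M_σ *v*) is optimized, a
convex program in both directions. This cap-and-linearize device is exact
when the extremum has the sign the cap can reach (positive maximum,
negative minimum). When instead every face point correlates with the same
sign being pushed against (e.g. the minimum of an all-positive face), the
convex program collapses to the cone apex; the extremum is then located by
deterministic multistart local optimization of the exact ratio over the
face. Both paths are verified against a dense grid oracle on every
≤ 3-degree-of-freedom fixture.

## Numerical choices

* LPs: HiGHS (scipy), feasibility tolerance 1e-9.
* QPs: OSQP (default) or scipy trust-constr, tolerance 1e-8, each followed
  by an exact active-set KKT polish (the identity-Hessian projection
  restricted to the detected active set has a closed form); the two
  independent backends agree to machine precision on the fixtures, which is
  how the uniqueness guarantees are tested.
* Infinite bounds are kept as IEEE infinities end to end; no big-M
  constants are introduced, since they would distort the l² and SPOT
  solutions.
* Ties in AND-minima and LP vertex selection are left to the solver and
  flagged, never canonicalized.

## Synthetic fixtures

The generator emulates the structural motifs the methods must handle —
linear chains, isozymatic branches, futile cycles, reversible steps,
multiple carbon exchanges, AND/OR GPRs and measured-flux mappings — with
ground-truth fluxes known in closed form, plus seeded Gaussian noise on the
measured tables (the acceptance script uses SD 0.5 in measured units, about
5 % of the largest fixture flux). Internal reaction columns balance carbon
exactly. What the fixtures do **not** emulate: genome-scale size and
degeneracy, compartmentalization, cofactor coupling, thermodynamically
infeasible loops, realistic expression noise, and incomplete GPR coverage.
Passing the fixture suite therefore demonstrates correctness of the
optimization machinery and bookkeeping, not predictive accuracy on real
organisms; the genome-scale benchmark tests document the accuracy check
that applies when the published model/data files are supplied.

## Known limitations

* The correlation-range fallback is a local search; on faces with many
  degrees of freedom it provides a bound certified only by its multistart
  coverage.
* AC carbon-source detection depends on metabolite formulas being present
  in the SBML file.
* Expression tables must already contain absolute abundances; probe-level
  normalization of two-color microarrays is out of scope.
* pFBA and E-Flux outputs depend on solver vertex selection; only their
  objective values and the flagged status are stable across solvers.
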