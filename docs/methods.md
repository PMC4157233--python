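# Methods

This note records the models, conventions and numerical choices behind
`pchor`, in the order the analyses run. Nothing here claims an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Mechanism states and energy tables

A mechanism state of the substrate–Asp274 system is (number of added
electrons 0–2, position of the Asp274-origin proton, position of the
propionate-origin proton). Each proton can sit on its donor, on a ring
carbon with correct or wrong stereochemistry, or be in flight (a
proton-transfer transition state); a state is a transition state iff
exactly one proton is in flight. Origin restrictions are enforced: the
Asp274 proton reaches C17 correctly and C18 with the wrong
stereochemistry, the propionate proton the mirror image, and two protons
never occupy one carbon.

Energy tables map (state, condition) to a relative enthalpy in kcal/mol.
Conditions are CSV columns — `eps4/eps10/eps20/eps78` for PCM dielectric
constants on the quantum-cluster surface, or arbitrary labels such as
`reduced_cluster`/`oniom` for other environments. Input normalization
folds typographic minus signs and the `•••` in-flight separator to ASCII;
energies are stored at the table's printed precision and re-emitted with
the same number of decimals, so load→write round-trips are byte-exact.
Validation requires the reference state (0 e⁻, both protons on donors) at
exactly 0.0 under every condition, every state present under every
condition, no duplicates, and `is_ts` flags consistent with the proton
labels. Lookups of untabulated states raise; there is no silent default.

The packaged `table1.csv` (25 states × 4 dielectrics), `table2.csv`
(cluster-present intermediates) and `table5.csv` (ensemble-corrected
energies) fixtures transcribe published tables and are deliberately kept
human-diffable. The companion tables omit some protonation patterns;
the fixtures mirror their sources rather than filling gaps.

## Barriers, pathways and redox potentials

A step barrier is E(TS) − E(reactant) on one reduction surface. A negative
step barrier is *returned* but flagged with a warning: transition states
below their reactants occur legitimately in zero-point-corrected tables
(the C17 proton transfer after the second reduction is barrier-less in
exactly this sense), but can also indicate an inconsistent table, so the
caller decides.

Pathways chain proton steps (reactant, TS, product) and electron steps
(fixed protonation pattern, n → n+1 electrons). The overall barrier uses
the energetic-span convention *within* a reduction surface: each proton
step's effective barrier is its TS energy minus the lowest resting-state
energy reached so far on that surface, and the overall barrier is the
maximum effective barrier. Electron steps reset the reference, because
relative enthalpies on different reduction surfaces are offset by the
(large) redox energy and are not commensurate; each electron step
contributes an externally supplied activation energy instead (default
4 kcal/mol, a ceiling consistent with the low reorganization energies of
the cluster/substrate couple — the geometries needed to recompute them
are not part of this package's inputs). Rate-limiting-step ties break to
the earliest step.

Reduction potentials difference the (n+1)- and n-electron energies of one
protonation pattern and convert via ΔG = −nFΔE with
F = 23.0605 kcal mol⁻¹ V⁻¹. Potentials are *absolute* (vacuum-referenced);
subtracting 4.43 V converts to the standard-hydrogen-electrode scale and
is an explicit separate helper. Closed thermodynamic cycles
(protonate-then-reduce vs. reduce-then-protonate) cancel to < 10⁻⁶ V by
construction, which the tests verify on the packaged table.

Two temperatures coexist deliberately: 300 K for titration and
protonation-probability work, 298.15 K for Eyring/vibrational contexts.
Every function accepts an explicit temperature; the probability-penalty
table values reproduce only at 300 K.

## Marcus construction

The reactant parabola E_R(x) = λ_R·x² has its minimum at x = 0, the
product parabola E_P(x) = ΔG + λ_P·(1−x)² at x = 1, each with its own
reorganization energy as curvature — the minimal construction consistent
with independently computed forward and backward reorganization energies.
The activation energy is E_R at the lowest-energy real intersection; with
equal λ this collapses to the classical (λ+ΔG)²/4λ. When the quadratic
for the intersection has no real root the result is status
`NO_CROSSING` — for strongly endergonic transfers with narrow reactant
wells the parabolas genuinely do not touch, and that is a finding to
report, not an exception. Degenerate flat-line inputs (both λ = 0) cross
only at ΔG = 0. No electronic-coupling or Landau–Zener prefactors are
applied; only barrier heights are produced.

## Titration model and sampler

A titration system is N sites — proton sites with intrinsic pKa, electron
sites with intrinsic midpoint E° (V) — plus a symmetric, zero-diagonal
interaction matrix W in kcal/mol, paid when both partners are occupied.
The microstate energy at pH and solution potential E is

    E(s) = Σᵢ sᵢ gᵢ + Σ_{i<j} W_ij sᵢ sⱼ,
    gᵢ = RT ln10 (pH − pKaᵢ)   (proton sites)
    gᵢ = F (E − E°ᵢ)           (electron sites)

so occupancy (protonated/reduced) is penalized above the site's midpoint
and a single site reproduces Henderson–Hasselbalch / Nernst exactly. The
occupancy convention is the package's own pin-down of a formula the
titration literature usually leaves implicit; everything downstream
(slopes, correlations, populations) is stated relative to it. Asymmetric
W input is rejected rather than symmetrized.

Sampling follows the scan/production protocol: a 2×10⁵-step scan at every
grid point (defaults pH 5–9 step 0.1, −750…−200 mV step 20 mV), then
sites whose scan occupancy stays ≥ 90 % bound (or unbound) across the
*whole* grid are clamped and excluded from production moves; the rest
titrate freely for 10⁶ production steps per point. Clamping is an
approximation, not a convenience: freezing a site whose true occupancy is
0.95 biases its coupled neighbours by roughly 0.05·W_ij worth of mean
field, which is far larger than the sampling error of a 10⁶-step chain.
Sampler-correctness tests therefore set the clamp threshold to 1.0; the
default 0.9 trades that small bias for tractability on large systems,
exactly as the underlying protocol intends.

Monte Carlo details: Metropolis single-site flips, plus joint double
flips for site pairs with |W| > 2.73 kcal/mol (two pKa units at 300 K) —
without them, strongly coupled pairs mix through an exponentially
suppressed intermediate state. Each grid point gets an independent seed
derived from (run seed, phase, grid indices) via numpy's `SeedSequence`,
so runs are bit-reproducible and grid points could be evaluated in any
order. Chains discard max(1000, steps/10) equilibration moves before
accumulating; means and standard errors come from 20 batch means.
Trajectories are recorded every `thin` (default 100) production steps for
correlation analysis.

One degenerate-input caveat: if two sites sit *exactly* at their
midpoints with zero coupling, every proposed flip has ΔE = 0 and is
accepted, so the chain's total occupancy alternates deterministically and
thinned samples can alias to spurious ±1 correlations. Real systems are
never exactly degenerate; tests avoid the measure-zero configuration.

The exact enumerator evaluates all 2^N microstates (N ≤ 20); since site
energies are affine in pH and potential, the states × sites projections
are computed once and each grid point costs one softmax.

Midpoint analysis interpolates the θ = 0.5 crossing of an electron site's
occupancy along the potential axis at each pH (monotone linear
interpolation; a crossing outside the window raises a specific error),
fits E_half against pH by least squares, and divides the slope by
RT ln10/F = 59.52 mV/pH (300 K) to report protons taken up per electron.
A fully coupled 1H⁺/1e⁻ pair shows the ideal −59.5 mV/pH only where the
measurement window lies between the oxidized and reduced pKa values of
the proton site; at pH equal to the oxidized pKa the textbook boundary
value is half that, which is physics, not error. Slope fits default to
the evaluated pH values; the CLI reports at pH {5, 7, 9}.

## Ensemble electrostatic correction

Δ_prot is a fixed-point-charge Coulomb difference at ε = 1 with constant
332.0636 kcal·Å·mol⁻¹·e⁻², no cutoffs, no periodicity: total electrostatic
energy minus the active-region internal energy, i.e. cross-region
interaction plus environment self-energy. The self-energy is constant
across intermediates sharing a frozen environment and cancels in step
differences; a `cross_only` flag drops it for diagnostics.

Per-site contributions to each reaction step are additive by assumption
(the defining approximation of the approach), so a microstate's step
energy is a fixed part plus the protonated sites' contributions. The
ensemble average −RT ln Σ pᵢ exp(−ΔEᵢ/RT) is evaluated with log-sum-exp
throughout — contributions span tens of kcal/mol and naive exponentials
overflow. When the population factorizes over site groups the average
decomposes into a sum of group averages; this is exact for product-form
populations (verified to 10⁻⁹ kcal/mol against full 2¹² enumeration) and
degrades gracefully as inter-group correlation grows (the tests quantify
the monotone growth). Group construction is greedy agglomeration under a
size cap (default 10 → ≤ 2¹⁰ sub-states per group), merging the most
correlated groups first and reporting the largest neglected inter-group
|correlation|. Populations can be given explicitly or frequency-counted
from titration trajectories.

Fixed-charge corrections neglect protein/solvent relaxation and so
overestimate stabilization; dividing by a site-dependent effective
dielectric (≥ 1) is the standard phenomenological remedy and is exposed
as an explicit operation rather than buried in a default.

## Synthetic data

Generators are pure functions of (spec, seed) on numpy's PCG64 stream.
Titration systems draw pKa values in 3–10 and midpoints in −0.6…−0.2 V —
straddling the default grid windows so planted midpoints are observable —
with sparse symmetric couplings. Energy tables are built on a
0.1 kcal/mol grid with minima descending along each protonation sequence
and reduction surfaces well separated; every planted transition-state
height is then exactly the forward barrier measured from the preceding
minimum, so pathway analysis must recover the planted rate-limiting step
bit-exactly. Charge fixtures place point charges with ≥ 1 Å separation by
rejection sampling. Correlated populations tilt a product distribution by
exp(α·n₁·n₂/size) across two groups, giving exactly product form at
α = 0 and tunable inter-group correlation otherwise.

The generators emulate the *structure* of protein-derived inputs (sizes,
magnitudes, coupling sparsity), not any real protein's topology: passing
recovery tests demonstrates the analysis machinery is correct, not that a
particular enzyme's electrostatics have been reproduced. Protein-specific
quantities (cluster midpoint slopes, per-residue contributions) require
structure-derived electrostatics that are inputs to, not products of,
this package.

## Problem sizes

Default test and acceptance runs use 10-site systems on reduced grids
(2×2 points) for sampler validation, 2¹²-state ensembles for the
factorization checks, and 50-atom charge fixtures — sizes at which the
exact oracles are unambiguous and the full suite runs in well under a
minute. The sampler itself is a compiled kernel and handles the full
default grid (41 × 28 points at 10⁶ steps) when asked.

## Known limitations

- Enthalpy tables are consumed as given; no zero-point, thermal or
  solvation recomputation. Conflicts between a source's prose and its
  printed tables are resolved in favour of the tables.
- Electron-transfer activations inside pathway bookkeeping are supplied,
  not derived, unless the caller routes Marcus results in explicitly.
- The titration model has no conformational relaxation and no
  site-specific dielectric; intrinsic values and couplings are inputs.
- The ensemble correction inherits the additivity assumption of per-site
  contributions and the factorization error quantified above.
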