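# Methods

## Excited-state kinetics

The photophysics module treats an organic photosensitizer as a three-state
system (S0, S1, T1) with five first-order channels: radiative decay
k_r(S1→S0), internal conversion k_ic(S1→S0), intersystem crossing
k_isc(S1→T1), reverse ISC k_risc(T1→S1) and the non-radiative T1→S0
crossing k_isc(T1→S0). Phosphorescence (radiative T1→S0) is omitted: it is
intrinsically weak in purely organic sensitizers and would add a sixth,
practically unidentifiable parameter. Assumptions: instantaneous
excitation, first-order kinetics throughout (no annihilation or
bimolecular quenching), and rate constants that are time-independent.

With [S1](0) = 1 the 2×2 rate matrix has real eigenvalues λ_fast ≤ λ_slow
≤ 0 (the discriminant (k_S1 − k_T1)² + 4 k_isc k_risc is non-negative).
Lifetimes are τ = −1/λ; the emission quantum yield is k_r times the
time-integral of [S1], which has the closed form
k_r (k_risc + k_isc^{T1→S0}) / (k_S1 k_T1 − k_isc k_risc). The
prompt/delayed split of Φ is **defined** as the fast/slow eigenmode shares
of that integral; published lifetime tables report biexponential pairs
without defining a split, so some convention is required and the eigenmode
one is the only choice that makes the split additive and closed-form.

Degenerate edge cases: coincident eigenvalues (relative gap ≤ 1e-12) are
reported as a single lifetime; when the T1 state has no exit channel the
delayed lifetime is `inf` and the delayed yield 0 (a slow mode with zero
decay rate can carry population only when k_r = 0, so no emission is
lost); an S1 state with no decay channel at all is rejected at
construction time.

### Numerical oracle

`integrate_populations` solves the same linear system with LSODA at
rtol = 1e-13, atol = 1e-18 and an analytic Jacobian. These tolerances were
chosen so that the worst-case pointwise disagreement with the closed form
over rate sets drawn log-uniformly from 1e4–1e9 s⁻¹ is ~3e-9 — comfortably
inside the 1e-6 agreement the tests assert — at roughly 10 ms per solve.
Population comparisons use a relative scale floored at 1e-9 of the initial
population; values below that floor are beneath the solver's absolute
tolerance and physically negligible.

### Inversion

`invert_observables` estimates rate constants from measured lifetimes and
quantum yields. When τ_p, τ_d, Φ_p and Φ_d are all supplied and one of
(k_ic, k_isc^{S1→T1}) is fixed, an exact algebraic path is used: the
prompt share of the emitted light pins the fast-eigenmode amplitude
c_fast = (Φ_p/τ_p)/(Φ_p/τ_p + Φ_d/τ_d), which pins the total T1 rate, and
the eigenvalue sum/product give the rest. Otherwise a bound-constrained
least-squares search runs in log10-rate space (box 1e-2..1e12 s⁻¹, rates
span more than ten decades) over deterministic multistarts, with lifetimes
and yields compared on a log scale. The number of independent observables
(Φ_total counts only when the split is absent) must be at least the number
of free rates; otherwise the solution set is a manifold — verified
numerically: with only (τ_p, τ_d, Φ_total) and k_ic fixed, k_r varies by
more than a factor of 2 along the zero-residual family — and the module
raises an identifiability error rather than returning an arbitrary point.
When a total quantum yield must be partitioned to make a literature
inversion identified, the package's eigenmode convention is the documented
choice.

The detailed-balance surrogate k_risc = k_isc exp(−ΔE_ST / k_B T)
(k_B = 8.617333e-5 eV/K, default T = 298.15 K) treats the singlet–triplet
gap as a Boltzmann activation energy. It reproduces the order of magnitude
of measured reverse-ISC rates (e.g. 2.3e6 s⁻¹ from a 0.08 eV gap on a
5.1e7 s⁻¹ ISC rate, against a measured 2.7e6 s⁻¹) but ignores vibronic and
spin–orbit structure; it is used only to give the synthetic generator a
physically coupled k_risc.

## Descriptors

`s_RC` divides each rate by the sum of all five, giving dimensionless
branching-like fractions that sum to one and are invariant under a common
rescaling; component ratios equal the underlying rate ratios exactly. Raw
`RC` columns are log10-transformed by default (tree models are
scale-robust, but logs make attribution scatter readable across ten
decades); rates below 1e-12 s⁻¹ are floored first, since detailed-balance
reverse-ISC values can underflow far below 1 s⁻¹. A raw mode is retained
via `rate_transform="raw"`. One-hot reaction columns keep every level (no
reference drop) so each reaction appears as its own `reaction_<id>`
feature in attribution outputs. No centering or standardization is applied
anywhere — gradient-boosted trees are invariant to monotone feature
scaling.

Feature-matrix column order is deterministic: rate block in canonical
order, auxiliaries in canonical order, extras, one-hot columns sorted by
reaction id. Dataset I/O is two UTF-8 CSVs (sensitizer table, reaction
table) written with round-trip float formatting and read with pandas'
round-trip parser, so write→read is bit-exact; unrecognized sensitizer
columns pass through untouched (this is how measured-lifetime columns and
decoy features travel).

## Modeling protocol

The regressor is sklearn's `HistGradientBoostingRegressor` with library
defaults; hyperparameters are exposed but deliberately not tuned — the
package's purpose is descriptor comparison and attribution, not leaderboard
accuracy. Evaluation uses uniformly random 80/20 row splits repeated
`n_runs` times with split seeds fixed to 0..n_runs−1, reporting mean and
sample SD of test R² and RMSE. Because the split seeds are shared, every
descriptor set in the exhaustive search is scored on identical partitions
(paired comparison). Row-level splitting means the same sensitizer can
appear in train and test under different reactions; a grouped-by-sensitizer
protocol would measure extrapolation to new compounds instead — that is a
different question and is deliberately out of scope here. Search ties are
broken by mean RMSE, then label, for deterministic reports. The exhaustive
enumeration is guarded at 15 auxiliary descriptors (32767 subsets).

## Attribution

Attributions are interventional Shapley values: the payoff of coalition S
is the mean model output over background rows with the features in S
replaced by the explained row's values. For tree ensembles this is
computed exactly and polynomially: for each (row, background-row, leaf)
triple, the grouped path conditions classify each path feature as
passing under both rows, only the explained row (must be in S), or only
the background row (must be out of S); with a and b features in the two
exclusive classes the leaf's Shapley contribution is
+v·(a−1)!b!/(a+b)! per x-only feature and −v·a!(b−1)!/(a+b)! per z-only
feature. Summing over leaves, trees and background rows reproduces the
brute-force coalition enumeration (the `exact_shapley` oracle) to machine
precision — the tests assert 1e-8 on all models with ≤ 6 features — and
additivity holds on every explained row by construction. The interventional
(rather than conditional/path-dependent) definition was chosen precisely
because it has a model-independent exact oracle, making the fast
implementation testable.

The default background is the full training matrix; a seeded subsample is
available for speed and is what the importance-recovery tests use (every
5th row). Waterfall exports sort features by |φ| descending with an
optional top-k cutoff and a "(remaining)" bucket so rows always sum from
base to prediction. Pairwise reports quote both the signed subset delta in
yield points and its share of the total predicted-yield difference; a zero
total with a nonzero subset delta yields an undefined (NaN) share rather
than an infinite one.

## Synthetic campaign generator

The generator emulates a screening campaign of 60 sensitizers × 5
reactions (300 yield measurements) — the scale at which repeated-split
R²/RMSE and attribution analyses of this kind operate. Electronic
descriptors come from a correlated Gaussian copula with an E_HOMO/E_LUMO
correlation of 0.86 (frontier orbitals shift together under donor/acceptor
substitution); S1 energies are Gaussian (3.0 ± 0.25 eV), the
singlet–triplet gap is uniform on 0.03–0.6 eV (spanning efficient-TADF to
TADF-silent regimes), oscillator strengths are lognormal and dipole-moment
differences folded-normal. Rates are log-uniform per channel (k_r
10⁶–10⁷·⁷, k_ic 10⁴–10⁹, k_isc 10⁵–10⁹, k_isc^{T1→S0} 10²–10⁷ s⁻¹ —
order-of-magnitude ranges typical of TADF-capable organics), and k_risc
follows the detailed-balance surrogate times 10^N(0, 0.5) scatter, so the
gap and the triplet kinetics are physically coupled.

The yield mechanism is an explicit design choice with every parameter in
config: Gaussian band-pass windows on log10 s_k_risc (center −4.5, width
1.5 decades) and log10 s_k_isc^{T1→S0} (center −3.5, width 1.2) — windows
rather than monotone terms because intermediate T1-exit branching helps
while both extremes hurt; a linear penalty on s_k_ic (sensitizers whose S1
drains non-radiatively underperform); a band-pass on E_HOMO for
energy-transfer-type reactions or on E_LUMO for photoredox-type (the two
reaction families switch the orbital driver); a decreasing term in ΔE_ST;
and per-reaction intercepts. The score passes through a logistic onto
[0, 100] and Gaussian noise (SD 8 yield points) is added before clipping.
The mechanism weights were balanced in a design pilot so that the intended
drivers — the gap, the frontier-orbital window and the two T1-exit ratios —
each carry attribution visibly above pure-noise decoy features at the
300-row scale; with the first draft the scaled internal-conversion and
reverse-ISC terms dominated so strongly that the remaining drivers fell
below decoy-level overfit noise, which would have made the generator's
documented structure unrecoverable by construction. Weights were frozen
before the acceptance suite was finalized.

What the generator does **not** emulate: real descriptor distributions of
any specific compound series, correlations between rates and orbital
energies beyond the gap–k_risc link, heteroscedastic or censored yield
noise, and inter-reaction correlations beyond shared sensitizer
properties. Passing tests therefore demonstrate that the pipeline recovers
a known mechanism at realistic scale and noise — not that any particular
chemistry conclusion transfers to real campaigns.

## Determinism

Every stochastic step is seeded: generator draws from `--seed`/config
seed, split seeds are 0..n_runs−1, the training seed is 0, background
subsampling uses a config seed. Identical configs produce byte-identical
report tables; the run manifest records seeds, config hash and library
versions sufficient for replay.

## Known limitations

* The kinetics model is strictly first-order and two-compartment; it cannot
  represent triplet–triplet annihilation, excimer formation or
  solvent-relaxation dynamics.
* Under-identified inversions are refused rather than regularized; callers
  must fix rates or supply the Φ split.
* Attribution is exact only for the histogram-gradient-boosting trees the
  package trains; other model families would need the enumeration oracle,
  which is exponential in the number of features.
* Row-level splits measure interpolative accuracy; generalization to unseen
  sensitizers is not evaluated.
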