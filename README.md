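# photoyield

Linking the excited-state kinetics of organic photosensitizers (OPSs) to
their photocatalytic activity. The package provides, as a tested and
reusable library:

* a **two-compartment (S1/T1) kinetics model** for TADF-capable
  sensitizers — forward mapping from five excited-state rate constants to
  prompt/delayed lifetimes and emission quantum yields, and the inverse
  estimation of rate constants from measured observables;
* **descriptor construction** — the raw rate-constant set `RC`, its
  sum-normalized variant `s_RC` (each rate divided by the sum of all five,
  a vector of branching-like ratios), seven auxiliary electronic
  descriptors, and one-hot reaction encodings;
* a **gradient-boosted yield-prediction harness** with repeated-split
  R²/RMSE evaluation and an exhaustive search over all auxiliary-descriptor
  combinations (2⁷ − 1 = 127 subsets for the full pool);
* **Shapley attribution** — exact interventional Tree-Shapley values for
  the fitted model (verified against a coalition-enumeration oracle),
  summary/bar/scatter/waterfall data products, and a pairwise decomposition
  that assigns a named descriptor subset its share of the predicted-yield
  difference between two sensitizers;
* a **synthetic-data generator** that emulates the statistical structure of
  a 60-OPS × 5-reaction screening campaign with a known ground-truth yield
  mechanism, so the whole pipeline is testable without quantum-chemistry
  calculations or experiments.

## The model

After an excitation pulse the S1 and T1 populations obey

```
d[S1]/dt = −(k_r + k_ic + k_isc^(S1→T1)) [S1] + k_risc [T1]
d[T1]/dt = k_isc^(S1→T1) [S1] − (k_risc + k_isc^(T1→S0)) [T1]
```

with [S1](0) = 1. Both eigenvalues of the rate matrix are real and
non-positive; the fast one gives the prompt lifetime τ_p, the slow one the
delayed (TADF) lifetime τ_d, and Φ = k_r ∫[S1]dt is the emission quantum
yield, split into prompt/delayed parts by the fast/slow eigenmode shares of
the integral. The scaled descriptors are s_k_X = k_X / Σ k, so they sum to
one and are invariant under a common rescaling of all rates.

Yields are modelled with a histogram-binned gradient-boosted regressor
(scikit-learn's `HistGradientBoostingRegressor`); attributions φ_j satisfy
local accuracy, `base + Σ_j φ_j = ŷ`, so for two rows A and B from the same
model the base values cancel and `Σ_j (φ_j^B − φ_j^A) = ŷ_B − ŷ_A` exactly
— the identity behind the pairwise subset shares.

## Worked example

```python
from photoyield import RateConstantSet, decay_eigenmodes

# 4CzIPN (OPS1), experimentally determined rate constants in s^-1
rates = RateConstantSet(k_r_S1S0=1.7e7, k_isc_S1T1=5.1e7, k_risc_T1S1=2.7e6)
obs = decay_eigenmodes(rates)
print(f"{obs.tau_prompt_s*1e9:.2f} ns, {obs.tau_delayed_s*1e6:.2f} us, phi={obs.phi_total:.3f}")
```

prints `14.28 ns, 1.53 us, phi=1.000`: the computed prompt lifetime agrees
with the measured 14.2 ns to 0.5%, and with no non-emissive channel every
absorbed photon is eventually emitted. Running
`python examples/03_yield_prediction.py` on the default synthetic campaign
prints

```
s_RC + E_HOMO_eV+f_S1+dEST_eV+dDM_debye
  test R^2  = 0.867 (0.029)  over 10 random splits
  test RMSE = 9.1 (0.8)  yield points
```

— the mean and SD of the test-set scores over splits seeded 0..9. The other
scripts in `examples/` walk through descriptor construction, attribution
(waterfalls and pairwise shares) and the one-shot pipeline; each prints the
numbers it computes and a line on what they mean.

There is also a thin CLI mirroring the library
(`photoyield simulate|featurize|evaluate|search|explain|compare|run`); see
`photoyield --help`.

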