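"""Two-compartment (S1/T1) excited-state kinetics of TADF-capable photosensitizers.

The model tracks the populations of the lowest excited singlet (S1) and
triplet (T1) states of an organic photosensitizer after an instantaneous
excitation pulse, coupled by five first-order rate constants:

* ``k_r_S1S0``    — radiative decay S1 -> S0 (fluorescence),
* ``k_ic_S1S0``   — internal conversion S1 -> S0 (non-radiative),
* ``k_isc_S1T1``  — intersystem crossing S1 -> T1,
* ``k_risc_T1S1`` — reverse intersystem crossing T1 -> S1,
* ``k_isc_T1S0``  — intersystem crossing T1 -> S0 (non-radiative).

The radiative T1 -> S0 channel (phosphorescence) is intrinsically weak in
purely organic sensitizers and is not part of the model.

With ``[S1](0) = 1`` and ``[T1](0) = 0`` the populations obey the linear
system ``d[S1]/dt = -kS [S1] + k_risc [T1]``,
``d[T1]/dt = k_isc_S1T1 [S1] - kT [T1]`` where ``kS`` is the total S1
depopulation rate and ``kT = k_risc_T1S1 + k_isc_T1S0``.  Both eigenvalues
of the rate matrix are real and non-positive; the fast one defines the
prompt emission lifetime, the slow one the delayed (TADF) lifetime, and the
radiative fraction of the time-integrated S1 population gives the emission
quantum yield.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

__all__ = [
    "K_B_EV_PER_K",
    "RateConstantSet",
    "PhotophysicsObservables",
    "NonDecayingSystemError",
    "IdentifiabilityError",
    "InversionError",
    "decay_eigenmodes",
    "integrate_populations",
    "invert_observables",
    "detailed_balance_risc",
]

#: Boltzmann constant in eV/K.
K_B_EV_PER_K = 8.617333e-5

RATE_NAMES = (
    "k_r_S1S0",
    "k_ic_S1S0",
    "k_isc_S1T1",
    "k_risc_T1S1",
    "k_isc_T1S0",
)


class NonDecayingSystemError(ValueError):
    """Raised when the S1 state has no depopulation channel at all."""


class IdentifiabilityError(ValueError):
    """Raised when fewer independent observables than free rates are supplied."""


class InversionError(RuntimeError):
    """Raised when the rate-constant inversion fails to converge."""


@dataclass(frozen=True)
class RateConstantSet:
    """The five excited-state rate constants of one sensitizer, in s^-1."""

    k_r_S1S0: float
    k_ic_S1S0: float = 0.0
    k_isc_S1T1: float = 0.0
    k_risc_T1S1: float = 0.0
    k_isc_T1S0: float = 0.0

    def __post_init__(self) -> None:
        for name in RATE_NAMES:
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.k_r_S1S0 + self.k_ic_S1S0 + self.k_isc_S1T1 <= 0:
            raise NonDecayingSystemError(
                "S1 has no decay channel: k_r_S1S0 + k_ic_S1S0 + k_isc_S1T1 must be > 0"
            )

    @property
    def total(self) -> float:
        """Sum of all five rate constants, s^-1."""
        return sum(self.as_tuple())

    @property
    def k_S1(self) -> float:
        """Total S1 depopulation rate, s^-1."""
        return self.k_r_S1S0 + self.k_ic_S1S0 + self.k_isc_S1T1

    @property
    def k_T1(self) -> float:
        """Total T1 depopulation rate, s^-1."""
        return self.k_risc_T1S1 + self.k_isc_T1S0

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in RATE_NAMES)

    def as_dict(self) -> dict[str, float]:
        return {n: getattr(self, n) for n in RATE_NAMES}

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "RateConstantSet":
        return cls(**{n: float(d[n]) for n in RATE_NAMES if n in d})

    def rate_matrix(self) -> np.ndarray:
        """2x2 rate matrix M with d[S1,T1]/dt = M @ [S1,T1]."""
        return np.array(
            [
                [-self.k_S1, self.k_risc_T1S1],
                [self.k_isc_S1T1, -self.k_T1],
            ]
        )


@dataclass(frozen=True)
class PhotophysicsObservables:
    """Biexponential emission observables of one sensitizer.

    Lifetimes are in seconds; quantum yields are dimensionless.  A missing
    observable (e.g. an unresolved prompt/delayed split) is ``nan``;
    ``tau_delayed_s`` is ``inf`` when the triplet reservoir never returns or
    decays (no delayed component).
    """

    tau_prompt_s: float
    tau_delayed_s: float = math.nan
    phi_prompt: float = math.nan
    phi_delayed: float = math.nan
    phi_total: float = math.nan

    def __post_init__(self) -> None:
        if not (self.tau_prompt_s > 0):
            raise ValueError(f"tau_prompt_s must be > 0, got {self.tau_prompt_s!r}")
        if math.isfinite(self.tau_delayed_s) and self.tau_delayed_s < self.tau_prompt_s:
            raise ValueError("tau_delayed_s must be >= tau_prompt_s")
        for name in ("phi_prompt", "phi_delayed", "phi_total"):
            v = getattr(self, name)
            if math.isfinite(v) and not (-1e-9 <= v <= 1 + 1e-9):
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        pp, pd, pt = self.phi_prompt, self.phi_delayed, self.phi_total
        if math.isfinite(pp) and math.isfinite(pd):
            if math.isnan(pt):
                object.__setattr__(self, "phi_total", pp + pd)
            elif abs(pp + pd - pt) > 1e-6:
                raise ValueError("phi_prompt + phi_delayed must equal phi_total")
        if math.isfinite(self.phi_total) and self.phi_total > 1 + 1e-9:
            raise ValueError("phi_total must not exceed 1")

    def as_dict(self) -> dict[str, float]:
        return {
            "tau_prompt_s": self.tau_prompt_s,
            "tau_delayed_s": self.tau_delayed_s,
            "phi_prompt": self.phi_prompt,
            "phi_delayed": self.phi_delayed,
            "phi_total": self.phi_total,
        }


def decay_eigenmodes(rates: RateConstantSet) -> PhotophysicsObservables:
    """Closed-form lifetimes and quantum yields of the two-compartment model.

    The 2x2 rate matrix has two real eigenvalues ``lam_fast <= lam_slow <= 0``.
    The prompt and delayed lifetimes are ``-1/lam``.  The total emission
    quantum yield is ``k_r_S1S0`` times the time integral of ``[S1]``; the
    prompt/delayed split is defined by the fast/slow eigenmode shares of
    that integral.
    """
    kS, kT = rates.k_S1, rates.k_T1
    k_isc, k_risc, k_r = rates.k_isc_S1T1, rates.k_risc_T1S1, rates.k_r_S1S0

    tr = -(kS + kT)
    disc = (kS - kT) ** 2 + 4.0 * k_isc * k_risc  # always >= 0: real eigenvalues
    sq = math.sqrt(disc)
    lam_fast = (tr - sq) / 2.0
    lam_slow = (tr + sq) / 2.0

    if abs(lam_fast - lam_slow) <= 1e-12 * abs(lam_fast):
        # Critically damped: a single observable lifetime.
        tau = -1.0 / lam_fast
        det = kS * kT - k_isc * k_risc
        phi_total = k_r * kT / det if det > 0 else 0.0
        return PhotophysicsObservables(
            tau_prompt_s=tau,
            tau_delayed_s=tau,
            phi_prompt=phi_total,
            phi_delayed=0.0,
        )

    # [S1](t) = c_fast exp(lam_fast t) + c_slow exp(lam_slow t), c_fast + c_slow = 1
    c_fast = (lam_fast + kT) / (lam_fast - lam_slow)
    c_slow = 1.0 - c_fast

    tau_prompt = -1.0 / lam_fast
    tau_delayed = -1.0 / lam_slow if lam_slow < 0 else math.inf

    phi_prompt = k_r * c_fast * tau_prompt
    # lam_slow == 0 implies k_r == 0 (no total decay requires no emissive loss),
    # so the slow-mode integral can only diverge when it carries no emission.
    phi_delayed = k_r * c_slow * tau_delayed if lam_slow < 0 else 0.0
    return PhotophysicsObservables(
        tau_prompt_s=tau_prompt,
        tau_delayed_s=tau_delayed,
        phi_prompt=phi_prompt,
        phi_delayed=phi_delayed,
    )


def integrate_populations(
    rates: RateConstantSet, t_grid: Sequence[float]
) -> np.ndarray:
    """Numerically integrate the S1/T1 populations on ``t_grid``.

    Brute-force oracle for :func:`decay_eigenmodes`: solves the same linear
    system with an implicit stiff solver (the five rates may span more than
    ten decades).  Returns an array of shape ``(len(t_grid), 2)`` with
    columns ``[S1], [T1]`` and initial condition ``[1, 0]``.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("t_grid must be a non-empty 1-D sequence")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing and non-negative")
    M = rates.rate_matrix()

    t0 = 0.0 if t[0] > 0 else t[0]
    sol = solve_ivp(
        lambda _t, y: M @ y,
        (t0, t[-1]),
        np.array([1.0, 0.0]),
        method="LSODA",
        t_eval=t,
        jac=lambda _t, _y: M,
        rtol=1e-13,
        atol=1e-18,
    )
    if not sol.success:
        raise RuntimeError(
            "stiff ODE integration failed "
            f"(rates span {min(r for r in rates.as_tuple() if r > 0):.2e}"
            f"..{max(rates.as_tuple()):.2e} s^-1): {sol.message}"
        )
    return sol.y.T


def detailed_balance_risc(
    k_isc_S1T1: float, delta_E_ST: float, temperature: float = 298.15
) -> float:
    """Boltzmann detailed-balance surrogate for the reverse-ISC rate.

    ``k_risc = k_isc_S1T1 * exp(-delta_E_ST / (k_B T))`` — the thermally
    activated up-conversion picture in which the singlet-triplet gap (eV)
    acts as the activation energy.  Used by the synthetic generator; the
    quantitative rates of real sensitizers additionally depend on vibronic
    and spin-orbit detail outside this model.
    """
    if k_isc_S1T1 < 0:
        raise ValueError("k_isc_S1T1 must be >= 0")
    if delta_E_ST < 0:
        raise ValueError("delta_E_ST must be >= 0")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    return k_isc_S1T1 * math.exp(-delta_E_ST / (K_B_EV_PER_K * temperature))


# ---------------------------------------------------------------------------
# Inversion: observables -> rate constants


_LOG_BOUNDS = (-2.0, 12.0)  # log10 s^-1 box for free rates


def _observable_residuals(
    obs: PhotophysicsObservables, pred: PhotophysicsObservables
) -> np.ndarray:
    """Residual vector between observed and predicted observables.

    Lifetimes and quantum yields are compared on a log10 scale (the rates,
    and hence the observables, span many decades); a quantum yield observed
    as exactly 0 is compared absolutely.
    """
    res = []

    def log_ratio(o: float, p: float) -> float:
        if p <= 0:
            return 12.0  # predicted channel absent but observed: large residual
        return math.log10(p / o)

    if math.isfinite(obs.tau_prompt_s):
        res.append(log_ratio(obs.tau_prompt_s, pred.tau_prompt_s))
    if math.isfinite(obs.tau_delayed_s):
        res.append(log_ratio(obs.tau_delayed_s, pred.tau_delayed_s))
    have_split = math.isfinite(obs.phi_prompt) or math.isfinite(obs.phi_delayed)
    for name in ("phi_prompt", "phi_delayed"):
        o = getattr(obs, name)
        if math.isfinite(o):
            p = getattr(pred, name)
            res.append(log_ratio(o, p) if o > 1e-12 else (p - o) * 1e3)
    if math.isfinite(obs.phi_total) and not have_split:
        p = pred.phi_total
        o = obs.phi_total
        res.append(log_ratio(o, p) if o > 1e-12 else (p - o) * 1e3)
    return np.array(res)


def _count_independent_observables(obs: PhotophysicsObservables) -> int:
    n = 0
    if math.isfinite(obs.tau_prompt_s):
        n += 1
    if math.isfinite(obs.tau_delayed_s):
        n += 1
    n_phi = sum(
        math.isfinite(getattr(obs, f)) for f in ("phi_prompt", "phi_delayed", "phi_total")
    )
    n += min(n_phi, 2)  # phi_total = phi_prompt + phi_delayed is dependent
    return n


def _heuristic_starts(
    obs: PhotophysicsObservables, free: Sequence[str], fixed: Mapping[str, float]
) -> list[np.ndarray]:
    """Deterministic multistart points in log10-rate space."""
    k_p = 1.0 / obs.tau_prompt_s
    k_d = 1.0 / obs.tau_delayed_s if math.isfinite(obs.tau_delayed_s) else k_p * 1e-3
    phi = obs.phi_total if math.isfinite(obs.phi_total) else 0.5
    base = {
        "k_r_S1S0": max(phi, 0.01) * k_p * 0.5,
        "k_ic_S1S0": max(1.0 - phi, 0.01) * k_p * 0.5,
        "k_isc_S1T1": 0.5 * k_p,
        "k_risc_T1S1": 3.0 * k_d,
        "k_isc_T1S0": 0.3 * k_d,
    }
    starts = []
    for shift in (0.0, 0.7, -0.7, 1.5, -1.5):
        x0 = np.array(
            [
                np.clip(math.log10(base[n]) + shift, *_LOG_BOUNDS)
                for n in free
            ]
        )
        starts.append(x0)
    return starts


def _closed_form_invert(
    obs: PhotophysicsObservables, fixed: Mapping[str, float]
) -> RateConstantSet | None:
    """Exact algebraic inversion for the fully observed biexponential case.

    Requires finite tau_prompt, tau_delayed and both quantum-yield
    components, plus exactly one of (k_ic_S1S0, k_isc_S1T1) fixed so the
    total S1 rate can be split.  The prompt share of the emitted light
    determines the fast-eigenmode amplitude ``c_fast``, which pins the
    total T1 rate; everything else follows from the eigenvalue sum/product.
    Returns None when the observables are outside this regime (the caller
    falls back to least squares).
    """
    needed = (obs.tau_prompt_s, obs.tau_delayed_s, obs.phi_prompt, obs.phi_delayed)
    if not all(math.isfinite(v) for v in needed):
        return None
    split_fixed = [n for n in ("k_ic_S1S0", "k_isc_S1T1") if n in fixed]
    if len(split_fixed) != 1:
        return None
    lam_f, lam_s = -1.0 / obs.tau_prompt_s, -1.0 / obs.tau_delayed_s
    rp = obs.phi_prompt / obs.tau_prompt_s
    rd = obs.phi_delayed / obs.tau_delayed_s
    if rp + rd <= 0 or lam_f >= lam_s:
        return None
    c_fast = rp / (rp + rd)
    kT = c_fast * (lam_f - lam_s) - lam_f
    kS = -(lam_f + lam_s) - kT
    k_r = rp / c_fast if c_fast > 0 else 0.0
    prod = kS * kT - lam_f * lam_s  # = k_isc_S1T1 * k_risc_T1S1
    try:
        if split_fixed[0] == "k_ic_S1S0":
            k_ic = fixed["k_ic_S1S0"]
            k_isc = kS - k_r - k_ic
        else:
            k_isc = fixed["k_isc_S1T1"]
            k_ic = kS - k_r - k_isc
        if k_isc > 0:
            k_risc = prod / k_isc
        elif abs(prod) <= 1e-9 * kS * kT + 1e-30:
            k_isc, k_risc = max(k_isc, 0.0), fixed.get("k_risc_T1S1", 0.0)
        else:
            return None
        k_t1s0 = kT - k_risc
        cand = {
            "k_r_S1S0": k_r,
            "k_ic_S1S0": k_ic,
            "k_isc_S1T1": k_isc,
            "k_risc_T1S1": k_risc,
            "k_isc_T1S0": k_t1s0,
        }
        for name, val in fixed.items():
            if abs(cand[name] - val) > 1e-6 * max(abs(val), 1.0):
                return None  # over-constrained and inconsistent
            cand[name] = val
        if any(v < -1e-9 * kS for v in cand.values()):
            return None
        return RateConstantSet(**{k: max(v, 0.0) for k, v in cand.items()})
    except (ValueError, NonDecayingSystemError, ZeroDivisionError):
        return None


def invert_observables(
    obs: PhotophysicsObservables,
    fixed: Mapping[str, float] | None = None,
    x0: RateConstantSet | None = None,
    max_residual: float = 1e-6,
) -> tuple[RateConstantSet, float]:
    """Estimate rate constants reproducing measured emission observables.

    Numerically inverts :func:`decay_eigenmodes` by bound-constrained least
    squares in log10-rate space (rates are searched within 1e-2..1e12 s^-1).
    ``fixed`` pins a subset of the five rates (values in s^-1); the rest are
    free.  The number of independent observables supplied must be at least
    the number of free rates, otherwise the problem is under-identified.

    Returns ``(estimate, residual_norm)``.  Raises :class:`InversionError`
    when no start converges below ``max_residual``.
    """
    fixed = dict(fixed or {})
    for name in fixed:
        if name not in RATE_NAMES:
            raise ValueError(f"unknown rate name in fixed: {name!r}")
    free = [n for n in RATE_NAMES if n not in fixed]
    n_obs = _count_independent_observables(obs)
    if n_obs < len(free):
        raise IdentifiabilityError(
            f"{len(free)} free rate(s) {free} but only {n_obs} independent "
            "observable(s); fix more rates or supply more observables"
        )

    exact = _closed_form_invert(obs, fixed)
    if exact is not None:
        pred = decay_eigenmodes(exact)
        norm = float(np.linalg.norm(_observable_residuals(obs, pred)))
        if norm <= max_residual:
            return exact, norm
        # printed observables can be mutually inconsistent; fall through and
        # let least squares find the best compromise, seeded by the algebra
        x0 = x0 or exact

    def build(x: np.ndarray) -> RateConstantSet:
        d = dict(fixed)
        d.update({n: 10.0 ** xi for n, xi in zip(free, x)})
        return RateConstantSet(**d)

    def residual(x: np.ndarray) -> np.ndarray:
        try:
            pred = decay_eigenmodes(build(x))
        except NonDecayingSystemError:
            return np.full(max(n_obs, 1), 1e3)
        return _observable_residuals(obs, pred)

    starts = _heuristic_starts(obs, free, fixed)
    if x0 is not None:
        starts.insert(
            0,
            np.array(
                [
                    np.clip(math.log10(max(getattr(x0, n), 1e-2)), *_LOG_BOUNDS)
                    for n in free
                ]
            ),
        )

    best = None
    for start in starts:
        sol = least_squares(
            residual,
            start,
            bounds=_LOG_BOUNDS,
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=2000,
        )
        norm = float(np.linalg.norm(sol.fun))
        if best is None or norm < best[1]:
            best = (sol.x, norm)
        # distinct rate sets can reproduce the observables to ~1e-6; only a
        # near-exact fit justifies skipping the remaining starts
        if norm < min(max_residual, 1e-10):
            break
    assert best is not None
    x_best, norm = best
    if norm > max_residual and norm > 1e-3:
        raise InversionError(
            f"inversion did not converge: final residual norm {norm:.3e} "
            f"(free rates: {free})"
        )
    return build(x_best), norm


# ---------------------------------------------------------------------------
# Delimited-text serialization

RATE_COLUMNS = list(RATE_NAMES)
OBSERVABLE_COLUMNS = [
    "tau_prompt_s",
    "tau_delayed_s",
    "phi_prompt",
    "phi_delayed",
]


def rates_to_frame(rates: Iterable[RateConstantSet], ids: Sequence[str]):
    """Tabulate rate sets as a DataFrame keyed by sensitizer_id."""
    import pandas as pd

    rows = [{"sensitizer_id": i, **r.as_dict()} for i, r in zip(ids, rates)]
    return pd.DataFrame(rows, columns=["sensitizer_id"] + RATE_COLUMNS)


def frame_to_rates(frame) -> dict[str, RateConstantSet]:
    """Inverse of :func:`rates_to_frame`."""
    out = {}
    for _, row in frame.iterrows():
        out[str(row["sensitizer_id"])] = RateConstantSet.from_dict(
            {c: float(row[c]) for c in RATE_COLUMNS}
        )
    return out
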