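"""Synthetic sensitizer populations and reaction-yield datasets.

The generator emulates the statistical structure of a photocatalysis
screening campaign — 60 sensitizers by 5 reactions by default — without any
quantum-chemistry input.  Electronic descriptors are drawn from a
correlated Gaussian copula (the frontier-orbital energies are strongly
correlated, 0.86 by default, as donor/acceptor substitution shifts both
levels together); the S1-manifold rate constants are log-uniform over
order-of-magnitude ranges typical of TADF-capable organic sensitizers, and
the reverse-ISC rate follows the detailed-balance surrogate with lognormal
scatter.

Yields are produced by an explicit, documented mechanism so every ground
truth is known to tests: band-pass windows on the scaled T1-exit rates
(s_k_risc_T1S1 and s_k_isc_T1S0 help within an intermediate range), a
penalty proportional to the scaled internal-conversion rate (poorly
emissive sensitizers underperform), a band-pass on a frontier-orbital
energy (E_HOMO for energy-transfer-type reactions, E_LUMO for
photoredox-type), a decreasing term in the singlet-triplet gap, and a
reaction-specific intercept, squashed through a logistic onto [0, 100] and
perturbed by Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .descriptors import (
    ElectronicDescriptors,
    ReactionDataset,
    SensitizerRecord,
    scale_rates,
    write_dataset,
)
from .kinetics import RateConstantSet, decay_eigenmodes, detailed_balance_risc

__all__ = [
    "GeneratorConfig",
    "generate_sensitizers",
    "generate_yields",
    "generate_dataset",
    "make_fixture",
    "radical_addition_config",
]

ENERGY_TRANSFER = "energy_transfer"
PHOTOREDOX = "photoredox"

_DEFAULT_RATE_RANGES = {
    "k_r_S1S0": (6.0, 7.7),
    "k_ic_S1S0": (4.0, 9.0),
    "k_isc_S1T1": (5.0, 9.0),
    "k_isc_T1S0": (2.0, 7.0),
}

_DEFAULT_WEIGHTS = {
    "w_risc": 1.2,
    "w_isc_t1s0": 1.8,
    "w_ic": 1.2,
    "w_orbital": 2.6,
    "w_dest": 5.0,  # per eV
    "risc_center": -4.5,  # window center on log10 s_k_risc_T1S1
    "risc_width": 1.5,
    "t1s0_center": -3.5,  # window center on log10 s_k_isc_T1S0
    "t1s0_width": 1.2,
    "homo_center": -5.8,  # eV, energy-transfer reactions
    "homo_width": 0.4,
    "lumo_center": -1.8,  # eV, photoredox reactions
    "lumo_width": 0.4,
    "intercept_span": 1.2,  # reaction intercepts span [-s/2, +s/2]
    "score_offset": -0.2,
}


@dataclass
class GeneratorConfig:
    """Study-design parameters of the synthetic campaign."""

    n_sensitizers: int = 60
    reaction_ids: tuple[str, ...] = ("CO-a", "CO-b", "CO-c", "CO-d", "CO-e")
    reaction_families: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0
    rate_ranges: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_RATE_RANGES)
    )
    homo_mean_eV: float = -5.8
    homo_sd_eV: float = 0.35
    lumo_mean_eV: float = -1.8
    lumo_sd_eV: float = 0.35
    homo_lumo_correlation: float = 0.86
    s1_mean_eV: float = 3.0
    s1_sd_eV: float = 0.25
    dest_range_eV: tuple[float, float] = (0.03, 0.6)
    f_s1_log10_mean: float = -1.3
    f_s1_log10_sd: float = 0.5
    dm_mean_debye: float = 5.0
    dm_sd_debye: float = 3.0
    risc_noise_log10_sd: float = 0.5
    temperature_K: float = 298.0
    noise_sd: float = 8.0  # yield percentage points
    mechanism_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_WEIGHTS)
    )
    n_decoys: int = 0

    def __post_init__(self) -> None:
        if self.n_sensitizers < 1:
            raise ValueError("n_sensitizers must be >= 1")
        if len(set(self.reaction_ids)) != len(self.reaction_ids) or not self.reaction_ids:
            raise ValueError("reaction_ids must be non-empty and unique")
        if not -1 < self.homo_lumo_correlation < 1:
            raise ValueError("homo_lumo_correlation must lie in (-1, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name, (lo, hi) in self.rate_ranges.items():
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"rate range for {name} must be finite with lo < hi")
        lo, hi = self.dest_range_eV
        if not 0 <= lo < hi:
            raise ValueError("dest_range_eV must satisfy 0 <= lo < hi")
        fam = dict(self.reaction_families)
        for rid in self.reaction_ids:
            fam.setdefault(rid, ENERGY_TRANSFER)
        bad = {r: f for r, f in fam.items() if f not in (ENERGY_TRANSFER, PHOTOREDOX)}
        if bad:
            raise ValueError(f"unknown reaction families: {bad}")
        self.reaction_families = fam
        w = dict(_DEFAULT_WEIGHTS)
        w.update(self.mechanism_weights)
        self.mechanism_weights = w


def radical_addition_config(**overrides) -> GeneratorConfig:
    """Preset mimicking a radical-addition (photoredox) campaign.

    Five radical-addition reactions whose orbital-energy driver is E_LUMO
    instead of E_HOMO.
    """
    ids = ("CF3", "CF3CH2", "CH2F", "Cy", "SCF3")
    cfg = dict(
        reaction_ids=ids,
        reaction_families={r: PHOTOREDOX for r in ids},
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


def generate_sensitizers(config: GeneratorConfig) -> list[SensitizerRecord]:
    """Draw a deterministic synthetic sensitizer population.

    Ids are OPS001..OPSnnn.  The reverse-ISC rate is tied to the ISC rate
    and the singlet-triplet gap through the detailed-balance surrogate with
    multiplicative lognormal scatter, so sensitizers with large gaps have
    vanishing s_k_risc — the structure the attribution analysis probes.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_sensitizers

    rho = config.homo_lumo_correlation
    cov = [
        [config.homo_sd_eV**2, rho * config.homo_sd_eV * config.lumo_sd_eV],
        [rho * config.homo_sd_eV * config.lumo_sd_eV, config.lumo_sd_eV**2],
    ]
    homo_lumo = rng.multivariate_normal(
        [config.homo_mean_eV, config.lumo_mean_eV], cov, size=n
    )
    # frontier gap must stay positive; with default means 4 eV apart this
    # resamples essentially never
    for i in range(n):
        while homo_lumo[i, 0] >= homo_lumo[i, 1]:
            homo_lumo[i] = rng.multivariate_normal(
                [config.homo_mean_eV, config.lumo_mean_eV], cov
            )

    e_s1 = np.maximum(rng.normal(config.s1_mean_eV, config.s1_sd_eV, size=n), 0.7)
    dest = rng.uniform(*config.dest_range_eV, size=n)
    f_s1 = 10.0 ** rng.normal(config.f_s1_log10_mean, config.f_s1_log10_sd, size=n)
    ddm = np.abs(rng.normal(config.dm_mean_debye, config.dm_sd_debye, size=n))

    logk = {
        name: rng.uniform(lo, hi, size=n)
        for name, (lo, hi) in config.rate_ranges.items()
    }
    risc_noise = rng.normal(0.0, config.risc_noise_log10_sd, size=n)

    decoys = rng.standard_normal(size=(n, config.n_decoys))

    records = []
    width = max(3, len(str(n)))
    for i in range(n):
        k_isc = 10.0 ** logk["k_isc_S1T1"][i]
        k_risc = detailed_balance_risc(
            k_isc, dest[i], config.temperature_K
        ) * 10.0 ** risc_noise[i]
        rates = RateConstantSet(
            k_r_S1S0=10.0 ** logk["k_r_S1S0"][i],
            k_ic_S1S0=10.0 ** logk["k_ic_S1S0"][i],
            k_isc_S1T1=k_isc,
            k_risc_T1S1=k_risc,
            k_isc_T1S0=10.0 ** logk["k_isc_T1S0"][i],
        )
        electronic = ElectronicDescriptors(
            E_HOMO_eV=homo_lumo[i, 0],
            E_LUMO_eV=homo_lumo[i, 1],
            E_S1_eV=e_s1[i],
            E_T1_eV=e_s1[i] - dest[i],
            f_S1=f_s1[i],
            dDM_debye=ddm[i],
        )
        extras = {f"decoy_{j + 1}": float(decoys[i, j]) for j in range(config.n_decoys)}
        records.append(
            SensitizerRecord(
                sensitizer_id=f"OPS{i + 1:0{width}d}",
                rates=rates,
                electronic=electronic,
                observables=decay_eigenmodes(rates),
                lifetime_columns=extras,
            )
        )
    return records


def _gauss_window(x: float, center: float, width: float) -> float:
    return math.exp(-0.5 * ((x - center) / width) ** 2)


def latent_score(
    record: SensitizerRecord, reaction_id: str, config: GeneratorConfig
) -> float:
    """Noise-free mechanism score of one (sensitizer, reaction) pair."""
    w = config.mechanism_weights
    s = scale_rates(record.rates)
    elec = record.electronic
    log_s_risc = math.log10(max(s.s_k_risc_T1S1, 1e-300))
    log_s_t1s0 = math.log10(max(s.s_k_isc_T1S0, 1e-300))
    family = config.reaction_families[reaction_id]
    if family == ENERGY_TRANSFER:
        orbital = _gauss_window(elec.E_HOMO_eV, w["homo_center"], w["homo_width"])
    else:
        orbital = _gauss_window(elec.E_LUMO_eV, w["lumo_center"], w["lumo_width"])
    ids = list(config.reaction_ids)
    k = ids.index(reaction_id)
    if len(ids) > 1:
        intercept = w["intercept_span"] * (k / (len(ids) - 1) - 0.5)
    else:
        intercept = 0.0
    return (
        w["w_risc"] * _gauss_window(log_s_risc, w["risc_center"], w["risc_width"])
        + w["w_isc_t1s0"] * _gauss_window(log_s_t1s0, w["t1s0_center"], w["t1s0_width"])
        - w["w_ic"] * s.s_k_ic_S1S0
        + w["w_orbital"] * orbital
        - w["w_dest"] * elec.dEST_eV
        + intercept
        + w["score_offset"]
    )


def generate_yields(
    sensitizers: Sequence[SensitizerRecord], config: GeneratorConfig
) -> ReactionDataset:
    """Yield table for every (sensitizer, reaction) pair.

    ``yield = clip(100 * logistic(score) + N(0, noise_sd), 0, 100)``; the
    noise stream is seeded from ``config.seed`` independently of the
    sensitizer draw.
    """
    if not sensitizers:
        raise ValueError("sensitizer list must be non-empty")
    for rid in config.reaction_ids:
        if rid not in config.reaction_families:
            raise KeyError(f"unknown reaction id: {rid}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    rows = []
    for rec in sensitizers:
        for rid in config.reaction_ids:
            score = latent_score(rec, rid, config)
            mean_yield = 100.0 / (1.0 + math.exp(-score))
            y = mean_yield + rng.normal(0.0, config.noise_sd) if config.noise_sd else mean_yield
            rows.append(
                {
                    "sensitizer_id": rec.sensitizer_id,
                    "reaction_id": rid,
                    "yield_percent": float(np.clip(y, 0.0, 100.0)),
                }
            )
    return ReactionDataset(pd.DataFrame(rows))


def generate_dataset(
    config: GeneratorConfig | None = None,
) -> tuple[ReactionDataset, list[SensitizerRecord]]:
    """Convenience wrapper: sensitizers + yields from one config."""
    config = config or GeneratorConfig()
    sensitizers = generate_sensitizers(config)
    return generate_yields(sensitizers, config), sensitizers


def make_fixture(
    size: str = "tiny", outdir: str | Path = ".", seed: int = 7
) -> tuple[Path, Path]:
    """Write a pinned on-disk dataset fixture (tiny: 8 x 2; default: 60 x 5).

    Returns the (sensitizer_table, reaction_table) paths.
    """
    if size == "tiny":
        config = GeneratorConfig(
            n_sensitizers=8, reaction_ids=("CO-a", "CO-b"), seed=seed
        )
    elif size == "default":
        config = GeneratorConfig(seed=seed)
    else:
        raise ValueError("size must be 'tiny' or 'default'")
    dataset, sensitizers = generate_dataset(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spath = outdir / f"sensitizers_{size}.csv"
    rpath = outdir / f"reactions_{size}.csv"
    write_dataset(sensitizers, dataset, spath, rpath)
    return spath, rpath
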