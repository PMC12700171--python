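"""End-to-end orchestration: config validation, the full analysis sequence,
and delimited-text report generation.

A run config (YAML or dict) declares the data source (on-disk tables or a
simulation block), the descriptor set (a fixed feature spec or an
exhaustive search block), the evaluation protocol, and optional pairwise
attribution comparisons.  ``run_pipeline`` executes
load/simulate -> assemble -> evaluate/search -> train -> explain ->
summarize -> compare and writes every table plus a machine-readable
manifest; identical configs produce identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .attribution import explain, pairwise_attribution, summarize, waterfall
from .descriptors import (
    ELECTRONIC_COLUMNS,
    FeatureSpec,
    ReactionDataset,
    SensitizerRecord,
    assemble_features,
    read_dataset,
    write_dataset,
)
from .modeling import evaluate_repeated, subset_search, train_model
from .simulate import GeneratorConfig, generate_dataset

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]

log = logging.getLogger("photoyield")


class ConfigError(ValueError):
    """Aggregated, human-readable configuration errors."""

    def __init__(self, errors: Sequence[str]):
        self.errors = list(errors)
        super().__init__("invalid config:\n" + "\n".join(f"  - {e}" for e in errors))


@dataclass
class RunConfig:
    """Normalized pipeline configuration (all defaults filled)."""

    simulate: GeneratorConfig | None = None
    sensitizer_table: Path | None = None
    reaction_table: Path | None = None
    features: FeatureSpec | None = None
    search: dict | None = None
    n_runs: int = 10
    test_fraction: float = 0.2
    hyperparams: dict = field(default_factory=dict)
    background_size: int | None = None
    background_seed: int = 0
    pairs: list[dict] = field(default_factory=list)
    waterfall_top_k: int | None = None
    output_dir: Path = Path("photoyield_run")
    raw: dict = field(default_factory=dict)


def validate_config(source: str | Path | Mapping | None) -> RunConfig:
    """Parse and fully validate a config file or mapping.

    Fills every default; raises :class:`ConfigError` listing all problems
    at once.  An empty file is a valid defaults-only config (simulated
    data, fixed default feature spec).
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, Mapping):
        raw = dict(source)
    else:
        text = Path(source).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ConfigError([f"top level of {source} must be a mapping"])

    errors: list[str] = []
    known = {
        "dataset", "simulate", "features", "search", "evaluation",
        "attribution", "output_dir",
    }
    for key in raw:
        if key not in known:
            errors.append(f"unknown top-level key: {key!r}")

    cfg = RunConfig(raw=raw)
    cfg.output_dir = Path(raw.get("output_dir", "photoyield_run"))

    has_dataset = "dataset" in raw
    has_sim = "simulate" in raw
    if has_dataset and has_sim:
        errors.append("exactly one of 'dataset' and 'simulate' may be present")
    if has_dataset:
        ds = raw["dataset"] or {}
        for key in ("sensitizers", "reactions"):
            if key not in ds:
                errors.append(f"dataset.{key} is required")
        cfg.sensitizer_table = Path(ds.get("sensitizers", ""))
        cfg.reaction_table = Path(ds.get("reactions", ""))
    else:
        sim = raw.get("simulate") or {}
        try:
            cfg.simulate = GeneratorConfig(**sim)
        except (TypeError, ValueError) as exc:
            errors.append(f"simulate: {exc}")

    has_search = "search" in raw
    if has_search and "features" in raw:
        errors.append("'features' and 'search' are mutually exclusive")
    if has_search:
        s = raw["search"] or {}
        pool = list(s.get("auxiliary_pool", ELECTRONIC_COLUMNS))
        bad = [p for p in pool if p not in ELECTRONIC_COLUMNS]
        if bad:
            errors.append(f"search.auxiliary_pool has unknown descriptors: {bad}")
        cfg.search = {
            "base_sets": list(s.get("base_sets", ["s_RC"])),
            "auxiliary_pool": pool,
            "include_base_only": bool(s.get("include_base_only", False)),
            "rate_transform": s.get("rate_transform", "log10"),
        }
    else:
        feat = raw.get("features") or {}
        try:
            cfg.features = FeatureSpec.from_dict(feat)
        except ValueError as exc:
            errors.append(f"features: {exc}")

    ev = raw.get("evaluation") or {}
    cfg.n_runs = int(ev.get("n_runs", 10))
    cfg.test_fraction = float(ev.get("test_fraction", 0.2))
    cfg.hyperparams = dict(ev.get("hyperparams", {}))
    if cfg.n_runs < 1:
        errors.append("evaluation.n_runs must be >= 1")
    if not 0 < cfg.test_fraction < 1:
        errors.append("evaluation.test_fraction must lie in (0, 1)")

    att = raw.get("attribution") or {}
    bs = att.get("background_size")
    cfg.background_size = None if bs in (None, "full") else int(bs)
    cfg.background_seed = int(att.get("background_seed", 0))
    cfg.waterfall_top_k = att.get("waterfall_top_k")
    for i, pair in enumerate(att.get("pairs", [])):
        for key in ("a", "b"):
            if key not in pair or len(pair[key]) != 2:
                errors.append(
                    f"attribution.pairs[{i}].{key} must be [sensitizer_id, reaction_id]"
                )
        cfg.pairs.append(
            {
                "a": tuple(map(str, pair.get("a", ("", "")))),
                "b": tuple(map(str, pair.get("b", ("", "")))),
                "subset": list(pair.get("subset", [])),
            }
        )

    if errors:
        raise ConfigError(errors)
    return cfg


def _config_hash(raw: Mapping) -> str:
    return hashlib.sha256(
        yaml.safe_dump(raw, sort_keys=True).encode()
    ).hexdigest()[:16]


def _write(frame: pd.DataFrame, path: Path, **kw) -> None:
    frame.to_csv(path, index=False, float_format="%.10g", **kw)


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis and write the report bundle.

    Returns a summary dict with the key numeric results and the paths of
    every artifact written.
    """
    t_start = time.time()
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    # --- stage: data ------------------------------------------------------
    try:
        if config.simulate is not None:
            dataset, sensitizers = generate_dataset(config.simulate)
            write_dataset(
                sensitizers, dataset, out / "sensitizers.csv", out / "reactions.csv"
            )
            artifacts["sensitizers"] = str(out / "sensitizers.csv")
            artifacts["reactions"] = str(out / "reactions.csv")
        else:
            dataset, sensitizers = read_dataset(
                config.sensitizer_table, config.reaction_table
            )
    except Exception as exc:
        raise RuntimeError(f"stage 'data': {exc}") from exc
    log.info("data: %d sensitizers, %d reaction rows", len(sensitizers), len(dataset))

    # --- stage: features / search ----------------------------------------
    search_frame = None
    if config.search is not None:
        try:
            result = subset_search(
                dataset,
                sensitizers,
                base_sets=config.search["base_sets"],
                auxiliary_pool=config.search["auxiliary_pool"],
                n_runs=config.n_runs,
                test_fraction=config.test_fraction,
                hyperparams=config.hyperparams,
                include_base_only=config.search["include_base_only"],
                rate_transform=config.search["rate_transform"],
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'search': {exc}") from exc
        search_frame = result.to_frame()
        _write(search_frame, out / "search.csv")
        artifacts["search"] = str(out / "search.csv")
        spec = result.best.spec
        evaluation = result.best
        log.info("search: best descriptor set %s", spec.label)
    else:
        spec = config.features
        try:
            matrix = assemble_features(dataset, sensitizers, spec)
            evaluation = evaluate_repeated(
                matrix,
                n_runs=config.n_runs,
                test_fraction=config.test_fraction,
                hyperparams=config.hyperparams,
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'evaluate': {exc}") from exc
    matrix = assemble_features(dataset, sensitizers, spec)
    eval_frame = pd.DataFrame([evaluation.to_row()])
    _write(eval_frame, out / "evaluation.csv")
    per_run = pd.DataFrame(
        evaluation.per_run, columns=["seed", "r2", "rmse"]
    )
    _write(per_run, out / "evaluation_runs.csv")
    artifacts["evaluation"] = str(out / "evaluation.csv")
    for seed, r2, rmse in evaluation.per_run:
        log.info("run seed=%d: R2=%.3f RMSE=%.2f", seed, r2, rmse)

    # --- stage: train + explain ------------------------------------------
    try:
        model = train_model(matrix, hyperparams=config.hyperparams, seed=0)
        background = matrix.X
        if config.background_size is not None and config.background_size < len(background):
            rng = np.random.default_rng(config.background_seed)
            idx = rng.choice(
                len(background), size=config.background_size, replace=False
            )
            background = background.iloc[np.sort(idx)]
        explanations = explain(model, matrix.X, background)
    except Exception as exc:
        raise RuntimeError(f"stage 'explain': {exc}") from exc

    phi_rows = [
        {"row_id": e.row_id, "feature": f, "phi": v}
        for e in explanations
        for f, v in e.phi.items()
    ]
    _write(pd.DataFrame(phi_rows), out / "shap_values.csv")
    bar, scatter = summarize(explanations)
    _write(bar, out / "shap_bar.csv")
    _write(scatter, out / "shap_scatter.csv")
    artifacts.update(
        shap_values=str(out / "shap_values.csv"),
        shap_bar=str(out / "shap_bar.csv"),
        shap_scatter=str(out / "shap_scatter.csv"),
    )

    # --- stage: pairwise comparisons -------------------------------------
    by_id = {e.row_id: e for e in explanations}
    pair_rows = []
    for pair in config.pairs:
        key_a = "/".join(pair["a"])
        key_b = "/".join(pair["b"])
        try:
            ea, eb = by_id[key_a], by_id[key_b]
        except KeyError as exc:
            raise RuntimeError(
                f"stage 'compare': row {exc} not in the dataset"
            ) from exc
        subset = pair["subset"] or list(ea.phi)
        pw = pairwise_attribution(ea, eb, subset)
        pair_rows.append(
            {
                "id_a": key_a,
                "id_b": key_b,
                "subset": "+".join(subset),
                "total_delta": pw.total_delta,
                "subset_delta": pw.subset_delta,
                "subset_share": pw.subset_share,
            }
        )
        for which, e in (("a", ea), ("b", eb)):
            wf = waterfall(e, top_k=config.waterfall_top_k)
            name = f"waterfall_{e.row_id.replace('/', '_')}.csv"
            _write(wf, out / name)
            artifacts[f"waterfall_{which}_{key_a}_{key_b}"] = str(out / name)
    if pair_rows:
        _write(pd.DataFrame(pair_rows), out / "pairwise.csv")
        artifacts["pairwise"] = str(out / "pairwise.csv")

    # --- manifest + summary ----------------------------------------------
    import sklearn

    manifest = {
        "photoyield_version": __version__,
        "sklearn_version": sklearn.__version__,
        "numpy_version": np.__version__,
        "config": config.raw,
        "config_hash": _config_hash(config.raw),
        "descriptor_set": spec.label,
        "feature_spec": spec.to_dict(),
        "n_rows": len(matrix),
        "split_seeds": list(range(config.n_runs)),
        "train_seed": 0,
        "background_size": config.background_size or len(matrix),
        "elapsed_s": round(time.time() - t_start, 3),
        "artifacts": artifacts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    lines = [
        f"photoyield run ({manifest['config_hash']})",
        f"dataset: {len(sensitizers)} sensitizers x "
        f"{len(dataset.reaction_ids)} reactions = {len(dataset)} rows",
        f"descriptor set: {spec.label} ({len(matrix.feature_names)} features)",
        f"test R2 = {evaluation.mean_r2:.3f} ({evaluation.sd_r2:.3f}), "
        f"RMSE = {evaluation.mean_rmse:.1f} ({evaluation.sd_rmse:.1f}) "
        f"over {config.n_runs} runs",
        "top features by mean |phi|: "
        + ", ".join(bar["feature"].head(5)),
    ]
    for row in pair_rows:
        lines.append(
            f"pair {row['id_a']} vs {row['id_b']}: "
            f"delta_yhat = {row['total_delta']:+.2f}, subset [{row['subset']}] "
            f"accounts for {row['subset_delta']:+.2f} "
            f"({100 * row['subset_share']:.1f}%)"
        )
    (out / "summary.txt").write_text("\n".join(lines) + "\n")

    return {
        "evaluation": evaluation,
        "search": search_frame,
        "bar": bar,
        "pairs": pair_rows,
        "manifest": manifest,
        "model": model,
        "matrix": matrix,
        "explanations": explanations,
    }
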