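"""Orchestration of the full factorial simulation experiment.

For each grade composition a cohort is generated and its bootstrap subsets
are drawn once; for each (subset, target variable, missingness pattern) the
subset is amputed once and every handling strategy is applied to the
identical amputed copy, so methods are compared on exactly the same missing
entries. All randomness derives from a stable hash of
(master_seed, cell coordinates), which gives two isolation guarantees:
changing the method list never changes the amputation masks, and changing
the pattern list never changes the subset draws.

Two profiles are shipped: ``paper`` (500 subsets, full tuning grids) and
``desk`` (100 subsets, reduced random-forest grid) for single-CPU runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from joblib import Parallel, delayed

from . import evaluation
from .amputation import MissingnessSpec, ampute, verify_mechanism
from .bootstrap import draw_subset
from .cohort import generate_cohort
from .config import COMPOSITIONS, GeneratorConfig, GradeDistribution, default_generator_config
from .errors import ConfigurationError, FitError
from .imputation import DEFAULT_GRIDS, DESK_GRIDS, METHODS, run_method
from ._util import derive_seed

logger = logging.getLogger(__name__)

PROFILES = {
    "paper": {"n_subsets": 500, "grids": DEFAULT_GRIDS},
    "desk": {"n_subsets": 100, "grids": DESK_GRIDS},
}


@dataclass(frozen=True)
class ExperimentConfig:
    master_seed: int = 0
    n_subsets: int = 500
    subset_size: int = 500
    compositions: tuple = ("empirical", "balanced")
    targets: tuple = ("lems_w0", "lems_w52")
    patterns: tuple = ("MCAR", "MAR", "MNAR")
    methods: tuple = tuple(m for m in METHODS)
    m: int = 25
    rate: float = 0.30
    generator: GeneratorConfig = field(default_factory=default_generator_config)
    profile: str = "paper"
    n_jobs: int = 1
    output_dir: str | None = None

    def __post_init__(self):
        if self.n_subsets < 1:
            raise ConfigurationError("n_subsets must be >= 1")
        if not self.methods:
            raise ConfigurationError("methods must be nonempty")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ConfigurationError(f"unknown methods {unknown}; choose from {METHODS}")
        if self.profile not in PROFILES:
            raise ConfigurationError(f"profile must be one of {sorted(PROFILES)}")
        for c in self.compositions:
            if c not in COMPOSITIONS:
                raise ConfigurationError(f"unknown composition {c!r}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "generator" in d and d["generator"] is not None:
            d["generator"] = GeneratorConfig.from_dict(d["generator"])
        for key in ("compositions", "targets", "patterns", "methods"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def for_profile(self) -> "ExperimentConfig":
        """Apply the profile's subset count (explicit field values win only
        when they differ from the class default)."""
        want = PROFILES[self.profile]["n_subsets"]
        if self.n_subsets == 500 and want != 500:
            return replace(self, n_subsets=want)
        return self


@dataclass
class ReportBundle:
    metrics: pd.DataFrame  # subset_id, composition, target, pattern, method, metric, value
    betas: pd.DataFrame  # composition, target, pattern, method, coefficient, mean_diff, ci, biased
    little: pd.DataFrame  # composition, target, pattern, subset_id, statistic, df, p_value
    manifest: dict

    def write(self, output_dir) -> None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.betas.to_csv(out / "beta_differences.csv", index=False)
        self.little.to_csv(out / "little_tests.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _outcome_for(target: str) -> str:
    """Analysis-model outcome: week 52, or week 26 in the time-shift variant."""
    return "lems_w26" if target == "lems_w26" else "lems_w52"


def _model_vars(target: str) -> list:
    return [_outcome_for(target), "lems_w0", "ais_grade", "nli", "age", "sex"]


def _process_subset(subset, b, comp, target, pattern, cfg, grids):
    """All methods on one amputed subset -> (metric rows, fits, little row)."""
    spec = MissingnessSpec(target_variable=target, pattern=pattern, rate=cfg.rate)
    amp_seed = derive_seed(cfg.master_seed, "ampute", comp, target, pattern, b)
    amp = ampute(subset, spec, seed=amp_seed)

    lt = verify_mechanism(amp, _model_vars(target))
    little_row = {
        "composition": comp, "target": target, "pattern": pattern, "subset_id": b,
        "statistic": lt.statistic, "df": lt.df, "n_patterns": lt.n_patterns,
        "p_value": lt.p_value,
    }

    mspec = evaluation.AnalysisModelSpec(outcome=_outcome_for(target))
    complete_fit = evaluation.fit_analysis_model(subset.table, mspec)

    rows, fits = [], {}
    for method in cfg.methods:
        if method == "locf" and target == "lems_w0":
            continue  # LOCF only applies to outcome (repeated-measure) targets
        seed = derive_seed(cfg.master_seed, "method", comp, target, pattern, b, method)
        res = run_method(amp, method, seed=seed, m=cfg.m, grids=grids,
                         model_vars=_model_vars(target))
        if not res.pooled.empty:
            truth = amp.vault.loc[res.pooled.index].astype(float)
            for metric, fn in (("mae", evaluation.mae), ("rmse", evaluation.rmse)):
                rows.append({
                    "subset_id": b, "composition": comp, "target": target,
                    "pattern": pattern, "method": method, "metric": metric,
                    "value": fn(truth.to_numpy(), res.pooled.to_numpy()),
                })
        try:
            fits[method] = evaluation.fit_analysis_model(res.completed_table, mspec)
        except FitError as err:
            # e.g. CCA under MNAR can drop an entire small AIS stratum
            logger.warning("subset %d %s: analysis fit unavailable (%s)", b, method, err)
            fits[method] = None
    return rows, complete_fit, fits, little_row


def run_experiment(config: ExperimentConfig) -> ReportBundle:
    """Run the factorial experiment and collect the report bundle.

    With ``output_dir`` set, each (composition, target, pattern) cell is
    written to ``cells/`` as soon as it completes and is reloaded instead of
    recomputed on a rerun, so partial runs resume from the manifest.
    """
    cfg = config.for_profile()
    grids = PROFILES[cfg.profile]["grids"]
    out = Path(cfg.output_dir) if cfg.output_dir else None
    if out is not None:
        (out / "cells").mkdir(parents=True, exist_ok=True)

    metric_rows, beta_rows, little_rows, cells = [], [], [], []
    for comp in cfg.compositions:
        dist: GradeDistribution = COMPOSITIONS[comp]
        gen = cfg.generator
        cohort = generate_cohort(gen, seed=derive_seed(cfg.master_seed, "cohort", comp))
        subsets = [
            draw_subset(cohort, dist, cfg.subset_size,
                        seed=derive_seed(cfg.master_seed, "subset", comp, b),
                        composition_label=comp)
            for b in range(cfg.n_subsets)
        ]
        for target in cfg.targets:
            for pattern in cfg.patterns:
                cell_id = f"{comp}_{target}_{pattern}"
                cells.append(cell_id)
                cached = _load_cell(out, cell_id)
                if cached is not None:
                    logger.info("cell %s: resumed from cache", cell_id)
                    mrows, brows, lrows = cached
                    metric_rows += mrows
                    beta_rows += brows
                    little_rows += lrows
                    continue
                logger.info("cell %s: %d subsets", cell_id, cfg.n_subsets)
                results = Parallel(n_jobs=cfg.n_jobs)(
                    delayed(_process_subset)(s, b, comp, target, pattern, cfg, grids)
                    for b, s in enumerate(subsets)
                )
                mrows, lrows = [], []
                complete_fits, per_method = [], {}
                for rows, cfit, fits, lrow in results:
                    mrows += rows
                    lrows.append(lrow)
                    complete_fits.append(cfit)
                    for meth, f in fits.items():
                        per_method.setdefault(meth, []).append(f)
                brows = []
                for meth, fits_m in per_method.items():
                    pairs = [(c, f) for c, f in zip(complete_fits, fits_m) if f is not None]
                    if len(pairs) < len(fits_m):
                        logger.warning(
                            "cell %s %s: %d/%d subsets lack an analysis fit",
                            cell_id, meth, len(fits_m) - len(pairs), len(fits_m),
                        )
                    if not pairs:
                        continue
                    summ = evaluation.beta_difference_summary(*map(list, zip(*pairs)))
                    for coef in summ.mean_diff.index:
                        brows.append({
                            "composition": comp, "target": target, "pattern": pattern,
                            "method": meth, "coefficient": coef,
                            "mean_diff": float(summ.mean_diff[coef]),
                            "ci_lower": float(summ.ci_lower[coef]),
                            "ci_upper": float(summ.ci_upper[coef]),
                            "biased": bool(summ.biased[coef]),
                        })
                _store_cell(out, cell_id, mrows, brows, lrows)
                metric_rows += mrows
                beta_rows += brows
                little_rows += lrows

    manifest = {
        "config": {
            "master_seed": cfg.master_seed, "n_subsets": cfg.n_subsets,
            "subset_size": cfg.subset_size, "compositions": list(cfg.compositions),
            "targets": list(cfg.targets), "patterns": list(cfg.patterns),
            "methods": list(cfg.methods), "m": cfg.m, "rate": cfg.rate,
            "profile": cfg.profile, "generator_digest": cfg.generator.digest(),
        },
        "cells": cells,
    }
    bundle = ReportBundle(
        metrics=pd.DataFrame(metric_rows),
        betas=pd.DataFrame(beta_rows),
        little=pd.DataFrame(little_rows),
        manifest=manifest,
    )
    if out is not None:
        bundle.write(out)
    return bundle


def _cell_path(out, cell_id):
    return None if out is None else out / "cells" / f"{cell_id}.json"


def _load_cell(out, cell_id):
    path = _cell_path(out, cell_id)
    if path is None or not path.exists():
        return None
    try:
        d = json.loads(path.read_text())
        return d["metrics"], d["betas"], d["little"]
    except (json.JSONDecodeError, KeyError):
        logger.warning("cell %s: corrupted cache, recomputing", cell_id)
        return None


def _store_cell(out, cell_id, mrows, brows, lrows):
    path = _cell_path(out, cell_id)
    if path is None:
        return
    tmp = path.with_suffix(".tmp")  # atomic per-cell write
    tmp.write_text(json.dumps({"metrics": mrows, "betas": brows, "little": lrows}))
    tmp.replace(path)


# -- summaries ---------------------------------------------------------------


def summarize(bundle: ReportBundle) -> dict[str, pd.DataFrame]:
    """Rank-proportion and bias tables in the style of the study's figures."""
    tables: dict[str, pd.DataFrame] = {}
    if not bundle.metrics.empty:
        rank_parts, mean_parts = [], []
        for (comp, target, pattern, metric), grp in bundle.metrics.groupby(
            ["composition", "target", "pattern", "metric"]
        ):
            ranked = evaluation.rank_methods(grp, metric)
            props = evaluation.rank_proportions(ranked)
            props.insert(0, "metric", metric)
            props.insert(0, "pattern", pattern)
            props.insert(0, "target", target)
            props.insert(0, "composition", comp)
            rank_parts.append(props)
            means = (
                ranked.groupby("method")["rank"].mean().rename("mean_rank").reset_index()
            )
            means.insert(0, "metric", metric)
            means.insert(0, "pattern", pattern)
            means.insert(0, "target", target)
            means.insert(0, "composition", comp)
            mean_parts.append(means)
        tables["rank_proportions"] = pd.concat(rank_parts, ignore_index=True)
        tables["mean_ranks"] = pd.concat(mean_parts, ignore_index=True)
    if not bundle.betas.empty:
        tables["beta_bias"] = bundle.betas.copy()
    if not bundle.little.empty:
        tally = (
            bundle.little.assign(reject=bundle.little["p_value"] < 0.05)
            .groupby(["composition", "target", "pattern"])["reject"]
            .agg(n_subsets="size", n_reject="sum")
            .reset_index()
        )
        tally["reject_fraction"] = tally["n_reject"] / tally["n_subsets"]
        tables["little_tally"] = tally
    return tables


def summary_markdown(tables: dict[str, pd.DataFrame]) -> str:
    parts = []
    for name, df in tables.items():
        header = "| " + " | ".join(df.columns) + " |"
        sep = "| " + " | ".join("---" for _ in df.columns) + " |"
        body = [
            "| " + " | ".join(_fmt(v) for v in row) + " |"
            for row in df.itertuples(index=False)
        ]
        parts.append(f"## {name}\n\n" + "\n".join([header, sep, *body]) + "\n")
    return "\n".join(parts)


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.4g}"
    return str(v)
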