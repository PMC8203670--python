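"""Pipeline stages: simulate -> analyze -> compare -> report.

Each stage is a plain function over CSV files so the command-line interface
stays a thin wrapper and the analysis scripts can drive the same code.  CSV
is the single interchange format (UTF-8, comma-separated, header row, '.'
decimals); every run records a manifest with the config snapshot, seed and
output paths, and rerunning a stage with the same config and seed
reproduces its CSV outputs byte-identically.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
import logging
import warnings
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .choice import (
    binomial_test_vs_chance,
    format_interval,
    proportion_from_choices,
)
from .compare import compare_models
from .difficulty import Contrast, DifficultyParams
from .exceptions import ConfigurationError, DataError, PipelineOrderError
from .generate import (
    CHOICE_COLUMNS,
    TRIAL_COLUMNS,
    GeneratorConfig,
    generate_choice_trials,
    generate_exploration_trials,
)
from .playtime import (
    condition_mean_correlation,
    fit_accuracy_regression,
    fit_playtime_regression,
    individual_slopes,
    normalize_playtimes,
    trial_dprime,
)

__all__ = [
    "DEFAULT_CHOICE_DESIGNS",
    "load_config",
    "run_simulate",
    "run_analyze",
    "run_compare",
    "run_report",
    "run_all",
]

logger = logging.getLogger(__name__)

# Forced-choice designs emulated by default: sample size and choice rate of
# the three box-choice experiments (13/16, 19/24, 18/24).
DEFAULT_CHOICE_DESIGNS: dict[str, dict[str, float]] = {
    "exp1": {"n_children": 16, "p_correct": 13 / 16},
    "exp2": {"n_children": 24, "p_correct": 19 / 24},
    "exp3": {"n_children": 24, "p_correct": 18 / 24},
}

_REQUIRED_TRIAL_COLUMNS = [
    "child_id",
    "experiment",
    "trial_order",
    "n_a",
    "n_b",
    "hidden",
    "playtime_s",
    "response_count",
    "correct",
]

_CI_METHODS = {"normal": "normal_approx", "exact": "exact_binomial"}


def _ci_method(name: str) -> str:
    if name in _CI_METHODS.values():
        return name
    try:
        return _CI_METHODS[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown CI method {name!r}; use 'normal' or 'exact'"
        ) from None


def load_config(path: str | Path | None) -> tuple[GeneratorConfig, dict]:
    """Load a YAML/JSON config into (GeneratorConfig, choice designs).

    A missing path returns the package defaults.  Recognized top-level
    keys: ``seed``, ``generator`` (GeneratorConfig fields, with
    ``contrast_sets`` as mapping experiment -> list of {n_a, n_b, hidden})
    and ``choice_designs`` (experiment -> {n_children, p_correct}).
    """
    if path is None:
        return GeneratorConfig(), dict(DEFAULT_CHOICE_DESIGNS)
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"malformed config {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigurationError(f"config {path} must be a mapping, got {type(raw)}")
    gen_kwargs: dict[str, Any] = dict(raw.get("generator", {}))
    if "seed" in raw:
        gen_kwargs.setdefault("seed", int(raw["seed"]))
    if "contrast_sets" in gen_kwargs:
        sets = {}
        for exp, items in gen_kwargs["contrast_sets"].items():
            contrasts = []
            for item in items:
                try:
                    contrasts.append(
                        Contrast(
                            n_a=int(item["n_a"]),
                            n_b=int(item["n_b"]),
                            hidden=int(item.get("hidden", max(item["n_a"], item["n_b"]))),
                            label=str(item.get("label", "")),
                        )
                    )
                except (KeyError, TypeError) as exc:
                    raise ConfigurationError(
                        f"config {path}: bad contrast entry {item!r} in {exp!r}: {exc}"
                    ) from exc
            sets[exp] = contrasts
        gen_kwargs["contrast_sets"] = sets
    if "fixed_content_experiments" in gen_kwargs:
        gen_kwargs["fixed_content_experiments"] = tuple(
            gen_kwargs["fixed_content_experiments"]
        )
    if "age_range" in gen_kwargs:
        gen_kwargs["age_range"] = tuple(gen_kwargs["age_range"])
    try:
        config = GeneratorConfig(**gen_kwargs)
    except TypeError as exc:
        raise ConfigurationError(f"config {path}: {exc}") from exc
    choice = {
        str(exp): dict(spec)
        for exp, spec in raw.get("choice_designs", DEFAULT_CHOICE_DESIGNS).items()
    }
    return config, choice


def _config_snapshot(config: GeneratorConfig) -> dict:
    snap = dataclasses.asdict(config)
    snap["contrast_sets"] = {
        exp: [
            {"n_a": c["n_a"], "n_b": c["n_b"], "hidden": c["hidden"], "label": c["label"]}
            for c in contrasts
        ]
        for exp, contrasts in snap["contrast_sets"].items()
    }
    return snap


def _update_manifest(out_dir: Path, stage: str, entry: dict) -> None:
    path = out_dir / "manifest.json"
    manifest = {}
    if path.exists():
        manifest = json.loads(path.read_text())
    manifest.setdefault("package_version", __version__)
    stages = manifest.setdefault("stages", {})
    entry = dict(entry)
    entry["timestamp"] = _dt.datetime.now(_dt.timezone.utc).isoformat()
    stages[stage] = entry
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def run_simulate(
    out_dir: str | Path,
    config: GeneratorConfig | None = None,
    config_path: str | Path | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Generate the synthetic cohort and write trials.csv / choices.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    choice_designs = dict(DEFAULT_CHOICE_DESIGNS)
    if config is None:
        config, choice_designs = load_config(config_path)
    if seed is not None:
        config = config.with_seed(seed)
    trials = generate_exploration_trials(config)
    trials_path = out_dir / "trials.csv"
    trials.to_csv(trials_path, index=False)

    seeder = np.random.default_rng(config.seed)
    frames = []
    for exp in sorted(choice_designs):
        spec = choice_designs[exp]
        frames.append(
            generate_choice_trials(
                n_children=int(spec["n_children"]),
                p_correct=float(spec["p_correct"]),
                seed=int(seeder.integers(2**31)),
                experiment=exp,
            )
        )
    choices = pd.concat(frames, ignore_index=True)
    choices_path = out_dir / "choices.csv"
    choices.to_csv(choices_path, index=False)

    logger.info(
        "simulate: seed=%s -> %d trial rows, %d choice rows",
        config.seed, len(trials), len(choices),
    )
    _update_manifest(
        out_dir,
        "simulate",
        {
            "seed": config.seed,
            "config": _config_snapshot(config),
            "choice_designs": choice_designs,
            "outputs": [str(trials_path), str(choices_path)],
            "n_trial_rows": len(trials),
            "n_choice_rows": len(choices),
        },
    )
    return {"trials": trials_path, "choices": choices_path}


def read_trials_csv(path: str | Path) -> pd.DataFrame:
    """Read and schema-validate the canonical trial CSV."""
    path = Path(path)
    try:
        trials = pd.read_csv(path)
    except (pd.errors.EmptyDataError, FileNotFoundError) as exc:
        raise DataError(f"cannot read trial CSV {path}: {exc}") from exc
    for col in _REQUIRED_TRIAL_COLUMNS:
        if col not in trials.columns:
            raise DataError(f"trial CSV {path} lacks required column '{col}'")
    if len(trials) == 0:
        raise DataError(f"trial CSV {path} has no rows")
    return trials


def run_analyze(
    trials_csv: str | Path,
    choices_csv: str | Path | None,
    out_dir: str | Path,
    sigma: float = 1.0,
    ci_method: str = "normal",
    estimator: str = "ols-cluster",
    playtime_scale: str = "normalized",
    make_figures: bool = True,
) -> dict[str, Path]:
    """Run the full playtime and forced-choice analysis battery."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = DifficultyParams(sigma=sigma)
    method = _ci_method(ci_method)
    trials = read_trials_csv(trials_csv)
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        norm = normalize_playtimes(trials)

        fit_rows = []
        predictors = ["neg_dprime", "hidden_count", "trial_order"]
        if "age_years" in norm.columns:
            predictors.append("age")
        for predictor in predictors:
            fit = fit_playtime_regression(
                norm, predictor, params, estimator=estimator,
                playtime_scale=playtime_scale,
            )
            fit_rows.append(dataclasses.asdict(fit))
        acc = fit_accuracy_regression(trials, params)
        fit_rows.append(dataclasses.asdict(acc))
        if not acc.converged:
            notes.append(f"accuracy fit flagged: {acc.notes}")
        corr = condition_mean_correlation(norm, params)
        fit_rows.append(dataclasses.asdict(corr))

        slope_rows = []
        summary_rows = []
        for exp, sub in norm.groupby("experiment", sort=True):
            summary = individual_slopes(sub, params, ci_method=method)
            for child, slope in summary.per_child_slopes:
                slope_rows.append(
                    {"experiment": exp, "child_id": child, "slope": slope,
                     "positive": slope > 0}
                )
            summary_rows.append(
                {
                    "experiment": exp,
                    "k_positive": summary.k_positive,
                    "n": summary.n,
                    "proportion": summary.proportion,
                    "ci_low": summary.ci_low,
                    "ci_high": summary.ci_high,
                    "ci_method": summary.ci_method,
                }
            )
        pooled = individual_slopes(norm, params, ci_method=method)
        summary_rows.append(
            {
                "experiment": "all",
                "k_positive": pooled.k_positive,
                "n": pooled.n,
                "proportion": pooled.proportion,
                "ci_low": pooled.ci_low,
                "ci_high": pooled.ci_high,
                "ci_method": pooled.ci_method,
            }
        )

        prop_rows = []
        if choices_csv is not None and Path(choices_csv).exists():
            choices = pd.read_csv(choices_csv)
            if "chose_discriminable" not in choices.columns:
                raise DataError(
                    f"choice CSV {choices_csv} lacks column 'chose_discriminable'"
                )
            for exp, sub in choices.groupby("experiment", sort=True):
                res = proportion_from_choices(sub, method=method)
                if res.degenerate:
                    notes.append(
                        f"{exp}: degenerate zero-width normal-approximation CI "
                        f"(p_hat={res.p_hat})"
                    )
                prop_rows.append(
                    {
                        "experiment": exp,
                        "k": res.k,
                        "n": res.n,
                        "p_hat": res.p_hat,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "method": res.method,
                        "p_value": binomial_test_vs_chance(res.k, res.n, 0.5),
                    }
                )
    for w in caught:
        notes.append(str(w.message))

    fits = pd.DataFrame(fit_rows)
    fits_path = out_dir / "fits.csv"
    fits.to_csv(fits_path, index=False)
    slopes_path = out_dir / "slopes.csv"
    pd.DataFrame(slope_rows).to_csv(slopes_path, index=False)
    slope_summary_path = out_dir / "slope_summary.csv"
    pd.DataFrame(summary_rows).to_csv(slope_summary_path, index=False)
    proportions_path = out_dir / "proportions.csv"
    pd.DataFrame(
        prop_rows,
        columns=["experiment", "k", "n", "p_hat", "ci_low", "ci_high", "method", "p_value"],
    ).to_csv(proportions_path, index=False)

    # condition means for the figure and the report
    cm = norm.copy()
    cm["_hi"] = cm[["n_a", "n_b"]].max(axis=1)
    cm["_lo"] = cm[["n_a", "n_b"]].min(axis=1)
    cm["neg_dprime"] = -trial_dprime(cm, params)
    cond = (
        cm.groupby(["experiment", "_hi", "_lo"])
        .agg(
            neg_dprime=("neg_dprime", "first"),
            mean_normalized_playtime=("normalized_playtime", "mean"),
            sem=("normalized_playtime", "sem"),
            n=("normalized_playtime", "size"),
        )
        .reset_index()
        .rename(columns={"_hi": "n_high", "_lo": "n_low"})
    )
    cond_path = out_dir / "condition_means.csv"
    cond.to_csv(cond_path, index=False)

    outputs = {
        "fits": fits_path,
        "slopes": slopes_path,
        "slope_summary": slope_summary_path,
        "proportions": proportions_path,
        "condition_means": cond_path,
    }
    if make_figures:
        outputs.update(_make_figures(out_dir, norm, cond, pd.DataFrame(slope_rows)))

    meta = {
        "sigma": sigma,
        "ci_method": method,
        "estimator": estimator,
        "playtime_scale": playtime_scale,
        "warnings": notes,
        "n_obs": int(len(norm)),
        "n_children": int(norm["child_id"].nunique()),
    }
    (out_dir / "analysis_meta.json").write_text(json.dumps(meta, indent=2) + "\n")
    _update_manifest(
        out_dir, "analyze",
        {"inputs": [str(trials_csv), str(choices_csv)],
         "outputs": [str(p) for p in outputs.values()], **meta},
    )
    logger.info("analyze: %d obs, %d children, %d warnings",
                meta["n_obs"], meta["n_children"], len(notes))
    return outputs


def _make_figures(
    out_dir: Path, norm: pd.DataFrame, cond: pd.DataFrame, slopes: pd.DataFrame
) -> dict[str, Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig_dir = out_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    out: dict[str, Path] = {}

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(
        cond["neg_dprime"], cond["mean_normalized_playtime"], yerr=cond["sem"],
        fmt="o", capsize=3,
    )
    ax.set_xlabel("negative discriminability (-d')")
    ax.set_ylabel("mean normalized playtime")
    ax.set_title("Exploration vs. contrast difficulty")
    fig.tight_layout()
    p = fig_dir / "playtime_vs_neg_dprime.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    out["fig_playtime_vs_neg_dprime"] = p

    fig, ax = plt.subplots(figsize=(5, 4))
    by_hidden = norm.groupby("hidden")["normalized_playtime"].agg(["mean", "sem"])
    ax.errorbar(by_hidden.index, by_hidden["mean"], yerr=by_hidden["sem"],
                fmt="s", capsize=3)
    ax.set_xlabel("number of marbles actually in the box")
    ax.set_ylabel("mean normalized playtime")
    ax.set_title("Exploration vs. hidden content")
    fig.tight_layout()
    p = fig_dir / "playtime_vs_hidden_count.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    out["fig_playtime_vs_hidden_count"] = p

    fig, ax = plt.subplots(figsize=(5, 4))
    if len(slopes):
        ax.hist(slopes["slope"], bins=20, edgecolor="black")
    ax.axvline(0.0, color="red", linestyle="--")
    ax.set_xlabel("per-child slope of normalized playtime on -d'")
    ax.set_ylabel("children")
    ax.set_title("Individual playtime-difficulty slopes")
    fig.tight_layout()
    p = fig_dir / "individual_slopes.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    out["fig_individual_slopes"] = p
    return out


def run_compare(
    trials_csv: str | Path, out_dir: str | Path, sigma: float = 1.0
) -> dict[str, Path]:
    """Model-comparison table over the registered difficulty models."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trials = read_trials_csv(trials_csv)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm = normalize_playtimes(trials)
    table = compare_models(norm, params=DifficultyParams(sigma=sigma))
    path = out_dir / "comparison.csv"
    table.to_csv(path, index=False)
    _update_manifest(
        out_dir, "compare",
        {"inputs": [str(trials_csv)], "outputs": [str(path)], "sigma": sigma},
    )
    return {"comparison": path}


def run_report(out_dir: str | Path) -> Path:
    """Assemble a human-readable markdown summary of a completed run."""
    out_dir = Path(out_dir)
    required = {
        "fits": out_dir / "fits.csv",
        "slope_summary": out_dir / "slope_summary.csv",
        "proportions": out_dir / "proportions.csv",
        "comparison": out_dir / "comparison.csv",
    }
    missing = [str(p) for p in required.values() if not p.exists()]
    if missing:
        raise PipelineOrderError(
            f"report requires completed analyze+compare stages; missing: {missing}"
        )
    fits = pd.read_csv(required["fits"])
    slope_summary = pd.read_csv(required["slope_summary"])
    proportions = pd.read_csv(required["proportions"])
    comparison = pd.read_csv(required["comparison"])
    meta = {}
    meta_path = out_dir / "analysis_meta.json"
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())

    def ci(row) -> str:
        return f"[{row.ci_low:.3f}, {row.ci_high:.3f}]"

    lines = ["# Box-shaking analysis report", ""]
    head = fits[fits.predictor == "neg_dprime"]
    if len(head) != 1:
        raise PipelineOrderError("expected exactly one discriminability playtime fit")
    row = head.iloc[0]
    lines.append(
        f"**Headline**: normalized playtime ~ -d' slope beta={row.beta:.3f}, "
        f"95% CI {ci(row)} ({row.estimator}, {int(row.n_obs)} trials, "
        f"{int(row.n_children)} children)."
    )
    lines.append("")
    lines.append("## Playtime and accuracy regressions")
    lines.append("")
    lines.append("| predictor | beta | 95% CI | estimator | n_obs |")
    lines.append("|---|---|---|---|---|")
    for row in fits.itertuples():
        beta = "NA" if pd.isna(row.beta) else f"{row.beta:.4f}"
        interval = "NA" if pd.isna(row.ci_low) else ci(row)
        flag = "" if row.converged else " (flagged: non-converged)"
        lines.append(
            f"| {row.predictor} | {beta} | {interval} | {row.estimator}{flag} "
            f"| {int(row.n_obs)} |"
        )
    lines.append("")
    lines.append("## Individual slopes (positive = longer play on harder contrasts)")
    lines.append("")
    for row in slope_summary.itertuples():
        lines.append(
            f"- {row.experiment}: {int(row.k_positive)}/{int(row.n)} positive "
            f"({100 * row.proportion:.0f}%; 95% CI [{row.ci_low:.2f}, {row.ci_high:.2f}])"
        )
    lines.append("")
    if len(proportions):
        lines.append("## Forced-choice proportions")
        lines.append("")
        for row in proportions.itertuples():
            lines.append(
                f"- {row.experiment}: {int(row.k)}/{int(row.n)} chose the "
                f"discriminable box ({100 * row.p_hat:.1f}%; 95% CI "
                f"[{row.ci_low:.2f}, {row.ci_high:.2f}], {row.method}; "
                f"two-sided binomial p={row.p_value:.2g})"
            )
        lines.append("")
    lines.append("## Model comparison")
    lines.append("")
    lines.append("| model | r (condition means) | R2 (trials) | AIC | rank agreement with d' |")
    lines.append("|---|---|---|---|---|")
    for row in comparison.itertuples():
        lines.append(
            f"| {row.model_name} | {row.r_condition_means:.3f} | "
            f"{row.r2_trial_level:.3f} | {row.aic_trial_level:.1f} | "
            f"{row.rank_agreement_with_dprime:.3f} |"
        )
    lines.append("")
    if meta.get("warnings"):
        lines.append("## Warnings")
        lines.append("")
        for w in meta["warnings"]:
            lines.append(f"- {w}")
        lines.append("")
    path = out_dir / "report.md"
    path.write_text("\n".join(lines))
    _update_manifest(out_dir, "report", {"outputs": [str(path)]})
    return path


def run_all(
    out_dir: str | Path,
    config_path: str | Path | None = None,
    seed: int | None = None,
    sigma: float = 1.0,
    ci_method: str = "normal",
    estimator: str = "ols-cluster",
    playtime_scale: str = "normalized",
) -> Path:
    """simulate -> analyze -> compare -> report in one call."""
    out_dir = Path(out_dir)
    sim = run_simulate(out_dir, config_path=config_path, seed=seed)
    run_analyze(
        sim["trials"], sim["choices"], out_dir,
        sigma=sigma, ci_method=ci_method, estimator=estimator,
        playtime_scale=playtime_scale,
    )
    run_compare(sim["trials"], out_dir, sigma=sigma)
    return run_report(out_dir)
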