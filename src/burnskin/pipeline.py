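"""End-to-end orchestration: generate -> process -> fit -> screen ->
univariate -> classify -> report.

Each stage reads the plain-text artifacts of the previous one and writes
its own, so any stage can be rerun in isolation from cached upstream
outputs.  One master seed in the configuration derives per-stage seeds
deterministically (stage-name hashing), and every artifact records the
package version and the resolved seed, so identical configuration implies
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassificationReport, classify_cohort
from .constitutive import fit_vw
from .curves import extract_properties, to_stress_strain
from .synthetic import (
    ParameterDistribution,
    SyntheticCohortConfig,
    derive_seed,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from .univariate import (
    DEFAULT_ALPHA,
    FEATURES,
    PowerQuery,
    min_sample_size,
    outlier_screen,
    run_univariate,
)

__all__ = ["PipelineConfig", "run_pipeline", "build_feature_table"]


@dataclass(frozen=True)
class PipelineConfig:
    """Resolved configuration of one pipeline run.

    ``input_dir`` may point at an existing cohort directory (written in the
    specimen text format); when None, a synthetic cohort is generated from
    ``generator`` with the generate-stage seed derived from ``seed``.
    """

    output_dir: str = "burnskin_out"
    input_dir: str | None = None
    generator: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    alpha: float = DEFAULT_ALPHA
    fence_scope: str = "pooled"
    fence_multiplier: float = 3.0
    quantile_convention: str = "linear"
    power_alpha: float = 0.05
    power_target: float = 0.85
    power_tails: str = "one"
    contribution_method: str = "coefficients"
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        d.pop("version", None)
        if "generator" in d and isinstance(d["generator"], dict):
            g = d["generator"]
            for key in ("mu_dist", "gamma_dist", "rupture_strain_dist"):
                if key in g and isinstance(g[key], dict):
                    g[key] = ParameterDistribution(**g[key])
            for key in ("n_per_class", "rate_classes"):
                if key in g:
                    g[key] = tuple(g[key])
            d["generator"] = SyntheticCohortConfig(**g)
        return cls(**d)


def _stamp(path: Path, seed: int) -> str:
    return f"# burnskin {__version__} seed={seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, seed: int) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(path, seed))
        df.to_csv(fh, index=False)


def read_artifact_csv(path: str | Path) -> pd.DataFrame:
    """Read a pipeline CSV artifact, skipping the provenance comment line."""
    return pd.read_csv(path, comment="#")


# ---------------------------------------------------------------------------
# stages


def stage_generate(config: PipelineConfig, outdir: Path) -> Path:
    gen = dataclasses.replace(config.generator, seed=derive_seed(config.seed, "generate"))
    records, truth = generate_cohort(gen)
    cohort_dir = outdir / "cohort"
    write_cohort(records, cohort_dir, truth=truth, seed=gen.seed)
    return cohort_dir


def build_feature_table(records, fit: bool = True) -> pd.DataFrame:
    """Feature table for a list of tensile records.

    Always includes the three curve properties; with ``fit=True`` also the
    Veronda-Westmann columns (fit on the curve truncated at its failure
    peak).
    """
    rows = []
    for rec in records:
        curve = to_stress_strain(rec)
        props = extract_properties(curve)
        row = {
            "sample_id": rec.sample_id,
            "rate_mm_per_s": rec.rate_class,
            "ut_stress_MPa": props.ut_stress,
            "ut_strain": props.ut_strain,
            "toughness_MPa": props.toughness,
        }
        if fit:
            vw = fit_vw(curve.truncated(props.failure_index))
            row.update(
                mu_MPa=vw.params.mu,
                gamma=vw.params.gamma,
                r_squared=vw.r_squared,
                converged=vw.converged,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def stage_process(cohort_dir: Path, outdir: Path, seed: int, fit: bool = True) -> Path:
    records = read_cohort(cohort_dir)
    features = build_feature_table(records, fit=fit)
    path = outdir / "features.csv"
    _write_csv(features, path, seed)
    return path


def stage_screen(config: PipelineConfig, outdir: Path) -> Path:
    features = read_artifact_csv(outdir / "features.csv")
    kept, removed = outlier_screen(
        features, multiplier=config.fence_multiplier, scope=config.fence_scope
    )
    _write_csv(kept, outdir / "screened_features.csv", config.seed)
    _write_csv(removed, outdir / "removed_samples.csv", config.seed)
    return outdir / "screened_features.csv"


def stage_univariate(config: PipelineConfig, outdir: Path) -> Path:
    kept = read_artifact_csv(outdir / "screened_features.csv")
    table, _ = run_univariate(kept, alpha=config.alpha)
    _write_csv(table, outdir / "univariate.csv", config.seed)

    d_grid = table["cohens_d"].to_numpy()
    query = PowerQuery(
        effect_size=max(float(np.mean(d_grid)), 1e-3),
        alpha=config.power_alpha,
        power=config.power_target,
        tails=config.power_tails,
    )
    n_req = min_sample_size(query)
    lines = [
        f"burnskin {__version__} univariate report (alpha = {config.alpha}, seed = {config.seed})",
        "",
        f"rejections: {int((table['conclusion'] == 'not equal').sum())} of {len(table)} "
        "parameter/rate-pair comparisons",
        f"mean Cohen's d across comparisons: {np.mean(d_grid):.4f} "
        f"(max {np.max(d_grid):.4f})",
        f"minimum per-group sample size at d = {query.effect_size:.2f}, "
        f"alpha = {query.alpha}, power = {query.power}, {query.tails}-tailed: {n_req}",
        "",
        table.to_string(index=False),
    ]
    (outdir / "univariate_report.txt").write_text("\n".join(lines) + "\n")
    return outdir / "univariate.csv"


def stage_classify(config: PipelineConfig, outdir: Path) -> ClassificationReport:
    kept = read_artifact_csv(outdir / "screened_features.csv")
    report = classify_cohort(kept)
    conf = pd.DataFrame(
        report.confusion.counts,
        index=[f"true_{r:g}" for r in report.confusion.class_labels],
        columns=[f"pred_{r:g}" for r in report.confusion.class_labels],
    )
    with open(outdir / "confusion.csv", "w") as fh:
        fh.write(_stamp(outdir / "confusion.csv", config.seed))
        conf.to_csv(fh)
    payload = {
        "version": __version__,
        "seed": config.seed,
        "accuracy": report.accuracy,
        "mcc": report.mcc,
        "fmi": report.fmi,
        "ari": report.ari,
    }
    (outdir / "metrics.json").write_text(json.dumps(payload, indent=2) + "\n")
    _write_csv(
        report.contributions.rename_axis("feature").reset_index(),
        outdir / "contributions.csv",
        config.seed,
    )
    return report


def stage_report(config: PipelineConfig, outdir: Path) -> Path:
    features = read_artifact_csv(outdir / "features.csv")
    kept = read_artifact_csv(outdir / "screened_features.csv")
    removed = read_artifact_csv(outdir / "removed_samples.csv")
    uni = read_artifact_csv(outdir / "univariate.csv")
    m = json.loads((outdir / "metrics.json").read_text())
    contrib = read_artifact_csv(outdir / "contributions.csv")

    med = kept[list(FEATURES)].quantile([0.5, 0.25, 0.75])
    kept_counts = kept.groupby("rate_mm_per_s").size()
    lines = [
        f"burnskin {__version__} summary (seed = {config.seed})",
        "",
        f"specimens processed: {len(features)}; kept after 3*IQR screen: {len(kept)} "
        f"({', '.join(f'{r:g} mm/s: {n}' for r, n in kept_counts.items())}); "
        f"removed: {len(removed)}",
        "",
        "pooled median [Q1, Q3] of the five material parameters:",
        *(
            f"  {feat}: {med.loc[0.5, feat]:.3g} [{med.loc[0.25, feat]:.3g}, "
            f"{med.loc[0.75, feat]:.3g}]"
            for feat in FEATURES
        ),
        "",
        "univariate decisions (alpha = %g): %d of %d comparisons rejected"
        % (config.alpha, int((uni["conclusion"] == "not equal").sum()), len(uni)),
        "",
        "multivariate LOOCV classification:",
        f"  accuracy = {m['accuracy']:.4f}  MCC = {m['mcc']:.4f}  "
        f"FMI = {m['fmi']:.4f}  ARI = {m['ari']:.4f}",
        "",
        "feature contributions (normalized mean |standardized coefficient|):",
        *(
            f"  {row.feature}: {row.contribution:.3f}"
            for row in contrib.itertuples()
        ),
    ]
    path = outdir / "summary.txt"
    path.write_text("\n".join(lines) + "\n")
    return path


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage; returns the output directory.

    Identical configuration (including seed) yields byte-identical numeric
    artifacts.  Any stage failure raises with a stage-labeled message.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "resolved_config.yaml")

    stage = "generate"
    try:
        if config.input_dir is not None:
            cohort_dir = Path(config.input_dir)
        else:
            cohort_dir = stage_generate(config, outdir)
        stage = "process"
        stage_process(cohort_dir, outdir, config.seed)
        stage = "screen"
        stage_screen(config, outdir)
        stage = "univariate"
        stage_univariate(config, outdir)
        stage = "classify"
        stage_classify(config, outdir)
        stage = "report"
        stage_report(config, outdir)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage label
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return outdir
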