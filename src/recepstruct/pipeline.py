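"""End-to-end pipeline: feature extraction → regression → report artifacts."""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .config import RunConfig
from .features.contacts import ContactParams
from .features.table import (
    FeatureConfig,
    build_feature_table,
    read_manifest,
    write_feature_table,
)
from .regression.family import AnalysisReport, FamilyConfig, run_family_analysis
from .structure.radii import VdwRadiusTable

logger = logging.getLogger("recepstruct")


def setup_logging(out_dir: Path, level: int = logging.INFO) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    handlers: list[logging.Handler] = [
        logging.StreamHandler(),
        logging.FileHandler(out_dir / "run.log", mode="w"),
    ]
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


def feature_config_from(config: RunConfig) -> FeatureConfig:
    radius_table = (
        VdwRadiusTable.from_config(config.radii_path)
        if config.radii_path
        else VdwRadiusTable()
    )
    return FeatureConfig(
        contact_params=ContactParams(
            overlap_cutoff=config.overlap_cutoff,
            bond_exclusion=config.bond_exclusion,
            radius_table=radius_table,
        ),
        ss_energy_cutoff=config.ss_energy_cutoff,
        exit_angle_projected=config.exit_angle_projected,
        skip_errors=config.skip_errors,
    )


def run_pipeline(
    config: RunConfig,
    manifest_path: str | Path,
    performance_path: str | Path,
) -> AnalysisReport:
    """Extract features from a manifest, regress against performance, write
    features.csv / report.json / report.md (plus run.log) to the output dir."""
    out_dir = Path(config.out_dir)
    setup_logging(out_dir)
    logger.info("configuration: %s", json.dumps(config.to_dict(), sort_keys=True))

    manifest = read_manifest(manifest_path)
    logger.info("manifest: %d design(s) from %s", len(manifest), manifest_path)
    features = build_feature_table(manifest, feature_config_from(config))
    write_feature_table(features, out_dir / "features.csv")
    logger.info("features written: %s", out_dir / "features.csv")

    performance = pd.read_csv(performance_path)
    report = analyze(features, performance, config)
    write_report(report, out_dir)
    return report


def analyze(
    features: pd.DataFrame, performance: pd.DataFrame, config: RunConfig
) -> AnalysisReport:
    family_config = FamilyConfig(
        family=config.family,
        dv=config.dv,
        log_dv=config.log_dv,
        vif_threshold=config.vif_threshold,
        alpha=config.alpha,
        combined=config.combined,
    )
    report = run_family_analysis(features, performance, family_config)
    # embed the full run configuration so any report is reproducible from it
    report.config["run_config"] = config.to_dict()
    return report


def write_report(report: AnalysisReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(report.to_json() + "\n")
    (out_dir / "report.md").write_text(report.to_markdown() + "\n")
    coef_rows = []
    for label in ("full_structural", "reduced_structural", "full_categorical",
                  "reduced_categorical", "combined"):
        fit = getattr(report, label)
        if fit is None:
            continue
        for name in fit.feature_names:
            coef_rows.append(
                {
                    "model": label,
                    "feature": name,
                    "coefficient": fit.coefficients[name],
                    "std_error": fit.std_errors[name],
                    "p_value": fit.p_values[name],
                    "ci_low": fit.conf_intervals[name][0],
                    "ci_high": fit.conf_intervals[name][1],
                }
            )
    pd.DataFrame(coef_rows).to_csv(out_dir / "coefficients.csv", index=False)
    logger.info("report written to %s", out_dir)
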