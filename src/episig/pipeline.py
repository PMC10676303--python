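"""End-to-end orchestration from a single declarative configuration.

A run simulates (or loads) a training and a testing cohort, filters and
normalizes each separately (normalizing train and test together would leak
test information into the training distribution), discovers both
episignature paradigms on the training set, trains the requested model
kinds on each paradigm's features, evaluates missing-probe robustness and
control-cohort specificity on the test side, and writes every artifact plus
a provenance manifest (config hash, seeds, package versions) under the
output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import (
    PlantedRegion,
    SimConfig,
    SimulatedCohort,
    simulate_cohort,
)
from .classify import EpisignatureClassifier, save_model, train_classifier
from .dmc import DMCEpisignature, build_dmc_signature
from .dmr import DMREpisignature, DMRParams, build_dmr_signature
from .evaluate import (
    RobustnessReport,
    SpecificityReport,
    cross_specificity,
    missing_probe_experiment,
)
from .features import dmc_features, dmr_features
from .preprocess import FilterReport, filter_probes, normalize

__all__ = ["RunConfig", "RunArtifacts", "run_pipeline"]

logger = logging.getLogger(__name__)

_TEST_SEED_OFFSET = 100_003
_CONTROL_SEED_OFFSET = 200_003


@dataclass
class RunConfig:
    """Declarative configuration of one end-to-end run."""

    n_probes: int = 5000
    n_train_case: int = 20
    n_train_control: int = 20
    n_test_case: int = 20
    n_test_control: int = 20
    planted_regions: list[dict] = field(default_factory=list)
    planted_dmcs: list[list] = field(default_factory=list)
    noise_sd: float = 0.30
    detection_fail_rate: float = 0.0
    probe_spacing: int = 500
    normalization: str = "raw"
    dmc_p_threshold: float = 0.05
    dmc_delta_threshold: float = 0.10
    dmr: dict = field(default_factory=dict)
    model_kinds: list[str] = field(default_factory=lambda: ["svm", "rf", "plr"])
    fractions: list[float] = field(default_factory=lambda: [0.0, 0.05, 0.10, 0.20, 0.30])
    n_repeats: int = 10
    specificity_controls: int = 20  # size of the held-out control-only cohort
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunArtifacts:
    filter_report: FilterReport
    dmc_signature: DMCEpisignature
    dmr_signature: DMREpisignature
    models: dict[str, dict[str, EpisignatureClassifier]]
    robustness: RobustnessReport | None
    specificity: SpecificityReport | None
    train: SimulatedCohort
    test: SimulatedCohort
    out_dir: Path | None
    provenance: dict


def _sim_config(config: RunConfig, n_case: int, n_control: int, seed: int) -> SimConfig:
    return SimConfig(
        n_probes=config.n_probes,
        n_case=n_case,
        n_control=n_control,
        noise_sd=config.noise_sd,
        planted_regions=[PlantedRegion(**r) for r in config.planted_regions],
        planted_dmcs=[tuple(t) for t in config.planted_dmcs],
        detection_fail_rate=config.detection_fail_rate,
        probe_spacing=config.probe_spacing,
        seed=seed,
        baseline_seed=config.seed,  # train/test share probe-level baselines
    )


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> RunArtifacts:
    """Execute all stages; identical config + seed reproduces identical artifacts."""
    train = simulate_cohort(
        _sim_config(config, config.n_train_case, config.n_train_control, config.seed)
    )
    test = simulate_cohort(
        _sim_config(
            config,
            config.n_test_case,
            config.n_test_control,
            config.seed + _TEST_SEED_OFFSET,
        )
    )

    logger.info("preprocessing: filtering and '%s' normalization", config.normalization)
    train_betas, filter_report = filter_probes(
        train.betas, train.manifest, train.detection_p
    )
    train_betas = normalize(train_betas, config.normalization)
    test_betas, _ = filter_probes(test.betas, test.manifest, test.detection_p)
    test_betas = normalize(test_betas, config.normalization)

    logger.info("discovering episignatures on %d training probes", len(train_betas))
    dmc_sig, _ = build_dmc_signature(
        train_betas,
        train.labels,
        manifest=train.manifest.loc[train_betas.index],
        p_threshold=config.dmc_p_threshold,
        delta_threshold=config.dmc_delta_threshold,
    )
    dmr_params = DMRParams(**{**config.dmr, "seed": config.seed})
    dmr_sig, _ = build_dmr_signature(
        train_betas, train.labels, train.manifest.loc[train_betas.index], dmr_params
    )

    signatures = {"dmc": dmc_sig, "dmr": dmr_sig}
    models: dict[str, dict[str, EpisignatureClassifier]] = {"dmc": {}, "dmr": {}}
    if config.model_kinds:
        train_feats = {
            "dmc": dmc_features(train_betas, dmc_sig, manifest=train.manifest),
            "dmr": dmr_features(train_betas, dmr_sig),
        }
        for paradigm, feats in train_feats.items():
            if feats.shape[1] == 0:
                logger.warning("%s signature is empty; skipping its models", paradigm)
                continue
            for kind in config.model_kinds:
                models[paradigm][kind] = train_classifier(
                    feats, train.labels, kind=kind, seed=config.seed
                )
    else:
        logger.warning("empty model list: evaluation skipped")

    robustness = None
    specificity = None
    trained = {p: m for p, m in models.items() if m}
    if trained:
        robustness = missing_probe_experiment(
            test_betas,
            test.labels,
            test.manifest,
            models=trained,
            signatures=signatures,
            fractions=tuple(config.fractions),
            n_repeats=config.n_repeats,
            base_seed=config.seed,
        )
        if config.specificity_controls > 0 and models["dmr"]:
            controls = simulate_cohort(
                SimConfig(
                    n_probes=config.n_probes,
                    n_case=1,  # discarded: only the control samples are used
                    n_control=config.specificity_controls,
                    noise_sd=config.noise_sd,
                    # same array, control state at the signature's regions
                    null_regions=[PlantedRegion(**r) for r in config.planted_regions],
                    probe_spacing=config.probe_spacing,
                    seed=config.seed + _CONTROL_SEED_OFFSET,
                    baseline_seed=config.seed,
                )
            )
            control_betas = controls.betas.loc[:, controls.labels == "control"]
            first_kind = next(iter(models["dmr"]))
            specificity = cross_specificity(
                models["dmr"][first_kind],
                dmr_sig,
                control_betas,
                controls.manifest,
                paradigm="dmr",
            )

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "episig_version": __version__,
    }

    out_path = None
    if out_dir is not None:
        out_path = Path(out_dir)
        _write_artifacts(
            out_path, filter_report, dmc_sig, dmr_sig, models,
            robustness, specificity, provenance,
        )

    return RunArtifacts(
        filter_report=filter_report,
        dmc_signature=dmc_sig,
        dmr_signature=dmr_sig,
        models=models,
        robustness=robustness,
        specificity=specificity,
        train=train,
        test=test,
        out_dir=out_path,
        provenance=provenance,
    )


def _write_artifacts(
    out, filter_report, dmc_sig, dmr_sig, models, robustness, specificity, provenance
) -> None:
    for sub in ("signatures", "models", "reports", "provenance"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    (out / "signatures" / "dmc_signature.json").write_text(dmc_sig.to_json())
    (out / "signatures" / "dmr_signature.json").write_text(dmr_sig.to_json())
    (out / "signatures" / "dmr_regions.bed").write_text(dmr_sig.to_bed())
    (out / "reports" / "filter_report.json").write_text(
        json.dumps(dataclasses.asdict(filter_report), sort_keys=True, indent=1)
    )
    for paradigm, kind_models in models.items():
        for kind, model in kind_models.items():
            save_model(model, out / "models" / f"{paradigm}_{kind}")
    if robustness is not None:
        robustness.records.to_csv(out / "reports" / "robustness_records.tsv", sep="\t", index=False)
        robustness.summary.to_csv(out / "reports" / "robustness_summary.tsv", sep="\t", index=False)
    if specificity is not None:
        specificity.predictions.to_csv(out / "reports" / "specificity_predictions.tsv", sep="\t")
        (out / "reports" / "specificity.json").write_text(
            json.dumps(
                {
                    "n_predicted_case": specificity.n_predicted_case,
                    "n_predicted_control": specificity.n_predicted_control,
                    "specificity": specificity.specificity,
                },
                sort_keys=True,
                indent=1,
            )
        )
    (out / "provenance" / "provenance.json").write_text(
        json.dumps(provenance, sort_keys=True, indent=1)
    )
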