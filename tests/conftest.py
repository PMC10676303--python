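"""Shared fixtures: small synthetic studies reused across the suite.

Heavy objects (cohorts, discovered signatures, trained models) are
session-scoped so each is built once.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
import pytest

from episig import (
    DMRParams,
    PlantedRegion,
    SimConfig,
    SimulatedCohort,
    build_dmc_signature,
    build_dmr_signature,
    dmc_features,
    dmr_features,
    simulate_cohort,
    train_classifier,
)


@dataclass
class Study:
    """A train/test pair sharing probe baselines and planted truth."""

    train: SimulatedCohort
    test: SimulatedCohort
    dmc_sig: object
    dmr_sig: object
    dmc_results: pd.DataFrame
    dmr_candidates: pd.DataFrame


def make_study(
    n_probes: int = 2000,
    n_case: int = 15,
    n_control: int = 15,
    delta: float = 0.35,
    n_regions: int = 4,
    region_probes: int = 12,
    n_dmcs: int = 20,
    n_permutations: int = 60,
    seed: int = 42,
) -> Study:
    regions = [
        PlantedRegion("chr1", 300 + i * 300, region_probes, delta)
        for i in range(n_regions)
    ]
    dmcs = [(1600 + 3 * i, delta) for i in range(n_dmcs)]
    train = simulate_cohort(
        SimConfig(
            n_probes=n_probes, n_case=n_case, n_control=n_control,
            planted_regions=regions, planted_dmcs=dmcs,
            seed=seed, baseline_seed=seed,
        )
    )
    test = simulate_cohort(
        SimConfig(
            n_probes=n_probes, n_case=n_case, n_control=n_control,
            planted_regions=regions, planted_dmcs=dmcs,
            seed=seed + 77_000, baseline_seed=seed,
        )
    )
    dmc_sig, dmc_results = build_dmc_signature(
        train.betas, train.labels, manifest=train.manifest
    )
    dmr_sig, dmr_candidates = build_dmr_signature(
        train.betas, train.labels, train.manifest,
        DMRParams(n_permutations=n_permutations, seed=seed),
    )
    return Study(train, test, dmc_sig, dmr_sig, dmc_results, dmr_candidates)


@pytest.fixture(scope="session")
def study() -> Study:
    """Well-separated study: strong planted signal, both signatures non-empty."""
    s = make_study()
    assert len(s.dmc_sig) > 0 and len(s.dmr_sig) > 0
    return s


@pytest.fixture(scope="session")
def train_features(study):
    return {
        "dmc": dmc_features(study.train.betas, study.dmc_sig, manifest=study.train.manifest),
        "dmr": dmr_features(study.train.betas, study.dmr_sig),
    }


@pytest.fixture(scope="session")
def trained_models(study, train_features):
    """All three model kinds on both paradigms' training features."""
    return {
        paradigm: {
            kind: train_classifier(feats, study.train.labels, kind=kind, seed=7)
            for kind in ("svm", "rf", "plr")
        }
        for paradigm, feats in train_features.items()
    }
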