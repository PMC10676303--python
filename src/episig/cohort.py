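"""Synthetic Infinium-like case/control cohorts with planted episignatures.

The generator emulates a balanced two-group methylation-array study: a
probe-by-sample matrix of beta-values (methylation fractions in [0, 1]) with
a bimodal baseline, log-odds-scale measurement noise, optional planted
differentially methylated regions (runs of consecutive probes shifted in the
case group) and planted single differentially methylated cytosines, plus a
detection-p matrix emulating per-(probe, sample) hybridisation quality.

Beta matrices are pandas DataFrames with probe ids as the index (rows, in
genomic order) and sample ids as the columns.  Probe manifests are DataFrames
indexed by probe id with columns ``chrom``, ``pos``, ``snp_overlap``,
``cross_reactive`` and ``sex_chrom``, sorted by (chrom, pos).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "BaselineMixture",
    "PlantedRegion",
    "SimConfig",
    "TruthSet",
    "SimulatedCohort",
    "make_manifest",
    "simulate_cohort",
    "inject_missing",
    "mask_array_version",
]

_EPS = 1e-3  # clip betas away from {0,1} before the logit transform

CASE = "case"
CONTROL = "control"


@dataclass(frozen=True)
class BaselineMixture:
    """Two-component beta mixture for per-probe baseline methylation.

    Array beta-values are bimodal: most CpGs are either essentially
    unmethylated (beta near 0.1-0.2) or essentially methylated (near 0.8-0.9).
    Component means default to 0.15 and 0.85 with a 60/40 split.
    """

    unmeth_weight: float = 0.6
    unmeth_a: float = 3.0
    unmeth_b: float = 17.0
    meth_a: float = 17.0
    meth_b: float = 3.0


@dataclass(frozen=True)
class PlantedRegion:
    """A run of consecutive probes shifted by ``delta`` (case minus control)."""

    chrom: str
    start_index: int  # index into the manifest's probe order
    n_probes: int
    delta: float


@dataclass
class SimConfig:
    """Configuration of one simulated cohort.

    ``delta`` values are signed beta-scale group differences; the shift is
    applied on the logit scale and mapped back so betas stay in range near
    the boundaries.  ``noise_sd`` is the per-(probe, sample) Gaussian noise
    standard deviation on the logit scale (0.30 gives a beta-scale spread of
    roughly 0.04-0.07, typical of blood-derived array data).

    ``baseline_seed`` controls the per-probe baseline stream separately from
    the sample draw, so that a training and a testing cohort of the same
    study can share probe-level baselines (pass the same ``baseline_seed``
    with different ``seed``); it defaults to ``seed``.

    ``null_regions`` declare regions that carry a planted shift in a
    *different* cohort of the same study design: their baseline component is
    reserved exactly as for planted regions (so both cohorts agree on the
    control-state methylation of those probes) but no shift is applied here.
    Use them to build disjoint-signature cohort pairs for specificity
    experiments.
    """

    n_probes: int
    n_case: int
    n_control: int
    baseline_mix: BaselineMixture = field(default_factory=BaselineMixture)
    noise_sd: float = 0.30
    planted_regions: Sequence[PlantedRegion] = ()
    planted_dmcs: Sequence[tuple[int, float]] = ()
    null_regions: Sequence[PlantedRegion] = ()
    null_dmcs: Sequence[tuple[int, float]] = ()
    detection_fail_rate: float = 0.0
    probe_spacing: int = 500
    n_chroms: int = 1
    seed: int = 0
    baseline_seed: int | None = None

    def validate(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValueError("both case and control counts must be positive")
        if not 0.0 <= self.detection_fail_rate < 1.0:
            raise ValueError("detection_fail_rate must be in [0, 1)")
        for reg in list(self.planted_regions) + list(self.null_regions):
            if reg.n_probes < 1:
                raise ValueError("planted region must span at least one probe")
            if abs(reg.delta) > 1:
                raise ValueError("|delta| must be <= 1")
            if reg.start_index < 0 or reg.start_index + reg.n_probes > self.n_probes:
                raise IndexError(
                    f"planted region [{reg.start_index}, "
                    f"{reg.start_index + reg.n_probes}) outside manifest "
                    f"of {self.n_probes} probes"
                )
        for idx, delta in list(self.planted_dmcs) + list(self.null_dmcs):
            if not 0 <= idx < self.n_probes:
                raise IndexError(f"planted DMC index {idx} outside manifest")
            if abs(delta) > 1:
                raise ValueError("|delta| must be <= 1")


@dataclass
class TruthSet:
    """Ground truth of planted signal, for parameter-recovery tests."""

    regions: pd.DataFrame  # chrom, start_index, end_index, start, end, n_probes, delta
    dmc_probe_ids: list[str]

    def to_json(self) -> str:
        payload = {
            "regions": self.regions.to_dict(orient="records"),
            "dmc_probe_ids": list(self.dmc_probe_ids),
        }
        return json.dumps(payload, sort_keys=True, indent=1)


@dataclass
class SimulatedCohort:
    betas: pd.DataFrame
    detection_p: pd.DataFrame
    labels: pd.Series  # sample id -> "case" / "control"
    manifest: pd.DataFrame
    truth: TruthSet
    config: SimConfig


def make_manifest(
    n_probes: int,
    spacing: int = 500,
    n_chroms: int = 1,
    start_pos: int = 1_000,
) -> pd.DataFrame:
    """Synthetic probe manifest: evenly spaced probes on one or few chromosomes.

    Positions are 1-based (Illumina manifest convention); rows sorted by
    (chrom, pos).  All QC flags default to False.
    """
    if n_probes <= 0:
        raise ValueError("n_probes must be positive")
    per_chrom = int(np.ceil(n_probes / n_chroms))
    chroms = [f"chr{1 + i // per_chrom}" for i in range(n_probes)]
    offsets = np.arange(n_probes) % per_chrom
    manifest = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": start_pos + offsets * spacing,
            "snp_overlap": False,
            "cross_reactive": False,
            "sex_chrom": False,
        },
        index=pd.Index([f"cg{i:08d}" for i in range(n_probes)], name="probe_id"),
    )
    return manifest


def _baseline_betas(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-probe baseline methylation from the two-component mixture.

    Planted probes draw from the component that leaves room for their shift:
    hypermethylation effects (delta > 0) start from the unmethylated
    component, hypomethylation effects from the methylated one.
    """
    mix = config.baseline_mix
    unmeth = rng.random(config.n_probes) < mix.unmeth_weight
    baseline = np.where(
        unmeth,
        rng.beta(mix.unmeth_a, mix.unmeth_b, size=config.n_probes),
        rng.beta(mix.meth_a, mix.meth_b, size=config.n_probes),
    )
    redraw_low = rng.beta(mix.unmeth_a, mix.unmeth_b, size=config.n_probes)
    redraw_high = rng.beta(mix.meth_a, mix.meth_b, size=config.n_probes)
    direction = _delta_vector(config, include_null=True)
    baseline = np.where(direction > 0, redraw_low, baseline)
    baseline = np.where(direction < 0, redraw_high, baseline)
    return baseline


def _delta_vector(config: SimConfig, include_null: bool = False) -> np.ndarray:
    delta = np.zeros(config.n_probes)
    regions = list(config.planted_regions)
    if include_null:
        regions += list(config.null_regions)
    for reg in regions:
        delta[reg.start_index : reg.start_index + reg.n_probes] = reg.delta
    dmcs = list(config.planted_dmcs)
    if include_null:
        dmcs += list(config.null_dmcs)
    for idx, d in dmcs:
        delta[idx] = d
    return delta


def _truth(config: SimConfig, manifest: pd.DataFrame) -> TruthSet:
    rows = []
    intervals: list[tuple[int, int]] = []
    for reg in config.planted_regions:
        lo, hi = reg.start_index, reg.start_index + reg.n_probes - 1
        for a, b in intervals:
            if lo <= b and hi >= a:
                raise ValueError("planted regions must not overlap")
        intervals.append((lo, hi))
        rows.append(
            {
                "chrom": manifest["chrom"].iloc[lo],
                "start_index": lo,
                "end_index": hi,
                "start": int(manifest["pos"].iloc[lo]),
                "end": int(manifest["pos"].iloc[hi]),
                "n_probes": reg.n_probes,
                "delta": reg.delta,
            }
        )
    regions = pd.DataFrame(
        rows,
        columns=["chrom", "start_index", "end_index", "start", "end", "n_probes", "delta"],
    )
    dmc_ids = [manifest.index[i] for i, _ in config.planted_dmcs]
    return TruthSet(regions=regions, dmc_probe_ids=dmc_ids)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate one balanced (or unbalanced) case/control cohort.

    Fully reproducible from ``config.seed`` (and ``baseline_seed``).
    """
    config.validate()
    manifest = make_manifest(config.n_probes, config.probe_spacing, config.n_chroms)
    truth = _truth(config, manifest)

    base_seed = config.seed if config.baseline_seed is None else config.baseline_seed
    baseline = _baseline_betas(config, np.random.default_rng(base_seed))
    delta = _delta_vector(config)

    mu_control = logit(np.clip(baseline, _EPS, 1 - _EPS))
    mu_case = logit(np.clip(baseline + delta, _EPS, 1 - _EPS))

    rng = np.random.default_rng(config.seed)
    n = config.n_case + config.n_control
    noise = rng.normal(0.0, config.noise_sd, size=(config.n_probes, n))
    mu = np.concatenate(
        [
            np.repeat(mu_case[:, None], config.n_case, axis=1),
            np.repeat(mu_control[:, None], config.n_control, axis=1),
        ],
        axis=1,
    )
    values = expit(mu + noise)

    sample_ids = [f"case_{i + 1:03d}" for i in range(config.n_case)] + [
        f"control_{i + 1:03d}" for i in range(config.n_control)
    ]
    betas = pd.DataFrame(values, index=manifest.index, columns=sample_ids)
    labels = pd.Series(
        [CASE] * config.n_case + [CONTROL] * config.n_control,
        index=sample_ids,
        name="label",
    )

    fails = rng.random(values.shape) < config.detection_fail_rate
    detection = np.where(
        fails,
        0.01 + 0.99 * rng.random(values.shape),
        0.01 * rng.random(values.shape),
    )
    detection_p = pd.DataFrame(detection, index=manifest.index, columns=sample_ids)

    return SimulatedCohort(
        betas=betas,
        detection_p=detection_p,
        labels=labels,
        manifest=manifest,
        truth=truth,
        config=config,
    )


def inject_missing(betas: pd.DataFrame, fraction: float, seed: int) -> pd.DataFrame:
    """Set ``floor(fraction * n_probes)`` whole probe rows to missing.

    Rows are chosen uniformly without replacement; removal is probe-wise
    across all samples, emulating probes dropped from a whole array
    (new array version, blacklist, failed hybridisation batch-wide).
    Non-selected rows are untouched.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    out = betas.copy()
    k = int(np.floor(fraction * len(betas)))
    if k == 0:
        return out
    rows = np.random.default_rng(seed).choice(len(betas), size=k, replace=False)
    out.iloc[rows] = np.nan
    return out


def mask_array_version(betas: pd.DataFrame, keep: Sequence[str] | set) -> pd.DataFrame:
    """Restrict the matrix to ``keep`` probes (emulates a newer array version).

    Row order of the original matrix is preserved.
    """
    keep = set(keep)
    if not keep:
        raise ValueError("keep set must be non-empty")
    unknown = keep - set(betas.index)
    if unknown:
        raise KeyError(f"{len(unknown)} probes in keep set absent from the matrix")
    return betas.loc[[p for p in betas.index if p in keep]]
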