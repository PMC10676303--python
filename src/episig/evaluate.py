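"""Evaluation procedures: missing-probe robustness, specificity, views.

- :func:`missing_probe_experiment` removes 5-30% of probes from the whole
  test array (10 repeats with distinct seeds), featurizes under BOTH
  missing-data policies, predicts with every supplied model and aggregates
  MCC (mean +/- std per cell).
- :func:`cross_specificity` applies one syndrome's model to another cohort,
  treating every sample there as a true negative.
- :func:`hierarchical_clusters` and :func:`embed_2d` are the unsupervised
  views (average-linkage Manhattan clustering; seeded 2-D UMAP embedding of
  standardized features).
- :func:`genomic_partition` assigns signature CpGs to promoter (<1 kb
  upstream of the strand-aware TSS), 1-5 kb upstream, gene body or
  intergenic, with that precedence, and compares against a background probe
  set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .cohort import CASE, CONTROL, inject_missing
from .classify import EpisignatureClassifier, mcc
from .features import dmc_features, dmr_features

__all__ = [
    "RobustnessReport",
    "SpecificityReport",
    "PartitionReport",
    "missing_probe_experiment",
    "cross_specificity",
    "hierarchical_clusters",
    "embed_2d",
    "genomic_partition",
]

PARTITION_CATEGORIES = ("promoter", "upstream_1to5kb", "gene_body", "intergenic")


@dataclass
class RobustnessReport:
    """Per-(fraction, repeat, paradigm, model) MCC plus aggregated cells."""

    records: pd.DataFrame  # fraction, repeat, paradigm, model, mcc
    summary: pd.DataFrame  # fraction, paradigm, model, mean_mcc, std_mcc, n


@dataclass
class SpecificityReport:
    predictions: pd.DataFrame  # sample_id, probability, label
    n_predicted_case: int
    n_predicted_control: int
    specificity: float


@dataclass
class PartitionReport:
    fractions: pd.DataFrame  # index: category; columns: signature, background
    counts: pd.DataFrame


def _featurize(paradigm: str, betas, signature, manifest):
    if paradigm == "dmc":
        return dmc_features(betas, signature, manifest=manifest)
    return dmr_features(betas, signature)


def missing_probe_experiment(
    test_betas: pd.DataFrame,
    test_labels: pd.Series,
    manifest: pd.DataFrame,
    models: Mapping[str, Mapping[str, EpisignatureClassifier]],
    signatures: Mapping[str, object],
    fractions=(0.0, 0.05, 0.10, 0.20, 0.30),
    n_repeats: int = 10,
    base_seed: int = 0,
) -> RobustnessReport:
    """Missing-probe robustness: MCC under increasing whole-array removal.

    ``models`` maps paradigm ("dmc"/"dmr") to {model kind: fitted model};
    ``signatures`` maps paradigm to the corresponding episignature.  For
    each nonzero fraction and repeat i, one shared missing set (seed
    ``base_seed + i``) is injected into the whole test array and every
    model is evaluated on it; fraction 0 is a single deterministic
    evaluation.
    """
    for f in fractions:
        if not 0.0 <= f < 1.0:
            raise ValueError("fractions must lie in [0, 1)")
    rows = []
    for fraction in fractions:
        repeats = [0] if fraction == 0 else range(1, n_repeats + 1)
        for rep in repeats:
            degraded = (
                test_betas
                if fraction == 0
                else inject_missing(test_betas, fraction, seed=base_seed + rep)
            )
            for paradigm, kind_models in models.items():
                feats = _featurize(paradigm, degraded, signatures[paradigm], manifest)
                for kind, model in kind_models.items():
                    pred = model.predict(feats)
                    rows.append(
                        {
                            "fraction": fraction,
                            "repeat": rep,
                            "paradigm": paradigm,
                            "model": kind,
                            "mcc": mcc(test_labels.loc[feats.index].to_numpy(), pred),
                        }
                    )
    records = pd.DataFrame(rows)
    summary = (
        records.groupby(["fraction", "paradigm", "model"], as_index=False)["mcc"]
        .agg(mean_mcc="mean", std_mcc="std", n="count")
        .fillna({"std_mcc": 0.0})
    )
    return RobustnessReport(records=records, summary=summary)


def cross_specificity(
    model: EpisignatureClassifier,
    signature,
    cohort_betas: pd.DataFrame,
    manifest: pd.DataFrame,
    paradigm: str = "dmr",
) -> SpecificityReport:
    """Apply a syndrome-A model to cohort B; every sample is a true negative.

    Specificity = TN / (TN + FP) = fraction predicted control.
    """
    if cohort_betas.shape[1] == 0:
        raise ValueError("cohort must contain at least one sample")
    feats = _featurize(paradigm, cohort_betas, signature, manifest)
    prob = model.case_probability(feats)
    label = np.where(prob > model.threshold_, CASE, CONTROL)
    predictions = pd.DataFrame(
        {"probability": prob, "label": label},
        index=pd.Index(feats.index, name="sample_id"),
    )
    n_case = int((label == CASE).sum())
    n_control = int((label == CONTROL).sum())
    return SpecificityReport(
        predictions=predictions,
        n_predicted_case=n_case,
        n_predicted_control=n_control,
        specificity=n_control / (n_case + n_control),
    )


def hierarchical_clusters(features: pd.DataFrame, k: int = 2) -> pd.Series:
    """Agglomerative clustering: average linkage, Manhattan (cityblock) distance."""
    if k > len(features):
        raise ValueError("k must not exceed the number of samples")
    Z = linkage(features.to_numpy(dtype=float), method="average", metric="cityblock")
    assignment = fcluster(Z, t=k, criterion="maxclust")
    return pd.Series(assignment, index=features.index, name="cluster")


def embed_2d(features: pd.DataFrame, seed: int = 0, n_neighbors: int = 15) -> pd.DataFrame:
    """Seeded 2-D UMAP embedding of standardized features.

    Features are centered and scaled first (zero-variance features divide
    by 1); requires at least 4 samples.
    """
    import umap  # deferred: numba-backed import is slow

    if len(features) < 4:
        raise ValueError("embedding requires at least 4 samples")
    X = features.to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mean) / sd
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=min(n_neighbors, len(features) - 1),
        random_state=seed,
    )
    coords = reducer.fit_transform(X)
    return pd.DataFrame(coords, index=features.index, columns=["umap1", "umap2"])


def _assign_category(
    chrom: str, pos: int, genes: pd.DataFrame
) -> str:
    """Precedence: promoter > 1-5 kb upstream > gene body > intergenic."""
    g = genes[genes["chrom"] == chrom]
    if len(g) == 0:
        return "intergenic"
    tss = np.where(g["strand"] == "+", g["start"], g["end"])
    upstream = np.where(g["strand"] == "+", tss - pos, pos - tss)
    if np.any((upstream >= 1) & (upstream <= 1000)):
        return "promoter"
    if np.any((upstream > 1000) & (upstream <= 5000)):
        return "upstream_1to5kb"
    if np.any((g["start"] <= pos) & (pos <= g["end"])):
        return "gene_body"
    return "intergenic"


def genomic_partition(
    probe_ids,
    manifest: pd.DataFrame,
    gene_model: pd.DataFrame,
    background_ids=None,
) -> PartitionReport:
    """Fraction of CpGs per genomic category, signature vs background.

    ``gene_model`` is BED-like: columns chrom, start, end, strand (and
    optionally name); the TSS is the strand-aware 5' end.  Categories are
    mutually exclusive by precedence, so fractions sum to 1 per set.
    """
    required = {"chrom", "start", "end", "strand"}
    if not required.issubset(gene_model.columns):
        raise ValueError(f"gene model must have columns {sorted(required)}")
    if (gene_model["start"] > gene_model["end"]).any():
        raise ValueError("gene model has start > end intervals")
    if not gene_model["strand"].isin(["+", "-"]).all():
        raise ValueError("gene model strand must be '+' or '-'")

    def tally(ids) -> pd.Series:
        cats = [
            _assign_category(manifest.loc[p, "chrom"], manifest.loc[p, "pos"], gene_model)
            for p in ids
        ]
        return pd.Series(cats).value_counts().reindex(PARTITION_CATEGORIES, fill_value=0)

    sig_counts = tally(list(probe_ids))
    bg_counts = (
        tally(list(background_ids))
        if background_ids is not None
        else pd.Series(0, index=list(PARTITION_CATEGORIES))
    )
    counts = pd.DataFrame({"signature": sig_counts, "background": bg_counts})
    fractions = counts / counts.sum(axis=0).replace(0, 1)
    return PartitionReport(fractions=fractions, counts=counts)
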