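"""DMC episignatures: per-probe Mann-Whitney testing with an effect threshold.

A differentially methylated cytosine (DMC) episignature is the classical
formulation: individual CpG probes whose beta-values separate cases from
controls.  Probes are tested one at a time with a two-sided Mann-Whitney U
test; selection requires both a (BH-adjusted, by default) p-value below
``p_threshold`` and an absolute group mean difference
``|mean(case) - mean(control)|`` of at least ``delta_threshold``.

The exact-mode p-value enumerates all C(n1+n2, n1) group assignments of the
pooled sample; the asymptotic mode uses the tie- and continuity-corrected
normal approximation.  ``auto`` switches to the approximation when
min(n1, n2) > 8 or ties are present.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from statsmodels.stats.multitest import multipletests

from .cohort import CASE, CONTROL

__all__ = [
    "mw_u_test",
    "bh_adjust",
    "DMCEpisignature",
    "build_dmc_signature",
    "DMCSelector",
]

_EXACT_MAX_N = 8


def mw_u_test(
    case_values,
    control_values,
    mode: str = "auto",
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for the case group, p).

    U is the rank-sum statistic ``R1 - n1(n1+1)/2`` with average ranks for
    ties, so ``0 <= U <= n1 * n2``.  ``mode``:

    - ``"exact"`` — full enumeration of group assignments (handles ties);
    - ``"normal_approx"`` — normal approximation with tie and continuity
      correction;
    - ``"auto"`` — exact when ``min(n1, n2) <= 8`` and the pooled sample is
      tie-free, approximation otherwise.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if mode not in ("exact", "normal_approx", "auto"):
        raise ValueError(f"unknown mode {mode!r}")

    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    has_ties = np.unique(pooled).size < pooled.size
    exact = mode == "exact" or (
        mode == "auto" and min(n1, n2) <= _EXACT_MAX_N and not has_ties
    )
    if exact:
        p = _exact_two_sided_p(ranks, n1, u)
    else:
        p = float(
            mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    return u, min(p, 1.0)


def _exact_two_sided_p(ranks: np.ndarray, n1: int, u_obs: float) -> float:
    """Exact p by enumerating every assignment of n1 pooled ranks to the cases."""
    n = ranks.size
    n2 = n - n1
    mu = n1 * n2 / 2.0
    dev = abs(u_obs - mu)
    offset = n1 * (n1 + 1) / 2.0
    hits = 0
    total = math.comb(n, n1)
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if abs(u - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (order-preserving, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DMCEpisignature:
    """Ordered selected-probe list with per-probe training statistics.

    ``probes`` is a DataFrame indexed by probe id (kept in genomic order)
    with columns ``delta_beta``, ``case_mean``, ``control_mean`` and, when a
    manifest was supplied at discovery, ``chrom`` and ``pos``.
    """

    probes: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.probes.index)

    def __len__(self) -> int:
        return len(self.probes)

    def to_json(self) -> str:
        payload = {
            "paradigm": "dmc",
            "params": self.params,
            "probes": [
                {"probe_id": pid, **{k: _jsonify(v) for k, v in row.items()}}
                for pid, row in self.probes.iterrows()
            ],
        }
        return json.dumps(payload, sort_keys=True, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DMCEpisignature":
        payload = json.loads(text)
        probes = pd.DataFrame(payload["probes"]).set_index("probe_id")
        return cls(probes=probes, params=payload["params"])


def _jsonify(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    return v


def _split_groups(betas: pd.DataFrame, labels: pd.Series):
    labels = labels.loc[betas.columns]
    classes = set(labels.unique())
    if classes != {CASE, CONTROL}:
        raise ValueError(
            f"labels must contain both '{CASE}' and '{CONTROL}' (got {sorted(classes)})"
        )
    case = betas.loc[:, labels == CASE].to_numpy(dtype=float)
    control = betas.loc[:, labels == CONTROL].to_numpy(dtype=float)
    return case, control


def build_dmc_signature(
    betas: pd.DataFrame,
    labels: pd.Series,
    manifest: pd.DataFrame | None = None,
    p_threshold: float = 0.05,
    delta_threshold: float = 0.10,
    use_adjusted: bool = True,
    mode: str = "auto",
) -> tuple[DMCEpisignature, pd.DataFrame]:
    """Per-probe differential methylation scan and probe selection.

    Returns the signature and the full per-probe result table with columns
    ``u_statistic``, ``p``, ``adj_p``, ``delta_beta``, ``case_mean``,
    ``control_mean``, ``selected``.
    """
    case, control = _split_groups(betas, labels)
    if np.isnan(case).all(axis=1).any() or np.isnan(control).all(axis=1).any():
        raise ValueError("a probe is entirely missing within one group")

    n1, n2 = case.shape[1], control.shape[1]
    case_mean = np.nanmean(case, axis=1)
    control_mean = np.nanmean(control, axis=1)
    delta = case_mean - control_mean

    if mode == "auto" and min(n1, n2) > _EXACT_MAX_N and not np.isnan(case).any() and not np.isnan(control).any():
        res = mannwhitneyu(
            case,
            control,
            alternative="two-sided",
            method="asymptotic",
            use_continuity=True,
            axis=1,
        )
        u = np.asarray(res.statistic, dtype=float)
        p = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    else:
        u = np.empty(len(betas))
        p = np.empty(len(betas))
        for i in range(len(betas)):
            xi = case[i][~np.isnan(case[i])]
            yi = control[i][~np.isnan(control[i])]
            u[i], p[i] = mw_u_test(xi, yi, mode=mode)

    adj_p = bh_adjust(p)
    crit_p = adj_p if use_adjusted else p
    selected = (crit_p < p_threshold) & (np.abs(delta) >= delta_threshold)

    results = pd.DataFrame(
        {
            "u_statistic": u,
            "p": p,
            "adj_p": adj_p,
            "delta_beta": delta,
            "case_mean": case_mean,
            "control_mean": control_mean,
            "selected": selected,
        },
        index=betas.index.rename("probe_id"),
    )

    probes = results.loc[selected, ["delta_beta", "case_mean", "control_mean"]].copy()
    if manifest is not None:
        probes["chrom"] = manifest.loc[probes.index, "chrom"]
        probes["pos"] = manifest.loc[probes.index, "pos"]
    params = {
        "p_threshold": p_threshold,
        "delta_threshold": delta_threshold,
        "use_adjusted": use_adjusted,
        "mode": mode,
    }
    return DMCEpisignature(probes=probes, params=params), results


class DMCSelector(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: discover a DMC episignature, emit features.

    ``fit`` expects ``X`` of shape (n_samples, n_probes) — a DataFrame whose
    columns are probe ids in genomic order — and ``y`` of "case"/"control"
    labels.  ``transform`` extracts the selected probes after whole-array
    forward-carry imputation of missing values (the manifest supplies the
    genomic probe order; see :func:`episig.features.dmc_features`).
    """

    def __init__(
        self,
        manifest: pd.DataFrame | None = None,
        p_threshold: float = 0.05,
        delta_threshold: float = 0.10,
        use_adjusted: bool = True,
        mode: str = "auto",
    ):
        self.manifest = manifest
        self.p_threshold = p_threshold
        self.delta_threshold = delta_threshold
        self.use_adjusted = use_adjusted
        self.mode = mode

    def fit(self, X: pd.DataFrame, y):
        y = pd.Series(y, index=X.index) if not isinstance(y, pd.Series) else y
        self.signature_, self.results_ = build_dmc_signature(
            X.T,
            y,
            manifest=self.manifest,
            p_threshold=self.p_threshold,
            delta_threshold=self.delta_threshold,
            use_adjusted=self.use_adjusted,
            mode=self.mode,
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from .features import dmc_features

        if not hasattr(self, "signature_"):
            raise RuntimeError("DMCSelector is not fitted")
        return dmc_features(X.T, self.signature_, manifest=self.manifest)
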