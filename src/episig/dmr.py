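"""Bump-hunting DMR episignatures.

The caller follows the bumphunter recipe for a two-group design:

1. probes are grouped into clusters — maximal runs of consecutive manifest
   probes on one chromosome with inter-probe gaps <= ``max_gap``;
2. a per-probe coefficient profile is computed (mean beta in cases minus
   mean beta in controls, optionally smoothed by a running mean within
   clusters);
3. candidate regions are maximal sign-homogeneous runs of consecutive probes
   within a cluster whose coefficient magnitude reaches the cutoff; each is
   scored by its area (sum of |coefficient|);
4. the null distribution of areas comes from relabelling: sample labels are
   permuted (class sizes preserved), the coefficient profile is recomputed
   and re-scanned with the SAME cutoff and clustering, and all resulting
   null areas are pooled over B permutations;
5. each candidate gets an add-one-smoothed empirical p,
   ``p = (1 + #{null >= area}) / (1 + N_null)``, BH-adjusted across
   candidates; regions with adjusted p below the threshold and at least
   ``min_probes`` probes are retained.

The ``"auto"`` cutoff is the nearest-rank quantile (default 0.99) of the
pooled permuted |coefficients| — the analogue of letting the software pick
the cutoff.  For each retained region the training median methylation
(overall and per class) is stored so that test-time featurization can fall
back when every probe of a region is missing.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cohort import CASE, CONTROL
from .dmc import bh_adjust

__all__ = [
    "DMRParams",
    "DMREpisignature",
    "cluster_probes",
    "group_coefficients",
    "pick_cutoff",
    "candidate_runs",
    "find_candidate_regions",
    "null_region_areas",
    "assign_region_pvalues",
    "build_dmr_signature",
    "DMRSelector",
]

logger = logging.getLogger(__name__)


@dataclass
class DMRParams:
    """Tunable parameters of the DMR caller.

    Defaults mirror common bumphunter practice: 1 kb maximum gap, at least
    10 probes per retained region, 1000 permutations, adjusted p < 0.05.
    """

    max_gap: int = 1000
    min_probes: int = 10
    cutoff: float | str = "auto"
    auto_quantile: float = 0.99
    n_permutations: int = 1000
    smooth_window: int = 0
    adj_p_threshold: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if not 0 < self.auto_quantile < 1:
            raise ValueError("auto_quantile must be in (0, 1)")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.cutoff != "auto" and (not np.isreal(self.cutoff) or self.cutoff <= 0):
            raise ValueError("cutoff must be 'auto' or a positive magnitude")


def cluster_probes(manifest: pd.DataFrame, max_gap: int = 1000) -> np.ndarray:
    """Dense 1-based cluster id per probe, increasing along the genome.

    Consecutive probes share a cluster iff they lie on the same chromosome
    with a positional gap <= ``max_gap``.  The manifest must be sorted by
    (chrom, pos).
    """
    chrom = manifest["chrom"].to_numpy()
    pos = manifest["pos"].to_numpy()
    for c in pd.unique(chrom):
        p = pos[chrom == c]
        if np.any(np.diff(p) < 0):
            raise ValueError("manifest must be sorted by (chrom, pos)")
    if len(manifest) == 0:
        return np.array([], dtype=int)
    new = np.ones(len(manifest), dtype=bool)
    same_chrom = chrom[1:] == chrom[:-1]
    small_gap = (pos[1:] - pos[:-1]) <= max_gap
    new[1:] = ~(same_chrom & small_gap)
    return np.cumsum(new)


def _smooth_within_clusters(coef: np.ndarray, clusters: np.ndarray, window: int) -> np.ndarray:
    """Running mean of width ``window`` within each cluster, shrinking at edges."""
    if window <= 1:
        return coef
    out = coef.astype(float).copy()
    half = window // 2
    for cid in np.unique(clusters):
        idx = np.flatnonzero(clusters == cid)
        seg = coef[idx]
        n = len(seg)
        smoothed = np.empty(n)
        for i in range(n):
            lo, hi = max(0, i - half), min(n, i + half + 1)
            window_vals = seg[lo:hi]
            smoothed[i] = np.nanmean(window_vals) if np.any(~np.isnan(window_vals)) else np.nan
        out[idx] = smoothed
    return out


def group_coefficients(
    betas: pd.DataFrame,
    labels: pd.Series,
    clusters: np.ndarray | None = None,
    smooth_window: int = 0,
) -> np.ndarray:
    """Per-probe coefficient: mean beta in cases minus mean beta in controls.

    Computed over non-missing entries; a probe with all values missing in
    either group gets a NaN coefficient (excluded from scanning).  For a
    balanced two-group design this equals the two-group linear-model
    coefficient bumphunter fits.
    """
    labels = labels.loc[betas.columns]
    classes = set(labels.unique())
    if classes != {CASE, CONTROL}:
        raise ValueError(f"labels must contain both classes (got {sorted(classes)})")
    case = betas.loc[:, labels == CASE].to_numpy(dtype=float)
    control = betas.loc[:, labels == CONTROL].to_numpy(dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows -> NaN
        coef = np.nanmean(case, axis=1) - np.nanmean(control, axis=1)
    if smooth_window and smooth_window > 1:
        if clusters is None:
            raise ValueError("smoothing requires cluster ids")
        coef = _smooth_within_clusters(coef, clusters, smooth_window)
    return coef


def pick_cutoff(null_coefficients, auto_quantile: float = 0.99) -> float:
    """Nearest-rank quantile of |null coefficients| (the 'auto' cutoff)."""
    a = np.abs(np.asarray(null_coefficients, dtype=float))
    a = a[~np.isnan(a)]
    if a.size == 0:
        raise ValueError("null coefficient pool must be non-empty")
    if not 0 < auto_quantile < 1:
        raise ValueError("auto_quantile must be in (0, 1)")
    k = math.ceil(auto_quantile * a.size)
    return float(np.sort(a)[k - 1])


def candidate_runs(
    coefficients: np.ndarray, clusters: np.ndarray, cutoff: float
) -> list[tuple[int, int, int]]:
    """Maximal above-cutoff sign-homogeneous runs: (start, end inclusive, sign).

    This is the detection kernel: within each cluster, consecutive probes
    with coefficient >= +cutoff (sign +1) or <= -cutoff (sign -1) form a
    run; runs of mixed sign never merge.  NaN coefficients break runs.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    coef = np.asarray(coefficients, dtype=float)
    code = np.zeros(coef.size, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        code[coef >= cutoff] = 1
        code[coef <= -cutoff] = -1
    if coef.size == 0:
        return []
    cl = np.asarray(clusters)
    boundary = np.ones(coef.size, dtype=bool)
    boundary[1:] = (code[1:] != code[:-1]) | (cl[1:] != cl[:-1])
    starts = np.flatnonzero(boundary)
    ends = np.append(starts[1:], coef.size) - 1
    return [
        (int(s), int(e), int(code[s]))
        for s, e in zip(starts, ends)
        if code[s] != 0
    ]


def find_candidate_regions(
    coefficients: np.ndarray,
    clusters: np.ndarray,
    manifest: pd.DataFrame,
    cutoff: float,
) -> pd.DataFrame:
    """Candidate DMRs as a table (p-value fields unset).

    Columns: chrom, start, end (1-based inclusive), width, L, value (mean
    coefficient), area (sum of |coefficient|), start_index, end_index.
    """
    runs = candidate_runs(coefficients, clusters, cutoff)
    coef = np.asarray(coefficients, dtype=float)
    pos = manifest["pos"].to_numpy()
    chrom = manifest["chrom"].to_numpy()
    rows = []
    for s, e, sign in runs:
        seg = coef[s : e + 1]
        rows.append(
            {
                "chrom": chrom[s],
                "start": int(pos[s]),
                "end": int(pos[e]),
                "width": int(pos[e] - pos[s] + 1),
                "L": e - s + 1,
                "value": float(seg.mean()),
                "area": float(np.abs(seg).sum()),
                "start_index": s,
                "end_index": e,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "width", "L",
            "value", "area", "start_index", "end_index",
        ],
    )


def _group_weight_vector(labels: pd.Series, order: pd.Index) -> np.ndarray:
    """Contrast weights w such that betas @ w = mean(case) - mean(control)."""
    lab = labels.loc[order].to_numpy()
    w = np.where(lab == CASE, 1.0 / (lab == CASE).sum(), -1.0 / (lab == CONTROL).sum())
    return w


def permuted_coefficients(
    betas: pd.DataFrame,
    labels: pd.Series,
    n_permutations: int,
    seed: int,
    clusters: np.ndarray | None = None,
    smooth_window: int = 0,
) -> np.ndarray:
    """Coefficient profiles under label permutation, shape (n_probes, B).

    Permutation b (1-based) draws from ``default_rng(seed + b)``; class
    sizes are preserved because the label vector itself is permuted.
    """
    n_samples = betas.shape[1]
    n_distinct = math.comb(n_samples, int((labels.loc[betas.columns] == CASE).sum()))
    if n_distinct < 10:
        logger.warning(
            "only %d distinct label arrangements; permutation null is coarse",
            n_distinct,
        )
    values = betas.to_numpy(dtype=float)
    w0 = _group_weight_vector(labels, betas.columns)
    has_nan = np.isnan(values).any()
    out = np.empty((betas.shape[0], n_permutations), dtype=np.float32)
    if not has_nan and smooth_window <= 1:
        W = np.empty((n_samples, n_permutations))
        for b in range(1, n_permutations + 1):
            perm = np.random.default_rng(seed + b).permutation(n_samples)
            W[:, b - 1] = w0[perm]
        out[:] = values @ W
    else:
        lab = labels.loc[betas.columns].to_numpy()
        for b in range(1, n_permutations + 1):
            perm = np.random.default_rng(seed + b).permutation(n_samples)
            perm_labels = pd.Series(lab[perm], index=betas.columns)
            out[:, b - 1] = group_coefficients(
                betas, perm_labels, clusters=clusters, smooth_window=smooth_window
            )
    return out


def null_region_areas(
    betas: pd.DataFrame,
    labels: pd.Series,
    clusters: np.ndarray,
    cutoff: float,
    n_permutations: int,
    seed: int,
    smooth_window: int = 0,
    perm_coefs: np.ndarray | None = None,
) -> np.ndarray:
    """Pooled null areas: re-scan each permuted profile with the same cutoff."""
    if perm_coefs is None:
        perm_coefs = permuted_coefficients(
            betas, labels, n_permutations, seed,
            clusters=clusters, smooth_window=smooth_window,
        )
    areas: list[float] = []
    coef64 = perm_coefs.astype(float, copy=False)
    for b in range(perm_coefs.shape[1]):
        col = coef64[:, b]
        for s, e, _sign in candidate_runs(col, clusters, cutoff):
            areas.append(float(np.abs(col[s : e + 1]).sum()))
    return np.asarray(areas)


def assign_region_pvalues(
    candidates: pd.DataFrame, null_areas: np.ndarray
) -> pd.DataFrame:
    """Add-one-smoothed empirical p per candidate, BH-adjusted across them."""
    out = candidates.copy()
    if len(candidates) == 0:
        out["p"] = pd.Series(dtype=float)
        out["adj_p"] = pd.Series(dtype=float)
        return out
    null_areas = np.asarray(null_areas, dtype=float)
    if null_areas.size == 0:
        raise ValueError("null area pool must be non-empty")
    n = null_areas.size
    p = np.array(
        [(1 + (null_areas >= a).sum()) / (1 + n) for a in out["area"].to_numpy()]
    )
    out["p"] = p
    out["adj_p"] = bh_adjust(p)
    return out


@dataclass
class DMREpisignature:
    """Retained DMRs with training medians (overall and per class).

    ``regions`` is a DataFrame indexed by region id (``DMR_1`` ...) with the
    candidate columns plus ``p``, ``adj_p``, ``probe_ids``, ``median_all``,
    ``median_case``, ``median_control``.
    """

    regions: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def region_ids(self) -> list[str]:
        return list(self.regions.index)

    def __len__(self) -> int:
        return len(self.regions)

    def to_json(self) -> str:
        records = []
        for rid, row in self.regions.iterrows():
            rec = {"region_id": rid}
            for k, v in row.items():
                if isinstance(v, (np.floating, np.integer)):
                    v = v.item()
                elif isinstance(v, (list, tuple, np.ndarray)):
                    v = list(v)
                rec[k] = v
            records.append(rec)
        return json.dumps(
            {"paradigm": "dmr", "params": self.params, "regions": records},
            sort_keys=True,
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "DMREpisignature":
        payload = json.loads(text)
        regions = pd.DataFrame(
            payload["regions"],
            columns=["region_id", "chrom", "start", "end", "width", "L", "value",
                     "area", "p", "adj_p", "probe_ids", "median_all",
                     "median_case", "median_control", "start_index", "end_index"],
        ).set_index("region_id")
        return cls(regions=regions, params=payload["params"])

    def to_bed(self) -> str:
        """Regions in BED format (0-based half-open)."""
        lines = [
            f"{row.chrom}\t{row.start - 1}\t{row.end}\t{rid}\t{row.area:.4f}"
            for rid, row in self.regions.iterrows()
        ]
        return "\n".join(lines) + ("\n" if lines else "")


def _region_medians(
    betas: pd.DataFrame, labels: pd.Series, probe_ids: list[str]
) -> tuple[float, float, float]:
    """Training medians of per-sample region medians (overall, case, control)."""
    sub = betas.loc[probe_ids]
    per_sample = sub.median(axis=0, skipna=True)
    lab = labels.loc[betas.columns]
    return (
        float(per_sample.median()),
        float(per_sample[lab == CASE].median()),
        float(per_sample[lab == CONTROL].median()),
    )


def build_dmr_signature(
    betas: pd.DataFrame,
    labels: pd.Series,
    manifest: pd.DataFrame,
    params: DMRParams | None = None,
) -> tuple[DMREpisignature, pd.DataFrame]:
    """Full DMR chain; returns the signature and the full candidate table.

    The candidate table carries all candidates with p/adj_p and a
    ``retained`` flag; the signature holds only the retained regions
    (adjusted p below threshold AND at least ``min_probes`` probes).
    """
    params = params or DMRParams()
    params.validate()
    if not betas.index.equals(manifest.index):
        manifest = manifest.loc[betas.index]

    clusters = cluster_probes(manifest, params.max_gap)
    coef = group_coefficients(
        betas, labels, clusters=clusters, smooth_window=params.smooth_window
    )
    perm_coefs = permuted_coefficients(
        betas, labels, params.n_permutations, params.seed,
        clusters=clusters, smooth_window=params.smooth_window,
    )
    if params.cutoff == "auto":
        cutoff = pick_cutoff(perm_coefs.ravel(), params.auto_quantile)
    else:
        cutoff = float(params.cutoff)

    candidates = find_candidate_regions(coef, clusters, manifest, cutoff)
    null_areas = null_region_areas(
        betas, labels, clusters, cutoff, params.n_permutations, params.seed,
        smooth_window=params.smooth_window, perm_coefs=perm_coefs,
    )
    if len(candidates) and null_areas.size:
        candidates = assign_region_pvalues(candidates, null_areas)
    else:
        candidates["p"] = np.ones(len(candidates))
        candidates["adj_p"] = np.ones(len(candidates))

    retained_mask = (candidates["adj_p"] < params.adj_p_threshold) & (
        candidates["L"] >= params.min_probes
    )
    candidates["retained"] = retained_mask
    if not retained_mask.any():
        logger.warning("DMR signature is empty (no region passed the filters)")

    rows = []
    for _, row in candidates[retained_mask].iterrows():
        probe_ids = list(betas.index[int(row.start_index) : int(row.end_index) + 1])
        med_all, med_case, med_control = _region_medians(betas, labels, probe_ids)
        rec = row.drop(labels="retained").to_dict()
        rec.update(
            probe_ids=probe_ids,
            median_all=med_all,
            median_case=med_case,
            median_control=med_control,
        )
        rows.append(rec)
    regions = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "width", "L", "value", "area", "p",
                 "adj_p", "start_index", "end_index", "probe_ids", "median_all",
                 "median_case", "median_control"],
        index=pd.Index([f"DMR_{i + 1}" for i in range(len(rows))], name="region_id"),
    )
    sig_params = asdict(params)
    sig_params["resolved_cutoff"] = cutoff
    return DMREpisignature(regions=regions, params=sig_params), candidates


class DMRSelector(BaseEstimator, TransformerMixin):
    """sklearn-style transformer: discover a DMR episignature, emit features.

    ``fit`` expects ``X`` of shape (n_samples, n_probes) with probe-id
    columns in genomic order; ``transform`` returns per-region median
    methylation values (no imputation — medians over the probes that remain;
    training-median fallback when a region loses every probe).
    """

    def __init__(self, manifest: pd.DataFrame | None = None, params: DMRParams | None = None):
        self.manifest = manifest
        self.params = params

    def fit(self, X: pd.DataFrame, y):
        if self.manifest is None:
            raise ValueError("DMRSelector requires a manifest")
        y = pd.Series(y, index=X.index) if not isinstance(y, pd.Series) else y
        self.signature_, self.candidates_ = build_dmr_signature(
            X.T, y, self.manifest, self.params
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        from .features import dmr_features

        if not hasattr(self, "signature_"):
            raise RuntimeError("DMRSelector is not fitted")
        return dmr_features(X.T, self.signature_)
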