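"""Probe-level quality filtering and simplified normalization of beta matrices.

Filtering removes probes with a failed detection p-value, cross-reactive
probes, SNP-overlapping probes and sex-chromosome probes.  Normalization
offers ``raw`` (identity), classical across-sample ``quantile``
normalization, and ``reference_scale`` — a per-sample affine adjustment on
the logit scale matching each sample's median and MAD to the across-sample
reference.  Fuller array-specific methods (Noob, Funnorm, SWAN, BMIQ, dasen)
are accepted as externally normalized input and are not reimplemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = ["FilterReport", "filter_probes", "normalize", "NORMALIZATION_METHODS"]

NORMALIZATION_METHODS = ("raw", "quantile", "reference_scale")

_EPS = 1e-3


@dataclass
class FilterReport:
    """Per-criterion removal counts (criteria may overlap; removal is the union)."""

    n_input: int
    n_detection_fail: int
    n_cross_reactive: int
    n_snp: int
    n_sex_chrom: int
    n_removed: int
    n_retained: int

    def __post_init__(self) -> None:
        assert self.n_retained + self.n_removed == self.n_input


def filter_probes(
    betas: pd.DataFrame,
    manifest: pd.DataFrame,
    detection_p: pd.DataFrame | None = None,
    detection_threshold: float = 0.01,
    detection_policy: str = "any",
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove low-quality and confounded probes.

    A probe fails detection when its detection p-value exceeds
    ``detection_threshold`` in any sample (``detection_policy="any"``,
    the conservative default) or in all samples (``"all"``).  Cross-reactive,
    SNP-overlapping and sex-chromosome probes are removed by manifest flag.
    """
    missing = betas.index.difference(manifest.index)
    if len(missing):
        raise KeyError(f"manifest missing {len(missing)} probes present in betas")
    if detection_policy not in ("any", "all"):
        raise ValueError("detection_policy must be 'any' or 'all'")

    man = manifest.loc[betas.index]
    if detection_p is not None:
        dp = detection_p.loc[betas.index, betas.columns]
        fails = dp.to_numpy() > detection_threshold
        det_fail = fails.any(axis=1) if detection_policy == "any" else fails.all(axis=1)
    else:
        det_fail = np.zeros(len(betas), dtype=bool)

    cross = man["cross_reactive"].to_numpy(dtype=bool)
    snp = man["snp_overlap"].to_numpy(dtype=bool)
    sex = man["sex_chrom"].to_numpy(dtype=bool)
    remove = det_fail | cross | snp | sex

    report = FilterReport(
        n_input=len(betas),
        n_detection_fail=int(det_fail.sum()),
        n_cross_reactive=int(cross.sum()),
        n_snp=int(snp.sum()),
        n_sex_chrom=int(sex.sum()),
        n_removed=int(remove.sum()),
        n_retained=int((~remove).sum()),
    )
    return betas.loc[~remove], report


def _quantile_normalize(betas: pd.DataFrame) -> pd.DataFrame:
    values = betas.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("quantile normalization requires a complete matrix")
    n = values.shape[0]
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        # average ranks for ties, mapped onto the reference distribution
        ranks = pd.Series(values[:, j]).rank(method="average").to_numpy()
        out[:, j] = np.interp(ranks, np.arange(1, n + 1), reference)
    return pd.DataFrame(out, index=betas.index, columns=betas.columns)


def _reference_scale(betas: pd.DataFrame) -> pd.DataFrame:
    values = np.clip(betas.to_numpy(dtype=float), _EPS, 1 - _EPS)
    x = logit(values)
    med = np.nanmedian(x, axis=0)
    mad = np.nanmedian(np.abs(x - med), axis=0)
    mad = np.where(mad == 0, 1.0, mad)
    ref_med = med.mean()
    ref_mad = mad.mean()
    adjusted = (x - med) / mad * ref_mad + ref_med
    out = np.clip(expit(adjusted), 0.0, 1.0)
    out[np.isnan(betas.to_numpy(dtype=float))] = np.nan
    return pd.DataFrame(out, index=betas.index, columns=betas.columns)


def normalize(betas: pd.DataFrame, method: str = "quantile") -> pd.DataFrame:
    """Normalize a beta matrix; probe/sample ordering is never altered."""
    if method not in NORMALIZATION_METHODS:
        raise ValueError(
            f"unknown normalization method {method!r}; expected one of "
            f"{NORMALIZATION_METHODS}"
        )
    all_missing = betas.isna().all(axis=0)
    if all_missing.any():
        raise ValueError("normalization requires no fully-missing sample")
    if method == "raw":
        return betas.copy()
    if method == "quantile":
        return _quantile_normalize(betas)
    return _reference_scale(betas)
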