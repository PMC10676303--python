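"""Featurization: beta matrices -> classifier features under each paradigm.

Two missing-data policies, matching the two episignature paradigms:

- DMC features are the beta-values of the signature probes after
  forward-carry imputation over the WHOLE array in genomic probe order
  (a missing value takes the nearest preceding observed value within the
  sample; a missing leading run is back-filled from the first observed
  value), applied before extraction of the signature probes.
- DMR features perform no imputation: each feature is the median beta over
  the region's probes that are present and non-missing for that sample;
  a region that loses every probe falls back to its stored training median
  and a warning is logged.

Feature matrices are sample x feature DataFrames with values in [0, 1] and
no missing entries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["dmc_features", "dmr_features"]

logger = logging.getLogger(__name__)


def dmc_features(
    betas: pd.DataFrame,
    signature,
    manifest: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Signature-probe betas with whole-array forward-carry imputation.

    ``betas`` is probe x sample; the returned matrix is sample x probe in
    signature order.  When a manifest is given, the matrix is first
    re-indexed to the manifest's genomic probe order so that probes absent
    from the matrix (e.g. a newer array version) are imputed from their
    nearest preceding present neighbour; without a manifest the matrix's own
    row order is used and all signature probes must be present.
    """
    probe_ids = list(signature.probe_ids)
    if manifest is not None:
        full = betas.reindex(manifest.index)
    else:
        missing = [p for p in probe_ids if p not in betas.index]
        if missing:
            raise KeyError(
                f"{len(missing)} signature probes absent from the matrix and no "
                "manifest supplied for whole-array imputation"
            )
        full = betas
    if full.isna().all(axis=0).any():
        bad = full.columns[full.isna().all(axis=0)]
        raise ValueError(f"samples entirely missing: {list(bad)}")
    imputed = full.ffill(axis=0).bfill(axis=0)
    feats = imputed.loc[probe_ids].T
    feats.columns.name = "probe_id"
    return feats


def dmr_features(betas: pd.DataFrame, signature) -> pd.DataFrame:
    """Per-region median methylation over the probes that remain.

    ``betas`` is probe x sample; output is sample x region in signature
    order.  No imputation: each sample's feature for a region is the median
    of that region's present, non-missing probes; if none remain, the
    signature's stored overall training median is substituted and a warning
    is logged.
    """
    present = set(betas.index)
    values = np.empty((betas.shape[1], len(signature.regions)))
    for j, (rid, row) in enumerate(signature.regions.iterrows()):
        probes = [p for p in row["probe_ids"] if p in present]
        if probes:
            sub = betas.loc[probes]
            med = sub.median(axis=0, skipna=True).to_numpy()
            fallback = np.isnan(med)
            if fallback.any():
                logger.warning(
                    "region %s: %d samples with no remaining probe values; "
                    "using training median",
                    rid,
                    int(fallback.sum()),
                )
                med = np.where(fallback, row["median_all"], med)
        else:
            logger.warning(
                "region %s: all probes missing from the matrix; using training median",
                rid,
            )
            med = np.full(betas.shape[1], row["median_all"])
        values[:, j] = med
    return pd.DataFrame(
        values,
        index=betas.columns,
        columns=pd.Index(signature.region_ids, name="region_id"),
    )
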