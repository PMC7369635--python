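"""Regions×genes expression matrix construction.

Starts from a probes×samples matrix with a probe→gene map and a
sample→(donor, region) assignment: probes are collapsed to one per gene
(highest mean expression across samples), samples are averaged within donor
and region and then across donors (so donors with more samples do not
dominate a region), and genes are z-scored across regions.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from srmtx.exceptions import DegenerateInputError, EstimationError

log = logging.getLogger(__name__)


def collapse_probes(probes: pd.DataFrame) -> pd.DataFrame:
    """Collapse a probes×samples matrix to one probe per gene.

    ``probes`` must carry ``probe_id`` and ``gene`` columns followed by
    sample columns.  For each gene the probe with the highest mean
    expression across all samples is retained; exact ties go to the
    lexicographically smallest probe id.  Probes with no gene mapping are
    dropped (counted in the log).

    Returns a genes×samples DataFrame indexed by gene.
    """
    if "probe_id" not in probes.columns or "gene" not in probes.columns:
        raise ValueError("probe matrix needs 'probe_id' and 'gene' columns")
    sample_cols = [c for c in probes.columns if c not in ("probe_id", "gene")]
    if not sample_cols:
        raise ValueError("probe matrix has no sample columns")
    unmapped = probes["gene"].isna() | (probes["gene"].astype(str).str.len() == 0)
    if unmapped.any():
        log.info("dropping %d probes with no gene mapping", int(unmapped.sum()))
    kept = probes.loc[~unmapped].copy()
    kept["_mean"] = kept[sample_cols].mean(axis=1)
    kept = kept.sort_values(["gene", "_mean", "probe_id"],
                            ascending=[True, False, True])
    best = kept.drop_duplicates("gene", keep="first")
    out = best.set_index("gene")[sample_cols]
    out.index.name = "gene"
    return out.sort_index()


def aggregate_to_regions(
    gene_by_sample: pd.DataFrame,
    samples: pd.DataFrame,
    regions: list[str],
) -> pd.DataFrame:
    """Average samples to regions: within donor first, then across donors.

    ``samples`` maps ``sample_id`` to ``donor`` and ``region``; samples
    assigned to no region (NaN) are dropped.  A region of the target
    parcellation with no sample in any donor is a hard error.

    Returns a regions×genes DataFrame in parcellation row order.
    """
    samples = samples.copy()
    no_region = samples["region"].isna()
    if no_region.any():
        log.info("dropping %d samples with no region assignment",
                 int(no_region.sum()))
        samples = samples.loc[~no_region]
    missing = sorted(set(regions) - set(samples["region"]))
    if missing:
        raise EstimationError(
            f"regions with zero samples across all donors: {missing}"
        )
    values = gene_by_sample.T  # samples × genes
    values = values.join(samples.set_index("sample_id")[["donor", "region"]],
                         how="inner")
    donor_means = values.groupby(["region", "donor"], sort=True).mean()
    region_means = donor_means.groupby("region", sort=True).mean()
    out = region_means.loc[regions]
    out.index.name = "region"
    return out


def normalize_expression(expression: pd.DataFrame) -> pd.DataFrame:
    """Z-score each gene across regions; zero-variance genes are dropped."""
    values = expression.to_numpy(dtype=float)
    sd = values.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.all():
        raise DegenerateInputError("all genes are constant across regions")
    if constant.any():
        dropped = expression.columns[constant].tolist()
        log.info("dropping %d zero-variance genes: %s", len(dropped), dropped[:10])
    kept = expression.loc[:, ~constant]
    v = kept.to_numpy(dtype=float)
    z = (v - v.mean(axis=0)) / v.std(axis=0, ddof=0)
    return pd.DataFrame(z, index=kept.index, columns=kept.columns)
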