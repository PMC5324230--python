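"""RAND-36 dimension reduction and region-level methylation regression.

The eight RAND-36 category scores are reduced by PCA on z-scored
categories; PC1 serves as the overall quality-of-life score, sign-
oriented so that a higher score means better health (positive loading on
General Health).  Differentially methylated regions are groups of probes
sharing a (gene, genic region) annotation with at least two member sites
each showing |mean beta-difference| >= 0.05; region methylation per
sample is the mean of member-probe betas, and each region is regressed
on PC1 by ordinary least squares with BH-FDR across regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    BetaMatrix,
    ProbeAnnotation,
    RAND36_CATEGORIES,
    SampleSheet,
    ValidationError,
)
from .diffmeth import bh_fdr


@dataclass
class PCAResult:
    loadings: pd.DataFrame          # categories x components
    scores: pd.DataFrame            # samples x components
    variance_explained: np.ndarray  # fractions, non-increasing, sums to 1


def rand36_pca(samples: SampleSheet) -> PCAResult:
    """PCA of the eight RAND-36 categories on the correlation scale.

    Each category is centered and unit-scaled over all samples; a
    zero-variance category is an error.  PC1 is oriented so that its
    loading on General Health is positive.
    """
    x = samples.rand36()
    sd = x.std(axis=0, ddof=1)
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise ValidationError(f"zero-variance RAND-36 categories: {dead}")
    z = (x - x.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
    var = s ** 2
    var_frac = var / var.sum()
    comps = [f"PC{i + 1}" for i in range(len(s))]
    loadings = pd.DataFrame(vt.T, index=list(RAND36_CATEGORIES),
                            columns=comps)
    scores = pd.DataFrame(u * s, index=x.index, columns=comps)
    # deterministic orientation: General Health loads positively on PC1,
    # remaining components oriented by their largest-magnitude loading
    for j, c in enumerate(comps):
        if c == "PC1":
            flip = loadings.loc["general_health", c] < 0
        else:
            flip = loadings[c].iloc[np.argmax(np.abs(loadings[c]))] < 0
        if flip:
            loadings[c] = -loadings[c]
            scores[c] = -scores[c]
    return PCAResult(loadings=loadings, scores=scores,
                     variance_explained=var_frac)


@dataclass
class RegionSet:
    """Gene-annotation regions with per-sample methylation."""

    table: pd.DataFrame             # indexed by region id
    methylation: pd.DataFrame       # region x sample mean beta
    members: dict                   # region id -> list of probe ids


def define_regions(dms: pd.DataFrame, annot: ProbeAnnotation,
                   beta: BetaMatrix, samples: SampleSheet,
                   diff_min: float = 0.05, min_sites: int = 2) -> RegionSet:
    """Group probes into (gene, genic region) regions.

    A region is emitted iff at least ``min_sites`` member probes each
    have |beta_diff| >= diff_min; only those qualifying probes are
    members.  Multi-gene probes contribute to every listed gene; a probe
    never appears twice within one region.  Region methylation per
    sample is the unweighted mean of member-probe betas.
    """
    qual = dms.index[dms["beta_diff"].abs() >= diff_min]
    genes = annot.gene_lists()
    groups: dict[tuple, list] = {}
    for probe in qual:
        if probe not in genes.index:
            continue
        region = annot.df.loc[probe, "genic_region"]
        for gene in genes.loc[probe]:
            groups.setdefault((gene, region), []).append(probe)

    case_ids = samples.group_samples("case")
    ctrl_ids = samples.group_samples("control")
    rows, meth, members = [], {}, {}
    for (gene, region), probes in sorted(groups.items()):
        probes = sorted(set(probes))
        if len(probes) < min_sites:
            continue
        rid = f"{gene}|{region}"
        vals = beta.values.loc[probes].mean(axis=0)
        meth[rid] = vals
        members[rid] = probes
        mean_case = vals[case_ids].mean()
        mean_ctrl = vals[ctrl_ids].mean()
        rows.append({"region_id": rid, "gene": gene, "genic_region": region,
                     "n_sites": len(probes),
                     "probes": ";".join(probes),
                     "mean_case": mean_case, "mean_control": mean_ctrl,
                     "beta_diff": mean_case - mean_ctrl})
    table = (pd.DataFrame(rows).set_index("region_id")
             if rows else pd.DataFrame(
                 columns=["gene", "genic_region", "n_sites", "probes",
                          "mean_case", "mean_control", "beta_diff"]))
    methylation = (pd.DataFrame(meth).T if meth
                   else pd.DataFrame(columns=beta.sample_ids))
    return RegionSet(table=table, methylation=methylation, members=members)


def region_qol_regression(regions: RegionSet, pc1: pd.Series) -> pd.DataFrame:
    """OLS of region methylation on PC1 across all samples (pooled groups).

    Adds ``slope``, ``r_squared``, ``p`` and ``q_fdr`` to the region
    table and sorts by r_squared descending.
    """
    if regions.methylation.shape[0] == 0:
        out = regions.table.copy()
        for c in ("slope", "r_squared", "p", "q_fdr"):
            out[c] = pd.Series(dtype=float)
        return out
    common = regions.methylation.columns.intersection(pc1.index)
    if len(common) < 3:
        raise ValidationError("regression requires at least 3 samples")
    x = pc1[common].to_numpy(dtype=float)
    rows = []
    for rid, vals in regions.methylation[common].iterrows():
        res = stats.linregress(x, vals.to_numpy(dtype=float))
        rows.append({"region_id": rid, "slope": res.slope,
                     "r_squared": res.rvalue ** 2, "p": res.pvalue})
    fit = pd.DataFrame(rows).set_index("region_id")
    fit["q_fdr"] = bh_fdr(fit["p"].to_numpy())
    out = regions.table.join(fit)
    return out.sort_values("r_squared", ascending=False)
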