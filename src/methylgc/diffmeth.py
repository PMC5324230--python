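"""Per-probe two-group differential methylation calling.

A probe is a differentially methylated site (DMS) when all of:
|mean beta-difference| >= 0.05, two-sided Wilcoxon rank-sum p <= 0.05,
and Benjamini-Hochberg q <= 0.05 (the q gate is dropped for the
assay-subgroup comparisons, which use the first two criteria only).
Direction is hyper when mean(group1) - mean(group2) > 0.

Context enrichment compares the hyper/hypo split of significant probes
across genomic-context categories (genic region, CpG-island relation)
with Pearson chi-squared tests, pairwise against a reference category
with BH adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import BetaMatrix, ProbeAnnotation, ValidationError

logger = logging.getLogger("methylgc")

EXACT_MAX_N = 12


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration when n1 + n2 <= 12 with no ties across the pooled
    sample; otherwise the normal approximation with midrank tie
    correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == pooled.size
    if x.size + y.size <= EXACT_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(min(res.pvalue, 1.0))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (order-preserving)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0,1]")
    return multipletests(p, method="fdr_bh")[1]


def dm_table(beta: BetaMatrix, group1_ids, group2_ids) -> pd.DataFrame:
    """Per-probe group means, beta-difference and Wilcoxon p + BH q.

    ``beta_diff = mean(group1) - mean(group2)``; by convention group1 is
    the case (or hypersensitive) stratum so positive = hypermethylated.
    """
    g1 = beta.values[list(group1_ids)].to_numpy(dtype=float)
    g2 = beta.values[list(group2_ids)].to_numpy(dtype=float)
    if g1.shape[1] == 0 or g2.shape[1] == 0:
        raise ValidationError("both groups must be non-empty")
    mean1 = g1.mean(axis=1)
    mean2 = g2.mean(axis=1)
    if g1.shape[1] + g2.shape[1] <= EXACT_MAX_N:
        p = np.array([wilcoxon_rank_sum(a, b) for a, b in zip(g1, g2)])
    else:
        res = stats.mannwhitneyu(g1, g2, alternative="two-sided",
                                 method="asymptotic", use_continuity=True,
                                 axis=1)
        p = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    out = pd.DataFrame({
        "mean_beta_g1": mean1,
        "mean_beta_g2": mean2,
        "beta_diff": mean1 - mean2,
        "p_wilcoxon": p,
        "q_bh": bh_fdr(p),
    }, index=beta.probe_ids)
    out["direction"] = np.where(out["beta_diff"] > 0, "hyper", "hypo")
    return out


def call_dms(records: pd.DataFrame, diff_min: float = 0.05,
             p_max: float = 0.05, q_max: float = 0.05,
             require_q: bool = True) -> pd.DataFrame:
    """Flag significant DMS by the three-part (or two-part) criteria."""
    sig = ((records["beta_diff"].abs() >= diff_min)
           & (records["p_wilcoxon"] <= p_max))
    if require_q:
        sig &= records["q_bh"] <= q_max
    out = records.copy()
    out["significant"] = sig
    return out


@dataclass
class ContextEnrichment:
    axis: str
    counts: pd.DataFrame        # category x {hyper, hypo}
    chi2: float
    p_global: float
    pairwise: pd.DataFrame      # category vs reference 2x2 chi-squared + q


def pearson_chi2(table) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on a contingency table."""
    chi2, p, _, _ = stats.chi2_contingency(np.asarray(table), correction=False)
    return float(chi2), float(p)


def context_enrichment(records: pd.DataFrame, annot: ProbeAnnotation,
                       axis: str = "island_relation",
                       reference: str = "Island",
                       extra_contrasts: tuple = (("S_Shelf", "S_Shore"),),
                       ) -> ContextEnrichment:
    """Hyper/hypo proportion differences across genomic-context categories.

    Only significant probes participate.  Categories with no significant
    probes are excluded with a warning.  Pairwise tests compare each
    category's hyper/hypo split against the reference, BH-adjusted
    across the pairwise set (including any extra contrasts).
    """
    sig = records[records["significant"]]
    cats = annot.df.loc[sig.index.intersection(annot.df.index), axis]
    tab = (pd.crosstab(cats, sig.loc[cats.index, "direction"])
           .reindex(columns=["hyper", "hypo"], fill_value=0))
    empty = tab.index[tab.sum(axis=1) == 0].tolist()
    if empty:
        logger.warning("context categories with no significant probes "
                       "excluded: %s", empty)
        tab = tab.drop(index=empty)
    if reference not in tab.index:
        raise ValidationError(f"reference category {reference!r} has no "
                              "significant probes")
    chi2, p_global = pearson_chi2(tab.to_numpy())

    pairs = [(c, reference) for c in tab.index if c != reference]
    pairs += [pc for pc in extra_contrasts
              if pc[0] in tab.index and pc[1] in tab.index
              and (pc[0], pc[1]) not in pairs and axis == "island_relation"]
    rows = []
    for a, b in pairs:
        sub = tab.loc[[a, b]].to_numpy()
        if (sub.sum(axis=0) == 0).any():
            c2, pv = np.nan, 1.0
        else:
            c2, pv = pearson_chi2(sub)
        rows.append({"category": a, "versus": b, "chi2": c2, "p": pv})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        pairwise["q"] = bh_fdr(pairwise["p"].to_numpy())
    return ContextEnrichment(axis=axis, counts=tab, chi2=chi2,
                             p_global=p_global, pairwise=pairwise)
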