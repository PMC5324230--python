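"""Glucocorticoid-sensitivity analytics.

From triplicate optical densities of the dexamethasone suppression assay
(control / PHA-stimulated / PHA + dexamethasone) the per-subject
sensitivity statistic is

    inhibition% = (stimulated - suppressed) / stimulated * 100

computed on condition means over replicate wells.  Cases are stratified
into a GC-Hypersensitive and a GC-Typical subgroup by a two-component
Gaussian mixture on inhibition% (the higher-mean component is
hypersensitive), with a fixed-threshold mode for reproducing hand-drawn
splits.  A three-comparison Venn over DMS sets (hypersensitive vs
typical, hypersensitive vs control, typical vs control) defines the
GC-sensitivity-associated loci.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .datatypes import BetaMatrix, SampleSheet, ValidationError

logger = logging.getLogger("methylgc")

CONDITIONS = ("control", "stimulated", "suppressed")


def inhibition_percent(stimulated: float, suppressed: float) -> float:
    """(stimulated - suppressed) / stimulated * 100; requires stimulated > 0.

    May be negative when proliferation under dexamethasone exceeds the
    stimulated condition.
    """
    if stimulated <= 0:
        raise ValidationError(
            f"stimulated OD must be positive, got {stimulated!r}"
        )
    return (stimulated - suppressed) / stimulated * 100.0


def compute_inhibition(assay: pd.DataFrame, cv_warn: float = 0.2
                       ) -> pd.DataFrame:
    """Condition means and inhibition% per subject from the plate table.

    Replicate wells are averaged arithmetically; a triplicate whose
    coefficient of variation exceeds ``cv_warn`` is logged.
    """
    out = {}
    for cond in CONDITIONS:
        cols = [f"{cond}_od_{i}" for i in (1, 2, 3)]
        vals = assay[cols].to_numpy(dtype=float)
        mean = vals.mean(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean > 0, vals.std(axis=1, ddof=1) / mean, np.inf)
        for sid, c in zip(assay.index, cv):
            if c > cv_warn:
                logger.warning("high replicate CV (%.2f) for %s/%s",
                               c, sid, cond)
        out[f"mean_{cond}_od"] = mean
    res = pd.DataFrame(out, index=assay.index)
    res["inhibition_pct"] = [
        inhibition_percent(s, u)
        for s, u in zip(res["mean_stimulated_od"], res["mean_suppressed_od"])
    ]
    return res


@dataclass
class SubgroupModel:
    """Two-way stratification of cases by inhibition%."""

    method: str                       # "mixture_em" or "fixed_threshold"
    assignments: pd.Series            # sample_id -> hypersensitive/typical
    means: tuple = ()
    sds: tuple = ()
    weights: tuple = ()
    threshold: float | None = None
    seed: int = 0
    fallback: bool = False


def assign_subgroups(inhibition: pd.Series, method: str = "mixture_em",
                     threshold: float | None = None, seed: int = 0
                     ) -> SubgroupModel:
    """Stratify case subjects into GC-Hypersensitive vs GC-Typical.

    ``mixture_em`` fits a two-component univariate Gaussian mixture (EM,
    10 random restarts, log-likelihood tolerance 1e-8) and assigns each
    subject to its maximum-posterior component; the component with the
    higher mean inhibition is hypersensitive, and posterior ties break
    toward typical.  If a fitted component captures fewer than 2
    subjects' worth of weight the fit is degenerate and the method falls
    back to a fixed threshold at the midpoint between the two most
    separated observed cluster means (all-typical when the values carry
    no spread).
    """
    x = inhibition.to_numpy(dtype=float)
    n = x.size
    if method == "fixed_threshold":
        if threshold is None:
            raise ValidationError("fixed_threshold mode requires a threshold")
        lab = np.where(x > threshold, "hypersensitive", "typical")
        return SubgroupModel("fixed_threshold",
                             pd.Series(lab, index=inhibition.index),
                             threshold=threshold, seed=seed)
    if method != "mixture_em":
        raise ValidationError(f"unknown subgroup method {method!r}")
    if n < 4:
        raise ValidationError("mixture stratification requires >= 4 subjects")

    if np.ptp(x) == 0.0:
        logger.warning("degenerate inhibition values; assigning all typical")
        lab = pd.Series("typical", index=inhibition.index)
        return SubgroupModel("fixed_threshold", lab, threshold=float(x[0]),
                             seed=seed, fallback=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm = GaussianMixture(n_components=2, n_init=10, tol=1e-8,
                             max_iter=1000, random_state=seed)
        gm.fit(x[:, None])
    means = gm.means_.ravel()
    order = np.argsort(means)          # [typical, hypersensitive]
    if gm.weights_.min() < 2.0 / n:
        # degenerate fit: midpoint between the two most separated
        # observed cluster means (here the fitted component means)
        thr = float(means.mean())
        logger.warning("degenerate mixture fit; falling back to fixed "
                       "threshold %.2f", thr)
        lab = np.where(x > thr, "hypersensitive", "typical")
        return SubgroupModel("fixed_threshold",
                             pd.Series(lab, index=inhibition.index),
                             threshold=thr, seed=seed, fallback=True)
    post = gm.predict_proba(x[:, None])
    hyper_comp = order[1]
    # ties (posterior exactly 0.5) break toward typical
    lab = np.where(post[:, hyper_comp] > 0.5, "hypersensitive", "typical")
    sds = np.sqrt(gm.covariances_.ravel())
    return SubgroupModel(
        "mixture_em", pd.Series(lab, index=inhibition.index),
        means=tuple(means[order]), sds=tuple(sds[order]),
        weights=tuple(gm.weights_[order]), seed=seed,
    )


def _welch(a: np.ndarray, b: np.ndarray):
    if a.size < 2 or b.size < 2:
        return np.nan, np.nan, "group too small"
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0, ""
        return np.nan, np.nan, "constant inhibition in both groups"
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p), ""


def group_tests(inhibition: pd.Series, samples: SampleSheet,
                subgroups: SubgroupModel) -> dict:
    """Between-group inhibition tests and covariate associations.

    Returns dict with ``ttests`` (Welch two-tailed, four comparisons),
    ``logistic`` (subgroup ~ sudden-onset indicator) and ``correlations``
    (Pearson r of inhibition% vs each RAND-36 category and PC1).
    """
    df = samples.df.loc[inhibition.index]
    group = df["group"]
    sub = subgroups.assignments.reindex(inhibition.index)
    strata = {
        "case": inhibition[group == "case"].to_numpy(),
        "control": inhibition[group == "control"].to_numpy(),
        "hypersensitive": inhibition[sub == "hypersensitive"].to_numpy(),
        "typical": inhibition[sub == "typical"].to_numpy(),
    }
    comparisons = [("case", "control"), ("hypersensitive", "control"),
                   ("typical", "control"), ("hypersensitive", "typical")]
    rows = []
    for a, b in comparisons:
        t, p, reason = _welch(strata[a], strata[b])
        rows.append({"group1": a, "group2": b, "n1": len(strata[a]),
                     "n2": len(strata[b]), "t": t, "p": p, "note": reason})
    ttests = pd.DataFrame(rows)

    # logistic regression of subgroup membership on onset type (cases only)
    cases = df[group == "case"]
    y = (sub.loc[cases.index] == "hypersensitive").astype(float)
    onset = (cases["onset"] == "sudden").astype(float)
    logistic = pd.DataFrame(
        [{"term": "onset_sudden", "coef": np.nan, "p": np.nan}]
    )
    if y.nunique() == 2 and onset.nunique() == 2:
        import statsmodels.api as sm
        try:
            fit = sm.Logit(y, sm.add_constant(onset)).fit(disp=0)
            logistic = pd.DataFrame([{
                "term": "onset_sudden",
                "coef": float(fit.params.iloc[1]),
                "p": float(fit.pvalues.iloc[1]),
            }])
        except Exception as exc:       # separation etc.
            logger.warning("logistic regression failed: %s", exc)

    from .qol import rand36_pca
    from .datatypes import RAND36_CATEGORIES
    pca = rand36_pca(samples)
    pc1 = pca.scores["PC1"].reindex(inhibition.index)
    rows = []
    for cat in list(RAND36_CATEGORIES) + ["pc1"]:
        v = (pc1 if cat == "pc1"
             else df[cat].astype(float)).to_numpy()
        r, p = stats.pearsonr(inhibition.to_numpy(), v)
        rows.append({"variable": cat, "pearson_r": float(r), "p": float(p)})
    correlations = pd.DataFrame(rows)
    return {"ttests": ttests, "logistic": logistic,
            "correlations": correlations}


@dataclass
class VennPartition:
    """Three-comparison set logic over significant DMS sets.

    Comparison order: HvT (hypersensitive vs typical), HvC
    (hypersensitive vs control), TvC (typical vs control).
    """

    s_hvt: frozenset
    s_hvc: frozenset
    s_tvc: frozenset
    region_counts: dict = field(default_factory=dict)
    gc_sensitivity_loci: frozenset = frozenset()
    gc_sensitivity_loci_inclusive: frozenset = frozenset()
    triple_overlap: frozenset = frozenset()
    mecfs_associated: frozenset = frozenset()
    typical_unique: frozenset = frozenset()


def significant_set(records: pd.DataFrame, alpha: float = 0.05,
                    diff_min: float = 0.05,
                    require_perm: bool = True) -> frozenset:
    """Probes with |diff| >= diff_min, nominal p <= alpha and (optionally)
    permutation p <= alpha."""
    mask = ((records["beta_diff"].abs() >= diff_min)
            & (records["p_wilcoxon"] <= alpha))
    if require_perm:
        if "perm_p" not in records.columns:
            raise ValidationError("records lack perm_p column")
        mask &= records["perm_p"] <= alpha
    return frozenset(records.index[mask])


def three_way_overlap(dms_hvt: pd.DataFrame, dms_hvc: pd.DataFrame,
                      dms_tvc: pd.DataFrame, alpha: float = 0.05,
                      diff_min: float = 0.05) -> VennPartition:
    """Venn partition of the three comparison DMS sets and derived loci.

    GC-sensitivity loci are sites significant in both hypersensitive
    comparisons but not typical-vs-control (the inclusive variant keeps
    the triple overlap); ME/CFS-associated loci are significant in both
    vs-control comparisons but not hypersensitive-vs-typical.
    """
    if not (dms_hvt.index.equals(dms_hvc.index)
            and dms_hvc.index.equals(dms_tvc.index)):
        raise ValidationError("comparisons cover different probe universes")
    s_hvt = significant_set(dms_hvt, alpha, diff_min)
    s_hvc = significant_set(dms_hvc, alpha, diff_min)
    s_tvc = significant_set(dms_tvc, alpha, diff_min)
    regions = {
        "hvt_only": s_hvt - s_hvc - s_tvc,
        "hvc_only": s_hvc - s_hvt - s_tvc,
        "tvc_only": s_tvc - s_hvt - s_hvc,
        "hvt_hvc": (s_hvt & s_hvc) - s_tvc,
        "hvt_tvc": (s_hvt & s_tvc) - s_hvc,
        "hvc_tvc": (s_hvc & s_tvc) - s_hvt,
        "all_three": s_hvt & s_hvc & s_tvc,
    }
    return VennPartition(
        s_hvt=s_hvt, s_hvc=s_hvc, s_tvc=s_tvc,
        region_counts={k: len(v) for k, v in regions.items()},
        gc_sensitivity_loci=frozenset(regions["hvt_hvc"]),
        gc_sensitivity_loci_inclusive=frozenset(s_hvt & s_hvc),
        triple_overlap=frozenset(regions["all_three"]),
        mecfs_associated=frozenset(regions["hvc_tvc"]),
        typical_unique=frozenset(regions["tvc_only"]),
    )


def magnitude_vs_pooled_reference(beta: BetaMatrix,
                                  hyper_ids, typical_ids, control_ids,
                                  probe: str) -> float:
    """Hypersensitive-stratum mean beta minus the unweighted average of
    the typical and control stratum means, in percentage points."""
    for name, ids in (("hypersensitive", hyper_ids),
                      ("typical", typical_ids), ("control", control_ids)):
        if len(list(ids)) == 0:
            raise ValidationError(f"empty stratum: {name}")
    if probe not in beta.probe_ids:
        raise ValidationError(f"probe {probe!r} not in matrix")
    row = beta.values.loc[probe]
    m_h = row[list(hyper_ids)].mean()
    m_t = row[list(typical_ids)].mean()
    m_c = row[list(control_ids)].mean()
    return float((m_h - (m_t + m_c) / 2.0) * 100.0)
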