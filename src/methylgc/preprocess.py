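"""Probe QC filtering and empirical-Bayes batch/covariate adjustment.

Probes are excluded by a sequential cascade (each probe is counted under
the first rule that removes it):

1. detection failure — detection p-value above ``detection_alpha`` in
   more than ``max_fail_fraction`` of samples (default: any sample);
2. SNP contamination — annotation ``snp_flag``;
3. invariance — cross-sample mean beta >= 0.95 or <= 0.05 (inclusive).

Batch adjustment is the parametric empirical-Bayes location/scale model
(ComBat): per probe, beta-values are standardized against a linear model
containing intercept, group, age, BMI and cell proportions; per-batch
additive and multiplicative effects are shrunk toward across-probe
normal / inverse-gamma priors estimated by method of moments, removed,
and the covariate fit restored.  Adjustment operates directly on the
beta scale, with output clipped into [eps, 1 - eps].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import BetaMatrix, ProbeAnnotation, SampleSheet, ValidationError

EPS = 1e-6


@dataclass
class FilterReport:
    """Sequential accounting of the probe-exclusion cascade."""

    n_input_probes: int
    removed_detection: list = field(default_factory=list)
    removed_snp: list = field(default_factory=list)
    removed_invariant: list = field(default_factory=list)
    removed_missing: list = field(default_factory=list)

    @property
    def n_removed_detection(self) -> int:
        return len(self.removed_detection)

    @property
    def n_removed_snp(self) -> int:
        return len(self.removed_snp)

    @property
    def n_removed_invariant(self) -> int:
        return len(self.removed_invariant)

    @property
    def n_removed_missing(self) -> int:
        return len(self.removed_missing)

    @property
    def n_retained(self) -> int:
        return (self.n_input_probes - self.n_removed_detection
                - self.n_removed_snp - self.n_removed_invariant
                - self.n_removed_missing)

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.n_input_probes),
                ("removed_detection", self.n_removed_detection),
                ("removed_snp", self.n_removed_snp),
                ("removed_invariant", self.n_removed_invariant),
                ("removed_missing", self.n_removed_missing),
                ("retained", self.n_retained)]
        return pd.DataFrame(rows, columns=["rule", "n_probes"])


def filter_probes(beta: BetaMatrix, annot: ProbeAnnotation,
                  detection_alpha: float = 0.01,
                  invariant_low: float = 0.05,
                  invariant_high: float = 0.95,
                  max_fail_fraction: float = 0.0,
                  use_detection: bool = True,
                  ) -> tuple[BetaMatrix, FilterReport]:
    """Apply the probe-exclusion cascade; returns retained matrix + report.

    A probe fails detection when its detection p-value exceeds
    ``detection_alpha`` in a fraction of samples strictly greater than
    ``max_fail_fraction`` (0.0 = failing in any sample removes it).
    Invariance bounds are inclusive.
    """
    report = FilterReport(n_input_probes=beta.shape[0])
    remaining = beta.probe_ids

    if use_detection:
        if beta.detection_p is None:
            raise ValidationError(
                "detection rule enabled but no detection matrix present"
            )
        fail_frac = (beta.detection_p.loc[remaining] > detection_alpha
                     ).mean(axis=1)
        hit = remaining[fail_frac > max_fail_fraction]
        report.removed_detection = hit.tolist()
        remaining = remaining.difference(hit, sort=False)

    snp_probes = annot.df.index[annot.df["snp_flag"]]
    hit = remaining.intersection(snp_probes, sort=False)
    report.removed_snp = hit.tolist()
    remaining = remaining.difference(hit, sort=False)

    means = beta.values.loc[remaining].mean(axis=1)
    hit = remaining[(means >= invariant_high) | (means <= invariant_low)]
    report.removed_invariant = hit.tolist()
    remaining = remaining.difference(hit, sort=False)

    # preserve original probe order
    keep = beta.probe_ids[beta.probe_ids.isin(remaining)]
    return beta.subset_probes(keep), report


def _design_matrices(samples: SampleSheet):
    """(batch one-hot, covariate matrix incl. intercept + group) as arrays."""
    df = samples.df
    batches = pd.Categorical(df["batch"])
    sizes = pd.Series(batches).value_counts()
    singles = sizes[sizes < 2]
    if len(singles):
        raise ValidationError(
            f"batch with fewer than 2 samples: {singles.index.tolist()}"
        )
    batch_design = pd.get_dummies(batches, dtype=float).to_numpy()
    cov_cols = [np.ones(len(df)),
                (df["group"] == "case").astype(float).to_numpy(),
                df["age"].astype(float).to_numpy(),
                df["bmi"].astype(float).to_numpy()]
    # cell proportions are compositional (sum ~= 1, collinear with the
    # intercept/batch block) -> drop the last type from the design
    for c in samples.cellprop_columns[:-1]:
        cov_cols.append(df[c].astype(float).to_numpy())
    mod = np.column_stack(cov_cols)
    return batch_design, mod, [str(c) for c in batches.categories]


def _it_solve(z_batch, gamma_hat, delta_hat, gamma_bar, t2, a_prior, b_prior,
              tol=1e-4):
    """Iterative EB shrinkage for one batch (vector over probes)."""
    n_b = z_batch.shape[1]
    gamma_old = gamma_hat.copy()
    delta_old = delta_hat.copy()
    change = 1.0
    while change > tol:
        gamma_new = ((n_b * t2 * gamma_hat + delta_old * gamma_bar)
                     / (n_b * t2 + delta_old))
        ssq = ((z_batch - gamma_new[:, None]) ** 2).sum(axis=1)
        delta_new = (2 * b_prior + ssq) / (n_b + 2 * a_prior - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            rg = np.abs(gamma_new - gamma_old) / np.abs(gamma_old)
            rd = np.abs(delta_new - delta_old) / np.abs(delta_old)
        change = float(max(np.nanmax(rg), np.nanmax(rd)))
        gamma_old, delta_old = gamma_new, delta_new
    return gamma_old, delta_old


def adjust_batch_covariates(beta: BetaMatrix, samples: SampleSheet,
                            eps: float = EPS) -> BetaMatrix:
    """Remove batch effects by parametric empirical Bayes, protecting
    group, age, BMI and cell-proportion covariates.

    With a single batch the input is returned unchanged (up to clipping
    into [eps, 1-eps]).
    """
    df_samples = samples.df.loc[beta.sample_ids]
    aligned = SampleSheet(df_samples.copy())
    batch_design, mod, batch_names = _design_matrices(aligned)
    n_batch = batch_design.shape[1]
    x = beta.values.to_numpy(dtype=float)
    n = x.shape[1]

    if n_batch == 1:
        out = pd.DataFrame(np.clip(x, eps, 1 - eps),
                           index=beta.probe_ids, columns=beta.sample_ids)
        return BetaMatrix(out, beta.detection_p)

    # full design: batch indicators + covariates (drop the covariate
    # intercept, which is collinear with the batch block)
    design = np.column_stack([batch_design, mod[:, 1:]])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValidationError(
            "design matrix is rank deficient (collinear covariates?)"
        )
    b_hat = np.linalg.solve(design.T @ design, design.T @ x.T)  # q x p
    batch_sizes = batch_design.sum(axis=0)
    grand_mean = (batch_sizes / n) @ b_hat[:n_batch]            # p
    resid = x - (design @ b_hat).T
    var_pooled = (resid ** 2).mean(axis=1)                       # p
    var_pooled = np.maximum(var_pooled, 1e-12)

    stand_mean = grand_mean[:, None] + (mod[:, 1:] @ b_hat[n_batch:]).T
    sd = np.sqrt(var_pooled)[:, None]
    z = (x - stand_mean) / sd

    z_adj = np.empty_like(z)
    for b in range(n_batch):
        cols = batch_design[:, b] == 1
        zb = z[:, cols]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        gamma_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        m = delta_hat.mean()
        s2 = delta_hat.var(ddof=1)
        a_prior = (2 * s2 + m ** 2) / s2
        b_prior = (m * s2 + m ** 3) / s2
        gamma_star, delta_star = _it_solve(zb, gamma_hat, delta_hat,
                                           gamma_bar, t2, a_prior, b_prior)
        z_adj[:, cols] = ((zb - gamma_star[:, None])
                          / np.sqrt(delta_star)[:, None])

    adj = z_adj * sd + stand_mean
    out = pd.DataFrame(np.clip(adj, eps, 1 - eps),
                       index=beta.probe_ids, columns=beta.sample_ids)
    return BetaMatrix(out, beta.detection_p)
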