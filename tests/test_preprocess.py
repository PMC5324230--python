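"""Probe-filter cascade semantics and empirical-Bayes batch adjustment,
cross-checked against the canonical Bioconductor implementation."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from methylgc import (
    BetaMatrix,
    ProbeAnnotation,
    SampleSheet,
    SimulationDesign,
    ValidationError,
    adjust_batch_covariates,
    filter_probes,
    simulate_beta_matrix,
)

from conftest import make_beta, make_sample_sheet


def annot_for(beta, snp=()):
    df = pd.DataFrame({
        "gene_symbols": "",
        "genic_region": "Body",
        "island_relation": "OpenSea",
        "snp_flag": [p in snp for p in beta.probe_ids],
    }, index=beta.probe_ids)
    return ProbeAnnotation(df)


class TestFilterProbes:
    def test_invariant_bounds_inclusive(self):
        beta = make_beta([[0.96, 0.96], [0.95, 0.95], [0.93, 0.94],
                          [0.05, 0.05], [0.5, 0.5]])
        kept, report = filter_probes(beta, annot_for(beta),
                                     use_detection=False)
        assert report.n_removed_invariant == 3  # 0.96, 0.95 and 0.05
        assert kept.shape[0] == 2

    def test_snp_probe_counted_once_before_invariance(self):
        # probe is both SNP-flagged and invariant: SNP rule comes first
        beta = make_beta([[0.96, 0.96], [0.5, 0.5]])
        kept, report = filter_probes(
            beta, annot_for(beta, snp={beta.probe_ids[0]}),
            use_detection=False)
        assert report.removed_snp == [beta.probe_ids[0]]
        assert report.n_removed_invariant == 0
        assert report.n_retained == 1

    def test_detection_failure_in_any_sample_removes(self):
        det = [[0.001, 0.02], [0.001, 0.001]]
        beta = make_beta([[0.5, 0.5], [0.4, 0.4]], detection=det)
        kept, report = filter_probes(beta, annot_for(beta))
        assert report.n_removed_detection == 1
        assert kept.shape[0] == 1

    def test_missing_detection_matrix_is_configuration_error(self):
        beta = make_beta([[0.5, 0.5]])
        with pytest.raises(ValidationError, match="detection"):
            filter_probes(beta, annot_for(beta), use_detection=True)

    def test_accounting_sums_to_input(self, small_study):
        kept, report = filter_probes(small_study["beta"],
                                     small_study["annot"])
        assert (report.n_retained + report.n_removed_detection
                + report.n_removed_snp + report.n_removed_invariant
                + report.n_removed_missing) == report.n_input_probes
        assert kept.shape[0] == report.n_retained

    def test_filtering_is_idempotent(self, small_study):
        kept, _ = filter_probes(small_study["beta"], small_study["annot"])
        again, report2 = filter_probes(kept, small_study["annot"])
        assert again.shape == kept.shape
        assert report2.n_retained == report2.n_input_probes


class TestBatchAdjustment:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(0)
        beta = make_beta(rng.uniform(0.2, 0.8, (30, 12)))
        sheet = make_sample_sheet(6, 6, batches=1)
        adj = adjust_batch_covariates(beta, sheet)
        np.testing.assert_allclose(adj.values.values, beta.values.values,
                                   atol=1e-6)

    def test_singleton_batch_named_in_error(self):
        beta = make_beta(np.full((5, 4), 0.5))
        sheet = make_sample_sheet(2, 2)
        sheet.df["batch"] = ["b0", "b0", "b0", "b9"]
        with pytest.raises(ValidationError, match="b9"):
            adjust_batch_covariates(beta, sheet)

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(1)
        beta = make_beta(rng.uniform(0.3, 0.7, (10, 8)))
        sheet = make_sample_sheet(4, 4)
        sheet.df["bmi"] = sheet.df["age"]  # exact collinearity
        with pytest.raises(ValidationError, match="rank"):
            adjust_batch_covariates(beta, sheet)

    def test_planted_batch_offset_removed(self):
        d = SimulationDesign(n_probes=1500, dm_fraction=0.0, gc_loci=0,
                             invariant_fraction=0.0, snp_fraction=0.0,
                             batch_shift=0.5, seed=8)
        beta, _, samples, _ = simulate_beta_matrix(d)
        adj = adjust_batch_covariates(beta, samples)
        df = samples.df
        b0 = df.index[df["batch"] == "batch0"]
        b1 = df.index[df["batch"] == "batch1"]
        gap_pre = (beta.values[b0].mean(axis=1)
                   - beta.values[b1].mean(axis=1)).mean()
        gap_post = (adj.values[b0].mean(axis=1)
                    - adj.values[b1].mean(axis=1)).mean()
        assert abs(gap_post) < 0.1 * abs(gap_pre)

    def test_group_effect_survives_adjustment(self):
        d = SimulationDesign(n_probes=1500, dm_fraction=0.05,
                             delta_low=0.12, delta_high=0.12,
                             hyper_fraction=1.0, gc_loci=0,
                             invariant_fraction=0.0, snp_fraction=0.0,
                             seed=9)
        beta, _, samples, truth = simulate_beta_matrix(d)
        adj = adjust_batch_covariates(beta, samples)
        probes = truth["dm_probes"].index
        diff = (adj.values.loc[probes, samples.group_samples("case")]
                .mean(axis=1)
                - adj.values.loc[probes, samples.group_samples("control")]
                .mean(axis=1))
        assert abs(diff.mean() - 0.12) < 0.02

    def test_shape_labels_and_range_preserved(self, small_study):
        kept, _ = filter_probes(small_study["beta"], small_study["annot"])
        adj = adjust_batch_covariates(kept, small_study["samples"])
        assert adj.shape == kept.shape
        assert list(adj.probe_ids) == list(kept.probe_ids)
        assert float(adj.values.values.min()) >= 0.0
        assert float(adj.values.values.max()) <= 1.0


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
def test_matches_bioconductor_combat(tmp_path):
    """Independent oracle: sva::ComBat on the same fixture."""
    rng = np.random.default_rng(5)
    p, n = 40, 16
    batch = np.array([0] * 8 + [1] * 8)
    x = expit(logit(rng.uniform(0.2, 0.8, p))[:, None]
              + 0.6 * (batch == 1)[None, :] + rng.normal(0, 0.3, (p, n)))
    beta = make_beta(x)
    sheet = make_sample_sheet(groups=["case", "control"] * 8, seed=5)
    sheet.df["batch"] = [f"b{b}" for b in batch]
    mine = adjust_batch_covariates(beta, sheet)

    beta.values.to_csv(tmp_path / "dat.tsv", sep="\t")
    sheet.df.to_csv(tmp_path / "pheno.tsv", sep="\t")
    cellprops = [c for c in sheet.df.columns
                 if c.startswith("cellprop_")][:-1]
    script = f"""
    suppressMessages(library(sva))
    dat <- as.matrix(read.delim("{tmp_path}/dat.tsv", row.names=1))
    ph <- read.delim("{tmp_path}/pheno.tsv", row.names=1)
    mod <- model.matrix(~ I(group=="case") + age + bmi +
                        {' + '.join(cellprops)}, data=ph)
    out <- ComBat(dat=dat, batch=factor(ph$batch), mod=mod, par.prior=TRUE)
    write.table(out, "{tmp_path}/ref.tsv", sep="\\t", quote=FALSE)
    """
    (tmp_path / "run.R").write_text(script)
    res = subprocess.run(["Rscript", str(tmp_path / "run.R")],
                         capture_output=True, text=True, timeout=300)
    if res.returncode != 0:
        pytest.skip(f"sva unavailable: {res.stderr[-200:]}")
    ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t", index_col=0)
    np.testing.assert_allclose(mine.values.values, ref.values, atol=1e-4)
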