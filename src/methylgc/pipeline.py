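"""End-to-end orchestration: preprocess -> diffmeth -> permutation ->
gc_assay -> qol -> reporting, with TSV outputs per stage and a run log.

Configuration is a flat YAML mapping; every analysis threshold appears
as a named key with the study defaults (detection alpha 0.01, invariant
bounds 0.05/0.95, beta-difference cutoff 0.05, nominal and FDR alpha
0.05, 10,000 permutations, minimum 2 sites per region).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .datatypes import ValidationError
from .diffmeth import call_dms, context_enrichment, dm_table
from .gc_assay import (
    assign_subgroups,
    compute_inhibition,
    group_tests,
    three_way_overlap,
)
from .io import (
    ensure_dir,
    read_assay_table,
    read_beta_matrix,
    read_probe_annotation,
    read_sample_sheet,
    write_beta_matrix,
    write_table,
)
from .permutation import concordance, permute_null
from .preprocess import adjust_batch_covariates, filter_probes
from .qol import define_regions, rand36_pca, region_qol_regression
from .reporting import summarize

logger = logging.getLogger("methylgc")


@dataclass
class PipelineConfig:
    """Flat pipeline configuration; defaults are the study thresholds."""

    beta_path: str | None = None
    detection_path: str | None = None
    annotation_path: str | None = None
    samples_path: str | None = None
    assay_path: str | None = None
    out_dir: str = "out"
    seed: int = 0
    detection_alpha: float = 0.01
    invariant_low: float = 0.05
    invariant_high: float = 0.95
    diff_min: float = 0.05
    p_max: float = 0.05
    q_max: float = 0.05
    n_perm: int = 10_000
    perm_alpha: float = 0.05
    min_region_sites: int = 2
    subgroup_method: str = "mixture_em"
    subgroup_threshold: float | None = None
    top_k: int = 5

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def thresholds(self) -> dict:
        keys = ("detection_alpha", "invariant_low", "invariant_high",
                "diff_min", "p_max", "q_max", "n_perm", "perm_alpha",
                "min_region_sites")
        d = asdict(self)
        return {k: d[k] for k in keys}


class StageError(RuntimeError):
    """An error in a named pipeline stage, wrapping its cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig, inputs: dict | None = None) -> dict:
    """Execute every stage in order and write outputs under ``out_dir``.

    ``inputs`` may supply in-memory objects (beta, annot, samples,
    assay) instead of paths — used by the simulate subcommand and tests.
    Outputs are a pure function of (inputs, config, seed).
    """
    out = ensure_dir(config.out_dir)
    if inputs is None:
        for key in ("beta_path", "annotation_path", "samples_path",
                    "assay_path"):
            p = getattr(config, key)
            if p is None or not Path(p).exists():
                raise ValidationError(f"config {key} missing or not found: {p}")
        inputs = {
            "beta": read_beta_matrix(config.beta_path, config.detection_path),
            "annot": read_probe_annotation(config.annotation_path),
            "samples": read_sample_sheet(config.samples_path),
            "assay": read_assay_table(config.assay_path),
        }
    beta, annot = inputs["beta"], inputs["annot"]
    samples, assay = inputs["samples"], inputs["assay"]
    results: dict = {"config": config}

    def stage(name, fn):
        logger.info("stage %s", name)
        try:
            return fn()
        except Exception as exc:
            raise StageError(name, exc) from exc

    # --- preprocess ---
    def _preprocess():
        filt, report = filter_probes(
            beta, annot, detection_alpha=config.detection_alpha,
            invariant_low=config.invariant_low,
            invariant_high=config.invariant_high,
            use_detection=beta.detection_p is not None)
        adj = adjust_batch_covariates(filt, samples)
        write_table(report.to_frame(), out / "filter_report.tsv")
        write_beta_matrix(adj, out / "beta_adjusted.tsv")
        return adj, report

    adjusted, results["filter_report"] = stage("preprocess", _preprocess)
    results["beta_adjusted"] = adjusted

    # --- case vs control differential methylation ---
    def _diffmeth():
        dms = call_dms(
            dm_table(adjusted, samples.group_samples("case"),
                     samples.group_samples("control")),
            diff_min=config.diff_min, p_max=config.p_max,
            q_max=config.q_max, require_q=True)
        write_table(dms.rename_axis("probe_id"), out / "dms.tsv",
                    index_label="probe_id")
        enr = None
        if dms["significant"].any():
            try:
                enr = context_enrichment(dms, annot, axis="island_relation")
                write_table(enr.pairwise, out / "context_enrichment.tsv")
            except ValidationError as exc:
                logger.warning("context enrichment skipped: %s", exc)
        return dms, enr

    dms, results["context"] = stage("diffmeth", _diffmeth)
    results["dms"] = dms

    # --- glucocorticoid assay ---
    def _gc_assay():
        inh = compute_inhibition(assay)
        write_table(inh.rename_axis("sample_id"), out / "inhibition.tsv",
                    index_label="sample_id")
        grp = samples.df.loc[inh.index, "group"]
        case_inh = inh.loc[grp == "case", "inhibition_pct"]
        model = assign_subgroups(case_inh, method=config.subgroup_method,
                                 threshold=config.subgroup_threshold,
                                 seed=config.seed)
        sub = pd.Series("unknown", index=samples.sample_ids, name="gc_subgroup")
        sub.loc[model.assignments.index] = model.assignments
        samples.df["gc_subgroup"] = sub
        write_table(sub.to_frame(), out / "subgroups.tsv",
                    index_label="sample_id")
        tests = group_tests(inh["inhibition_pct"], samples, model)
        write_table(tests["ttests"], out / "tests.tsv")
        return inh, model, tests

    inh, model, results["gc_tests"] = stage("gc_assay", _gc_assay)
    results["inhibition"] = inh
    results["subgroup_model"] = model

    # --- subgroup comparisons + permutation null ---
    def _permute():
        hyper = samples.subgroup_samples("hypersensitive")
        typical = samples.subgroup_samples("typical")
        if "in_assay" in samples.df.columns:
            ctrl = samples.df.index[(samples.df["group"] == "control")
                                    & samples.df["in_assay"].astype(bool)]
        else:
            ctrl = samples.group_samples("control")
        comps = {"hvt": (hyper, typical), "hvc": (hyper, ctrl),
                 "tvc": (typical, ctrl)}
        tables, conc = {}, {}
        for i, (name, (g1, g2)) in enumerate(comps.items()):
            nom = call_dms(dm_table(adjusted, g1, g2),
                           diff_min=config.diff_min, p_max=config.p_max,
                           require_q=False)
            perm = permute_null(adjusted, g1, g2, n_perm=config.n_perm,
                                seed=config.seed + 101 + i,
                                alpha=config.perm_alpha)
            merged = nom.join(perm[["n_extreme", "perm_p",
                                    "significant_perm"]])
            tables[name] = merged
            conc[name] = concordance(nom, perm, alpha=config.perm_alpha,
                                     diff_min=config.diff_min)
            write_table(merged.rename_axis("probe_id"),
                        out / f"perm_{name}.tsv", index_label="probe_id")
        venn = three_way_overlap(tables["hvt"], tables["hvc"], tables["tvc"],
                                 alpha=config.perm_alpha,
                                 diff_min=config.diff_min)
        write_table(pd.DataFrame(sorted(venn.region_counts.items()),
                                 columns=["region", "n_probes"]),
                    out / "venn.tsv")
        write_table(pd.DataFrame(
            {"probe_id": sorted(venn.gc_sensitivity_loci)}),
            out / "gc_loci.tsv")
        return tables, conc, venn

    (results["subgroup_dms"], results["concordance"],
     results["venn"]) = stage("permutation", _permute)

    # --- quality of life ---
    def _qol():
        pca = rand36_pca(samples)
        write_table(pca.scores.rename_axis("sample_id"),
                    out / "pca_scores.tsv", index_label="sample_id")
        write_table(pd.DataFrame(
            {"component": pca.scores.columns,
             "variance_fraction": pca.variance_explained}),
            out / "pca_summary.tsv")
        regions = define_regions(dms, annot, adjusted, samples,
                                 diff_min=config.diff_min,
                                 min_sites=config.min_region_sites)
        fitted = region_qol_regression(regions, pca.scores["PC1"])
        write_table(fitted.rename_axis("region_id"), out / "regions.tsv",
                    index_label="region_id")
        return pca, fitted

    results["pca"], results["regions"] = stage("qol", _qol)

    # --- reporting ---
    def _report():
        rep = summarize(dms, venn=results["venn"],
                        concordance=results["concordance"],
                        regions=results["regions"],
                        thresholds=config.thresholds(), seed=config.seed,
                        top_k=config.top_k)
        (out / "report.txt").write_text(rep.to_text())
        write_table(rep.to_frame(), out / "report.tsv")
        (out / "run_log.txt").write_text(
            f"methylgc {__version__}\nseed: {config.seed}\n"
            f"thresholds: {config.thresholds()}\n")
        return rep

    results["report"] = stage("reporting", _report)
    return results
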