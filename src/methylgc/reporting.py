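"""Run-level summary: direction fractions, Venn counts, top-loci tables.

Every number in the report is recomputed from the stage outputs passed
in — the report holds no independent state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .gc_assay import VennPartition


@dataclass
class RunReport:
    n_probes_tested: int
    n_significant: int
    hyper_pct: float | None
    hypo_pct: float | None
    top_hyper: pd.DataFrame
    top_hypo: pd.DataFrame
    venn_counts: dict = field(default_factory=dict)
    n_gc_loci: int | None = None
    concordance: dict = field(default_factory=dict)
    top_regions: pd.DataFrame | None = None
    thresholds: dict = field(default_factory=dict)
    seed: int | None = None

    def to_text(self) -> str:
        lines = [
            "methylation pipeline run report",
            "=" * 34,
            f"seed: {self.seed}",
            f"thresholds: {self.thresholds}",
            f"probes tested: {self.n_probes_tested}",
            f"significant DMS: {self.n_significant}",
        ]
        if self.hyper_pct is None:
            lines.append("direction split: NA (no significant probes)")
        else:
            lines.append(f"hypermethylated: {self.hyper_pct:.1f}%  "
                         f"hypomethylated: {self.hypo_pct:.1f}%")
        if self.venn_counts:
            lines.append(f"three-comparison venn: {self.venn_counts}")
        if self.n_gc_loci is not None:
            lines.append(f"GC-sensitivity loci: {self.n_gc_loci}")
        for name, val in self.concordance.items():
            lines.append(f"perm/nominal concordance {name}: "
                         + ("NA" if pd.isna(val) else f"{100 * val:.1f}%"))
        if len(self.top_hyper):
            lines.append("top hypermethylated sites:")
            lines.append(self.top_hyper.to_string())
        if len(self.top_hypo):
            lines.append("top hypomethylated sites:")
            lines.append(self.top_hypo.to_string())
        if self.top_regions is not None and len(self.top_regions):
            lines.append("top QoL-associated regions by R^2:")
            lines.append(self.top_regions.to_string())
        return "\n".join(lines) + "\n"

    def to_frame(self) -> pd.DataFrame:
        rows = [("n_probes_tested", self.n_probes_tested),
                ("n_significant", self.n_significant),
                ("hyper_pct", self.hyper_pct),
                ("hypo_pct", self.hypo_pct),
                ("n_gc_loci", self.n_gc_loci),
                ("seed", self.seed)]
        rows += [(f"venn_{k}", v) for k, v in self.venn_counts.items()]
        rows += [(f"concordance_{k}", v) for k, v in self.concordance.items()]
        return pd.DataFrame(rows, columns=["metric", "value"])


def _top_k(dms: pd.DataFrame, direction: str, k: int) -> pd.DataFrame:
    sig = dms[dms["significant"] & (dms["direction"] == direction)].copy()
    sig["abs_diff"] = sig["beta_diff"].abs()
    # ties in |beta_diff| break by probe id (stable sort over sorted index)
    sig = sig.sort_index().sort_values("abs_diff", ascending=False,
                                       kind="mergesort")
    cols = ["mean_beta_g1", "mean_beta_g2", "beta_diff", "p_wilcoxon", "q_bh"]
    return sig.head(k)[cols]


def summarize(dms: pd.DataFrame, venn: VennPartition | None = None,
              concordance: dict | None = None,
              regions: pd.DataFrame | None = None,
              thresholds: dict | None = None, seed: int | None = None,
              top_k: int = 5) -> RunReport:
    """Assemble the run report from stage outputs.

    Top-k per direction is selected by |beta_diff| with ties broken by
    probe id; direction fractions are NA when nothing is significant.
    """
    n_sig = int(dms["significant"].sum())
    if n_sig:
        n_hyper = int((dms["significant"]
                       & (dms["direction"] == "hyper")).sum())
        hyper_pct = 100.0 * n_hyper / n_sig
        hypo_pct = 100.0 - hyper_pct
    else:
        hyper_pct = hypo_pct = None
    top_regions = None
    if regions is not None and len(regions):
        cols = [c for c in ("gene", "genic_region", "beta_diff",
                            "r_squared", "q_fdr") if c in regions.columns]
        top_regions = regions.sort_values("r_squared",
                                          ascending=False).head(top_k)[cols]
    return RunReport(
        n_probes_tested=len(dms),
        n_significant=n_sig,
        hyper_pct=hyper_pct,
        hypo_pct=hypo_pct,
        top_hyper=_top_k(dms, "hyper", top_k),
        top_hypo=_top_k(dms, "hypo", top_k),
        venn_counts=dict(venn.region_counts) if venn is not None else {},
        n_gc_loci=(len(venn.gc_sensitivity_loci)
                   if venn is not None else None),
        concordance=dict(concordance or {}),
        top_regions=top_regions,
        thresholds=dict(thresholds or {}),
        seed=seed,
    )
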