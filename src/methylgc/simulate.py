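"""Synthetic 450K-style data with planted, recoverable effects.

The generator emulates the structure of a two-group methylation study with
an in-vitro glucocorticoid (GC) sensitivity assay on a subset of subjects:

* a probe x sample beta matrix built on the logit scale — per-probe
  baseline + planted group effect + additive batch offset + Gaussian
  noise, mapped back to (0, 1) by the inverse logit (no clipping
  artifacts);
* probe annotations over the 450K closed vocabularies, with SNP-flagged
  and invariant (near-0/near-1) probes for the QC filter to remove;
* a case/control sample sheet with age, BMI, cell-composition and batch
  covariates, RAND-36 quality-of-life scores whose group separation is
  parameterized by published cohort means/SEs, and onset labels;
* a dexamethasone suppression assay plate (triplicate optical densities
  per condition) whose implied inhibition% distribution is unimodal for
  controls and bimodal for cases — a GC-hypersensitive mode and a
  control-like GC-typical mode;
* truth tables listing every planted effect, sufficient to score the
  sensitivity and specificity of each downstream caller.

Default dimensions mirror the study design: 49 cases vs 25 controls on
the array, an assay subset of 33 cases and 24 controls, a 14/19
hypersensitive/typical split, and 71.6% of planted case-control effects
hypermethylated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datatypes import (
    BetaMatrix,
    ProbeAnnotation,
    RAND36_CATEGORIES,
    SampleSheet,
    ValidationError,
)

# Cohort RAND-36 category means and standard errors (cases, controls),
# in the category order of RAND36_CATEGORIES.
RAND36_CASE_MEANS = (40.6, 7.7, 55.9, 25.2, 16.9, 33.0, 71.4, 73.2)
RAND36_CASE_SES = (3.9, 3.1, 3.6, 2.3, 2.3, 3.7, 5.9, 2.4)
RAND36_CONTROL_MEANS = (95.3, 96.9, 90.0, 81.8, 71.7, 91.9, 84.5, 80.6)
RAND36_CONTROL_SES = (1.4, 2.2, 1.8, 2.4, 2.5, 2.4, 5.4, 2.6)

# Island-relation frequencies loosely matching the 450K manifest mix.
ISLAND_FREQS = {
    "Island": 0.31,
    "N_Shore": 0.13,
    "S_Shore": 0.10,
    "N_Shelf": 0.05,
    "S_Shelf": 0.04,
    "OpenSea": 0.37,
}
GENIC_FREQS = {
    "TSS1500": 0.14,
    "TSS200": 0.10,
    "5'UTR": 0.12,
    "1stExon": 0.05,
    "Body": 0.31,
    "3'UTR": 0.04,
    "intergenic": 0.24,
}

CELL_TYPES = ("cd4t", "cd8t", "bcell", "nk", "mono")
CELL_DIRICHLET = (35.0, 20.0, 10.0, 10.0, 15.0)


@dataclass
class SimulationDesign:
    """Parameters of a synthetic study.

    Fractions are of the probe set unless stated; effect sizes (deltas)
    are beta-scale group differences; ``batch_shift`` and ``noise_sd``
    are on the logit (M-value-like) scale.
    """

    n_probes: int = 5000
    n_cases: int = 49
    n_controls: int = 25
    n_assay_cases: int = 33
    n_assay_controls: int = 24
    fraction_hypersensitive: float = 14 / 33
    n_batches: int = 2
    dm_fraction: float = 0.03
    delta_low: float = 0.05
    delta_high: float = 0.17
    hyper_fraction: float = 0.716
    gc_loci: int = 13
    gc_delta: float = 0.12
    #: fraction of planted case-control effects placed as pairs of probes
    #: sharing a (gene, genic region) annotation block — differential
    #: methylation clusters at neighbouring CpGs, which is what makes
    #: region-level analysis possible
    dm_pair_fraction: float = 0.5
    invariant_fraction: float = 0.10
    snp_fraction: float = 0.05
    batch_shift: float = 0.5
    noise_sd: float = 0.15
    detection_fail_fraction: float = 0.002
    # inhibition% modes (mean, sd): controls unimodal; cases a mixture of
    # a control-like "typical" mode and an elevated "hypersensitive" mode
    inhibition_control: tuple[float, float] = (40.0, 5.0)
    inhibition_typical: tuple[float, float] = (45.0, 5.0)
    inhibition_hypersensitive: tuple[float, float] = (85.0, 3.0)
    stimulated_od: tuple[float, float] = (1.6, 0.15)
    control_od: tuple[float, float] = (0.35, 0.04)
    replicate_cv: float = 0.03
    rand36_case_means: tuple = RAND36_CASE_MEANS
    rand36_case_ses: tuple = RAND36_CASE_SES
    rand36_control_means: tuple = RAND36_CONTROL_MEANS
    rand36_control_ses: tuple = RAND36_CONTROL_SES
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dm_fraction", "hyper_fraction", "invariant_fraction",
                     "snp_fraction", "fraction_hypersensitive",
                     "detection_fail_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0,1], got {v}")
        for name in ("n_probes", "n_cases", "n_controls", "n_batches"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (-1.0 < self.delta_low < 1.0 and -1.0 < self.delta_high < 1.0):
            raise ValidationError("delta grid must lie in (-1, 1)")
        if self.n_assay_cases > self.n_cases:
            raise ValidationError("assay case subset exceeds n_cases")
        if self.n_assay_controls > self.n_controls:
            raise ValidationError("assay control subset exceeds n_controls")
        n_dm = round(self.dm_fraction * self.n_probes)
        n_special = (n_dm + self.gc_loci
                     + round(self.invariant_fraction * self.n_probes))
        if n_special > self.n_probes:
            raise ValidationError(
                f"design plants {n_special} special probes but has only "
                f"{self.n_probes}"
            )


def _choice_freqs(rng, vocab_freqs: dict, n: int) -> np.ndarray:
    cats = list(vocab_freqs)
    p = np.array([vocab_freqs[c] for c in cats], dtype=float)
    return rng.choice(cats, size=n, p=p / p.sum())


def simulate_rand36(design: SimulationDesign, groups,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw RAND-36 category scores per sample, truncated to [0, 100].

    ``groups`` is a Series of 'case'/'control' indexed by sample id.
    Reported SEs are converted to SDs via SD = SE * sqrt(n) with each
    group's design cohort size.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed + 2)
    groups = pd.Series(groups)
    # per-subject SDs derive from the reference cohort sizes the SEs were
    # reported with, not from however many subjects are being drawn
    n_case = design.n_cases
    n_ctrl = design.n_controls
    out = pd.DataFrame(index=groups.index, columns=list(RAND36_CATEGORIES),
                       dtype=float)
    for j, cat in enumerate(RAND36_CATEGORIES):
        case_sd = design.rand36_case_ses[j] * np.sqrt(max(n_case, 1))
        ctrl_sd = design.rand36_control_ses[j] * np.sqrt(max(n_ctrl, 1))
        mean = np.where(groups == "case", design.rand36_case_means[j],
                        design.rand36_control_means[j])
        sd = np.where(groups == "case", case_sd, ctrl_sd)
        out[cat] = np.clip(rng.normal(mean, sd), 0.0, 100.0)
    return out


def simulate_beta_matrix(design: SimulationDesign):
    """Generate (BetaMatrix, ProbeAnnotation, SampleSheet, truth tables).

    Effects are additive on the logit scale.  For a probe with baseline
    beta b0 and planted case-control difference delta, group means are
    set to logit(b0 +/- delta/2) so the beta-scale gap is delta by
    construction (up to inverse-logit smoothing of the noise).

    The truth dict carries: ``dm_probes`` (probe, signed delta),
    ``gc_probes`` (probe, signed delta for hypersensitive cases),
    ``snp_probes``, ``invariant_probes``, and ``subgroups`` (true
    assay-subgroup label per sample).
    """
    d = design
    rng = np.random.default_rng(d.seed)

    probe_ids = np.array([f"cg{i:08d}" for i in range(d.n_probes)])
    sample_ids = ([f"case{i:03d}" for i in range(d.n_cases)]
                  + [f"ctrl{i:03d}" for i in range(d.n_controls)])
    groups = np.array(["case"] * d.n_cases + ["control"] * d.n_controls)
    n_samples = len(sample_ids)

    # --- probe roles (disjoint: DM pairs, singles, invariant, GC) ---
    # genes are blocks of 4 consecutive probes sharing a genic region;
    # a fraction of planted effects lands on within-block probe pairs
    n_dm = round(d.dm_fraction * d.n_probes)
    n_pairs = round(d.dm_pair_fraction * n_dm / 2)
    n_blocks = d.n_probes // 4
    block_order = rng.permutation(n_blocks)
    pair_blocks = block_order[:n_pairs]
    pair_idx = np.concatenate([[4 * b, 4 * b + 1] for b in pair_blocks]
                              ) if n_pairs else np.empty(0, dtype=int)
    rest = rng.permutation(np.setdiff1d(np.arange(d.n_probes), pair_idx))
    n_singles = n_dm - len(pair_idx)
    n_invariant = round(d.invariant_fraction * d.n_probes)
    dm_idx = np.concatenate([pair_idx, rest[:n_singles]]).astype(int)
    invariant_idx = rest[n_singles:n_singles + n_invariant]
    gc_idx = rest[n_singles + n_invariant:
                  n_singles + n_invariant + d.gc_loci]
    # SNP flags avoid probes carrying planted effects so that effect
    # recovery is not confounded with SNP filtering
    n_snp = round(d.snp_fraction * d.n_probes)
    snp_idx = rest[n_singles + n_invariant + d.gc_loci:
                   n_singles + n_invariant + d.gc_loci + n_snp]

    # --- baselines ---
    base = rng.uniform(0.15, 0.85, size=d.n_probes)
    low_mask = rng.random(n_invariant) < 0.5
    inv_base = np.where(low_mask, rng.uniform(0.005, 0.03, n_invariant),
                        rng.uniform(0.97, 0.995, n_invariant))
    base[invariant_idx] = inv_base

    # --- planted case-control deltas (exact hyper count) ---
    deltas = rng.uniform(d.delta_low, d.delta_high, size=n_dm)
    n_hyper = round(d.hyper_fraction * n_dm)
    signs = np.full(n_dm, -1.0)
    signs[rng.permutation(n_dm)[:n_hyper]] = 1.0
    deltas *= signs
    # keep both shifted group means inside (0.02, 0.98)
    base[dm_idx] = np.clip(base[dm_idx], 0.02 + d.delta_high / 2 + 0.01,
                           0.98 - d.delta_high / 2 - 0.01)

    # --- GC-hypersensitive-specific deltas ---
    gc_deltas = np.full(d.gc_loci, d.gc_delta)
    n_gc_hyper = round(d.hyper_fraction * d.gc_loci)
    gc_signs = np.full(d.gc_loci, -1.0)
    gc_signs[rng.permutation(d.gc_loci)[:n_gc_hyper]] = 1.0
    gc_deltas *= gc_signs
    base[gc_idx] = np.clip(base[gc_idx], 0.02 + d.gc_delta + 0.01,
                           0.98 - d.gc_delta - 0.01)

    # --- subgroup truth on the assay subset ---
    assay_cases = list(range(d.n_assay_cases))
    n_hyp = round(d.fraction_hypersensitive * d.n_assay_cases)
    hyp_cases = set(rng.permutation(assay_cases)[:n_hyp].tolist())
    subgroup_truth = np.array(["unknown"] * n_samples, dtype=object)
    for i in assay_cases:
        subgroup_truth[i] = "hypersensitive" if i in hyp_cases else "typical"
    in_assay = np.zeros(n_samples, dtype=bool)
    in_assay[assay_cases] = True
    in_assay[d.n_cases:d.n_cases + d.n_assay_controls] = True
    is_hyper_sample = subgroup_truth == "hypersensitive"

    # --- per-probe per-sample logit means ---
    mu = np.tile(logit(base)[:, None], (1, n_samples))
    is_case = groups == "case"
    for k, pi in enumerate(dm_idx):
        mu[pi, is_case] = logit(base[pi] + deltas[k] / 2)
        mu[pi, ~is_case] = logit(base[pi] - deltas[k] / 2)
    for k, pi in enumerate(gc_idx):
        mu[pi, is_hyper_sample] = logit(base[pi] + gc_deltas[k])

    # --- batch assignment (balanced within group) and offsets ---
    batch = np.empty(n_samples, dtype=int)
    batch[is_case] = np.arange(is_case.sum()) % d.n_batches
    batch[~is_case] = np.arange((~is_case).sum()) % d.n_batches
    offsets = (np.arange(d.n_batches) - (d.n_batches - 1) / 2) * d.batch_shift
    mu = mu + offsets[batch][None, :]

    beta_vals = expit(mu + rng.normal(0.0, d.noise_sd, size=mu.shape))

    # --- detection p-values ---
    det = rng.uniform(0.0, 0.005, size=mu.shape)
    n_fail = round(d.detection_fail_fraction * d.n_probes)
    fail_pool = np.setdiff1d(np.arange(d.n_probes),
                             np.concatenate([dm_idx, gc_idx]))
    fail_idx = rng.permutation(fail_pool)[:n_fail]
    for pi in fail_idx:
        det[pi, rng.integers(n_samples)] = rng.uniform(0.02, 0.5)

    beta = BetaMatrix(
        pd.DataFrame(beta_vals, index=probe_ids, columns=sample_ids),
        pd.DataFrame(det, index=probe_ids, columns=sample_ids),
    )

    # --- annotation: gene blocks of 4 probes with a shared genic region ---
    genic_block = _choice_freqs(rng, GENIC_FREQS, n_blocks + 1)
    genic = np.repeat(genic_block, 4)[:d.n_probes]
    island = _choice_freqs(rng, ISLAND_FREQS, d.n_probes)
    genes = np.array([f"GENE{i // 4:05d}" for i in range(d.n_probes)])
    gene_col = np.where(genic == "intergenic", "", genes)
    # probes carrying planted pair effects must map to a gene region
    if len(pair_idx):
        hit = np.isin(np.arange(d.n_probes) // 4, pair_blocks)
        genic[hit & (genic == "intergenic")] = "Body"
        gene_col = np.where(genic == "intergenic", "", genes)
    snp_flag = np.zeros(d.n_probes, dtype=bool)
    snp_flag[snp_idx] = True
    annot = ProbeAnnotation(pd.DataFrame(
        {"gene_symbols": gene_col, "genic_region": genic,
         "island_relation": island, "snp_flag": snp_flag},
        index=probe_ids,
    ))

    # --- sample sheet ---
    age = np.where(is_case,
                   rng.normal(49.4, 1.9 * np.sqrt(d.n_cases), n_samples),
                   rng.normal(51.1, 2.7 * np.sqrt(d.n_controls), n_samples))
    bmi = np.where(is_case,
                   rng.normal(23.3, 0.5 * np.sqrt(d.n_cases), n_samples),
                   rng.normal(23.4, 0.6 * np.sqrt(d.n_controls), n_samples))
    cells = rng.dirichlet(CELL_DIRICHLET, size=n_samples)
    onset = np.where(is_case,
                     np.where(rng.random(n_samples) < 33 / 49, "sudden",
                              "gradual"),
                     "not_applicable")
    sheet_df = pd.DataFrame({
        "group": groups,
        "gc_subgroup": "unknown",
        "age": np.clip(age, 20.0, 85.0),
        "bmi": np.clip(bmi, 17.0, 29.9),
        "batch": [f"batch{b}" for b in batch],
        "onset": onset,
        "in_assay": in_assay,
    }, index=pd.Index(sample_ids, name="sample_id"))
    for j, ct in enumerate(CELL_TYPES):
        sheet_df[f"cellprop_{ct}"] = cells[:, j]
    rand = simulate_rand36(d, sheet_df["group"],
                           rng=np.random.default_rng(d.seed + 2))
    sheet_df = pd.concat([sheet_df, rand], axis=1)
    samples = SampleSheet(sheet_df, extras=["in_assay"])

    truth = {
        "dm_probes": pd.DataFrame(
            {"probe_id": probe_ids[dm_idx], "delta": deltas}
        ).set_index("probe_id"),
        "gc_probes": pd.DataFrame(
            {"probe_id": probe_ids[gc_idx], "delta": gc_deltas}
        ).set_index("probe_id"),
        "snp_probes": pd.DataFrame(index=pd.Index(probe_ids[snp_idx],
                                                  name="probe_id")),
        "invariant_probes": pd.DataFrame(
            index=pd.Index(probe_ids[invariant_idx], name="probe_id")),
        "subgroups": pd.DataFrame(
            {"gc_subgroup": subgroup_truth},
            index=pd.Index(sample_ids, name="sample_id")),
    }
    return beta, annot, samples, truth


def simulate_assay_plate(design: SimulationDesign, samples: SampleSheet,
                         truth_subgroups: pd.DataFrame | None = None,
                         rng: np.random.Generator | None = None
                         ) -> pd.DataFrame:
    """Triplicate optical densities per subject for the suppression assay.

    Each assay subject draws a target inhibition% from its mode
    (control / typical / hypersensitive); the suppressed-condition mean
    OD is set to stimulated * (1 - inhibition/100) and triplicate wells
    scatter around each condition mean with a small CV, so the implied
    inhibition distribution is unimodal for controls and bimodal for
    cases.
    """
    d = design
    if rng is None:
        rng = np.random.default_rng(d.seed + 1)
    df = samples.df
    if "in_assay" in df.columns:
        assay_ids = df.index[df["in_assay"].astype(bool)]
    else:
        assay_ids = df.index
    rows = {}
    for sid in assay_ids:
        group = df.loc[sid, "group"]
        label = "control"
        if group == "case":
            if truth_subgroups is not None:
                label = truth_subgroups.loc[sid, "gc_subgroup"]
            else:
                label = ("hypersensitive"
                         if rng.random() < d.fraction_hypersensitive
                         else "typical")
        mean, sd = {"control": d.inhibition_control,
                    "typical": d.inhibition_typical,
                    "hypersensitive": d.inhibition_hypersensitive}[label]
        inh = rng.normal(mean, sd)
        stim = max(rng.normal(*d.stimulated_od), 0.05)
        ctrl = max(rng.normal(*d.control_od), 0.01)
        supp = max(stim * (1.0 - inh / 100.0), 0.0)
        row = {}
        for cond, m in (("control", ctrl), ("stimulated", stim),
                        ("suppressed", supp)):
            reps = np.abs(rng.normal(m, d.replicate_cv * max(m, 0.05), 3))
            for i in range(3):
                row[f"{cond}_od_{i + 1}"] = reps[i]
        rows[sid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def simulate_dataset(design: SimulationDesign):
    """Full synthetic study: beta matrix, annotation, samples, assay, truth."""
    beta, annot, samples, truth = simulate_beta_matrix(design)
    assay = simulate_assay_plate(design, samples,
                                 truth_subgroups=truth["subgroups"])
    return beta, annot, samples, assay, truth
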