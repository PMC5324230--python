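"""Core data containers for the methylation pipeline.

The central object is a probe x sample matrix of beta-values (methylation
proportions in [0, 1]), optionally paired with a same-shape matrix of
detection p-values.  Probe annotations and the sample sheet travel as
validated pandas DataFrames wrapped in thin container classes that enforce
the closed vocabularies of the 450K annotation scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENIC_REGIONS = frozenset(
    {"TSS1500", "TSS200", "5'UTR", "1stExon", "Body", "3'UTR", "intergenic"}
)
ISLAND_RELATIONS = frozenset(
    {"Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea"}
)
GROUPS = frozenset({"case", "control"})
GC_SUBGROUPS = frozenset({"hypersensitive", "typical", "unknown"})
ONSET_TYPES = frozenset({"sudden", "gradual", "not_applicable"})

#: RAND-36 category order used throughout (Physical Health block then Mental
#: Health block, matching the survey's standard presentation).
RAND36_CATEGORIES = (
    "physical_functioning",
    "role_physical",
    "pain",
    "general_health",
    "energy",
    "social_functioning",
    "role_emotional",
    "emotion",
)


class ValidationError(ValueError):
    """Raised when an input table violates the data model."""


def _check_unique(index: pd.Index, what: str) -> None:
    if index.has_duplicates:
        dups = index[index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class BetaMatrix:
    """Probe x sample methylation proportions.

    Parameters
    ----------
    values
        DataFrame indexed by probe id with one column per sample; every
        cell a finite proportion in [0, 1].
    detection_p
        Optional same-shape DataFrame of per-probe per-sample detection
        p-values (probability that a probe signal is background noise).
    """

    values: pd.DataFrame
    detection_p: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite beta at probe {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}"
            )
        if arr.size and (arr.min() < 0.0 or arr.max() > 1.0):
            bad = np.argwhere((arr < 0.0) | (arr > 1.0))[0]
            raise ValidationError(
                f"beta outside [0,1] at probe {self.values.index[bad[0]]!r}, "
                f"sample {self.values.columns[bad[1]]!r}: "
                f"{arr[bad[0], bad[1]]!r}"
            )
        if self.detection_p is not None:
            d = self.detection_p
            if not (
                d.index.equals(self.values.index)
                and d.columns.equals(self.values.columns)
            ):
                raise ValidationError(
                    "detection matrix labels do not align with beta matrix"
                )
            darr = d.to_numpy(dtype=float)
            if darr.size and (
                not np.all(np.isfinite(darr))
                or darr.min() < 0.0
                or darr.max() > 1.0
            ):
                raise ValidationError("detection p-values must lie in [0,1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes) -> "BetaMatrix":
        det = (
            self.detection_p.loc[probes] if self.detection_p is not None else None
        )
        return BetaMatrix(self.values.loc[probes], det)

    def subset_samples(self, samples) -> "BetaMatrix":
        det = (
            self.detection_p[samples] if self.detection_p is not None else None
        )
        return BetaMatrix(self.values[samples], det)


@dataclass
class ProbeAnnotation:
    """Per-probe 450K-style annotation.

    ``df`` is indexed by probe id with columns ``gene_symbols`` (semicolon
    separated, may be empty), ``genic_region``, ``island_relation`` and
    boolean ``snp_flag``.
    """

    df: pd.DataFrame

    REQUIRED = ("gene_symbols", "genic_region", "island_relation", "snp_flag")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        _check_unique(self.df.index, "probe ids")
        bad_region = set(self.df["genic_region"]) - GENIC_REGIONS
        if bad_region:
            raise ValidationError(
                f"genic_region outside vocabulary {sorted(GENIC_REGIONS)}: "
                f"{sorted(bad_region)[:5]}"
            )
        bad_island = set(self.df["island_relation"]) - ISLAND_RELATIONS
        if bad_island:
            raise ValidationError(
                f"island_relation outside vocabulary "
                f"{sorted(ISLAND_RELATIONS)}: {sorted(bad_island)[:5]}"
            )
        self.df["snp_flag"] = self.df["snp_flag"].astype(bool)

    @property
    def probe_ids(self) -> pd.Index:
        return self.df.index

    def gene_lists(self) -> pd.Series:
        """Gene symbols per probe as lists (empty list for intergenic)."""
        return self.df["gene_symbols"].fillna("").map(
            lambda s: [g for g in str(s).split(";") if g and g != "NA"]
        )


@dataclass
class SampleSheet:
    """Per-sample metadata: group labels, covariates, survey scores.

    ``df`` is indexed by sample id.  Required columns: ``group``, ``age``,
    ``bmi``, ``batch``, at least one ``cellprop_*`` column, and the eight
    RAND-36 categories.  ``gc_subgroup`` and ``onset`` default to
    ``unknown`` / ``not_applicable`` when absent.
    """

    df: pd.DataFrame
    extras: list[str] = field(default_factory=list)

    REQUIRED = ("group", "age", "bmi", "batch") + RAND36_CATEGORIES

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        _check_unique(df.index, "sample ids")
        bad_group = set(df["group"]) - GROUPS
        if bad_group:
            raise ValidationError(
                f"group outside vocabulary {sorted(GROUPS)}: {sorted(bad_group)}"
            )
        if "gc_subgroup" not in df.columns:
            df["gc_subgroup"] = "unknown"
        df["gc_subgroup"] = df["gc_subgroup"].fillna("unknown")
        bad_sub = set(df["gc_subgroup"]) - GC_SUBGROUPS
        if bad_sub:
            raise ValidationError(
                f"gc_subgroup outside vocabulary {sorted(GC_SUBGROUPS)}: "
                f"{sorted(bad_sub)}"
            )
        labelled = df[df["gc_subgroup"].isin({"hypersensitive", "typical"})]
        if (labelled["group"] != "case").any():
            raise ValidationError(
                "gc_subgroup hypersensitive/typical is only valid for cases"
            )
        if "onset" not in df.columns:
            df["onset"] = "not_applicable"
        df["onset"] = df["onset"].fillna("not_applicable")
        bad_onset = set(df["onset"]) - ONSET_TYPES
        if bad_onset:
            raise ValidationError(
                f"onset outside vocabulary {sorted(ONSET_TYPES)}: "
                f"{sorted(bad_onset)}"
            )
        for col in ("age", "bmi"):
            if (df[col].astype(float) <= 0).any():
                raise ValidationError(f"{col} must be positive")
        rand = df[list(RAND36_CATEGORIES)].astype(float)
        if ((rand < 0) | (rand > 100)).any().any():
            bad = rand[((rand < 0) | (rand > 100)).any(axis=1)].index[0]
            raise ValidationError(
                f"RAND-36 score outside [0,100] for sample {bad!r}"
            )
        props = df[self.cellprop_columns].astype(float)
        if props.shape[1] == 0:
            raise ValidationError("sample sheet has no cellprop_* columns")
        # tolerance covers TSV round-trips at 6 significant digits
        if (props < 0).any().any() or (props.sum(axis=1) > 1 + 1e-4).any():
            raise ValidationError(
                "cell proportions must be non-negative and sum to <= 1"
            )

    @property
    def sample_ids(self) -> pd.Index:
        return self.df.index

    @property
    def cellprop_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("cellprop_")]

    def group_samples(self, group: str) -> pd.Index:
        return self.df.index[self.df["group"] == group]

    def subgroup_samples(self, subgroup: str) -> pd.Index:
        return self.df.index[self.df["gc_subgroup"] == subgroup]

    def rand36(self) -> pd.DataFrame:
        return self.df[list(RAND36_CATEGORIES)].astype(float)

    def counts(self) -> tuple[int, int]:
        """(n cases, n controls)."""
        return (
            int((self.df["group"] == "case").sum()),
            int((self.df["group"] == "control").sum()),
        )
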