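"""Core data containers for CT-level qPCR analysis.

The pipeline's unit conventions:

* ``ct`` -- raw cycle-threshold values in cycles; lower CT means higher
  abundance; the scale is approximately log2 of template amount.
  An undetermined reaction is stored as ``NaN`` in memory and written as
  the literal ``NA`` on disk (never silently dropped).
* ``-dCT`` (negative delta-CT) -- target expression normalised to the
  reference-gene mean, ``mean(CT of references) - CT(target)``.  Larger
  -dCT means more expressed; a +1 difference is a twofold change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, SchemaError

ASSAY_CLASSES = (
    "mrna_target",
    "mirna_target",
    "endogenous_candidate",
    "endogenous_fixed",
)

CT_COLUMNS = ["sample_id", "assay_id", "assay_class", "replicate_index", "ct"]
ANNOTATION_REQUIRED = [
    "sample_id",
    "group",
    "os_time",
    "os_event",
    "css_time",
    "css_event",
]
GROUPS = ("metastatic", "localized")


@dataclass
class CtTable:
    """Raw or replicate-aggregated cycle-threshold measurements.

    ``data`` is a long-format frame with columns ``sample_id``,
    ``assay_id``, ``assay_class``, ``replicate_index`` and ``ct``.
    After :func:`penmark.quant.aggregate_replicates` the table carries one
    row per (sample, assay) with ``replicate_index == 1`` plus the quality
    columns ``ct_sd`` and ``n_replicates``; after
    :func:`penmark.quant.apply_ct_filter` it also carries ``excluded``.
    """

    data: pd.DataFrame
    aggregated: bool = False

    def __post_init__(self) -> None:
        missing = [c for c in CT_COLUMNS if c not in self.data.columns]
        if missing:
            raise SchemaError(
                f"CT table is missing required column(s): {', '.join(missing)}",
                columns=missing,
            )
        bad_class = set(self.data["assay_class"]) - set(ASSAY_CLASSES)
        if bad_class:
            raise SchemaError(
                f"unknown assay_class value(s): {sorted(bad_class)}"
            )
        key = self.data[["sample_id", "assay_id", "replicate_index"]]
        if key.duplicated().any():
            dupes = key[key.duplicated()].head(5).to_records(index=False)
            raise SchemaError(
                f"duplicate (sample_id, assay_id, replicate_index) rows, e.g. {list(dupes)}"
            )
        ct = self.data["ct"]
        finite = ct.dropna()
        if (finite <= 0).any():
            raise SchemaError("finite CT values must be > 0 cycles")

    @property
    def samples(self) -> list[str]:
        return sorted(self.data["sample_id"].unique())

    @property
    def assays(self) -> list[str]:
        return sorted(self.data["assay_id"].unique())

    def assays_of_class(self, *classes: str) -> list[str]:
        mask = self.data["assay_class"].isin(classes)
        return sorted(self.data.loc[mask, "assay_id"].unique())

    def pivot_ct(self, include_excluded: bool = False) -> pd.DataFrame:
        """Samples x assays matrix of CT values (NaN = undetermined/excluded).

        Only meaningful on aggregated tables.
        """
        df = self.data
        if "excluded" in df.columns and not include_excluded:
            df = df.copy()
            df.loc[df["excluded"].astype(bool), "ct"] = np.nan
        wide = df.pivot_table(
            index="sample_id", columns="assay_id", values="ct", aggfunc="mean"
        )
        return wide.sort_index(axis=0).sort_index(axis=1)


@dataclass
class SampleAnnotation:
    """Per-sample group labels, clinicopathological covariates and outcomes.

    ``data`` is indexed by ``sample_id`` and carries ``group``
    (metastatic/localized), the survival columns (``os_time``, ``os_event``,
    ``css_time``, ``css_event``; times in months) and any number of
    covariate columns.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.name != "sample_id":
            if "sample_id" not in df.columns:
                raise SchemaError(
                    "annotation is missing required column(s): sample_id",
                    columns=["sample_id"],
                )
            df = df.set_index("sample_id")
        missing = [c for c in ANNOTATION_REQUIRED[1:] if c not in df.columns]
        if missing:
            raise SchemaError(
                f"annotation is missing required column(s): {', '.join(missing)}",
                columns=missing,
            )
        if df.index.duplicated().any():
            raise SchemaError("duplicate sample_id rows in annotation")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise SchemaError(f"unknown group label(s): {sorted(bad)}")
        for col in ("os_event", "css_event"):
            if not df[col].isin([0, 1]).all():
                raise SchemaError(f"{col} must be 0/1")
        for col in ("os_time", "css_time"):
            if (df[col] < 0).any():
                raise SchemaError(f"{col} must be non-negative")
        self.data = df

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def group(self) -> pd.Series:
        return self.data["group"]

    def is_metastatic(self) -> pd.Series:
        return (self.data["group"] == "metastatic").astype(int)

    @property
    def covariates(self) -> list[str]:
        skip = set(ANNOTATION_REQUIRED[1:])
        return [c for c in self.data.columns if c not in skip]


@dataclass
class ExpressionMatrix:
    """Normalised expression: samples x targets matrix of -dCT values.

    ``values`` holds -dCT (larger = more expressed, unit = log2 fold);
    missing cells are targets excluded or undetermined in that sample.
    ``normalization_refs`` records the reference assays whose CT mean was
    subtracted; they never appear among the target columns.
    """

    values: pd.DataFrame
    normalization_refs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.normalization_refs:
            raise SchemaError("normalization_refs must be non-empty")
        overlap = set(self.normalization_refs) & set(self.values.columns)
        if overlap:
            raise SchemaError(
                f"reference assay(s) also present as targets: {sorted(overlap)}"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def targets(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.values.loc[list(samples)], list(self.normalization_refs)
        )


@dataclass
class AnalysisConfig:
    """Analysis thresholds; defaults are the study's printed conventions."""

    ct_filter_threshold: float = 24.0  # strict less-than, cycles
    de_alpha: float = 0.05
    pair_screen_alpha: float = 0.10  # inclusive (<=)
    pair_auc_cutoff: float = 0.8  # strict (>)
    pair_score_mode: str = "difference"
    t_test_variant: str = "pooled"
    correlation_class_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("de_alpha", "pair_screen_alpha", "correlation_class_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0,1), got {v}")
        if not 0.5 < self.pair_auc_cutoff <= 1.0:
            raise ConfigError(
                f"pair_auc_cutoff must be in (0.5, 1], got {self.pair_auc_cutoff}"
            )
        if self.pair_score_mode not in ("difference", "quotient"):
            raise ConfigError(f"unknown pair_score_mode {self.pair_score_mode!r}")
        if self.t_test_variant not in ("pooled", "welch"):
            raise ConfigError(f"unknown t_test_variant {self.t_test_variant!r}")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"unknown analysis config key(s): {sorted(unknown)}")
        return cls(**dict(mapping))
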