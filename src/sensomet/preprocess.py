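"""Feature filtering and intensity normalization for aligned LC-MS tables.

Three filters, applied in this order, each with a strict boundary:

1. low intensity — drop features whose mean observed intensity is
   strictly below ``frac`` (default 0.1%) of the highest per-feature mean;
2. missingness — drop features with strictly more than ``max_missing``
   (default 30%) missing values;
3. early elution — drop features with retention time strictly below
   ``min_rt`` (default 0.45 min), i.e. the unretained solvent front.

Normalization then proceeds per sample (divide by injection volume, then
by the sample's median observed intensity) and per feature within batch
(divide by the feature's median across the batch's samples) to compensate
instrument sensitivity drift between measurement runs. All statistics are
computed over observed (non-missing) entries only; missing entries stay
missing throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tables import FeatureTable, SampleMetadata


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessReport:
    """Per-stage accounting of a preprocessing run.

    Each removed feature is attributed to the first filter (in run order)
    that removes it, so counts are additive:
    ``n_input = n_output + n_removed_low_intensity + n_removed_missing +
    n_removed_early_rt``.
    """

    n_input_features: int = 0
    n_removed_low_intensity: int = 0
    n_removed_missing: int = 0
    n_removed_early_rt: int = 0
    n_output_features: int = 0
    normalization_steps: list[str] = field(default_factory=list)
    removed_low_intensity: list[str] = field(default_factory=list)
    removed_missing: list[str] = field(default_factory=list)
    removed_early_rt: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_input_features": self.n_input_features,
            "n_removed_low_intensity": self.n_removed_low_intensity,
            "n_removed_missing": self.n_removed_missing,
            "n_removed_early_rt": self.n_removed_early_rt,
            "n_output_features": self.n_output_features,
            "normalization_steps": list(self.normalization_steps),
            "removed_low_intensity": list(self.removed_low_intensity),
            "removed_missing": list(self.removed_missing),
            "removed_early_rt": list(self.removed_early_rt),
        }


def _check_nonempty(table: FeatureTable, stage: str) -> None:
    if table.n_features == 0:
        raise PreprocessError(f"{stage}: all features removed (degenerate table)")


def filter_low_intensity(table: FeatureTable, frac: float = 0.001) -> FeatureTable:
    """Drop features whose mean observed intensity < frac x the maximum
    per-feature mean observed intensity (strict)."""
    _check_nonempty(table, "filter_low_intensity")
    means = table.intensities.mean(axis=1, skipna=True)
    threshold = frac * means.max()
    keep = ~(means < threshold)
    out = table.subset(table.feature_ids[keep])
    _check_nonempty(out, "filter_low_intensity")
    return out


def filter_missing(table: FeatureTable, max_missing: float = 0.30) -> FeatureTable:
    """Drop features with strictly more than ``max_missing`` missing."""
    _check_nonempty(table, "filter_missing")
    frac_missing = table.intensities.isna().mean(axis=1)
    keep = ~(frac_missing > max_missing)
    out = table.subset(table.feature_ids[keep])
    _check_nonempty(out, "filter_missing")
    return out


def filter_early_rt(table: FeatureTable, min_rt: float = 0.45) -> FeatureTable:
    """Drop features eluting strictly before ``min_rt`` minutes."""
    _check_nonempty(table, "filter_early_rt")
    keep = ~(table.rt < min_rt)
    out = table.subset(table.feature_ids[keep])
    _check_nonempty(out, "filter_early_rt")
    return out


def apply_filters(
    table: FeatureTable,
    frac: float = 0.001,
    max_missing: float = 0.30,
    min_rt: float = 0.45,
) -> tuple[FeatureTable, PreprocessReport]:
    """Run the three filters in order, attributing each removal to the
    first filter responsible."""
    report = PreprocessReport(n_input_features=table.n_features)

    after_low = filter_low_intensity(table, frac=frac)
    removed = table.feature_ids.difference(after_low.feature_ids)
    report.removed_low_intensity = sorted(map(str, removed))
    report.n_removed_low_intensity = len(removed)

    after_miss = filter_missing(after_low, max_missing=max_missing)
    removed = after_low.feature_ids.difference(after_miss.feature_ids)
    report.removed_missing = sorted(map(str, removed))
    report.n_removed_missing = len(removed)

    after_rt = filter_early_rt(after_miss, min_rt=min_rt)
    removed = after_miss.feature_ids.difference(after_rt.feature_ids)
    report.removed_early_rt = sorted(map(str, removed))
    report.n_removed_early_rt = len(removed)

    report.n_output_features = after_rt.n_features
    return after_rt, report


def normalize_samples(
    table: FeatureTable, meta: SampleMetadata
) -> FeatureTable:
    """Per-sample normalization: divide each sample by its injection
    volume, then by its median observed intensity. Afterwards every
    sample's median observed intensity is exactly 1."""
    aligned = meta.aligned_to(table)
    X = table.intensities.astype(float)
    volumes = aligned["injection_volume"].to_numpy(dtype=float)
    X = X / volumes[np.newaxis, :]
    sample_medians = X.median(axis=0, skipna=True)
    bad = sample_medians.index[~(sample_medians > 0) | sample_medians.isna()]
    if len(bad):
        raise PreprocessError(
            f"zero or undefined median intensity for sample(s): {bad.tolist()}"
        )
    return table.with_intensities(X / sample_medians)


def normalize_batches(
    table: FeatureTable, meta: SampleMetadata
) -> FeatureTable:
    """Within-batch per-feature median normalization, compensating
    instrument sensitivity drift between runs. Afterwards every feature's
    median within each batch is exactly 1."""
    aligned = meta.aligned_to(table)
    X = table.intensities.copy().astype(float)
    batches = aligned["batch"]
    for batch, cols in X.T.groupby(batches, observed=True).groups.items():
        block = X[cols]
        med = block.median(axis=1, skipna=True)
        bad = med.index[~(med > 0) | med.isna()]
        if len(bad):
            raise PreprocessError(
                f"zero or undefined within-batch median for feature(s) {bad.tolist()} "
                f"in batch {batch!r}"
            )
        X[cols] = block.div(med, axis=0)
    return table.with_intensities(X)


def normalize(
    table: FeatureTable, meta: SampleMetadata, report: PreprocessReport | None = None
) -> tuple[FeatureTable, PreprocessReport]:
    """Volume, sample-median and within-batch per-feature median
    normalization (in that order). Missing entries stay missing."""
    if report is None:
        report = PreprocessReport(
            n_input_features=table.n_features, n_output_features=table.n_features
        )
    out = normalize_samples(table, meta)
    report.normalization_steps += ["injection_volume", "sample_median"]
    out = normalize_batches(out, meta)
    report.normalization_steps.append("batch_median")
    return out, report


def preprocess(
    table: FeatureTable,
    meta: SampleMetadata,
    frac: float = 0.001,
    max_missing: float = 0.30,
    min_rt: float = 0.45,
) -> tuple[FeatureTable, PreprocessReport]:
    """Full chain: three filters then the three normalization steps."""
    filtered, report = apply_filters(table, frac=frac, max_missing=max_missing, min_rt=min_rt)
    return normalize(filtered, meta, report)
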