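"""Core tabular containers: feature table, sample metadata, sensory scores,
compound database.

All containers wrap pandas objects and validate their schema on
construction. Missing intensities are ``NaN``; an explicit zero is a
measured value, never a stand-in for missing (the missing-value filter
depends on this distinction).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .attributes import SENSORY_ATTRIBUTES

IONIZATION_MODES = ("positive", "negative")
CLUSTER_TYPES = ("i", "ii", "iii")

METADATA_COLUMNS = (
    "season",
    "cluster_type",
    "batch",
    "injection_volume",
    "biological_rep",
    "technical_rep",
)


class ValidationError(ValueError):
    """A table violated its schema contract."""


@dataclass
class FeatureTable:
    """Aligned molecular-feature table for one ionization mode.

    Parameters
    ----------
    features
        DataFrame indexed by feature id with columns ``mz`` (Thomson) and
        ``rt`` (minutes).
    intensities
        features x samples DataFrame of nonnegative relative intensities;
        ``NaN`` marks a missing measurement.
    mode
        ``"positive"`` or ``"negative"``; modes are analysed separately
        end to end.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    mode: str = "positive"

    def __post_init__(self) -> None:
        self.validate()

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    @property
    def n_features(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    @property
    def mz(self) -> pd.Series:
        return self.features["mz"]

    @property
    def rt(self) -> pd.Series:
        return self.features["rt"]

    def subset(self, feature_ids) -> "FeatureTable":
        """Return a new table restricted to ``feature_ids`` (order kept)."""
        idx = self.feature_ids[self.feature_ids.isin(set(feature_ids))]
        return FeatureTable(
            features=self.features.loc[idx].copy(),
            intensities=self.intensities.loc[idx].copy(),
            mode=self.mode,
        )

    def with_intensities(self, intensities: pd.DataFrame) -> "FeatureTable":
        return replace(self, intensities=intensities)

    def validate(self) -> None:
        if self.mode not in IONIZATION_MODES:
            raise ValidationError(
                f"unknown ionization mode {self.mode!r}; expected one of {IONIZATION_MODES}"
            )
        if not self.features.index.equals(self.intensities.index):
            raise ValidationError("feature metadata and intensity matrix indexes differ")
        if self.features.index.has_duplicates:
            dupes = self.features.index[self.features.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated feature ids: {dupes}")
        if self.intensities.columns.has_duplicates:
            dupes = self.intensities.columns[self.intensities.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample ids: {dupes}")
        for col in ("mz", "rt"):
            if col not in self.features.columns:
                raise ValidationError(f"feature metadata lacks required column {col!r}")
        mz = self.features["mz"].to_numpy(dtype=float)
        if not np.all(mz > 0):
            bad = self.features.index[~(mz > 0)].tolist()
            raise ValidationError(f"non-positive m/z for features: {bad}")
        rt = self.features["rt"].to_numpy(dtype=float)
        if not np.all(rt >= 0):
            bad = self.features.index[~(rt >= 0)].tolist()
            raise ValidationError(f"negative retention time for features: {bad}")
        vals = self.intensities.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            if np.any(vals < 0):
                rows = self.intensities.index[np.any(vals < 0, axis=1)].tolist()
                raise ValidationError(f"negative intensities in features: {rows}")


@dataclass
class SampleMetadata:
    """Per-sample study design: season, cluster type, batch, injection
    volume and the biological / technical replicate structure."""

    table: pd.DataFrame  # indexed by sample_id

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample metadata lacks columns: {missing}")
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample ids in metadata: {dupes}")
        vol = self.table["injection_volume"].to_numpy(dtype=float)
        if not np.all(vol > 0):
            bad = self.table.index[~(vol > 0)].tolist()
            raise ValidationError(f"non-positive injection volume for samples: {bad}")

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def check_covers(self, table: FeatureTable) -> None:
        """Every sample in the feature table must have exactly one row here."""
        missing = table.sample_ids.difference(self.sample_ids)
        if len(missing):
            raise ValidationError(
                f"samples present in feature table but absent from metadata: {missing.tolist()}"
            )

    def aligned_to(self, table: FeatureTable) -> pd.DataFrame:
        self.check_covers(table)
        return self.table.loc[table.sample_ids]


@dataclass
class SensoryScores:
    """Expert-panel scores, samples (or wines) x the 15 fixed attributes."""

    table: pd.DataFrame  # indexed by sample_id, columns = attributes

    def __post_init__(self) -> None:
        unknown = [a for a in self.table.columns if a not in SENSORY_ATTRIBUTES]
        if unknown:
            raise ValidationError(
                f"unknown sensory attributes {unknown}; the fixed vocabulary is "
                f"{list(SENSORY_ATTRIBUTES)}"
            )
        absent = [a for a in SENSORY_ATTRIBUTES if a not in self.table.columns]
        if absent:
            raise ValidationError(f"incomplete attribute set; missing {absent}")
        if self.table.index.has_duplicates:
            raise ValidationError("duplicated sample ids in sensory scores")

    @property
    def attributes(self) -> list[str]:
        return [a for a in SENSORY_ATTRIBUTES if a in self.table.columns]

    def aligned_to(self, table: FeatureTable) -> pd.DataFrame:
        missing = table.sample_ids.difference(self.table.index)
        if len(missing):
            raise ValidationError(
                f"samples without sensory scores: {missing.tolist()}"
            )
        return self.table.loc[table.sample_ids]


@dataclass
class CompoundDB:
    """User-supplied compound table for exact-mass annotation.

    ``intrinsic_charge`` is 0 for neutral molecules and +1 for
    intrinsically cationic species (flavylium anthocyanins), which ionize
    as M+ rather than via a neutral adduct.
    """

    table: pd.DataFrame  # columns name, formula, compound_class, intrinsic_charge

    REQUIRED = ("name", "formula", "compound_class", "intrinsic_charge")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"compound table lacks columns: {missing}")
        if self.table["name"].duplicated().any():
            dupes = self.table.loc[self.table["name"].duplicated(), "name"].tolist()
            raise ValidationError(f"duplicated compound names: {dupes}")
        charges = set(self.table["intrinsic_charge"].astype(int))
        if not charges <= {0, 1}:
            raise ValidationError(f"intrinsic_charge must be 0 or +1, got {sorted(charges)}")
        # formula parseability checked by annotate.formula_monoisotopic_mass,
        # invoked lazily here to avoid a circular import
        from .annotate import formula_monoisotopic_mass

        for name, formula in zip(self.table["name"], self.table["formula"]):
            try:
                formula_monoisotopic_mass(formula)
            except Exception as exc:  # re-raise naming the offending compound
                raise ValidationError(
                    f"unparseable formula {formula!r} for compound {name!r}: {exc}"
                ) from exc

    def __len__(self) -> int:
        return len(self.table)
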