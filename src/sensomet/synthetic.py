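"""Synthetic untargeted LC-MS + sensory dataset generator with known
ground truth.

The generator emulates a two-season, three-cluster-type wine study with
nested biological and technical replicates (2 x 3 x 4 x 3 = 72 samples by
default):

* per-feature baseline log10 intensities (log-normal dynamic range);
* a dominant season effect and weaker cluster-type effects on configurable
  fractions of features;
* per-attribute latent "wine chemistry" factors that each attribute's
  planted biomarker features load on, so that biomarkers co-vary with one
  another and with the attribute score (as co-regulated metabolites do);
* sensory scores built as the spec'd linear combination of standardized
  biomarker log intensities plus panel noise, generated at the wine level
  and inherited by every technical replicate;
* multiplicative per-batch sensitivity shifts (batches are contiguous
  sample blocks, mimicking instrument run order);
* missing values, at a base rate plus a boost for the lowest-decile
  intensities;
* features planted to violate each preprocessing filter (early retention
  time, sub-threshold mean intensity, excess missingness), with guards
  that keep every *non*-planted feature clear of the filter boundaries so
  filter removal counts are known exactly by construction;
* features whose m/z is placed exactly on (or at a configured ppm offset
  from) adduct m/z values of the bundled wine-compound table.

Everything is drawn from one seeded generator, so identical seed + config
gives byte-identical outputs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .annotate import adduct_mz, formula_monoisotopic_mass
from .attributes import SENSORY_ATTRIBUTES
from .tables import CLUSTER_TYPES, CompoundDB, FeatureTable, SampleMetadata, SensoryScores


class SyntheticConfigError(ValueError):
    pass


@dataclass
class SyntheticConfig:
    """Study-design and effect-size knobs for the generator.

    Effect sizes are in log10-intensity units; attribute scores are on an
    arbitrary continuous panel scale (the real panel's scale is unknown).
    """

    seed: int = 0
    n_features: int = 2000
    n_seasons: int = 2
    n_cluster_types: int = 3
    n_biological: int = 4
    n_technical: int = 3
    n_batches: int = 4
    season_effect_sd: float = 0.6
    cluster_effect_sd: float = 0.25
    frac_season_affected: float = 0.30
    frac_cluster_affected: float = 0.10
    n_biomarkers_per_attribute: int = 20
    biomarker_effect: float = 1.0
    biomarker_latent_sd: float = 0.3
    attribute_noise_sd: float = 1.0
    bio_noise_sd: float = 0.15
    tech_noise_sd: float = 0.05
    missing_rate: float = 0.05
    low_intensity_missing_boost: float = 1.0
    batch_effect_sd: float = 0.10
    rt_range: tuple[float, float] = (0.0, 19.0)
    mz_range: tuple[float, float] = (100.0, 1500.0)
    ionization_mode: str = "positive"
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    baseline_truncation: float = 1.25  # sd units; keeps all features above the 0.1% cut
    n_planted_low_intensity: int = 15
    n_planted_high_missing: int = 15
    n_planted_early_rt: int = 15
    planted_missing_frac: float = 0.40
    max_background_missing: float = 0.28
    n_planted_annotations: int = 10
    planted_ppm_offset: float = 0.0
    injection_volume: float = 2.0  # microlitres

    def validate(self) -> None:
        counts = {
            "n_features": self.n_features,
            "n_seasons": self.n_seasons,
            "n_cluster_types": self.n_cluster_types,
            "n_biological": self.n_biological,
            "n_technical": self.n_technical,
            "n_batches": self.n_batches,
        }
        for name, v in counts.items():
            if v < 1:
                raise SyntheticConfigError(f"{name} must be positive, got {v}")
        fracs = {
            "frac_season_affected": self.frac_season_affected,
            "frac_cluster_affected": self.frac_cluster_affected,
            "missing_rate": self.missing_rate,
            "planted_missing_frac": self.planted_missing_frac,
            "max_background_missing": self.max_background_missing,
        }
        for name, v in fracs.items():
            if not 0.0 <= v <= 1.0:
                raise SyntheticConfigError(f"{name} must be in [0, 1], got {v}")
        if self.low_intensity_missing_boost < 0:
            raise SyntheticConfigError("low_intensity_missing_boost must be nonnegative")
        if self.n_samples == 0 or self.n_features == 0:
            raise SyntheticConfigError("configuration yields zero samples or features")
        n_special = (
            self.n_planted_low_intensity
            + self.n_planted_high_missing
            + self.n_planted_early_rt
            + self.n_planted_annotations
            + len(SENSORY_ATTRIBUTES) * self.n_biomarkers_per_attribute
        )
        if n_special > self.n_features:
            raise SyntheticConfigError(
                f"{n_special} planted/biomarker features exceed n_features={self.n_features}"
            )

    @property
    def n_samples(self) -> int:
        return self.n_seasons * self.n_cluster_types * self.n_biological * self.n_technical

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rt_range"] = list(self.rt_range)
        d["mz_range"] = list(self.mz_range)
        return d


@dataclass
class GroundTruth:
    """What was planted, so tests can check it is recovered."""

    biomarker_map: dict[str, dict[str, float]] = field(default_factory=dict)
    season_affected: set[str] = field(default_factory=set)
    cluster_affected: set[str] = field(default_factory=set)
    planted_low_intensity: set[str] = field(default_factory=set)
    planted_high_missing: set[str] = field(default_factory=set)
    planted_early_rt: set[str] = field(default_factory=set)
    planted_compounds: dict[str, tuple[str, str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "biomarker_map": self.biomarker_map,
            "season_affected": sorted(self.season_affected),
            "cluster_affected": sorted(self.cluster_affected),
            "planted_low_intensity": sorted(self.planted_low_intensity),
            "planted_high_missing": sorted(self.planted_high_missing),
            "planted_early_rt": sorted(self.planted_early_rt),
            "planted_compounds": {
                k: list(v) for k, v in self.planted_compounds.items()
            },
        }


def default_compound_db() -> CompoundDB:
    """The bundled wine-compound table (synthetic fixture, not a KEGG
    export): common phenolics, anthocyanins (intrinsic cations), acids."""
    from .io import read_compound_db

    path = importlib.resources.files("sensomet.data") / "compounds.csv"
    return read_compound_db(str(path))


def _cluster_type_names(n: int) -> list[str]:
    if n <= len(CLUSTER_TYPES):
        return list(CLUSTER_TYPES[:n])
    return list(CLUSTER_TYPES) + [f"type{k}" for k in range(len(CLUSTER_TYPES) + 1, n + 1)]


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[FeatureTable, SampleMetadata, SensoryScores, CompoundDB, GroundTruth]:
    """Generate one synthetic dataset; see the module docstring."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_feat, n_samp = config.n_features, config.n_samples

    # ---- sample design --------------------------------------------------
    seasons = [f"S{i + 1}" for i in range(config.n_seasons)]
    ctypes = _cluster_type_names(config.n_cluster_types)
    rows = []
    for s in seasons:
        for ct in ctypes:
            for b in range(1, config.n_biological + 1):
                for t in range(1, config.n_technical + 1):
                    rows.append((f"{s}_{ct}_b{b}_t{t}", s, ct, b, t, f"{s}_{ct}_b{b}"))
    design = pd.DataFrame(
        rows, columns=["sample_id", "season", "cluster_type", "biological_rep",
                       "technical_rep", "wine_id"]
    ).set_index("sample_id")
    # measurement batches: randomized but stratified by season x cluster
    # type (a balanced block design, as samples randomized before MS
    # acquisition would give). Imbalanced batches would let the
    # within-batch median normalization inject design-correlated offsets.
    batch = np.empty(n_samp, dtype=object)
    cell = design["season"].astype(str) + "|" + design["cluster_type"].astype(str)
    for _, idx in pd.Series(np.arange(n_samp)).groupby(cell.to_numpy()):
        members = rng.permutation(idx.to_numpy())
        start = int(rng.integers(config.n_batches))
        for i, s in enumerate(members):
            batch[s] = f"B{(start + i) % config.n_batches + 1}"
    design["batch"] = batch
    design["injection_volume"] = config.injection_volume

    wines = design["wine_id"].unique().tolist()
    wine_of_sample = design["wine_id"].to_numpy()
    wine_pos = {w: i for i, w in enumerate(wines)}
    sample_wine_idx = np.array([wine_pos[w] for w in wine_of_sample])

    # ---- feature roles --------------------------------------------------
    fids = np.array([f"F{i + 1:05d}" for i in range(n_feat)])
    perm = rng.permutation(n_feat)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        out = perm[cursor:cursor + k]
        cursor += k
        return out

    planted_low = take(config.n_planted_low_intensity)
    planted_missing = take(config.n_planted_high_missing)
    planted_rt = take(config.n_planted_early_rt)
    planted_ann = take(config.n_planted_annotations)
    biomarkers = {
        attr: take(config.n_biomarkers_per_attribute) for attr in SENSORY_ATTRIBUTES
    }
    # season- and cluster-affected sets are disjoint (and disjoint from
    # biomarkers and filter plants) so each planted signal is attributable
    remaining = perm[cursor:]
    n_season_aff = min(int(round(config.frac_season_affected * n_feat)), len(remaining))
    season_aff = take(n_season_aff)
    remaining = perm[cursor:]
    n_cluster_aff = min(int(round(config.frac_cluster_affected * n_feat)), len(remaining))
    cluster_aff = take(n_cluster_aff)

    # ---- retention times and m/z ---------------------------------------
    rt_lo, rt_hi = config.rt_range
    rt_cut = 0.45
    rt = rng.uniform(max(rt_lo, rt_cut), rt_hi, size=n_feat)
    if len(planted_rt):
        rt[planted_rt] = rng.uniform(rt_lo, min(rt_cut, rt_hi) * 0.999, size=len(planted_rt))
    mz = rng.uniform(config.mz_range[0], config.mz_range[1], size=n_feat)

    db = default_compound_db()
    gt_compounds: dict[str, tuple[str, str, float]] = {}
    if len(planted_ann):
        candidates = []
        for rec in db.table.itertuples(index=False):
            m = formula_monoisotopic_mass(rec.formula)
            if int(rec.intrinsic_charge) == 1:
                if config.ionization_mode == "positive":
                    candidates.append((rec.name, "M+", adduct_mz(m, "M+")))
            elif config.ionization_mode == "positive":
                candidates.append((rec.name, "M+H", adduct_mz(m, "M+H")))
            else:
                candidates.append((rec.name, "M-H", adduct_mz(m, "M-H")))
        pick = rng.choice(len(candidates), size=len(planted_ann),
                          replace=len(candidates) < len(planted_ann))
        for f_idx, c_idx in zip(planted_ann, pick):
            name, adduct, theo = candidates[int(c_idx)]
            mz[f_idx] = theo * (1.0 + config.planted_ppm_offset * 1e-6)
            gt_compounds[str(fids[f_idx])] = (name, adduct, config.planted_ppm_offset)

    # ---- log10 intensity surface ----------------------------------------
    trunc = config.baseline_truncation
    mu = config.baseline_log_mean + config.baseline_log_sd * stats.truncnorm.rvs(
        -trunc, trunc, size=n_feat, random_state=rng
    )
    if len(planted_low):
        mu[planted_low] = mu.max() - 4.0  # far below the 0.1%-of-max cut

    L = np.tile(mu[:, None], (1, n_samp))

    # per-feature season shifts ~ N(0, sd) per season, centered across
    # seasons so the common part stays in the baseline; centering keeps
    # the between-season contrast while leaving per-feature means honest
    season_shift = np.zeros((n_feat, config.n_seasons))
    if len(season_aff):
        draw = rng.normal(
            0.0, config.season_effect_sd, size=(len(season_aff), config.n_seasons)
        )
        season_shift[season_aff, :] = draw - draw.mean(axis=1, keepdims=True)
    cluster_shift = np.zeros((n_feat, config.n_cluster_types))
    if len(cluster_aff):
        cluster_shift[cluster_aff, :] = rng.normal(
            0.0, config.cluster_effect_sd, size=(len(cluster_aff), config.n_cluster_types)
        )
    season_idx = np.array([seasons.index(s) for s in design["season"]])
    ctype_idx = np.array([ctypes.index(c) for c in design["cluster_type"]])
    L += season_shift[:, season_idx]
    L += cluster_shift[:, ctype_idx]

    # latent per-attribute wine factors; biomarkers load on them with
    # random sign so associations go both ways
    latent = rng.standard_normal((len(SENSORY_ATTRIBUTES), len(wines)))
    loading_sign: dict[str, np.ndarray] = {}
    for ai, attr in enumerate(SENSORY_ATTRIBUTES):
        feats = biomarkers[attr]
        if not len(feats):
            continue
        signs = rng.choice([-1.0, 1.0], size=len(feats))
        loading_sign[attr] = signs
        L[feats, :] += (
            config.biomarker_latent_sd
            * signs[:, None]
            * latent[ai, sample_wine_idx][None, :]
        )

    bio_noise = rng.normal(0.0, config.bio_noise_sd, size=(n_feat, len(wines)))
    L += bio_noise[:, sample_wine_idx]
    L += rng.normal(0.0, config.tech_noise_sd, size=(n_feat, n_samp))

    # ---- sensory scores (wine level, inherited by replicates) -----------
    feat_mean = L.mean(axis=1)
    feat_sd = L.std(axis=1, ddof=1)
    feat_sd[feat_sd == 0] = 1.0
    Z = (L - feat_mean[:, None]) / feat_sd[:, None]
    gt = GroundTruth(
        season_affected={str(f) for f in fids[season_aff]},
        cluster_affected={str(f) for f in fids[cluster_aff]},
        planted_low_intensity={str(f) for f in fids[planted_low]},
        planted_high_missing={str(f) for f in fids[planted_missing]},
        planted_early_rt={str(f) for f in fids[planted_rt]},
        planted_compounds=gt_compounds,
    )
    scores = pd.DataFrame(
        0.0, index=design.index, columns=list(SENSORY_ATTRIBUTES)
    )
    wine_members = {w: np.flatnonzero(wine_of_sample == w) for w in wines}
    for ai, attr in enumerate(SENSORY_ATTRIBUTES):
        feats = biomarkers[attr]
        effects = config.biomarker_effect * loading_sign.get(attr, np.ones(len(feats)))
        gt.biomarker_map[attr] = {
            str(fids[f]): float(e) for f, e in zip(feats, effects)
        }
        noise = rng.normal(0.0, config.attribute_noise_sd, size=len(wines))
        wine_scores = np.empty(len(wines))
        for wi, w in enumerate(wines):
            cols = wine_members[w]
            zbar = Z[feats][:, cols].mean(axis=1) if len(feats) else np.zeros(0)
            wine_scores[wi] = float(effects @ zbar) + noise[wi]
        scores[attr] = wine_scores[sample_wine_idx]

    # ---- batch effects and linear intensities ---------------------------
    batch_names = [f"B{k + 1}" for k in range(config.n_batches)]
    batch_shift = rng.normal(0.0, config.batch_effect_sd, size=(n_feat, config.n_batches))
    batch_pos = np.array([batch_names.index(b) for b in design["batch"]])
    measured = L + batch_shift[:, batch_pos]
    intensity = 10.0 ** measured

    # guard: keep non-planted features clear of the 0.1%-of-max mean cut
    means = intensity.mean(axis=1)
    thr = 0.001 * means.max()
    lift = np.flatnonzero((means < 2.0 * thr))
    lift = np.setdiff1d(lift, planted_low)
    if len(lift):
        intensity[lift, :] *= (2.0 * thr / means[lift])[:, None]

    # ---- missingness -----------------------------------------------------
    rate = np.full((n_feat, n_samp), config.missing_rate)
    low_cut = np.quantile(measured, 0.10)
    rate[measured <= low_cut] = min(
        1.0, config.missing_rate * (1.0 + config.low_intensity_missing_boost)
    )
    mask = rng.random((n_feat, n_samp)) < rate
    # planted high-missing features: exact missing count above the 30% cut
    n_missing_planted = int(np.ceil(config.planted_missing_frac * n_samp))
    for f in planted_missing:
        mask[f, :] = False
        mask[f, rng.choice(n_samp, size=n_missing_planted, replace=False)] = True
    # background cap: everyone else stays at or below max_background_missing
    cap = int(np.floor(config.max_background_missing * n_samp))
    counts = mask.sum(axis=1)
    over = np.setdiff1d(np.flatnonzero(counts > cap), planted_missing)
    for f in over:
        hit = np.flatnonzero(mask[f])
        drop = rng.choice(hit, size=counts[f] - cap, replace=False)
        mask[f, drop] = False

    intensity = np.where(mask, np.nan, intensity)

    # ---- assemble --------------------------------------------------------
    features = pd.DataFrame({"mz": mz, "rt": rt}, index=pd.Index(fids, name="feature_id"))
    table = FeatureTable(
        features=features,
        intensities=pd.DataFrame(intensity, index=features.index, columns=design.index),
        mode=config.ionization_mode,
    )
    meta = SampleMetadata(
        table=design[["season", "cluster_type", "batch", "injection_volume",
                      "biological_rep", "technical_rep", "wine_id"]].copy()
    )
    sensory = SensoryScores(table=scores)
    return table, meta, sensory, db, gt
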