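"""End-to-end orchestration: simulate/load -> preprocess -> PCA ->
sPLS-DA / sPLS -> VIP -> networks -> annotation.

One :class:`PipelineConfig` drives the whole run; a serialized copy of it
is written next to the outputs, all randomness flows from the single root
seed (child seeds drawn from one generator in a fixed order), and every
stage writes its artifact so intermediates can be inspected or re-run.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .annotate import match_features
from .attributes import SENSORY_ATTRIBUTES
from .network import network_summary, split_networks
from .pca import fit_pca
from .preprocess import preprocess
from .spls import (
    DEFAULT_COMP_GRID_SPLS,
    DEFAULT_COMP_GRID_SPLSDA,
    DEFAULT_KEEPX_GRID,
    fit_spls,
    fit_splsda,
    grid_search,
    model_summary,
)
from .synthetic import SyntheticConfig, generate_dataset
from .tables import CompoundDB, FeatureTable, SampleMetadata, SensoryScores

logger = logging.getLogger(__name__)

REDUCED_COMP_GRID = (1, 2, 3)
REDUCED_KEEPX_GRID = (50, 100, 200)
REDUCED_REPEATS = 10


@dataclass
class PipelineConfig:
    """Everything one run needs. Either ``synthetic`` is set or all four
    input paths are."""

    out_dir: str = "sensomet_run"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    feature_table_path: str | None = None
    sample_metadata_path: str | None = None
    sensory_scores_path: str | None = None
    compound_db_path: str | None = None
    ionization_mode: str = "positive"
    # preprocessing
    low_intensity_frac: float = 0.001
    max_missing: float = 0.30
    min_rt: float = 0.45
    # PCA
    pca_components: int = 5
    # grid search (reduced desk-scale defaults; paper_grid restores the
    # full 1..12 x {50..1000} x 100-repeat search)
    paper_grid: bool = False
    comp_grid_spls: tuple[int, ...] = REDUCED_COMP_GRID
    comp_grid_splsda: tuple[int, ...] = REDUCED_COMP_GRID
    keepX_grid: tuple[int, ...] = REDUCED_KEEPX_GRID
    cv_repeats: int = REDUCED_REPEATS
    cv_folds: int = 5
    # network / annotation
    vip_threshold: float = 1.0
    ppm_tolerance: float = 5.0

    def grids(self) -> tuple[tuple[int, ...], tuple[int, ...], tuple[int, ...], int]:
        if self.paper_grid:
            return (
                DEFAULT_COMP_GRID_SPLS,
                DEFAULT_COMP_GRID_SPLSDA,
                DEFAULT_KEEPX_GRID,
                100,
            )
        return self.comp_grid_spls, self.comp_grid_splsda, self.keepX_grid, self.cv_repeats

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d


def load_inputs(
    config: PipelineConfig,
) -> tuple[FeatureTable, SampleMetadata, SensoryScores, CompoundDB]:
    if config.synthetic is not None:
        table, meta, scores, db, _ = generate_dataset(config.synthetic)
        return table, meta, scores, db
    paths = (
        config.feature_table_path,
        config.sample_metadata_path,
        config.sensory_scores_path,
        config.compound_db_path,
    )
    if any(p is None for p in paths):
        raise ValueError("either a synthetic config or all four input paths are required")
    table = io.read_feature_table(config.feature_table_path, mode=config.ionization_mode)
    meta = io.read_sample_metadata(config.sample_metadata_path)
    scores = io.read_sensory_scores(config.sensory_scores_path)
    db = io.read_compound_db(config.compound_db_path)
    meta.check_covers(table)
    return table, meta, scores, db


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "models").mkdir(exist_ok=True)
    io.write_json(config.to_dict(), out / "config.json")
    timings: dict[str, float] = {}
    log: dict = {"seed": config.seed, "stages": timings}

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("stage %s ...", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                if exc is not None:
                    logger.error("stage %s failed on %s", name, exc)
                return False

        return _T()

    rng = np.random.default_rng(config.seed)

    def child_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    with stage("load"):
        table, meta, scores, db = load_inputs(config)

    with stage("preprocess"):
        processed, report = preprocess(
            table, meta,
            frac=config.low_intensity_frac,
            max_missing=config.max_missing,
            min_rt=config.min_rt,
        )
        io.write_json(report.to_dict(), out / "preprocess_report.json")
        io.write_feature_table(processed, out / "processed_table.csv")

    with stage("pca"):
        ncomp = min(config.pca_components, processed.n_samples - 1, processed.n_features)
        pca = fit_pca(processed, n_components=ncomp)
        pd.DataFrame(
            pca.scores, index=pca.sample_ids,
            columns=[f"PC{i + 1}" for i in range(ncomp)],
        ).to_csv(out / "pca_scores.csv", index_label="sample_id")
        pd.DataFrame(
            pca.loadings, index=pca.feature_ids,
            columns=[f"PC{i + 1}" for i in range(ncomp)],
        ).to_csv(out / "pca_loadings.csv", index_label="feature_id")
        io.write_json(
            {"r2_per_component": pca.r2_per_component.tolist(), "n_components": ncomp},
            out / "pca_summary.json",
        )

    X = processed.intensities.to_numpy(dtype=float).T
    feature_ids = [str(f) for f in processed.feature_ids]
    aligned_meta = meta.aligned_to(processed)
    comp_spls, comp_splsda, keepx_grid, repeats = config.grids()

    vip_by_attribute: dict[str, pd.Series] = {}
    with stage("splsda"):
        for label in ("season", "cluster_type"):
            y = aligned_meta[label].to_numpy()
            cv = grid_search(
                X, y, "splsda", comp_grid=comp_splsda, keepX_grid=keepx_grid,
                n_repeats=repeats, k=config.cv_folds, seed=child_seed(),
            )
            c, kx = cv.best_pair
            model = fit_splsda(X, y, c, kx, feature_ids=feature_ids)
            io.write_json(model_summary(model, cv), out / "models" / f"splsda_{label}.json")

    with stage("spls"):
        score_table = scores.aligned_to(processed)
        for attr in SENSORY_ATTRIBUTES:
            y = score_table[attr].to_numpy(dtype=float)
            cv = grid_search(
                X, y, "spls", comp_grid=comp_spls, keepX_grid=keepx_grid,
                n_repeats=repeats, k=config.cv_folds, seed=child_seed(),
            )
            c, kx = cv.best_pair
            model = fit_spls(X, y, c, kx, feature_ids=feature_ids)
            safe = attr.replace("/", "_").replace(" ", "_")
            io.write_json(model_summary(model, cv), out / "models" / f"spls_{safe}.json")
            vip_by_attribute[attr] = pd.Series(model.vip, index=feature_ids, name=attr)

    with stage("annotate"):
        annotations = match_features(processed, db, tol_ppm=config.ppm_tolerance)
        io.write_annotations(annotations, out / "annotations.tsv")
        best_by_feature = {
            a.feature_id: a.candidates[0].compound_class for a in annotations if a.candidates
        }

    with stage("network"):
        vip_frame = pd.DataFrame(vip_by_attribute)
        vip_frame.index.name = "feature_id"
        vip_frame.to_csv(out / "vip_table.tsv", sep="\t")
        supra = vip_frame[(vip_frame > config.vip_threshold).any(axis=1)]
        supra.to_csv(out / "vip_biomarkers.tsv", sep="\t")
        feature_info = processed.features[["mz", "rt"]].copy()
        feature_info.index = feature_info.index.astype(str)
        feature_info["annotation"] = pd.Series(best_by_feature)
        nets = split_networks(
            vip_by_attribute, threshold=config.vip_threshold, feature_info=feature_info
        )
        summaries = {}
        for name, net in nets.items():
            io.write_network(net, out / f"network_{name}.graphml", format="graphml")
            io.write_network(net, out / f"network_{name}_edges.tsv", format="edge_tsv")
            summaries[name] = network_summary(net)
        io.write_json(summaries, out / "network_summary.json")

    import sensomet

    log["version"] = getattr(sensomet, "__version__", "unknown")
    io.write_json(log, out / "run_log.json")
    logger.info("pipeline done: %s", json.dumps(timings))
    return out
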