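"""End-to-end orchestration of the CIF pipeline on synthetic cohorts.

This module wires the stages together — simulate, tile, rank-train, score,
feature extraction, topology, cohort statistics — at a desk-scale study
geometry: 768x768 images tiled with 128-px windows at a 64-px stride
(the same 2:1 window:stride ratio and identical inclusion thresholds as the
full-resolution defaults), with tiles downscaled to 32x32 network inputs.
Both the test suite and the reproduction script run through these entry
points so that reported numbers always come from the same code path as
library usage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import cohort as cohort_mod
from . import features as feat_mod
from . import ranker as rank_mod
from . import synthetic as syn_mod
from . import tiling as tile_mod
from . import topology as topo_mod


@dataclass(frozen=True)
class StudyConfig:
    """Scaled-down study geometry and training protocol."""

    image_shape: tuple[int, int] = (768, 768)
    tile_size: int = 128
    stride: int = 64
    input_size: int = 32
    rounds: int = 3
    pairs_per_round: int = 700
    epochs: int = 20
    batch_size: int = 64
    learning_rate: float = 2e-3
    concordance: float = 0.884
    n_annotators: int = 3
    hotspot_threshold: float = 0.5


DEMO = StudyConfig()


def extract_labeled_tiles(
    samples: list[syn_mod.SyntheticSample], cfg: StudyConfig = DEMO
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All included tiles of a cohort as network inputs with ground truth.

    Returns (tile_images [n, input, input], tile_severity [n], sample_idx [n]).
    """
    images, severities, owners = [], [], []
    for si, s in enumerate(samples):
        grid = tile_mod.extract_grid(s.image.shape, cfg.tile_size, cfg.stride)
        grid = tile_mod.apply_filters(grid, s.layout)
        for t in grid.included_tiles:
            images.append(t.pixels(s.image))
            severities.append(float(t.pixels(s.severity_field).mean()))
            owners.append(si)
    if not images:
        raise ValueError("cohort produced no included tiles")
    x = rank_mod.preprocess_tiles(np.stack(images), input_size=cfg.input_size)
    return x, np.asarray(severities), np.asarray(owners)


def train_demo_ranker(
    seed: int = 0,
    n_samples: int = 24,
    cfg: StudyConfig = DEMO,
    concordance: float = 1.0,
) -> dict:
    """Train the ranking model on a severity-spectrum cohort.

    The training cohort spans the whole fibrosis range (the way ranking
    training sets are assembled from biopsies chosen to cover the severity
    spectrum). Samples are split at the sample level (not the tile level)
    into training and held-out sets, so the Spearman check measures transfer
    to unseen images.

    By default pairs carry clean oracle labels, isolating what the ranking
    objective itself can learn; pass concordance < 1 to run the full noisy
    annotator panel instead (its label-noise arithmetic is validated by its
    own closed-form checks). Returns the calibrated model plus the study
    metrics.
    """
    samples = syn_mod.generate_spectrum_cohort(
        n_samples=n_samples, seed=seed, shape=cfg.image_shape
    )
    # hold out every fourth sample across the severity ramp
    test_idx = set(range(1, len(samples), 4))
    train_samples = [s for i, s in enumerate(samples) if i not in test_idx]
    test_samples = [s for i, s in enumerate(samples) if i in test_idx]

    x_train, sev_train, _ = extract_labeled_tiles(train_samples, cfg)
    model, rounds, annotations = rank_mod.train_ranker(
        x_train,
        sev_train,
        rounds=cfg.rounds,
        pairs_per_round=cfg.pairs_per_round,
        config=rank_mod.TrainConfig(
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            learning_rate=cfg.learning_rate,
            seed=seed,
        ),
        concordance=concordance,
        n_annotators=cfg.n_annotators,
        seed=seed,
        n_eval_pairs=800,
    )
    x_test, sev_test, _ = extract_labeled_tiles(test_samples, cfg)
    cif_test = rank_mod.score_tiles(model, x_test)
    rho = float(sps.spearmanr(cif_test, sev_test).statistic)
    return {
        "model": model,
        "rounds": rounds,
        "annotations": annotations,
        "heldout_accuracy": rounds[-1].heldout_accuracy,
        "spearman_cif_vs_severity": rho,
        "n_train_tiles": len(x_train),
        "n_test_tiles": len(x_test),
    }


def sample_cif_map(
    model: rank_mod.RankingModel,
    sample: syn_mod.SyntheticSample,
    cfg: StudyConfig = DEMO,
) -> feat_mod.CIFMap:
    grid = tile_mod.extract_grid(sample.image.shape, cfg.tile_size, cfg.stride)
    grid = tile_mod.apply_filters(grid, sample.layout)
    return feat_mod.build_cif_map(model, grid, sample.image)


def sample_feature_row(
    model: rank_mod.RankingModel,
    sample: syn_mod.SyntheticSample,
    cfg: StudyConfig = DEMO,
    with_topology: bool = True,
) -> dict:
    """Fibrosis (and optionally topological) features for one sample."""
    cif_map = sample_cif_map(model, sample, cfg)
    fv = feat_mod.feature_vector(
        cif_map, sample_id=sample.sample_id, class_label=sample.class_label
    )
    row = fv.as_dict()
    if with_topology:
        filt = topo_mod.Filtration(cif_map.scores)
        bc = topo_mod.barcode(filt)
        row.update(topo_mod.barcode_features(bc, cfg.hotspot_threshold).as_dict())
    return row


def cohort_feature_table(
    model: rank_mod.RankingModel,
    samples: list[syn_mod.SyntheticSample],
    cfg: StudyConfig = DEMO,
    with_topology: bool = True,
) -> pd.DataFrame:
    return pd.DataFrame(
        [sample_feature_row(model, s, cfg, with_topology) for s in samples]
    )


#: Controlled two-class experiment for the topology question: both classes
#: share the same diffuse severity background and the same expected total
#: focal area (so marginal statistics — average score, bin fractions —
#: overlap), and differ only in hotspot prevalence: ET-like marrows carry an
#: occasional larger focus, pre-PMF-like marrows several smaller, spatially
#: clustered microfoci. What separates them is the number and arrangement of
#: foci, the structure persistent homology is built to see.
HOTSPOT_CLASS_SPECS = {
    "ET-like": syn_mod.ClassSpec(
        0.14, 0.04, hotspot_count_mean=1.0, hotspot_radius_px=150.0,
        hotspot_boost=0.45,
    ),
    "prePMF-like": syn_mod.ClassSpec(
        0.14, 0.04, hotspot_count_mean=4.2, hotspot_radius_px=75.0,
        hotspot_boost=0.45, hotspot_clustering=0.8,
    ),
}


def hotspot_discrimination_study(
    model: rank_mod.RankingModel,
    seed: int = 0,
    n_per_class: int = 30,
    cfg: StudyConfig = DEMO,
) -> dict:
    """ET-like vs pre-PMF-like classification with and without topology.

    Generates a two-class cohort, scores it with the trained ranking model,
    and compares pooled 3-fold random-forest AUC for the fibrosis feature
    set alone (average CIF, bins, heterogeneity) against the fibrosis +
    topological feature set.
    """
    samples = syn_mod.generate_cohort(
        class_specs=HOTSPOT_CLASS_SPECS,
        n_per_class=n_per_class,
        seed=seed,
        shape=cfg.image_shape,
    )
    table = cohort_feature_table(model, samples, cfg, with_topology=True)
    fib = cohort_mod.CohortMatrix.from_dataframe(
        table, feature_names=list(cohort_mod.FIBROSIS_FEATURES)
    )
    full = cohort_mod.CohortMatrix.from_dataframe(
        table,
        feature_names=list(cohort_mod.FIBROSIS_FEATURES)
        + list(topo_mod.TOPO_ARRANGEMENT_FEATURES),
    )
    rep_fib = cohort_mod.classify(fib, positive_label="prePMF-like", seed=seed)
    rep_full = cohort_mod.classify(full, positive_label="prePMF-like", seed=seed)
    avg_only = cohort_mod.CohortMatrix.from_dataframe(
        table, feature_names=["avg_cif"]
    )
    rep_avg = cohort_mod.classify(avg_only, positive_label="prePMF-like", seed=seed)
    return {
        "auc_fibrosis_only": rep_fib.auc,
        "auc_full": rep_full.auc,
        "auc_avg_cif_only": rep_avg.auc,
        "report_full": rep_full,
        "table": table,
    }


def run_pipeline(
    out_dir,
    seed: int = 0,
    n_per_class: int = 4,
    cfg: StudyConfig = DEMO,
    config_hash: str = "",
    n_spectrum_samples: int = 24,
) -> dict:
    """Full demo pipeline: simulate -> train -> score -> features -> TDA -> space.

    Writes the feature table, barcodes, disease-space JSON and a run report
    under out_dir and returns the report dict.
    """
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    study = train_demo_ranker(seed=seed, n_samples=n_spectrum_samples, cfg=cfg)
    model = study["model"]
    rank_mod.save_model(model, out / "ranker.npz")

    samples = syn_mod.generate_cohort(
        n_per_class=n_per_class, seed=seed + 1, shape=cfg.image_shape
    )
    table = cohort_feature_table(model, samples, cfg, with_topology=True)
    table.to_csv(out / "features.csv", index=False)

    barcode_frames = []
    for s in samples:
        cif_map = sample_cif_map(model, s, cfg)
        bc = topo_mod.barcode(topo_mod.Filtration(cif_map.scores))
        barcode_frames.append(bc.as_dataframe(s.sample_id))
    pd.concat(barcode_frames).to_csv(out / "barcodes.csv", index=False)

    cohort = cohort_mod.CohortMatrix.from_dataframe(
        table,
        feature_names=list(cohort_mod.FIBROSIS_FEATURES),
    )
    space = cohort_mod.fit_disease_space(cohort)
    space.to_json(out / "disease_space.json")

    report = {
        "seed": seed,
        "config_hash": config_hash,
        "n_samples": len(samples),
        "heldout_accuracy": study["heldout_accuracy"],
        "spearman_cif_vs_severity": study["spearman_cif_vs_severity"],
        "explained_variance": space.explained_variance.tolist(),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1))
    return report
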