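"""Reproducible synthetic benchmark experiments.

Each function renders scenes with the generator's study conditions, runs the
pipeline on them, and returns the measured quantities.  They are the shared
backend of the acceptance checks and of the ``rcpscope evaluate`` style
reporting: the same code path, the same problem sizes, seeded end to end.

Problem sizes are desk-scale: 1024x1024 px tiles (~0.18 mm^2 at 0.42 µm/px),
three replicates per condition, and a handful of tiles per scene — enough
for the statistical properties being measured while keeping a full run in
minutes on one core.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd

from . import classify, genotype, pipeline
from .datasets import kras_tumour_counts
from .synthscope import SceneConfig, render_scene


def _child_seed(*parts: int) -> int:
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0]
               % (2 ** 31))


# ---------------------------------------------------------------------------
# genotype scoring on the published tumour count table

def table_scores(threshold_percent: float = genotype.DEFAULT_THRESHOLD_PERCENT
                 ) -> pd.DataFrame:
    """Recompute ratio and score for each built-in tumour sample."""
    df = kras_tumour_counts()
    calls = [genotype.score(int(r.n_mutant), int(r.n_wildtype),
                            threshold_percent=threshold_percent,
                            sample_id=str(r.sample_id), n_rois=int(r.n_rois))
             for r in df.itertuples()]
    out = df.copy()
    out["ratio_percent"] = [c.ratio_percent for c in calls]
    out["score"] = [c.score for c in calls]
    return out


def table_concordance() -> float:
    """Percent agreement of recomputed scores with the clinical genotypes."""
    df = kras_tumour_counts()
    calls = [genotype.score(int(r.n_mutant), int(r.n_wildtype),
                            sample_id=str(r.sample_id), n_rois=int(r.n_rois))
             for r in df.itertuples()]
    reference = dict(zip(df["sample_id"], df["clinical"]))
    return genotype.concordance(calls, reference)


# ---------------------------------------------------------------------------
# dilution-series linearity

#: five log10-spaced template concentrations, 1 fM .. 10 pM
DILUTION_CONCENTRATIONS = tuple(1e-15 * 10 ** i for i in range(5))
#: expected spots per 1024^2 tile at each concentration
DILUTION_DENSITIES = tuple(2.0 * 10 ** i for i in range(5))
#: extra tiles per replicate at sparse concentrations (counting statistics)
_SPARSE_DENSITY_CUTOFF = 50.0
_SPARSE_TILES = 4


def dilution_linearity(seed: int = 0, n_replicates: int = 3,
                       tile_px: int = 1024) -> genotype.DilutionFit:
    """Render, count and regress a five-point log10 dilution series.

    Densities run 2 → 20,000 expected spots per tile, proportional to
    concentration; the two sparsest points use several tiles per replicate
    so each replicate's mean count is based on a workable number of spots.
    Counts are detected objects per tile after the full preprocessing and
    size/intensity gating chain.
    """
    base = SceneConfig(image_height_px=tile_px, image_width_px=tile_px,
                       channels=("cy3",), artifact_density=0.0)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # near-blank tiles warn on register
        for i, (conc, density) in enumerate(
                zip(DILUTION_CONCENTRATIONS, DILUTION_DENSITIES)):
            n_tiles = _SPARSE_TILES if density < _SPARSE_DENSITY_CUTOFF else 1
            for rep in range(n_replicates):
                counts = []
                for tile in range(n_tiles):
                    cfg = dataclasses.replace(
                        base, spot_density=density,
                        seed=_child_seed(seed, i, rep, tile))
                    stacks, _ = render_scene(cfg)
                    result = pipeline.count_scene(stacks,
                                                  use_anchor_gate=False)
                    counts.append(len(result.objects))
                rows.append((conc, float(np.mean(counts))))
    return genotype.dilution_regression(rows)


# ---------------------------------------------------------------------------
# classifier benchmark

def classifier_labelled_set(seed: int = 0, n_per_class: int = 500,
                            peak_snr: float = 5.0,
                            tile_px: int = 1024) -> classify.TrainingSet:
    """A balanced labelled object set rendered at the given peak SNR.

    Scenes of ~100 RCPs + ~100 artifacts each are rendered and their
    detections labelled against ground truth until at least ``n_per_class``
    examples of each class are collected; the set is then truncated to an
    exact balance in deterministic order.
    """
    X_parts, label_parts = [], []
    scene_idx = 0
    while True:
        cfg = SceneConfig(image_height_px=tile_px, image_width_px=tile_px,
                          spot_density=100.0, artifact_density=100.0,
                          peak_snr=peak_snr, mutant_fraction=0.5,
                          seed=_child_seed(seed, 7, scene_idx))
        stacks, truth = render_scene(cfg)
        ts = classify.labelled_set_from_scene(stacks, truth)
        X_parts.append(ts.X)
        label_parts.append(ts.labels)
        labels = np.concatenate(label_parts)
        n_rcp = int((labels == classify.LABEL_RCP).sum())
        n_neg = int((labels == classify.LABEL_NOT_RCP).sum())
        scene_idx += 1
        if n_rcp >= n_per_class and n_neg >= n_per_class:
            break
        if scene_idx > 40:
            raise RuntimeError("failed to collect enough labelled objects")
    X = np.concatenate(X_parts)
    labels = np.concatenate(label_parts)
    keep = np.concatenate([
        np.flatnonzero(labels == classify.LABEL_RCP)[:n_per_class],
        np.flatnonzero(labels == classify.LABEL_NOT_RCP)[:n_per_class],
    ])
    return classify.TrainingSet(X[keep], labels[keep])


def classifier_cv_accuracy(seed: int = 0, n_per_class: int = 500,
                           peak_snr: float = 5.0, k_folds: int = 5
                           ) -> tuple[float, float]:
    """Stratified k-fold CV accuracy of the forest on a balanced 1,000-object set."""
    ts = classifier_labelled_set(seed, n_per_class, peak_snr)
    model = classify.train(ts, n_trees=100, seed=_child_seed(seed, 11))
    return classify.evaluate(model, ts, k_folds=k_folds,
                             seed=_child_seed(seed, 13))


# ---------------------------------------------------------------------------
# mixture recovery (heterozygote and rare-allele spike-in stand-ins)

def _scene_base_counts(seed_parts: tuple[int, ...], n_tiles: int,
                       density: float, mutant_fraction: float,
                       artifact_density: float, tile_px: int = 1024
                       ) -> tuple[int, int, int]:
    """(accepted A calls, accepted G calls, true mutant count) over tiles."""
    n_a = n_g = n_true_mut = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for tile in range(n_tiles):
            cfg = SceneConfig(image_height_px=tile_px, image_width_px=tile_px,
                              spot_density=density,
                              artifact_density=artifact_density,
                              mutant_fraction=mutant_fraction,
                              seed=_child_seed(*seed_parts, tile))
            stacks, truth = render_scene(cfg)
            result = pipeline.count_scene(stacks, use_anchor_gate=False)
            n_a += result.tally["base_counts"]["A"]
            n_g += result.tally["base_counts"]["G"]
            n_true_mut += int((truth["base"] == "A").sum())
    return n_a, n_g, n_true_mut


def mixture_recovery(seed: int = 0) -> dict:
    """Base-fraction recovery on 50:50 and 1:1,000 two-channel mixtures.

    Returns the measured mutant (Cy5/A) fraction of a heterozygote-like
    50:50 mixture (>= 2,000 RCPs), the measured and true mutant fractions of
    a 1:1,000 spike-in, and the false mutant-call fraction on pure wild-type
    scenes — all with artifact double-stain rejection active and ~20
    auto-fluorescent artifacts per tile.
    """
    a50, g50, _ = _scene_base_counts((seed, 21), n_tiles=4, density=550.0,
                                     mutant_fraction=0.5,
                                     artifact_density=20.0)
    a_spike, g_spike, true_mut = _scene_base_counts(
        (seed, 22), n_tiles=4, density=1500.0, mutant_fraction=0.001,
        artifact_density=20.0)
    a_wt, g_wt, _ = _scene_base_counts((seed, 23), n_tiles=2, density=1500.0,
                                       mutant_fraction=0.0,
                                       artifact_density=20.0)
    return {
        "fifty_fifty_mutant_fraction": a50 / (a50 + g50),
        "fifty_fifty_total": a50 + g50,
        "spikein_measured_fraction": a_spike / (a_spike + g_spike),
        "spikein_true_mutants": true_mut,
        "spikein_total": a_spike + g_spike,
        "wildtype_false_fraction": a_wt / (a_wt + g_wt) if (a_wt + g_wt) else 0.0,
        "wildtype_total": a_wt + g_wt,
    }


__all__ = [
    "table_scores", "table_concordance", "dilution_linearity",
    "classifier_labelled_set", "classifier_cv_accuracy", "mixture_recovery",
    "DILUTION_CONCENTRATIONS", "DILUTION_DENSITIES",
]
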