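"""End-to-end orchestration: features → labels → training → enhancement.

The canonical flow mirrors the three-study design: the smaller study A
contributes input features X, the larger study B contributes labels Y
(p < 5e-8); the trained network is applied to study B's own features, and
significance in the still-larger study C serves as ground truth for
evaluating what the enhancement recovered.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from deepgwas import annotations as ann
from deepgwas import data_io, evaluation, popgen, training
from deepgwas import nn as deep_nn
from deepgwas.schema import DEFAULT_SCHEMA
from deepgwas.simulate import AnnotationBundle, Benchmark

logger = logging.getLogger(__name__)


def build_features(
    stats: pd.DataFrame,
    panel: popgen.GenotypePanel,
    bundle: AnnotationBundle,
    schema: list[str] | None = None,
    alpha: float = training.GWS_ALPHA,
    window_bp: int = popgen.WINDOW_BP_DEFAULT,
    meta_tracks: list[ann.IntervalAnnotation] | None = None,
    ld_cache: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble the feature matrix for one study against one panel.

    Harmonises the stats to the panel, computes MAF and the two LD scores
    (the known-variant score uses this study's own significant set), builds
    the 28 annotation features (clustering the epigenome tracks into 11
    meta-annotations unless pre-clustered tracks are supplied), and returns
    (X, harmonised stats) aligned row for row.
    """
    stats_h, _ = data_io.harmonize(stats, panel)
    idx = np.asarray([panel.loc(k) for k in stats_h["key"]])
    maf = popgen.maf_vector(panel)[idx]

    if ld_cache is None:
        sig_mask = np.zeros(panel.n_variants, dtype=bool)
        sig_mask[idx[stats_h["p_value"].to_numpy() < alpha]] = True
        overall_all, known_all = popgen.ld_scores(
            panel, {"study": sig_mask}, window_bp=window_bp
        )
        ld_overall, ld_known = overall_all[idx], known_all["study"][idx]
    else:
        ld_overall, ld_known = ld_cache[0][idx], ld_cache[1][idx]

    if meta_tracks is None:
        meta_tracks = ann.cluster_annotations(bundle.epigenome_tracks, n_groups=11)
    indicator = dict(bundle.indicator_tracks)
    indicator.update({t.name: t for t in meta_tracks})
    eqtl_keys = ann.filter_eqtls(bundle.eqtl_table)
    X = ann.assemble_features(
        stats_h,
        maf,
        ld_overall,
        ld_known,
        indicator_tracks=indicator,
        score_tracks=bundle.score_tracks,
        eqtl_keys=eqtl_keys,
        schema=schema or DEFAULT_SCHEMA,
    )
    return X, stats_h


@dataclass
class EnhancementRun:
    """Everything produced by one train-and-enhance pass on a benchmark."""

    trained: bool
    model: deep_nn.ModelState | None
    mask: np.ndarray | None  # under-sampling mask over training rows
    predictions: pd.DataFrame  # chrom,pos,key,prob,p_value for the applied study
    enhancement: evaluation.EnhancementResult
    truth_loci: list[evaluation.Locus]
    baseline_loci: list[evaluation.Locus]
    X_features: pd.DataFrame  # study-A features (training X)
    X_apply: pd.DataFrame  # study-B features (application X)
    y_labels: np.ndarray
    stats_a: pd.DataFrame
    stats_b: pd.DataFrame
    stats_c: pd.DataFrame

    @property
    def n_enhanced_loci(self) -> int:
        return len(self.enhancement.enhanced_loci)


def enhance_benchmark(
    bench: Benchmark,
    seed: int = 0,
    undersample_ratio: float = training.UNDERSAMPLE_RATIO_DEFAULT,
    prob_threshold: float = evaluation.PROB_THRESHOLD_DEFAULT,
    alpha: float = training.GWS_ALPHA,
    merge_bp: int = evaluation.MERGE_BP_DEFAULT,
    hyper: deep_nn.TrainingHyper | None = None,
) -> EnhancementRun:
    """Train on (study-A features, study-B labels), enhance study B.

    When the label study has no genome-wide-significant variant (e.g. a
    null simulation) the network is untrainable by contract; the run then
    reports zero predicted-significant variants and zero enhanced loci
    rather than failing.
    """
    panel = bench.panel
    meta_tracks = ann.cluster_annotations(bench.annotations.epigenome_tracks, 11)

    # one LD pass serving both studies' known-variant masks
    idx_map = {k: i for i, k in enumerate(panel.variants["key"])}
    masks = {}
    for name, stats in (("a", bench.study_a), ("b", bench.study_b)):
        m = np.zeros(panel.n_variants, dtype=bool)
        sig = stats.loc[stats["p_value"] < alpha, "key"]
        m[[idx_map[k] for k in sig]] = True
        masks[name] = m
    overall, known = popgen.ld_scores(panel, masks)

    X_a, stats_a = build_features(
        bench.study_a, panel, bench.annotations, meta_tracks=meta_tracks,
        ld_cache=(overall, known["a"]), alpha=alpha,
    )
    X_b, stats_b = build_features(
        bench.study_b, panel, bench.annotations, meta_tracks=meta_tracks,
        ld_cache=(overall, known["b"]), alpha=alpha,
    )
    labels = training.label_variants(stats_b, alpha=alpha)
    keep, y, _ = training.align_labels(X_a.index, labels)
    X_a, stats_a = X_a.iloc[keep], stats_a.iloc[keep]

    truth_sig = bench.study_c.loc[bench.study_c["p_value"] < alpha].assign(
        score=lambda d: -np.log10(np.clip(d["p_value"], 1e-320, None))
    )
    truth_loci = evaluation.call_loci(truth_sig, merge_bp=merge_bp)
    baseline_sig = stats_b.loc[stats_b["p_value"] < alpha].assign(
        score=lambda d: -np.log10(np.clip(d["p_value"], 1e-320, None))
    )
    baseline_loci = evaluation.call_loci(baseline_sig, merge_bp=merge_bp)

    if y.sum() == 0:
        logger.warning("label study has zero significant variants; model untrainable, "
                       "reporting an empty enhancement")
        predictions = stats_b.assign(prob=0.0)[["chrom", "pos", "key", "prob", "p_value"]]
        enh = evaluation.find_enhanced(predictions, prob_threshold, alpha, merge_bp)
        return EnhancementRun(False, None, None, predictions, enh, truth_loci,
                             baseline_loci, X_a, X_b, y, stats_a, stats_b,
                             bench.study_c)

    labeled = training.LabeledSet(
        X_a, y, stats_a["p_value"].to_numpy() < alpha
    )
    subset, mask = training.undersample(labeled, ratio=undersample_ratio, seed=seed)
    subset_std, (X_b_std,), scaler = training.standardize(subset, [X_b])

    hyper = hyper or deep_nn.TrainingHyper(seed=seed)
    model = deep_nn.init_model(
        deep_nn.NetworkConfig(input_width=X_a.shape[1]),
        seed=seed,
        feature_names=list(X_a.columns),
    )
    model.scaler = scaler
    model, _ = deep_nn.train(model, subset_std.X.to_numpy(), subset.y, hyper)

    prob = deep_nn.forward(model, X_b_std.to_numpy())
    predictions = stats_b.assign(prob=prob)[["chrom", "pos", "key", "prob", "p_value"]]
    enh = evaluation.find_enhanced(predictions, prob_threshold, alpha, merge_bp)
    return EnhancementRun(True, model, mask, predictions, enh, truth_loci,
                         baseline_loci, X_a, X_b, y, stats_a, stats_b, bench.study_c)


def transfer_to_study(
    run: EnhancementRun,
    bench: Benchmark,
    stats_new: pd.DataFrame,
    alpha: float = training.GWS_ALPHA,
) -> pd.DataFrame:
    """Apply a benchmark-trained model, weights frozen, to another trait's study.

    The new study's features are built against the same panel and
    annotation bundle (the transfer setting: annotations and LD are trait
    agnostic; only the summary statistics change). Returns the prediction
    table (chrom, pos, key, prob, p_value).
    """
    if not run.trained:
        raise ValueError("the source run has no trained model to transfer")
    meta_tracks = ann.cluster_annotations(bench.annotations.epigenome_tracks, 11)
    X_new, stats_h = build_features(
        stats_new, bench.panel, bench.annotations, meta_tracks=meta_tracks, alpha=alpha
    )
    prob = deep_nn.transfer_apply(run.model, X_new)
    return stats_h.assign(prob=prob)[["chrom", "pos", "key", "prob", "p_value"]]


def summarize_run(run: EnhancementRun, bench: Benchmark,
                  merge_bp: int = evaluation.MERGE_BP_DEFAULT) -> dict:
    """Benchmark-level summary: enhancement counts, locus TPRs, causal AUROC."""
    model_loci = run.enhancement.predicted_loci
    lm_model = evaluation.locus_metrics(model_loci, run.truth_loci, slack_bp=merge_bp)
    lm_input = evaluation.locus_metrics(run.baseline_loci, run.truth_loci,
                                        slack_bp=merge_bp)

    causal_keys = set(bench.truth.causal_keys)
    b_sig_keys = set(run.stats_b.loc[run.stats_b["p_value"] < 5e-8, "key"])
    novel_causal = [
        locus
        for locus in run.enhancement.enhanced_loci
        if any(m in causal_keys and m not in b_sig_keys for m in locus.members)
    ]
    key_to_causal = dict(zip(bench.panel.variants["key"], bench.truth.causal_mask))
    truth_vec = run.predictions["key"].map(key_to_causal).to_numpy(dtype=bool)
    vm = evaluation.variant_metrics(run.predictions["prob"].to_numpy(), truth_vec)
    validated = evaluation.match_loci(
        run.enhancement.enhanced_loci, run.truth_loci, slack_bp=merge_bp
    )
    return {
        "n_enhanced_loci": run.n_enhanced_loci,
        "n_enhanced_loci_causal": len(novel_causal),
        "n_enhanced_validated": int(validated.sum()),
        "locus_tpr_model": lm_model["tpr"],
        "locus_tpr_input": lm_input["tpr"],
        "locus_f1_model": lm_model["f1"],
        "locus_f1_input": lm_input["f1"],
        "auroc_vs_causal": vm["auroc"],
        "n_input_loci": len(run.baseline_loci),
        "n_truth_loci": len(run.truth_loci),
        "trained": run.trained,
    }
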