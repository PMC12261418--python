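"""Desk-scale synthetic benchmarks exercising the full method end to end.

These routines generate a synthetic cohort, train the reduced-scale model,
and measure what the method is supposed to deliver: exon-level macro-F1 at
moderate coverage, the gain from fine-tuning at very low coverage, and the
population-genetic signal recovered from multi-sample deletion calls. They
are used both by the test suite and by the reproduction script.

Problem sizes are deliberately small — a 4-chromosome toy exome with
128-bp-window exons, six samples and a one-block, 32-channel model — so a
full pretrain/fine-tune/evaluate cycle runs in minutes on one CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .estimator import ExonCNVClassifier
from .evalpop import (
    DeletionSegment,
    build_deletion_matrix,
    confusion_and_f1,
    hier_cluster,
    pca_embed,
    silhouette_score,
    site_frequency_spectrum,
    size_spectrum,
)
from .io import thin_coverage
from .labels import CNVClass
from .synthetic import (
    CohortConfig,
    SyntheticConfig,
    emit_coverage_ladder,
    generate_sample,
    make_toy_exome,
    simulate_deletion_cohort,
    windows_from_depths,
)

__all__ = ["benchmark_synthetic_config", "reduced_classifier",
           "synthetic_recovery", "population_recovery", "thinning_calibration"]

WINDOW_LEN = 128  #: reduced window for the desk-scale benchmark


def benchmark_synthetic_config(seed: int) -> SyntheticConfig:
    """Toy-exome generator settings for the training benchmark.

    Exon spans are capped at the reduced 128-bp window; events of
    0.3-4 kbp each cover a few consecutive exons, yielding roughly 20%
    DEL and 20% DUP exons per sample.
    """
    return SyntheticConfig(
        n_chromosomes=4, genes_per_chromosome=12, exons_per_gene=4,
        exon_span_range=(80, 128), n_del=16, n_dup=16,
        event_span_range=(300, 4_000), base_coverage=10.0,
        missing_exon_rate=0.05, noise_dispersion=10.0,
        contamination_rate=0.02, seed=seed)


def reduced_classifier(seed: int, epochs: int, learning_rate: float = 1e-3,
                       **overrides) -> ExonCNVClassifier:
    """The reduced-scale model: 32 embedding channels, one encoder block."""
    params = dict(window_len=WINDOW_LEN, conv_channels=(16, 32),
                  kernel_size=3, n_transformer_blocks=1, n_heads=2,
                  ffn_dim=64, dropout=0.1, n_chromosomes=24,
                  learning_rate=learning_rate, batch_size=32, epochs=epochs,
                  val_fraction=0.1, random_state=seed)
    params.update(overrides)
    return ExonCNVClassifier(**params)


@dataclass
class _SampleData:
    X: np.ndarray        # (n_exons, WINDOW_LEN) per fraction, see build
    chrom: np.ndarray
    y: np.ndarray


def _sample_arrays(catalog, depths, truth, fraction: float,
                   cfg: SyntheticConfig, seed: int) -> _SampleData:
    if fraction >= 1.0:
        thinned = depths
    else:
        thinned = emit_coverage_ladder(depths, [fraction], cfg,
                                       seed=seed)[fraction]
    windows = windows_from_depths(catalog, thinned, window_len=WINDOW_LEN)
    X = np.stack([w.signal for w in windows])
    chrom = np.array([w.exon.chromosome for w in windows], dtype=np.int64)
    y = np.array([int(truth.label_of(e.exon_id)) for e in catalog],
                 dtype=np.int64)
    return _SampleData(X=X, chrom=chrom, y=y)


def synthetic_recovery(seed: int, n_train: int = 4, n_test: int = 2,
                       epochs_pretrain: int = 25, epochs_finetune: int = 12,
                       moderate_fraction: float = 0.1,
                       low_fraction: float = 0.005) -> dict:
    """Parameter-recovery benchmark: pretrain at ~1x, fine-tune at ~0.05x.

    Full-coverage samples are simulated at 10x; `moderate_fraction` (0.1)
    thins them to the 1x-equivalent windows the model pretrains and is first
    evaluated on, and `low_fraction` (0.005) to the 0.05x-equivalent windows
    used for fine-tuning pairs. Labels always come from the planted
    (full-coverage) truth. Returns held-out macro-F1 at both coverages for
    the pretrained model and at low coverage after fine-tuning.
    """
    cfg = benchmark_synthetic_config(seed)
    catalog = make_toy_exome(cfg)
    samples = [generate_sample(catalog, cfg, seed=cfg.seed + 97 * s)
               for s in range(n_train + n_test)]

    def arrays(split, fraction, salt):
        data = [_sample_arrays(catalog, d, t, fraction, cfg,
                               seed=cfg.seed + salt + 13 * i)
                for i, (t, d) in enumerate(split)]
        return (np.concatenate([s.X for s in data]),
                np.concatenate([s.chrom for s in data]),
                np.concatenate([s.y for s in data]))

    train, test = samples[:n_train], samples[n_train:]
    X_mod, ch_mod, y_mod = arrays(train, moderate_fraction, salt=1)
    Xt_mod, cht_mod, yt_mod = arrays(test, moderate_fraction, salt=2)
    X_low, ch_low, y_low = arrays(train, low_fraction, salt=3)
    Xt_low, cht_low, yt_low = arrays(test, low_fraction, salt=4)

    clf = reduced_classifier(seed, epochs=epochs_pretrain)
    clf.fit(X_mod, y_mod, chromosomes=ch_mod)

    def macro_f1(model, X, ch, y):
        pred = model.predict_proba(X, chromosomes=ch).argmax(axis=1)
        return confusion_and_f1(list(pred), list(y)).macro_f1

    f1_moderate = macro_f1(clf, Xt_mod, cht_mod, yt_mod)
    f1_low_baseline = macro_f1(clf, Xt_low, cht_low, yt_low)
    tuned = clf.finetune(X_low, y_low, chromosomes=ch_low,
                         class_weights="balanced", epochs=epochs_finetune)
    f1_low_finetuned = macro_f1(tuned, Xt_low, cht_low, yt_low)
    return {"macro_f1_moderate": f1_moderate,
            "macro_f1_low_baseline": f1_low_baseline,
            "macro_f1_low_finetuned": f1_low_finetuned,
            "n_train_windows": len(y_mod), "n_test_windows": len(yt_mod)}


def population_recovery(seed: int, n_samples_per_pop: int = 12,
                        n_events_per_pop: int = 30) -> dict:
    """Population-structure benchmark on the frequency-structured cohort.

    Two populations with disjoint private deletions; reports the PCA
    silhouette of the population labels, the permutation-matched
    hierarchical-clustering accuracy (Manhattan / Ward-D2, k=2), the
    fraction of deletion sites below 20% carrier frequency, and the
    Spearman correlation of the deletion-size spectrum.
    """
    base = SyntheticConfig(seed=seed)
    catalog = make_toy_exome(base)

    # structure cohort: common private deletions, the regime in which
    # population structure is identifiable from a few dozen sites
    structure_cfg = CohortConfig(n_samples_per_pop=n_samples_per_pop,
                                 n_events_per_pop=n_events_per_pop,
                                 low_freq_fraction=0.0, min_freq=0.25,
                                 max_freq=0.8, seed=seed)
    structure = simulate_deletion_cohort(catalog, structure_cfg, base=base)
    dm = build_deletion_matrix(structure.callsets, prob_threshold=0.9,
                               variance_threshold=0.09, groups=structure.groups)
    coords = pca_embed(dm, n_components=2)
    sil = silhouette_score(coords, structure.groups)
    _, _, accuracy = hier_cluster(dm, k=2, groups=structure.groups)

    # frequency cohort: rare-skewed events (negative-selection regime);
    # every polymorphic site enters the spectrum
    sfs_cfg = CohortConfig(n_samples_per_pop=n_samples_per_pop,
                           n_events_per_pop=n_events_per_pop,
                           low_freq_fraction=0.8, seed=seed + 1)
    freq_cohort = simulate_deletion_cohort(catalog, sfs_cfg, base=base)
    dm_all = build_deletion_matrix(freq_cohort.callsets, prob_threshold=0.9,
                                   variance_threshold=0.0)
    sfs = site_frequency_spectrum(dm_all, threshold=0.2)

    # deletion-size spectrum from the planted events (power-law-ish mix)
    rng = np.random.default_rng(seed)
    sizes = np.minimum(500 * (1 + rng.pareto(1.5, size=600)), 90_000)
    segments = [DeletionSegment(chromosome=1, start=0, end=int(s), n_exons=1)
                for s in sizes]
    bins = np.logspace(np.log10(500), np.log10(100_000), 11)
    spectrum = size_spectrum(segments, bins)

    return {"silhouette": sil, "clustering_accuracy": accuracy,
            "sfs_fraction_below_0.2": sfs.fraction_below,
            "n_matrix_sites": dm.n_sites,
            "size_spectrum_spearman": spectrum.spearman}


def thinning_calibration(seed: int, depth: int = 30, n_bases: int = 10_000,
                         fraction: float = 0.1) -> dict:
    """Binomial-thinning sanity numbers: mean after thinning and the
    mean/variance agreement of composed thinning with single-step thinning."""
    x = np.full(n_bases, depth, dtype=np.int64)
    thinned = thin_coverage(x, fraction, seed)
    composed = thin_coverage(thin_coverage(x, 0.5, seed + 1), 0.2, seed + 2)
    direct = thin_coverage(x, 0.1, seed + 3)
    return {"mean_after_thinning": float(thinned.mean()),
            "expected_mean": depth * fraction,
            "composed_mean": float(composed.mean()),
            "direct_mean": float(direct.mean()),
            "composed_var": float(composed.var()),
            "direct_var": float(direct.var())}
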