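"""Metrics, deletion-matrix filters, ordination, clustering and spectra."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from exocnv.calling import CallSet, ExonCall
from exocnv.evalpop import (
    DeletionMatrix,
    DeletionSegment,
    build_deletion_matrix,
    confusion_and_f1,
    hier_cluster,
    linkage_to_newick,
    merge_deletion_segments,
    pca_embed,
    silhouette_score,
    site_frequency_spectrum,
    size_spectrum,
)
from exocnv.io import ExonCatalog, ExonDef
from exocnv.labels import CNVClass


# ---------------------------------------------------------------------------
# confusion / F1
# ---------------------------------------------------------------------------

def test_perfect_predictions():
    y = [0, 1, 2, 1, 0, 2]
    m = confusion_and_f1(y, y)
    for cls in ("DEL", "DUP"):
        assert m.per_class[cls].precision == m.per_class[cls].recall == 1.0
    assert m.macro_f1 == 1.0


def test_hand_computed_del_metrics():
    # DEL: TP=2, FP=1, FN=1
    truth = ["DEL", "DEL", "DEL", "NOCALL", "NOCALL", "DUP"]
    pred = ["DEL", "DEL", "NOCALL", "DEL", "NOCALL", "DUP"]
    m = confusion_and_f1(pred, truth)
    d = m.per_class["DEL"]
    assert (d.tp, d.fp, d.fn) == (2, 1, 1)
    assert d.precision == pytest.approx(2 / 3)
    assert d.recall == pytest.approx(2 / 3)
    assert d.f1 == pytest.approx(2 / 3)


def test_absent_class_f1_is_zero():
    m = confusion_and_f1(["NOCALL", "NOCALL"], ["NOCALL", "NOCALL"])
    assert m.per_class["DEL"].f1 == 0.0
    assert m.macro_f1 == 0.0


def test_length_mismatch_rejected():
    with pytest.raises(ValueError):
        confusion_and_f1([0], [0, 1])


def test_f1_matches_brute_force_on_random_labels():
    rng = np.random.default_rng(0)
    for _ in range(100):
        n = int(rng.integers(3, 40))
        truth = rng.integers(0, 3, size=n)
        pred = rng.integers(0, 3, size=n)
        m = confusion_and_f1(list(pred), list(truth))
        for cls, name in ((1, "DEL"), (2, "DUP")):
            tp = fp = fn = 0
            for p, t in zip(pred, truth):
                tp += p == cls and t == cls
                fp += p == cls and t != cls
                fn += p != cls and t == cls
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert m.per_class[name].f1 == pytest.approx(f1)


# ---------------------------------------------------------------------------
# deletion matrix
# ---------------------------------------------------------------------------

def callset_from_probs(sample_id, p_del_rows):
    calls = []
    for i, p_del in enumerate(p_del_rows):
        label = CNVClass.DEL if p_del > 0.5 else CNVClass.NOCALL
        probs = np.array([1 - p_del - 0.001, p_del, 0.001])
        calls.append(ExonCall(f"e{i}", probs, label))
    return CallSet(sample_id=sample_id, calls=calls)


def test_matrix_filters():
    # site 0: all carriers (variance 0) -> dropped
    # site 1: half carriers (population variance exactly 0.25) -> dropped
    # site 2: 0.85-confidence call counts as 0 -> monomorphic -> dropped
    # site 3: 1/4 carriers (variance 0.1875) -> kept at threshold 0.09
    rows = [
        [0.99, 0.99, 0.85, 0.99],
        [0.99, 0.99, 0.0, 0.0],
        [0.99, 0.0, 0.0, 0.0],
        [0.99, 0.0, 0.0, 0.0],
    ]
    callsets = [callset_from_probs(f"s{i}", r) for i, r in enumerate(rows)]
    dm = build_deletion_matrix(callsets, prob_threshold=0.9,
                               variance_threshold=0.09)
    assert dm.site_exon_ids == ["e1", "e3"]
    np.testing.assert_array_equal(dm.matrix[:, 0], [1, 1, 0, 0])
    dm_strict = build_deletion_matrix(callsets, prob_threshold=0.9,
                                      variance_threshold=0.25)
    assert dm_strict.n_sites == 0  # 0.25 unattainable with divide-by-n variance
    dm_r = build_deletion_matrix(callsets, prob_threshold=0.9,
                                 variance_threshold=0.25, ddof=1)
    assert "e1" in dm_r.site_exon_ids  # R-style variance 1/3 > 0.25


def test_matrix_requires_aligned_catalogs():
    a = callset_from_probs("a", [0.99, 0.0])
    b = callset_from_probs("b", [0.99, 0.0, 0.0])
    with pytest.raises(ValueError):
        build_deletion_matrix([a, b])
    with pytest.raises(ValueError):
        build_deletion_matrix([a])


def test_matrix_frequencies_are_column_means():
    rows = [[0.99, 0.99], [0.99, 0.0], [0.0, 0.0], [0.99, 0.0]]
    dm = build_deletion_matrix([callset_from_probs(f"s{i}", r)
                                for i, r in enumerate(rows)],
                               variance_threshold=0.0)
    np.testing.assert_allclose(sorted(dm.frequencies), [0.25, 0.75])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def test_pca_separates_anticorrelated_groups():
    X = np.array([[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]],
                 dtype=float)
    coords = pca_embed(X, n_components=2)
    pc1 = coords[:, 0]
    assert np.sign(pc1[0]) == np.sign(pc1[1]) != np.sign(pc1[2])
    # duplicated rows land on identical coordinates
    np.testing.assert_allclose(coords[0], coords[1], atol=1e-12)


def test_pca_variance_conservation():
    rng = np.random.default_rng(1)
    X = (rng.random((10, 7)) > 0.5).astype(float)
    sd = X.std(axis=0, ddof=1)
    n_kept = int((sd > 0).sum())
    coords = pca_embed(X, n_components=min(9, n_kept))
    pc_var = coords.var(axis=0, ddof=1)
    assert pc_var.sum() == pytest.approx(n_kept, rel=1e-9)


def test_pca_sign_convention_deterministic():
    rng = np.random.default_rng(2)
    X = (rng.random((8, 6)) > 0.5).astype(float)
    np.testing.assert_array_equal(pca_embed(X, 2), pca_embed(X, 2))


def test_pca_too_few_sites_rejected():
    X = np.array([[1.0, 1.0], [0.0, 1.0], [1.0, 1.0]])  # one variable column
    with pytest.raises(ValueError):
        pca_embed(X, n_components=2)


# ---------------------------------------------------------------------------
# silhouette
# ---------------------------------------------------------------------------

def test_silhouette_separated_vs_interleaved():
    tight = np.array([[0, 0], [0.1, 0], [5, 5], [5.1, 5]])
    assert silhouette_score(tight, ["a", "a", "b", "b"]) > 0.5
    inter = np.array([[0, 0], [1, 1], [0.05, 0], [1.05, 1]])
    assert silhouette_score(inter, ["a", "a", "b", "b"]) <= 0.05
    same = np.zeros((4, 2))
    assert silhouette_score(same, ["a", "b", "a", "b"]) <= 0.0


def test_silhouette_single_group_rejected():
    with pytest.raises(ValueError):
        silhouette_score(np.zeros((3, 2)), ["a", "a", "a"])


# ---------------------------------------------------------------------------
# hierarchical clustering
# ---------------------------------------------------------------------------

def brute_force_ward_d2_heights(X):
    """Independent Ward-D2 agglomeration via the Lance-Williams update on
    Manhattan dissimilarities, returning sorted merge heights."""
    d2 = {}
    active = {i: 1 for i in range(len(X))}  # cluster -> size
    D = squareform(pdist(X, metric="cityblock"))
    for i in range(len(X)):
        for j in range(i + 1, len(X)):
            d2[(i, j)] = D[i, j] ** 2
    heights = []
    nxt = len(X)
    while len(active) > 1:
        (a, b), best = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(np.sqrt(best))
        na, nb = active[a], active[b]
        merged = {}
        for c in active:
            if c in (a, b):
                continue
            nc = active[c]
            dac = d2[tuple(sorted((a, c)))]
            dbc = d2[tuple(sorted((b, c)))]
            dab = best
            merged[c] = ((na + nc) * dac + (nb + nc) * dbc - nc * dab) \
                / (na + nb + nc)
        del active[a], active[b]
        d2 = {k: v for k, v in d2.items()
              if a not in k and b not in k}
        for c, v in merged.items():
            d2[tuple(sorted((c, nxt)))] = v
        active[nxt] = na + nb
        nxt += 1
    return heights


def test_ward_d2_merge_heights_match_brute_force():
    rng = np.random.default_rng(3)
    X = (rng.random((7, 9)) > 0.5).astype(float)
    _, Z, _ = hier_cluster(X, k=2)
    np.testing.assert_allclose(sorted(Z[:, 2]),
                               sorted(brute_force_ward_d2_heights(X)),
                               rtol=1e-9)


def test_disjoint_profiles_cluster_perfectly():
    X = np.array([[1, 1, 1, 0, 0, 0]] * 4 + [[0, 0, 0, 1, 1, 1]] * 4,
                 dtype=float)
    groups = ["w"] * 4 + ["e"] * 4
    _, _, acc = hier_cluster(X, k=2, groups=groups)
    assert acc == 1.0


def test_accuracy_invariant_under_label_renaming():
    rng = np.random.default_rng(4)
    X = (rng.random((10, 12)) > 0.5).astype(float)
    groups = ["a"] * 5 + ["b"] * 5
    _, _, acc1 = hier_cluster(X, k=2, groups=groups)
    renamed = ["zzz" if g == "a" else "aaa" for g in groups]
    _, _, acc2 = hier_cluster(X, k=2, groups=renamed)
    assert acc1 == acc2


def test_permuted_labels_drop_to_chance():
    X = np.array([[1, 1, 1, 0, 0, 0]] * 6 + [[0, 0, 0, 1, 1, 1]] * 6,
                 dtype=float)
    groups = np.array(["w"] * 6 + ["e"] * 6)
    rng = np.random.default_rng(5)
    accs = []
    for _ in range(200):
        perm = rng.permutation(len(groups))
        _, _, acc = hier_cluster(X, k=2, groups=list(groups[perm]))
        accs.append(acc)
    # null expectation near max class proportion (0.5 here, plus
    # the positive bias of maximizing over matchings)
    assert 0.5 <= np.mean(accs) < 0.72


def test_k_exceeding_samples_rejected():
    with pytest.raises(ValueError):
        hier_cluster(np.zeros((3, 2)), k=4)


def test_newick_export_parses():
    X = np.array([[1, 1, 0, 0], [1, 0, 0, 0], [0, 0, 1, 1], [0, 0, 1, 0]],
                 dtype=float)
    _, Z, _ = hier_cluster(X, k=2)
    nwk = linkage_to_newick(Z, ["s1", "s2", "s3", "s4"])
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(nwk), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == \
        ["s1", "s2", "s3", "s4"]


# ---------------------------------------------------------------------------
# segments and spectra
# ---------------------------------------------------------------------------

def segment_catalog(positions, chromosome=1, span=100):
    return ExonCatalog([ExonDef(f"e{i}", f"g{i}", chromosome, p, p + span)
                        for i, p in enumerate(positions)])


def callset_with_labels(catalog, labels):
    calls = [ExonCall(e.exon_id,
                      np.array([0.01, 0.98, 0.01]) if l == CNVClass.DEL
                      else np.array([0.98, 0.01, 0.01]), l)
             for e, l in zip(catalog, labels)]
    return CallSet(sample_id="s", calls=calls)


def test_consecutive_dels_merge_to_one_segment():
    cat = segment_catalog([0, 200, 400])
    cs = callset_with_labels(cat, [CNVClass.DEL] * 3)
    segs = merge_deletion_segments(cs, cat)
    assert len(segs) == 1
    assert (segs[0].start, segs[0].end, segs[0].n_exons) == (0, 500, 3)


def test_segments_never_cross_chromosomes():
    exons = [ExonDef("a", "g", 1, 0, 100), ExonDef("b", "g", 2, 0, 100)]
    cat = ExonCatalog(exons)
    cs = callset_with_labels(cat, [CNVClass.DEL, CNVClass.DEL])
    assert len(merge_deletion_segments(cs, cat)) == 2


def test_max_gap_splits_segments():
    cat = segment_catalog([0, 5_100, 10_200])  # 5 kb gaps between exons
    cs = callset_with_labels(cat, [CNVClass.DEL] * 3)
    assert len(merge_deletion_segments(cs, cat, max_gap=1_000)) == 3
    assert len(merge_deletion_segments(cs, cat, max_gap=6_000)) == 1


def test_nondel_exon_breaks_run_and_autosome_filter():
    exons = [ExonDef("a", "g", 1, 0, 100), ExonDef("b", "g", 1, 200, 300),
             ExonDef("c", "g", 1, 400, 500), ExonDef("x", "h", 23, 0, 100)]
    cat = ExonCatalog(exons)
    cs = callset_with_labels(cat, [CNVClass.DEL, CNVClass.NOCALL,
                                   CNVClass.DEL, CNVClass.DEL])
    segs = merge_deletion_segments(cs, cat, autosome_only=True)
    assert len(segs) == 2
    assert all(s.chromosome == 1 for s in segs)


def test_sfs_counting():
    dm = DeletionMatrix(matrix=np.zeros((10, 3), dtype=np.int8),
                        sample_ids=[f"s{i}" for i in range(10)],
                        site_exon_ids=["a", "b", "c"],
                        frequencies=np.array([0.1, 0.1, 0.3]))
    sfs = site_frequency_spectrum(dm, bin_width=0.05, threshold=0.2)
    assert sfs.fraction_below == pytest.approx(2 / 3)
    assert sfs.counts.sum() == 3
    dm_fixed = DeletionMatrix(matrix=np.ones((4, 2), dtype=np.int8),
                              sample_ids=list("abcd"),
                              site_exon_ids=["a", "b"],
                              frequencies=np.array([1.0, 1.0]))
    assert site_frequency_spectrum(dm_fixed).fraction_below == 0.0


def test_size_spectrum_monotone_and_degenerate():
    segs = [DeletionSegment(1, 0, size, 1)
            for size, n in ((100, 8), (1_000, 4), (10_000, 2)) for _ in range(n)]
    bins = np.array([50, 500, 5_000, 50_000])
    spectrum = size_spectrum(segs, bins)
    assert spectrum.spearman == pytest.approx(-1.0)
    flat = [DeletionSegment(1, 0, s, 1) for s in (100, 1_000, 10_000)]
    assert size_spectrum(flat, bins).degenerate


def test_power_law_sizes_give_strong_negative_spearman():
    bins = np.logspace(np.log10(500), np.log10(100_000), 11)
    for seed in (0, 1, 2):
        rng = np.random.default_rng(seed)
        sizes = np.minimum(500 * (1 + rng.pareto(1.5, size=500)), 90_000)
        segs = [DeletionSegment(1, 0, int(s), 1) for s in sizes]
        assert size_spectrum(segs, bins).spearman < -0.8
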