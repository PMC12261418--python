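"""Performance metrics and population-genetic analyses of deletion calls.

Exon- and gene-level calls are scored one-vs-rest (precision/recall/F1 for
DEL and DUP; macro-F1 averages the two). Multi-sample deletion calls are
assembled into a binary samples x exon-sites matrix (confident, variable
sites only) that feeds PCA, silhouette, hierarchical clustering
(Manhattan distance, Ward-D2 linkage), the site frequency spectrum and the
deletion-size spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from scipy.stats import spearmanr

from .calling import CallSet
from .io import ExonCatalog
from .labels import CNVClass

__all__ = ["ConfusionMetrics", "DeletionMatrix", "DeletionSegment",
           "confusion_and_f1", "build_deletion_matrix", "pca_embed",
           "silhouette_score", "hier_cluster", "merge_deletion_segments",
           "site_frequency_spectrum", "size_spectrum", "linkage_to_newick"]


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

@dataclass
class ClassMetrics:
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    f1: float


@dataclass
class ConfusionMetrics:
    per_class: dict[str, ClassMetrics]
    macro_f1: float


def _as_class(v) -> CNVClass:
    if isinstance(v, CNVClass):
        return v
    if isinstance(v, str):
        return CNVClass[v]
    return CNVClass(int(v))


def confusion_and_f1(pred, truth) -> ConfusionMetrics:
    """One-vs-rest precision/recall/F1 for DEL and DUP over aligned units.

    Zero-denominator convention: precision/recall default to 0, and F1 is 0
    whenever precision + recall is 0.
    """
    if len(pred) != len(truth):
        raise ValueError(f"length mismatch: {len(pred)} vs {len(truth)}")
    p = np.array([int(_as_class(v)) for v in pred])
    t = np.array([int(_as_class(v)) for v in truth])
    per_class = {}
    f1s = []
    for cls in (CNVClass.DEL, CNVClass.DUP):
        c = int(cls)
        tp = int(np.sum((p == c) & (t == c)))
        fp = int(np.sum((p == c) & (t != c)))
        fn = int(np.sum((p != c) & (t == c)))
        tn = int(np.sum((p != c) & (t != c)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[cls.name] = ClassMetrics(tp, fp, fn, tn, prec, rec, f1)
        f1s.append(f1)
    return ConfusionMetrics(per_class=per_class, macro_f1=float(np.mean(f1s)))


# ---------------------------------------------------------------------------
# deletion matrix
# ---------------------------------------------------------------------------

@dataclass
class DeletionMatrix:
    """Binary samples x exon-sites deletion indicators after filtering."""

    matrix: np.ndarray           # (n_samples, n_sites) of {0,1}
    sample_ids: list[str]
    site_exon_ids: list[str]
    frequencies: np.ndarray      # per-site carrier frequency (column mean)
    groups: list[str] | None = None

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]


def build_deletion_matrix(callsets: list[CallSet], prob_threshold: float = 0.9,
                          variance_threshold: float = 0.25, ddof: int = 0,
                          groups: list[str] | None = None) -> DeletionMatrix:
    """High-confidence, variable deletion indicators across samples.

    Entry (s, e) is 1 iff sample s calls DEL at exon e with
    P(DEL) > prob_threshold (strict). Sites are retained iff the
    cross-sample variance of the indicator exceeds variance_threshold
    (strict; divide-by-n variance by default, ddof=1 for the R-style
    sample variance).
    """
    if len(callsets) < 2:
        raise ValueError("need at least two call sets")
    exon_ids = [c.exon_id for c in callsets[0].calls]
    for cs in callsets[1:]:
        if [c.exon_id for c in cs.calls] != exon_ids:
            raise ValueError("call sets are over mismatched catalogs")
    mat = np.zeros((len(callsets), len(exon_ids)), dtype=np.int8)
    for s, cs in enumerate(callsets):
        for e, call in enumerate(cs.calls):
            if (call.label == CNVClass.DEL
                    and call.probabilities[int(CNVClass.DEL)] > prob_threshold):
                mat[s, e] = 1
    var = mat.astype(np.float64).var(axis=0, ddof=ddof)
    keep = var > variance_threshold
    kept = mat[:, keep]
    return DeletionMatrix(
        matrix=kept, sample_ids=[cs.sample_id for cs in callsets],
        site_exon_ids=[eid for eid, k in zip(exon_ids, keep) if k],
        frequencies=kept.mean(axis=0), groups=groups)


# ---------------------------------------------------------------------------
# ordination and clustering
# ---------------------------------------------------------------------------

def pca_embed(matrix: DeletionMatrix | np.ndarray, n_components: int = 2) -> np.ndarray:
    """PCA of the centered, unit-variance-scaled site indicators.

    Constant columns (zero variance) are removed before scaling. Component
    signs are fixed by making the largest-magnitude loading entry of each
    component positive, so embeddings are reproducible.
    """
    X = matrix.matrix if isinstance(matrix, DeletionMatrix) else np.asarray(matrix)
    X = X.astype(np.float64)
    if X.shape[0] < 2:
        raise ValueError("need at least two samples")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    X = X[:, keep]
    if X.shape[1] < n_components:
        raise ValueError(f"only {X.shape[1]} variable sites for "
                         f"{n_components} components")
    Z = (X - X.mean(axis=0)) / X[:, :].std(axis=0, ddof=1)
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    for i in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1
            U[:, i] *= -1
    return (U * S)[:, :n_components]


def silhouette_score(coords: np.ndarray, groups: list[str],
                     metric: str = "euclidean") -> float:
    """Mean silhouette of the samples in PCA space (first two components)."""
    from sklearn.metrics import silhouette_score as _sk_sil

    groups = list(groups)
    if len(set(groups)) < 2:
        raise ValueError("silhouette needs at least two groups")
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim != 2:
        raise ValueError("coords must be 2-D")
    return float(_sk_sil(coords[:, :2], groups, metric=metric))


def hier_cluster(matrix: DeletionMatrix | np.ndarray, k: int,
                 groups: list[str] | None = None):
    """Agglomerative clustering: Manhattan distances, Ward-D2 linkage.

    Returns (assignments, linkage_matrix, accuracy); accuracy (None without
    groups) is the best matching fraction over all assignments of cluster
    ids to group labels.
    """
    X = matrix.matrix if isinstance(matrix, DeletionMatrix) else np.asarray(matrix)
    X = X.astype(np.float64)
    if groups is None and isinstance(matrix, DeletionMatrix):
        groups = matrix.groups
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds {X.shape[0]} samples")
    dist = pdist(X, metric="cityblock")
    Z = hierarchy.linkage(dist, method="ward")
    assignments = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    accuracy = None
    if groups is not None:
        accuracy = _permutation_accuracy(assignments, list(groups))
    return assignments, Z, accuracy


def _permutation_accuracy(assignments: np.ndarray, groups: list[str]) -> float:
    """Max fraction of samples matched under any cluster->group relabeling."""
    from scipy.optimize import linear_sum_assignment

    clusters = sorted(set(assignments))
    labels = sorted(set(groups))
    cont = np.zeros((len(clusters), len(labels)))
    for a, g in zip(assignments, groups):
        cont[clusters.index(a), labels.index(g)] += 1
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum() / len(groups))


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick tree string."""
    tree = hierarchy.to_tree(Z)

    def render(node) -> str:
        if node.is_leaf():
            return leaf_names[node.id]
        left, right = render(node.left), render(node.right)
        dl = node.dist - node.left.dist
        dr = node.dist - node.right.dist
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return render(tree) + ";"


# ---------------------------------------------------------------------------
# segmental deletions, SFS and size spectrum
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeletionSegment:
    chromosome: int
    start: int
    end: int
    n_exons: int

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("segment end <= start")

    @property
    def size(self) -> int:
        return self.end - self.start


def merge_deletion_segments(callset: CallSet, catalog: ExonCatalog,
                            max_gap: float = np.inf,
                            autosome_only: bool = False) -> list[DeletionSegment]:
    """Merge maximal runs of consecutive DEL-labeled exons into segments.

    Runs never cross chromosomes; a run breaks when the genomic gap between
    successive DEL exons exceeds `max_gap` or a non-DEL exon intervenes.
    """
    if len(callset.calls) != len(catalog):
        raise ValueError("callset not aligned to catalog")
    segments: list[DeletionSegment] = []
    run: list = []

    def flush():
        if run:
            segments.append(DeletionSegment(
                chromosome=run[0].chromosome, start=run[0].start,
                end=run[-1].end, n_exons=len(run)))
            run.clear()

    for exon, call in zip(catalog, callset.calls):
        if autosome_only and exon.chromosome > 22:
            flush()
            continue
        if call.label != CNVClass.DEL:
            flush()
            continue
        if run and (exon.chromosome != run[-1].chromosome
                    or exon.start - run[-1].end > max_gap):
            flush()
        run.append(exon)
    flush()
    return segments


@dataclass
class SFSResult:
    bin_edges: np.ndarray
    counts: np.ndarray
    fraction_below: float
    threshold: float


def site_frequency_spectrum(matrix: DeletionMatrix, bin_width: float = 0.05,
                            threshold: float = 0.2) -> SFSResult:
    """Histogram of per-site carrier frequencies over (0, 1].

    Also reports the fraction of retained sites with frequency strictly
    below `threshold` — an excess of rare deletions is the signature of
    negative selection.
    """
    if matrix.n_sites == 0:
        raise ValueError("empty deletion matrix")
    freqs = matrix.frequencies
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    counts, _ = np.histogram(freqs, bins=edges)
    return SFSResult(bin_edges=edges, counts=counts,
                     fraction_below=float(np.mean(freqs < threshold)),
                     threshold=threshold)


@dataclass
class SizeSpectrum:
    bin_edges: np.ndarray
    counts: np.ndarray
    spearman: float          # NaN when degenerate
    degenerate: bool


def size_spectrum(segments: list[DeletionSegment],
                  bins: np.ndarray) -> SizeSpectrum:
    """Counts of deletion segments per size bin, plus the Spearman rank
    correlation between bin midpoint and count (negative under a
    size-biased deficit of long deletions)."""
    sizes = np.array([s.size for s in segments])
    bins = np.asarray(bins, dtype=np.float64)
    counts, _ = np.histogram(sizes, bins=bins)
    nonempty = counts > 0
    if nonempty.sum() < 2 or len(set(counts.tolist())) < 2:
        return SizeSpectrum(bin_edges=bins, counts=counts,
                            spearman=float("nan"), degenerate=True)
    mids = 0.5 * (bins[:-1] + bins[1:])
    rho = spearmanr(mids, counts).statistic
    return SizeSpectrum(bin_edges=bins, counts=counts,
                        spearman=float(rho), degenerate=False)
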