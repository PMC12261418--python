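"""Exon catalogs, per-base read depth, window construction and coverage thinning.

Coordinates are BED-style 0-based half-open everywhere. Chromosome names are
normalized to integers 1..24 (23 = X, 24 = Y); a leading "chr" prefix is
stripped on input.

An exon's model input is its per-base read depth, divided by the sample's
mean per-base depth (so the diploid baseline sits near 1) and right-padded
with zeros to a fixed window length. Exons longer than the window are
discarded at catalog load time.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOW_LEN = 1000  #: default maximum exon span / padded window length

__all__ = [
    "WINDOW_LEN", "ExonDef", "ExonCatalog", "ExonWindow", "SampleManifest",
    "normalize_chromosome", "chromosome_name", "load_exon_catalog",
    "write_catalog", "open_depth_source", "DepthSource", "extract_raw_depth",
    "sample_mean_depth", "normalize_signal", "build_window", "thin_coverage",
    "load_manifest",
]

_SPECIAL_CHROMS = {"X": 23, "Y": 24}
_SPECIAL_NAMES = {23: "X", 24: "Y"}


def normalize_chromosome(name: str | int) -> int:
    """Map "chr1".."chr22"/"chrX"/"chrY" (or bare) to an integer in 1..24."""
    s = str(name)
    if s.lower().startswith("chr"):
        s = s[3:]
    if s.upper() in _SPECIAL_CHROMS:
        return _SPECIAL_CHROMS[s.upper()]
    try:
        ch = int(s)
    except ValueError as exc:
        raise ValueError(f"unrecognized chromosome name: {name!r}") from exc
    if not 1 <= ch <= 24:
        raise ValueError(f"chromosome {ch} outside 1..24")
    return ch


def chromosome_name(ch: int) -> str:
    return _SPECIAL_NAMES.get(ch, str(ch))


@dataclass(frozen=True)
class ExonDef:
    exon_id: str
    gene_id: str
    chromosome: int  # 1..24; 23=X, 24=Y
    start: int       # 0-based inclusive
    end: int         # 0-based exclusive

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.exon_id}: end {self.end} <= start {self.start}")
        if not 1 <= self.chromosome <= 24:
            raise ValueError(f"{self.exon_id}: chromosome {self.chromosome} out of range")

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)


@dataclass
class ExonCatalog:
    """Ordered exon set, sorted by (chromosome, start), with a gene index."""

    exons: list[ExonDef]
    gene_index: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.exons:
            raise ValueError("empty exon catalog")
        self.exons = sorted(self.exons, key=lambda e: (e.chromosome, e.start))
        ids = [e.exon_id for e in self.exons]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate exon_id in catalog")
        if not self.gene_index:
            gi: dict[str, list[str]] = {}
            for e in self.exons:
                gi.setdefault(e.gene_id, []).append(e.exon_id)
            self.gene_index = gi

    def __len__(self) -> int:
        return len(self.exons)

    def __iter__(self):
        return iter(self.exons)

    def by_id(self, exon_id: str) -> ExonDef:
        if not hasattr(self, "_id_map"):
            object.__setattr__(self, "_id_map", {e.exon_id: e for e in self.exons})
        return self._id_map[exon_id]


@dataclass
class ExonWindow:
    """Fixed-length, right-padded normalized depth vector for one exon."""

    exon: ExonDef
    signal: np.ndarray          # (window_len,) float, zero beyond valid_length
    valid_length: int
    has_depth: bool             # False iff every raw base count was zero

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if not np.all(np.isfinite(self.signal)):
            raise ValueError(f"{self.exon.exon_id}: non-finite signal")
        if np.any(self.signal[self.valid_length:] != 0):
            raise ValueError(f"{self.exon.exon_id}: nonzero padding")


@dataclass(frozen=True)
class SampleManifest:
    sample_id: str
    role: str                   # pretrain | finetune_train | test
    nominal_coverage: float
    depth_source: Path

    def __post_init__(self):
        if self.nominal_coverage <= 0:
            raise ValueError(f"{self.sample_id}: coverage must be positive")
        if self.role not in ("pretrain", "finetune_train", "test"):
            raise ValueError(f"{self.sample_id}: unknown role {self.role!r}")


def load_exon_catalog(bed_path: str | Path, max_span: int = WINDOW_LEN) -> ExonCatalog:
    """Read a BED3/BED4 exon annotation.

    Column 4, when present, is the gene id; otherwise the gene id defaults to
    the interval string. Exons spanning more than `max_span` bp are discarded
    (they cannot fit the model window); the discard count is logged.
    """
    exons: list[ExonDef] = []
    n_discarded = 0
    counts: dict[str, int] = {}
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{bed_path}:{lineno}: expected >=3 BED columns")
            try:
                ch = normalize_chromosome(fields[0])
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{lineno}: {exc}") from exc
            if end <= start:
                raise ValueError(f"{bed_path}:{lineno}: end <= start")
            if end - start > max_span:
                n_discarded += 1
                continue
            interval = f"{chromosome_name(ch)}:{start}-{end}"
            gene_id = fields[3] if len(fields) >= 4 and fields[3] else interval
            counts[gene_id] = counts.get(gene_id, 0) + 1
            exons.append(ExonDef(
                exon_id=f"{gene_id}.e{counts[gene_id]}",
                gene_id=gene_id, chromosome=ch, start=start, end=end))
    if n_discarded:
        logger.info("discarded %d exon(s) longer than %d bp", n_discarded, max_span)
    if not exons:
        raise ValueError(f"{bed_path}: no exons within {max_span} bp")
    return ExonCatalog(exons)


def write_catalog(catalog: ExonCatalog, bed_path: str | Path) -> None:
    with open(bed_path, "w") as fh:
        for e in catalog:
            fh.write(f"chr{chromosome_name(e.chromosome)}\t{e.start}\t{e.end}"
                     f"\t{e.gene_id}\n")


# ---------------------------------------------------------------------------
# depth sources
# ---------------------------------------------------------------------------

class DepthSource:
    """Per-base depth lookup keyed by (chromosome, interval).

    Backends: indexed BAM/CRAM (via pysam pileup counts), gzipped TSV
    "chrom<TAB>pos0<TAB>depth", or NPZ of per-chromosome depth arrays.
    """

    def depth(self, chromosome: int, start: int, end: int) -> np.ndarray:
        raise NotImplementedError

    def close(self) -> None:
        pass


class _BamDepthSource(DepthSource):
    def __init__(self, path: Path):
        import pysam

        self._af = pysam.AlignmentFile(str(path))
        if not self._af.has_index():
            raise FileNotFoundError(f"{path}: alignment index (.bai/.crai) required")
        self._contigs = {}
        for ref in self._af.references:
            try:
                self._contigs[normalize_chromosome(ref)] = ref
            except ValueError:
                continue  # scaffolds etc.

    def depth(self, chromosome: int, start: int, end: int) -> np.ndarray:
        ref = self._contigs.get(chromosome)
        if ref is None:
            logger.warning("contig for chromosome %s absent; returning zero depth",
                           chromosome_name(chromosome))
            return np.zeros(end - start, dtype=np.int64)
        acgt = self._af.count_coverage(ref, start, end, quality_threshold=0)
        return np.sum(acgt, axis=0).astype(np.int64)

    def close(self) -> None:
        self._af.close()


class _TableDepthSource(DepthSource):
    """Depth from a gzipped TSV (chrom, pos0, depth) or an NPZ archive."""

    def __init__(self, path: Path):
        self._arrays: dict[int, np.ndarray] = {}
        if path.suffix == ".npz":
            with np.load(path) as npz:
                for key in npz.files:
                    self._arrays[normalize_chromosome(key)] = npz[key].astype(np.int64)
        else:
            opener = gzip.open if "".join(path.suffixes).endswith(".gz") else open
            with opener(path, "rt") as fh:
                df = pd.read_csv(fh, sep="\t", header=None,
                                 names=["chrom", "pos0", "depth"],
                                 dtype={"chrom": str})
            for chrom, grp in df.groupby("chrom", sort=False):
                ch = normalize_chromosome(chrom)
                arr = np.zeros(int(grp["pos0"].max()) + 1, dtype=np.int64)
                arr[grp["pos0"].to_numpy()] = grp["depth"].to_numpy()
                self._arrays[ch] = arr

    def depth(self, chromosome: int, start: int, end: int) -> np.ndarray:
        arr = self._arrays.get(chromosome)
        if arr is None:
            logger.warning("chromosome %s absent from depth track; returning zeros",
                           chromosome_name(chromosome))
            return np.zeros(end - start, dtype=np.int64)
        out = np.zeros(end - start, dtype=np.int64)
        hi = min(end, len(arr))
        if hi > start:
            out[:hi - start] = arr[start:hi]
        return out


def open_depth_source(path: str | Path) -> DepthSource:
    path = Path(path)
    if path.suffix in (".bam", ".cram", ".sam"):
        return _BamDepthSource(path)
    return _TableDepthSource(path)


def extract_raw_depth(depth_source: DepthSource | str | Path, exon: ExonDef) -> np.ndarray:
    """Per-base aligned-read counts over the exon, length end - start."""
    src = depth_source
    opened = False
    if not isinstance(src, DepthSource):
        src = open_depth_source(src)
        opened = True
    try:
        return src.depth(exon.chromosome, exon.start, exon.end)
    finally:
        if opened:
            src.close()


def sample_mean_depth(depths: list[np.ndarray] | dict) -> float:
    """Mean per-base depth pooled over all supplied exon depth vectors."""
    vecs = list(depths.values()) if isinstance(depths, dict) else depths
    total = sum(int(v.sum()) for v in vecs)
    nbase = sum(len(v) for v in vecs)
    if nbase == 0:
        raise ValueError("no bases to average over")
    return total / nbase


def normalize_signal(raw: np.ndarray, sample_mean_depth: float) -> np.ndarray:
    """Divide per-base counts by the sample's mean per-base depth."""
    if sample_mean_depth <= 0:
        raise ValueError(f"sample_mean_depth must be positive, got {sample_mean_depth}")
    return np.asarray(raw, dtype=np.float64) / float(sample_mean_depth)


def build_window(normalized: np.ndarray, exon: ExonDef,
                 window_len: int = WINDOW_LEN,
                 raw: np.ndarray | None = None) -> ExonWindow:
    """Right-pad the normalized depth vector to `window_len` positions.

    `has_depth` is decided on the raw counts when given, else on the
    normalized values (equivalent: normalization preserves zeros).
    """
    normalized = np.asarray(normalized, dtype=np.float64)
    n = len(normalized)
    if n != exon.span:
        raise ValueError(f"{exon.exon_id}: signal length {n} != span {exon.span}")
    if n > window_len:
        raise ValueError(f"{exon.exon_id}: span {n} exceeds window {window_len}; "
                         "should have been discarded at catalog load")
    signal = np.zeros(window_len, dtype=np.float64)
    signal[:n] = normalized
    basis = normalized if raw is None else np.asarray(raw)
    return ExonWindow(exon=exon, signal=signal, valid_length=n,
                      has_depth=bool(np.any(basis > 0)))


def thin_coverage(raw: np.ndarray, fraction: float, seed: int) -> np.ndarray:
    """Binomially thin per-base counts: out[j] ~ Binomial(raw[j], fraction).

    Emulates down-sampling a sample's reads to a fraction of its coverage;
    deterministic for a fixed (input, fraction, seed).
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    raw = np.asarray(raw)
    if fraction == 1.0:
        return raw.astype(np.int64).copy()
    rng = np.random.default_rng(seed)
    return rng.binomial(raw.astype(np.int64), fraction)


def load_manifest(path: str | Path) -> list[SampleManifest]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "role", "coverage", "path"}
    if missing := required - set(df.columns):
        raise ValueError(f"{path}: manifest missing columns {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id")
    return [SampleManifest(sample_id=r.sample_id, role=r.role,
                           nominal_coverage=float(r.coverage),
                           depth_source=Path(r.path))
            for r in df.itertuples()]
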