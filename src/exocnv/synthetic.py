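"""Desk-scale synthetic ancient-exome generator.

Produces a toy multi-chromosome exon catalog, plants non-overlapping DEL and
DUP events, and simulates per-base read depth whose mean is proportional to
copy number (x0.5 for a heterozygous deletion, x1.5 for a duplication),
with negative-binomial overdispersion and a Poisson contamination term.
Coverage ladders (5x .. 0.05x equivalents) are produced by binomial
thinning, and a configurable fraction of exons is zeroed entirely to mimic
regions with no surviving aligned reads.

Read-level degradation realism (fragment-length spectra, deamination
damage) is deliberately collapsed into this depth-level noise model: the
classifier consumes depth only, so that is the level at which the generator
is faithful. A frequency-structured cohort mode assigns each deletion event
a population frequency and draws carrier samples, feeding the
population-genetic analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calling import CallSet, ExonCall
from .io import ExonCatalog, ExonDef, ExonWindow, build_window, normalize_signal, \
    sample_mean_depth, thin_coverage
from .labels import CNVClass, CNVInterval, LabeledExon, label_exons

__all__ = ["SyntheticConfig", "TruthSet", "make_toy_exome", "plant_cnv_events",
           "simulate_depth", "emit_coverage_ladder", "generate_sample",
           "windows_from_depths", "CohortConfig", "DeletionCohort",
           "simulate_deletion_cohort"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    The full-scale simulation design plants 2000 deletions and 2000
    duplications of 500 bp - 100 kbp at 10x coverage; the defaults here keep
    those event sizes and coverage but shrink the genome and event counts to
    a desk-scale toy exome (the event-span ceiling is reduced so the events
    still fit a toy chromosome).
    """

    n_chromosomes: int = 4
    genes_per_chromosome: int = 10
    exons_per_gene: int = 5
    exon_span_range: tuple[int, int] = (120, 600)
    n_del: int = 12
    n_dup: int = 12
    event_span_range: tuple[int, int] = (500, 15_000)
    base_coverage: float = 10.0
    del_factor: float = 0.5     # heterozygous deletion; 0.0 for homozygous
    dup_factor: float = 1.5     # single-copy gain
    missing_exon_rate: float = 0.05
    noise_dispersion: float = 10.0   # NB size parameter; larger = closer to Poisson
    contamination_rate: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.exon_span_range[0] <= self.exon_span_range[1]:
            raise ValueError("invalid exon_span_range")
        if self.exon_span_range[1] > 1000:
            raise ValueError("exon spans above 1000 bp violate the window contract")
        if not 0 < self.event_span_range[0] <= self.event_span_range[1]:
            raise ValueError("invalid event_span_range")
        for r in (self.missing_exon_rate, self.contamination_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.base_coverage <= 0:
            raise ValueError("base_coverage must be positive")
        if self.del_factor < 0 or self.dup_factor < 0:
            raise ValueError("copy-number factors must be >= 0")


@dataclass
class TruthSet:
    """Planted events plus the per-exon labels they induce."""

    events: list[CNVInterval]
    labels: list[LabeledExon]

    def label_of(self, exon_id: str) -> CNVClass:
        if not hasattr(self, "_map"):
            self._map = {l.exon_id: l.label for l in self.labels}
        return self._map[exon_id]


def make_toy_exome(cfg: SyntheticConfig) -> ExonCatalog:
    """Non-overlapping exons laid down gene by gene along each chromosome."""
    rng = np.random.default_rng(cfg.seed)
    exons: list[ExonDef] = []
    lo, hi = cfg.exon_span_range
    for ch in range(1, cfg.n_chromosomes + 1):
        pos = 1_000
        for g in range(cfg.genes_per_chromosome):
            gene_id = f"gene_c{ch}g{g + 1}"
            for e in range(cfg.exons_per_gene):
                span = int(rng.integers(lo, hi + 1))
                exons.append(ExonDef(exon_id=f"{gene_id}.e{e + 1}",
                                     gene_id=gene_id, chromosome=ch,
                                     start=pos, end=pos + span))
                pos += span + int(rng.integers(200, 1_500))  # intra-gene gap
            pos += int(rng.integers(3_000, 10_000))          # inter-gene gap
    return ExonCatalog(exons)


def _chromosome_extent(catalog: ExonCatalog) -> dict[int, int]:
    ext: dict[int, int] = {}
    for e in catalog:
        ext[e.chromosome] = max(ext.get(e.chromosome, 0), e.end)
    return ext


def plant_cnv_events(catalog: ExonCatalog, cfg: SyntheticConfig,
                     seed: int | None = None) -> TruthSet:
    """Place exactly n_del DELs and n_dup DUPs uniformly, without overlap."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    extents = _chromosome_extent(catalog)
    chroms = sorted(extents)
    placed: list[CNVInterval] = []
    wanted = [CNVClass.DEL] * cfg.n_del + [CNVClass.DUP] * cfg.n_dup
    lo, hi = cfg.event_span_range
    for cls in wanted:
        for _ in range(1000):  # bounded retries
            ch = int(rng.choice(chroms))
            span = int(rng.integers(lo, min(hi, extents[ch] - 1) + 1))
            if span >= extents[ch]:
                continue
            start = int(rng.integers(0, extents[ch] - span))
            cand = CNVInterval(chromosome=ch, start=start, end=start + span,
                               cnv_class=cls, source="planted")
            if all(c.chromosome != cand.chromosome
                   or c.end <= cand.start or cand.end <= c.start
                   for c in placed):
                placed.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place a {cls.name} event of {lo}-{hi} bp without "
                "overlap; shrink events or enlarge the toy genome")
    events = sorted(placed, key=lambda c: (c.chromosome, c.start))
    return TruthSet(events=events, labels=label_exons(catalog, events))


def simulate_depth(catalog: ExonCatalog, truth: TruthSet, cfg: SyntheticConfig,
                   seed: int | None = None) -> dict[str, np.ndarray]:
    """Per-exon per-base raw depth: NB(mean = coverage x copy factor) + contamination.

    The negative binomial has mean mu = base_coverage * factor and variance
    mu + mu^2 / noise_dispersion; contamination adds Poisson reads at
    contamination_rate * base_coverage independent of the host copy number.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    factor = {CNVClass.NOCALL: 1.0, CNVClass.DEL: cfg.del_factor,
              CNVClass.DUP: cfg.dup_factor}
    out: dict[str, np.ndarray] = {}
    r = cfg.noise_dispersion
    for exon in catalog:
        mu = cfg.base_coverage * factor[truth.label_of(exon.exon_id)]
        n = exon.span
        if mu <= 0:
            depth = np.zeros(n, dtype=np.int64)
        else:
            p = r / (r + mu)
            depth = rng.negative_binomial(r, p, size=n).astype(np.int64)
        if cfg.contamination_rate > 0:
            depth = depth + rng.poisson(cfg.contamination_rate * cfg.base_coverage,
                                        size=n)
        out[exon.exon_id] = depth
    return out


def emit_coverage_ladder(depths: dict[str, np.ndarray], fractions: list[float],
                         cfg: SyntheticConfig,
                         seed: int | None = None) -> dict[float, dict[str, np.ndarray]]:
    """Thin full-coverage depth to each ladder fraction, then zero a
    missing_exon_rate fraction of exons entirely (independently per
    fraction). Truth labels are untouched by construction."""
    rng = np.random.default_rng(cfg.seed + 2 if seed is None else seed)
    ladder: dict[float, dict[str, np.ndarray]] = {}
    for fraction in fractions:
        thinned = {eid: thin_coverage(v, fraction, int(rng.integers(2**31)))
                   for eid, v in depths.items()}
        if cfg.missing_exon_rate > 0:
            for eid in thinned:
                if rng.random() < cfg.missing_exon_rate:
                    thinned[eid] = np.zeros_like(thinned[eid])
        ladder[fraction] = thinned
    return ladder


def generate_sample(catalog: ExonCatalog, cfg: SyntheticConfig,
                    seed: int) -> tuple[TruthSet, dict[str, np.ndarray]]:
    """One synthetic individual: its own planted events and depth draw."""
    truth = plant_cnv_events(catalog, cfg, seed=seed)
    depths = simulate_depth(catalog, truth, cfg, seed=seed + 10_000)
    return truth, depths


def windows_from_depths(catalog: ExonCatalog, depths: dict[str, np.ndarray],
                        window_len: int = 1000) -> list[ExonWindow]:
    """Normalize a sample's exon depth vectors and pad them into windows."""
    mean_depth = sample_mean_depth(depths)
    if mean_depth <= 0:
        # an all-zero sample still yields (depth-less) windows
        mean_depth = 1.0
    return [build_window(normalize_signal(depths[e.exon_id], mean_depth), e,
                         window_len=window_len, raw=depths[e.exon_id])
            for e in catalog]


# ---------------------------------------------------------------------------
# frequency-structured cohort (population-genetics fixture)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Two-population deletion cohort with event frequencies.

    Each planted deletion is private to one population and carries a
    population frequency; a sample in that population is a carrier with
    that probability. `low_freq_fraction` of events get a frequency below
    `low_freq_cutoff` (rare, mimicking negative selection); the rest are
    drawn from the common range.
    """

    n_samples_per_pop: int = 12
    n_events_per_pop: int = 30
    low_freq_fraction: float = 0.8
    low_freq_cutoff: float = 0.2
    min_freq: float = 0.05
    max_freq: float = 0.9
    event_span_range: tuple[int, int] = (500, 4_000)
    carrier_prob_del: float = 0.99   # P(DEL) reported at carrier exons
    seed: int = 0


@dataclass
class DeletionCohort:
    callsets: list[CallSet]
    groups: list[str]                  # population label per sample
    event_frequencies: np.ndarray      # planted frequency per event
    events: list[CNVInterval]
    event_population: list[str]


def simulate_deletion_cohort(catalog: ExonCatalog, cohort: CohortConfig,
                             base: SyntheticConfig | None = None) -> DeletionCohort:
    """Draw carrier samples for frequency-structured private deletions.

    Returns per-sample exon call sets (carrier exons get a confident DEL,
    everything else a confident NOCALL) ready for the deletion-matrix,
    PCA/clustering and site-frequency analyses.
    """
    base = base or SyntheticConfig()
    rng = np.random.default_rng(cohort.seed)
    cfg_events = SyntheticConfig(
        n_chromosomes=base.n_chromosomes,
        genes_per_chromosome=base.genes_per_chromosome,
        exons_per_gene=base.exons_per_gene,
        exon_span_range=base.exon_span_range,
        n_del=2 * cohort.n_events_per_pop, n_dup=0,
        event_span_range=cohort.event_span_range, seed=cohort.seed)
    truth = plant_cnv_events(catalog, cfg_events, seed=cohort.seed + 1)
    events = truth.events
    pops = ["A", "B"]
    event_population = [pops[i % 2] for i in range(len(events))]

    n_low = int(round(cohort.low_freq_fraction * len(events)))
    freqs = np.empty(len(events))
    low_idx = rng.choice(len(events), size=n_low, replace=False)
    is_low = np.zeros(len(events), dtype=bool)
    is_low[low_idx] = True
    if n_low:
        freqs[is_low] = rng.uniform(min(cohort.min_freq, cohort.low_freq_cutoff),
                                    cohort.low_freq_cutoff, size=n_low)
    n_common = len(events) - n_low
    if n_common:
        freqs[~is_low] = rng.uniform(max(cohort.min_freq, cohort.low_freq_cutoff),
                                     cohort.max_freq, size=n_common)

    # which exons each event covers
    exon_list = list(catalog)
    event_exons = []
    for ev in events:
        event_exons.append([i for i, e in enumerate(exon_list)
                            if e.chromosome == ev.chromosome
                            and min(e.end, ev.end) - max(e.start, ev.start) > 0])

    callsets, groups = [], []
    p_hi = cohort.carrier_prob_del
    for pop in pops:
        for s in range(cohort.n_samples_per_pop):
            carried = np.zeros(len(exon_list), dtype=bool)
            for ev_i, ev in enumerate(events):
                if event_population[ev_i] != pop:
                    continue
                if rng.random() < freqs[ev_i]:
                    carried[event_exons[ev_i]] = True
            calls = []
            for i, exon in enumerate(exon_list):
                if carried[i]:
                    probs = np.array([1 - p_hi - 0.001, p_hi, 0.001])
                    calls.append(ExonCall(exon_id=exon.exon_id,
                                          probabilities=probs,
                                          label=CNVClass.DEL))
                else:
                    probs = np.array([p_hi, 1 - p_hi - 0.001, 0.001])
                    calls.append(ExonCall(exon_id=exon.exon_id,
                                          probabilities=probs,
                                          label=CNVClass.NOCALL))
            callsets.append(CallSet(sample_id=f"{pop}{s + 1}", calls=calls))
            groups.append(pop)
    return DeletionCohort(callsets=callsets, groups=groups,
                          event_frequencies=freqs, events=events,
                          event_population=event_population)


# ---------------------------------------------------------------------------
# on-disk emission (consumed by the CLI and round-trip tests)
# ---------------------------------------------------------------------------

def write_depth_tsv(catalog: ExonCatalog, depths: dict[str, np.ndarray],
                    path: str | Path) -> None:
    """Gzipped TSV depth track: chrom<TAB>pos0<TAB>depth (nonzero bases only)."""
    import gzip

    from .io import chromosome_name

    with gzip.open(path, "wt") as fh:
        for exon in catalog:
            v = depths[exon.exon_id]
            for j in np.flatnonzero(v):
                fh.write(f"chr{chromosome_name(exon.chromosome)}"
                         f"\t{exon.start + int(j)}\t{int(v[j])}\n")


def write_manifest(rows: list[tuple[str, str, float, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\trole\tcoverage\tpath\n")
        for sid, role, cov, p in rows:
            fh.write(f"{sid}\t{role}\t{cov}\t{p}\n")
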