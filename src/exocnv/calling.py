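"""Inference over a sample: exon calls, imputation, gene aggregation, output.

Roughly 5% of exonic regions in degraded low-coverage samples carry no
aligned reads at all, so the model cannot call them directly. Those exons
are resolved post hoc by majority vote over the hard labels of their three
nearest called exons on the same chromosome (midpoint distance). Gene-level
labels are then obtained by majority voting across each gene's exons.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import ExonCatalog, ExonWindow, chromosome_name
from .labels import CNVClass
from .model import CNVTransformer, predict_class

__all__ = ["ExonCall", "CallSet", "GeneCall", "call_exons",
           "impute_missing_calls", "aggregate_gene_calls", "write_calls",
           "read_calls_tsv"]


@dataclass
class ExonCall:
    exon_id: str
    probabilities: np.ndarray  # (3,): NOCALL, DEL, DUP
    label: CNVClass
    imputed: bool = False

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if not np.isclose(self.probabilities.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{self.exon_id}: probabilities do not sum to 1")


@dataclass
class CallSet:
    sample_id: str
    calls: list[ExonCall]

    def labels(self) -> list[CNVClass]:
        return [c.label for c in self.calls]


@dataclass
class GeneCall:
    gene_id: str
    label: CNVClass
    n_exons: int
    votes: tuple[int, int, int]  # (NOCALL, DEL, DUP) counts

    def __post_init__(self):
        if sum(self.votes) != self.n_exons:
            raise ValueError(f"{self.gene_id}: votes do not sum to n_exons")


def call_exons(model: CNVTransformer, windows: list[ExonWindow],
               catalog: ExonCatalog | None = None,
               sample_id: str = "sample", batch_size: int = 64) -> CallSet:
    """One deterministic inference pass per exon window.

    Depth-less windows (no aligned reads) get a uniform probability row and
    a provisional NOCALL; `impute_missing_calls` resolves them afterwards.
    """
    if catalog is not None:
        if len(windows) != len(catalog):
            raise ValueError(f"{len(windows)} windows != {len(catalog)} catalog exons")
        for w, e in zip(windows, catalog):
            if w.exon.exon_id != e.exon_id:
                raise ValueError(f"window order mismatch at {w.exon.exon_id}")
    signals = np.stack([w.signal for w in windows])
    chrom = np.array([w.exon.chromosome for w in windows], dtype=np.int64)
    probs = model.predict_proba(signals, chrom, batch_size=batch_size)
    calls = []
    for w, p in zip(windows, probs):
        if not w.has_depth:
            calls.append(ExonCall(exon_id=w.exon.exon_id,
                                  probabilities=np.full(3, 1.0 / 3),
                                  label=CNVClass.NOCALL, imputed=False))
        else:
            calls.append(ExonCall(exon_id=w.exon.exon_id, probabilities=p,
                                  label=predict_class(p), imputed=False))
    cs = CallSet(sample_id=sample_id, calls=calls)
    cs._depthless = {w.exon.exon_id for w in windows if not w.has_depth}
    return cs


def _majority(labels: list[CNVClass]) -> CNVClass:
    """Plurality with ties (including empty input) resolved to NOCALL."""
    counts = {c: 0 for c in CNVClass}
    for l in labels:
        counts[l] += 1
    best = max(counts.values())
    winners = [c for c, n in counts.items() if n == best]
    return winners[0] if len(winners) == 1 else CNVClass.NOCALL


def impute_missing_calls(callset: CallSet, catalog: ExonCatalog) -> CallSet:
    """Resolve depth-less exons by 3-nearest-neighbor majority vote.

    Neighbors are the closest called (non-depth-less) exons on the same
    chromosome by interval-midpoint distance; distance ties break toward
    the smaller start coordinate. Fewer than three candidates → vote over
    what is available; none → NOCALL.
    """
    if len(callset.calls) != len(catalog):
        raise ValueError("callset not aligned to catalog")
    depthless = getattr(callset, "_depthless", set())
    exons = list(catalog)
    by_chrom: dict[int, list[int]] = {}
    for i, e in enumerate(exons):
        by_chrom.setdefault(e.chromosome, []).append(i)
    new_calls = list(callset.calls)
    for i, (exon, call) in enumerate(zip(exons, callset.calls)):
        if exon.exon_id not in depthless:
            continue
        candidates = [j for j in by_chrom[exon.chromosome]
                      if j != i and exons[j].exon_id not in depthless]
        candidates.sort(key=lambda j: (abs(exons[j].midpoint - exon.midpoint),
                                       exons[j].start))
        neighbors = [callset.calls[j].label for j in candidates[:3]]
        new_calls[i] = ExonCall(exon_id=exon.exon_id,
                                probabilities=call.probabilities,
                                label=_majority(neighbors), imputed=True)
    out = CallSet(sample_id=callset.sample_id, calls=new_calls)
    out._depthless = depthless
    return out


def aggregate_gene_calls(callset: CallSet, catalog: ExonCatalog,
                         mode: str = "all-class") -> list[GeneCall]:
    """Majority-vote exon labels up to gene level.

    mode="all-class": plurality over {NOCALL, DEL, DUP}; ties → NOCALL.
    mode="event-only": plurality over DEL/DUP exons only; a gene is NOCALL
    iff no exon carries an event; DEL/DUP tie → NOCALL.
    """
    if mode not in ("all-class", "event-only"):
        raise ValueError(f"unknown gene-vote mode {mode!r}")
    call_by_id = {c.exon_id: c for c in callset.calls}
    out = []
    for gene_id, exon_ids in catalog.gene_index.items():
        if not exon_ids:
            raise ValueError(f"gene {gene_id} has no exons")
        labels = [call_by_id[eid].label for eid in exon_ids]
        votes = (labels.count(CNVClass.NOCALL), labels.count(CNVClass.DEL),
                 labels.count(CNVClass.DUP))
        if mode == "all-class":
            label = _majority(labels)
        else:
            events = [l for l in labels if l != CNVClass.NOCALL]
            label = _majority(events) if events else CNVClass.NOCALL
        out.append(GeneCall(gene_id=gene_id, label=label,
                            n_exons=len(exon_ids), votes=votes))
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_calls(calls: CallSet | list[GeneCall], catalog: ExonCatalog,
                path: str | Path, format: str = "tsv") -> None:
    path = Path(path)
    if isinstance(calls, CallSet):
        if format == "tsv":
            _write_exon_tsv(calls, catalog, path)
        elif format == "bed":
            _write_exon_bed(calls, catalog, path)
        elif format == "vcf":
            _write_exon_vcf(calls, catalog, path)
        else:
            raise ValueError(f"unknown format {format!r}")
    else:
        if format != "tsv":
            raise ValueError("gene calls are written as TSV")
        with open(path, "w") as fh:
            fh.write("gene_id\tlabel\tn_exons\tvotes_nocall\tvotes_del\tvotes_dup\n")
            for g in calls:
                fh.write(f"{g.gene_id}\t{g.label.name}\t{g.n_exons}"
                         f"\t{g.votes[0]}\t{g.votes[1]}\t{g.votes[2]}\n")


def _write_exon_tsv(cs: CallSet, catalog: ExonCatalog, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("exon_id\tgene_id\tchrom\tstart\tend\tlabel"
                 "\tp_nocall\tp_del\tp_dup\timputed\n")
        for exon, call in zip(catalog, cs.calls):
            p = call.probabilities
            fh.write(f"{call.exon_id}\t{exon.gene_id}"
                     f"\tchr{chromosome_name(exon.chromosome)}"
                     f"\t{exon.start}\t{exon.end}\t{call.label.name}"
                     f"\t{p[0]:.17g}\t{p[1]:.17g}\t{p[2]:.17g}"
                     f"\t{int(call.imputed)}\n")


def _write_exon_bed(cs: CallSet, catalog: ExonCatalog, path: Path) -> None:
    """BED4 of event (DEL/DUP) exons only."""
    with open(path, "w") as fh:
        for exon, call in zip(catalog, cs.calls):
            if call.label != CNVClass.NOCALL:
                fh.write(f"chr{chromosome_name(exon.chromosome)}\t{exon.start}"
                         f"\t{exon.end}\t{call.label.name}\n")


def _write_exon_vcf(cs: CallSet, catalog: ExonCatalog, path: Path) -> None:
    from .labels import CNVInterval, intervals_to_vcf

    events = [CNVInterval(chromosome=e.chromosome, start=e.start, end=e.end,
                          cnv_class=c.label, source=cs.sample_id)
              for e, c in zip(catalog, cs.calls) if c.label != CNVClass.NOCALL]
    contig_lengths = {e.chromosome: max(x.end for x in catalog
                                        if x.chromosome == e.chromosome) + 1
                      for e in catalog}
    intervals_to_vcf(events, path, contig_lengths=contig_lengths)


def read_calls_tsv(path: str | Path, sample_id: str = "sample") -> CallSet:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    calls = [ExonCall(exon_id=r.exon_id,
                      probabilities=np.array([r.p_nocall, r.p_del, r.p_dup]),
                      label=CNVClass[r.label], imputed=bool(r.imputed))
             for r in df.itertuples()]
    return CallSet(sample_id=sample_id, calls=calls)
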