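"""Semi-ground-truth labels: caller-output parsing, exon labeling, fine-tune pairs.

Conventional callers (run on the high-coverage version of each sample)
provide interval-level DEL/DUP calls; these are mapped onto the exon catalog
to produce per-exon labels. Fine-tuning pairs combine a coverage-thinned
window (the feature) with the full-coverage label, teaching the model to
recognize events from degraded signal.
"""

from __future__ import annotations

import enum
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import (
    DepthSource,
    ExonCatalog,
    ExonWindow,
    SampleManifest,
    build_window,
    chromosome_name,
    extract_raw_depth,
    normalize_chromosome,
    normalize_signal,
    open_depth_source,
    sample_mean_depth,
    thin_coverage,
)

logger = logging.getLogger(__name__)

__all__ = ["CNVClass", "CNVInterval", "LabeledExon", "TrainingPair",
           "parse_caller_calls", "label_exons", "build_finetune_pairs"]


class CNVClass(enum.IntEnum):
    """Exon-level call state. NOCALL is the diploid / absorbing default."""

    NOCALL = 0
    DEL = 1
    DUP = 2


@dataclass(frozen=True)
class CNVInterval:
    """One caller-reported or planted DEL/DUP segment (0-based half-open)."""

    chromosome: int
    start: int
    end: int
    cnv_class: CNVClass
    source: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"interval end {self.end} <= start {self.start}")
        if self.cnv_class == CNVClass.NOCALL:
            raise ValueError("CNVInterval cannot carry NOCALL")


@dataclass(frozen=True)
class LabeledExon:
    exon_id: str
    label: CNVClass


@dataclass
class TrainingPair:
    """(thinned-window feature, full-coverage label) for one exon."""

    window: ExonWindow
    label: CNVClass
    sample_id: str
    fraction: float


_CNVNATOR_CLASS = {"deletion": CNVClass.DEL, "duplication": CNVClass.DUP}
_REGION_RE = re.compile(r"^(?P<chrom>[^:]+):(?P<start>\d+)-(?P<end>\d+)$")


def _parse_cnvnator_txt(path: Path) -> list[CNVInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'type region ...'")
            kind = fields[0].lower()
            if kind not in _CNVNATOR_CLASS:
                logger.warning("%s:%d: unknown call type %r skipped", path, lineno, kind)
                continue
            m = _REGION_RE.match(fields[1])
            if m is None:
                raise ValueError(f"{path}:{lineno}: malformed region {fields[1]!r}")
            # CNVnator regions are 1-based inclusive
            out.append(CNVInterval(
                chromosome=normalize_chromosome(m["chrom"]),
                start=int(m["start"]) - 1, end=int(m["end"]),
                cnv_class=_CNVNATOR_CLASS[kind], source="cnvnator"))
    return out


def _parse_vcf(path: Path) -> list[CNVInterval]:
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype not in ("DEL", "DUP"):
                if svtype is not None:
                    logger.warning("%s: SVTYPE=%s skipped at %s:%d",
                                   path, svtype, rec.chrom, rec.pos)
                continue
            end = rec.stop  # pysam: 0-based exclusive END
            out.append(CNVInterval(
                chromosome=normalize_chromosome(rec.chrom),
                start=rec.start, end=end,
                cnv_class=CNVClass[svtype], source="vcf"))
    return out


def _parse_bed_calls(path: Path) -> list[CNVInterval]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: BED4 with class column required")
            cls = fields[3].upper()
            if cls not in ("DEL", "DUP"):
                logger.warning("%s:%d: class %r skipped", path, lineno, cls)
                continue
            out.append(CNVInterval(
                chromosome=normalize_chromosome(fields[0]),
                start=int(fields[1]), end=int(fields[2]),
                cnv_class=CNVClass[cls], source="bed"))
    return out


def parse_caller_calls(path: str | Path, dialect: str) -> list[CNVInterval]:
    """Parse DEL/DUP interval calls; dialect in {vcf, cnvnator_txt, bed_calls}.

    Output is sorted by (chromosome, start) with 0-based half-open
    coordinates regardless of the input convention.
    """
    path = Path(path)
    parsers = {"vcf": _parse_vcf, "cnvnator_txt": _parse_cnvnator_txt,
               "bed_calls": _parse_bed_calls}
    if dialect not in parsers:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(parsers)}")
    calls = parsers[dialect](path)
    return sorted(calls, key=lambda c: (c.chromosome, c.start, c.end))


def label_exons(catalog: ExonCatalog, calls: list[CNVInterval]) -> list[LabeledExon]:
    """Map interval calls onto exons; >=1 bp overlap labels an exon.

    An exon overlapped by both DEL and DUP intervals takes the class with
    the larger total overlap in bp; an exact tie falls back to NOCALL.
    """
    out = []
    for exon in catalog:
        overlap = {CNVClass.DEL: 0, CNVClass.DUP: 0}
        for call in calls:
            if call.chromosome != exon.chromosome:
                continue
            bp = min(exon.end, call.end) - max(exon.start, call.start)
            if bp > 0:
                overlap[call.cnv_class] += bp
        if overlap[CNVClass.DEL] == overlap[CNVClass.DUP]:
            label = CNVClass.NOCALL  # no overlap, or an exact DEL/DUP tie
        elif overlap[CNVClass.DEL] > overlap[CNVClass.DUP]:
            label = CNVClass.DEL
        else:
            label = CNVClass.DUP
        out.append(LabeledExon(exon_id=exon.exon_id, label=label))
    return out


def write_labels_tsv(catalog: ExonCatalog, labels: list[LabeledExon],
                     path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("exon_id\tgene_id\tlabel\n")
        for exon, lab in zip(catalog, labels):
            fh.write(f"{exon.exon_id}\t{exon.gene_id}\t{lab.label.name}\n")


def build_finetune_pairs(sample: SampleManifest, catalog: ExonCatalog,
                         calls: list[CNVInterval], fractions: list[float],
                         seed: int, window_len: int = 1000,
                         depth_source: DepthSource | None = None) -> list[TrainingPair]:
    """Pair coverage-thinned windows with full-coverage labels.

    For every retained exon and every thinning fraction, the feature window
    is built from binomially thinned depth while the label comes from
    `label_exons` on the sample's full-coverage call set — never recomputed
    on thinned data. Yields |exons| x |fractions| pairs.
    """
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fraction {f} outside (0, 1]")
    src = depth_source or open_depth_source(sample.depth_source)
    try:
        raw = {e.exon_id: extract_raw_depth(src, e) for e in catalog}
    finally:
        if depth_source is None:
            src.close()
    labels = {le.exon_id: le.label for le in label_exons(catalog, calls)}
    rng = np.random.default_rng(seed)
    pairs: list[TrainingPair] = []
    for frac_i, fraction in enumerate(fractions):
        thinned = {eid: thin_coverage(v, fraction, int(rng.integers(2**31)))
                   for eid, v in raw.items()}
        mean_depth = sample_mean_depth(thinned)
        if mean_depth <= 0:
            logger.warning("%s: zero depth after thinning to %g; skipping fraction",
                           sample.sample_id, fraction)
            continue
        for exon in catalog:
            t = thinned[exon.exon_id]
            window = build_window(normalize_signal(t, mean_depth), exon,
                                  window_len=window_len, raw=t)
            pairs.append(TrainingPair(window=window, label=labels[exon.exon_id],
                                      sample_id=sample.sample_id, fraction=fraction))
    return pairs


def intervals_to_vcf(calls: list[CNVInterval], path: str | Path,
                     contig_lengths: dict[int, int] | None = None) -> None:
    """Write DEL/DUP intervals as a minimal SV VCF (SVTYPE/END in INFO)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_meta("INFO", items=[("ID", "SVTYPE"), ("Number", "1"),
                                   ("Type", "String"),
                                   ("Description", "Type of structural variant")])
    header.add_meta("INFO", items=[("ID", "END"), ("Number", "1"),
                                   ("Type", "Integer"),
                                   ("Description", "End position of the variant")])
    chroms = sorted({c.chromosome for c in calls})
    for ch in chroms:
        length = (contig_lengths or {}).get(ch) or max(
            c.end for c in calls if c.chromosome == ch) + 1
        header.contigs.add(f"chr{chromosome_name(ch)}", length=length)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in sorted(calls, key=lambda c: (c.chromosome, c.start)):
            rec = out.new_record(
                contig=f"chr{chromosome_name(c.chromosome)}",
                start=c.start, stop=c.end, alleles=("N", f"<{c.cnv_class.name}>"))
            rec.info["SVTYPE"] = c.cnv_class.name
            out.write(rec)
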