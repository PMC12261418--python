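"""Exon calling, 3-NN imputation, gene-level voting and call serialization."""

import numpy as np
import pysam
import pytest

from exocnv.calling import (
    CallSet,
    ExonCall,
    aggregate_gene_calls,
    call_exons,
    impute_missing_calls,
    read_calls_tsv,
    write_calls,
)
from exocnv.io import ExonCatalog, ExonDef, build_window
from exocnv.labels import CNVClass
from exocnv.model import CNVTransformer, ModelConfig

SMALL = ModelConfig(window_len=32, conv_channels=(4, 8), n_transformer_blocks=1,
                    n_heads=2, ffn_dim=16)

EVENT_PROBS = {
    CNVClass.NOCALL: np.array([0.98, 0.01, 0.01]),
    CNVClass.DEL: np.array([0.01, 0.98, 0.01]),
    CNVClass.DUP: np.array([0.01, 0.01, 0.98]),
}


def manual_callset(catalog, labels, depthless=()):
    """Build a call set directly from intended labels (depth-less exons get
    the provisional uniform row that `call_exons` assigns)."""
    calls = []
    for exon, lab in zip(catalog, labels):
        if exon.exon_id in depthless:
            calls.append(ExonCall(exon.exon_id, np.full(3, 1 / 3),
                                  CNVClass.NOCALL))
        else:
            calls.append(ExonCall(exon.exon_id, EVENT_PROBS[lab], lab))
    cs = CallSet(sample_id="s", calls=calls)
    cs._depthless = set(depthless)
    return cs


def spaced_catalog(labels_count, chromosome=1, spacing=1_000, span=100):
    exons = [ExonDef(f"e{i}", f"g{i}", chromosome, i * spacing,
                     i * spacing + span) for i in range(labels_count)]
    return ExonCatalog(exons)


# ---------------------------------------------------------------------------
# call_exons
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def model():
    return CNVTransformer(SMALL, seed=0)


def windows_for(catalog, rng, depthless=()):
    out = []
    for e in catalog:
        sig = np.zeros(e.span) if e.exon_id in depthless else rng.random(e.span)
        out.append(build_window(sig, e, window_len=SMALL.window_len))
    return out


def test_callset_cardinality_and_determinism(model):
    cat = spaced_catalog(6, span=30)
    rng = np.random.default_rng(0)
    windows = windows_for(cat, rng)
    cs1 = call_exons(model, windows, cat)
    cs2 = call_exons(model, windows, cat)
    assert len(cs1.calls) == len(cat)
    for a, b in zip(cs1.calls, cs2.calls):
        np.testing.assert_array_equal(a.probabilities, b.probabilities)


def test_depthless_windows_get_provisional_nocall(model):
    cat = spaced_catalog(4, span=30)
    rng = np.random.default_rng(1)
    windows = windows_for(cat, rng, depthless={"e2"})
    cs = call_exons(model, windows, cat)
    provisional = cs.calls[2]
    assert provisional.label == CNVClass.NOCALL
    assert not provisional.imputed
    np.testing.assert_allclose(provisional.probabilities, 1 / 3)


def test_window_catalog_mismatch_rejected(model):
    cat = spaced_catalog(3, span=30)
    rng = np.random.default_rng(2)
    with pytest.raises(ValueError):
        call_exons(model, windows_for(cat, rng)[:2], cat)


# ---------------------------------------------------------------------------
# imputation truth tables
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("neighbors,expected", [
    ((CNVClass.DEL, CNVClass.DEL, CNVClass.DUP), CNVClass.DEL),
    ((CNVClass.DEL, CNVClass.DUP, CNVClass.NOCALL), CNVClass.NOCALL),
    ((CNVClass.DUP, CNVClass.DUP, CNVClass.DUP), CNVClass.DUP),
    ((CNVClass.NOCALL, CNVClass.NOCALL, CNVClass.DEL), CNVClass.NOCALL),
])
def test_imputation_majority_truth_table(neighbors, expected):
    # depth-less exon e0 sits closest to e1, e2, e3 (its 3 nearest neighbors)
    cat = spaced_catalog(5)
    labels = [CNVClass.NOCALL, *neighbors, CNVClass.DUP]
    cs = manual_callset(cat, labels, depthless={"e0"})
    out = impute_missing_calls(cs, cat)
    assert out.calls[0].label == expected
    assert out.calls[0].imputed


def test_imputation_touches_only_depthless():
    cat = spaced_catalog(5)
    labels = [CNVClass.DEL, CNVClass.DEL, CNVClass.NOCALL, CNVClass.DUP,
              CNVClass.DUP]
    cs = manual_callset(cat, labels, depthless={"e2"})
    out = impute_missing_calls(cs, cat)
    assert sum(c.imputed for c in out.calls) == 1
    for i in (0, 1, 3, 4):
        assert out.calls[i].label == labels[i]
        assert not out.calls[i].imputed


def test_imputation_stays_on_chromosome():
    # depth-less exon on chr2 has no called neighbor on chr2 -> NOCALL,
    # even though chr1 neighbors are all DEL
    exons = [ExonDef("a1", "g", 1, 0, 100), ExonDef("a2", "g", 1, 200, 300),
             ExonDef("a3", "g", 1, 400, 500), ExonDef("b1", "h", 2, 0, 100)]
    cat = ExonCatalog(exons)
    labels = [CNVClass.DEL, CNVClass.DEL, CNVClass.DEL, CNVClass.NOCALL]
    cs = manual_callset(cat, labels, depthless={"b1"})
    out = impute_missing_calls(cs, cat)
    assert out.calls[3].label == CNVClass.NOCALL
    assert out.calls[3].imputed


def test_imputation_with_fewer_than_three_candidates():
    exons = [ExonDef("a1", "g", 1, 0, 100), ExonDef("a2", "g", 1, 200, 300),
             ExonDef("a3", "g", 1, 400, 500)]
    cat = ExonCatalog(exons)
    labels = [CNVClass.DUP, CNVClass.DUP, CNVClass.NOCALL]
    cs = manual_callset(cat, labels, depthless={"a3"})
    out = impute_missing_calls(cs, cat)
    assert out.calls[2].label == CNVClass.DUP  # majority of the 2 available


def test_imputation_count_matches_depthless_count(model):
    cat = spaced_catalog(10, span=30)
    rng = np.random.default_rng(3)
    depthless = {"e1", "e5", "e6"}
    windows = windows_for(cat, rng, depthless=depthless)
    cs = impute_missing_calls(call_exons(model, windows, cat), cat)
    assert sum(c.imputed for c in cs.calls) == len(depthless)


# ---------------------------------------------------------------------------
# gene voting truth tables
# ---------------------------------------------------------------------------

def gene_catalog(labels):
    exons = [ExonDef(f"e{i}", "gene1", 1, i * 1_000, i * 1_000 + 100)
             for i in range(len(labels))]
    return ExonCatalog(exons)


@pytest.mark.parametrize("labels,all_class,event_only", [
    ((CNVClass.DEL, CNVClass.DEL, CNVClass.NOCALL), CNVClass.DEL, CNVClass.DEL),
    ((CNVClass.NOCALL,) * 5 + (CNVClass.DUP,), CNVClass.NOCALL, CNVClass.DUP),
    ((CNVClass.DEL, CNVClass.DEL, CNVClass.DUP, CNVClass.DUP),
     CNVClass.NOCALL, CNVClass.NOCALL),
    ((CNVClass.NOCALL, CNVClass.NOCALL), CNVClass.NOCALL, CNVClass.NOCALL),
    ((CNVClass.DUP, CNVClass.DUP, CNVClass.DEL), CNVClass.DUP, CNVClass.DUP),
])
def test_gene_vote_truth_table(labels, all_class, event_only):
    cat = gene_catalog(labels)
    cs = manual_callset(cat, list(labels))
    g_all = aggregate_gene_calls(cs, cat, mode="all-class")[0]
    g_evt = aggregate_gene_calls(cs, cat, mode="event-only")[0]
    assert g_all.label == all_class
    assert g_evt.label == event_only
    assert g_all.votes == g_evt.votes
    assert sum(g_all.votes) == g_all.n_exons == len(labels)


def test_gene_vote_permutation_invariant():
    labels = [CNVClass.DEL, CNVClass.NOCALL, CNVClass.DEL, CNVClass.DUP]
    cat = gene_catalog(labels)
    rng = np.random.default_rng(0)
    results = set()
    for _ in range(5):
        perm = rng.permutation(len(labels))
        cs = manual_callset(cat, [labels[i] for i in perm])
        results.add(aggregate_gene_calls(cs, cat)[0].label)
    assert results == {CNVClass.DEL}


def test_mixed_gene_votes_are_reported():
    labels = [CNVClass.DEL, CNVClass.DUP, CNVClass.DEL]
    cat = gene_catalog(labels)
    g = aggregate_gene_calls(manual_callset(cat, labels), cat)[0]
    assert g.votes == (0, 2, 1)  # mixed DEL+DUP gene measurable downstream


def test_unknown_mode_rejected(tiny_catalog):
    cs = manual_callset(tiny_catalog, [CNVClass.NOCALL] * len(tiny_catalog))
    with pytest.raises(ValueError):
        aggregate_gene_calls(cs, tiny_catalog, mode="plurality")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_tsv_round_trip(tmp_path, tiny_catalog):
    labels = [CNVClass.DEL, CNVClass.NOCALL, CNVClass.DUP, CNVClass.NOCALL,
              CNVClass.DEL, CNVClass.NOCALL]
    cs = manual_callset(tiny_catalog, labels)
    path = tmp_path / "calls.tsv"
    write_calls(cs, tiny_catalog, path, format="tsv")
    back = read_calls_tsv(path)
    for a, b in zip(cs.calls, back.calls):
        assert a.exon_id == b.exon_id and a.label == b.label
        np.testing.assert_array_equal(a.probabilities, b.probabilities)


def test_bed_output_events_only(tmp_path, tiny_catalog):
    labels = [CNVClass.DEL, CNVClass.NOCALL, CNVClass.NOCALL, CNVClass.DUP,
              CNVClass.NOCALL, CNVClass.NOCALL]
    cs = manual_callset(tiny_catalog, labels)
    path = tmp_path / "calls.bed"
    write_calls(cs, tiny_catalog, path, format="bed")
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 2
    assert lines[0].split("\t") == ["chr1", "100", "300", "DEL"]


def test_vcf_output_is_well_formed(tmp_path, tiny_catalog):
    labels = [CNVClass.DEL, CNVClass.DUP, CNVClass.NOCALL, CNVClass.DEL,
              CNVClass.NOCALL, CNVClass.DEL]
    cs = manual_callset(tiny_catalog, labels)
    path = tmp_path / "calls.vcf"
    write_calls(cs, tiny_catalog, path, format="vcf")
    with pysam.VariantFile(str(path)) as vcf:
        recs = list(vcf)
    assert len(recs) == 4
    assert all(r.info["SVTYPE"] in ("DEL", "DUP") for r in recs)
    starts = [(r.chrom, r.start) for r in recs]
    assert starts == sorted(starts)


def test_end_to_end_byte_identical_output(tmp_path, model):
    cat = spaced_catalog(8, span=30)
    rng = np.random.default_rng(9)
    windows = windows_for(cat, rng, depthless={"e4"})
    paths = []
    for run in (1, 2):
        cs = impute_missing_calls(call_exons(model, windows, cat), cat)
        p = tmp_path / f"calls{run}.tsv"
        write_calls(cs, cat, p, format="tsv")
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_gene_calls_tsv(tmp_path, tiny_catalog):
    labels = [CNVClass.DEL] * 3 + [CNVClass.NOCALL] * 3
    cs = manual_callset(tiny_catalog, labels)
    genes = aggregate_gene_calls(cs, tiny_catalog)
    path = tmp_path / "genes.tsv"
    write_calls(genes, tiny_catalog, path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1 + 3  # header + gA, gB, gC
    assert lines[1].startswith("gA\tDEL\t3")
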