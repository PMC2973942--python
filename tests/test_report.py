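import json

import numpy as np
import pytest

from mitokit import io as mio
from mitokit.datasets import NAD6_REPEAT_UNIT, load_reference_gene_set
from mitokit.model import AnnotatedGenome, GeneFeature
from mitokit.report import (
    build_report,
    detect_overlaps,
    find_direct_repeats,
    gene_content_check,
    intergenic_census,
    strand_partition,
)


def F(name, start, end, strand="+", cls="PCG"):
    return GeneFeature(name, cls, strand, start, end)


# ---------------------------------------------------------------------------
# Intergenic census

def test_census_on_published_annotation(table1):
    """The printed coordinates yield 29 maximal non-coding regions of 1-137
    bp (28 internal gaps plus the 64-bp wrap segment after trnT)."""
    census = intergenic_census(table1)
    assert (census.count, census.min_len, census.max_len) == (29, 1, 137)
    wrap = census.regions[-1]
    assert wrap.flanking == ("trnT", "cox1")
    assert (wrap.start, wrap.end, wrap.length) == (14740, 14803, 64)
    assert not wrap.wraps  # cox1 starts at position 1, so no true wrap here


def test_census_single_covering_gene_and_empty_genome():
    full = AnnotatedGenome("g", 500, features=[F("x", 1, 500)])
    assert intergenic_census(full).count == 0
    empty = intergenic_census(AnnotatedGenome("g", 500))
    assert empty.count == 1 and empty.regions[0].length == 500


def test_census_with_planted_gaps():
    # gaps of 5, 1, 0, 12 between four genes on a 100-bp circle
    feats = [F("a", 1, 20), F("b", 26, 45), F("c", 47, 60), F("d", 61, 88)]
    census = intergenic_census(AnnotatedGenome("g", 100, features=feats))
    assert sorted(census.lengths()) == [1, 5, 12]
    assert census.count == 3


def test_census_ignores_nested_features():
    feats = [F("outer", 1, 100), F("inner", 10, 20), F("next", 150, 200)]
    census = intergenic_census(AnnotatedGenome("g", 200, features=feats))
    assert census.lengths() == [49]  # 101..149 only; 21..100 is covered


def test_census_wrap_region_through_origin():
    feats = [F("a", 10, 50), F("b", 60, 90)]
    census = intergenic_census(AnnotatedGenome("g", 100, features=feats))
    wrap = [r for r in census.regions if r.wraps]
    assert len(wrap) == 1
    assert (wrap[0].start, wrap[0].end, wrap[0].length) == (91, 9, 19)


# ---------------------------------------------------------------------------
# Overlaps

def test_no_overlaps_in_published_annotation(table1):
    assert detect_overlaps(table1) == []


def test_overlap_detection():
    g = AnnotatedGenome("g", 100, features=[F("a", 1, 10), F("b", 5, 20)])
    [(a, b, ov)] = detect_overlaps(g)
    assert {a.name, b.name} == {"a", "b"} and ov == 6
    nested = AnnotatedGenome("g", 100, features=[F("a", 1, 50), F("b", 10, 20)])
    [(_, inner, ov)] = detect_overlaps(nested)
    assert ov == inner.length == 11


# ---------------------------------------------------------------------------
# Gene content and strand partition

def test_missing_genes_from_canonical_complement(table1):
    missing, extra = gene_content_check(table1)
    assert missing == {"atp8", "trnL-CUN", "trnL-UUR"}
    assert extra == []


def test_canonical_against_itself_is_clean():
    ref = load_reference_gene_set()
    names = [n for grp in ref.values() for n in grp]
    feats = [GeneFeature(n, "PCG", "+", 10 * i + 1, 10 * i + 5)
             for i, n in enumerate(names)]
    g = AnnotatedGenome("g", 10 * len(names) + 10, features=feats)
    assert gene_content_check(g, ref) == (set(), [])


def test_duplicate_gene_reported_as_extra(table1):
    feats = list(table1.features) + [F("trnM", 14750, 14799, cls="tRNA")]
    g = AnnotatedGenome("dup", table1.length, features=feats)
    missing, extra = gene_content_check(g)
    assert "trnM" in extra
    assert missing == {"atp8", "trnL-CUN", "trnL-UUR"}


def test_strand_partition(table1):
    parts = strand_partition(table1)
    assert set(parts["+"]["PCG"] + parts["+"]["rRNA"]) == {
        "cox1", "cox2", "cox3", "atp6", "rrnS", "rrnL", "nad6", "nad4"}
    assert len(parts["+"]["tRNA"]) == 14
    assert len(parts["-"]["tRNA"]) == 6
    assert set(parts["-"]["PCG"]) == {"nad5", "nad2", "cytb", "nad1", "nad4L", "nad3"}


def test_strand_partition_all_plus():
    g = AnnotatedGenome("g", 100, features=[F("a", 1, 10), F("b", 20, 40)])
    parts = strand_partition(g)
    assert parts["-"] == {"PCG": [], "rRNA": [], "tRNA": []}


# ---------------------------------------------------------------------------
# Direct repeats

from _oracles import maximal_repeats as oracle_repeats


def test_trivial_tandem_repeat():
    [(unit, positions, copies)] = find_direct_repeats("ACGTACGT", min_unit=4)
    assert (unit, positions, copies) == ("ACGT", (0, 4), 2)


def test_min_unit_guard():
    with pytest.raises(ValueError):
        find_direct_repeats("ACGT", min_unit=1)


def test_planted_42mer_repeat():
    from mitokit.synthetic import plant_tandem_unit

    rng = np.random.default_rng(3)
    seq, planted_at = plant_tandem_unit(rng, NAD6_REPEAT_UNIT, copies=2,
                                        spacer=17, context=200)
    hits = find_direct_repeats(seq, min_unit=20, min_copies=2)
    assert hits, "planted repeat not found"
    unit, positions, copies = hits[0]
    assert len(unit) == 42 and copies == 2
    assert unit == NAD6_REPEAT_UNIT
    assert list(positions) == planted_at


def test_random_sequence_has_no_long_repeats():
    rng = np.random.default_rng(11)
    seq = "".join(rng.choice(list("ATGC"), size=500,
                             p=[0.386, 0.367, 0.128, 0.119]))
    assert find_direct_repeats(seq, min_unit=20) == []


@pytest.mark.parametrize("seed", range(6))
def test_repeat_finder_agrees_with_quadratic_oracle(seed):
    rng = np.random.default_rng(seed)
    # short alphabet-skewed sequences make chance repeats plentiful
    length = int(rng.integers(50, 400))
    seq = "".join(rng.choice(list("AT" if seed % 2 else "ATGC"), size=length))
    min_unit = int(rng.integers(4, 9))
    got = {(unit, starts) for unit, starts, _ in
           find_direct_repeats(seq, min_unit=min_unit)}
    assert got == oracle_repeats(seq, min_unit)


# ---------------------------------------------------------------------------
# Aggregate report

def test_report_is_deterministic_and_recomputable(table1, tmp_path):
    r1 = build_report(table1)
    r2 = build_report(table1)
    p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
    mio.write_report(r1, p1)
    mio.write_report(r2, p2)
    assert p1.read_bytes() == p2.read_bytes()
    data = json.loads(p1.read_text())
    assert data["counts"] == {"PCG": 12, "rRNA": 2, "tRNA": 20}
    assert data["non_coding"]["count"] == 29
    assert data["gene_lengths"]["nad5"] == 1776
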