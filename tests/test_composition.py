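import math

import pytest
from hypothesis import given, settings, strategies as st

from mitokit.composition import (
    base_frequencies,
    composition_report,
    genome_skew_report,
    per_gene_skews,
    skews,
    terminal_codons,
)
from mitokit.model import AnnotatedGenome, GeneFeature, reverse_complement

dna = st.text(alphabet="ACGT", min_size=1, max_size=200)


def test_base_frequencies_trivial_cases():
    assert base_frequencies("AATT") == {"A": 50.0, "T": 50.0, "G": 0.0, "C": 0.0}
    assert base_frequencies("ACGT") == {"A": 25.0, "T": 25.0, "G": 25.0, "C": 25.0}


def test_skews_formula_and_undefined_flag():
    at, gc = skews("AATT")
    assert at == 0.0 and gc is None  # no G/C -> GC skew undefined, not an error
    at, _ = skews("AAAT")
    assert at == pytest.approx(0.5)  # (3-1)/(3+1)


def test_empty_sequence_is_an_error():
    with pytest.raises(ValueError):
        base_frequencies("")
    with pytest.raises(ValueError, match="no unambiguous"):
        composition_report("NNN")


def test_ambiguity_codes_excluded_from_percentages():
    rep = composition_report("ACGTNNRY")
    assert rep.a_pct == 25.0 and rep.n_ambiguous == 4
    assert rep.a_pct + rep.t_pct + rep.g_pct + rep.c_pct == pytest.approx(100.0)


@given(seq=dna)
@settings(max_examples=200, deadline=None)
def test_skew_antisymmetry_and_bounds(seq):
    at, gc = skews(seq)
    rat, rgc = skews(reverse_complement(seq))
    for fwd, rev in ((at, rat), (gc, rgc)):
        if fwd is None:
            assert rev is None
        else:
            assert -1.0 <= fwd <= 1.0
            assert rev == pytest.approx(-fwd)


@given(seq=dna)
@settings(max_examples=100, deadline=None)
def test_at_content_invariant_under_reverse_complement(seq):
    a = composition_report(seq)
    b = composition_report(reverse_complement(seq))
    assert a.at_content == pytest.approx(b.at_content)
    assert a.at_content == pytest.approx(a.a_pct + a.t_pct)


def test_per_gene_skews_by_direct_count():
    #           1234567890
    sequence = "AAATGCGTTC"
    g = AnnotatedGenome("g", 10, sequence=sequence, features=[
        GeneFeature("fwd", "PCG", "+", 1, 6),   # AAATGC
        GeneFeature("rev", "PCG", "-", 5, 10),  # revcomp(GCGTTC) = GAACGC
    ])
    fwd, rev = per_gene_skews(g, convention="coding")
    assert fwd.at_skew == pytest.approx((3 - 1) / 4)  # AAATGC: A3 T1
    assert fwd.gc_skew == pytest.approx(0.0)
    # minus-strand gene: statistics on its coding strand, counted directly
    from collections import Counter
    counts = Counter("GAACGC")  # revcomp of positions 5..10
    assert rev.gc_skew == pytest.approx(
        (counts["G"] - counts["C"]) / (counts["G"] + counts["C"]))
    assert rev.at_skew == pytest.approx(
        (counts["A"] - counts["T"]) / (counts["A"] + counts["T"]))


def test_per_gene_skews_negate_between_conventions_for_minus_genes():
    g = AnnotatedGenome("g", 12, sequence="AAATGCGTTCAG", features=[
        GeneFeature("rev", "PCG", "-", 2, 11),
    ])
    coding = per_gene_skews(g, convention="coding")[0]
    plus = per_gene_skews(g, convention="plus")[0]
    assert coding.at_skew == pytest.approx(-plus.at_skew)
    assert coding.gc_skew == pytest.approx(-plus.gc_skew)


def test_whole_genome_composition_matches_generator_targets(synthetic_genome):
    """Measured base frequencies converge to the generator's targets within
    3-sigma binomial bounds at the generated length."""
    genome, truth = synthetic_genome
    rep = genome_skew_report(genome)
    n = genome.length
    for base, pct in (("A", rep.a_pct), ("T", rep.t_pct),
                      ("G", rep.g_pct), ("C", rep.c_pct)):
        p = truth["composition"][base]
        sigma = math.sqrt(p * (1 - p) / n)
        assert abs(pct / 100.0 - p) < 3 * sigma, base


def test_terminal_codons_planted(synthetic_genome):
    genome, truth = synthetic_genome
    for f in genome.features_of_class("PCG"):
        start, stop = terminal_codons(genome, f)
        assert [start, stop] == truth["codons"][f.name]
        assert stop in ("TAA", "TAG")


def test_terminal_codons_errors():
    g = AnnotatedGenome("g", 20, sequence="A" * 20, features=[
        GeneFeature("tiny", "PCG", "+", 1, 5),
        GeneFeature("rna", "rRNA", "+", 6, 20),
    ])
    with pytest.raises(ValueError, match="too short"):
        terminal_codons(g, g.features[0])
    with pytest.raises(ValueError, match="not a protein-coding gene"):
        terminal_codons(g, g.features[1])


def test_display_rounding():
    rep = composition_report("AAATTTTGGC")
    shown = rep.rounded()
    assert shown["a_pct"] == 30.0 and shown["at_content"] == 70.0
    assert shown["at_skew"] == round((3 - 4) / 7, 2)
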