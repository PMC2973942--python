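import numpy as np
import pytest

from mitokit.model import AnnotatedGenome, SequenceUnavailableError
from mitokit.synthetic import PlannedTrna, sample_trna
from mitokit.trna import (
    ANTICODONS,
    anticodon_to_amino_acid,
    fold_candidate,
    scan_genome,
    validate_annotation,
)

PROBS = (0.386, 0.367, 0.128, 0.119)


def test_anticodon_labels_use_invertebrate_mito_code():
    assert anticodon_to_amino_acid("GAA") == "F"
    assert anticodon_to_amino_acid("CAT") == "M"
    assert anticodon_to_amino_acid("TCA") == "W"  # TGA codes Trp in mito code


def test_planted_canonical_trna_recovered_exactly():
    rng = np.random.default_rng(21)
    for name in ("trnF", "trnK", "trnG"):
        seq, planted = sample_trna(rng, PlannedTrna(name, "+"), PROBS)
        folded = fold_candidate(seq)
        assert folded == planted
        assert folded.mismatches == 0
        assert folded.anticodon == ANTICODONS[name]
        assert folded.dhu.present and folded.tpsic.present


def test_planted_armless_variants_flagged():
    rng = np.random.default_rng(22)
    seq, _ = sample_trna(rng, PlannedTrna("trnS-AGY", "+", dhu_absent=True), PROBS)
    folded = fold_candidate(seq)
    assert not folded.dhu.present and folded.tpsic.present
    seq, _ = sample_trna(rng, PlannedTrna("trnY", "+", t_absent=True), PROBS)
    folded = fold_candidate(seq)
    assert folded.dhu.present and not folded.tpsic.present


def test_ablating_the_t_arm_is_detected():
    """Replacing the whole TψC arm with an unpairable poly-A stretch makes
    the folder flag the arm as absent."""
    rng = np.random.default_rng(23)
    seq, planted = sample_trna(rng, PlannedTrna("trnF", "+"), PROBS)
    t = planted.tpsic
    t_len = 2 * t.stem + t.loop
    t_start = planted.length - planted.acceptor_stem - t_len
    ablated = seq[:t_start] + "A" * t_len + seq[t_start + t_len:]
    folded = fold_candidate(ablated, min_score=float("-inf"))
    assert not folded.tpsic.present
    assert folded.dhu.present


def test_fold_is_deterministic_and_context_free(synthetic_genome):
    genome, truth = synthetic_genome
    for name, info in list(truth["trnas"].items())[:5]:
        seq = info["sense_sequence"]
        assert fold_candidate(seq) == fold_candidate(seq)
        # same span, different flanking context: scan structures match fold
        assert fold_candidate(seq).to_dict() == info["structure"]


def test_expected_anticodon_constrains_the_fold():
    rng = np.random.default_rng(24)
    seq, planted = sample_trna(rng, PlannedTrna("trnF", "+"), PROBS)
    constrained = fold_candidate(seq, expected_anticodon=ANTICODONS["trnF"])
    assert constrained.anticodon == ANTICODONS["trnF"]


def test_fold_length_bounds():
    with pytest.raises(ValueError, match="outside"):
        fold_candidate("ACGT" * 5)
    with pytest.raises(ValueError, match="outside"):
        fold_candidate("ACGT" * 25)


def test_random_sequence_usually_folds_below_threshold():
    rng = np.random.default_rng(25)
    bases = np.array(list("ATGC"))
    passed = sum(
        fold_candidate("".join(rng.choice(bases, size=70, p=list(PROBS))))
        is not None
        for _ in range(100)
    )
    assert passed <= 10


def test_score_monotone_under_introduced_stem_mismatches():
    rng = np.random.default_rng(26)
    seq, planted = sample_trna(rng, PlannedTrna("trnQ", "+"), PROBS)
    # break acceptor pairs from the 3' end inward, one at a time
    scores = [planted.score]
    chars = list(seq)
    for i in range(3):
        pos = len(chars) - 1 - i
        partner = chars[i]
        bad = {"A": "C", "C": "A", "G": "G", "T": "T"}[partner]
        chars[pos] = bad
        folded = fold_candidate("".join(chars), min_score=float("-inf"))
        scores.append(folded.score)
    assert all(a >= b for a, b in zip(scores, scores[1:]))


def test_scan_recovers_all_planted_trnas(synthetic_genome):
    """Whole-genome scan: every planted tRNA is returned at its exact span,
    strand and anticodon, and any residual spurious candidate scores below
    every planted one."""
    genome, truth = synthetic_genome
    candidates = scan_genome(genome)
    by_key = {(c.start, c.end, c.strand): c for c in candidates}
    plant_scores = []
    for name, info in truth["trnas"].items():
        key = (info["start"], info["end"], info["strand"])
        assert key in by_key, f"{name} not recovered"
        assert by_key[key].anticodon == info["anticodon"]
        plant_scores.append(info["score"])
    spurious = [c for c in candidates
                if (c.start, c.end, c.strand) not in
                {(v["start"], v["end"], v["strand"]) for v in truth["trnas"].values()}]
    assert all(c.score < min(plant_scores) for c in spurious)


def test_scan_requires_sequence():
    genome = AnnotatedGenome("empty", 1000)
    with pytest.raises(SequenceUnavailableError, match="sequence unavailable"):
        scan_genome(genome)


def test_scan_is_deterministic(synthetic_genome):
    genome, _ = synthetic_genome
    a = scan_genome(genome, strand="+")
    b = scan_genome(genome, strand="+")
    assert [(c.start, c.end, c.score) for c in a] == \
        [(c.start, c.end, c.score) for c in b]


def test_validate_annotation_matches_ground_truth(synthetic_genome):
    genome, truth = synthetic_genome
    report = validate_annotation(genome)
    assert len(report) == 20
    for entry in report:
        info = truth["trnas"][entry["gene"]]
        assert entry["anticodon"] == info["anticodon"]
        assert entry["dhu_present"] == info["dhu_present"]
        assert entry["tpsic_present"] == info["tpsic_present"]
        assert entry["mismatches"] == info["mismatches"]


def test_validate_annotation_requires_sequence(table1):
    with pytest.raises(SequenceUnavailableError):
        validate_annotation(table1)
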