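"""Base composition and strand-skew statistics.

AT skew = (A% − T%)/(A% + T%) and GC skew = (G% − C%)/(G% + C%) measure
strand asymmetry of base usage; both lie in [−1, 1] and negate under
reverse complementation.  Whole-genome statistics are computed on the plus
strand; per-gene statistics default to the coding strand of each gene.
Ambiguity codes are excluded from all numerators and denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .model import (
    AnnotatedGenome,
    GeneFeature,
    coding_strand_sequence,
    normalize_sequence,
)


@dataclass(frozen=True)
class SkewReport:
    """Composition and skew of one sequence scope (whole genome or one gene)."""

    scope: str
    length: int
    a_pct: float
    t_pct: float
    g_pct: float
    c_pct: float
    at_content: float
    at_skew: float | None  # None flags an undefined (0/0) skew
    gc_skew: float | None
    n_ambiguous: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def rounded(self) -> dict:
        """Display form: 1 decimal for percentages, 2 for skews."""
        return {
            "scope": self.scope,
            "a_pct": round(self.a_pct, 1),
            "t_pct": round(self.t_pct, 1),
            "g_pct": round(self.g_pct, 1),
            "c_pct": round(self.c_pct, 1),
            "at_content": round(self.at_content, 1),
            "at_skew": None if self.at_skew is None else round(self.at_skew, 2),
            "gc_skew": None if self.gc_skew is None else round(self.gc_skew, 2),
        }


def _skew(x: int, y: int) -> float | None:
    return None if x + y == 0 else (x - y) / (x + y)


def composition_report(seq: str, scope: str = "sequence") -> SkewReport:
    """Counts, percentages and skews of one sequence."""
    seq = normalize_sequence(seq)
    if not seq:
        raise ValueError("empty sequence")
    a, t, g, c = (seq.count(b) for b in "ATGC")
    acgt = a + t + g + c
    if acgt == 0:
        raise ValueError("sequence contains no unambiguous A/C/G/T bases")
    return SkewReport(
        scope=scope,
        length=len(seq),
        a_pct=100.0 * a / acgt,
        t_pct=100.0 * t / acgt,
        g_pct=100.0 * g / acgt,
        c_pct=100.0 * c / acgt,
        at_content=100.0 * (a + t) / acgt,
        at_skew=_skew(a, t),
        gc_skew=_skew(g, c),
        n_ambiguous=len(seq) - acgt,
    )


def base_frequencies(seq: str) -> dict[str, float]:
    """Percentages of A, T, G, C (ambiguity codes excluded)."""
    rep = composition_report(seq)
    return {"A": rep.a_pct, "T": rep.t_pct, "G": rep.g_pct, "C": rep.c_pct}


def skews(seq: str) -> tuple[float | None, float | None]:
    """(AT skew, GC skew); a zero denominator yields None, not an exception."""
    rep = composition_report(seq)
    return rep.at_skew, rep.gc_skew


def genome_skew_report(genome: AnnotatedGenome) -> SkewReport:
    """Whole-genome plus-strand composition report."""
    if genome.sequence is None:
        raise ValueError(f"{genome.identifier}: sequence unavailable")
    return composition_report(genome.sequence, scope="whole-genome-plus-strand")


def per_gene_skews(genome: AnnotatedGenome, convention: str = "coding",
                   classes: tuple[str, ...] = ("PCG", "rRNA")) -> list[SkewReport]:
    """One report per protein-coding / rRNA gene.

    ``convention`` selects the strand the statistics are computed on:
    ``"coding"`` (default) uses each gene's own coding strand, ``"plus"``
    uses the plus strand regardless of gene orientation.
    """
    if convention not in ("coding", "plus"):
        raise ValueError("convention must be 'coding' or 'plus'")
    if genome.sequence is None:
        raise ValueError(f"{genome.identifier}: sequence unavailable")
    reports = []
    for f in genome.features_of_class(*classes):
        if convention == "coding":
            sub = coding_strand_sequence(genome, f)
        else:
            sub = genome.sequence[f.start - 1: f.end]
        reports.append(composition_report(sub, scope=f.name))
    return reports


def terminal_codons(genome: AnnotatedGenome, feature: GeneFeature) -> tuple[str, str]:
    """(start codon, stop codon): first and last 3 nt of the coding strand."""
    if feature.cls != "PCG":
        raise ValueError(f"{feature.name} is not a protein-coding gene")
    if feature.length < 6:
        raise ValueError(f"{feature.name}: too short ({feature.length} nt) for codons")
    seq = coding_strand_sequence(genome, feature)
    return seq[:3], seq[-3:]
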