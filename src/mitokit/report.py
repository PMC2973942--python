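"""Genome-organisation analysis: intergenic census, overlaps, gene content,
strand partition and the exact direct-repeat finder.

The census treats the genome as a circle: the stretch between the last
feature and the first one (through the origin) is one region like any
other.  Feature classes are never special-cased here; the input annotation
decides what counts as coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

from .composition import terminal_codons
from .model import AnnotatedGenome, GeneFeature


@dataclass(frozen=True)
class NonCodingRegion:
    """A maximal unannotated circular segment (1-based closed coordinates).

    ``wraps`` marks the region running through the origin, in which case
    ``start > end`` and the length counts through position 1.
    """

    start: int
    end: int
    length: int
    flanking: tuple[str, str]
    wraps: bool = False


@dataclass
class CensusResult:
    count: int
    min_len: int | None
    max_len: int | None
    regions: list[NonCodingRegion]

    def lengths(self) -> list[int]:
        return [r.length for r in self.regions]


def intergenic_census(genome: AnnotatedGenome) -> CensusResult:
    """All maximal non-coding circular segments of length >= 1.

    Works from the union of annotated intervals, so nested or overlapping
    features (which :func:`detect_overlaps` reports separately) never
    resurrect a covered stretch as a gap.
    """
    feats = genome.features
    if not feats:
        whole = NonCodingRegion(1, genome.length, genome.length, ("", ""))
        return CensusResult(1, genome.length, genome.length, [whole])
    # merge into maximal covered blocks; remember the flanking gene of each
    # block edge (the feature reaching furthest right / starting the block)
    blocks: list[list] = []  # [start, end, first_name, last_name]
    for f in feats:
        if blocks and f.start <= blocks[-1][1] + 1:
            if f.end > blocks[-1][1]:
                blocks[-1][1] = f.end
                blocks[-1][3] = f.name
        else:
            blocks.append([f.start, f.end, f.name, f.name])
    regions: list[NonCodingRegion] = []
    for (s1, e1, _, prev_name), (s2, _, next_name, _) in zip(blocks, blocks[1:]):
        regions.append(NonCodingRegion(e1 + 1, s2 - 1, s2 - e1 - 1,
                                       (prev_name, next_name)))
    first_start, last_end = blocks[0][0], blocks[-1][1]
    first_name, last_name = blocks[0][2], blocks[-1][3]
    if genome.circular:
        gap = (genome.length - last_end) + (first_start - 1)
        if gap > 0:
            start = last_end + 1 if last_end < genome.length else 1
            end = first_start - 1 if first_start > 1 else genome.length
            wraps = last_end < genome.length and first_start > 1
            regions.append(NonCodingRegion(start, end, gap,
                                           (last_name, first_name), wraps=wraps))
    else:
        if first_start > 1:
            regions.insert(0, NonCodingRegion(1, first_start - 1, first_start - 1,
                                              ("", first_name)))
        if last_end < genome.length:
            regions.append(NonCodingRegion(last_end + 1, genome.length,
                                           genome.length - last_end, (last_name, "")))
    lengths = [r.length for r in regions]
    return CensusResult(len(regions), min(lengths) if lengths else None,
                        max(lengths) if lengths else None, regions)


def detect_overlaps(genome: AnnotatedGenome) -> list[tuple[GeneFeature, GeneFeature, int]]:
    """All feature pairs that share bases, with the overlap length in bp.

    Origin-spanning features are rejected at construction time, so circular
    overlap reduces to linear interval intersection.
    """
    feats = genome.features
    hits = []
    for i, a in enumerate(feats):
        for b in feats[i + 1:]:
            ov = min(a.end, b.end) - max(a.start, b.start) + 1
            if ov > 0:
                hits.append((a, b, ov))
    return hits


def strand_partition(genome: AnnotatedGenome) -> dict[str, dict[str, list[str]]]:
    """Feature names grouped by strand, then by class."""
    out: dict[str, dict[str, list[str]]] = {
        "+": {"PCG": [], "rRNA": [], "tRNA": []},
        "-": {"PCG": [], "rRNA": [], "tRNA": []},
    }
    for f in genome.features:
        out[f.strand][f.cls].append(f.name)
    return out


def gene_content_check(
    genome: AnnotatedGenome,
    reference: Mapping[str, Sequence[str]] | Iterable[str] | None = None,
) -> tuple[set[str], list[str]]:
    """(missing, extra) gene names relative to a reference complement.

    The default reference is the canonical bilaterian set (13 protein-coding
    genes, 2 rRNAs, 22 tRNAs).  ``extra`` is a list so duplicated names of a
    reference gene also surface.
    """
    if reference is None:
        from .datasets import load_reference_gene_set

        reference = load_reference_gene_set()
    if isinstance(reference, Mapping):
        ref_names = {name for names in reference.values() for name in names}
    else:
        ref_names = set(reference)
    present = [f.name for f in genome.features]
    missing = ref_names - set(present)
    extra = sorted(set(present) - ref_names)
    seen: set[str] = set()
    for name in present:  # duplicates of reference genes
        if name in seen and name in ref_names:
            extra.append(name)
        seen.add(name)
    return missing, extra


# ---------------------------------------------------------------------------
# Exact direct repeats

def find_direct_repeats(seq: str, min_unit: int = 8,
                        min_copies: int = 2) -> list[tuple[str, tuple[int, ...], int]]:
    """Maximal exact direct repeats (tandem or dispersed) within ``seq``.

    Returns ``(unit, 0-based start positions, copies)`` triples, longest
    unit first.  A repeat is maximal when its unit cannot be extended one
    base left or right with *all* copies intact.  The default minimum unit
    of 8 bp reflects that shorter hits are mostly noise in AT-rich
    mitochondrial sequence; smaller values are accepted for toy inputs.
    """
    if min_unit < 2:
        raise ValueError("min_unit must be >= 2")
    if min_copies < 2:
        raise ValueError("min_copies must be >= 2")
    n = len(seq)
    k = min_unit
    if n < k:
        return []
    seeds: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        seeds.setdefault(seq[i:i + k], []).append(i)
    found: dict[tuple[int, ...], tuple[str, int]] = {}
    for positions in seeds.values():
        if len(positions) < min_copies:
            continue
        left, right = _extend(seq, tuple(positions), k)
        unit = seq[positions[0] - left: positions[0] + k + right]
        starts = tuple(p - left for p in positions)
        found[starts] = (unit, len(positions))
    results = [(unit, starts, copies) for starts, (unit, copies) in found.items()]
    results.sort(key=lambda r: (-len(r[0]), r[1]))
    return results


def _extend(seq: str, positions: tuple[int, ...], k: int) -> tuple[int, int]:
    """How far a seed at ``positions`` extends left/right with all copies intact."""
    n = len(seq)
    left = 0
    while all(p - left - 1 >= 0 for p in positions):
        column = {seq[p - left - 1] for p in positions}
        # overlapping copies may not run past the next copy's start
        if len(column) > 1:
            break
        left += 1
    right = 0
    while all(p + k + right < n for p in positions):
        column = {seq[p + k + right] for p in positions}
        if len(column) > 1:
            break
        right += 1
    return left, right


# ---------------------------------------------------------------------------
# Aggregate report

@dataclass
class GenomeReport:
    identifier: str
    length: int
    counts: dict[str, int]
    strands: dict[str, dict[str, list[str]]]
    census: CensusResult
    missing_genes: list[str]
    extra_genes: list[str]
    overlaps: list[dict]
    repeats: list[dict]
    gene_lengths: dict[str, int]
    codons: dict[str, list[str]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "identifier": self.identifier,
            "length": self.length,
            "counts": self.counts,
            "strands": self.strands,
            "non_coding": {
                "count": self.census.count,
                "min_len": self.census.min_len,
                "max_len": self.census.max_len,
                "regions": [asdict(r) for r in self.census.regions],
            },
            "missing_genes": self.missing_genes,
            "extra_genes": self.extra_genes,
            "overlaps": self.overlaps,
            "repeats": self.repeats,
            "gene_lengths": self.gene_lengths,
            "codons": self.codons,
        }


def build_report(genome: AnnotatedGenome,
                 reference: Mapping[str, Sequence[str]] | None = None,
                 repeat_min_unit: int = 20,
                 repeat_min_copies: int = 2) -> GenomeReport:
    """The full organisation report for one annotated genome.

    Deterministic: the same genome always yields byte-identical JSON via
    :func:`mitokit.io.write_report`.
    """
    census = intergenic_census(genome)
    missing, extra = gene_content_check(genome, reference)
    overlaps = [
        {"pair": [a.name, b.name], "overlap_bp": ov}
        for a, b, ov in detect_overlaps(genome)
    ]
    repeats = []
    codons: dict[str, list[str]] = {}
    if genome.sequence is not None:
        repeats = [
            {"unit": unit, "unit_len": len(unit), "positions": list(pos), "copies": c}
            for unit, pos, c in find_direct_repeats(
                genome.sequence, min_unit=repeat_min_unit, min_copies=repeat_min_copies)
        ]
        for f in genome.features_of_class("PCG"):
            if f.length >= 6:
                codons[f.name] = list(terminal_codons(genome, f))
    counts = {cls: len(genome.features_of_class(cls)) for cls in ("PCG", "rRNA", "tRNA")}
    return GenomeReport(
        identifier=genome.identifier,
        length=genome.length,
        counts=counts,
        strands=strand_partition(genome),
        census=census,
        missing_genes=sorted(missing),
        extra_genes=list(extra),
        overlaps=overlaps,
        repeats=repeats,
        gene_lengths={f.name: f.length for f in genome.features},
        codons=codons,
    )
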