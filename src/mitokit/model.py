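"""Core domain model for annotated circular mitochondrial genomes.

Coordinates are 1-based closed intervals, the convention used by GenBank
flat files and by printed mitogenome tables.  Circularity is handled by
index arithmetic (position ``n + 1`` wraps to 1); features that span the
origin are rejected in this version.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

FEATURE_CLASSES = ("PCG", "rRNA", "tRNA")

#: Protein-coding gene labels of the canonical bilaterian mitogenome.
PCG_NAMES = (
    "cox1", "cox2", "cox3", "cytb", "atp6", "atp8",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
RRNA_NAMES = ("rrnS", "rrnL")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

# Synonyms seen in mitochondrial GenBank records, lower-cased and stripped
# of punctuation.  Extendable at run time via ``normalize_gene_name``'s
# ``extra`` argument.
_GENE_SYNONYMS = {
    "co1": "cox1", "coi": "cox1", "cox1": "cox1", "coxi": "cox1",
    "co2": "cox2", "coii": "cox2", "cox2": "cox2", "coxii": "cox2",
    "co3": "cox3", "coiii": "cox3", "cox3": "cox3", "coxiii": "cox3",
    "cob": "cytb", "cytb": "cytb", "cyb": "cytb",
    "atp6": "atp6", "atpase6": "atp6", "atp8": "atp8", "atpase8": "atp8",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    "nad1": "nad1", "nad2": "nad2", "nad3": "nad3", "nad4": "nad4",
    "nad4l": "nad4L", "nad5": "nad5", "nad6": "nad6",
    "12s": "rrnS", "rrns": "rrnS", "srrna": "rrnS", "12srrna": "rrnS",
    "ssurrna": "rrnS", "smallsubunitribosomalrna": "rrnS", "12sribosomalrna": "rrnS",
    "16s": "rrnL", "rrnl": "rrnL", "lrrna": "rrnL", "16srrna": "rrnL",
    "lsurrna": "rrnL", "largesubunitribosomalrna": "rrnL", "16sribosomalrna": "rrnL",
    # numbered serine / leucine isoacceptors, as printed in many tables
    "trns1": "trnS-AGY", "trns2": "trnS-UCN",
    "trnl1": "trnL-CUN", "trnl2": "trnL-UUR",
}


def normalize_sequence(seq: str) -> str:
    """Upper-case a nucleotide string and map RNA U to DNA T."""
    return seq.upper().replace("U", "T")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SequenceUnavailableError(ValueError):
    """Raised when an operation needs the genome sequence and it is absent."""


def normalize_gene_name(raw: str, cls: str | None = None,
                        codon_family: str | None = None,
                        extra: dict[str, str] | None = None) -> str:
    """Map a gene/product label onto the controlled ``cox1``/``trnX`` vocabulary.

    ``codon_family`` disambiguates serine and leucine tRNA isoacceptors
    (e.g. ``"AGY"``); without it those tRNAs get the suffix ``-unk``.
    Unknown labels are returned stripped but otherwise unchanged.
    """
    label = raw.strip()
    key = re.sub(r"[\s_\-()']+", "", label).lower()
    if extra and key in extra:
        return extra[key]
    if key in _GENE_SYNONYMS:
        return _GENE_SYNONYMS[key]
    # tRNA-Ser, trnS, trn-S(uga), tRNA-Ser(AGY) ...
    m = re.match(r"^trna?([a-z]{1,3})(?:\(?([acgtunry]{3})\)?)?$", key)
    if m and (cls in (None, "tRNA")):
        aa, anticodon = m.groups()
        one = _AA3_TO_1.get(aa, aa.upper() if len(aa) == 1 else None)
        if one is not None and len(one) == 1:
            family = codon_family
            if family is None and anticodon is not None:
                family = anticodon.upper().replace("T", "U")
            if one in ("S", "L"):
                return f"trn{one}-{family.upper()}" if family else f"trn{one}-unk"
            return f"trn{one}"
    return label


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a circular genome (1-based, closed interval)."""

    name: str
    cls: str
    strand: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.cls not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.cls!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"{self.name}: need 1 <= start <= end, got {self.start}..{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def feature_length(feature: GeneFeature) -> int:
    """Length in bp of a feature under the closed-interval convention."""
    return feature.length


@dataclass
class AnnotatedGenome:
    """A circular (or linear) genome plus its ordered feature list.

    The in-memory form of a GenBank record or of a printed genome
    organisation table; ``sequence`` may be absent when only coordinates
    are known.
    """

    identifier: str
    length: int
    circular: bool = True
    sequence: str | None = None
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = normalize_sequence(self.sequence)
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"sequence has {len(self.sequence)} nt but length is {self.length}"
                )
        for f in self.features:
            if f.end > self.length:
                raise ValueError(
                    f"feature {f.name} ends at {f.end}, beyond genome length "
                    f"{self.length} (origin-spanning features are not supported)"
                )
        # duplicated gene names (e.g. a duplicated trnM) are legal input;
        # the annotation report surfaces them against a reference set
        self.features = sorted(self.features, key=lambda f: (f.start, f.end, f.name))

    def features_of_class(self, *classes: str) -> list[GeneFeature]:
        return [f for f in self.features if f.cls in classes]

    def with_sequence(self, sequence: str) -> "AnnotatedGenome":
        return replace(self, sequence=sequence)


def circular_gap(prev: GeneFeature, nxt: GeneFeature, genome_len: int) -> int:
    """Bases strictly between ``prev.end`` and ``nxt.start`` walking forward.

    For the wrap pair (last feature -> first feature) the gap runs through
    the origin.  A negative value signals that ``nxt`` overlaps ``prev``;
    it is returned, not raised, so that annotation reports can surface it.
    """
    d = nxt.start - prev.end - 1
    if nxt.start > prev.start:
        return d
    return d + genome_len


def coding_strand_sequence(genome: AnnotatedGenome, feature: GeneFeature) -> str:
    """Feature subsequence on its coding strand (reverse-complemented for −)."""
    if genome.sequence is None:
        raise SequenceUnavailableError(
            f"{genome.identifier}: sequence unavailable, cannot extract {feature.name}"
        )
    sub = genome.sequence[feature.start - 1: feature.end]
    return reverse_complement(sub) if feature.strand == "-" else sub
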