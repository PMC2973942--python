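"""Readers and writers for the formats the toolkit touches.

GenBank and FASTA go through Biopython; the feature-table TSV (a plain-text
mirror of a printed genome-organisation table), the signed gene-order token
list and the JSON/TSV reports are simple line formats handled here.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq, UndefinedSequenceError
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .model import (
    AnnotatedGenome,
    GeneFeature,
    normalize_gene_name,
    normalize_sequence,
)

_FEATURE_KEY_TO_CLASS = {"CDS": "PCG", "rRNA": "rRNA", "tRNA": "tRNA"}
_CLASS_TO_FEATURE_KEY = {v: k for k, v in _FEATURE_KEY_TO_CLASS.items()}


# ---------------------------------------------------------------------------
# GenBank

def _genbank_feature_name(feat: SeqFeature, cls: str,
                          name_map: dict[str, str] | None) -> str:
    raw = None
    for qualifier in ("gene", "product"):
        values = feat.qualifiers.get(qualifier)
        if values:
            raw = values[0]
            break
    if raw is None:
        raw = feat.type
    family = None
    note = " ".join(feat.qualifiers.get("note", []))
    m = re.search(r"codons?[ _]recognized[:= ]+([ACGTUN]{3})", note, re.I)
    if m:
        family = m.group(1).replace("T", "U")
    return normalize_gene_name(raw, cls=cls, codon_family=family, extra=name_map)


def read_genbank(path: str | Path, name_map: dict[str, str] | None = None) -> AnnotatedGenome:
    """Parse a GenBank flat file into an :class:`AnnotatedGenome`.

    Gene identification order: ``/gene`` qualifier, else ``/product``, else
    the feature key; names are normalized to the trnX/cox1 vocabulary, with
    ``name_map`` taking precedence.  Records whose ORIGIN block is missing
    yield a genome without sequence (length from the LOCUS line).  Features
    with compound (origin-spanning) locations are rejected.
    """
    record = SeqIO.read(str(path), "genbank")
    try:
        sequence: str | None = normalize_sequence(str(record.seq))
    except UndefinedSequenceError:
        sequence = None
    length = len(record.seq)
    circular = record.annotations.get("topology", "").lower() == "circular"
    features = []
    for feat in record.features:
        cls = _FEATURE_KEY_TO_CLASS.get(feat.type)
        if cls is None:
            continue
        if len(feat.location.parts) != 1:
            raise ValueError(
                f"{record.id}: feature {feat.type} at {feat.location} has a "
                "compound location (origin-spanning joins are not supported)"
            )
        name = _genbank_feature_name(feat, cls, name_map)
        features.append(
            GeneFeature(
                name=name,
                cls=cls,
                strand="-" if feat.location.strand == -1 else "+",
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
            )
        )
    return AnnotatedGenome(
        identifier=record.id or record.name,
        length=length,
        circular=circular,
        sequence=sequence,
        features=features,
    )


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    """Emit a minimal GenBank flat file (used mainly by the simulator)."""
    if genome.sequence is None:
        raise ValueError("cannot write GenBank without a sequence")
    record = SeqRecord(
        Seq(genome.sequence),
        id=genome.identifier,
        name=genome.identifier[:16].replace(" ", "_"),
        description="synthetic mitochondrial genome" if "synthetic" in genome.identifier
        else genome.identifier,
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if genome.circular else "linear",
        },
    )
    for f in genome.features:
        location = SimpleLocation(f.start - 1, f.end, strand=-1 if f.strand == "-" else 1)
        record.features.append(
            SeqFeature(location, type=_CLASS_TO_FEATURE_KEY[f.cls],
                       qualifiers={"gene": [f.name]})
        )
    SeqIO.write([record], str(path), "genbank")


# ---------------------------------------------------------------------------
# Feature table (TSV mirror of a printed genome-organisation table)

_TABLE_COLUMNS = ("gene", "class", "strand", "start", "end")


def read_feature_table(path: str | Path, genome_len: int | None = None,
                       circular: bool = True,
                       identifier: str | None = None) -> AnnotatedGenome:
    """Read a gene/class/strand/start/end TSV into a sequence-less genome.

    Header row is required.  ``# key=value`` comment lines may carry
    ``genome_length`` and ``circular``, overridden by the arguments.
    Coordinate sanity beyond basic parsing is deliberately not checked here;
    overlap detection is the annotation report's job.
    """
    path = Path(path)
    header: list[str] | None = None
    features: list[GeneFeature] = []
    meta: dict[str, str] = {}
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            for m in re.finditer(r"(\w+)=(\S+)", line):
                meta[m.group(1)] = m.group(2)
            continue
        parts = line.split("\t")
        if header is None:
            header = [p.strip().lower() for p in parts]
            missing = set(_TABLE_COLUMNS) - set(header)
            if missing:
                raise ValueError(f"{path}:{lineno}: missing columns {sorted(missing)}")
            continue
        try:
            row = dict(zip(header, (p.strip() for p in parts)))
            features.append(
                GeneFeature(
                    name=normalize_gene_name(row["gene"], cls=row["class"]),
                    cls=row["class"],
                    strand=row["strand"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                )
            )
        except (KeyError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed row: {exc}") from exc
    if header is None:
        raise ValueError(f"{path}: no header row found")
    if genome_len is None:
        if "genome_length" not in meta:
            raise ValueError(f"{path}: genome length neither given nor in header comments")
        genome_len = int(meta["genome_length"])
    if "circular" in meta:
        circular = meta["circular"].lower() in ("true", "1", "yes")
    return AnnotatedGenome(
        identifier=identifier or path.stem,
        length=genome_len,
        circular=circular,
        sequence=None,
        features=features,
    )


def write_feature_table(genome: AnnotatedGenome, path: str | Path) -> None:
    lines = [f"# genome_length={genome.length} circular={str(genome.circular).lower()}",
             "\t".join(_TABLE_COLUMNS)]
    for f in genome.features:
        lines.append(f"{f.name}\t{f.cls}\t{f.strand}\t{f.start}\t{f.end}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Multi-record FASTA -> ordered {id: sequence}; duplicate ids are an error."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{path}: duplicate FASTA identifier {record.id!r}")
        sequences[record.id] = normalize_sequence(str(record.seq))
    return sequences


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene-order token lists (one genome per line, '-' prefix = minus strand)

def read_gene_orders(path: str | Path):
    """Read a gene-order file into a list of :class:`~mitokit.geneorder.GeneOrder`."""
    from .geneorder import GeneOrder  # local import to avoid a cycle

    orders = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ValueError(f"{path}:{lineno}: need an identifier and >= 3 gene tokens")
        tokens = []
        for tok in fields[1:]:
            sign = -1 if tok.startswith("-") else 1
            label = tok.lstrip("+-")
            if not label:
                raise ValueError(f"{path}:{lineno}: empty gene token")
            tokens.append((label, sign))
        orders.append(GeneOrder(fields[0], tuple(tokens)))
    return orders


def write_gene_orders(orders: Iterable, path: str | Path) -> None:
    lines = []
    for order in orders:
        toks = " ".join(("-" if s < 0 else "") + label for label, s in order.tokens)
        lines.append(f"{order.identifier}\t{toks}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Reports

def write_report(report, path: str | Path, fmt: str = "json") -> None:
    """Serialize a report (dict or dataclass with ``to_dict``) deterministically."""
    data = report.to_dict() if hasattr(report, "to_dict") else report
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(data, indent=2, sort_keys=False) + "\n")
    elif fmt == "tsv":
        lines = [f"{key}\t{_tsv_cell(value)}" for key, value in _flatten(data)]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _tsv_cell(value) -> str:
    if isinstance(value, (list, tuple)):
        return ",".join(str(v) for v in value)
    return str(value)


def _flatten(data, prefix=""):
    for key, value in data.items():
        name = f"{prefix}{key}"
        if isinstance(value, dict):
            yield from _flatten(value, prefix=f"{name}.")
        else:
            yield name, value
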