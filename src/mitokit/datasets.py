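"""Accessors for the data shipped with the package.

The Symsagittifera roscoffensis fixture is a transcription of the published
genome-organisation table for GenBank HM237350 (coordinates only; the
sequence itself is not redistributed).  A checksum guards the transcription
against accidental edits.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path

import yaml

from .io import read_feature_table, read_gene_orders
from .model import AnnotatedGenome

#: 42-bp direct-repeat unit found in the nad6 gene of S. roscoffensis
#: (5'->3' on the coding strand).
NAD6_REPEAT_UNIT = "TGAGAAATTTACAATCAAATTTTAACTATTTCTCCTAGATTT"

_ROSCOFFENSIS_TSV = "symsagittifera_roscoffensis.tsv"
#: sha256 of the transcription, pinned when the table was transcribed
_ROSCOFFENSIS_SHA256 = \
    "d291a6801b1e56ecdcca4ef7cf132b590fd30b422d43ae20783653703943033c"


def _data_path(name: str) -> Path:
    return Path(resources.files("mitokit.data") / name)


def data_checksum(name: str = _ROSCOFFENSIS_TSV) -> str:
    return hashlib.sha256(_data_path(name).read_bytes()).hexdigest()


def load_roscoffensis() -> AnnotatedGenome:
    """The S. roscoffensis annotation fixture (14803 bp, circular, 34 genes)."""
    digest = data_checksum()
    if digest != _ROSCOFFENSIS_SHA256:
        raise ValueError(
            "shipped annotation table has been modified "
            f"(sha256 {digest}, expected {_ROSCOFFENSIS_SHA256})")
    return read_feature_table(_data_path(_ROSCOFFENSIS_TSV),
                              identifier="S_roscoffensis_HM237350")


def load_reference_gene_set(name: str = "bilaterian_canonical") -> dict[str, list[str]]:
    """A reference gene complement, as {class: [gene names]}."""
    with open(_data_path("reference_sets.yaml")) as handle:
        sets = yaml.safe_load(handle)
    if name not in sets:
        raise KeyError(f"unknown reference set {name!r}; have {sorted(sets)}")
    return sets[name]


def load_gene_orders():
    """Shipped comparative gene orders (protein-coding + rRNA, signed)."""
    return read_gene_orders(_data_path("mitogenome_orders.order"))
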