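"""Synthetic annotated-mitogenome generator with machine-readable ground truth.

The generator emulates a small AT-rich circular mitochondrial genome:
~15 kb, features of three classes on both strands, short intergenic gaps
(a configurable mixture of exactly planted gap lengths and geometric
noise), planted cloverleaf tRNAs with optionally missing DHU/TψC arms and
planted stem mismatches, planted terminal codons, and a planted direct
repeat inside one gene.  Everything downstream modules should find is
recorded in the returned ground-truth dictionary, so tests can compare
reports against the plan rather than against the implementation.

Sequence is sampled i.i.d. per base from the target composition on the
plus strand (no codon model: the composition claims the generator backs
only need base frequencies).  Structured elements (tRNAs, codons, repeat
units) overwrite their spans afterwards.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import trna as trna_mod
from .geneorder import GeneOrder
from .io import write_fasta, write_feature_table, write_genbank, write_gene_orders
from .model import AnnotatedGenome, GeneFeature, reverse_complement
from .trna import ANTICODONS, DEFAULT_CONFIG, FoldConfig, fold_candidate

_BASES = np.array(list("ATGC"))
_WC = {"A": "T", "T": "A", "G": "C", "C": "G"}

START_CODONS = ("ATG", "ATT", "ATA", "ATC")
STOP_CODONS = ("TAA", "TAG")


@dataclass(frozen=True)
class PlannedGene:
    name: str
    cls: str
    length: int
    strand: str


@dataclass(frozen=True)
class PlannedTrna:
    name: str
    strand: str
    anticodon: str | None = None  # None -> conventional anticodon for the name
    dhu_absent: bool = False
    t_absent: bool = False
    mismatches: int = 0


@dataclass(frozen=True)
class PlannedRepeat:
    unit: str  # sense-strand unit sequence
    copies: int
    host: str  # gene name the copies are planted into
    spacer: int = 10


@dataclass(frozen=True)
class GenomeSpec:
    """Everything :func:`generate` needs; fully determines the output
    together with nothing else (the seed is part of the spec)."""

    identifier: str
    length: int
    composition: tuple[float, float, float, float]  # pA, pT, pG, pC
    genes: tuple[PlannedGene, ...]  # PCG + rRNA plan
    trnas: tuple[PlannedTrna, ...]
    planted_gaps: tuple[int, ...] = ()
    gap_mean: float = 20.0
    repeat: PlannedRepeat | None = None
    order: tuple[str, ...] | None = None  # explicit circular order, else shuffled
    #: fraction of A/T probability mass moved to G/C inside tRNA stems;
    #: structural RNA stems are GC-enriched relative to AT-rich genomes
    stem_gc_shift: float = 0.25
    seed: int = 1

    def __post_init__(self) -> None:
        if abs(sum(self.composition) - 1.0) > 1e-9:
            raise ValueError("composition probabilities must sum to 1")


def roscoffensis_like(seed: int = 1) -> GenomeSpec:
    """The default study spec: a 14803-bp AT-rich genome with 12 protein
    genes, 2 rRNAs and 20 tRNAs, strand usage, gene lengths, gap extremes
    (1 and 137 bp plus five zero gaps) and tRNA arm losses modelled on the
    S. roscoffensis annotation; one 42-bp direct repeat planted in nad6."""
    from .datasets import NAD6_REPEAT_UNIT

    pcg_lengths = {
        "cox1": (1551, "+"), "cox2": (741, "+"), "cox3": (792, "+"),
        "atp6": (702, "+"), "nad5": (1776, "-"), "nad6": (480, "+"),
        "nad4": (1350, "+"), "nad2": (990, "-"), "cytb": (1161, "-"),
        "nad1": (870, "-"), "nad4L": (270, "-"), "nad3": (393, "-"),
    }
    genes = tuple(PlannedGene(n, "PCG", ln, st) for n, (ln, st) in pcg_lengths.items())
    genes += (PlannedGene("rrnS", "rRNA", 764, "+"),
              PlannedGene("rrnL", "rRNA", 942, "+"))
    plus_trnas = ("trnF", "trnY", "trnV", "trnN", "trnH", "trnE", "trnK",
                  "trnA", "trnR", "trnS-AGY", "trnS-UCN", "trnM", "trnG", "trnT")
    minus_trnas = ("trnD", "trnI", "trnQ", "trnW", "trnP", "trnC")
    dhu_absent = {"trnS-AGY", "trnD"}
    t_absent = {"trnA", "trnH", "trnI", "trnM", "trnT", "trnE", "trnY"}
    trnas = tuple(
        PlannedTrna(name, strand, dhu_absent=name in dhu_absent,
                    t_absent=name in t_absent)
        for names, strand in ((plus_trnas, "+"), (minus_trnas, "-"))
        for name in names
    )
    return GenomeSpec(
        identifier="roscoffensis_like",
        length=14803,
        composition=(0.386, 0.367, 0.128, 0.119),
        genes=genes,
        trnas=trnas,
        planted_gaps=(137, 1, 0, 0, 0, 0, 0),
        gap_mean=20.0,
        repeat=PlannedRepeat(NAD6_REPEAT_UNIT, 2, "nad6", spacer=12),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# tRNA sampling

def _rand_seq(rng: np.random.Generator, k: int, probs) -> str:
    return "".join(rng.choice(_BASES, size=k, p=list(probs)))


def stem_composition(probs, shift: float = 0.25) -> tuple[float, ...]:
    """Move a fraction of A/T probability mass to G/C (stem enrichment)."""
    p_a, p_t, p_g, p_c = probs
    moved = shift * (p_a + p_t)
    return (p_a * (1 - shift), p_t * (1 - shift),
            p_g + moved / 2, p_c + moved / 2)


def _sample_trna_once(rng, plan: PlannedTrna, probs, stem_probs,
                      cfg: FoldConfig):
    """One draw of a cloverleaf sequence plus its intended structure."""
    anticodon = plan.anticodon or ANTICODONS.get(plan.name)
    if anticodon is None:
        raise ValueError(f"no conventional anticodon known for {plan.name}")
    a, sp1, sp2, c, cl = 7, 2, 1, 5, 7

    def stem(length):
        left = _rand_seq(rng, length, stem_probs)
        right = "".join(_WC[b] for b in reversed(left))
        return left, right

    parts: list[str] = []
    acc5, acc3 = stem(a)
    parts.append(acc5)
    parts.append(_rand_seq(rng, sp1, probs))
    if plan.dhu_absent:
        d, dl = 0, int(rng.integers(4, 7))
        parts.append(_rand_seq(rng, dl, probs))
    else:
        d = int(rng.integers(3, 5))
        dl = int(rng.integers(7, 10))
        dl5, dl3 = stem(d)
        parts.extend([dl5, _rand_seq(rng, dl, probs), dl3])
    parts.append(_rand_seq(rng, sp2, probs))
    ac5, ac3 = stem(c)
    # anticodon loop follows the universal pattern: U(T) immediately 5' of
    # the anticodon (position 33) and a purine immediately 3' of it (37)
    flank = (cl - 3) // 2
    left_flank = _rand_seq(rng, flank - 1, probs) + "T"
    purine = str(rng.choice(["A", "G"], p=[0.75, 0.25]))
    right_flank = purine + _rand_seq(rng, flank - 1, probs)
    parts.extend([ac5, left_flank, anticodon, right_flank, ac3])
    if plan.t_absent:
        t, tl = 0, 0
        v = int(rng.integers(6, 11))
    else:
        t, tl = 5, 7
        v = int(rng.integers(3, 6))
    parts.append(_rand_seq(rng, v, probs))
    if not plan.t_absent:
        t5, t3 = stem(t)
        parts.extend([t5, _rand_seq(rng, tl, probs), t3])
    parts.append(acc3)
    seq = list("".join(parts))

    # plant stem mismatches: break the 3' partner of randomly chosen pairs
    pair_index: list[tuple[int, int]] = []
    L = len(seq)
    pair_index += [(i, L - 1 - i) for i in range(a)]
    off = a + sp1
    if d:
        pair_index += [(off + i, off + 2 * d + dl - 1 - i) for i in range(d)]
    ac_base = a + sp1 + (2 * d + dl) + sp2
    pair_index += [(ac_base + i, ac_base + 2 * c + cl - 1 - i) for i in range(c)]
    if t:
        t_base = L - a - (2 * t + tl)
        pair_index += [(t_base + i, t_base + 2 * t + tl - 1 - i) for i in range(t)]
    chosen = rng.choice(len(pair_index), size=plan.mismatches, replace=False)
    for idx in sorted(int(i) for i in chosen):
        i, j = pair_index[idx]
        bad = [b for b in "ATGC"
               if not trna_mod._PAIRS[trna_mod.encode(seq[i])[0],
                                      trna_mod.encode(b)[0]]]
        seq[j] = str(rng.choice(bad))
    expected = {
        "length": L, "acceptor_stem": a, "spacer1": sp1,
        "dhu_present": not plan.dhu_absent, "dhu_stem": d, "dhu_loop": dl,
        "spacer2": sp2, "ac_stem": c, "ac_loop": cl,
        "anticodon": anticodon, "variable_loop": v,
        "tpsic_present": not plan.t_absent, "t_stem": t, "t_loop": tl,
        "mismatches": plan.mismatches,
    }
    return "".join(seq), expected


def _structure_matches(structure, expected) -> bool:
    s = structure
    return (
        s.length == expected["length"]
        and s.acceptor_stem == expected["acceptor_stem"]
        and s.spacer1 == expected["spacer1"]
        and s.dhu.present == expected["dhu_present"]
        and s.dhu.stem == expected["dhu_stem"]
        and (not s.dhu.present or s.dhu.loop == expected["dhu_loop"])
        and s.spacer2 == expected["spacer2"]
        and s.anticodon_arm.stem == expected["ac_stem"]
        and s.anticodon_arm.loop == expected["ac_loop"]
        and s.anticodon == expected["anticodon"]
        and s.variable_loop == expected["variable_loop"]
        and s.tpsic.present == expected["tpsic_present"]
        and (not s.tpsic.present or (s.tpsic.stem == expected["t_stem"]
                                     and s.tpsic.loop == expected["t_loop"]))
        and s.mismatches == expected["mismatches"]
    )


def sample_trna(rng: np.random.Generator, plan: PlannedTrna, probs,
                stem_probs=None, cfg: FoldConfig = DEFAULT_CONFIG,
                max_tries: int = 100):
    """A cloverleaf sequence whose best fold is exactly the planted one.

    Draws are rejected until the deterministic folder recovers the planted
    geometry, so 'planted structure' and 'recoverable structure' coincide
    by construction (see the methods note).
    """
    from .trna import _scan_linear

    if stem_probs is None:
        stem_probs = stem_composition(probs)
    for _ in range(max_tries):
        seq, expected = _sample_trna_once(rng, plan, probs, stem_probs, cfg)
        structure = fold_candidate(seq, cfg=cfg, min_score=float("-inf"))
        if structure is None or not _structure_matches(structure, expected):
            continue
        # the planted span must strictly dominate every sub-window and every
        # reverse-complement reading (stems pair equally well both ways), or
        # the ground truth would be ambiguous to any detector
        hits = _scan_linear(seq, cfg, structure.score, False)
        if [(s, l) for s, l, _ in hits] != [(0, len(seq))]:
            continue
        if _scan_linear(reverse_complement(seq), cfg, structure.score, False):
            continue
        return seq, structure
    raise RuntimeError(f"could not sample a uniquely foldable tRNA for {plan.name}")


# ---------------------------------------------------------------------------
# Genome assembly

def generate(spec: GenomeSpec) -> tuple[AnnotatedGenome, dict]:
    """Build the genome and its ground-truth record (deterministic per spec)."""
    rng = np.random.default_rng(spec.seed)
    probs = tuple(spec.composition)

    # conservative over-packing check before any sampling
    fixed = sum(g.length for g in spec.genes)
    min_total = fixed + 40 * len(spec.trnas) + sum(spec.planted_gaps)
    if min_total > spec.length:
        raise ValueError(
            f"spec over-packed: >= {min_total} bp of features/gaps in a "
            f"{spec.length} bp genome")

    trna_seqs: dict[str, tuple[str, object]] = {}
    stem_probs = stem_composition(probs, spec.stem_gc_shift)
    for plan in spec.trnas:
        trna_seqs[plan.name] = sample_trna(rng, plan, probs, stem_probs)

    planned: list[tuple[str, str, int, str]] = [
        (g.name, g.cls, g.length, g.strand) for g in spec.genes
    ] + [
        (p.name, "tRNA", len(trna_seqs[p.name][0]), p.strand) for p in spec.trnas
    ]
    total_features = sum(ln for _, _, ln, _ in planned)
    remaining = spec.length - total_features
    if remaining < sum(spec.planted_gaps):
        raise ValueError("spec over-packed after tRNA sampling")

    if spec.order is not None:
        by_name = {p[0]: p for p in planned}
        if set(spec.order) != set(by_name):
            raise ValueError("explicit order must list every planned gene once")
        planned = [by_name[n] for n in spec.order]
    else:
        planned = [planned[i] for i in rng.permutation(len(planned))]

    n_slots = len(planned)
    gaps = _place_gaps(rng, n_slots, spec.planted_gaps, remaining, spec.gap_mean)

    features: list[GeneFeature] = []
    cursor = 1
    for (name, cls, length, strand), gap_after in zip(planned, gaps):
        features.append(GeneFeature(name, cls, strand, cursor, cursor + length - 1))
        cursor += length + gap_after
    assert cursor - 1 == spec.length

    seq = list(_rand_seq(rng, spec.length, probs))
    codons: dict[str, list[str]] = {}
    for feat in features:
        if feat.cls == "tRNA":
            plus_seg = trna_seqs[feat.name][0]
            if feat.strand == "-":
                plus_seg = reverse_complement(plus_seg)
            seq[feat.start - 1: feat.end] = plus_seg
        elif feat.cls == "PCG":
            start_codon = str(rng.choice(START_CODONS))
            stop_codon = str(rng.choice(STOP_CODONS, p=[0.9, 0.1]))
            _write_sense(seq, feat, 0, start_codon)
            _write_sense(seq, feat, feat.length - 3, stop_codon)
            codons[feat.name] = [start_codon, stop_codon]

    repeats_truth = []
    if spec.repeat is not None:
        repeats_truth.append(_plant_repeat(rng, seq, features, spec.repeat))

    _ensure_trna_uniqueness(rng, seq, features, trna_seqs, codons,
                            repeats_truth, spec)

    genome = AnnotatedGenome(
        identifier=f"synthetic_{spec.identifier}_seed{spec.seed}",
        length=spec.length,
        circular=True,
        sequence="".join(seq),
        features=features,
    )
    truth = _ground_truth(spec, genome, gaps, trna_seqs, codons, repeats_truth)
    return genome, truth


def _place_gaps(rng, n_slots, planted, remaining, gap_mean) -> list[int]:
    """Assign planted gap lengths to random slots; fill the rest with scaled
    geometric noise so the circle closes exactly."""
    if len(planted) > n_slots:
        raise ValueError("more planted gaps than inter-feature slots")
    gaps = [-1] * n_slots
    slots = rng.choice(n_slots, size=len(planted), replace=False)
    for slot, value in zip(slots, planted):
        gaps[int(slot)] = int(value)
    free = [i for i, g in enumerate(gaps) if g < 0]
    rest = remaining - sum(planted)
    if not free:
        if rest:
            raise ValueError("no free slots left to absorb remaining length")
        return gaps
    raw = rng.geometric(1.0 / (gap_mean + 1.0), size=len(free)).astype(float)
    scaled = raw * (rest / raw.sum())
    base = np.floor(scaled).astype(int)
    shortfall = rest - int(base.sum())
    order = np.argsort(-(scaled - base), kind="stable")
    for j in range(shortfall):
        base[order[j]] += 1
    for i, g in zip(free, base):
        gaps[i] = int(g)
    return gaps


def _write_sense(seq: list[str], feat: GeneFeature, sense_offset: int,
                 text: str) -> None:
    """Write ``text`` at a sense-strand offset of a feature (strand-aware)."""
    if feat.strand == "+":
        start0 = feat.start - 1 + sense_offset
        seq[start0: start0 + len(text)] = text
    else:
        rc = reverse_complement(text)
        end0 = feat.end - 1 - sense_offset
        seq[end0 - len(text) + 1: end0 + 1] = rc


def _ensure_trna_uniqueness(rng, seq, features, trna_seqs, codons,
                            repeats_truth, spec, max_mutations: int = 400) -> None:
    """Make every planted tRNA span the strict best fold in its neighbourhood.

    Flanking sequence is random, so occasionally a window overlapping a
    planted tRNA (often the same span extended by a base, or its reverse
    complement) outscores the plant; such ground truth would be ambiguous.
    Free bases (anything outside tRNA spans, planted codons and the planted
    repeat) are redrawn until each plant is the unique local optimum.
    """
    cfg = DEFAULT_CONFIG
    n = len(seq)
    protected = np.zeros(n, dtype=bool)
    for f in features:
        if f.cls == "tRNA":
            protected[f.start - 1: f.end] = True
        elif f.cls == "PCG":
            protected[f.start - 1: f.start + 2] = True
            protected[f.end - 3: f.end] = True
    for rec in repeats_truth:
        for pos in rec["positions"]:
            protected[pos: pos + rec["unit_len"]] = True

    trna_feats = [f for f in features if f.cls == "tRNA"]
    plant_spans = [(f.start - 1, f.end, trna_seqs[f.name][1].score)
                   for f in trna_feats]
    mutations = 0
    queue = list(trna_feats)
    while queue:
        feat = queue.pop(0)
        plant_score = trna_seqs[feat.name][1].score
        offender = _best_overlapping_window(seq, feat, plant_score, cfg, n,
                                            plant_spans)
        if offender is None:
            continue
        candidates = [i for i in offender if not protected[i]]
        if not candidates:
            neighbourhood = [(feat.start - 1 - cfg.max_len + j) % n
                             for j in range(feat.length + 2 * cfg.max_len)]
            candidates = [i for i in neighbourhood if not protected[i]]
        if not candidates or mutations >= max_mutations:
            raise RuntimeError(
                f"could not make {feat.name} the unique local fold optimum")
        i = int(rng.choice(candidates))
        seq[i] = str(rng.choice([b for b in "ATGC" if b != seq[i]]))
        mutations += 1
        # a mutation may affect any tRNA whose neighbourhood contains it
        queue.append(feat)
        for other in trna_feats:
            if other is not feat and other not in queue and \
                    abs(other.start - feat.start) < 2 * cfg.max_len:
                queue.append(other)


def _best_overlapping_window(seq, feat, plant_score, cfg, n, plant_spans):
    """Genome positions of the best window overlapping ``feat`` that would
    displace it under greedy selection, or None if the plant is safe.

    The neighbourhood is taken circularly (plants at the origin are windows
    like any other) and both strands are checked.  A window that also
    overlaps another planted tRNA of higher score is harmless: that plant
    claims its bases first.
    """
    from .trna import _scan_linear
    s0, e0 = feat.start - 1, feat.end - 1
    start = s0 - (cfg.max_len - 1)
    idx = [(start + j) % n for j in range(feat.length + 2 * (cfg.max_len - 1))]
    region = "".join(seq[i] for i in idx)
    plant_lo = cfg.max_len - 1  # local coordinates of the planted span
    plant_hi = plant_lo + feat.length
    worst = None
    for strand in "+-":
        text = region if strand == "+" else reverse_complement(region)
        for start0, length, score in _scan_linear(text, cfg, plant_score, False):
            if strand == "+":
                local_lo = start0
            else:
                local_lo = len(region) - start0 - length
            local_hi = local_lo + length
            if local_hi <= plant_lo or local_lo >= plant_hi:
                continue  # does not overlap the plant
            exact_span = local_lo == plant_lo and local_hi == plant_hi
            if exact_span and strand == feat.strand and score <= plant_score:
                continue  # the plant itself
            positions = [idx[j] for j in range(local_lo, local_hi)]
            blocked = any(
                pscore > score and any(ps <= p < pe for p in positions)
                for ps, pe, pscore in plant_spans
                if not (ps == s0 and pe == e0 + 1))
            if blocked:
                continue
            if worst is None or score > worst[1]:
                worst = (positions, score)
    return None if worst is None else worst[0]


def plant_tandem_unit(rng: np.random.Generator, unit: str, copies: int = 2,
                      spacer: int = 12, context: int = 150) -> tuple[str, list[int]]:
    """A random sequence carrying ``copies`` exact copies of ``unit``.

    Flanking bases are drawn so that the columns just outside the copies
    disagree, making the planted unit itself the maximal repeat.  Returns
    the sequence and the 0-based copy start positions.
    """
    probs = (0.386, 0.367, 0.128, 0.119)
    parts = [_rand_seq(rng, context, probs)]
    positions = []
    cursor = context
    for i in range(copies):
        positions.append(cursor)
        parts.append(unit)
        cursor += len(unit)
        if i < copies - 1:
            parts.append(_rand_seq(rng, spacer, probs))
            cursor += spacer
    parts.append(_rand_seq(rng, context, probs))
    chars = list("".join(parts))
    for edge in (-1, len(unit)):
        cols = [p + edge for p in positions]
        while len({chars[c] for c in cols}) == 1:
            c = cols[0]
            chars[c] = str(rng.choice([b for b in "ATGC" if b != chars[c]]))
    return "".join(chars), positions


def _plant_repeat(rng, seq, features, plan: PlannedRepeat) -> dict:
    host = next(f for f in features if f.name == plan.host)
    unit_len = len(plan.unit)
    block = plan.copies * unit_len + (plan.copies - 1) * plan.spacer
    lo, hi = 3, host.length - 3 - block
    if hi < lo:
        raise ValueError(f"repeat block of {block} bp does not fit inside {plan.host}")
    offset = int(rng.integers(lo, hi + 1))
    sense_offsets = [offset + i * (unit_len + plan.spacer) for i in range(plan.copies)]
    for o in sense_offsets:
        _write_sense(seq, host, o, plan.unit)
    # pin down maximality: flanking columns must disagree across copies
    _break_extension(rng, seq, host, sense_offsets, unit_len)
    if host.strand == "+":
        plus_positions = sorted(host.start - 1 + o for o in sense_offsets)
        plus_unit = plan.unit
    else:
        plus_positions = sorted(host.end - unit_len - o for o in sense_offsets)
        plus_unit = reverse_complement(plan.unit)
    return {"unit": plus_unit, "unit_len": unit_len, "sense_unit": plan.unit,
            "positions": plus_positions, "copies": plan.copies, "host": plan.host}


def _break_extension(rng, seq, host, sense_offsets, unit_len) -> None:
    for edge in (-1, unit_len):
        cols = [o + edge for o in sense_offsets]
        while True:
            bases = {_read_sense(seq, host, c) for c in cols}
            if len(bases) > 1:
                break
            c = cols[0]
            _write_sense(seq, host, c,
                         str(rng.choice([b for b in "ATGC"
                                         if b != _read_sense(seq, host, c)])))


def _read_sense(seq, feat, sense_offset):
    if feat.strand == "+":
        return seq[feat.start - 1 + sense_offset]
    return _WC[seq[feat.end - 1 - sense_offset]]


def _ground_truth(spec, genome, gaps, trna_seqs, codons, repeats) -> dict:
    features = genome.features
    order_tokens = [(f.name, 1 if f.strand == "+" else -1)
                    for f in features if f.cls in ("PCG", "rRNA")]
    gap_entries = []
    # gaps[i] follows the i-th feature; placement order equals coordinate order
    placed = sorted(features, key=lambda f: f.start)
    for i, gap in enumerate(gaps):
        prev = placed[i]
        nxt = placed[(i + 1) % len(placed)]
        gap_entries.append({"after": prev.name, "before": nxt.name, "length": int(gap)})
    positive = [g["length"] for g in gap_entries if g["length"] > 0]
    trna_truth = {}
    for plan in spec.trnas:
        feat = next(f for f in features if f.name == plan.name)
        seq, structure = trna_seqs[plan.name]
        trna_truth[plan.name] = {
            "start": feat.start, "end": feat.end, "strand": feat.strand,
            "anticodon": structure.anticodon,
            "dhu_present": structure.dhu.present,
            "tpsic_present": structure.tpsic.present,
            "mismatches": structure.mismatches,
            "score": structure.score,
            "structure": structure.to_dict(),
            "sense_sequence": seq,
        }
    strands = {"+": {"PCG": [], "rRNA": [], "tRNA": []},
               "-": {"PCG": [], "rRNA": [], "tRNA": []}}
    for f in features:
        strands[f.strand][f.cls].append(f.name)
    return {
        "identifier": genome.identifier,
        "seed": spec.seed,
        "length": spec.length,
        "composition": {"A": spec.composition[0], "T": spec.composition[1],
                        "G": spec.composition[2], "C": spec.composition[3]},
        "features": [{"name": f.name, "class": f.cls, "strand": f.strand,
                      "start": f.start, "end": f.end, "length": f.length}
                     for f in features],
        "gaps": gap_entries,
        "census": {"count": len(positive),
                   "min": min(positive) if positive else None,
                   "max": max(positive) if positive else None,
                   "lengths": sorted(positive)},
        "strand_partition": strands,
        "gene_order_pcg_rrna": [[n, s] for n, s in order_tokens],
        "codons": codons,
        "trnas": trna_truth,
        "repeats": repeats,
    }


# ---------------------------------------------------------------------------
# Gene-order scrambling (supports rearrangement property tests)

def scramble_order(order: GeneOrder, k: int,
                   ops: tuple[str, ...] = ("transposition", "inversion", "tdrl"),
                   seed: int | None = None,
                   rng: np.random.Generator | None = None,
                   ) -> tuple[GeneOrder, list[dict]]:
    """Apply ``k`` random rearrangement events and return the event log.

    Supported events mirror the mechanisms common in mitochondrial genome
    evolution: segment transposition, signed inversion, and tandem
    duplication – random loss (TDRL).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    toks = list(order.tokens)
    events: list[dict] = []
    for _ in range(k):
        op = str(rng.choice(list(ops)))
        n = len(toks)
        if op == "inversion":
            i = int(rng.integers(0, n))
            j = int(rng.integers(i, n))
            toks[i:j + 1] = [(label, -s) for label, s in reversed(toks[i:j + 1])]
            events.append({"op": "inversion", "span": [i, j]})
        elif op == "transposition":
            i = int(rng.integers(0, n))
            j = int(rng.integers(i + 1, n + 1))
            seg = toks[i:j]
            rest = toks[:i] + toks[j:]
            m = int(rng.integers(0, len(rest) + 1))
            toks = rest[:m] + seg + rest[m:]
            events.append({"op": "transposition", "span": [i, j - 1], "to": m})
        elif op == "tdrl":
            mask = rng.integers(0, 2, size=n)
            if mask.min() == mask.max():  # degenerate: everything in one copy
                mask[int(rng.integers(0, n))] ^= 1
            first = [t for t, m in zip(toks, mask) if m == 0]
            second = [t for t, m in zip(toks, mask) if m == 1]
            toks = first + second
            events.append({"op": "tdrl", "kept_in_first": [int(m) for m in mask]})
        else:
            raise ValueError(f"unknown rearrangement op {op!r}")
    return GeneOrder(f"{order.identifier}_x{k}", tuple(toks)), events


# ---------------------------------------------------------------------------
# Output bundle (used by the CLI `simulate` command)

def write_outputs(genome: AnnotatedGenome, truth: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta({genome.identifier: genome.sequence}, outdir / "genome.fasta")
    write_genbank(genome, outdir / "genome.gb")
    write_feature_table(genome, outdir / "features.tsv")
    from .geneorder import extract_order

    write_gene_orders([extract_order(genome)], outdir / "genome.order")
    (outdir / "ground_truth.json").write_text(
        json.dumps(truth, indent=2, sort_keys=False) + "\n")
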