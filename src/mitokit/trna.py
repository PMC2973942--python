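"""Simplified mitochondrial tRNA cloverleaf folding and detection.

A candidate span is decomposed as

    acceptor-5' | spacer | DHU arm | spacer | anticodon arm | variable
    loop | TψC arm | acceptor-3'

where the DHU or the TψC arm may be replaced by an unpaired stretch
(mitochondrial tRNAs frequently lack one of the two).  Every admissible
geometry within the configured bounds is scored by summing hydrogen bonds
over the intended stem positions (G·C = 3, A·T = 2, G·T wobble = 1),
subtracting penalties for stem mismatches and non-canonical loop sizes,
and adding a completeness bonus for every full-length, perfectly paired
stem.  The bond weighting and the completeness bonus are what separate
genuine cloverleaves from the spurious folds that AT-rich random sequence
produces in abundance; thresholds are calibrated empirically on simulated
sequence (see the methods note).  This is a secondary-structure heuristic
in the spirit of lightweight mitochondrial tRNA finders, not a covariance
model: scores have no probabilistic interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from functools import lru_cache

import numpy as np

from Bio.Data import CodonTable

from .model import AnnotatedGenome, SequenceUnavailableError, reverse_complement

_PAD = 96  # longer than any candidate, pads score arrays at the 3' end

# encoding A C G T other -> 0..4
_ENCODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i

# Stem pairing: Watson-Crick plus G·T wobble.  Scores sum hydrogen-bond
# weights; wobble pairs are tolerated but rewarded far below WC pairs,
# which is what keeps AT-rich random sequence from faking stems.
_PAIRS = np.zeros((5, 5), dtype=bool)
_BONDS = np.zeros((5, 5), dtype=np.float32)
for _x, _y, _w in ((0, 3, 2.0), (3, 0, 2.0),   # A·T
                   (1, 2, 3.0), (2, 1, 3.0),   # C·G
                   (2, 3, 0.5), (3, 2, 0.5)):  # G·T wobble
    _PAIRS[_x, _y] = True
    _BONDS[_x, _y] = _w

#: Conventional (DNA) anticodons used for labelling and by the simulator.
ANTICODONS = {
    "trnA": "TGC", "trnR": "TCG", "trnN": "GTT", "trnD": "GTC",
    "trnC": "GCA", "trnQ": "TTG", "trnE": "TTC", "trnG": "TCC",
    "trnH": "GTG", "trnI": "GAT", "trnK": "TTT", "trnL-CUN": "TAG",
    "trnL-UUR": "TAA", "trnM": "CAT", "trnF": "GAA", "trnP": "TGG",
    "trnS-AGY": "GCT", "trnS-UCN": "TGA", "trnT": "TGT", "trnV": "TAC",
    "trnW": "TCA", "trnY": "GTA",
}

# plain-Python mirrors of the pairing tables (fast scalar access)
_PAIRS_T = tuple(tuple(bool(v) for v in row) for row in _PAIRS)
_BONDS_T = tuple(tuple(float(v) for v in row) for row in _BONDS)

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[5]  # invertebrate mitochondrial


def anticodon_to_amino_acid(anticodon: str) -> str:
    """One-letter amino acid for a DNA anticodon (invertebrate mito code)."""
    codon = reverse_complement(anticodon.upper().replace("U", "T"))
    if codon in _MITO_TABLE.stop_codons:
        return "*"
    return _MITO_TABLE.forward_table.get(codon, "X")


@dataclass(frozen=True)
class FoldConfig:
    """Geometry bounds, scoring weights and thresholds of the folder.

    The arm bounds span the truncated stems and enlarged loops seen in
    mitochondrial tRNAs while keeping the search space finite.  The
    completeness bonus is granted per arm whose stem is full length
    (acceptor 7, DHU >= 3, anticodon 5, TψC >= 4) and pairs perfectly.
    """

    acceptor_lens: tuple[int, ...] = (7, 6)
    spacer1: tuple[int, ...] = (2, 1)
    dhu_stem: tuple[int, int] = (2, 4)
    dhu_loop: tuple[int, int] = (3, 10)
    dhu_absent_gap: tuple[int, int] = (2, 10)
    spacer2: tuple[int, ...] = (1, 0)
    ac_stem: tuple[int, int] = (3, 5)
    ac_loops: tuple[int, ...] = (5, 7, 9)  # anticodon centered -> odd loops
    var_loop: tuple[int, int] = (2, 23)
    t_stem: tuple[int, int] = (2, 5)
    t_loop: tuple[int, int] = (3, 9)
    merged_loop: tuple[int, int] = (4, 30)  # variable + TψC region when TψC absent
    loop_target: int = 7
    var_target: int = 5
    merged_target: int = 8
    w_mismatch: float = 1.5
    w_loop_dev: float = 0.5
    w_ac_loop_dev: float = 1.5  # anticodon loops are canonically 7 nt
    w_var_dev: float = 0.5
    w_spacer_dev: float = 1.0  # canonical spacers are 2 nt and 1 nt
    arm_bonus: float = 2.0
    bonus_min_stem: tuple[int, int, int, int] = (7, 3, 5, 4)  # acc, DHU, AC, TψC
    #: reward for the universal anticodon-loop motif (U33 before the
    #: anticodon, purine at position 37 after it)
    motif_bonus: float = 3.0
    min_len: int = 40
    max_len: int = 80
    #: fold acceptance threshold, calibrated so that random AT-rich 70-mers
    #: pass in < 5% of cases while planted tRNAs with <= 2 stem mismatches pass
    min_score: float = 25.0
    #: stricter threshold for whole-genome scans (many more trials)
    scan_min_score: float = 40.0


DEFAULT_CONFIG = FoldConfig()


@dataclass(frozen=True)
class Arm:
    present: bool
    stem: int = 0
    loop: int = 0
    mismatches: int = 0


@dataclass(frozen=True)
class CloverleafStructure:
    """The arms, loops and pairing quality of one folded candidate."""

    length: int
    acceptor_stem: int
    acceptor_mismatches: int
    spacer1: int
    dhu: Arm
    spacer2: int
    anticodon_arm: Arm
    anticodon: str
    anticodon_offset: int  # 0-based offset of the triplet within the span
    variable_loop: int
    tpsic: Arm
    paired: int  # base pairs formed
    mismatches: int  # intended stem positions that do not pair
    score: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TrnaCandidate:
    start: int  # 1-based, plus strand
    end: int
    strand: str
    anticodon: str
    amino_acid: str
    score: float
    structure: CloverleafStructure

    @property
    def name(self) -> str:
        return f"trn{self.amino_acid}"


# ---------------------------------------------------------------------------
# Geometry enumeration (shared by the exact folder and the vectorized scan)

@dataclass(frozen=True)
class _ArmOption:
    length: int
    stem: int
    loop: int
    absent: bool
    pairs: tuple[tuple[int, int], ...]  # (i, j) offsets relative to arm start
    penalty: float  # w_mismatch·stem + loop deviation, subtracted as constants
    bonus_eligible: bool
    motif: tuple[int, int] | None = None  # offsets of positions 33 and 37


def _arm_options(stem_range, loop_values, cfg: FoldConfig, bonus_min: int,
                 dev_weight: float, absent_gaps=(),
                 with_motif: bool = False) -> tuple[_ArmOption, ...]:
    opts = []
    for d in range(stem_range[0], stem_range[1] + 1):
        for dl in loop_values:
            pairs = tuple((i, 2 * d + dl - 1 - i) for i in range(d))
            penalty = cfg.w_mismatch * d + dev_weight * abs(dl - cfg.loop_target)
            motif = None
            if with_motif:
                flank = (dl - 3) // 2
                motif = (d + flank - 1, d + flank + 3)
            opts.append(_ArmOption(2 * d + dl, d, dl, False, pairs, penalty,
                                   d >= bonus_min, motif))
    for r in absent_gaps:
        opts.append(_ArmOption(r, 0, r, True, (), 0.0, False))
    return tuple(opts)


@lru_cache(maxsize=8)
def _geometry(cfg: FoldConfig):
    dhu = _arm_options(cfg.dhu_stem, range(cfg.dhu_loop[0], cfg.dhu_loop[1] + 1),
                       cfg, cfg.bonus_min_stem[1], cfg.w_loop_dev,
                       absent_gaps=range(cfg.dhu_absent_gap[0],
                                         cfg.dhu_absent_gap[1] + 1))
    ac = _arm_options(cfg.ac_stem, cfg.ac_loops, cfg, cfg.bonus_min_stem[2],
                      cfg.w_ac_loop_dev, with_motif=True)
    t = _arm_options(cfg.t_stem, range(cfg.t_loop[0], cfg.t_loop[1] + 1),
                     cfg, cfg.bonus_min_stem[3], cfg.w_loop_dev)
    return dhu, ac, t


def encode(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _arm_values(enc: list[int], base: int, opt: _ArmOption,
                cfg: FoldConfig) -> tuple[int, float]:
    """(pairs formed, score) of one arm at one position (scalar path)."""
    formed = 0
    bonds = 0.0
    for i, j in opt.pairs:
        x, y = enc[base + i], enc[base + j]
        if _PAIRS_T[x][y]:
            formed += 1
            bonds += _BONDS_T[x][y]
    # an arm whose stem mostly fails to pair is no arm
    if opt.stem > 0 and formed < (opt.stem + 1) // 2:
        return formed, float("-inf")
    score = bonds + cfg.w_mismatch * formed - opt.penalty
    if opt.bonus_eligible and formed == opt.stem:
        score += cfg.arm_bonus
    if opt.motif is not None:
        o33, o37 = opt.motif
        if enc[base + o33] == 3 and enc[base + o37] in (0, 2):
            score += cfg.motif_bonus
    return formed, score


class _ScoreTables:
    """Vectorized per-position arm scores for one sequence."""

    def __init__(self, enc: np.ndarray, cfg: FoldConfig):
        self.enc = enc
        self.cfg = cfg
        self.n = len(enc)
        self._pair_cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self._isT = np.zeros(self.n + _PAD, dtype=np.float32)
        self._isT[: self.n] = enc == 3
        self._isR = np.zeros(self.n + _PAD, dtype=np.float32)
        self._isR[: self.n] = (enc == 0) | (enc == 2)
        self._build()

    def _pairok(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(pair indicator, bond weight) arrays over positions, at offset k."""
        arrs = self._pair_cache.get(k)
        if arrs is None:
            ok = np.zeros(self.n + _PAD, dtype=np.float32)
            bonds = np.zeros(self.n + _PAD, dtype=np.float32)
            if k < self.n:
                ok[: self.n - k] = _PAIRS[self.enc[: self.n - k], self.enc[k:]]
                bonds[: self.n - k] = _BONDS[self.enc[: self.n - k], self.enc[k:]]
            arrs = (ok, bonds)
            self._pair_cache[k] = arrs
        return arrs

    def _arm_score(self, opt: _ArmOption) -> np.ndarray:
        size = self.n + _PAD
        formed = np.zeros(size, dtype=np.float32)
        bonds = np.zeros(size, dtype=np.float32)
        for i, j in opt.pairs:
            ok, bw = self._pairok(j - i)
            formed[: size - i] += ok[i:]
            bonds[: size - i] += bw[i:]
        total = bonds + self.cfg.w_mismatch * formed - opt.penalty
        if opt.stem > 0:  # an arm whose stem mostly fails to pair is no arm
            total[formed < (opt.stem + 1) // 2] = -np.inf
        if opt.bonus_eligible:
            total += self.cfg.arm_bonus * (formed == opt.stem)
        if opt.motif is not None:
            o33, o37 = opt.motif
            motif = np.zeros(size, dtype=np.float32)
            motif[: size - o33] += self._isT[o33:]
            motif[: size - o37] += self._isR[o37:]
            total += self.cfg.motif_bonus * (motif == 2)
        return total

    def _build(self) -> None:
        cfg = self.cfg
        dhu_opts, ac_opts, t_opts = _geometry(cfg)
        dhu_scores = [self._arm_score(o) for o in dhu_opts]
        ac_scores = [self._arm_score(o) for o in ac_opts]
        # best interior-5' score by (AC-arm end offset delta, DHU-absent flag)
        best5: dict[tuple[int, bool], np.ndarray] = {}
        size = self.n + _PAD
        sp1_canon, sp2_canon = cfg.spacer1[0], cfg.spacer2[0]
        for sp1 in cfg.spacer1:
            for dopt, dvec in zip(dhu_opts, dhu_scores):
                for sp2 in cfg.spacer2:
                    spacer_pen = cfg.w_spacer_dev * (abs(sp1 - sp1_canon)
                                                     + abs(sp2 - sp2_canon))
                    ac_off = sp1 + dopt.length + sp2
                    for aopt, avec in zip(ac_opts, ac_scores):
                        delta = ac_off + aopt.length
                        vec = np.full(size, -np.inf, dtype=np.float32)
                        vec[: size - ac_off] = avec[ac_off:] - spacer_pen
                        vec[: size - sp1] += dvec[sp1:]
                        key = (delta, dopt.absent)
                        if key in best5:
                            np.maximum(best5[key], vec, out=best5[key])
                        else:
                            best5[key] = vec
        self.best5 = best5
        bestT: dict[int, np.ndarray] = {}
        for topt in t_opts:
            vec = self._arm_score(topt)
            if topt.length in bestT:
                np.maximum(bestT[topt.length], vec, out=bestT[topt.length])
            else:
                bestT[topt.length] = vec
        self.bestT = bestT
        self.key_max = {key: float(np.max(v)) for key, v in best5.items()}
        self.max5_present = max(v for (d, ab), v in self.key_max.items() if not ab)
        self.max5_absent = max(v for (d, ab), v in self.key_max.items() if ab)
        self.maxT = max(float(np.max(v)) for v in bestT.values())

    def acceptor(self, L: int, a: int) -> np.ndarray:
        """Acceptor-stem score for every start p with this span length."""
        m = self.n - L + 1
        if m <= 0:
            return np.empty(0, dtype=np.float32)
        formed = np.zeros(m, dtype=np.float32)
        bonds = np.zeros(m, dtype=np.float32)
        for i in range(a):
            ok, bw = self._pairok(L - 1 - 2 * i)
            formed += ok[i: i + m]
            bonds += bw[i: i + m]
        total = bonds + self.cfg.w_mismatch * (formed - a)
        if a >= self.cfg.bonus_min_stem[0]:
            total += self.cfg.arm_bonus * (formed == a)
        return total

    def interior_bound(self, allow_both_missing: bool) -> float:
        bound = self.max5_present + max(self.maxT, 0.0)
        bound = max(bound, self.max5_absent + self.maxT)
        if allow_both_missing:
            bound = max(bound, self.max5_absent)
        return bound


def _combine(tables: _ScoreTables, u: np.ndarray, w: np.ndarray,
             allow_both_missing: bool, prune_below: float = -np.inf) -> np.ndarray:
    """Best interior score for candidates with interior [u, w) (vectorized).

    Key groups that cannot reach ``prune_below`` even with the best TψC arm
    anywhere in the sequence are skipped wholesale.
    """
    cfg = tables.cfg
    vmin, vmax = cfg.var_loop
    mmin, mmax = cfg.merged_loop
    best = np.full(len(u), -np.inf, dtype=np.float32)
    for (delta, dhu_absent), vec5 in tables.best5.items():
        if tables.key_max[(delta, dhu_absent)] + max(tables.maxT, 0.0) < prune_below:
            continue
        s5 = vec5[u]
        # TψC arm present
        for tlen, vecT in tables.bestT.items():
            v = w - tlen - u - delta
            mask = (v >= vmin) & (v <= vmax)
            if not mask.any():
                continue
            cand = (s5 + vecT[w - tlen]
                    - cfg.w_var_dev * np.abs(v - cfg.var_target))
            np.maximum(best, np.where(mask, cand, -np.inf), out=best)
        # TψC arm absent (merged variable + T region); at most one arm may
        # be missing unless explicitly allowed
        if dhu_absent and not allow_both_missing:
            continue
        v = w - u - delta
        mask = (v >= mmin) & (v <= mmax)
        cand = s5 - cfg.w_var_dev * np.abs(v - cfg.merged_target)
        np.maximum(best, np.where(mask, cand, -np.inf), out=best)
    return best


# ---------------------------------------------------------------------------
# Exact (per-candidate) enumeration, used for structure reconstruction

def _best_structure(enc: np.ndarray, p: int, L: int, cfg: FoldConfig,
                    allow_both_missing: bool = False,
                    expected_anticodon: str | None = None,
                    ) -> CloverleafStructure | None:
    """Deterministic exhaustive search over the geometry for one span.

    Ties break toward the earliest arrangement in enumeration order
    (larger acceptor first, then geometry order), making folding a pure
    function of the span.
    """
    dhu_opts, ac_opts, t_opts = _geometry(cfg)
    t_by_len: dict[int, list[tuple[int, _ArmOption]]] = {}
    for ti, topt in enumerate(t_opts):
        t_by_len.setdefault(topt.length, []).append((ti, topt))
    # static optimistic bound on any TψC arm score, used to prune the T loop
    t_bound = max(3.0 * o.stem + (cfg.arm_bonus if o.bonus_eligible else 0.0)
                  - cfg.w_loop_dev * abs(o.loop - cfg.loop_target) for o in t_opts)
    vmin, vmax = cfg.var_loop
    mmin, mmax = cfg.merged_loop
    expected = (expected_anticodon.upper().replace("U", "T")
                if expected_anticodon else None)
    enc_l: list[int] = enc.tolist() if hasattr(enc, "tolist") else list(enc)
    cache: dict[int, tuple[int, float]] = {}
    n_ac = len(ac_opts)
    n_t = len(t_opts)

    def arm(base: int, idx: int, opt: _ArmOption) -> tuple[int, float]:
        key = base * 128 + idx
        val = cache.get(key)
        if val is None:
            val = _arm_values(enc_l, base, opt, cfg)
            cache[key] = val
        return val

    best: CloverleafStructure | None = None
    best_score = -np.inf
    for a in cfg.acceptor_lens:
        acc_formed = 0
        acc_bonds = 0.0
        for i in range(a):
            x, y = enc_l[p + i], enc_l[p + L - 1 - i]
            if _PAIRS_T[x][y]:
                acc_formed += 1
                acc_bonds += _BONDS_T[x][y]
        acc_score = acc_bonds - cfg.w_mismatch * (a - acc_formed)
        if a >= cfg.bonus_min_stem[0] and acc_formed == a:
            acc_score += cfg.arm_bonus
        u = p + a
        interior = L - 2 * a
        sp1_canon, sp2_canon = cfg.spacer1[0], cfg.spacer2[0]
        for sp1 in cfg.spacer1:
            for di, dopt in enumerate(dhu_opts):
                d_base = u + sp1
                d_formed, d_score = arm(d_base, n_ac + n_t + di, dopt)
                for sp2 in cfg.spacer2:
                    spacer_pen = cfg.w_spacer_dev * (abs(sp1 - sp1_canon)
                                                     + abs(sp2 - sp2_canon))
                    ac_base = d_base + dopt.length + sp2
                    for ai, aopt in enumerate(ac_opts):
                        delta = sp1 + dopt.length + sp2 + aopt.length
                        rest = interior - delta
                        if rest < min(vmin, mmin):
                            continue
                        anticodon_off = (ac_base - p) + aopt.stem + (aopt.loop - 3) // 2
                        if expected is not None:
                            triplet = "".join(
                                "ACGTN"[enc_l[p + anticodon_off + z]]
                                for z in range(3))
                            if triplet != expected:
                                continue
                        a_formed, a_score = arm(ac_base, ai, aopt)
                        partial = acc_score + d_score + a_score - spacer_pen
                        # TψC present
                        if partial + t_bound > best_score:
                            for tlen, topts in t_by_len.items():
                                v = rest - tlen
                                if not (vmin <= v <= vmax):
                                    continue
                                t_base = p + L - a - tlen
                                var_pen = cfg.w_var_dev * abs(v - cfg.var_target)
                                for ti, topt in topts:
                                    t_formed, t_score = arm(t_base, n_ac + ti, topt)
                                    score = partial + t_score - var_pen
                                    if score > best_score:
                                        best_score = score
                                        best = _make_structure(
                                            enc_l, p, L, a, acc_formed, sp1, dopt,
                                            d_formed, sp2, aopt, a_formed,
                                            anticodon_off, v, topt, t_formed, score)
                        # TψC absent
                        if dopt.absent and not allow_both_missing:
                            continue
                        if mmin <= rest <= mmax:
                            score = (partial
                                     - cfg.w_var_dev * abs(rest - cfg.merged_target))
                            if score > best_score:
                                best_score = score
                                best = _make_structure(
                                    enc_l, p, L, a, acc_formed, sp1, dopt, d_formed,
                                    sp2, aopt, a_formed, anticodon_off, rest,
                                    None, 0, score)
    return best


def _make_structure(enc, p, L, a, acc_formed, sp1, dopt, d_formed, sp2,
                    aopt, a_formed, anticodon_off, var_loop, topt, t_formed,
                    score) -> CloverleafStructure:
    anticodon = "".join("ACGTN"[enc[p + anticodon_off + z]] for z in range(3))
    paired = acc_formed + d_formed + a_formed + t_formed
    intended = a + dopt.stem + aopt.stem + (topt.stem if topt else 0)
    return CloverleafStructure(
        length=L,
        acceptor_stem=a,
        acceptor_mismatches=a - acc_formed,
        spacer1=sp1,
        dhu=Arm(not dopt.absent, dopt.stem, dopt.loop, dopt.stem - d_formed),
        spacer2=sp2,
        anticodon_arm=Arm(True, aopt.stem, aopt.loop, aopt.stem - a_formed),
        anticodon=anticodon,
        anticodon_offset=anticodon_off,
        variable_loop=var_loop,
        tpsic=(Arm(True, topt.stem, topt.loop, topt.stem - t_formed)
               if topt else Arm(False)),
        paired=paired,
        mismatches=intended - paired,
        score=round(float(score), 6),
    )


# ---------------------------------------------------------------------------
# Public operations

def fold_candidate(seq: str, expected_anticodon: str | None = None,
                   cfg: FoldConfig = DEFAULT_CONFIG,
                   min_score: float | None = None,
                   allow_both_missing: bool = False) -> CloverleafStructure | None:
    """Best cloverleaf arrangement of a whole candidate span, or None.

    ``min_score`` defaults to the calibrated fold threshold; pass
    ``float("-inf")`` to always obtain the best arrangement.  A candidate
    below threshold returns None — absence is a value, not an error.
    """
    seq = seq.upper().replace("U", "T")
    if not (cfg.min_len <= len(seq) <= cfg.max_len):
        raise ValueError(
            f"candidate length {len(seq)} outside {cfg.min_len}..{cfg.max_len}")
    enc = np.concatenate([encode(seq), np.full(_PAD, 4, dtype=np.int8)])
    structure = _best_structure(enc, 0, len(seq), cfg,
                                allow_both_missing=allow_both_missing,
                                expected_anticodon=expected_anticodon)
    threshold = cfg.min_score if min_score is None else min_score
    if structure is None or structure.score < threshold:
        return None
    return structure


def _scan_linear(seq: str, cfg: FoldConfig, min_score: float,
                 allow_both_missing: bool) -> list[tuple[int, int, float]]:
    """All (start0, length, score) spans folding at or above ``min_score``."""
    n = len(seq)
    if n < cfg.min_len:
        return []
    tables = _ScoreTables(encode(seq), cfg)
    bound = tables.interior_bound(allow_both_missing)
    hits: list[tuple[int, int, float]] = []
    for a in cfg.acceptor_lens:
        p_list: list[np.ndarray] = []
        L_list: list[np.ndarray] = []
        acc_list: list[np.ndarray] = []
        for L in range(cfg.min_len, min(cfg.max_len, n) + 1):
            acc = tables.acceptor(L, a)
            keep = np.nonzero(acc + bound >= min_score)[0]
            if keep.size:
                p_list.append(keep)
                L_list.append(np.full(keep.size, L, dtype=np.int64))
                acc_list.append(acc[keep])
        if not p_list:
            continue
        p = np.concatenate(p_list)
        L = np.concatenate(L_list)
        acc = np.concatenate(acc_list)
        interior = _combine(tables, p + a, p + L - a, allow_both_missing,
                            prune_below=min_score - float(np.max(acc)))
        total = acc + interior
        for idx in np.nonzero(total >= min_score)[0]:
            hits.append((int(p[idx]), int(L[idx]), float(total[idx])))
    # the same span may clear the bar with both acceptor lengths; keep the best
    dedup: dict[tuple[int, int], float] = {}
    for start, length, score in hits:
        key = (start, length)
        if key not in dedup or score > dedup[key]:
            dedup[key] = score
    return sorted((s, l, sc) for (s, l), sc in dedup.items())


def scan_genome(genome: AnnotatedGenome, strand: str = "both",
                cfg: FoldConfig = DEFAULT_CONFIG,
                min_score: float | None = None,
                allow_both_missing: bool = False,
                require_standard_anticodon: bool = True) -> list[TrnaCandidate]:
    """Non-overlapping tRNA candidates of a genome, greedily kept by score.

    Both strands are scanned by default; on circular genomes the window is
    extended across the origin.  Overlap resolution works on plus-strand
    coordinates regardless of candidate strand.  By default a candidate must
    carry one of the conventional mitochondrial anticodons — the identity
    assignment step any tRNA annotation pipeline applies; disable it to see
    every structural hit.
    """
    if genome.sequence is None:
        raise SequenceUnavailableError(f"{genome.identifier}: sequence unavailable")
    threshold = cfg.scan_min_score if min_score is None else min_score
    standard = frozenset(ANTICODONS.values())
    n = genome.length
    strands = ("+", "-") if strand == "both" else (strand,)
    raw: list[tuple] = []  # (score, s1, e1, strand, start0, length, enc)
    for st in strands:
        seq = genome.sequence if st == "+" else reverse_complement(genome.sequence)
        ext = seq + (seq[: cfg.max_len - 1] if genome.circular else "")
        enc = np.concatenate([encode(ext), np.full(_PAD, 4, dtype=np.int8)])
        for start0, length, score in _scan_linear(ext, cfg, threshold,
                                                  allow_both_missing):
            if start0 >= n:
                continue  # rotation duplicate of a wrapped hit
            if st == "+":
                s1 = start0 + 1
            else:
                s1 = n - ((start0 + length - 1) % n)
            e1 = (s1 + length - 2) % n + 1
            raw.append((score, s1, e1, st, start0, length, enc))
    raw.sort(key=lambda r: (-r[0], r[1], r[2], r[3]))
    covered = np.zeros(n, dtype=bool)
    kept = []
    for score, s1, e1, st, start0, length, enc in raw:
        span = np.arange(s1 - 1, s1 - 1 + length) % n
        if covered[span].any():
            continue
        # reconstruct only for hits that could still be reported
        structure = _best_structure(enc, start0, length, cfg,
                                    allow_both_missing=allow_both_missing)
        if require_standard_anticodon and structure.anticodon not in standard:
            continue  # discarded hits do not claim their bases
        covered[span] = True
        kept.append(TrnaCandidate(
            start=s1, end=e1, strand=st,
            anticodon=structure.anticodon,
            amino_acid=anticodon_to_amino_acid(structure.anticodon),
            score=structure.score,
            structure=structure,
        ))
    kept.sort(key=lambda c: (c.start, c.end))
    return kept


def validate_annotation(genome: AnnotatedGenome,
                        cfg: FoldConfig = DEFAULT_CONFIG) -> list[dict]:
    """Fold every annotated tRNA on its own span and report arm findings."""
    if genome.sequence is None:
        raise SequenceUnavailableError(f"{genome.identifier}: sequence unavailable")
    from .model import coding_strand_sequence

    reports = []
    for f in genome.features_of_class("tRNA"):
        entry: dict = {"gene": f.name, "start": f.start, "end": f.end,
                       "strand": f.strand, "length": f.length}
        if not (cfg.min_len <= f.length <= cfg.max_len):
            entry["structure"] = None
            entry["note"] = "span outside foldable length range"
        else:
            seq = coding_strand_sequence(genome, f)
            structure = fold_candidate(seq, cfg=cfg, min_score=float("-inf"))
            entry["structure"] = structure.to_dict()
            entry["anticodon"] = structure.anticodon
            entry["amino_acid"] = anticodon_to_amino_acid(structure.anticodon)
            entry["dhu_present"] = structure.dhu.present
            entry["tpsic_present"] = structure.tpsic.present
            entry["mismatches"] = structure.mismatches
            entry["score"] = structure.score
        reports.append(entry)
    return reports
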