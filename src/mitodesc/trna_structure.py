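"""Constrained cloverleaf folding of annotated mitochondrial tRNAs.

A metazoan mitochondrial tRNA folds into at most four arms in 5'->3' order:
the amino-acid acceptor stem (7 bp, pairing the 5' end against the 3' end
offset by an optional discriminator base), the DHU arm (stem 0-4 bp; a
0-bp stem models the trnS1(AGN)-type tRNA whose DHU arm forms no stable
stem-loop), the anticodon arm (5-bp stem around a 7-nt loop whose positions
3-5 carry the annotated anticodon) and the TpsiC arm (stem 0-6 bp), with
short spacers and a 0-23 nt variable loop between anticodon and TpsiC arms.

Given the sequence and the anticodon position the anticodon arm is pinned,
so folding reduces to placing the DHU and TpsiC arms.  Among all placements
satisfying the constraints the fold maximizes

    score = 2 * (Watson-Crick pairs) + 1 * (G-U wobble pairs) - 1 * (mismatches)

with a documented deterministic tie-break (longer DHU stem, then longer
TpsiC stem, then leftmost arm starts).  Because the left (DHU) and right
(TpsiC) placements contribute independently to the score, each side is
optimized separately; this is exactly equivalent to exhaustive search over
the joint placement space.

CCA tails are not expected on mitochondrial tRNA genes and are trimmed when
present.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TextIO

from .genome_model import FeatureTableError

ACCEPTOR_STEM = 7
ANTICODON_STEM = 5
ANTICODON_LOOP = 7

DHU_STEM_RANGE = (0, 4)
DHU_LOOP_RANGE = (3, 12)
SPACER1_RANGE = (0, 4)
SPACER2_RANGE = (0, 4)
VAR_LOOP_RANGE = (0, 23)
T_STEM_RANGE = (0, 6)
T_LOOP_RANGE = (3, 9)

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def pair_class(x: str, y: str) -> str:
    """Classify one stem pair: WC, GU (wobble) or MM (mismatch)."""
    x = "T" if x == "U" else x
    y = "T" if y == "U" else y
    if (x, y) in _WC:
        return "WC"
    if (x, y) in _GU:
        return "GU"
    return "MM"


_PAIR_SCORE = {"WC": 2, "GU": 1, "MM": -1}


class FoldError(FeatureTableError):
    """No arm placement satisfies the cloverleaf constraints."""


@dataclass
class StemPair:
    pos5: int      # 0-based indices into the (trimmed) sequence
    pos3: int
    base5: str
    base3: str
    cls: str
    arm: str       # acceptor | dhu | anticodon | tpsic


@dataclass
class CloverleafStructure:
    sequence: str
    anticodon_pos: int           # 1-based position of the first anticodon base
    discriminator: int           # 0 or 1 trailing unpaired bases
    layout: dict                 # s1, dhu_stem, dhu_loop, s2, var, t_stem, t_loop
    pairs: list[StemPair] = field(default_factory=list)
    score: int = 0

    def pair_counts(self) -> tuple[int, int, int]:
        wc = sum(p.cls == "WC" for p in self.pairs)
        gu = sum(p.cls == "GU" for p in self.pairs)
        mm = sum(p.cls == "MM" for p in self.pairs)
        return wc, gu, mm

    def arm_lengths(self) -> dict[str, tuple[int, int]]:
        """(stem bp, loop nt) per arm."""
        L = self.layout
        return {
            "acceptor": (ACCEPTOR_STEM, 0),
            "dhu": (L["dhu_stem"], L["dhu_loop"]),
            "anticodon": (ANTICODON_STEM, ANTICODON_LOOP),
            "tpsic": (L["t_stem"], L["t_loop"]),
        }

    def dot_bracket(self) -> str:
        marks = ["." for _ in self.sequence]
        for p in self.pairs:
            marks[p.pos5] = "("
            marks[p.pos3] = ")"
        return "".join(marks)


def _score_pairs(seq: str, pairing: list[tuple[int, int]], arm: str) -> tuple[int, list[StemPair]]:
    total = 0
    pairs = []
    for i, j in pairing:
        cls = pair_class(seq[i], seq[j])
        total += _PAIR_SCORE[cls]
        pairs.append(StemPair(i, j, seq[i], seq[j], cls, arm))
    return total, pairs


def _left_options(left_len: int):
    """DHU-arm placements within the left region: (s1, d1, l1, s2)."""
    yield (left_len, 0, 0, 0)     # no stable DHU stem: region unpaired
    for d1 in range(DHU_STEM_RANGE[1], 0, -1):
        for s1 in range(SPACER1_RANGE[0], SPACER1_RANGE[1] + 1):
            for l1 in range(DHU_LOOP_RANGE[0], DHU_LOOP_RANGE[1] + 1):
                s2 = left_len - s1 - 2 * d1 - l1
                if SPACER2_RANGE[0] <= s2 <= SPACER2_RANGE[1]:
                    yield (s1, d1, l1, s2)


def _right_options(right_len: int):
    """TpsiC-arm placements within the right region: (v, t, lt)."""
    yield (right_len, 0, 0)       # no TpsiC stem
    for t in range(T_STEM_RANGE[1], 0, -1):
        for lt in range(T_LOOP_RANGE[0], T_LOOP_RANGE[1] + 1):
            v = right_len - 2 * t - lt
            if VAR_LOOP_RANGE[0] <= v <= VAR_LOOP_RANGE[1]:
                yield (v, t, lt)


def fold_cloverleaf(seq: str, anticodon_pos: int,
                    min_len: int = 55, max_len: int = 80) -> CloverleafStructure:
    """Best-scoring cloverleaf of a tRNA sequence with a known anticodon.

    ``anticodon_pos`` is the 1-based index of the first anticodon base.
    Raises :class:`FoldError` when no placement satisfies the constraints.
    """
    seq = seq.upper().replace("U", "T")
    if seq.endswith("CCA"):
        seq = seq[:-3]
    n = len(seq)
    if not (min_len <= n <= max_len):
        raise FoldError(f"tRNA length {n} outside [{min_len}, {max_len}]")
    a0 = anticodon_pos - 1
    if a0 < 0 or a0 + 3 > n:
        raise FoldError("anticodon outside the sequence")
    left_len = a0 - ACCEPTOR_STEM - ANTICODON_STEM - 2
    if left_len < 0:
        raise FoldError("anticodon too close to the 5' end for a cloverleaf")

    best = None  # (score, d, left, right, left_score, right_score)
    for d in (1, 0):
        right_len = (n - ACCEPTOR_STEM - d) - (a0 + 10)
        if right_len < 0:
            continue
        acc_pairing = [(k, n - 1 - d - k) for k in range(ACCEPTOR_STEM)]
        acc_score, _ = _score_pairs(seq, acc_pairing, "acceptor")

        best_left = None
        for opt in _left_options(left_len):
            s1, d1, l1, s2 = opt
            p5 = ACCEPTOR_STEM + s1
            pairing = [(p5 + k, p5 + 2 * d1 + l1 - 1 - k) for k in range(d1)]
            sc, _ = _score_pairs(seq, pairing, "dhu")
            key = (sc, d1, -s1, -l1)
            if best_left is None or key > best_left[0]:
                best_left = (key, opt, sc)

        best_right = None
        for opt in _right_options(right_len):
            v, t, lt = opt
            p5 = a0 + 10 + v
            pairing = [(p5 + k, p5 + 2 * t + lt - 1 - k) for k in range(t)]
            sc, _ = _score_pairs(seq, pairing, "tpsic")
            key = (sc, t, -v, -lt)
            if best_right is None or key > best_right[0]:
                best_right = (key, opt, sc)

        if best_left is None or best_right is None:
            continue
        total = acc_score + best_left[2] + best_right[2]
        key = (total, best_left[0][1], best_right[0][1], d)
        if best is None or key > best[0]:
            best = (key, d, best_left[1], best_right[1])

    if best is None:
        raise FoldError("no arm placement satisfies the cloverleaf constraints")

    _, d, (s1, d1, l1, s2), (v, t, lt) = best
    layout = {"s1": s1, "dhu_stem": d1, "dhu_loop": l1, "s2": s2,
              "var": v, "t_stem": t, "t_loop": lt}
    pairs: list[StemPair] = []
    sc_acc, p = _score_pairs(
        seq, [(k, n - 1 - d - k) for k in range(ACCEPTOR_STEM)], "acceptor")
    pairs += p
    p5 = ACCEPTOR_STEM + s1
    sc_dhu, p = _score_pairs(
        seq, [(p5 + k, p5 + 2 * d1 + l1 - 1 - k) for k in range(d1)], "dhu")
    pairs += p
    sc_ac, p = _score_pairs(
        seq, [(a0 - 7 + k, a0 + 9 - k) for k in range(ANTICODON_STEM)],
        "anticodon")
    pairs += p
    p5 = a0 + 10 + v
    sc_t, p = _score_pairs(
        seq, [(p5 + k, p5 + 2 * t + lt - 1 - k) for k in range(t)], "tpsic")
    pairs += p

    return CloverleafStructure(
        sequence=seq, anticodon_pos=anticodon_pos, discriminator=d,
        layout=layout, pairs=pairs,
        score=sc_acc + sc_dhu + sc_ac + sc_t)


def classify_pairs(struct: CloverleafStructure) -> tuple[int, int, int]:
    """(WC, GU, MM) counts over all stem pairs of a fold."""
    return struct.pair_counts()


def summary_tsv(folds: dict[str, CloverleafStructure], handle: TextIO) -> None:
    handle.write("gene\tlength\tscore\tacceptor_stem\tdhu_stem\tdhu_loop\t"
                 "t_stem\tt_loop\tvar_loop\twc\tgu\tmm\tdot_bracket\n")
    for name, s in folds.items():
        wc, gu, mm = s.pair_counts()
        L = s.layout
        handle.write("\t".join(map(str, [
            name, len(s.sequence), s.score, ACCEPTOR_STEM,
            L["dhu_stem"], L["dhu_loop"], L["t_stem"], L["t_loop"], L["var"],
            wc, gu, mm, s.dot_bracket()])) + "\n")
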