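"""Synthetic mitogenomes and alignments with fully known planted structure.

The generator emulates a lepidopteran mitogenome: a circular ~15.4 kb
molecule carrying 13 protein-coding genes, 22 tRNAs, two rRNAs and one
A+T-rich control region in the noctuid gene order, with the junction gaps
(spacers and overlaps) of the reference annotation reproduced exactly.  The
default :class:`GenomeSpec` mirrors the study conditions of the reference
genome: AT-rich composition per region, ATN/CGA initiation and
complete/truncated termination codons per gene, an ``ATAGA`` + 19-bp poly-T
replication-origin signature, a duplicated 17-bp repeat, a decuplicated
divergent 8-bp ``ATATTAAT`` segment, an ``(AT)7`` microsatellite and a
TATA/GAAAAT-flanked stem-loop in the control region, and the ``AAGCCTTA``
motif at the trnW/trnC junction.

Every generated base is accounted for in a :class:`PlantLedger` that
records, from the realized sequence, the per-region base counts, the codon
multiset of every protein-coding gene, the stem pair classes of every tRNA
and the coordinates and attributes of every control-region plant — enough
to predict the output of each downstream analysis stage exactly.

All randomness flows from one ``numpy`` generator seeded by ``spec.seed``;
the same spec produces byte-identical genomes.  Features that overlap on
the genome (a hallmark of real mitogenomes, e.g. atp8/atp6) are handled by
generating hard constraints (start/stop codons, planted motifs) first and
letting each later feature adapt to already-fixed bases; tRNAs pair their
free stem arm against any fixed bases, and protein genes sample codons
conditionally on fixed positions.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from . import trna_structure
from .architecture import junction_ledger
from .genome_model import (FeatureTableError, GeneFeature, MitogenomeRecord,
                           load_reference_annotation,
                           write_feature_table, write_genbank, write_fasta)

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}
_STOPS = ("TAA", "TAG")
_BASES = "ACGT"


class SpecError(FeatureTableError):
    """The genome spec is infeasible (plants exceed regions, etc.)."""


class _Retry(Exception):
    """Internal: a stochastic constraint failed; redraw this genome."""


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass
class TandemPlant:
    period: int
    copies: int
    substitutions: int = 0
    unit: Optional[str] = None        # None: drawn AT-rich, primitive


@dataclass
class StemLoopPlant:
    stem: int = 8
    loop: int = 6
    tata: bool = True
    gaat: str = "GAAAAT"


@dataclass
class ControlRegionPlan:
    """What to plant in the A+T-rich region (defaults mirror the reference)."""

    at_fraction: float = 0.958
    origin_t_run: Optional[int] = 19
    tandem_repeats: list[TandemPlant] = field(default_factory=lambda: [
        TandemPlant(period=17, copies=2, substitutions=1),
        TandemPlant(period=8, copies=10, substitutions=12, unit="ATATTAAT"),
    ])
    microsatellites: list[tuple[str, int]] = field(
        default_factory=lambda: [("AT", 7)])
    stem_loop: Optional[StemLoopPlant] = field(default_factory=StemLoopPlant)
    poly_a: bool = False              # 9-bp poly-A upstream of trnM


@dataclass
class GenomeSpec:
    """Study conditions for one synthetic mitogenome."""

    seed: int = 0
    template: Optional[MitogenomeRecord] = None   # default: packaged reference
    # per-region composition targets (fractions; skews dimensionless)
    rrna_at: float = 0.841
    rrna_at_skew: float = 0.05
    rrna_gc_skew: float = 0.05
    spacer_at: float = 0.90
    spacer_at_skew: float = 0.0
    spacer_gc_skew: float = 0.0
    # protein-coding genes: AT fraction per codon position, and skews
    pcg_pos_at: tuple[float, float, float] = (0.877, 0.729, 0.752)
    pcg_at_skew: float = -0.148
    pcg_gc_skew: float = 0.037
    # tRNA free (loop/spacer) base AT fraction and stem pair-class rates
    trna_loop_at: float = 0.85
    gu_prob: float = 0.05
    mm_prob: float = 0.03
    control: ControlRegionPlan = field(default_factory=ControlRegionPlan)
    plant_wc_junction_motif: bool = True     # AAGCCTTA in the trnW/trnC overlap
    plant_s4_motif: bool = False             # ATACTAA in the trnS2-nad1 spacer
    #: gene names folded without a DHU stem (the trnS1(AGN) anomaly)
    dhu_less: tuple[str, ...] = ("trnS1",)


@dataclass
class PlantLedger:
    """Ground truth for every planted element of one synthetic genome."""

    seed: int = 0
    whole_genome_counts: dict = field(default_factory=dict)
    region_base_counts: dict = field(default_factory=dict)   # category -> counts
    spacer_base_counts: dict = field(default_factory=dict)
    per_gene: dict = field(default_factory=dict)    # PCG -> start/stop/codons
    codon_counts: dict = field(default_factory=dict)
    total_codons: int = 0
    trna: dict = field(default_factory=dict)        # gene -> layout + classes
    cr_plants: list = field(default_factory=list)
    junction_gaps: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


# ---------------------------------------------------------------------------
# Buffer with fixed-base bookkeeping
# ---------------------------------------------------------------------------

class _Buffer:
    def __init__(self, length: int):
        self.b: list[Optional[str]] = [None] * length

    def set_genome(self, pos0: int, base: str) -> None:
        cur = self.b[pos0]
        if cur is not None and cur != base:
            raise SpecError(
                f"conflicting constraints at genome position {pos0 + 1}: "
                f"{cur} vs {base}")
        self.b[pos0] = base

    # feature-local, strand-oriented access (template features never wrap)
    @staticmethod
    def _gpos(f: GeneFeature, k: int) -> int:
        return f.start - 1 + k if f.strand == "F" else f.end - 1 - k

    def read_local(self, f: GeneFeature, k: int) -> Optional[str]:
        base = self.b[self._gpos(f, k)]
        if base is None or f.strand == "F":
            return base
        return _COMP[base]

    def write_local(self, f: GeneFeature, k: int, base: str) -> None:
        self.set_genome(self._gpos(f, k),
                        base if f.strand == "F" else _COMP[base])


def _base_probs(at: float, at_skew: float, gc_skew: float) -> np.ndarray:
    gc = 1.0 - at
    return np.array([
        at * (1 + at_skew) / 2,        # A
        gc * (1 - gc_skew) / 2,        # C
        gc * (1 + gc_skew) / 2,        # G
        at * (1 - at_skew) / 2,        # T
    ])


def _multiset_fill(n: int, at: float, at_skew: float, gc_skew: float,
                   rng: np.random.Generator,
                   at_budget: Optional[int] = None) -> list[str]:
    """A shuffled base multiset of size n hitting the composition targets
    exactly (up to rounding); ``at_budget`` overrides the A+T count."""
    n_at = int(round(at * n)) if at_budget is None else max(0, min(n, at_budget))
    n_gc = n - n_at
    n_a = int(round(n_at * (1 + at_skew) / 2))
    n_g = int(round(n_gc * (1 + gc_skew) / 2))
    pool = (["A"] * n_a + ["T"] * (n_at - n_a)
            + ["G"] * n_g + ["C"] * (n_gc - n_g))
    perm = rng.permutation(n)
    return [pool[i] for i in perm]


# ---------------------------------------------------------------------------
# Per-feature generators
# ---------------------------------------------------------------------------

_SENSE = [a + b + c for a in _BASES for b in _BASES for c in _BASES
          if a + b + c not in _STOPS]


def _gen_pcg(buf: _Buffer, f: GeneFeature, spec: GenomeSpec,
             rng: np.random.Generator) -> None:
    n = f.end - f.start + 1
    stop = f.stop_codon or "TAA"
    n_codons = (n - 3 - len(stop)) // 3
    if (n - 3 - len(stop)) % 3:
        raise SpecError(f"{f.name}: length {n} inconsistent with stop {stop!r}")
    pos_probs = [
        _base_probs(spec.pcg_pos_at[j], spec.pcg_at_skew, spec.pcg_gc_skew)
        for j in range(3)]

    def codon_weight(codon: str) -> float:
        w = 1.0
        for j, b in enumerate(codon):
            w *= pos_probs[j][_BASES.index(b)]
        return w

    for k in range(n_codons):
        off = 3 + 3 * k
        fixed = [buf.read_local(f, off + j) for j in range(3)]
        cands = [c for c in _SENSE
                 if all(fx is None or fx == c[j] for j, fx in enumerate(fixed))]
        if not cands:
            raise _Retry  # fixed bases force a stop codon here
        w = np.array([codon_weight(c) for c in cands])
        codon = cands[int(rng.choice(len(cands), p=w / w.sum()))]
        for j in range(3):
            if fixed[j] is None:
                buf.write_local(f, off + j, codon[j])


def _solve_trna_layout(n: int, a0: int, dhu_less: bool) -> dict:
    left = a0 - 14
    right_by_d = {d: n - a0 - 17 - d for d in (1, 0)}
    if left < 0:
        raise SpecError("anticodon too close to the 5' end")
    for d in (1, 0):
        right = right_by_d[d]
        if right < 0:
            continue
        if dhu_less:
            left_opt = (left, 0, 0, 0)
        else:
            left_opt = None
            for d1 in (4, 3):
                for s1 in (1, 2, 3, 0, 4):
                    for s2 in (1, 0, 2):
                        l1 = left - s1 - 2 * d1 - s2
                        if 3 <= l1 <= 12:
                            left_opt = (s1, d1, l1, s2)
                            break
                    if left_opt:
                        break
                if left_opt:
                    break
            if left_opt is None:
                continue
        right_opt = None
        for t in (5, 4, 6, 3):
            for lt in range(3, 10):
                v = right - 2 * t - lt
                if 0 <= v <= 23:
                    right_opt = (v, t, lt)
                    break
            if right_opt:
                break
        if right_opt is None:
            continue
        s1, d1, l1, s2 = left_opt
        v, t, lt = right_opt
        return {"d": d, "s1": s1, "dhu_stem": d1, "dhu_loop": l1, "s2": s2,
                "var": v, "t_stem": t, "t_loop": lt}
    raise SpecError(f"no cloverleaf layout for tRNA of length {n}, "
                    f"anticodon offset {a0}")


def _layout_pairs(n: int, a0: int, L: dict) -> list[tuple[int, int, str]]:
    pairs = [(k, n - 1 - L["d"] - k, "acceptor") for k in range(7)]
    p5 = 7 + L["s1"]
    d1 = L["dhu_stem"]
    pairs += [(p5 + k, p5 + 2 * d1 + L["dhu_loop"] - 1 - k, "dhu")
              for k in range(d1)]
    pairs += [(a0 - 7 + k, a0 + 9 - k, "anticodon") for k in range(5)]
    p5 = a0 + 10 + L["var"]
    t = L["t_stem"]
    pairs += [(p5 + k, p5 + 2 * t + L["t_loop"] - 1 - k, "tpsic")
              for k in range(t)]
    return pairs


def _draw_base(rng: np.random.Generator, at: float) -> str:
    probs = _base_probs(at, 0.0, 0.0)
    return _BASES[int(rng.choice(4, p=probs / probs.sum()))]


_MM_PARTNERS = {b: [x for x in _BASES
                    if trna_structure.pair_class(b, x) == "MM"]
                for b in _BASES}


def _gen_trna(buf: _Buffer, f: GeneFeature, spec: GenomeSpec,
              rng: np.random.Generator, ledger: PlantLedger,
              max_tries: int = 60) -> None:
    n = f.end - f.start + 1
    ac = f.anticodon
    if ac is None or ac.start is None:
        raise SpecError(f"{f.name}: template tRNA lacks anticodon coordinates")
    a0 = (ac.start - f.start) if f.strand == "F" else (f.end - ac.end)
    dhu_less = f.name in spec.dhu_less
    layout = _solve_trna_layout(n, a0, dhu_less)
    pair_list = _layout_pairs(n, a0, layout)
    paired_idx = {i for i, j, _ in pair_list} | {j for i, j, _ in pair_list}
    fixed = {k: buf.read_local(f, k) for k in range(n)}

    for _ in range(max_tries):
        seq: list[Optional[str]] = [fixed[k] for k in range(n)]
        for j, b in enumerate(ac.triplet.upper()):
            if seq[a0 + j] not in (None, b):
                raise SpecError(f"{f.name}: anticodon conflicts with fixed base")
            seq[a0 + j] = b
        planted: list[tuple[str, str, str, str]] = []
        for i, j, arm in pair_list:
            bi, bj = seq[i], seq[j]
            if bi is not None and bj is not None:
                cls = trna_structure.pair_class(bi, bj)
            elif bi is not None or bj is not None:
                known = bi if bi is not None else bj
                other = _COMP[known]
                if bi is None:
                    seq[i] = other
                else:
                    seq[j] = other
                cls = "WC"
            else:
                u = rng.random()
                if u < spec.mm_prob:
                    cls = "MM"
                elif u < spec.mm_prob + spec.gu_prob:
                    cls = "GU"
                else:
                    cls = "WC"
                if cls == "GU":
                    seq[i], seq[j] = ("G", "T") if rng.random() < 0.5 else ("T", "G")
                else:
                    b5 = _draw_base(rng, spec.trna_loop_at)
                    if cls == "WC":
                        seq[i], seq[j] = b5, _COMP[b5]
                    else:
                        partners = _MM_PARTNERS[b5]
                        seq[i] = b5
                        seq[j] = partners[int(rng.choice(len(partners)))]
            planted.append((str(seq[i]), str(seq[j]),
                            trna_structure.pair_class(seq[i], seq[j]), arm))
        for k in range(n):
            if seq[k] is None:
                if dhu_less and 7 <= k < a0 - 7 and k not in paired_idx:
                    # an all-A DHU region admits no spurious stem (A-A never pairs)
                    seq[k] = "A"
                else:
                    seq[k] = _draw_base(rng, spec.trna_loop_at)
        s = "".join(seq)  # type: ignore[arg-type]
        fold = trna_structure.fold_cloverleaf(s, a0 + 1)
        want = Counter(cls for _, _, cls, _ in planted)
        got = Counter(p.cls for p in fold.pairs)
        if (got.get("WC", 0), got.get("GU", 0), got.get("MM", 0)) == \
                (want.get("WC", 0), want.get("GU", 0), want.get("MM", 0)):
            for k in range(n):
                if fixed[k] is None:
                    buf.write_local(f, k, s[k])
            ledger.trna[f.name] = {
                "length": n, "anticodon_pos": a0 + 1, "layout": layout,
                "pairs": planted,
                "wc": want.get("WC", 0), "gu": want.get("GU", 0),
                "mm": want.get("MM", 0),
            }
            return
    raise _Retry


def _gen_background_feature(buf: _Buffer, f: GeneFeature, at: float,
                            at_skew: float, gc_skew: float,
                            rng: np.random.Generator) -> None:
    n = f.end - f.start + 1
    free = [k for k in range(n) if buf.read_local(f, k) is None]
    pool = _multiset_fill(len(free), at, at_skew, gc_skew, rng)
    for k, b in zip(free, pool):
        buf.write_local(f, k, b)


# ---------------------------------------------------------------------------
# Control region assembly
# ---------------------------------------------------------------------------

def _draw_unit(period: int, rng: np.random.Generator) -> str:
    # repeat units are pure A/T: the region's small G+C budget is reserved
    # for the guard bases that delimit planted elements
    while True:
        u = "".join("AT"[int(rng.choice(2))] for _ in range(period))
        if len(set(u)) > 1 and not any(
                period % p == 0 and u == u[:p] * (period // p)
                for p in range(1, period)):
            return u


def _substitute(base: str, rng: np.random.Generator) -> str:
    """A/T-preserving substitution (A<->T transversion); G/C revert to A/T."""
    if base == "A":
        return "T"
    if base == "T":
        return "A"
    return ("A", "T")[int(rng.choice(2))]


def _guard(rng: np.random.Generator) -> str:
    return "G" if rng.random() < 0.5 else "C"


def _build_control_region(length: int, plan: ControlRegionPlan,
                          rng: np.random.Generator) -> tuple[str, list[dict]]:
    elements: list[tuple[Optional[dict], str]] = []   # (annotation, text)

    if plan.origin_t_run:
        text = "ATAGA" + "T" * plan.origin_t_run + _guard(rng)
        elements.append((
            {"kind": "origin_signature", "t_run": plan.origin_t_run,
             "length": len(text) - 1}, text))
    for tp in plan.tandem_repeats:
        unit = (tp.unit or _draw_unit(tp.period, rng)).upper()
        block = list(unit * tp.copies)
        # substitutions fall in copies 2..n so copy 1 stays the consensus
        positions = rng.choice(
            np.arange(tp.period, len(block)),
            size=min(tp.substitutions, len(block) - tp.period), replace=False)
        for p in sorted(int(x) for x in positions):
            block[p] = _substitute(block[p], rng)
        text = _guard(rng) + "".join(block) + _guard(rng)
        elements.append((
            {"kind": "tandem_repeat", "period": tp.period, "copies": tp.copies,
             "unit": unit, "substitutions": tp.substitutions,
             "length": len(block), "offset_in_element": 1}, text))
    for unit, copies in plan.microsatellites:
        text = _guard(rng) + unit * copies + _guard(rng)
        elements.append((
            {"kind": "microsatellite", "unit": unit, "period": len(unit),
             "copies": copies, "length": len(unit) * copies,
             "offset_in_element": 1}, text))
    if plan.stem_loop is not None:
        sl = plan.stem_loop
        # innermost pair fixed to G-C so the all-A loop (which cannot pair
        # with itself, keeping the planted innermost pair innermost) never
        # merges with arm bases into a poly-A-like run
        arm = "".join("AT"[int(rng.choice(2))] for _ in range(sl.stem - 1)) + "G"
        arm3 = "".join(_COMP[b] for b in reversed(arm))
        loop = "A" * sl.loop
        text = ("TATA" if sl.tata else "") + arm + loop + arm3 + sl.gaat
        elements.append((
            {"kind": "stem_loop", "stem": sl.stem, "loop": sl.loop,
             "tata": sl.tata, "gaat": sl.gaat,
             "length": 2 * sl.stem + sl.loop,
             "offset_in_element": 4 if sl.tata else 0}, text))
    if plan.poly_a:
        elements.append((
            {"kind": "poly_a", "run": 9, "length": 9,
             "offset_in_element": 1}, _guard(rng) + "A" * 9 + _guard(rng)))

    planted_len = sum(len(t) for _, t in elements)
    leftover = length - planted_len
    if leftover < 0:
        raise SpecError(
            f"control-region plants ({planted_len} bp) exceed region "
            f"length {length}")
    n_slots = len(elements) + 1
    cuts = np.sort(rng.integers(0, leftover + 1, n_slots - 1)) \
        if n_slots > 1 else np.array([], dtype=int)
    slot_sizes = np.diff(np.concatenate(([0], cuts, [leftover])))

    planted_at = sum(t.count("A") + t.count("T") for _, t in elements)
    target_at = int(round(plan.at_fraction * length))
    pool = _multiset_fill(leftover, plan.at_fraction, 0.0, 0.0, rng,
                          at_budget=target_at - planted_at)

    out: list[str] = []
    annotations: list[dict] = []
    background_idx: list[int] = []    # 0-based region positions we may edit
    pool_pos = 0
    for slot, element in zip(slot_sizes, elements + [(None, "")]):
        cur = sum(len(x) for x in out)
        out.append("".join(pool[pool_pos:pool_pos + int(slot)]))
        background_idx.extend(range(cur, cur + int(slot)))
        pool_pos += int(slot)
        ann, text = element
        if ann is not None:
            start = sum(len(x) for x in out) + 1 + ann.get("offset_in_element", 0)
            ann = dict(ann)
            ann.pop("offset_in_element", None)
            ann["start"] = start
            ann["end"] = start + ann["length"] - 1
            annotations.append(ann)
        out.append(text)
    region = list("".join(out))
    assert len(region) == length

    if not plan.poly_a:
        # the region's tail sits directly upstream of trnM; break any
        # chance A-run that would mimic a planted poly-A element there,
        # swapping background bases so the exact base counts are kept
        bg = set(background_idx)
        donors = [i for i in background_idx
                  if i < length - 30 and region[i] != "A"]
        for _ in range(30):
            m = re.search("A{9,}", "".join(region[length - 30:]))
            if m is None or not donors:
                break
            run_positions = [length - 30 + k
                             for k in range(m.start(), m.end()) if
                             (length - 30 + k) in bg]
            if not run_positions:
                break
            i = run_positions[len(run_positions) // 2]
            j = donors.pop()
            region[i], region[j] = region[j], region[i]
    return "".join(region), annotations


# ---------------------------------------------------------------------------
# Whole-genome generation
# ---------------------------------------------------------------------------

def _apply_hard_constraints(buf: _Buffer, template: MitogenomeRecord,
                            spec: GenomeSpec) -> None:
    for f in template.sorted_features():
        if f.category != "PCG":
            continue
        start = f.start_codon or "ATG"
        stop = f.stop_codon or "TAA"
        n = f.end - f.start + 1
        for j, b in enumerate(start.upper()):
            buf.write_local(f, j, b)
        for j, b in enumerate(stop.upper()):
            buf.write_local(f, n - len(stop) + j, b)
    if spec.plant_wc_junction_motif:
        try:
            w = template.get_feature("trnW")
            c = template.get_feature("trnC")
        except KeyError:
            return
        if w.end - c.start + 1 == 8:
            for j, b in enumerate("AAGCCTTA"):
                buf.set_genome(c.start - 1 + j, b)


def _spacer_intervals(template: MitogenomeRecord) -> list[tuple[str, int, int]]:
    """(junction label, genome start, genome end) of every positive gap."""
    ledger = junction_ledger(template)
    by_name = {f.name: f for f in template.features}
    out = []
    for e in ledger.entries:
        if e.gap <= 0:
            continue
        up = by_name[e.upstream]
        start = up.end + 1
        out.append((f"{e.upstream}-{e.downstream}", start, start + e.gap - 1))
    return out


def _count_bases(seq: str) -> dict[str, int]:
    return {b: seq.count(b) for b in "ACGT"}


def simulate_mitogenome(spec: GenomeSpec,
                        max_attempts: int = 10) -> tuple[MitogenomeRecord, PlantLedger]:
    """Generate one synthetic annotated mitogenome with its plant ledger."""
    template = (spec.template or load_reference_annotation()).copy()
    for f in template.features:
        if f.wraps_origin:
            raise SpecError("wrap-around template features are not supported")
    rng = np.random.default_rng(spec.seed)
    last_err: Optional[Exception] = None
    for _ in range(max_attempts):
        try:
            return _generate(template, spec, rng)
        except _Retry as exc:
            last_err = exc
            continue
    raise SpecError(f"generation failed after {max_attempts} attempts "
                    f"({last_err!r})")


def _generate(template: MitogenomeRecord, spec: GenomeSpec,
              rng: np.random.Generator) -> tuple[MitogenomeRecord, PlantLedger]:
    L = template.length
    buf = _Buffer(L)
    ledger = PlantLedger(seed=spec.seed)
    _apply_hard_constraints(buf, template, spec)

    control = None
    for f in template.sorted_features():
        if f.category == "PCG":
            _gen_pcg(buf, f, spec, rng)
        elif f.category == "tRNA":
            _gen_trna(buf, f, spec, rng, ledger)
        elif f.category == "rRNA":
            _gen_background_feature(
                buf, f, spec.rrna_at, spec.rrna_at_skew, spec.rrna_gc_skew, rng)
        elif f.category == "control":
            control = f

    if control is not None:
        region, annotations = _build_control_region(
            control.end - control.start + 1, spec.control, rng)
        for k, b in enumerate(region):
            # plants win over any fixed base only if they agree; conflicts
            # are spec errors (the control region overlaps nothing by default)
            buf.write_local(control, k, b)
        ledger.cr_plants = annotations

    spacer_seqs: dict[str, str] = {}
    for label, start, end in _spacer_intervals(template):
        n = end - start + 1
        free = [k for k in range(n) if buf.b[start - 1 + k] is None]
        if label == "trnS2-nad1" and spec.plant_s4_motif and n >= 7:
            at = int(rng.integers(0, n - 7 + 1))
            for j, b in enumerate("ATACTAA"):
                buf.set_genome(start - 1 + at + j, b)
            free = [k for k in range(n) if buf.b[start - 1 + k] is None]
        pool = _multiset_fill(len(free), spec.spacer_at, spec.spacer_at_skew,
                              spec.spacer_gc_skew, rng)
        for k, b in zip(free, pool):
            buf.set_genome(start - 1 + k, b)
        spacer_seqs[label] = "".join(
            buf.b[start - 1 + k] for k in range(n))  # type: ignore[arg-type]

    # defensive: any position not covered by a feature or spacer
    holes = [i for i, b in enumerate(buf.b) if b is None]
    if holes:
        pool = _multiset_fill(len(holes), spec.spacer_at, 0.0, 0.0, rng)
        for i, b in zip(holes, pool):
            buf.b[i] = b

    sequence = "".join(buf.b)  # type: ignore[arg-type]
    rec = MitogenomeRecord(id=f"synthetic-{spec.seed}", length=L,
                           features=template.features, sequence=sequence)
    rec.validate()

    # --- ledger bookkeeping from the realized sequence -------------------
    from .genome_model import extract_feature_sequence  # local slice helper

    total = Counter()
    for f in rec.sorted_features():
        if f.category != "PCG":
            continue
        cds = extract_feature_sequence(rec, f)
        stop = f.stop_codon or "TAA"
        body = cds[3:len(cds) - len(stop)]
        codons = [body[i:i + 3] for i in range(0, len(body), 3)]
        if any(c in _STOPS for c in codons):
            raise _Retry  # an overlap fixed an in-frame stop; redraw
        ledger.per_gene[f.name] = {
            "start_codon": cds[:3], "stop": stop,
            "n_codons": len(codons), "codons": dict(Counter(codons)),
        }
        total.update(codons)
    ledger.codon_counts = dict(total)
    ledger.total_codons = sum(total.values())

    ledger.whole_genome_counts = _count_bases(sequence)
    for category in ("PCG", "tRNA", "rRNA", "control"):
        parts = [extract_feature_sequence(rec, f)
                 for f in rec.sorted_features() if f.category == category]
        if parts:
            ledger.region_base_counts[category] = _count_bases("".join(parts))
    ledger.spacer_base_counts = {
        label: _count_bases(s) for label, s in spacer_seqs.items()}
    ledger.junction_gaps = [
        (e.upstream, e.downstream, e.gap)
        for e in junction_ledger(rec).entries]
    return rec, ledger


# ---------------------------------------------------------------------------
# Alignment simulation
# ---------------------------------------------------------------------------

def simulate_alignment(tree, columns: int, seed: int = 0):
    """Evolve an amino-acid alignment on a tree under equal-rate substitution.

    Each site evolves independently; along a branch of length b (expected
    substitutions/site) the probability that the end state differs from the
    start state is (19/20) * (1 - exp(-20 b / 19)), the 20-state analogue of
    the Jukes-Cantor transition probability, and the new state is uniform
    over the other 19.  Deterministic given ``seed``.
    """
    from .phylo import AlignedMatrix  # cycle-free: phylo does not import us

    rng = np.random.default_rng(seed)
    states = {}
    root_state = rng.integers(0, 20, columns)

    rows: dict[str, np.ndarray] = {}

    def walk(node, state):
        for child in node.children:
            b = max(child.length, 0.0)
            p_change = (19 / 20) * (1 - np.exp(-20 * b / 19))
            child_state = state.copy()
            mask = rng.random(columns) < p_change
            k = int(mask.sum())
            if k:
                child_state[mask] = (
                    child_state[mask] + rng.integers(1, 20, k)) % 20
            if child.is_leaf:
                rows[child.name] = child_state
            else:
                walk(child, child_state)

    walk(tree.root, root_state)
    from .phylo import AA_ALPHABET
    names = sorted(rows)
    return AlignedMatrix(
        names=names,
        rows=["".join(AA_ALPHABET[s] for s in rows[n]) for n in names])


# ---------------------------------------------------------------------------
# Bundle writer
# ---------------------------------------------------------------------------

def write_bundle(rec: MitogenomeRecord, ledger: PlantLedger,
                 outdir: Path) -> None:
    """Write GenBank + FASTA + TSV feature table + JSON plant ledger."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{rec.id}.gb", "w") as fh:
        write_genbank(rec, fh)
    with open(outdir / f"{rec.id}.fasta", "w") as fh:
        write_fasta(rec.id, rec.sequence or "", fh)
    with open(outdir / f"{rec.id}.tsv", "w") as fh:
        write_feature_table(rec, fh)
    with open(outdir / f"{rec.id}.ledger.json", "w") as fh:
        fh.write(ledger.to_json())
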