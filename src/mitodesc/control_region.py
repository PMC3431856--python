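"""Structural scanner for the A+T-rich (control) region.

The control region of an insect mitogenome carries the replication and
transcription initiation elements.  This module locates, with its own
detectors rather than external programs:

* the light-strand replication-origin signature: an ``ATAGA`` motif followed
  closely by a long poly-T stretch;
* microsatellites: maximal perfect tandem runs of a 1-6 bp unit;
* longer tandem repeats (possibly degenerate), through a gapless
  self-alignment scan scored +2 per matching and -3 per mismatching
  position, reported when a period's best local segment reaches a score
  threshold (a deliberately simple, fully specified relative of classic
  tandem-repeat finders);
* bulge-free stem-loop (hairpin) structures, with the ``TATA`` 5' and
  ``G(A)nT`` 3' flanking motifs that mark the initiation site of secondary
  strand synthesis;
* fixed diagnostic motifs at named junctions of the annotated genome
  (``ATACTAA`` in the trnS2-nad1 spacer, ``AAGCCTTA`` at the trnW/trnC
  junction, and a poly-A run upstream of trnM).

All coordinates in annotations are 1-based closed and local to the scanned
region (the region's first base is position 1).
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, TextIO

import numpy as np

from .genome_model import (FeatureTableError, MitogenomeRecord, extract_arc,
                           reverse_complement)


@dataclass
class RepeatAnnotation:
    kind: str                 # origin_signature | tandem_repeat | microsatellite
    #                         # | stem_loop | fixed_motif | poly_a
    start: int                # 1-based closed, region-local
    end: int
    attributes: dict = field(default_factory=dict)

    def shifted(self, offset: int) -> "RepeatAnnotation":
        return RepeatAnnotation(self.kind, self.start + offset,
                                self.end + offset, dict(self.attributes))


# ---------------------------------------------------------------------------
# Replication-origin signature
# ---------------------------------------------------------------------------

def find_origin_signature(region: str, min_t_run: int = 10,
                          max_gap: int = 5) -> list[RepeatAnnotation]:
    """``ATAGA`` motifs followed within ``max_gap`` bases by a poly-T run.

    The reported span covers the motif through the end of the T run; the
    run length and the gap between motif and run are recorded.
    """
    region = region.upper()
    out: list[RepeatAnnotation] = []
    for m in re.finditer("ATAGA", region):
        motif_end = m.end()            # 0-based exclusive
        for gap in range(0, max_gap + 1):
            i = motif_end + gap
            if i >= len(region) or region[i] != "T":
                continue
            j = i
            while j < len(region) and region[j] == "T":
                j += 1
            if j - i >= min_t_run:
                out.append(RepeatAnnotation(
                    "origin_signature", m.start() + 1, j,
                    {"t_run": j - i, "gap": gap}))
            break  # only the first T encountered can start the run
    return out


# ---------------------------------------------------------------------------
# Microsatellites
# ---------------------------------------------------------------------------

def _is_primitive(unit: str) -> bool:
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return False
    return True


def _min_rotation(unit: str) -> str:
    return min(unit[i:] + unit[:i] for i in range(len(unit)))


def find_microsatellites(region: str, unit_range: tuple[int, int] = (1, 6),
                         min_copies: int = 5) -> list[RepeatAnnotation]:
    """Maximal perfect tandem runs of short units.

    A run is reported when it contains at least ``min_copies`` complete
    copies of a primitive unit; the unit is normalized to its
    lexicographically minimal rotation.  Runs whose unit is itself a
    repetition of a shorter unit are suppressed (an ``ATATAT`` stretch is an
    ``AT`` run, never an ``ATAT`` run), as are alternative phases of the
    same run.
    """
    region = region.upper()
    n = len(region)
    out: list[RepeatAnnotation] = []
    for u in range(unit_range[0], unit_range[1] + 1):
        i = 0
        while i + u <= n:
            if i > 0 and i - 1 + u < n and region[i - 1] == region[i - 1 + u]:
                i += 1  # not the leftmost phase of this stretch
                continue
            # maximal period-u matched stretch starting at i
            j = i
            while j + u < n and region[j] == region[j + u]:
                j += 1
            if j == i:
                i += 1
                continue
            span = (j - i) + u
            unit = region[i:i + u]
            copies = span // u
            if copies >= min_copies and _is_primitive(unit):
                out.append(RepeatAnnotation(
                    "microsatellite", i + 1, i + span,
                    {"unit": _min_rotation(unit), "period": u,
                     "copies": copies, "span": span}))
            i = j + 1
    out.sort(key=lambda a: (a.start, a.attributes["period"]))
    return out


# ---------------------------------------------------------------------------
# Tandem repeats (gapless self-alignment scan)
# ---------------------------------------------------------------------------

def _best_interval(P: np.ndarray, lo: int, hi: int) -> Optional[tuple[int, int, int]]:
    """Maximum-score interval [a, b] within match-array slice [lo, hi).

    Scores are differences of the prefix array ``P``; ties prefer the
    smallest start, then the smallest end.  Returns (a, b, score).
    """
    if hi <= lo:
        return None
    seg = P[lo:hi + 1]
    best_score = None
    best_a = best_b = -1
    min_val = seg[0]
    min_idx = 0
    for b in range(1, len(seg)):
        sc = seg[b] - min_val
        if best_score is None or sc > best_score:
            best_score, best_a, best_b = sc, min_idx, b - 1
        if seg[b] < min_val:
            min_val = seg[b]
            min_idx = b
    return lo + best_a, lo + best_b, int(best_score)


def _segments_for_period(scores: np.ndarray, min_score: int) -> list[tuple[int, int, int]]:
    """Greedy disjoint maximum-score intervals with score >= min_score."""
    P = np.concatenate(([0], np.cumsum(scores)))
    found: list[tuple[int, int, int]] = []
    stack = [(0, len(scores))]
    while stack:
        lo, hi = stack.pop()
        res = _best_interval(P, lo, hi)
        if res is None or res[2] < min_score:
            continue
        a, b, sc = res
        found.append((a, b, sc))
        stack.append((lo, a))
        stack.append((b + 1, hi))
    found.sort()
    return found


def _consensus_identity(region: str, a: int, b: int, p: int) -> tuple[str, float]:
    window = region[a:b + 1 + p]
    cons = []
    for phase in range(p):
        col = window[phase::p]
        cons.append(Counter(col).most_common(1)[0][0])
    matches = sum(region[i] == region[i + p] for i in range(a, b + 1))
    return "".join(cons), 100.0 * matches / (b - a + 1)


def _span_overlap(x: RepeatAnnotation, y: RepeatAnnotation) -> float:
    inter = min(x.end, y.end) - max(x.start, y.start) + 1
    if inter <= 0:
        return 0.0
    return inter / min(x.end - x.start + 1, y.end - y.start + 1)


def find_tandem_repeats(region: str,
                        period_range: tuple[int, int] = (2, 50),
                        match: int = 2, mismatch: int = -3,
                        min_score: int = 20,
                        dedup_overlap: float = 0.5) -> list[RepeatAnnotation]:
    """Tandem repeats by scored comparison of the region with its own shift.

    For every candidate period p, position i matches when base i equals
    base i+p; matches score ``match`` and mismatches ``mismatch``.  The
    detector reports, per period, the greedy sequence of disjoint
    maximum-score segments reaching ``min_score`` (each detected segment
    splits its flanks, which are then searched recursively).  A segment
    [a, b] of the match array corresponds to the repeat region [a, b+p],
    with fractional copy number (b - a + 1 + p) / p, a majority-rule
    consensus unit and the percent identity of the self-alignment.

    Candidate periods are seeded by dinucleotides recurring at distance p;
    because any segment scoring above zero under the default scores must
    contain two adjacent matches, seeding loses no detection.  Overlapping
    detections at different periods are deduplicated, keeping the higher
    score (ties: shorter period, then leftmost).
    """
    region = region.upper()
    n = len(region)
    arr = np.frombuffer(region.encode(), dtype=np.uint8)
    raw: list[RepeatAnnotation] = []
    p_lo, p_hi = period_range
    for p in range(p_lo, min(p_hi, n - 1) + 1):
        if n - p < 2:
            break
        m = arr[:-p] == arr[p:]
        if not np.any(m[:-1] & m[1:]):
            continue  # no dinucleotide seed at this period
        scores = np.where(m, match, mismatch)
        for a, b, sc in _segments_for_period(scores, min_score):
            cons, ident = _consensus_identity(region, a, b, p)
            raw.append(RepeatAnnotation(
                "tandem_repeat", a + 1, b + 1 + p,
                {"period": p, "copies": round((b - a + 1 + p) / p, 3),
                 "score": sc, "consensus": cons,
                 "identity": round(ident, 2)}))
    raw.sort(key=lambda x: (-x.attributes["score"], x.attributes["period"], x.start))
    kept: list[RepeatAnnotation] = []
    for cand in raw:
        if all(_span_overlap(cand, k) <= dedup_overlap for k in kept):
            kept.append(cand)
    kept.sort(key=lambda x: (x.start, x.attributes["period"]))
    return kept


# ---------------------------------------------------------------------------
# Stem-loops
# ---------------------------------------------------------------------------

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


def _pairable(x: str, y: str, allow_gu: bool) -> bool:
    return (x, y) in _WC or (allow_gu and (x, y) in _GU)


def find_stem_loops(region: str, min_stem: int = 5,
                    loop_range: tuple[int, int] = (3, 20),
                    allow_gu: bool = True,
                    flank_window: int = 10) -> list[RepeatAnnotation]:
    """All maximal bulge-free hairpins with the flank-motif flags.

    A hairpin pairs positions (i-t, j+t) for t = 0..stem-1 around an
    unpaired loop of ``j - i - 1`` bases; every pair must be Watson-Crick
    (or G-T wobble when ``allow_gu``).  Maximality holds on both sides: the
    stem cannot be grown outward, and the innermost pair cannot be moved
    further in without shrinking the loop below its minimum.  Each hit
    carries ``tata_5prime`` (a TATA within ``flank_window`` nt upstream) and
    ``gaat_3prime`` (a G(A)1-8T within ``flank_window`` nt downstream).
    """
    region = region.upper()
    n = len(region)
    lo, hi = loop_range
    out: list[RepeatAnnotation] = []
    for i in range(n):
        for loop in range(lo, hi + 1):
            j = i + loop + 1
            if j >= n:
                break
            if not _pairable(region[i], region[j], allow_gu):
                continue
            # innermost check: a smaller admissible loop must not pair
            if loop - 2 >= lo and _pairable(region[i + 1], region[j - 1], allow_gu):
                continue
            s = 1
            while (i - s >= 0 and j + s < n
                   and _pairable(region[i - s], region[j + s], allow_gu)):
                s += 1
            if s < min_stem:
                continue
            a, e = i - s + 1, j + s - 1   # 0-based ends of the hairpin
            upstream = region[max(0, a - flank_window):a]
            downstream = region[e + 1:e + 1 + flank_window]
            out.append(RepeatAnnotation(
                "stem_loop", a + 1, e + 1,
                {"stem": s, "loop": loop,
                 "tata_5prime": "TATA" in upstream,
                 "gaat_3prime": re.search("GA{1,8}T", downstream) is not None}))
    out.sort(key=lambda x: (x.start, x.end))
    return out


# ---------------------------------------------------------------------------
# Fixed motifs at named junctions
# ---------------------------------------------------------------------------

def _search_both_strands(arc: str, motif: str) -> Optional[tuple[int, str]]:
    i = arc.find(motif)
    if i >= 0:
        return i + 1, "F"
    i = reverse_complement(arc).find(motif)
    if i >= 0:
        return len(arc) - i - len(motif) + 1, "R"
    return None


def find_fixed_motifs(rec: MitogenomeRecord,
                      polya_min_run: int = 9,
                      polya_window: int = 30) -> list[RepeatAnnotation]:
    """Presence/absence report for the three diagnostic junction motifs.

    * ``ATACTAA`` in the trnS2-nad1 intergenic spacer (the lepidopteran
      conserved spacer motif);
    * ``AAGCCTTA`` within +/-20 nt of the trnW/trnC junction;
    * an A-run of at least ``polya_min_run`` in the ``polya_window`` nt
      immediately upstream of trnM.

    Coordinates in the annotations are local to each searched window, whose
    genome-global start is recorded in the attributes.
    """
    if rec.sequence is None:
        raise FeatureTableError("motif search requires a sequence")
    try:
        s2 = rec.get_feature("trnS2")
        nad1 = rec.get_feature("nad1")
        trnw = rec.get_feature("trnW")
        trnc = rec.get_feature("trnC")
        trnm = rec.get_feature("trnM")
    except KeyError as exc:
        raise FeatureTableError(f"junction gene absent from annotation: {exc}")

    out: list[RepeatAnnotation] = []

    # s4 spacer: between trnS2 and nad1
    if nad1.start - 1 >= s2.end + 1:
        arc = extract_arc(rec.sequence, s2.end + 1, nad1.start - 1)
    else:
        arc = ""
    hit = _search_both_strands(arc, "ATACTAA") if arc else None
    out.append(RepeatAnnotation(
        "fixed_motif",
        hit[0] if hit else 0, hit[0] + 6 if hit else 0,
        {"motif": "ATACTAA", "where": "trnS2-nad1 spacer",
         "present": hit is not None,
         "strand": hit[1] if hit else None,
         "window_genome_start": s2.end + 1, "window_length": len(arc)}))

    # trnW/trnC junction neighborhood (covers their overlap +/- 20 nt)
    w_start = min(trnc.start, trnw.end) - 20
    w_end = max(trnc.start, trnw.end) + 20
    arc = extract_arc(rec.sequence, max(1, w_start), min(rec.length, w_end))
    hit = _search_both_strands(arc, "AAGCCTTA")
    out.append(RepeatAnnotation(
        "fixed_motif",
        hit[0] if hit else 0, hit[0] + 7 if hit else 0,
        {"motif": "AAGCCTTA", "where": "trnW-trnC junction",
         "present": hit is not None,
         "strand": hit[1] if hit else None,
         "window_genome_start": max(1, w_start), "window_length": len(arc)}))

    # poly-A upstream of trnM (circular)
    up_start = trnm.start - polya_window
    if up_start < 1:
        up_start += rec.length
    up_end = trnm.start - 1
    if up_end < 1:
        up_end += rec.length
    arc = extract_arc(rec.sequence, up_start, up_end)
    best = max((len(m.group()) for m in re.finditer("A+", arc)), default=0)
    m = re.search("A{%d,}" % polya_min_run, arc)
    out.append(RepeatAnnotation(
        "poly_a",
        m.start() + 1 if m else 0, m.end() if m else 0,
        {"where": "upstream of trnM", "present": m is not None,
         "longest_a_run": best,
         "window_genome_start": up_start, "window_length": len(arc)}))
    return out


# ---------------------------------------------------------------------------
# Combined scan
# ---------------------------------------------------------------------------

def scan_control_region(region: str, **params) -> list[RepeatAnnotation]:
    """Run all region-local detectors and merge their reports.

    When a microsatellite and a tandem-repeat detection share the period and
    overlap, only one survives: the tandem report when it scores higher
    (it extends the perfect run with degenerate copies), otherwise the
    microsatellite, whose label is the more specific one.
    """
    origin = find_origin_signature(
        region, params.get("min_t_run", 10), params.get("max_gap", 5))
    msats = find_microsatellites(
        region, params.get("unit_range", (1, 6)), params.get("min_copies", 5))
    tandems = find_tandem_repeats(
        region, params.get("period_range", (2, 50)),
        params.get("match", 2), params.get("mismatch", -3),
        params.get("min_score", 20))
    stems = find_stem_loops(
        region, params.get("min_stem", 5), params.get("loop_range", (3, 20)),
        params.get("allow_gu", True))

    drop_tandem: set[int] = set()
    kept_msats: list[RepeatAnnotation] = []
    for ms in msats:
        ms_score = 2 * (ms.attributes["span"] - ms.attributes["period"])
        shadowed = False
        for ti, td in enumerate(tandems):
            if (td.attributes["period"] == ms.attributes["period"]
                    and _span_overlap(ms, td) > 0):
                if td.attributes["score"] > ms_score:
                    shadowed = True
                else:
                    drop_tandem.add(ti)
        if not shadowed:
            kept_msats.append(ms)
    merged = origin + kept_msats + [
        t for i, t in enumerate(tandems) if i not in drop_tandem] + stems
    merged.sort(key=lambda a: (a.start, a.end, a.kind))
    return merged


def annotations_to_tsv(annotations: list[RepeatAnnotation], handle: TextIO,
                       genome_offset: int = 0) -> None:
    """BED-like TSV; ``genome_offset`` maps region-local to global coords."""
    handle.write("kind\tstart\tend\tglobal_start\tglobal_end\tattributes\n")
    for a in annotations:
        attrs = ";".join(f"{k}={v}" for k, v in sorted(a.attributes.items()))
        handle.write(f"{a.kind}\t{a.start}\t{a.end}\t"
                     f"{a.start + genome_offset}\t{a.end + genome_offset}\t{attrs}\n")
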