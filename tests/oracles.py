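"""Independent brute-force oracles used to validate the detectors.

Each oracle restates the detector's declarative contract with the dumbest
implementation that will run in test time; none of them share code with the
package beyond the contract itself.
"""

from __future__ import annotations


# ---------------------------------------------------------------------------
# Tandem repeats: greedy disjoint maximum-score intervals per period
# ---------------------------------------------------------------------------

def tandem_oracle(region: str, period_range=(2, 50), match=2, mismatch=-3,
                  min_score=20, dedup_overlap=0.5):
    """All-period, all-phase scan.

    For each period, every interval of the self-shift match array is scored
    by exhaustive enumeration; intervals are accepted greedily (best score,
    ties to the smallest end then smallest start) and the search recurses
    into the flanks.  Returns (start, end, period, score) tuples after
    cross-period dedup by score.
    """
    region = region.upper()
    n = len(region)
    raw = []
    for p in range(period_range[0], min(period_range[1], n - 1) + 1):
        m = [region[i] == region[i + p] for i in range(n - p)]
        if len(m) < 2:
            continue

        def best_in(lo, hi):
            best = None  # (score, b, a)
            for b in range(lo, hi):
                if not m[b]:
                    continue
                running = 0
                # scan a downward accumulating the interval score
                for a in range(b, lo - 1, -1):
                    running += match if m[a] else mismatch
                    if not m[a]:
                        continue
                    cand = (running, b, a)
                    if best is None or cand[0] > best[0] \
                            or (cand[0] == best[0]
                                and (b, a) < (best[1], best[2])):
                        best = cand
            return best

        segments = [(0, len(m))]
        while segments:
            lo, hi = segments.pop()
            got = best_in(lo, hi)
            if got is None or got[0] < min_score:
                continue
            score, b, a = got
            raw.append((a + 1, b + 1 + p, p, score))
            segments.append((lo, a))
            segments.append((b + 1, hi))
    raw.sort(key=lambda r: (-r[3], r[2], r[0]))
    kept = []
    for cand in raw:
        ok = True
        for k in kept:
            inter = min(cand[1], k[1]) - max(cand[0], k[0]) + 1
            shorter = min(cand[1] - cand[0], k[1] - k[0]) + 1
            if inter > 0 and inter / shorter > dedup_overlap:
                ok = False
                break
        if ok:
            kept.append(cand)
    return sorted(kept)


# ---------------------------------------------------------------------------
# Stem-loops: exhaustive hairpin enumeration
# ---------------------------------------------------------------------------

_PAIRS_WC = {"AT", "TA", "GC", "CG"}
_PAIRS_GU = {"GT", "TG"}


def _can_pair(x, y, allow_gu):
    return x + y in _PAIRS_WC or (allow_gu and x + y in _PAIRS_GU)


def stemloop_oracle(region: str, min_stem=5, loop_range=(3, 20), allow_gu=True):
    """All (start, stem, loop) hairpins that are maximal inward and outward.

    Returns (start, end, stem, loop) in 1-based closed coordinates.
    """
    region = region.upper()
    n = len(region)
    lo, hi = loop_range
    out = set()
    for a in range(n):
        for s in range(min_stem, n):
            for loop in range(lo, hi + 1):
                b = a + 2 * s + loop - 1   # 0-based hairpin end
                if b >= n:
                    continue
                ok = all(_can_pair(region[a + k], region[b - k], allow_gu)
                         for k in range(s))
                if not ok:
                    continue
                # outward maximality
                if a - 1 >= 0 and b + 1 < n and \
                        _can_pair(region[a - 1], region[b + 1], allow_gu):
                    continue
                # inward maximality
                if loop - 2 >= lo and _can_pair(
                        region[a + s], region[b - s], allow_gu):
                    continue
                out.add((a + 1, b + 1, s, loop))
    return sorted(out)


# ---------------------------------------------------------------------------
# Cloverleaf: exhaustive joint arm-placement search
# ---------------------------------------------------------------------------

def _pair_score(x, y):
    if x + y in _PAIRS_WC:
        return 2
    if x + y in _PAIRS_GU:
        return 1
    return -1


def cloverleaf_best_score(seq: str, anticodon_pos: int):
    """Maximum score over every legal joint placement, or None when no
    placement exists.  Mirrors the published arm constraints: acceptor 7 bp,
    anticodon stem 5 bp with the anticodon at loop positions 3-5, DHU stem
    0-4 bp (loop 3-12), TpsiC stem 0-6 bp (loop 3-9), spacers 0-4 nt,
    variable loop 0-23 nt, discriminator 0-1 nt."""
    seq = seq.upper().replace("U", "T")
    if seq.endswith("CCA"):
        seq = seq[:-3]
    n = len(seq)
    a0 = anticodon_pos - 1
    left = a0 - 14
    if left < 0:
        return None
    best = None
    ac_score = sum(_pair_score(seq[a0 - 7 + k], seq[a0 + 9 - k])
                   for k in range(5))
    for d in (0, 1):
        right = n - 7 - d - (a0 + 10)
        if right < 0:
            continue
        acc = sum(_pair_score(seq[k], seq[n - 1 - d - k]) for k in range(7))
        lefts = [0]   # DHU absent
        for s1 in range(0, 5):
            for d1 in range(1, 5):
                for l1 in range(3, 13):
                    s2 = left - s1 - 2 * d1 - l1
                    if not 0 <= s2 <= 4:
                        continue
                    p5 = 7 + s1
                    lefts.append(sum(
                        _pair_score(seq[p5 + k], seq[p5 + 2 * d1 + l1 - 1 - k])
                        for k in range(d1)))
        rights = [0]  # TpsiC absent
        for v in range(0, 24):
            for t in range(1, 7):
                for lt in range(3, 10):
                    if v + 2 * t + lt != right:
                        continue
                    p5 = a0 + 10 + v
                    rights.append(sum(
                        _pair_score(seq[p5 + k], seq[p5 + 2 * t + lt - 1 - k])
                        for k in range(t)))
        for ls in lefts:
            for rs in rights:
                total = acc + ac_score + ls + rs
                if best is None or total > best:
                    best = total
    return best
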