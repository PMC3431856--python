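"""Genome architecture: junction ledger, spacer/overlap summary, gene order.

Consecutive genes on the circular genome either abut, are separated by an
intergenic spacer (positive gap) or overlap (negative gap).  The junction
ledger records the signed gap after every feature, including the wrap
junction from the last feature back to the first, so circular closure holds:

    sum(feature lengths) + sum(gaps) == genome length

whenever no feature is nested inside another (nesting is rejected).

The module also compares gene orders between genomes as rotation-aligned
name/strand signatures anchored at trnM, and QC-checks an annotation table
whose printed size/spacer columns were carried through parsing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, TextIO

from .genome_model import FeatureTableError, MitogenomeRecord, feature_length


@dataclass
class JunctionEntry:
    upstream: str
    downstream: str
    gap: int

    @property
    def kind(self) -> str:
        if self.gap > 0:
            return "spacer"
        if self.gap < 0:
            return "overlap"
        return "abutting"


@dataclass
class JunctionLedger:
    """Signed gaps between consecutive features around the circle."""

    entries: list[JunctionEntry]
    genome_length: int
    control_names: frozenset[str] = frozenset()

    def to_tsv(self, handle: TextIO) -> None:
        handle.write("upstream\tdownstream\tgap\tclass\n")
        for e in self.entries:
            handle.write(f"{e.upstream}\t{e.downstream}\t{e.gap}\t{e.kind}\n")

    def gap_between(self, upstream: str, downstream: str) -> int:
        for e in self.entries:
            if e.upstream == upstream and e.downstream == downstream:
                return e.gap
        raise KeyError(f"no junction {upstream} -> {downstream}")


@dataclass
class LedgerSummary:
    spacer_count: int
    spacer_total_bp: int
    overlap_count: int
    overlap_total_bp: int
    longest_spacer: int
    longest_overlap: int

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _circular_gap(prev_end: int, next_start: int, length: int) -> int:
    """Signed gap on the circle, taken in the window (-L/2, L/2]."""
    raw = next_start - prev_end - 1
    half = length // 2
    return (raw + half) % length - half


def junction_ledger(rec: MitogenomeRecord) -> JunctionLedger:
    """Compute the gap after each feature, in circular order.

    Raises :class:`FeatureTableError` when one feature is nested inside
    another, since the circular-closure identity breaks there.
    """
    feats = rec.sorted_features()
    if not feats:
        raise FeatureTableError("junction ledger requires at least one feature")
    entries: list[JunctionEntry] = []
    n = len(feats)
    for i, f in enumerate(feats):
        g = feats[(i + 1) % n]
        if n == 1:
            entries.append(JunctionEntry(
                f.name, g.name, rec.length - feature_length(f, rec.length)))
            continue
        gap = _circular_gap(f.end, g.start, rec.length)
        # nesting checks: the downstream feature must extend beyond this one
        if i + 1 < n and not g.wraps_origin and not f.wraps_origin \
                and g.end <= f.end and g.start >= f.start:
            raise FeatureTableError(
                f"feature {g.name} is nested inside {f.name}")
        if -gap > min(feature_length(f, rec.length),
                      feature_length(g, rec.length)):
            raise FeatureTableError(
                f"features {f.name} and {g.name} overlap deeper than the "
                "shorter feature (nesting)")
        entries.append(JunctionEntry(f.name, g.name, gap))
    return JunctionLedger(
        entries=entries, genome_length=rec.length,
        control_names=frozenset(
            f.name for f in feats if f.category == "control"))


def ledger_summary(ledger: JunctionLedger,
                   exclude: Optional[Iterable[str]] = None) -> LedgerSummary:
    """Spacer/overlap counts and totals over the ledger.

    Junctions whose upstream or downstream feature is excluded are skipped.
    By default the control region's flanking junctions are excluded,
    following the convention of counting intergenic spacers "with the
    exception of the A+T-rich region".
    """
    excluded = frozenset(ledger.control_names if exclude is None else exclude)
    spacers: list[int] = []
    overlaps: list[int] = []
    for e in ledger.entries:
        if e.upstream in excluded or e.downstream in excluded:
            continue
        if e.gap > 0:
            spacers.append(e.gap)
        elif e.gap < 0:
            overlaps.append(-e.gap)
    return LedgerSummary(
        spacer_count=len(spacers),
        spacer_total_bp=sum(spacers),
        overlap_count=len(overlaps),
        overlap_total_bp=sum(overlaps),
        longest_spacer=max(spacers, default=0),
        longest_overlap=max(overlaps, default=0),
    )


# ---------------------------------------------------------------------------
# Gene order
# ---------------------------------------------------------------------------

def gene_order_signature(rec: MitogenomeRecord,
                         anchor: str = "trnM") -> list[tuple[str, str]]:
    """Rotation-normalized (name, strand) signature starting at ``anchor``."""
    feats = rec.sorted_features()
    names = [f.name for f in feats]
    if anchor not in names:
        raise FeatureTableError(f"anchor gene {anchor!r} absent from annotation")
    i = names.index(anchor)
    rotated = feats[i:] + feats[:i]
    return [(f.name, f.strand) for f in rotated]


def compare_gene_order(signature: Sequence[tuple[str, str]],
                       reference: Sequence[tuple[str, str]]) -> list[str]:
    """Genes displaced between two same-content circular gene orders.

    The query is rotated into the register that minimizes the number of
    position/strand mismatches against the reference; the genes mismatching
    under that best rotation are reported (sorted).  A strand flip counts as
    displacement.
    """
    if len(signature) != len(reference):
        raise ValueError("gene orders have different feature counts")
    if sorted(n for n, _ in signature) != sorted(n for n, _ in reference):
        raise ValueError("gene orders do not share the same gene set")
    n = len(reference)
    best: Optional[list[str]] = None
    for off in range(n):
        displaced = [reference[i][0]
                     for i in range(n)
                     if signature[(i + off) % n] != reference[i]]
        if best is None or len(displaced) < len(best):
            best = displaced
    assert best is not None
    return sorted(best)


# ---------------------------------------------------------------------------
# Annotation-table QC
# ---------------------------------------------------------------------------

@dataclass
class Discrepancy:
    kind: str          # "size" or "spacer"
    where: str         # feature name or "upstream->downstream"
    printed: int
    computed: int

    def __str__(self) -> str:
        return (f"{self.kind} mismatch at {self.where}: printed "
                f"{self.printed}, computed {self.computed}")


def table_qc(rec: MitogenomeRecord) -> list[Discrepancy]:
    """Cross-check printed size/spacer columns against the coordinates.

    Annotation tables in genome descriptions occasionally print a gene size
    or intergenic-spacer value that contradicts the coordinates in the same
    row.  Coordinates are treated as authoritative; every disagreement with
    a carried printed column is reported.
    """
    out: list[Discrepancy] = []
    for f in rec.sorted_features():
        if f.printed_size is not None:
            computed = feature_length(f, rec.length)
            if computed != f.printed_size:
                out.append(Discrepancy("size", f.name, f.printed_size, computed))
    ledger = junction_ledger(rec)
    by_upstream = {e.upstream: e for e in ledger.entries}
    for f in rec.sorted_features():
        if f.printed_spacer is None:
            continue
        e = by_upstream[f.name]
        if e.gap != f.printed_spacer:
            out.append(Discrepancy(
                "spacer", f"{e.upstream}->{e.downstream}",
                f.printed_spacer, e.gap))
    return out


def printed_spacer_summary(rec: MitogenomeRecord) -> LedgerSummary:
    """Spacer/overlap summary over the *printed* spacer column of a table.

    Available only for records parsed from a table that carries the printed
    intergenic-spacer column (the packaged reference annotation does).
    """
    gaps = [f.printed_spacer for f in rec.sorted_features()
            if f.printed_spacer is not None and f.category != "control"]
    if not gaps:
        raise FeatureTableError("record carries no printed spacer column")
    spacers = [g for g in gaps if g > 0]
    overlaps = [-g for g in gaps if g < 0]
    return LedgerSummary(
        spacer_count=len(spacers), spacer_total_bp=sum(spacers),
        overlap_count=len(overlaps), overlap_total_bp=sum(overlaps),
        longest_spacer=max(spacers, default=0),
        longest_overlap=max(overlaps, default=0))


def category_length_totals(rec: MitogenomeRecord) -> dict[str, int]:
    """Total bp per feature category (PCG, tRNA, rRNA, control)."""
    totals: dict[str, int] = {}
    for f in rec.features:
        totals[f.category] = totals.get(f.category, 0) + feature_length(f, rec.length)
    return totals
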