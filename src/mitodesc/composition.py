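"""Nucleotide composition and strand-skew statistics per genome region.

AT skew = (A - T) / (A + T) and GC skew = (G - C) / (G + C) quantify the
compositional asymmetry between the two strands of a genome region; both lie
in [-1, 1] and negate under reverse complement.  AT content is
(A + T) / (A + T + G + C) * 100, with N bases excluded from both numerator
and denominator.

Region rows follow the conventional layout of mitogenome description tables:
one row for the whole genome (majority strand), one per gene category (PCGs,
tRNAs, rRNAs, each on concatenated, strand-oriented gene sequences) and one
for the control region.  The whole-genome skews are computed on the F strand,
including the control region; per-category skews are computed on the coding
strand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, TextIO

from . import codon_usage
from .genome_model import (FeatureTableError, MitogenomeRecord,
                           extract_feature_sequence)


@dataclass
class CompositionStats:
    a: int
    t: int
    g: int
    c: int
    other: int

    @property
    def length(self) -> int:
        return self.a + self.t + self.g + self.c + self.other

    @property
    def at_content(self) -> Optional[float]:
        denom = self.a + self.t + self.g + self.c
        return 100.0 * (self.a + self.t) / denom if denom else None

    @property
    def at_skew(self) -> Optional[float]:
        denom = self.a + self.t
        return (self.a - self.t) / denom if denom else None

    @property
    def gc_skew(self) -> Optional[float]:
        denom = self.g + self.c
        return (self.g - self.c) / denom if denom else None

    def as_row(self) -> dict:
        def r(x, nd):
            return None if x is None else round(x, nd)
        return {
            "length": self.length,
            "at_percent": r(self.at_content, 1),
            "at_skew": r(self.at_skew, 3),
            "gc_skew": r(self.gc_skew, 3),
        }


def composition(seq: str) -> CompositionStats:
    """Exact base counts and skews of a sequence."""
    if not seq:
        raise FeatureTableError("empty sequence")
    seq = seq.upper()
    a, t = seq.count("A"), seq.count("T")
    g, c = seq.count("G"), seq.count("C")
    return CompositionStats(a=a, t=t, g=g, c=c,
                            other=len(seq) - a - t - g - c)


_REGION_ORDER = ("whole_genome", "PCG", "tRNA", "rRNA", "control")


def region_composition_report(rec: MitogenomeRecord) -> dict[str, CompositionStats]:
    """Composition rows per region: whole genome, PCGs, tRNAs, rRNAs, control.

    Category rows concatenate the strand-oriented sequences of their genes;
    the whole-genome row uses the F strand as stored.
    """
    if rec.sequence is None:
        raise FeatureTableError("region composition requires a sequence")
    out = {"whole_genome": composition(rec.sequence)}
    for category in ("PCG", "tRNA", "rRNA", "control"):
        parts = [extract_feature_sequence(rec, f)
                 for f in rec.sorted_features() if f.category == category]
        if parts:
            out[category] = composition("".join(parts))
    return out


def codon_position_composition(rec: MitogenomeRecord) -> tuple[float, float, float]:
    """AT% at codon positions 1-3 over all PCGs.

    Positions are indexed within the reading frame after removing the start
    codon and the complete or truncated stop, consistent with the codon
    extraction used for usage statistics.
    """
    if rec.sequence is None:
        raise FeatureTableError("codon-position composition requires a sequence")
    counts = [[0, 0], [0, 0], [0, 0]]  # per position: [AT, ACGT]
    n_pcg = 0
    for f in rec.sorted_features():
        if f.category != "PCG":
            continue
        n_pcg += 1
        cds = extract_feature_sequence(rec, f)
        cls = codon_usage.classify_start_stop(f, cds)
        for codon in codon_usage.coding_codons(cds, cls.stop_len):
            for pos, base in enumerate(codon):
                if base in "ACGT":
                    counts[pos][1] += 1
                    if base in "AT":
                        counts[pos][0] += 1
    if n_pcg == 0 or any(tot == 0 for _, tot in counts):
        raise FeatureTableError("no codon material in record")
    return tuple(100.0 * at / tot for at, tot in counts)  # type: ignore[return-value]


def report_to_tsv(report: dict[str, CompositionStats], handle: TextIO) -> None:
    handle.write("region\tlength\tat_percent\tat_skew\tgc_skew\n")
    for region in _REGION_ORDER:
        if region not in report:
            continue
        row = report[region].as_row()
        handle.write("\t".join([
            region, str(row["length"]),
            *("NA" if row[k] is None else f"{row[k]:.3f}"
              for k in ("at_percent", "at_skew", "gc_skew")),
        ]) + "\n")


def report_to_json(report: dict[str, CompositionStats]) -> str:
    return json.dumps({k: v.as_row() for k, v in report.items()}, indent=2)
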