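"""Codon usage under the invertebrate mitochondrial genetic code.

Covers start/stop classification (including the truncated T / TA stops that
are completed to UAA by post-transcriptional polyadenylation), extraction of
in-frame codons excluding initiation and termination codons, counts per
thousand codons, and relative synonymous codon usage (RSCU).

The code table is NCBI translation table 5 (invertebrate mitochondrial):
AGA/AGG encode Ser, ATA Met, TGA Trp, leaving 62 sense codons (TAA and TAG
are the only stops).  Synonymous families follow the conventional split of
the six-fold amino acids into Leu1 (CTN), Leu2 (TTA/TTG), Ser1 (AGN) and
Ser2 (TCN).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, TextIO

from Bio.Data import CodonTable

from .genome_model import (FeatureTableError, GeneFeature, MitogenomeRecord,
                           extract_feature_sequence)

_TABLE5 = CodonTable.unambiguous_dna_by_id[5]

STOP_CODONS = tuple(_TABLE5.stop_codons)          # ("TAA", "TAG")
SENSE_CODONS = tuple(sorted(_TABLE5.forward_table))  # 62 codons

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


def _family_of(codon: str) -> str:
    aa = _TABLE5.forward_table[codon]
    name = _AA3[aa]
    if aa == "L":
        return "Leu1" if codon.startswith("CT") else "Leu2"
    if aa == "S":
        return "Ser1" if codon.startswith("AG") else "Ser2"
    return name


#: codon -> synonymous family label (Leu and Ser split into two families each)
FAMILY_OF: dict[str, str] = {c: _family_of(c) for c in SENSE_CODONS}

#: family label -> tuple of member codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _c, _f in FAMILY_OF.items():
    FAMILIES.setdefault(_f, ())
FAMILIES = {f: tuple(sorted(c for c in SENSE_CODONS if FAMILY_OF[c] == f))
            for f in FAMILIES}


def translate(cds: str, first_is_start: bool = False) -> str:
    """Translate under the invertebrate mitochondrial code.

    The length must be a multiple of 3 (trim any truncated stop first).
    Codons with ambiguous bases translate to X.  With ``first_is_start`` the
    leading codon translates to M regardless of identity, matching the
    convention that nonstandard initiation codons (ATN, CGA) specify
    methionine.
    """
    if len(cds) % 3:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    out: list[str] = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3].upper()
        if i == 0 and first_is_start:
            out.append("M")
        elif codon in _TABLE5.forward_table:
            out.append(_TABLE5.forward_table[codon])
        elif codon in STOP_CODONS:
            out.append("*")
        else:
            out.append("X")
    return "".join(out)


@dataclass
class StartStop:
    start_codon: str
    stop_class: str          # "TAA", "TAG", "TA", "T" or "anomalous"
    stop_len: int            # 3, 2, 1 (0 when anomalous and frame-complete)

    @property
    def truncated(self) -> bool:
        return self.stop_class in ("TA", "T")


def classify_start_stop(f: Optional[GeneFeature], cds: str) -> StartStop:
    """Classify the initiation codon and the (possibly truncated) stop.

    The stop class is forced by length mod 3 together with the terminal
    bases: an in-frame gene must end with a complete TAA/TAG, a gene one
    base over frame with T, two bases over with TA; anything else is
    flagged ``anomalous``.
    """
    cds = cds.upper()
    if len(cds) < 6:
        name = f.name if f is not None else "CDS"
        raise FeatureTableError(f"{name}: CDS shorter than 6 bp")
    start = cds[:3]
    rem = len(cds) % 3
    if rem == 0:
        tail = cds[-3:]
        if tail in STOP_CODONS:
            return StartStop(start, tail, 3)
        return StartStop(start, "anomalous", 0)
    if rem == 1 and cds.endswith("T"):
        return StartStop(start, "T", 1)
    if rem == 2 and cds.endswith("TA"):
        return StartStop(start, "TA", 2)
    return StartStop(start, "anomalous", rem)


def coding_codons(cds: str, stop_len: Optional[int] = None) -> list[str]:
    """In-frame codons of a CDS after removing start and stop codons."""
    if stop_len is None:
        stop_len = classify_start_stop(None, cds).stop_len
    body = cds[3:len(cds) - stop_len]
    return [body[i:i + 3] for i in range(0, len(body) - len(body) % 3, 3)]


@dataclass
class GeneCodonReport:
    name: str
    start_codon: str
    stop_class: str
    n_codons: int
    internal_stops: list[int] = field(default_factory=list)  # codon indices


@dataclass
class CodonUsageTable:
    """Per-codon counts over the sense codons, with derived statistics."""

    counts: Counter = field(default_factory=Counter)
    genes: list[GeneCodonReport] = field(default_factory=list)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def per_thousand(self) -> dict[str, float]:
        total = self.total
        if total == 0:
            raise FeatureTableError("empty codon table")
        return {c: 1000.0 * self.counts.get(c, 0) / total for c in SENSE_CODONS}

    def rscu(self) -> dict[str, Optional[float]]:
        """RSCU(c) = count(c) * degeneracy / family total; None when the
        whole family is unused (those codons are 'missing')."""
        out: dict[str, Optional[float]] = {}
        for fam, members in FAMILIES.items():
            fam_total = sum(self.counts.get(c, 0) for c in members)
            for c in members:
                if fam_total == 0:
                    out[c] = None
                else:
                    out[c] = self.counts.get(c, 0) * len(members) / fam_total
        return out

    def family_counts(self) -> dict[str, int]:
        return {fam: sum(self.counts.get(c, 0) for c in members)
                for fam, members in FAMILIES.items()}

    def to_tsv(self, handle: TextIO) -> None:
        pt = self.per_thousand() if self.total else {}
        rscu = self.rscu()
        handle.write("codon\tfamily\tcount\tper_thousand\trscu\n")
        for c in SENSE_CODONS:
            r = rscu.get(c)
            handle.write("\t".join([
                c, FAMILY_OF[c], str(self.counts.get(c, 0)),
                f"{pt.get(c, 0.0):.3f}",
                "NA" if r is None else f"{r:.3f}",
            ]) + "\n")


def extract_codons(rec: MitogenomeRecord) -> CodonUsageTable:
    """Codon counts over all protein-coding genes of a genome.

    For each PCG the CDS is taken in coding orientation, the start codon and
    the complete or truncated stop are removed, and the remaining in-frame
    codons are tallied.  Internal in-frame stop codons are recorded per gene
    (they indicate an annotation or assembly problem) but do not abort the
    tally; stop codons are never counted as sense codons.
    """
    table = CodonUsageTable()
    for f in rec.sorted_features():
        if f.category != "PCG":
            continue
        cds = extract_feature_sequence(rec, f)
        cls = classify_start_stop(f, cds)
        codons = coding_codons(cds, cls.stop_len)
        report = GeneCodonReport(
            name=f.name, start_codon=cls.start_codon,
            stop_class=cls.stop_class, n_codons=len(codons))
        for idx, codon in enumerate(codons):
            if codon in STOP_CODONS:
                report.internal_stops.append(idx)
            elif codon in _TABLE5.forward_table:
                table.counts[codon] += 1
            # codons containing N are skipped from the tally
        table.genes.append(report)
    return table


def per_thousand(table: CodonUsageTable) -> dict[str, float]:
    return table.per_thousand()


def rscu(table: CodonUsageTable) -> dict[str, Optional[float]]:
    return table.rscu()
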