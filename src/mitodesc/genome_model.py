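"""Data model and IO for annotated circular mitochondrial genomes.

The central objects are :class:`GeneFeature` (one annotated gene with 1-based
closed coordinates on the circle) and :class:`MitogenomeRecord` (the circular
genome with its ordered feature list and optional nucleotide sequence).

Readers and writers cover three plain-text dialects:

* a TSV feature table (one row per gene, columns documented in
  :data:`TSV_COLUMNS`), the format of the packaged annotation fixture;
* a minimal GenBank flat file (LOCUS / FEATURES / ORIGIN; gene, CDS, tRNA,
  rRNA, misc_feature and D-loop keys), parsed and emitted through Biopython;
* FASTA (70-column wrap).

Coordinates follow the GenBank convention: 1-based, closed intervals, with a
wrap-around feature represented as a single feature whose ``end`` is smaller
than its ``start`` (serialized to GenBank as ``join(start..L,1..end)``).
Strands are labelled ``F``/``R`` for the majority and minority strand; ``R``
features are reverse-complemented on extraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Optional, TextIO, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

CATEGORIES = ("PCG", "tRNA", "rRNA", "control")
VALID_BASES = set("ACGTN")

#: Columns of the TSV feature-table dialect, in order.  ``size_printed`` and
#: ``spacer_printed`` are optional reference columns used only by QC.
TSV_COLUMNS = (
    "name", "category", "strand", "start", "end",
    "anticodon", "anticodon_start", "anticodon_end",
    "start_codon", "stop_codon",
)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FeatureTableError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


@dataclass
class Anticodon:
    """Anticodon triplet with its absolute genome coordinates."""

    triplet: str
    start: Optional[int] = None
    end: Optional[int] = None


@dataclass
class GeneFeature:
    """One annotated gene on the circular genome.

    ``start``/``end`` are 1-based closed; ``end < start`` denotes a feature
    crossing the coordinate origin.  ``printed_size``/``printed_spacer`` hold
    the published table's "Size (bp)" and "Intergenic spacer" columns when the
    source provides them; they are carried for QC only.
    """

    name: str
    category: str
    strand: str
    start: int
    end: int
    anticodon: Optional[Anticodon] = None
    start_codon: Optional[str] = None
    stop_codon: Optional[str] = None
    printed_size: Optional[int] = None
    printed_spacer: Optional[int] = None

    def validate(self, genome_length: Optional[int] = None) -> None:
        if self.category not in CATEGORIES:
            raise FeatureTableError(
                f"{self.name}: unknown category {self.category!r}")
        if self.strand not in ("F", "R"):
            raise FeatureTableError(
                f"{self.name}: strand must be 'F' or 'R', got {self.strand!r}")
        if self.start < 1 or self.end < 1:
            raise FeatureTableError(
                f"{self.name}: coordinates must be >= 1 "
                f"({self.start}..{self.end})")
        if genome_length is not None and (
                self.start > genome_length or self.end > genome_length):
            raise FeatureTableError(
                f"{self.name}: coordinates {self.start}..{self.end} exceed "
                f"genome length {genome_length}")
        if self.category == "tRNA" and self.anticodon is None:
            raise FeatureTableError(f"{self.name}: tRNA lacks an anticodon")
        if self.category == "PCG" and not self.start_codon:
            raise FeatureTableError(f"{self.name}: PCG lacks a start codon")
        if self.stop_codon is not None and len(self.stop_codon) not in (1, 2, 3):
            raise FeatureTableError(
                f"{self.name}: stop codon {self.stop_codon!r} has invalid length")

    @property
    def wraps_origin(self) -> bool:
        return self.end < self.start


def feature_length(f: GeneFeature, genome_length: int) -> int:
    """Span of a feature in bp on a circle of ``genome_length``.

    A wrap-around feature (``end < start``) contributes the two arcs
    ``start..L`` and ``1..end``.
    """
    if f.wraps_origin:
        return (genome_length - f.start + 1) + f.end
    return f.end - f.start + 1


@dataclass
class MitogenomeRecord:
    """A circular annotated mitogenome."""

    id: str
    length: int
    features: list[GeneFeature] = field(default_factory=list)
    sequence: Optional[str] = None
    circular: bool = True

    def validate(self) -> None:
        if self.length < 1:
            raise FeatureTableError("genome length must be positive")
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise FeatureTableError(
                    f"sequence length {len(self.sequence)} != declared "
                    f"genome length {self.length}")
            bad = set(self.sequence) - VALID_BASES
            if bad:
                raise FeatureTableError(
                    f"sequence contains invalid characters {sorted(bad)!r}; "
                    "only A, C, G, T, N are accepted")
        controls = [f for f in self.features if f.category == "control"]
        if len(controls) > 1:
            names = ", ".join(f.name for f in controls)
            raise FeatureTableError(
                f"more than one control-region feature: {names}")
        for f in self.features:
            f.validate(self.length)
        starts = [f.start for f in self.features]
        if starts != sorted(starts):
            raise FeatureTableError("features are not sorted by start")

    def sorted_features(self) -> list[GeneFeature]:
        return sorted(self.features, key=lambda f: (f.start, f.end))

    def get_feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(f"no feature named {name!r}")

    def copy(self) -> "MitogenomeRecord":
        return MitogenomeRecord(
            id=self.id, length=self.length,
            features=[replace(f, anticodon=(replace(f.anticodon)
                                            if f.anticodon else None))
                      for f in self.features],
            sequence=self.sequence, circular=self.circular)


def extract_feature_sequence(rec: MitogenomeRecord, f: GeneFeature) -> str:
    """Feature sequence in coding orientation (R features reverse-complemented)."""
    if rec.sequence is None:
        raise FeatureTableError(
            f"cannot extract {f.name}: record has no sequence (sequence required)")
    s = extract_arc(rec.sequence, f.start, f.end)
    return reverse_complement(s) if f.strand == "R" else s


def extract_arc(sequence: str, start: int, end: int) -> str:
    """F-strand bases of the closed interval ``start..end`` on the circle."""
    if end >= start:
        return sequence[start - 1:end]
    return sequence[start - 1:] + sequence[:end]


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------

def _opt(value: str) -> Optional[str]:
    value = value.strip()
    return None if value in ("", ".", "-") else value


def _parse_tsv(handle: TextIO) -> MitogenomeRecord:
    declared_length: Optional[int] = None
    header: Optional[list[str]] = None
    features: list[GeneFeature] = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if body.startswith("length="):
                declared_length = int(body.split("=", 1)[1])
            continue
        cells = line.split("\t")
        if header is None:
            header = [c.strip() for c in cells]
            missing = [c for c in ("name", "category", "strand", "start", "end")
                       if c not in header]
            if missing:
                raise FeatureTableError(
                    f"line {lineno}: header lacks required columns {missing}")
            continue
        row = dict(zip(header, cells))
        try:
            start = int(row["start"])
            end = int(row["end"])
        except (KeyError, ValueError) as exc:
            raise FeatureTableError(
                f"line {lineno}: malformed coordinates ({exc})") from exc
        anticodon = None
        trip = _opt(row.get("anticodon", "."))
        if trip is not None:
            ac_start = _opt(row.get("anticodon_start", "."))
            ac_end = _opt(row.get("anticodon_end", "."))
            anticodon = Anticodon(
                triplet=trip.upper(),
                start=int(ac_start) if ac_start else None,
                end=int(ac_end) if ac_end else None)

        def _opt_int(col: str) -> Optional[int]:
            v = _opt(row.get(col, "."))
            return int(v) if v is not None else None

        features.append(GeneFeature(
            name=row["name"].strip(),
            category=row["category"].strip(),
            strand=row["strand"].strip() or "F",
            start=start, end=end,
            anticodon=anticodon,
            start_codon=_opt(row.get("start_codon", ".")),
            stop_codon=_opt(row.get("stop_codon", ".")),
            printed_size=_opt_int("size_printed"),
            printed_spacer=_opt_int("spacer_printed"),
        ))
    if header is None and declared_length is None:
        raise FeatureTableError("empty feature table with no declared length")
    length = declared_length
    if length is None:
        length = max((max(f.start, f.end) for f in features), default=0)
        if length == 0:
            raise FeatureTableError("cannot infer genome length from 0 features")
    features.sort(key=lambda f: (f.start, f.end))
    rec = MitogenomeRecord(id="feature_table", length=length, features=features)
    rec.validate()
    return rec


def write_feature_table(rec: MitogenomeRecord, handle: TextIO) -> None:
    handle.write(f"# length={rec.length}\n")
    handle.write("\t".join(TSV_COLUMNS) + "\n")
    for f in rec.features:
        ac = f.anticodon
        cells = [
            f.name, f.category, f.strand, str(f.start), str(f.end),
            ac.triplet if ac else ".",
            str(ac.start) if ac and ac.start else ".",
            str(ac.end) if ac and ac.end else ".",
            f.start_codon or ".", f.stop_codon or ".",
        ]
        handle.write("\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# GenBank dialect (via Biopython, restricted key set)
# ---------------------------------------------------------------------------

_GB_HANDLED = {"source", "gene", "CDS", "tRNA", "rRNA", "misc_feature", "D-loop"}


def _category_for(ftype: str, name: str) -> str:
    if ftype == "tRNA" or name.startswith("trn"):
        return "tRNA"
    if ftype == "rRNA" or name.startswith("rrn"):
        return "rRNA"
    if ftype in ("misc_feature", "D-loop"):
        return "control"
    return "PCG"


def _parse_genbank(handle: TextIO) -> MitogenomeRecord:
    seqrec = SeqIO.read(handle, "genbank")
    length = len(seqrec.seq)
    sequence: Optional[str] = None
    seq_str = str(seqrec.seq).upper()
    if seq_str and set(seq_str) != {"N"}:
        bad = set(seq_str) - VALID_BASES
        if bad:
            raise FeatureTableError(
                f"ambiguity codes other than N are not accepted: {sorted(bad)}")
        sequence = seq_str

    features: list[GeneFeature] = []
    for ft in seqrec.features:
        if ft.type == "source":
            continue
        if ft.type not in _GB_HANDLED:
            log.warning("ignoring unsupported feature key %r", ft.type)
            continue
        if ft.type == "gene":
            # gene keys mirror the typed features; the typed ones carry more
            continue
        quals = ft.qualifiers
        name = (quals.get("gene") or quals.get("product")
                or quals.get("note") or [ft.type])[0]
        parts = ft.location.parts
        start = int(parts[0].start) + 1
        end = int(parts[-1].end)
        anticodon = None
        if "anticodon" in quals:
            anticodon = _parse_anticodon_qualifier(quals["anticodon"][0])
        features.append(GeneFeature(
            name=name,
            category=_category_for(ft.type, name),
            strand="R" if ft.location.strand == -1 else "F",
            start=start, end=end,
            anticodon=anticodon,
            start_codon=(quals.get("start_codon") or [None])[0],
            stop_codon=(quals.get("stop_codon") or [None])[0],
        ))
    features.sort(key=lambda f: (f.start, f.end))
    rec = MitogenomeRecord(
        id=seqrec.id or "genbank", length=length,
        features=features, sequence=sequence)
    rec.validate()
    return rec


def _parse_anticodon_qualifier(text: str) -> Anticodon:
    # accepts "(pos:3064..3066,seq:taa)" and bare triplets
    text = text.strip("()")
    start = end = None
    triplet = text
    if "pos:" in text:
        for part in text.split(","):
            part = part.strip()
            if part.startswith("pos:"):
                span = part[4:]
                a, _, b = span.partition("..")
                start, end = int(a), int(b or a)
            elif part.startswith("seq:"):
                triplet = part[4:]
    return Anticodon(triplet=triplet.upper(), start=start, end=end)


def write_genbank(rec: MitogenomeRecord, handle: TextIO) -> None:
    seq = Seq(rec.sequence if rec.sequence is not None else "N" * rec.length)
    seqrec = SeqRecord(seq, id=rec.id, name=rec.id[:16].replace(" ", "_"),
                       description="")
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = "circular" if rec.circular else "linear"
    seqrec.annotations["data_file_division"] = "INV"
    type_for = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                "control": "misc_feature"}
    for f in rec.features:
        strand = -1 if f.strand == "R" else 1
        if f.wraps_origin:
            loc = CompoundLocation([
                SimpleLocation(f.start - 1, rec.length, strand=strand),
                SimpleLocation(0, f.end, strand=strand)])
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand=strand)
        quals: dict[str, list[str]] = {"gene": [f.name]}
        if f.anticodon is not None:
            ac = f.anticodon
            if ac.start and ac.end:
                quals["anticodon"] = [
                    f"(pos:{ac.start}..{ac.end},seq:{ac.triplet.lower()})"]
            else:
                quals["anticodon"] = [ac.triplet.lower()]
        if f.start_codon:
            quals["start_codon"] = [f.start_codon]
        if f.stop_codon:
            quals["stop_codon"] = [f.stop_codon]
        seqrec.features.append(SeqFeature(loc, type=type_for[f.category],
                                          qualifiers=quals))
    SeqIO.write([seqrec], handle, "genbank")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(source: Union[str, Path, TextIO]) -> tuple[str, str]:
    """Read a single-record FASTA; returns ``(id, sequence)``."""
    close = False
    if isinstance(source, (str, Path)):
        source = open(source)
        close = True
    try:
        seqrec = SeqIO.read(source, "fasta")
    finally:
        if close:
            source.close()
    seq = str(seqrec.seq).upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise FeatureTableError(
            f"ambiguity codes other than N are not accepted: {sorted(bad)}")
    return seqrec.id, seq


def write_fasta(name: str, sequence: str, handle: TextIO, wrap: int = 70) -> None:
    handle.write(f">{name}\n")
    for i in range(0, len(sequence), wrap):
        handle.write(sequence[i:i + wrap] + "\n")


# ---------------------------------------------------------------------------
# Entry points
# ---------------------------------------------------------------------------

def read_feature_table(source: Union[str, Path, TextIO],
                       format: str = "tsv") -> MitogenomeRecord:
    """Read an annotated mitogenome from ``tsv`` or ``genbank`` input."""
    close = False
    if isinstance(source, (str, Path)):
        source = open(source)
        close = True
    try:
        if format == "tsv":
            return _parse_tsv(source)
        if format == "genbank":
            return _parse_genbank(source)
        raise ValueError(f"unknown format {format!r}")
    finally:
        if close:
            source.close()


def load_reference_annotation() -> MitogenomeRecord:
    """The packaged Sesamia inferens annotation table (37 genes + control region)."""
    ref = resources.files("mitodesc.data") / "sesamia_inferens_table1.tsv"
    with ref.open() as handle:
        rec = _parse_tsv(handle)
    rec.id = "JN039362"
    return rec
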