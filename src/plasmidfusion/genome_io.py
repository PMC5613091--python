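"""Replicon containers and coordinate-safe sequence access.

Reads annotated replicons from GenBank flat files (or FASTA plus a feature
table TSV), writes FASTA/TSV back out, and provides region extraction that is
aware of circular topology.  Coordinates are 1-based inclusive throughout the
public surface, following the GenBank convention; slicing internals are
0-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation, CompoundLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class GenomeParseError(ValueError):
    """Raised when an input record cannot be interpreted as a replicon."""


@dataclass
class GeneFeature:
    """A gene/CDS interval on a replicon.

    ``start``/``end`` are 1-based inclusive.  A feature annotated across the
    origin of a circular molecule keeps its native start > end coordinates and
    is flagged ``wraps_origin`` instead of being split.
    """

    locus_tag: str
    start: int
    end: int
    strand: str  # "+" or "-"
    kind: str = "CDS"  # CDS, gene, other
    product: str = ""
    role: Optional[str] = None  # repA, repB, repC, other
    wraps_origin: bool = False
    frame_warning: bool = False

    def length(self, replicon_length: Optional[int] = None) -> int:
        if not self.wraps_origin:
            return self.end - self.start + 1
        if replicon_length is None:
            raise ValueError("replicon length required for origin-spanning feature")
        return replicon_length - self.start + 1 + self.end


@dataclass
class Replicon:
    """A circular or linear nucleotide molecule plus ordered gene features."""

    id: str
    sequence: str
    topology: str = "circular"  # circular | linear
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise GenomeParseError(
                f"replicon {self.id!r}: unsupported characters {sorted(bad)} "
                "(alphabet is A/C/G/T/N)"
            )
        if self.topology not in ("circular", "linear"):
            raise GenomeParseError(f"replicon {self.id!r}: bad topology {self.topology!r}")
        self.features.sort(key=lambda f: (f.start, f.end))
        for f in self.features:
            if not (1 <= f.start <= self.length and 1 <= f.end <= self.length):
                raise GenomeParseError(
                    f"feature {f.locus_tag} outside [1, {self.length}] on {self.id}"
                )
            if f.start > f.end and not f.wraps_origin:
                raise GenomeParseError(
                    f"feature {f.locus_tag}: start > end but not flagged wraps_origin"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def cds_features(self) -> list[GeneFeature]:
        return [f for f in self.features if f.kind == "CDS"]


@dataclass
class GenomeSet:
    """All replicons of one genome with a designated chromosome."""

    replicons: list[Replicon]
    designated_chromosome: str

    def __post_init__(self) -> None:
        ids = [r.id for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise GenomeParseError(f"duplicate replicon ids: {ids}")
        if self.designated_chromosome not in ids:
            raise GenomeParseError(
                f"designated chromosome {self.designated_chromosome!r} not among {ids}"
            )

    def __getitem__(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.id == replicon_id:
                return r
        raise KeyError(replicon_id)


def reverse_complement(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet (involution; N -> N)."""
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise ValueError(f"cannot complement symbols {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def extract_region(replicon: Replicon, start: int, end: int) -> str:
    """Extract [start, end] (1-based inclusive); start > end wraps on circular
    molecules through position 1."""
    n = replicon.length
    if not (1 <= start <= n and 1 <= end <= n):
        raise ValueError(f"coordinates ({start}, {end}) outside [1, {n}]")
    if start <= end:
        return replicon.sequence[start - 1 : end]
    if replicon.topology != "circular":
        raise ValueError(
            f"wrap-around region ({start}, {end}) requested on linear replicon {replicon.id}"
        )
    return replicon.sequence[start - 1 :] + replicon.sequence[:end]


def feature_sequence(replicon: Replicon, feature: GeneFeature) -> str:
    """Coding-strand sequence of a feature (reverse-complemented for '-')."""
    if feature.wraps_origin:
        raw = extract_region(replicon, feature.start, feature.end)
    else:
        raw = replicon.sequence[feature.start - 1 : feature.end]
    return reverse_complement(raw) if feature.strand == "-" else raw


# ---------------------------------------------------------------------------
# GenBank / FASTA / feature-table IO
# ---------------------------------------------------------------------------

_ROLE_QUALIFIER = "note"


def _feature_from_seqfeature(sf: SeqFeature, rec_len: int) -> GeneFeature:
    locus = sf.qualifiers.get("locus_tag", [""])[0]
    product = sf.qualifiers.get("product", [""])[0]
    role = None
    for note in sf.qualifiers.get(_ROLE_QUALIFIER, []):
        if note.startswith("role:"):
            role = note.split(":", 1)[1]
    strand = "-" if sf.location.strand == -1 else "+"
    wraps = False
    loc = sf.location
    if isinstance(loc, CompoundLocation) and len(loc.parts) == 2:
        p1, p2 = loc.parts
        if int(p1.end) == rec_len and int(p2.start) == 0:
            wraps = True
            start, end = int(p1.start) + 1, int(p2.end)
        else:
            start, end = int(loc.start) + 1, int(loc.end)
    else:
        start, end = int(loc.start) + 1, int(loc.end)
    feat = GeneFeature(
        locus_tag=locus,
        start=start,
        end=end,
        strand=strand,
        kind="CDS" if sf.type == "CDS" else ("gene" if sf.type == "gene" else "other"),
        product=product,
        role=role,
        wraps_origin=wraps,
    )
    if feat.kind == "CDS":
        length = feat.length(rec_len)
        if length % 3 != 0:
            feat.frame_warning = True
    return feat


def read_genbank(path: str | Path, designated_chromosome: Optional[str] = None) -> GenomeSet:
    """Parse a (possibly multi-record) GenBank flat file into a GenomeSet.

    Topology is taken from the LOCUS line.  The chromosome defaults to the
    longest replicon when not named explicitly.
    """
    path = Path(path)
    replicons = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # malformed record
        raise GenomeParseError(f"cannot parse GenBank file {path}: {exc}") from exc
    if not records:
        raise GenomeParseError(f"no GenBank records in {path}")
    for rec in records:
        seq = str(rec.seq)
        if not seq:
            raise GenomeParseError(f"record {rec.id}: missing ORIGIN sequence")
        topology = rec.annotations.get("topology", "linear")
        feats = [
            _feature_from_seqfeature(sf, len(seq))
            for sf in rec.features
            if sf.type in ("CDS", "gene")
        ]
        # keep CDS over duplicate gene records sharing a locus_tag
        seen_cds = {f.locus_tag for f in feats if f.kind == "CDS"}
        feats = [f for f in feats if f.kind == "CDS" or f.locus_tag not in seen_cds]
        try:
            replicons.append(Replicon(rec.id, seq, topology, feats))
        except GenomeParseError as exc:
            raise GenomeParseError(f"LOCUS {rec.name}: {exc}") from exc
    if designated_chromosome is None:
        designated_chromosome = max(replicons, key=lambda r: r.length).id
    return GenomeSet(replicons, designated_chromosome)


def _to_seqrecord(replicon: Replicon) -> SeqRecord:
    rec = SeqRecord(Seq(replicon.sequence), id=replicon.id, name=replicon.id[:16],
                    description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = replicon.topology
    for f in replicon.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps_origin:
            loc = CompoundLocation(
                [SimpleLocation(f.start - 1, replicon.length, strand),
                 SimpleLocation(0, f.end, strand)]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        quals = {"locus_tag": [f.locus_tag]}
        if f.product:
            quals["product"] = [f.product]
        if f.role:
            quals[_ROLE_QUALIFIER] = [f"role:{f.role}"]
        rec.features.append(SeqFeature(loc, type=f.kind if f.kind != "other" else "misc_feature",
                                       qualifiers=quals))
    return rec


def write_genbank(genome: GenomeSet | Replicon, path: str | Path) -> None:
    replicons = genome.replicons if isinstance(genome, GenomeSet) else [genome]
    SeqIO.write([_to_seqrecord(r) for r in replicons], str(path), "genbank")


def write_fasta(genome: GenomeSet | Replicon, path: str | Path) -> None:
    """Write sequences as 70-column-wrapped FASTA."""
    replicons = genome.replicons if isinstance(genome, GenomeSet) else [genome]
    with open(path, "w") as fh:
        for r in replicons:
            fh.write(f">{r.id}\n")
            for i in range(0, r.length, 70):
                fh.write(r.sequence[i : i + 70] + "\n")


def read_fasta(path: str | Path, topology: str = "circular") -> list[Replicon]:
    return [
        Replicon(rec.id, str(rec.seq), topology)
        for rec in SeqIO.parse(str(path), "fasta")
    ]


FEATURE_TABLE_COLUMNS = ["locus_tag", "replicon", "start", "end", "strand", "kind",
                         "product", "role"]


def write_feature_table(genome: GenomeSet | Replicon, path: str | Path) -> None:
    replicons = genome.replicons if isinstance(genome, GenomeSet) else [genome]
    with open(path, "w") as fh:
        fh.write("\t".join(FEATURE_TABLE_COLUMNS) + "\n")
        for r in replicons:
            for f in r.features:
                fh.write(
                    "\t".join(
                        [f.locus_tag, r.id, str(f.start), str(f.end), f.strand,
                         f.kind, f.product, f.role or ""]
                    )
                    + "\n"
                )


def read_feature_table(path: str | Path) -> dict[str, list[GeneFeature]]:
    """Read the TSV fallback; returns features grouped by replicon id."""
    import csv

    grouped: dict[str, list[GeneFeature]] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(FEATURE_TABLE_COLUMNS[:6]) - set(reader.fieldnames or [])
        if missing:
            raise GenomeParseError(f"feature table missing columns {sorted(missing)}")
        for row in reader:
            start, end = int(row["start"]), int(row["end"])
            grouped.setdefault(row["replicon"], []).append(
                GeneFeature(
                    locus_tag=row["locus_tag"],
                    start=start,
                    end=end,
                    strand=row["strand"],
                    kind=row["kind"],
                    product=row.get("product", "") or "",
                    role=row.get("role") or None,
                    wraps_origin=start > end,
                )
            )
    return grouped


def load_genome(sequence_path: str | Path,
                feature_table: Optional[str | Path] = None,
                designated_chromosome: Optional[str] = None) -> GenomeSet:
    """Load from GenBank, or from FASTA + feature-table TSV."""
    sequence_path = Path(sequence_path)
    if feature_table is None:
        return read_genbank(sequence_path, designated_chromosome)
    replicons = read_fasta(sequence_path)
    feats = read_feature_table(feature_table)
    replicons = [replace(r, features=feats.get(r.id, [])) for r in replicons]
    if designated_chromosome is None:
        designated_chromosome = max(replicons, key=lambda r: r.length).id
    return GenomeSet(replicons, designated_chromosome)
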