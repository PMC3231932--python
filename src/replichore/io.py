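"""Sequence and annotation input/output.

All coordinates are 1-based inclusive (GenBank convention). Features that
span the circular junction keep ``start <= end`` by letting ``end`` exceed
the sequence length; :meth:`FeatureAnnotation.segments` splits them into
junction-free pieces for interval arithmetic. Track export (bedGraph)
converts to 0-based half-open on the way out.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "CircularSequence",
    "FeatureAnnotation",
    "AnnotationSet",
    "FormatError",
    "ValidationError",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_gff3",
    "write_track",
]

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
FEATURE_TYPES = ("CDS", "rRNA", "tRNA", "pseudogene", "other")
RRNA_SUBUNITS = ("16S", "23S", "5S", "none")

_RRNA_PRODUCT_RE = re.compile(r"\b(16S|23S|5S)\b", re.IGNORECASE)


class FormatError(ValueError):
    """Malformed input file (syntax, alphabet, duplicate identifiers)."""


class ValidationError(ValueError):
    """Structurally valid file with semantically inconsistent content."""


@dataclass
class CircularSequence:
    """A nucleotide sequence with explicit topology.

    ``residues`` are upper-cased on construction and restricted to the
    IUPAC DNA alphabet. Ambiguity codes other than N are kept verbatim but
    treated as unknown by all composition statistics downstream.
    """

    id: str
    residues: str
    topology: Literal["circular", "linear"] = "circular"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        self.residues = self.residues.upper()
        bad = set(self.residues) - IUPAC_DNA
        if bad:
            raise FormatError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        if self.topology not in ("circular", "linear"):
            raise ValidationError(f"unknown topology {self.topology!r}")

    @property
    def length(self) -> int:
        return len(self.residues)

    def fetch(self, start: int, end: int) -> str:
        """Residues of the 1-based inclusive interval [start, end].

        ``end`` may exceed the sequence length on a circular sequence, in
        which case the slice wraps through the junction.
        """
        L = self.length
        if not (1 <= start <= L):
            raise ValueError(f"start {start} outside [1, {L}]")
        if end < start:
            raise ValueError("end < start is not a valid interval")
        if end <= L:
            return self.residues[start - 1 : end]
        if self.topology != "circular":
            raise ValueError("interval exceeds length of linear sequence")
        if end - start + 1 > L:
            raise ValueError("interval longer than the sequence")
        return self.residues[start - 1 :] + self.residues[: end - L]


@dataclass
class FeatureAnnotation:
    """A typed genomic feature with 1-based inclusive coordinates.

    For features spanning the circular junction, ``wraps`` is set and
    ``end`` exceeds the sequence length (``end - start + 1`` is always the
    feature length); ``end < start`` is never used.
    """

    feature_type: str
    start: int
    end: int
    strand: Optional[str] = None
    locus_tag: str = ""
    gene: str = ""
    product: str = ""
    rrna_subunit: str = "none"
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.feature_type not in FEATURE_TYPES:
            raise ValidationError(f"unknown feature type {self.feature_type!r}")
        if self.start < 1:
            raise ValidationError(f"start {self.start} < 1")
        if self.end < self.start:
            raise ValidationError("end < start representation is forbidden")
        if self.strand is not None and self.strand not in "+-":
            raise ValidationError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.feature_type in ("CDS", "rRNA", "tRNA") and self.strand is None:
            raise ValidationError(f"{self.feature_type} feature requires a strand")
        if self.rrna_subunit not in RRNA_SUBUNITS:
            raise ValidationError(f"unknown rRNA subunit {self.rrna_subunit!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def segments(self, seq_length: int) -> list[tuple[int, int]]:
        """Junction-free 1-based inclusive intervals covering the feature."""
        if not self.wraps and self.end <= seq_length:
            return [(self.start, self.end)]
        if self.end - seq_length > seq_length:
            raise ValidationError("feature longer than the sequence")
        return [(self.start, seq_length), (1, self.end - seq_length)]

    def validate(self, seq_length: int) -> None:
        if self.wraps:
            if self.end <= seq_length:
                raise ValidationError(
                    f"feature {self.locus_tag!r} flagged wrapped but lies within "
                    "the sequence"
                )
        elif self.end > seq_length:
            raise ValidationError(
                f"feature {self.locus_tag!r} end {self.end} exceeds sequence "
                f"length {seq_length} without wrap flag"
            )


@dataclass
class AnnotationSet:
    """Features of one sequence, kept sorted by start coordinate."""

    sequence_id: str
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def __iter__(self) -> Iterator[FeatureAnnotation]:
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def of_type(self, *types: str) -> list[FeatureAnnotation]:
        return [f for f in self.features if f.feature_type in types]

    def find_gene(self, name: str, product_pattern: str | None = None):
        """First feature whose gene name matches, or whose product matches
        ``product_pattern`` (case-insensitive substring)."""
        name_l = name.lower()
        for f in self.features:
            if f.gene.lower() == name_l:
                return f
        if product_pattern:
            pat = product_pattern.lower()
            for f in self.features:
                if pat in f.product.lower():
                    return f
        return None

    def validate(self, seq: CircularSequence) -> None:
        if self.sequence_id != seq.id:
            raise ValidationError(
                f"annotation set for {self.sequence_id!r} does not match "
                f"sequence {seq.id!r}"
            )
        for f in self.features:
            f.validate(seq.length)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(
    path: str | Path, topology: Literal["circular", "linear"] = "circular"
) -> list[CircularSequence]:
    """Read a (multi-)FASTA file into :class:`CircularSequence` records.

    Topology defaults to circular; pass ``topology="linear"`` for fragments.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    out: list[CircularSequence] = []
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out.append(CircularSequence(rec.id, str(rec.seq), topology))
    return out


def write_fasta(
    seqs: Sequence[CircularSequence] | CircularSequence,
    path: str | Path,
    width: int = 70,
) -> Path:
    if isinstance(seqs, CircularSequence):
        seqs = [seqs]
    path = Path(path)
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, s.length, width):
                fh.write(s.residues[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# Annotations (GenBank flat file, GFF3)


def _classify(ftype: str, pseudo: bool) -> str | None:
    if ftype in ("CDS", "gene") and pseudo:
        return "pseudogene"
    if ftype == "pseudogene" or ftype == "pseudogenic_transcript":
        return "pseudogene"
    if ftype in ("CDS", "rRNA", "tRNA"):
        return ftype
    return None


def _rrna_subunit(product: str) -> str:
    m = _RRNA_PRODUCT_RE.search(product)
    return m.group(1).upper() if m else "none"


def _read_genbank(path: Path) -> AnnotationSet:
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise FormatError(f"{path}: no GenBank records")
    rec = records[0]
    feats: list[FeatureAnnotation] = []
    seqlen = len(rec.seq)
    for f in rec.features:
        pseudo = "pseudo" in f.qualifiers or "pseudogene" in f.qualifiers
        kind = _classify(f.type, pseudo)
        if kind is None:
            continue
        quals = f.qualifiers
        product = quals.get("product", [""])[0]
        parts = f.location.parts
        if len(parts) > 1 and int(parts[0].end) == seqlen and int(parts[-1].start) == 0:
            # compound location joined across the origin
            start = int(parts[0].start) + 1
            end = seqlen + int(parts[-1].end)
            wraps = True
        else:
            start = int(f.location.start) + 1
            end = int(f.location.end)
            wraps = False
        feats.append(
            FeatureAnnotation(
                feature_type=kind,
                start=start,
                end=end,
                strand="+" if f.location.strand != -1 else "-",
                locus_tag=quals.get("locus_tag", [""])[0],
                gene=quals.get("gene", [""])[0],
                product=product,
                rrna_subunit=_rrna_subunit(product) if kind == "rRNA" else "none",
                wraps=wraps,
            )
        )
    ann = AnnotationSet(rec.id, feats)
    for f in ann.features:
        f.validate(seqlen)
    return ann


def _read_gff3(path: Path) -> AnnotationSet:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    region_len: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) >= 4:
                    region_len[parts[1]] = int(parts[3])
            elif not line.startswith("#"):
                break
    feats: list[FeatureAnnotation] = []
    seq_id: str | None = None
    for f in db.all_features():
        pseudo = "true" in [v.lower() for v in f.attributes.get("pseudo", [])]
        kind = _classify(f.featuretype, pseudo)
        if kind is None:
            continue
        seq_id = seq_id or f.seqid
        product = (f.attributes.get("product") or [""])[0]
        L = region_len.get(f.seqid)
        wraps = bool(L and f.end > L)
        if L and not wraps and f.end > L:
            raise ValidationError(
                f"{path}: feature at {f.start}..{f.end} outside sequence of "
                f"length {L}"
            )
        feats.append(
            FeatureAnnotation(
                feature_type=kind,
                start=f.start,
                end=f.end,
                strand=f.strand if f.strand in "+-" else None,
                locus_tag=(f.attributes.get("locus_tag") or f.attributes.get("ID") or [""])[0],
                gene=(f.attributes.get("gene") or f.attributes.get("Name") or [""])[0],
                product=product,
                rrna_subunit=_rrna_subunit(product) if kind == "rRNA" else "none",
                wraps=wraps,
            )
        )
    if seq_id is None:
        seq_id = next(iter(region_len), "unknown")
    ann = AnnotationSet(seq_id, feats)
    if seq_id in region_len:
        for f in ann.features:
            f.validate(region_len[seq_id])
    return ann


def read_annotations(path: str | Path, format: str) -> AnnotationSet:
    """Read CDS/rRNA/tRNA/pseudogene features from GenBank or GFF3.

    GenBank ``/pseudo`` qualifiers and the GFF3 ``pseudogene`` type both map
    to the ``pseudogene`` feature type; rRNA product text is parsed into
    16S/23S/5S subunit labels.
    """
    path = Path(path)
    if format == "genbank":
        return _read_genbank(path)
    if format == "gff3":
        return _read_gff3(path)
    raise FormatError(f"unknown annotation format {format!r}")


def write_gff3(
    ann: AnnotationSet, seq_length: int, path: str | Path
) -> Path:
    """Emit an AnnotationSet as GFF3. Wrapped features keep end > length
    (circular-genome convention), declared via ``Is_circular``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {ann.sequence_id} 1 {seq_length}\n")
        for i, f in enumerate(ann.features):
            attrs = [f"ID={f.locus_tag or f'feat{i}'}"]
            if f.gene:
                attrs.append(f"gene={f.gene}")
            if f.product:
                attrs.append(f"product={f.product}")
            fh.write(
                "\t".join(
                    [
                        ann.sequence_id,
                        "replichore",
                        f.feature_type,
                        str(f.start),
                        str(f.end),
                        ".",
                        f.strand or ".",
                        "0" if f.feature_type == "CDS" else ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
    return path


# ---------------------------------------------------------------------------
# Track export


def write_track(profile, path: str | Path, format: str = "bedgraph") -> Path:
    """Write a windowed profile as a bedGraph or wiggle track.

    One interval per window, carrying the window's skew value. bedGraph
    intervals are 0-based half-open; each covers one step starting at the
    window center.
    """
    import numpy as np

    path = Path(path)
    centers = np.asarray(profile.centers)
    values = np.asarray(profile.skew)
    if centers.size == 0:
        raise ValidationError("empty profile")
    L = profile.length
    step = profile.step
    with open(path, "w") as fh:
        if format == "bedgraph":
            for c, v in zip(centers, values):
                start0 = int(c) - 1
                end0 = min(start0 + step, L)
                fh.write(f"{profile.sequence_id}\t{start0}\t{end0}\t{v:.6f}\n")
        elif format == "wig":
            fh.write(
                f"variableStep chrom={profile.sequence_id} span={step}\n"
            )
            for c, v in zip(centers, values):
                fh.write(f"{int(c)}\t{v:.6f}\n")
        else:
            raise FormatError(f"unknown track format {format!r}")
    return path
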