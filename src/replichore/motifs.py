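"""IUPAC consensus scanning and DnaA-box reporting.

The canonical use is locating DnaA boxes (consensus TTATNCACA) around a
bacterial replication origin: counts are reported separately for the
intergenic region upstream of dnaA and for the dnaA-dnaN intergenic gap.
Both strands are scanned, overlapping matches count individually, and
minus-strand sites are reported by their forward start coordinate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional

from .io import AnnotationSet, CircularSequence, FeatureAnnotation

__all__ = [
    "MotifHit",
    "DnaABoxReport",
    "scan_iupac",
    "dnaa_box_report",
    "expected_hit_count",
    "DNAA_BOX",
]

DNAA_BOX = "TTATNCACA"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}
_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class MotifError(ValueError):
    pass


@dataclass(frozen=True)
class MotifHit:
    position: int          # 1-based forward-coordinate start of the site
    strand: str            # '+' or '-'
    matched: str           # site sequence read on the reported strand
    consensus: str


@dataclass
class DnaABoxReport:
    upstream_count: int
    intergenic_count: int
    upstream_region: tuple[int, int]
    intergenic_region: Optional[tuple[int, int]]
    upstream_hits: list[MotifHit]
    intergenic_hits: list[MotifHit]
    consensus: str = DNAA_BOX


def reverse_complement(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


def iupac_regex(consensus: str) -> str:
    parts = []
    for ch in consensus.upper():
        try:
            exp = IUPAC[ch]
        except KeyError:
            raise MotifError(f"invalid IUPAC character {ch!r} in consensus")
        parts.append(ch if len(exp) == 1 else f"[{exp}]")
    return "".join(parts)


def expected_hit_count(consensus: str, length: int, strands: str = "both") -> float:
    """Expected number of hits on i.i.d. uniform sequence of given length,
    ignoring edge effects: length * prod(|expansion|/4) per strand."""
    p = 1.0
    for ch in consensus.upper():
        p *= len(IUPAC[ch]) / 4.0
    return length * p * (2 if strands == "both" else 1)


def _scan_text(text: str, pattern: str) -> list[int]:
    """0-based start offsets of all (overlapping) matches."""
    rx = re.compile(f"(?=({pattern}))")
    return [m.start() for m in rx.finditer(text)]


def scan_iupac(
    seq: CircularSequence,
    consensus: str,
    region: Optional[tuple[int, int]] = None,
    strands: str = "both",
) -> list[MotifHit]:
    """All exact IUPAC matches of ``consensus`` in the sequence (or the
    1-based inclusive ``region``, which may wrap on a circular sequence).

    Minus-strand sites are found by matching the reverse complement of the
    consensus against the forward sequence; their ``position`` is the
    forward start and ``matched`` is the site read 5'->3' on the minus
    strand (hence consistent with the consensus).
    """
    if not consensus:
        raise MotifError("empty consensus")
    consensus = consensus.upper()
    k = len(consensus)
    L = seq.length
    if region is None:
        if seq.topology == "circular" and L >= k:
            text = seq.residues + seq.residues[: k - 1]
        else:
            text = seq.residues
        origin = 1
        limit = L
    else:
        a, b = region
        text = seq.fetch(a, b)
        origin = a
        limit = None

    hits: list[MotifHit] = []
    if strands in ("both", "+"):
        for off in _scan_text(text, iupac_regex(consensus)):
            pos = (origin - 1 + off) % L + 1
            if limit is not None and off >= limit:
                continue
            hits.append(MotifHit(pos, "+", text[off : off + k], consensus))
    if strands in ("both", "-"):
        rc_pattern = iupac_regex(reverse_complement(consensus))
        for off in _scan_text(text, rc_pattern):
            pos = (origin - 1 + off) % L + 1
            if limit is not None and off >= limit:
                continue
            hits.append(
                MotifHit(pos, "-", reverse_complement(text[off : off + k]), consensus)
            )
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def _circular_gap_before(
    target: FeatureAnnotation, features: list[FeatureAnnotation], L: int
) -> int:
    """End position of the annotated feature closest upstream (in forward
    coordinates, circularly) of ``target.start``."""
    best_gap = None
    best_end = None
    for f in features:
        if f is target:
            continue
        end = (f.end - 1) % L + 1  # wrap-aware effective end
        gap = (target.start - 1 - end) % L
        if best_gap is None or gap < best_gap:
            best_gap, best_end = gap, end
    if best_end is None:
        return (target.start - 2) % L + 1  # no other features: whole circle
    return best_end


def dnaa_box_report(
    seq: CircularSequence,
    annotations: AnnotationSet,
    consensus: str = DNAA_BOX,
    upstream_cap: int = 1000,
) -> DnaABoxReport:
    """Count consensus hits (both strands) upstream of dnaA and in the
    dnaA-dnaN intergenic region.

    The upstream region runs from the end of the previous annotated feature
    to the base before dnaA's 5' end, capped at ``upstream_cap`` bases
    (strand-aware). The intergenic region is strictly between dnaA and
    dnaN; overlapping matches are counted individually.
    """
    from .skew import DNAA_PRODUCT_PATTERN

    L = seq.length
    dnaA = annotations.find_gene("dnaA", DNAA_PRODUCT_PATTERN)
    if dnaA is None:
        raise ValueError("annotation has no dnaA gene")
    dnaN = annotations.find_gene("dnaN", "DNA polymerase III, beta")
    if dnaN is None:
        raise ValueError("annotation has no dnaN gene")

    if dnaA.strand != "-":
        prev_end = _circular_gap_before(dnaA, annotations.features, L)
        gap = (dnaA.start - 1 - prev_end) % L
        gap = min(gap, upstream_cap)
        if gap > 0:
            up_start = (dnaA.start - 1 - gap) % L + 1
            up_end = up_start + gap - 1
            upstream_region = (up_start, up_end)
        else:
            upstream_region = None
    else:
        # dnaA on the minus strand: upstream lies after its right end
        nxt = min(
            (f for f in annotations.features if f is not dnaA),
            key=lambda f: (f.start - dnaA.end - 1) % L,
            default=None,
        )
        gap = (nxt.start - dnaA.end - 1) % L if nxt is not None else L - dnaA.length
        gap = min(gap, upstream_cap)
        upstream_region = (
            ((dnaA.end) % L + 1, (dnaA.end) % L + gap) if gap > 0 else None
        )

    if dnaA.end < dnaN.start:
        lo, hi = dnaA.end + 1, dnaN.start - 1
    else:
        lo, hi = dnaN.end + 1, dnaA.start - 1
    intergenic_region = (lo, hi) if hi >= lo else None

    def count(region: Optional[tuple[int, int]]) -> list[MotifHit]:
        if region is None or region[1] - region[0] + 1 < len(consensus):
            return []
        return scan_iupac(seq, consensus, region=region, strands="both")

    up_hits = count(upstream_region)
    ig_hits = count(intergenic_region)
    return DnaABoxReport(
        upstream_count=len(up_hits),
        intergenic_count=len(ig_hits),
        upstream_region=upstream_region or (dnaA.start, dnaA.start),
        intergenic_region=intergenic_region,
        upstream_hits=up_hits,
        intergenic_hits=ig_hits,
        consensus=consensus,
    )
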