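"""Codon usage bias against a highly-expressed reference set.

Implements the classical reference-set adaptation index: relative
adaptiveness w of each codon is its pooled count in the reference genes
divided by the count of the commonest synonymous codon, and a gene's score
is the geometric mean of w over its codons (stop codons and the
single-codon amino acids Met/Trp excluded). Ribosomal-protein genes are
the default reference set. RSCU vectors are provided for inspection.

The bacterial genetic code (translation table 11) defines synonymous
families and stop codons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "CodonCountTable",
    "AdaptivenessTable",
    "codon_counts",
    "relative_adaptiveness",
    "adaptation_index",
    "rscu",
    "rank_optimized",
    "SYNONYMOUS_FAMILIES",
    "STOP_CODONS",
]

_TABLE = CodonTable.unambiguous_dna_by_id[11]
STOP_CODONS = frozenset(_TABLE.stop_codons)
ALL_CODONS = tuple(
    a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"
)

#: amino acid -> tuple of synonymous codons (stops kept under '*')
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon in ALL_CODONS:
    _aa = "*" if _codon in STOP_CODONS else _TABLE.forward_table[_codon]
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

CODON_TO_AA = {
    c: aa for aa, codons in SYNONYMOUS_FAMILIES.items() for c in codons
}

#: codons skipped by the adaptation index: stops plus the single-codon
#: amino acids (ATG/Met, TGG/Trp carry no synonymous choice)
EXCLUDED_CODONS = STOP_CODONS | {"ATG", "TGG"}

DEFAULT_FLOOR = 0.01


@dataclass
class CodonCountTable:
    gene_id: str
    counts: dict[str, int]
    valid: bool
    invalid_reason: str = ""

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class AdaptivenessTable:
    w: dict[str, float]
    reference_ids: list[str]
    floor: float = DEFAULT_FLOOR


def codon_counts(cds: str, gene_id: str) -> CodonCountTable:
    """In-frame codon counts of a coding sequence.

    A gene is flagged invalid (and excluded from ranking) if its length is
    not a multiple of 3, it contains ambiguous bases, or it has an
    in-frame stop before the final codon.
    """
    cds = cds.upper()
    counts: dict[str, int] = {}
    reason = ""
    if len(cds) == 0 or len(cds) % 3 != 0:
        reason = "length not a multiple of 3"
    codons = [cds[i : i + 3] for i in range(0, len(cds) - len(cds) % 3, 3)]
    for i, codon in enumerate(codons):
        if codon not in CODON_TO_AA:
            reason = reason or f"ambiguous codon {codon!r}"
            continue
        if codon in STOP_CODONS and i < len(codons) - 1 and not reason:
            reason = "internal stop codon"
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(gene_id, counts, valid=not reason, invalid_reason=reason)


def relative_adaptiveness(
    reference: Sequence[CodonCountTable], floor: float = DEFAULT_FLOOR
) -> AdaptivenessTable:
    """Relative adaptiveness w from pooled reference-set codon counts.

    For every amino acid, w(codon) = pooled count / max pooled count among
    its synonymous codons; codons absent from the reference receive a
    small floor value. Stop codons are excluded.
    """
    reference = [r for r in reference]
    if not reference:
        raise ValueError("empty reference set")
    pooled: dict[str, int] = {c: 0 for c in ALL_CODONS}
    for table in reference:
        for codon, n in table.counts.items():
            pooled[codon] += n
    w: dict[str, float] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        if aa == "*":
            continue
        family_max = max(pooled[c] for c in codons)
        if family_max == 0:
            raise ValueError(
                f"reference set has no codon for amino acid {aa!r}"
            )
        for c in codons:
            w[c] = pooled[c] / family_max if pooled[c] > 0 else floor
    return AdaptivenessTable(
        w=w, reference_ids=[t.gene_id for t in reference], floor=floor
    )


def adaptation_index(gene: CodonCountTable, w: AdaptivenessTable) -> float:
    """Geometric mean of w over a gene's codons, excluding stop codons and
    the single-codon amino acids (ATG, TGG). 1.0 iff the gene uses only
    major codons."""
    if not gene.valid:
        raise ValueError(f"gene {gene.gene_id!r} is invalid: {gene.invalid_reason}")
    log_sum = 0.0
    n = 0
    for codon, count in gene.counts.items():
        if codon in EXCLUDED_CODONS:
            continue
        log_sum += count * math.log(w.w[codon])
        n += count
    if n == 0:
        raise ValueError(f"gene {gene.gene_id!r} has no countable codons")
    return math.exp(log_sum / n)


def rscu(gene: CodonCountTable) -> dict[str, float]:
    """Relative synonymous codon usage: observed count divided by the
    expected count under uniform synonymous usage. Codons of unobserved
    amino acids get 0."""
    out: dict[str, float] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        if aa == "*":
            continue
        family_total = sum(gene.counts.get(c, 0) for c in codons)
        for c in codons:
            if family_total == 0:
                out[c] = 0.0
            else:
                out[c] = gene.counts.get(c, 0) * len(codons) / family_total
    return out


@dataclass
class RankedGenes:
    table: pd.DataFrame           # all valid genes, ranked
    top: pd.DataFrame             # the top_k slice
    category_counts: dict[str, int]
    warning: str = ""


def rank_optimized(
    genes: Iterable[CodonCountTable],
    w: AdaptivenessTable,
    top_k: int = 80,
    categories: Optional[Mapping[str, str]] = None,
) -> RankedGenes:
    """Rank genes by adaptation index (descending; ties by gene_id) and
    count category labels among the top ``top_k``."""
    rows = []
    for g in genes:
        if not g.valid:
            continue
        rows.append(
            {
                "gene_id": g.gene_id,
                "score": adaptation_index(g, w),
                "category": (categories or {}).get(g.gene_id, ""),
            }
        )
    warning = ""
    if len(rows) < top_k:
        warning = f"only {len(rows)} valid genes for top_k={top_k}"
    df = pd.DataFrame(rows, columns=["gene_id", "score", "category"])
    df = df.sort_values(
        ["score", "gene_id"], ascending=[False, True]
    ).reset_index(drop=True)
    df.insert(0, "rank", range(1, len(df) + 1))
    top = df.head(top_k).copy()
    counts = (
        top[top["category"] != ""]["category"].value_counts().to_dict()
        if not top.empty
        else {}
    )
    return RankedGenes(table=df, top=top, category_counts=counts, warning=warning)
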