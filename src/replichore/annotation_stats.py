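"""Whole-genome feature statistics (genome-table style).

Computes the standard summary block for a bacterial genome: size, GC%,
ORF count and mean length, coding density, tRNA count, rRNA operon count,
pseudogene count. Coding density is reported twice: as the fraction of
bases covered by the union of CDS intervals (circular-aware), and as the
summed-CDS-length variant, since published tables use either definition.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import AnnotationSet, CircularSequence, ValidationError
from .stable_rna import DEFAULT_OPERON_GAP, group_rrna_operons

__all__ = ["GenomeStats", "genome_stats", "compare_table", "TABLE_ROWS"]

TABLE_ROWS = [
    "size_bp",
    "gc_percent",
    "orf_count",
    "pseudogene_count",
    "coding_density_union",
    "coding_density_summed",
    "mean_orf_length",
    "trna_count",
    "rrna_operon_count",
]


@dataclass
class GenomeStats:
    genome_id: str
    size_bp: int
    gc_percent: float             # percent over unambiguous bases
    orf_count: int
    pseudogene_count: int
    coding_density_union: float   # percent of bases covered by >=1 CDS
    coding_density_summed: float  # percent, sum of CDS lengths / size
    mean_orf_length: float
    trna_count: int
    rrna_operon_count: int


def _coverage(features, L: int) -> int:
    """Bases covered by the union of the features' intervals (wrap-aware)."""
    covered = np.zeros(L, dtype=bool)
    for f in features:
        for s, e in f.segments(L):
            covered[s - 1 : e] = True
    return int(covered.sum())


def genome_stats(
    seq: CircularSequence,
    annotations: AnnotationSet,
    include_pseudogenes: bool = False,
    operon_gap: int = DEFAULT_OPERON_GAP,
) -> GenomeStats:
    """Summary statistics for one genome.

    ``include_pseudogenes`` controls whether pseudogenes enter the ORF
    count and mean ORF length (off by default; they are always counted
    separately).
    """
    annotations.validate(seq)
    L = seq.length
    res = seq.residues
    gc = res.count("G") + res.count("C")
    acgt = gc + res.count("A") + res.count("T")
    gc_percent = 100.0 * gc / acgt if acgt else 0.0

    cds = annotations.of_type("CDS")
    pseudo = annotations.of_type("pseudogene")
    orfs = cds + pseudo if include_pseudogenes else cds
    coding_feats = cds + pseudo  # pseudogene bodies still occupy sequence

    union_cov = _coverage(coding_feats, L)
    summed = sum(f.length for f in coding_feats)
    operons = group_rrna_operons(annotations, L, max_gap=operon_gap)

    return GenomeStats(
        genome_id=seq.id,
        size_bp=L,
        gc_percent=gc_percent,
        orf_count=len(orfs),
        pseudogene_count=len(pseudo),
        coding_density_union=100.0 * union_cov / L,
        coding_density_summed=100.0 * summed / L,
        mean_orf_length=(
            sum(f.length for f in orfs) / len(orfs) if orfs else 0.0
        ),
        trna_count=len(annotations.of_type("tRNA")),
        rrna_operon_count=len(operons),
    )


def compare_table(
    stats: Sequence[GenomeStats], path: Optional[str | Path] = None
) -> pd.DataFrame:
    """Side-by-side table: one column per genome, fixed row order.

    Optionally written as TSV with the row names in the first column.
    """
    if not stats:
        raise ValueError("at least one GenomeStats record required")
    data = {}
    for s in stats:
        d = asdict(s)
        data[s.genome_id] = [
            round(d[row], 2) if isinstance(d[row], float) else d[row]
            for row in TABLE_ROWS
        ]
    df = pd.DataFrame(data, index=TABLE_ROWS)
    df.index.name = "feature"
    if path is not None:
        df.to_csv(path, sep="\t")
    return df
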