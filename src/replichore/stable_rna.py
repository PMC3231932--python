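"""rRNA operon grouping, stable-RNA density, and the cross-genome survey.

rRNA genes are grouped into operons by single-linkage chaining along the
circular chromosome (consecutive rRNA features closer than a gap threshold
join one operon; intergenic tRNAs do not break a chain). Density is operons
per Mbp of genome. The survey ranks genomes by that density after dropping
Candidatus / non-free-living entries, deduplicating species by their best
representative, and applying a strict density threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import AnnotationSet, FeatureAnnotation

__all__ = [
    "RrnaOperon",
    "RnaDensityRecord",
    "group_rrna_operons",
    "rrn_density",
    "survey",
    "read_survey_tsv",
    "write_survey_tsv",
]

DEFAULT_OPERON_GAP = 3000
DEFAULT_DENSITY_THRESHOLD = 2.9

SURVEY_COLUMNS = [
    "genome_id",
    "species",
    "size_bp",
    "rrna_operons",
    "trna_genes",
    "candidatus",
    "free_living",
]


@dataclass
class RrnaOperon:
    start: int
    end: int                      # may exceed sequence length if wrapped
    members: list[FeatureAnnotation]
    subunits_present: frozenset[str]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class RnaDensityRecord:
    genome_id: str
    species: str
    size_bp: int
    rrna_operons: int
    trna_genes: int
    candidatus: bool = False
    free_living: bool = True

    @property
    def size_mbp(self) -> float:
        return self.size_bp / 1_000_000

    @property
    def density(self) -> float:
        return rrn_density(self.rrna_operons, self.size_bp)


def group_rrna_operons(
    annotations: AnnotationSet,
    genome_length: int,
    max_gap: int = DEFAULT_OPERON_GAP,
) -> list[RrnaOperon]:
    """Single-linkage clustering of rRNA genes into operons.

    Consecutive rRNA features whose gap is <= ``max_gap`` join one operon;
    a chain split across the circular junction is merged into one operon.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    rrnas = sorted(annotations.of_type("rRNA"), key=lambda f: (f.start, f.end))
    if not rrnas:
        return []

    clusters: list[list[FeatureAnnotation]] = [[rrnas[0]]]
    for f in rrnas[1:]:
        prev_end = max(m.end for m in clusters[-1])
        gap = f.start - prev_end - 1
        if gap <= max_gap:
            clusters[-1].append(f)
        else:
            clusters.append([f])

    # merge across the circular junction; the merged span is expressed with
    # end > genome_length so start <= end still holds
    wrapped: RrnaOperon | None = None
    if len(clusters) > 1:
        first, last = clusters[0], clusters[-1]
        # member ends may exceed genome_length (wrapped features); working on
        # the linear extension keeps the gap arithmetic uniform
        last_end = max(m.end for m in last)
        wrap_gap = min(m.start for m in first) + genome_length - last_end - 1
        if wrap_gap <= max_gap:
            members = last + first
            wrapped = RrnaOperon(
                start=min(m.start for m in last),
                end=genome_length + max(m.end for m in first),
                members=members,
                subunits_present=frozenset(
                    m.rrna_subunit for m in members if m.rrna_subunit != "none"
                ),
            )
            clusters = clusters[1:-1]

    out = []
    for members in clusters:
        out.append(
            RrnaOperon(
                start=min(m.start for m in members),
                end=max(m.end for m in members),
                members=members,
                subunits_present=frozenset(
                    m.rrna_subunit for m in members if m.rrna_subunit != "none"
                ),
            )
        )
    if wrapped is not None:
        out.append(wrapped)
    out.sort(key=lambda o: o.start)
    return out


def rrn_density(operon_count: int, genome_size: int) -> float:
    """rRNA operons per Mbp of genome (full precision; round for reports)."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if operon_count < 0:
        raise ValueError("operon count must be >= 0")
    return operon_count / (genome_size / 1_000_000)


def _to_frame(records: Iterable[RnaDensityRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        rows = list(records)
        df = pd.DataFrame(
            [
                {
                    "genome_id": r.genome_id,
                    "species": r.species,
                    "size_bp": r.size_bp,
                    "rrna_operons": r.rrna_operons,
                    "trna_genes": r.trna_genes,
                    "candidatus": r.candidatus,
                    "free_living": r.free_living,
                }
                for r in rows
            ],
            columns=SURVEY_COLUMNS,
        )
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survey input missing columns {sorted(missing)}")
    df["candidatus"] = df["candidatus"].astype(bool)
    df["free_living"] = df["free_living"].astype(bool)
    df["density"] = df["rrna_operons"] / (df["size_bp"] / 1_000_000)
    return df


@dataclass
class SurveyTable:
    ranked: pd.DataFrame          # all survivors, ranked
    top: pd.DataFrame             # the top_k slice
    threshold: float
    n_input: int
    n_excluded_lifestyle: int
    n_deduplicated: int


def survey(
    records: Iterable[RnaDensityRecord] | pd.DataFrame,
    threshold: float = DEFAULT_DENSITY_THRESHOLD,
    top_k: int = 20,
) -> SurveyTable:
    """Rank genomes by rRNA operon density under the survey rules:

    1. drop Candidatus and non-free-living genomes;
    2. keep only the highest-density genome per species;
    3. keep densities strictly above ``threshold``;
    4. sort descending by density, ties broken by genome_id.
    """
    df = _to_frame(records)
    if df.empty:
        raise ValueError("survey requires at least one record")
    n_input = len(df)
    kept = df[(~df["candidatus"]) & (df["free_living"])]
    n_lifestyle = n_input - len(kept)
    kept = kept.sort_values(
        ["species", "density", "genome_id"], ascending=[True, False, True]
    ).drop_duplicates("species", keep="first")
    n_dedup = n_input - n_lifestyle - len(kept)
    kept = kept[kept["density"] > threshold]
    ranked = kept.sort_values(
        ["density", "genome_id"], ascending=[False, True]
    ).reset_index(drop=True)
    ranked.insert(0, "rank", range(1, len(ranked) + 1))
    return SurveyTable(
        ranked=ranked,
        top=ranked.head(top_k).copy(),
        threshold=threshold,
        n_input=n_input,
        n_excluded_lifestyle=n_lifestyle,
        n_deduplicated=n_dedup,
    )


def example_survey() -> pd.DataFrame:
    """The packaged 12-genome metadata example for the density survey.

    Genome sizes and stable-RNA counts follow public annotations of the
    listed accessions; it contains duplicate-species rows and Candidatus
    endosymbionts so every survey rule is exercised.
    """
    from importlib import resources

    with resources.files("replichore").joinpath(
        "data/rrn_survey_example.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")


def read_survey_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing survey columns {sorted(missing)}")
    return df


def write_survey_tsv(table: SurveyTable, path: str | Path) -> Path:
    path = Path(path)
    out = table.ranked.copy()
    out["density"] = out["density"].round(2)
    out.to_csv(path, sep="\t", index=False)
    return path
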