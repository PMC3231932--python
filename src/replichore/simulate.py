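"""Synthetic bacterial genomes and 16S alignments with known ground truth.

The genome generator emulates the architecture of a small circular
lactic-acid-bacterium chromosome: two equal replichores whose background
composition carries opposite G/C strand bias switching at oriC and the
terminus; dnaA and dnaN at the origin with DnaA boxes planted upstream of
dnaA and in the dnaA-dnaN gap; 16S-23S-5S rRNA operons with sub-threshold
internal gaps; tRNA genes; non-overlapping CDSs preferentially coded on
the leading strand whose codons are drawn from an expression-weighted
major-codon mixture; and a fraction of CDSs turned into pseudogenes by a
single-base frameshift.

Strand bias model: on the leading strand the background base probabilities
are  P(G) = gc/2 + skew_delta  and  P(C) = gc/2 - skew_delta, so the
leading-strand G-C frequency difference is 2*skew_delta. Coding sequences
carry the same mutational bias at their neutral positions: wherever the
third codon base has both a G- and a C-ending synonym, the G variant is
chosen with probability 0.5 + skew_delta when the coding strand is the
leading strand (0.5 - skew_delta otherwise). This mirrors real genomes,
where GC skew is strongest at intergenic and synonymous sites.

All randomness flows from the single mandatory spec seed: identical specs
give byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .codon_usage import STOP_CODONS, SYNONYMOUS_FAMILIES
from .io import (
    AnnotationSet,
    CircularSequence,
    FeatureAnnotation,
    write_fasta,
    write_gff3,
)
from .motifs import DNAA_BOX, reverse_complement, scan_iupac
from .phylogeny import Alignment, PhyloTree, TreeNode

__all__ = [
    "SyntheticGenomeSpec",
    "GenomeTruth",
    "AlignmentTruth",
    "simulate_genome",
    "simulate_alignment",
    "sanfranciscensis_like",
    "MAJOR_CODONS",
]

_COMP = str.maketrans("ACGT", "TGCA")

# sizes of the planted replication/stable-RNA features (bases)
DNAA_LEN = 1350
DNAN_LEN = 1100
UPSTREAM_LEN = 300
DNAA_DNAN_GAP = 200
RRNA_16S, RRNA_23S, RRNA_5S = 1550, 2900, 115
OPERON_INTERNAL_GAP = 150
TRNA_LEN = 75

#: major codon per amino acid: the A/T-ending synonym (alphabetically first
#: on ties), the pattern typical of low-GC firmicutes
MAJOR_CODONS: dict[str, str] = {}
for _aa, _codons in SYNONYMOUS_FAMILIES.items():
    if _aa == "*":
        continue
    MAJOR_CODONS[_aa] = sorted(
        _codons, key=lambda c: (c[2] not in "AT", c)
    )[0]

_AMINO_ACIDS = sorted(a for a in SYNONYMOUS_FAMILIES if a != "*")

#: codon -> (G-ending variant, C-ending variant) where both are synonymous
_WOBBLE_GC: dict[str, tuple[str, str]] = {}
for _aa, _codons in SYNONYMOUS_FAMILIES.items():
    if _aa == "*":
        continue
    by_prefix: dict[str, set[str]] = {}
    for c in _codons:
        by_prefix.setdefault(c[:2], set()).add(c[2])
    for prefix, thirds in by_prefix.items():
        if {"G", "C"} <= thirds:
            for t in thirds:
                _WOBBLE_GC[prefix + t] = (prefix + "G", prefix + "C")


@dataclass
class SyntheticGenomeSpec:
    """Parameters of one synthetic genome; ``seed`` is mandatory."""

    seed: int
    length: int = 100_000
    ori: int = 1
    gc: float = 0.35
    skew_delta: float = 0.05
    n_genes: int = 60
    mean_gene_length: int = 900
    strand_bias: float = 0.8
    n_rrna_operons: int = 2
    n_trna: int = 8
    n_dnaA_boxes_upstream: int = 5
    n_dnaA_boxes_intergenic: int = 3
    pseudogene_fraction: float = 0.1
    expression_levels: Optional[Sequence[float]] = None
    codon_bias_strength: float = 0.7
    place_replication_genes: bool = True
    sequence_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0 <= self.skew_delta < 0.5):
            raise ValueError("skew_delta must be in [0, 0.5)")
        if not (0 < self.gc < 1):
            raise ValueError("gc must be in (0, 1)")
        if self.gc / 2 + self.skew_delta >= 1 or self.gc / 2 - self.skew_delta <= 0:
            raise ValueError("gc and skew_delta are incompatible")
        for name in ("strand_bias", "pseudogene_fraction", "codon_bias_strength"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (1 <= self.ori <= self.length):
            raise ValueError("ori outside the sequence")


@dataclass
class GenomeTruth:
    ori: int
    ter: int
    gene_strands: dict[str, str]
    gene_replichores: dict[str, int]
    expression: dict[str, float]
    pseudogene_ids: list[str]
    operon_spans: list[tuple[int, int]]
    box_positions_upstream: list[int]
    box_positions_intergenic: list[int]
    upstream_box_count: int       # post-hoc rescan (chance matches absorbed)
    intergenic_box_count: int
    upstream_region: Optional[tuple[int, int]] = None
    intergenic_region: Optional[tuple[int, int]] = None


def _draw_background(spec: SyntheticGenomeSpec, rng: np.random.Generator) -> np.ndarray:
    """Background bases in ori-frame coordinates (index 0 = ori)."""
    L = spec.length
    half = L // 2
    at = (1 - spec.gc) / 2
    lead = [at, spec.gc / 2 - spec.skew_delta, spec.gc / 2 + spec.skew_delta, at]
    lag = [at, spec.gc / 2 + spec.skew_delta, spec.gc / 2 - spec.skew_delta, at]
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    out = np.empty(L, dtype=np.uint8)
    out[:half] = rng.choice(bases, size=half, p=lead)    # replichore 1: G-rich fwd
    out[half:] = rng.choice(bases, size=L - half, p=lag)
    return out


def _gene_codons(
    n_codons: int,
    mixing: float,
    leading: bool,
    skew_delta: float,
    rng: np.random.Generator,
) -> str:
    """Body codons of a gene: expression-weighted major-codon mixture with
    a wobble G/C tilt matching the background strand bias."""
    aas = rng.choice(_AMINO_ACIDS, size=n_codons)
    use_major = rng.random(n_codons) < mixing
    wobble_u = rng.random(n_codons)
    tilt = 0.5 + (skew_delta if leading else -skew_delta)
    out = []
    for aa, major, u in zip(aas, use_major, wobble_u):
        if major:
            codon = MAJOR_CODONS[aa]
        else:
            fam = SYNONYMOUS_FAMILIES[aa]
            codon = fam[rng.integers(0, len(fam))]
        gc_pair = _WOBBLE_GC.get(codon)
        if gc_pair is not None:
            codon = gc_pair[0] if u < tilt else gc_pair[1]
        out.append(codon)
    return "".join(out)


def _write_into(
    arr: np.ndarray, start: int, text: str, L: int
) -> None:
    """Write ``text`` at ori-frame position ``start`` (1-based), wrapping."""
    idx = (np.arange(len(text)) + start - 1) % L
    arr[idx] = np.frombuffer(text.encode("ascii"), dtype=np.uint8)


def simulate_genome(
    spec: SyntheticGenomeSpec, out_dir: Optional[str | Path] = None
) -> tuple[CircularSequence, AnnotationSet, GenomeTruth]:
    """Simulate one circular genome; optionally write FASTA + GFF3.

    Returns the sequence, its annotation and the ground-truth record. The
    DnaA-box truth counts are defined by rescanning the emitted sequence,
    so chance matches arising in the background are absorbed into truth.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    ori = spec.ori
    half = L // 2
    ter = (ori - 1 + half) % L + 1

    # ---- layout in ori-frame coordinates (position 1 == ori) -------------
    blocks: list[tuple[str, int, dict]] = []   # (kind, length, payload)
    if spec.place_replication_genes:
        blocks.append(("ori_module", UPSTREAM_LEN + DNAA_LEN + DNAA_DNAN_GAP + DNAN_LEN, {}))
    for k in range(spec.n_rrna_operons):
        blocks.append(
            (
                "operon",
                RRNA_16S + OPERON_INTERNAL_GAP + RRNA_23S + OPERON_INTERNAL_GAP + RRNA_5S,
                {"k": k},
            )
        )
    for k in range(spec.n_trna):
        blocks.append(("trna", TRNA_LEN, {"k": k}))
    gene_lengths = []
    for k in range(spec.n_genes):
        n_codons = max(
            50, int(round(rng.normal(spec.mean_gene_length / 3, spec.mean_gene_length / 12)))
        )
        gene_lengths.append(3 * n_codons)
        blocks.append(("gene", 3 * n_codons, {"k": k}))

    total = sum(b[1] for b in blocks)
    n_gaps = len(blocks)
    if total + n_gaps > L:
        raise ValueError(
            f"infeasible packing: {total} feature bases + gaps exceed length {L}"
        )
    if not blocks:
        # pure background genome: nothing to place
        seq = CircularSequence(
            spec.sequence_id,
            np.roll(_draw_background(spec, rng), ori - 1).tobytes().decode("ascii"),
            "circular",
        )
        truth = GenomeTruth(
            ori=ori, ter=ter, gene_strands={}, gene_replichores={},
            expression={}, pseudogene_ids=[], operon_spans=[],
            box_positions_upstream=[], box_positions_intergenic=[],
            upstream_box_count=0, intergenic_box_count=0,
        )
        ann = AnnotationSet(spec.sequence_id, [])
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_fasta(seq, out_dir / f"{spec.sequence_id}.fasta")
            write_gff3(ann, seq.length, out_dir / f"{spec.sequence_id}.gff3")
        return seq, ann, truth

    # keep the ori module first; shuffle everything else
    head = [b for b in blocks if b[0] == "ori_module"]
    tail = [b for b in blocks if b[0] != "ori_module"]
    order = rng.permutation(len(tail))
    blocks = head + [tail[i] for i in order]

    # minimum gaps: rRNA operons must stay separated by more than the
    # operon-grouping threshold so the planted operon count is recoverable
    from .stable_rna import DEFAULT_OPERON_GAP

    margin = DEFAULT_OPERON_GAP + 1
    min_gaps = np.ones(n_gaps, dtype=int)
    for i, (kind, _, _) in enumerate(blocks):
        if kind == "operon":
            min_gaps[i] = max(min_gaps[i], margin)            # after the operon
            min_gaps[i - 1] = max(min_gaps[i - 1], margin)    # before (circular)
    spare = L - total - int(min_gaps.sum())
    if spare < 0:
        raise ValueError(
            f"infeasible packing: {total} feature bases + minimum gaps exceed "
            f"length {L}"
        )
    extra = (
        rng.multinomial(spare, np.full(n_gaps, 1.0 / n_gaps))
        if spare > 0
        else np.zeros(n_gaps, dtype=int)
    )
    gaps = min_gaps + extra

    # ---- background ------------------------------------------------------
    arr = _draw_background(spec, rng)

    # expression levels
    if spec.expression_levels is not None:
        expr = np.asarray(spec.expression_levels, dtype=float)
        if len(expr) != spec.n_genes:
            raise ValueError("expression_levels length must equal n_genes")
        if np.any(expr <= 0):
            raise ValueError("expression levels must be positive")
    else:
        expr = rng.lognormal(mean=0.0, sigma=1.0, size=spec.n_genes)
    # expression -> major-codon mixing weight: saturating response with
    # half-maximal bias at the median expression level
    if spec.n_genes:
        e50 = float(np.median(expr))
        mixing_weights = spec.codon_bias_strength * expr / (expr + e50)
    else:
        mixing_weights = expr

    features: list[FeatureAnnotation] = []
    truth_boxes_up: list[int] = []
    truth_boxes_ig: list[int] = []
    operon_spans: list[tuple[int, int]] = []
    gene_strands: dict[str, str] = {}
    gene_repl: dict[str, int] = {}
    expression: dict[str, float] = {}
    up_region = ig_region = None

    def to_genome(pos: int) -> int:
        return (pos - 1 + ori - 1) % L + 1

    def add_feature(kind: str, start_of: int, length: int, **kw) -> FeatureAnnotation:
        gstart = to_genome(start_of)
        gend = gstart + length - 1
        f = FeatureAnnotation(
            feature_type=kind, start=gstart, end=gend, wraps=gend > L, **kw
        )
        features.append(f)
        return f

    def plant_boxes(region_start: int, region_len: int, n: int) -> list[int]:
        """Non-overlapping consensus instances at random offsets; returns
        genome positions of their starts."""
        k = len(DNAA_BOX)
        if n == 0:
            return []
        slack = region_len - n * k
        if slack < 0:
            raise ValueError("box region too small for requested boxes")
        cuts = np.sort(rng.integers(0, slack + 1, size=n))
        positions = []
        for idx, cut in enumerate(cuts):
            off = cut + idx * k
            box = DNAA_BOX.replace("N", "ACGT"[rng.integers(0, 4)])
            if rng.random() < 0.5:
                box = reverse_complement(box)
            pos = region_start + off
            _write_into(arr_ori, pos, box, L)
            positions.append(to_genome(pos))
        return positions

    # work on an ori-frame view for writing, rotate at the end
    arr_ori = np.roll(arr, 0)  # already ori-frame

    cursor = 1
    gene_features: list[tuple[FeatureAnnotation, int]] = []  # (feature, gene idx)
    for (kind, blen, payload), gap in zip(blocks, gaps):
        if kind == "ori_module":
            up_start = cursor
            truth_boxes_up = plant_boxes(
                up_start, UPSTREAM_LEN, spec.n_dnaA_boxes_upstream
            )
            up_region = (to_genome(up_start), to_genome(up_start + UPSTREAM_LEN - 1))
            dnaa_start = cursor + UPSTREAM_LEN
            fa = add_feature(
                "CDS",
                dnaa_start,
                DNAA_LEN,
                strand="+",
                locus_tag="SYN_dnaA",
                gene="dnaA",
                product="chromosomal replication initiator protein DnaA",
            )
            ig_start = dnaa_start + DNAA_LEN
            truth_boxes_ig = plant_boxes(
                ig_start, DNAA_DNAN_GAP, spec.n_dnaA_boxes_intergenic
            )
            ig_region = (to_genome(ig_start), to_genome(ig_start + DNAA_DNAN_GAP - 1))
            add_feature(
                "CDS",
                ig_start + DNAA_DNAN_GAP,
                DNAN_LEN,
                strand="+",
                locus_tag="SYN_dnaN",
                gene="dnaN",
                product="DNA polymerase III, beta subunit",
            )
        elif kind == "operon":
            k = payload["k"]
            s16 = cursor
            s23 = s16 + RRNA_16S + OPERON_INTERNAL_GAP
            s5 = s23 + RRNA_23S + OPERON_INTERNAL_GAP
            for sub, start_of, ln in (
                ("16S", s16, RRNA_16S),
                ("23S", s23, RRNA_23S),
                ("5S", s5, RRNA_5S),
            ):
                add_feature(
                    "rRNA",
                    start_of,
                    ln,
                    strand="+",
                    locus_tag=f"SYN_rrn{k}_{sub}",
                    product=f"{sub} ribosomal RNA",
                    rrna_subunit=sub,
                )
            operon_spans.append((to_genome(s16), to_genome(s5 + RRNA_5S - 1)))
        elif kind == "trna":
            add_feature(
                "tRNA",
                cursor,
                TRNA_LEN,
                strand="+" if rng.random() < 0.5 else "-",
                locus_tag=f"SYN_trna{payload['k']}",
                product="tRNA",
            )
        elif kind == "gene":
            k = payload["k"]
            on_rep1 = cursor <= half          # ori-frame replichore 1
            leading_strand = "+" if on_rep1 else "-"
            if rng.random() < spec.strand_bias:
                strand = leading_strand
            else:
                strand = "-" if leading_strand == "+" else "+"
            mixing = float(mixing_weights[k])
            body = _gene_codons(
                blen // 3 - 2,
                mixing,
                leading=strand == leading_strand,
                skew_delta=spec.skew_delta,
                rng=rng,
            )
            cds = "ATG" + body + "TAA"
            written = cds if strand == "+" else reverse_complement(cds)
            _write_into(arr_ori, cursor, written, L)
            gid = f"SYN_{k:05d}"
            f = add_feature(
                "CDS",
                cursor,
                blen,
                strand=strand,
                locus_tag=gid,
                product="hypothetical protein",
            )
            gene_features.append((f, k))
            gene_strands[gid] = strand
            gene_repl[gid] = 1 if on_rep1 else 2
            expression[gid] = float(expr[k])
        cursor += blen + gap

    # ---- pseudogenes: single-base frameshift, coordinates preserved ------
    n_pseudo = int(math.floor(spec.pseudogene_fraction * len(gene_features)))
    pseudo_ids: list[str] = []
    if n_pseudo:
        chosen = rng.choice(len(gene_features), size=n_pseudo, replace=False)
        for ci in sorted(chosen):
            f, k = gene_features[ci]
            glen = f.length
            # feature is stored in genome coords; recover its ori-frame start
            start_of = (f.start - ori) % L + 1
            idx = (np.arange(glen) + start_of - 1) % L
            seq_bytes = arr_ori[idx]
            cut = int(rng.integers(10, glen - 10))
            shifted = np.concatenate(
                [seq_bytes[:cut], seq_bytes[cut + 1 :],
                 np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4) :][:1]]
            )
            arr_ori[idx] = shifted
            f.feature_type = "pseudogene"
            f.product = "hypothetical protein (frameshifted)"
            pseudo_ids.append(f.locus_tag)

    # ---- rotate into genome coordinates ----------------------------------
    genome_arr = np.roll(arr_ori, ori - 1)
    residues = genome_arr.tobytes().decode("ascii")
    seq = CircularSequence(spec.sequence_id, residues, "circular")
    ann = AnnotationSet(spec.sequence_id, features)
    ann.validate(seq)

    # post-hoc truth for box counts: rescan the emitted sequence over the
    # regions the reporting rule will examine (upstream intergenic capped at
    # 1000 bases), so chance background matches are absorbed into truth
    up_count = ig_count = 0
    if spec.place_replication_genes:
        final_gap = int(gaps[-1])
        dnaa_start_of = UPSTREAM_LEN + 1
        up_len = min(1000, UPSTREAM_LEN + final_gap)
        a_of = dnaa_start_of - up_len          # may be <= 0: wraps
        a = to_genome((a_of - 1) % L + 1)
        b = a + up_len - 1
        up_region = (a, b)
        up_count = len(scan_iupac(seq, DNAA_BOX, region=(a, b)))
        if ig_region is not None:
            a, b = ig_region
            if b < a:
                b += L
            ig_count = len(scan_iupac(seq, DNAA_BOX, region=(a, b)))

    truth = GenomeTruth(
        ori=ori,
        ter=ter,
        gene_strands=gene_strands,
        gene_replichores=gene_repl,
        expression=expression,
        pseudogene_ids=pseudo_ids,
        operon_spans=operon_spans,
        box_positions_upstream=truth_boxes_up,
        box_positions_intergenic=truth_boxes_ig,
        upstream_box_count=up_count,
        intergenic_box_count=ig_count,
        upstream_region=up_region,
        intergenic_region=ig_region,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_fasta(seq, out_dir / f"{spec.sequence_id}.fasta")
        write_gff3(ann, seq.length, out_dir / f"{spec.sequence_id}.gff3")
    return seq, ann, truth


def sanfranciscensis_like(seed: int, **overrides) -> SyntheticGenomeSpec:
    """Preset mirroring the headline architecture of a small sourdough
    lactobacillus chromosome: 1.3 Mb, GC 34.7%, 7 rRNA operons, 61 tRNAs,
    5 DnaA boxes upstream of dnaA and 3 in the dnaA-dnaN gap, ~10% of
    genes pseudogenized."""
    params = dict(
        seed=seed,
        length=1_298_316,
        gc=0.347,
        skew_delta=0.05,
        n_genes=1250,
        mean_gene_length=835,
        strand_bias=0.8,
        n_rrna_operons=7,
        n_trna=61,
        n_dnaA_boxes_upstream=5,
        n_dnaA_boxes_intergenic=3,
        pseudogene_fraction=0.106,
        codon_bias_strength=0.7,
        sequence_id="synthetic-chromosome",
    )
    params.update(overrides)
    return SyntheticGenomeSpec(**params)


# ---------------------------------------------------------------------------
# Alignment simulation


@dataclass
class AlignmentTruth:
    tree_newick: str
    expected_p: dict[tuple[str, str], float]


def _jc_p_sub(t: float) -> float:
    """Jukes-Cantor probability that a site differs after branch length t
    (expected substitutions per site)."""
    return 0.75 * (1.0 - math.exp(-4.0 * t / 3.0))


def simulate_alignment(
    tree: PhyloTree,
    site_count: int,
    seed: int,
    substitution_model: str = "jukes_cantor",
) -> tuple[Alignment, AlignmentTruth]:
    """Evolve an ungapped alignment along a tree under Jukes-Cantor.

    The root sequence is i.i.d. uniform over A,C,G,T; each site evolves
    independently down every branch with substitution probability
    3/4 (1 - e^(-4t/3)); a substituting site picks one of the other three
    bases uniformly. No indels, so the alignment is the sequence matrix.
    """
    if substitution_model != "jukes_cantor":
        raise ValueError(f"unknown substitution model {substitution_model!r}")
    if site_count < 1:
        raise ValueError("site_count must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    root_seq = rng.choice(bases, size=site_count)

    rows: dict[str, np.ndarray] = {}

    def evolve(node: TreeNode, seq_arr: np.ndarray) -> None:
        if node.length < 0:
            raise ValueError("branch lengths must be non-negative")
        p = _jc_p_sub(node.length)
        out = seq_arr.copy()
        if p > 0:
            hit = rng.random(site_count) < p
            n_hit = int(hit.sum())
            if n_hit:
                shift = rng.integers(1, 4, size=n_hit)
                cur = np.searchsorted(bases, out[hit])
                out[hit] = bases[(cur + shift) % 4]
        if node.is_leaf:
            rows[node.name] = out
        else:
            for c in node.children:
                evolve(c, out)

    for child in tree.root.children:
        evolve(child, root_seq)
    if tree.root.is_leaf:
        rows[tree.root.name] = root_seq

    taxa = sorted(rows)
    aln = Alignment(taxa, [rows[t].tobytes().decode("ascii") for t in taxa])

    pd = tree.leaf_distances()
    expected = {}
    for i, a in enumerate(pd.taxa):
        for j in range(i + 1, len(pd.taxa)):
            expected[(a, pd.taxa[j])] = _jc_p_sub(pd.d[i, j])
    return aln, AlignmentTruth(tree_newick=tree.newick(), expected_p=expected)
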