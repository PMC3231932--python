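"""Replication architecture from nucleotide composition.

Windowed GC%/GC-skew profiles, per-base cumulative skew, origin/terminus
prediction from the cumulative-skew extrema, genome rotation so that oriC
becomes base 1, and leading-strand coding bias statistics.

The skew of a window is (G-C)/(G+C) under the default ``G_minus_C`` sign
convention (negated under ``C_minus_G``); every result records the
convention used. On a circular chromosome with two replichores the
cumulative skew walk drifts upward along the arm replicated on the G-rich
leading strand, so its global minimum marks oriC and its global maximum the
terminus. Bases other than A, C, G, T contribute nothing to the skew and
are excluded from GC% denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import stats

from .io import AnnotationSet, CircularSequence, FeatureAnnotation

__all__ = [
    "SkewProfile",
    "CumulativeSkew",
    "ReplicationPrediction",
    "StrandBias",
    "SkewSignalError",
    "windowed_profile",
    "cumulative_skew",
    "predict_ori_ter",
    "rotate_to_origin",
    "strand_bias",
    "circular_distance",
]

SIGN_CONVENTIONS = ("G_minus_C", "C_minus_G")

DNAA_PRODUCT_PATTERN = "chromosomal replication initiat"


class SkewSignalError(ValueError):
    """The sequence carries no G/C skew signal (e.g. no G or C at all)."""


def circular_distance(a: int, b: int, length: int) -> int:
    """Shortest distance between positions a and b on a circle."""
    d = abs(a - b) % length
    return min(d, length - d)


@dataclass
class SkewProfile:
    sequence_id: str
    length: int
    window: int
    step: int
    centers: np.ndarray          # 1-based window centers
    gc_percent: np.ndarray       # fraction in [0, 1]
    skew: np.ndarray             # dimensionless in [-1, 1]
    sign_convention: str = "G_minus_C"


@dataclass
class CumulativeSkew:
    sequence_id: str
    length: int
    values: np.ndarray           # running sum, one entry per base
    start_phase: int = 1         # genome position where the walk begins
    sign_convention: str = "G_minus_C"

    def position_of(self, walk_index: int) -> int:
        """Genome position (1-based) of walk step ``walk_index`` (0-based)."""
        return int(self.start_phase - 1 + walk_index) % self.length + 1


@dataclass
class ReplicationPrediction:
    ori: int
    ter: int
    method: str
    replichore_1_len: int
    replichore_2_len: int
    sign_convention: str
    lead_strand_cds_fraction: Optional[tuple[float, float]] = None
    dnaA_distance: Optional[int] = None
    dnaA_supported: bool = False
    length: int = 0


@dataclass
class StrandBias:
    fraction_replichore_1: float
    fraction_replichore_2: float
    counts: dict
    pooled_fraction: float
    p_value: float


_BASES = {b: ord(b) for b in "ACGT"}


def _base_masks(seq: CircularSequence) -> dict[str, np.ndarray]:
    arr = np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)
    return {b: arr == code for b, code in _BASES.items()}


def windowed_profile(
    seq: CircularSequence,
    window: int = 10_000,
    step: int = 200,
    sign_convention: str = "G_minus_C",
) -> SkewProfile:
    """GC% and GC skew in sliding windows.

    Windows are anchored at positions 1, 1+step, ... and wrap around the
    circular junction, giving ceil(length/step) windows; on a linear
    sequence only fully contained windows are evaluated. The reported
    center is ``start + window//2``. Windows with no G or C get skew 0.
    """
    if sign_convention not in SIGN_CONVENTIONS:
        raise ValueError(f"unknown sign convention {sign_convention!r}")
    L = seq.length
    if L == 0:
        raise ValueError("empty sequence")
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    if window > L:
        raise ValueError(f"window {window} exceeds sequence length {L}")

    masks = _base_masks(seq)
    circular = seq.topology == "circular"
    if circular:
        starts = np.arange(0, L, step)      # 0-based anchors
    else:
        starts = np.arange(0, L - window + 1, step)

    def window_counts(mask: np.ndarray) -> np.ndarray:
        ext = np.concatenate([mask, mask[: window - 1]]) if circular else mask
        cs = np.concatenate([[0], np.cumsum(ext)])
        return cs[starts + window] - cs[starts]

    g = window_counts(masks["G"]).astype(float)
    c = window_counts(masks["C"]).astype(float)
    a = window_counts(masks["A"]).astype(float)
    t = window_counts(masks["T"]).astype(float)

    acgt = a + c + g + t
    gc_percent = np.divide(g + c, acgt, out=np.zeros_like(acgt), where=acgt > 0)
    denom = g + c
    skew = np.divide(g - c, denom, out=np.zeros_like(denom), where=denom > 0)
    if sign_convention == "C_minus_G":
        skew = -skew

    centers = (starts + window // 2) % L + 1
    return SkewProfile(
        sequence_id=seq.id,
        length=L,
        window=window,
        step=step,
        centers=centers,
        gc_percent=gc_percent,
        skew=skew,
        sign_convention=sign_convention,
    )


def cumulative_skew(seq: CircularSequence, start_phase: int = 1) -> CumulativeSkew:
    """Running sum of per-base G-C contributions (+1 G, -1 C, 0 otherwise),
    starting at ``start_phase`` and wrapping around the circle."""
    L = seq.length
    if L == 0:
        raise ValueError("empty sequence")
    if not (1 <= start_phase <= L):
        raise ValueError(f"start_phase {start_phase} outside [1, {L}]")
    masks = _base_masks(seq)
    contrib = masks["G"].astype(np.int64) - masks["C"].astype(np.int64)
    if start_phase != 1:
        contrib = np.roll(contrib, -(start_phase - 1))
    return CumulativeSkew(
        sequence_id=seq.id,
        length=L,
        values=np.cumsum(contrib),
        start_phase=start_phase,
    )


def _extremum_position(cs: CumulativeSkew, kind: str) -> int:
    """Genome position just after the first walk index attaining the
    extremum; ties broken by the smallest genome position."""
    vals = cs.values
    target = vals.min() if kind == "min" else vals.max()
    idx = np.flatnonzero(vals == target)
    positions = [(cs.position_of(i) % cs.length) + 1 for i in idx]
    return min(positions)


def predict_ori_ter(
    cumskew: CumulativeSkew,
    annotations: Optional[AnnotationSet] = None,
    dnaa_distance_threshold: int = 20_000,
) -> ReplicationPrediction:
    """Locate oriC and the terminus from the cumulative-skew extrema.

    Under ``G_minus_C`` the origin sits at the global minimum of the walk
    and the terminus at the global maximum (positions just after the
    extremal step; smallest position wins ties). When annotations contain a
    dnaA gene, the circular distance from the predicted origin to dnaA is
    reported and the prediction flagged dnaA-supported if it is within
    ``dnaa_distance_threshold`` (default 20 kb).
    """
    vals = cumskew.values
    if vals.min() == vals.max():
        raise SkewSignalError("no skew signal: cumulative skew is flat")
    if cumskew.sign_convention == "G_minus_C":
        ori = _extremum_position(cumskew, "min")
        ter = _extremum_position(cumskew, "max")
    else:
        ori = _extremum_position(cumskew, "max")
        ter = _extremum_position(cumskew, "min")
    if ori == ter:
        raise SkewSignalError("degenerate prediction: ori == ter")
    L = cumskew.length
    r1 = (ter - ori) % L
    r2 = L - r1
    pred = ReplicationPrediction(
        ori=ori,
        ter=ter,
        method="cumulative-skew extrema",
        replichore_1_len=r1,
        replichore_2_len=r2,
        sign_convention=cumskew.sign_convention,
        length=L,
    )
    if annotations is not None:
        dnaA = annotations.find_gene("dnaA", DNAA_PRODUCT_PATTERN)
        if dnaA is not None:
            d = circular_distance(ori, dnaA.start, L)
            pred.dnaA_distance = d
            pred.dnaA_supported = d <= dnaa_distance_threshold
        if annotations.of_type("CDS"):
            sb = strand_bias(pred, annotations)
            pred.lead_strand_cds_fraction = (
                sb.fraction_replichore_1,
                sb.fraction_replichore_2,
            )
    return pred


def rotate_to_origin(
    seq: CircularSequence, annotations: Optional[AnnotationSet], ori: int
) -> tuple[CircularSequence, Optional[AnnotationSet]]:
    """Rotate a circular genome so that ``ori`` becomes base 1.

    Feature coordinates are remapped modulo the length; features pushed
    across the new junction get the wrap flag. Rotating by ori=1 is the
    identity.
    """
    if seq.topology != "circular":
        raise ValueError("cannot rotate a linear sequence")
    L = seq.length
    if not (1 <= ori <= L):
        raise ValueError(f"ori {ori} outside [1, {L}]")
    rotated = CircularSequence(
        seq.id, seq.residues[ori - 1 :] + seq.residues[: ori - 1], "circular"
    )
    if annotations is None:
        return rotated, None
    feats = []
    for f in annotations.features:
        ns = (f.start - ori) % L + 1
        ne = ns + f.length - 1
        feats.append(replace(f, start=ns, end=ne, wraps=ne > L))
    return rotated, AnnotationSet(annotations.sequence_id, feats)


def _replichore_of(pos: int, pred: ReplicationPrediction) -> int:
    """1 for the ori->ter arm (leading strand +), 2 for the other."""
    L = pred.length
    return 1 if (pos - pred.ori) % L < pred.replichore_1_len else 2


def strand_bias(
    prediction: ReplicationPrediction, annotations: AnnotationSet
) -> StrandBias:
    """Per-replichore fraction of CDSs coded on the leading strand.

    The leading strand is '+' on replichore 1 (ori->ter in increasing
    coordinates) and '-' on replichore 2; a CDS belongs to the replichore
    containing its start. The pooled leading-strand count is assessed with
    a two-sided binomial test against 0.5.
    """
    cds = annotations.of_type("CDS")
    if not cds:
        raise ValueError("no CDS features to assess")
    counts = {1: {"leading": 0, "lagging": 0}, 2: {"leading": 0, "lagging": 0}}
    for f in cds:
        rep = _replichore_of(f.start, prediction)
        leading_strand = "+" if rep == 1 else "-"
        key = "leading" if f.strand == leading_strand else "lagging"
        counts[rep][key] += 1

    def frac(rep: int) -> float:
        n = counts[rep]["leading"] + counts[rep]["lagging"]
        return counts[rep]["leading"] / n if n else float("nan")

    lead = counts[1]["leading"] + counts[2]["leading"]
    total = len(cds)
    test = stats.binomtest(lead, total, 0.5, alternative="two-sided")
    return StrandBias(
        fraction_replichore_1=frac(1),
        fraction_replichore_2=frac(2),
        counts=counts,
        pooled_fraction=lead / total,
        p_value=test.pvalue,
    )
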