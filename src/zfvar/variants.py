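"""Mapping missense variants onto zinc finger positions and prediction flags.

Variants arrive as protein-level substitutions (variant_id, protein_id,
1-based residue position, reference/alternate amino acid, minor allele
frequency).  Each variant is located against the scanned fingers: a residue
that coincides with one of the eight tracked finger positions gets that
position label and the corresponding class — DNA-contacting for helix
positions -1, 2, 3, 6; non-DNA-contacting for C2, -2, 1, 5; anything else is
designated unknown.  A variant is "common" when its MAF is at least 1%.

Deleteriousness calls from four prediction methods are aggregated with the
standard per-method thresholds: SIFT < 0.05, PolyPhen2-HDIV > 0.95,
MutationTaster > 0.90, FATHMM < -1.5 (all strict; a missing score never
flags).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .scan import ZincFinger

__all__ = [
    "CONTACTING_LABELS",
    "NON_CONTACTING_LABELS",
    "METHODS",
    "THRESHOLDS",
    "VariantRecord",
    "PredictionFlags",
    "map_variant_to_finger",
    "classify_effect",
    "classify_frequency",
    "filter_retained",
    "flag_deleterious",
    "count_method_agreement",
    "annotate_variants",
    "flag_score_table",
]

CONTACTING_LABELS = frozenset({"-1", "2", "3", "6"})
NON_CONTACTING_LABELS = frozenset({"C2", "-2", "1", "5"})

#: Prediction methods in canonical column order.
METHODS: tuple[str, ...] = ("sift", "polyphen2_hdiv", "mutation_taster", "fathmm")

#: (operator, cutoff): 'lt' flags score < cutoff, 'gt' flags score > cutoff.
THRESHOLDS: dict[str, tuple[str, float]] = {
    "sift": ("lt", 0.05),
    "polyphen2_hdiv": ("gt", 0.95),
    "mutation_taster": ("gt", 0.90),
    "fathmm": ("lt", -1.5),
}

COMMON_MAF_THRESHOLD = 0.01

_DNA = set("ACGT")


@dataclass
class VariantRecord:
    variant_id: str
    protein_id: str
    residue_pos: int
    ref_aa: str
    alt_aa: str
    effect: str  # missense | silent | other
    position_label: str  # one of the tracked labels or "none"
    position_class: str  # contacting | non_contacting | unknown
    maf: float
    is_common: bool


@dataclass
class PredictionFlags:
    variant_id: str
    scores: dict[str, float | None]
    flags: frozenset[str]

    @property
    def n_methods_deleterious(self) -> int:
        return len(self.flags)


def label_to_class(label: str) -> str:
    if label in CONTACTING_LABELS:
        return "contacting"
    if label in NON_CONTACTING_LABELS:
        return "non_contacting"
    return "unknown"


def map_variant_to_finger(
    residue_pos: int,
    fingers: Sequence[ZincFinger],
    protein_length: int | None = None,
) -> tuple[str, str]:
    """Return ``(position_label, position_class)`` for a protein residue.

    If the residue coincides with a tracked helix-map index of a finger, the
    finger's label and class are returned; otherwise ``("none", "unknown")``.
    When two overlapping fingers both track the residue (should not happen
    with non-overlapping scan output) the earlier finger wins.
    """
    if residue_pos < 1 or (protein_length is not None and residue_pos > protein_length):
        raise ValueError(f"residue position {residue_pos} outside protein")
    for finger in sorted(fingers, key=lambda f: f.start):
        for label, (idx, _aa) in finger.helix_map.items():
            if idx == residue_pos:
                return label, label_to_class(label)
    return "none", "unknown"


def classify_effect(cds_codon_ref: str, cds_codon_alt: str) -> str:
    """Classify a codon substitution as missense, silent, or other.

    Translation uses the standard genetic code.  Gain or loss of a stop codon
    is "other"; an unchanged amino acid (including stop→stop) is "silent".
    """
    for codon in (cds_codon_ref, cds_codon_alt):
        if len(codon) != 3 or set(codon) - _DNA:
            raise ValueError(f"invalid codon {codon!r}")
    ref_aa = str(Seq(cds_codon_ref).translate())
    alt_aa = str(Seq(cds_codon_alt).translate())
    if ref_aa == alt_aa:
        return "silent"
    if ref_aa == "*" or alt_aa == "*":
        return "other"
    return "missense"


def classify_frequency(maf: float, threshold: float = COMMON_MAF_THRESHOLD) -> bool:
    """True when the variant is common (MAF >= 1% by default)."""
    if not (0.0 <= maf <= 0.5):
        raise ValueError(f"MAF {maf} outside [0, 0.5]")
    return maf >= threshold


def filter_retained(
    variants: Iterable[VariantRecord],
) -> tuple[list[VariantRecord], dict[str, int]]:
    """Keep missense variants at contacting/non-contacting positions.

    Returns the retained list plus a tally of how many records each rule
    dropped (non-missense effect; untracked/unknown position).
    """
    retained: list[VariantRecord] = []
    dropped = {"not_missense": 0, "position_unknown": 0}
    for v in variants:
        if v.effect != "missense":
            dropped["not_missense"] += 1
        elif v.position_class not in ("contacting", "non_contacting"):
            dropped["position_unknown"] += 1
        else:
            retained.append(v)
    return retained, dropped


def _is_missing(score: float | None) -> bool:
    return score is None or (isinstance(score, float) and math.isnan(score))


def flag_deleterious(scores: Mapping[str, float | None]) -> frozenset[str]:
    """Apply the four strict per-method thresholds; missing scores never flag."""
    flags = set()
    for method, (op, cutoff) in THRESHOLDS.items():
        s = scores.get(method)
        if _is_missing(s):
            continue
        if (op == "lt" and s < cutoff) or (op == "gt" and s > cutoff):
            flags.add(method)
    return frozenset(flags)


def flag_score_table(scores: pd.DataFrame) -> list[PredictionFlags]:
    """Flag every row of a score table (columns: variant_id + the 4 methods)."""
    out = []
    for row in scores.itertuples(index=False):
        d = {m: getattr(row, m, None) for m in METHODS}
        out.append(
            PredictionFlags(
                variant_id=row.variant_id, scores=d, flags=flag_deleterious(d)
            )
        )
    return out


def count_method_agreement(
    all_flags: Iterable[PredictionFlags],
) -> tuple[dict[frozenset[str], int], dict[int, int]]:
    """Partition flagged variants by their exact method subset.

    Returns the 15-cell overlap partition (every non-empty subset of the four
    methods, keyed by frozenset) and counts of variants flagged by exactly
    n methods for n = 0..4.  Overlap cells sum to the number of variants
    flagged by at least one method.
    """
    overlap: dict[frozenset[str], int] = {
        frozenset(c): 0
        for k in range(1, 5)
        for c in itertools.combinations(METHODS, k)
    }
    by_n = {n: 0 for n in range(5)}
    for pf in all_flags:
        by_n[pf.n_methods_deleterious] += 1
        if pf.flags:
            overlap[pf.flags] += 1
    return overlap, by_n


def annotate_variants(
    variants: pd.DataFrame,
    fingers_by_protein: Mapping[str, Sequence[ZincFinger]],
    *,
    common_threshold: float = COMMON_MAF_THRESHOLD,
) -> pd.DataFrame:
    """Annotate a variant table with position label/class and commonness.

    ``variants`` needs columns variant_id, protein_id, residue_pos, ref_aa,
    alt_aa, maf and optionally effect (inferred from ref/alt amino acids if
    absent: equal → silent, '*' involved → other, else missense).  Duplicate
    (protein_id, residue_pos, alt_aa) records are dropped, keeping the first.
    """
    df = variants.drop_duplicates(
        subset=["protein_id", "residue_pos", "alt_aa"], keep="first"
    ).copy()
    if "effect" not in df.columns:
        df["effect"] = [
            "silent" if r == a else ("other" if "*" in (r, a) else "missense")
            for r, a in zip(df["ref_aa"], df["alt_aa"])
        ]
    labels, classes = [], []
    for pid, pos in zip(df["protein_id"], df["residue_pos"]):
        fingers = fingers_by_protein.get(pid, ())
        label, cls = map_variant_to_finger(int(pos), fingers)
        labels.append(label)
        classes.append(cls)
    df["position_label"] = labels
    df["position_class"] = classes
    df["is_common"] = [
        classify_frequency(float(m), common_threshold) for m in df["maf"]
    ]
    return df
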