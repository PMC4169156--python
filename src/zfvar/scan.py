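"""Detection of C2H2 zinc finger repeats and DNA-binding finger arrays.

A C2H2 zinc finger is a ~23-28 residue repeat that coordinates a zinc ion
through two conserved cysteines and two conserved histidines.  Tandem arrays
of three or more fingers joined by short "TGEKP-like" linkers are the
strongest sequence-level predictor that the array binds DNA.  Sequence
recognition is dominated by the residues of the recognition alpha-helix,
numbered by convention from the first helix residue: positions -1, 2, 3 and 6
contact DNA bases, while C2 (in the beta-turn), -2, 1 and 5 face away from
the DNA.

This module finds fingers with a configurable spacing pattern
(default ``C-x(2,4)-C-x(11,14)-H-x(3,5)-H``), scores inter-finger linkers for
identity to the canonical TGEKP linker, assembles arrays of >= 3 fingers, and
anchors the tracked helix-position map on the first conserved histidine so
that positions -2..6 are well defined regardless of loop-length variation.

All residue coordinates in the public API are 1-based inclusive (protein
convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

__all__ = [
    "ZincFinger",
    "LinkerScore",
    "FingerArray",
    "MalformedFingerError",
    "find_fingers",
    "helix_position_map",
    "score_linker",
    "assemble_arrays",
    "scan_proteome",
    "HELIX_OFFSETS",
    "TRACKED_LABELS",
]

# Offset of each tracked recognition-helix position relative to the first
# conserved His (which sits at helix position 7 in the canonical finger).
# Position 1 is the first residue of the alpha-helix.
HELIX_OFFSETS: dict[str, int] = {
    "-2": -8,
    "-1": -7,
    "1": -6,
    "2": -5,
    "3": -4,
    "5": -2,
    "6": -1,
}

#: Tracked position labels, helix positions plus the beta-turn position C2.
TRACKED_LABELS: tuple[str, ...] = ("C2", "-2", "-1", "1", "2", "3", "5", "6")

TGEKP = "TGEKP"

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWY") | {"X"}


class MalformedFingerError(ValueError):
    """A finger whose conserved-residue spacing breaks the helix anchoring."""


@dataclass(frozen=True)
class ZincFinger:
    """One detected C2H2 repeat with its anchored helix position map.

    ``start``/``end`` delimit the match (first Cys to second His), 1-based
    inclusive.  ``helix_map`` maps each tracked label to ``(residue_index,
    amino_acid)``.
    """

    protein_id: str
    start: int
    end: int
    cys1_pos: int
    cys2_pos: int
    his1_pos: int
    his2_pos: int
    helix_map: dict[str, tuple[int, str]] = field(hash=False)

    def __post_init__(self) -> None:
        if not (self.cys1_pos < self.cys2_pos < self.his1_pos < self.his2_pos):
            raise MalformedFingerError(
                f"conserved residues out of order in {self.protein_id}: "
                f"C{self.cys1_pos} C{self.cys2_pos} H{self.his1_pos} H{self.his2_pos}"
            )
        if self.start != self.cys1_pos or self.end != self.his2_pos:
            raise MalformedFingerError("finger interval must span Cys1..His2")


@dataclass(frozen=True)
class LinkerScore:
    """Inter-finger linker scored for similarity to the canonical TGEKP."""

    sequence: str
    identity_to_tgekp: int
    is_tgekp_like: bool


@dataclass(frozen=True)
class FingerArray:
    """A run of >= 3 fingers in one protein, all joined by TGEKP-like linkers."""

    protein_id: str
    fingers: tuple[ZincFinger, ...]
    linkers: tuple[LinkerScore, ...]

    @property
    def start(self) -> int:
        return self.fingers[0].start

    @property
    def end(self) -> int:
        return self.fingers[-1].end


def _validate_sequence(sequence: str) -> None:
    bad = set(sequence) - _VALID_AA
    if bad:
        raise ValueError(f"non-amino-acid characters in sequence: {sorted(bad)!r}")


def helix_position_map(
    sequence: str, cys1_pos: int, cys2_pos: int, his1_pos: int
) -> dict[str, tuple[int, str]]:
    """Map tracked position labels to ``(1-based residue index, amino acid)``.

    Helix positions are anchored on the first conserved His (helix position
    7); C2 is the residue two after the first conserved Cys, in the
    beta-turn.  Raises :class:`MalformedFingerError` when a helix position
    would fall at or before the second Cys, or C2 at or after it.
    """
    out: dict[str, tuple[int, str]] = {}
    c2_index = cys1_pos + 2
    if c2_index >= cys2_pos:
        raise MalformedFingerError("position C2 collides with the second Cys")
    out["C2"] = (c2_index, sequence[c2_index - 1])
    for label, off in HELIX_OFFSETS.items():
        idx = his1_pos + off
        if idx <= cys2_pos:
            raise MalformedFingerError(
                f"helix position {label} falls inside the Cys knuckle"
            )
        out[label] = (idx, sequence[idx - 1])
    return out


def _finger_pattern(
    cys_gap: tuple[int, int], loop_gap: tuple[int, int], his_gap: tuple[int, int]
) -> re.Pattern[str]:
    # Lazy quantifiers give leftmost, then shortest-gap-first (lexicographic
    # over gap1, gap2, gap3) matching; X may occur in gaps but never anchors.
    return re.compile(
        f"C[A-Z]{{{cys_gap[0]},{cys_gap[1]}}}?"
        f"C[A-Z]{{{loop_gap[0]},{loop_gap[1]}}}?"
        f"H[A-Z]{{{his_gap[0]},{his_gap[1]}}}?"
        "H"
    )


def find_fingers(
    sequence: str,
    protein_id: str = "",
    *,
    cys_gap: tuple[int, int] = (2, 4),
    loop_gap: tuple[int, int] = (11, 14),
    his_gap: tuple[int, int] = (3, 5),
) -> list[ZincFinger]:
    """Find all non-overlapping C2H2 repeats, left-to-right greedy.

    The default pattern is ``C-x(2,4)-C-x(11,14)-H-x(3,5)-H``.  Matches are
    taken leftmost-first; at a given start the shortest gaps win, compared
    first-gap-first.  Fingers whose spacing cannot support the helix map are
    skipped (cannot occur with the default gap ranges).
    """
    _validate_sequence(sequence)
    if not sequence:
        return []
    pat = _finger_pattern(cys_gap, loop_gap, his_gap)
    fingers: list[ZincFinger] = []
    for m in pat.finditer(sequence):
        cys1 = m.start() + 1
        his2 = m.end()  # last char of the match is the second His
        cys2, his1 = _recover_parse(sequence, cys1, his2, cys_gap, loop_gap, his_gap)
        try:
            hmap = helix_position_map(sequence, cys1, cys2, his1)
        except MalformedFingerError:
            continue
        fingers.append(
            ZincFinger(
                protein_id=protein_id,
                start=cys1,
                end=his2,
                cys1_pos=cys1,
                cys2_pos=cys2,
                his1_pos=his1,
                his2_pos=his2,
                helix_map=hmap,
            )
        )
    return fingers


def _recover_parse(
    sequence: str,
    cys1: int,
    his2: int,
    cys_gap: tuple[int, int],
    loop_gap: tuple[int, int],
    his_gap: tuple[int, int],
) -> tuple[int, int]:
    """Re-derive (cys2, his1) of a lazy-regex match, 1-based.

    Gap regions may themselves contain C or H, so the inner anchors are not
    simply the first such letters.  All parses sharing the match span have
    the same gap total, and the lazy engine's parse is the lexicographically
    smallest (gap1, gap2, gap3); an ascending scan recovers it.
    """
    for gap1 in range(cys_gap[0], cys_gap[1] + 1):
        c2 = cys1 + gap1 + 1
        if c2 >= his2 or sequence[c2 - 1] != "C":
            continue
        for gap2 in range(loop_gap[0], loop_gap[1] + 1):
            h1 = c2 + gap2 + 1
            if h1 >= his2:
                break
            gap3 = his2 - h1 - 1
            if sequence[h1 - 1] == "H" and his_gap[0] <= gap3 <= his_gap[1]:
                return c2, h1
    raise MalformedFingerError("could not recover conserved residues from match")


def _tgekp_identity(linker: str) -> int:
    """Best exact-match count between the linker and the TGEKP 5-mer.

    For linkers of length >= 5 every length-5 window is compared with TGEKP;
    shorter linkers are compared with every same-length window of TGEKP.
    """
    if not linker:
        return 0
    if len(linker) >= len(TGEKP):
        windows = (linker[i : i + 5] for i in range(len(linker) - 4))
        ref_windows = [TGEKP]
    else:
        windows = [linker]
        ref_windows = [
            TGEKP[i : i + len(linker)] for i in range(len(TGEKP) - len(linker) + 1)
        ]
    best = 0
    for w in windows:
        for ref in ref_windows:
            best = max(best, sum(a == b for a, b in zip(w, ref)))
    return best


def score_linker(
    left: ZincFinger,
    right: ZincFinger,
    sequence: str,
    *,
    min_identity: int = 3,
    min_len: int = 4,
    max_len: int = 8,
) -> LinkerScore:
    """Score the residues strictly between two consecutive fingers.

    The linker is the substring between the left finger's second His and the
    right finger's first Cys.  It is TGEKP-like when its best window identity
    to TGEKP is at least ``min_identity`` and its length is within
    ``[min_len, max_len]``.
    """
    if left.end >= right.start:
        raise ValueError("fingers overlap or are out of order")
    linker = sequence[left.his2_pos : right.cys1_pos - 1]
    ident = _tgekp_identity(linker)
    like = ident >= min_identity and min_len <= len(linker) <= max_len
    return LinkerScore(sequence=linker, identity_to_tgekp=ident, is_tgekp_like=like)


def assemble_arrays(
    fingers: Sequence[ZincFinger],
    sequence: str,
    *,
    min_fingers: int = 3,
    min_identity: int = 3,
    min_len: int = 4,
    max_len: int = 8,
) -> list[FingerArray]:
    """Assemble maximal runs of fingers joined by TGEKP-like linkers.

    Fingers must be sorted and non-overlapping (as produced by
    :func:`find_fingers`).  Runs shorter than ``min_fingers`` are discarded.
    """
    arrays: list[FingerArray] = []
    if not fingers:
        return arrays
    run: list[ZincFinger] = [fingers[0]]
    links: list[LinkerScore] = []
    for prev, nxt in zip(fingers, fingers[1:]):
        sc = score_linker(
            prev, nxt, sequence, min_identity=min_identity, min_len=min_len, max_len=max_len
        )
        if sc.is_tgekp_like:
            run.append(nxt)
            links.append(sc)
        else:
            if len(run) >= min_fingers:
                arrays.append(
                    FingerArray(run[0].protein_id, tuple(run), tuple(links))
                )
            run, links = [nxt], []
    if len(run) >= min_fingers:
        arrays.append(FingerArray(run[0].protein_id, tuple(run), tuple(links)))
    return arrays


def scan_proteome(
    records: Iterable[tuple[str, str]],
    *,
    min_fingers: int = 3,
    min_identity: int = 3,
) -> tuple[dict[str, list[ZincFinger]], dict[str, list[FingerArray]]]:
    """Scan ``(protein_id, sequence)`` pairs; return fingers and arrays per protein."""
    fingers_by: dict[str, list[ZincFinger]] = {}
    arrays_by: dict[str, list[FingerArray]] = {}
    for pid, seq in records:
        fs = find_fingers(seq, pid)
        if fs:
            fingers_by[pid] = fs
            arrs = assemble_arrays(
                fs, seq, min_fingers=min_fingers, min_identity=min_identity
            )
            if arrs:
                arrays_by[pid] = arrs
    return fingers_by, arrays_by
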