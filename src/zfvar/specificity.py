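"""Predicted DNA-binding specificity change as summed Kullback-Leibler distance.

A position frequency matrix (PFM) gives per-position base probabilities of a
finger's predicted binding site.  The divergence between the reference
finger's PFM R and the variant finger's PFM S is quantified as
D(R||S) = sum_i R_i * ln(R_i / S_i) over every cell, plus the reciprocal
D(S||R); their sum is the (symmetric) summed KL distance.  Because real PFMs
contain zeros, a small global pseudocount is added to every cell and columns
are renormalized before taking logarithms.  A summed KL above 2.5 is treated
as a dramatic predicted specificity shift.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import rel_entr

__all__ = [
    "PFM",
    "KLResult",
    "read_pfm",
    "kl_distance",
    "summed_kl",
    "classify_shift",
    "DRAMATIC_THRESHOLD",
]

BASES = ("A", "C", "G", "T")
DRAMATIC_THRESHOLD = 2.5


@dataclass
class PFM:
    """Column-stochastic base-probability matrix, shape (4, width), rows ACGT."""

    id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError("PFM must have 4 rows (A,C,G,T) and >=1 column")
        if (m < 0).any():
            raise ValueError("PFM entries must be non-negative")
        sums = m.sum(axis=0)
        if (sums <= 0).any():
            raise ValueError("PFM has an all-zero column")
        self.matrix = m / sums

    @property
    def width(self) -> int:
        return int(self.matrix.shape[1])


@dataclass
class KLResult:
    forward: float  # D(R||S)
    reverse: float  # D(S||R)
    summed: float
    is_dramatic: bool
    pseudocount: float


def read_pfm(path: str, pfm_id: str | None = None) -> PFM:
    """Read a PFM from a 4-row TSV (rows labeled A,C,G,T) or JASPAR text.

    Counts or frequencies are accepted; columns are normalized to sum to 1.
    """
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise ValueError(f"empty PFM file {path}")
    if "[" in text:
        return _read_jaspar(text, pfm_id or path)
    df = pd.read_csv(io.StringIO(text), sep="\t", index_col=0, header=None)
    df.index = df.index.astype(str).str.strip().str.upper()
    missing = set(BASES) - set(df.index)
    if missing:
        raise ValueError(f"PFM {path} missing base rows {sorted(missing)}")
    return PFM(pfm_id or path, df.loc[list(BASES)].to_numpy(dtype=float))


def _read_jaspar(text: str, pfm_id: str) -> PFM:
    rows: dict[str, list[float]] = {}
    name = pfm_id
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            continue
        base = line[0].upper()
        inner = line[line.index("[") + 1 : line.rindex("]")]
        rows[base] = [float(x) for x in inner.split()]
    missing = set(BASES) - set(rows)
    if missing:
        raise ValueError(f"JASPAR matrix missing base rows {sorted(missing)}")
    return PFM(name, np.array([rows[b] for b in BASES], dtype=float))


def _smoothed(pfm: PFM, pseudocount: float) -> np.ndarray:
    m = pfm.matrix + pseudocount
    return m / m.sum(axis=0)


def kl_distance(r: PFM, s: PFM, pseudocount: float = 1e-6) -> float:
    """D(R||S) = sum over all cells of R_i * ln(R_i / S_i), natural log.

    Both matrices receive the pseudocount in every cell and are column
    renormalized first, so zeros in S never produce infinities.
    """
    if r.width != s.width:
        raise ValueError(f"PFM width mismatch: {r.width} vs {s.width}")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    return float(rel_entr(_smoothed(r, pseudocount), _smoothed(s, pseudocount)).sum())


def summed_kl(
    r: PFM,
    s: PFM,
    pseudocount: float = 1e-6,
    threshold: float = DRAMATIC_THRESHOLD,
) -> KLResult:
    """Symmetric summed KL distance D(R||S) + D(S||R) with the shift call."""
    fwd = kl_distance(r, s, pseudocount)
    rev = kl_distance(s, r, pseudocount)
    total = fwd + rev
    return KLResult(
        forward=fwd,
        reverse=rev,
        summed=total,
        is_dramatic=classify_shift(total, threshold),
        pseudocount=pseudocount,
    )


def classify_shift(summed: float, threshold: float = DRAMATIC_THRESHOLD) -> bool:
    """A dramatic specificity shift is summed KL strictly above the threshold."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return summed > threshold


def kl_manifest(
    pairs: pd.DataFrame,
    pseudocount: float = 1e-6,
    threshold: float = DRAMATIC_THRESHOLD,
    base_dir: str = ".",
) -> pd.DataFrame:
    """Evaluate a manifest of PFM pairs (pair_id, ref_path, snp_path[, maf]).

    Relative paths are resolved against ``base_dir`` (typically the
    manifest's own directory).  Rows whose files are missing yield NA
    distances rather than failing, mirroring predictor outputs that are
    unavailable for some fingers.
    """
    import os

    rows = []
    for rec in pairs.itertuples(index=False):
        try:
            r = read_pfm(
                os.path.join(base_dir, rec.ref_path), f"{rec.pair_id}_ref"
            )
            s = read_pfm(
                os.path.join(base_dir, rec.snp_path), f"{rec.pair_id}_snp"
            )
        except (OSError, ValueError):
            rows.append(
                {
                    "pair_id": rec.pair_id,
                    "forward": float("nan"),
                    "reverse": float("nan"),
                    "summed": float("nan"),
                    "is_dramatic": pd.NA,
                    "maf": getattr(rec, "maf", float("nan")),
                }
            )
            continue
        res = summed_kl(r, s, pseudocount, threshold)
        rows.append(
            {
                "pair_id": rec.pair_id,
                "forward": res.forward,
                "reverse": res.reverse,
                "summed": res.summed,
                "is_dramatic": res.is_dramatic,
                "maf": getattr(rec, "maf", float("nan")),
            }
        )
    return pd.DataFrame(rows)
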