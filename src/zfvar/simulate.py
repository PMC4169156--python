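"""Synthetic study generator with planted ground truth.

Every input the pipeline consumes can be generated here with known truth:

* a proteome in which a chosen number of proteins carry an array of
  canonical C2H2 fingers (``C-x(4)-C-x(12)-H-x(3)-H``) joined by exact TGEKP
  linkers, with the remaining proteins being residue-shuffled decoys of the
  planted ones (same length and composition, motifs destroyed);
* diploid genotype vectors drawn from the inbreeding model
  P(het) = 2pq(1-f), P(hom_alt) = q^2 + pqf, P(hom_ref) = p^2 + pqf, so a
  positive inbreeding coefficient f produces the heterozygote deficits
  (negative D) that the Hardy-Weinberg module is designed to detect;
* a variant table with planted position classes (contacting,
  non-contacting, unknown), effects (missense/silent/other) and a minor
  allele frequency spectrum mixing rare (0.001-0.01) and common (0.01-0.5)
  uniform draws, optionally with a class-dependent common-variant odds
  ratio to plant depletion of common variants at DNA-contacting positions;
* reference/variant PFM pairs whose columns are mixed with random columns
  at a weight controlled by a divergence parameter (0 = identical);
* a four-method prediction score table in which a planted subset of
  variants crosses each method's deleteriousness threshold.

Outside the fingers and linkers, planted protein sequence is drawn from an
alphabet without C and H, so the planted arrays are exactly the pattern
matches and boundary recovery can be asserted exactly.

Each generator draws from its own seed stream derived from
``(cfg.seed, stream_index)``; identical configuration reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .scan import HELIX_OFFSETS
from .variants import (
    CONTACTING_LABELS,
    METHODS,
    NON_CONTACTING_LABELS,
    label_to_class,
)

__all__ = [
    "SimConfig",
    "GroundTruth",
    "gen_proteome",
    "gen_genotypes",
    "gen_variant_table",
    "gen_pfm_pair",
    "gen_scores",
    "gen_cohort",
    "simulate_study",
    "write_fasta",
    "write_vcf",
]

# 18 residues: the 20 standard amino acids minus Cys and His, used for all
# non-anchor positions of planted proteins.
_BG_ALPHABET = np.array(list("ADEFGIKLMNPQRSTVWY"))
_ALL_AA = list("ACDEFGHIKLMNPQRSTVWY")

FINGER_LEN = 23  # C xxxx C xxxxxxxxxxxx H xxx H
LINKER = "TGEKP"

# seed-stream indices, one per generator
_STREAMS = {"proteome": 0, "variants": 1, "genotypes": 2, "pfm": 3, "scores": 4}

# phase1-style population labels (cohort of 14 populations)
_DEFAULT_POPULATIONS = (
    "ASW", "CEU", "CHB", "CHS", "CLM", "FIN", "GBR",
    "IBS", "JPT", "LWK", "MXL", "PUR", "TSI", "YRI",
)


@dataclass(frozen=True)
class SimConfig:
    """Study-generation parameters; the seed makes every output reproducible."""

    seed: int = 0
    n_proteins: int = 200
    n_planted_arrays: int = 50
    fingers_per_array: int = 3
    n_variants: int = 200
    maf_spectrum: tuple[float, ...] | None = None
    n_individuals: int = 100  # per population
    populations: tuple[str, ...] = _DEFAULT_POPULATIONS
    inbreeding_f: float = 0.0
    f_snp_fraction: float = 0.0  # fraction of SNPs planted with inbreeding_f
    deleterious_fraction: float = 0.09  # per-method flag probability
    missing_score_rate: float = 0.05
    pfm_divergence: float = 0.3
    pfm_width: int = 4
    common_odds_ratio: float = 1.0  # odds of being common, contacting vs not
    p_common_noncontacting: float = 0.5

    def __post_init__(self) -> None:
        if self.fingers_per_array < 3:
            raise ValueError("fingers_per_array must be >= 3")
        if self.n_planted_arrays > self.n_proteins:
            raise ValueError("more planted arrays than proteins")
        if self.maf_spectrum is not None:
            if any(not (0.0 <= m <= 0.5) for m in self.maf_spectrum):
                raise ValueError("maf_spectrum entries must lie in [0, 0.5]")
        if not -1.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding_f must lie in [-1, 1]")
        for name in ("f_snp_fraction", "deleterious_fraction", "missing_score_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.pfm_divergence < 0:
            raise ValueError("pfm_divergence must be >= 0")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), _STREAMS[stream]])
        )


@dataclass
class GroundTruth:
    """Everything planted, one record per planted item."""

    arrays: list[dict] = field(default_factory=list)
    variant_labels: dict[str, str] = field(default_factory=dict)
    variant_classes: dict[str, str] = field(default_factory=dict)
    variant_effects: dict[str, str] = field(default_factory=dict)
    planted_f: dict[str, float] = field(default_factory=dict)
    deleterious: dict[str, list[str]] = field(default_factory=dict)
    pfm_divergence: dict[str, float] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# proteome


def _random_residues(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BG_ALPHABET, size=n))


def _make_finger(rng: np.random.Generator) -> str:
    return (
        "C" + _random_residues(rng, 4) + "C" + _random_residues(rng, 12)
        + "H" + _random_residues(rng, 3) + "H"
    )


def gen_proteome(cfg: SimConfig) -> tuple[list[tuple[str, str]], GroundTruth]:
    """Generate the synthetic proteome and its planted-array ground truth.

    Returns ``(records, truth)`` where records are ``(protein_id, sequence)``
    pairs: ``cfg.n_planted_arrays`` proteins each carrying one array of
    ``cfg.fingers_per_array`` canonical fingers with TGEKP linkers, and
    decoys that are residue-shuffled copies of the planted sequences.
    """
    rng = cfg.rng("proteome")
    truth = GroundTruth()
    records: list[tuple[str, str]] = []
    planted_seqs: list[str] = []
    for i in range(cfg.n_planted_arrays):
        pid = f"ZNF{i:04d}"
        prefix = _random_residues(rng, int(rng.integers(10, 31)))
        fingers = [_make_finger(rng) for _ in range(cfg.fingers_per_array)]
        array = LINKER.join(fingers)
        suffix = _random_residues(rng, int(rng.integers(10, 31)))
        seq = prefix + array + suffix
        start = len(prefix) + 1
        end = len(prefix) + len(array)
        finger_starts = [
            start + k * (FINGER_LEN + len(LINKER))
            for k in range(cfg.fingers_per_array)
        ]
        truth.arrays.append(
            {
                "protein_id": pid,
                "start": start,
                "end": end,
                "n_fingers": cfg.fingers_per_array,
                "finger_starts": finger_starts,
            }
        )
        records.append((pid, seq))
        planted_seqs.append(seq)
    n_decoys = cfg.n_proteins - cfg.n_planted_arrays
    for j in range(n_decoys):
        if planted_seqs:
            src = planted_seqs[j % len(planted_seqs)]
        else:
            src = _random_residues(rng, 100)
        shuffled = "".join(rng.permutation(list(src)))
        records.append((f"DECOY{j:04d}", shuffled))
    return records, truth


# ---------------------------------------------------------------------------
# genotypes


def genotype_probs(maf: float, f: float) -> tuple[float, float, float]:
    """(hom_ref, het, hom_alt) probabilities under the inbreeding model."""
    if not 0.0 < maf <= 0.5:
        raise ValueError("maf must lie in (0, 0.5]")
    q = maf
    p = 1.0 - q
    if f < -q / p or f > 1.0:
        raise ValueError(f"inbreeding f={f} yields negative genotype probabilities")
    het = 2 * p * q * (1.0 - f)
    hom_alt = q * q + p * q * f
    hom_ref = p * p + p * q * f
    return hom_ref, het, hom_alt


def gen_genotypes(
    rng: np.random.Generator, maf: float, f: float, n: int
) -> np.ndarray:
    """Draw n diploid genotypes coded 0=hom_ref, 1=het, 2=hom_alt."""
    probs = genotype_probs(maf, f)
    return rng.choice(3, size=n, p=probs).astype(np.int8)


# ---------------------------------------------------------------------------
# variant table


def _draw_maf(rng: np.random.Generator, cfg: SimConfig, common: bool) -> float:
    if cfg.maf_spectrum is not None:
        return float(rng.choice(np.asarray(cfg.maf_spectrum)))
    if common:
        return float(rng.uniform(0.01, 0.5))
    return float(rng.uniform(0.001, 0.01))


def _p_common(cfg: SimConfig, position_class: str) -> float:
    p_nc = cfg.p_common_noncontacting
    if position_class != "contacting" or cfg.common_odds_ratio == 1.0:
        return p_nc
    odds = cfg.common_odds_ratio * p_nc / (1.0 - p_nc)
    return odds / (1.0 + odds)


def gen_variant_table(
    cfg: SimConfig,
    truth: GroundTruth,
    sequences: dict[str, str],
    *,
    n_contacting: int | None = None,
    n_non_contacting: int | None = None,
    n_unknown: int | None = None,
    n_silent: int | None = None,
    n_other: int | None = None,
) -> pd.DataFrame:
    """Plant variants at known finger positions with known classes and MAFs.

    By default ``cfg.n_variants`` splits 40% contacting, 40% non-contacting,
    10% unknown (helix position 4), 5% silent, 5% other; explicit counts
    override.  Truth labels/classes/effects are recorded per variant_id.
    """
    if not truth.arrays:
        return pd.DataFrame(
            columns=["variant_id", "protein_id", "residue_pos", "ref_aa", "alt_aa", "maf"]
        )
    rng = cfg.rng("variants")
    nv = cfg.n_variants
    counts = {
        "contacting": n_contacting if n_contacting is not None else int(0.40 * nv),
        "non_contacting": (
            n_non_contacting if n_non_contacting is not None else int(0.40 * nv)
        ),
        "unknown": n_unknown if n_unknown is not None else int(0.10 * nv),
        "silent": n_silent if n_silent is not None else int(0.05 * nv),
        "other": n_other if n_other is not None else int(0.05 * nv),
    }
    rows = []
    seen: set[tuple[str, int, str]] = set()
    vid_counter = 0
    for kind, n_kind in counts.items():
        for _ in range(n_kind):
            for _attempt in range(200):
                arr = truth.arrays[int(rng.integers(len(truth.arrays)))]
                pid = arr["protein_id"]
                seq = sequences[pid]
                c1 = arr["finger_starts"][int(rng.integers(arr["n_fingers"]))]
                his1 = c1 + 18
                if kind == "contacting":
                    label = str(rng.choice(sorted(CONTACTING_LABELS)))
                elif kind == "non_contacting":
                    label = str(rng.choice(sorted(NON_CONTACTING_LABELS)))
                elif kind == "unknown":
                    label = "4"  # untracked helix position
                else:  # silent / other sit at any tracked contacting position
                    label = str(rng.choice(sorted(CONTACTING_LABELS)))
                if label == "C2":
                    pos = c1 + 2
                elif label == "4":
                    pos = his1 - 3
                else:
                    pos = his1 + HELIX_OFFSETS[label]
                ref = seq[pos - 1]
                if kind == "silent":
                    alt = ref
                elif kind == "other":
                    alt = "*"
                else:
                    choices = [a for a in _ALL_AA if a != ref]
                    alt = str(rng.choice(choices))
                key = (pid, pos, alt)
                if key in seen:
                    continue
                seen.add(key)
                break
            else:
                raise RuntimeError("could not place a unique variant")
            vid = f"var{vid_counter:05d}"
            vid_counter += 1
            # class follows the planted position, not the effect: a silent
            # variant sitting at a contacting label is class "contacting"
            cls = label_to_class(label)
            common = bool(rng.random() < _p_common(cfg, cls))
            maf = _draw_maf(rng, cfg, common)
            rows.append(
                {
                    "variant_id": vid,
                    "protein_id": pid,
                    "residue_pos": pos,
                    "ref_aa": ref,
                    "alt_aa": alt,
                    "maf": maf,
                }
            )
            truth.variant_labels[vid] = label if kind not in ("unknown",) else "4"
            truth.variant_classes[vid] = cls
            truth.variant_effects[vid] = (
                "missense"
                if kind in ("contacting", "non_contacting", "unknown")
                else kind
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort genotypes / VCF


def gen_cohort(
    cfg: SimConfig, variant_table: pd.DataFrame, truth: GroundTruth
) -> tuple[list[str], dict[str, str], np.ndarray]:
    """Draw cohort genotypes for every variant (samples x SNPs matrix).

    A seeded fraction ``cfg.f_snp_fraction`` of SNPs is planted with
    inbreeding coefficient ``cfg.inbreeding_f`` (recorded in truth); the rest
    are at Hardy-Weinberg equilibrium (f = 0).  The same per-SNP MAF is used
    in every population.
    """
    rng = cfg.rng("genotypes")
    samples = [
        f"{pop}{i:04d}" for pop in cfg.populations for i in range(cfg.n_individuals)
    ]
    panel = {s: s[:-4] for s in samples}
    snp_ids = list(variant_table["variant_id"])
    n_f = int(round(cfg.f_snp_fraction * len(snp_ids)))
    f_snps = set(
        rng.choice(np.asarray(snp_ids, dtype=object), size=n_f, replace=False)
    ) if n_f else set()
    geno = np.zeros((len(samples), len(snp_ids)), dtype=np.int8)
    for j, (vid, maf) in enumerate(
        zip(variant_table["variant_id"], variant_table["maf"])
    ):
        f = cfg.inbreeding_f if vid in f_snps else 0.0
        truth.planted_f[str(vid)] = f
        maf = max(float(maf), 1e-4)  # guard the genotype model's maf>0 domain
        col = np.concatenate(
            [
                gen_genotypes(rng, maf, f, cfg.n_individuals)
                for _ in cfg.populations
            ]
        )
        geno[:, j] = col
    return samples, panel, geno


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(
    path: str,
    variant_table: pd.DataFrame,
    samples: Sequence[str],
    genotypes: np.ndarray,
) -> None:
    """Write a minimal VCF v4.2 (biallelic SNPs, GT only, uncompressed)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        for j, vid in enumerate(variant_table["variant_id"]):
            gts = "\t".join(_GT_STR[int(g)] for g in genotypes[:, j])
            fh.write(f"1\t{1000 * (j + 1)}\t{vid}\tA\tG\t.\tPASS\t.\tGT\t{gts}\n")


def write_panel(path: str, panel: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for sample in panel:
            fh.write(f"{sample}\t{panel[sample]}\n")


def write_fasta(path: str, records: Sequence[tuple[str, str]]) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write(
        [SeqRecord(Seq(seq), id=pid, description="") for pid, seq in records],
        path,
        "fasta",
    )


# ---------------------------------------------------------------------------
# PFM pairs


def _random_column(rng: np.random.Generator) -> np.ndarray:
    return rng.dirichlet(np.full(4, 0.5))


def gen_pfm_pair(
    rng: np.random.Generator, divergence: float, width: int = 4
) -> tuple[np.ndarray, np.ndarray]:
    """Reference PFM plus a variant PFM mixed toward random columns.

    Each variant column is ``(1-w) * ref + w * random`` with mixing weight
    ``w = min(divergence, 1)``; divergence 0 reproduces the reference.
    """
    if divergence < 0:
        raise ValueError("divergence must be >= 0")
    w = min(float(divergence), 1.0)
    ref = np.column_stack([_random_column(rng) for _ in range(width)])
    var = np.column_stack(
        [(1.0 - w) * ref[:, i] + w * _random_column(rng) for i in range(width)]
    )
    return ref, var


def write_pfm(path: str, matrix: np.ndarray) -> None:
    with open(path, "w") as fh:
        for base, row in zip("ACGT", matrix):
            fh.write(base + "\t" + "\t".join(f"{x:.8f}" for x in row) + "\n")


def gen_pfm_manifest(
    cfg: SimConfig,
    variant_table: pd.DataFrame,
    truth: GroundTruth,
    outdir: str,
) -> pd.DataFrame:
    """One PFM pair per variant; rarer variants get larger divergence.

    Divergence is drawn uniformly on [0, 2*pfm_divergence] for variants with
    MAF < 0.1 and on [0, 0.5*pfm_divergence] otherwise, echoing the pattern
    that dramatic specificity shifts concentrate among rare variants.
    """
    import os

    rng = cfg.rng("pfm")
    os.makedirs(outdir, exist_ok=True)
    base = os.path.basename(os.path.normpath(outdir))
    rows = []
    for vid, maf in zip(variant_table["variant_id"], variant_table["maf"]):
        hi = 2.0 * cfg.pfm_divergence if maf < 0.1 else 0.5 * cfg.pfm_divergence
        div = float(rng.uniform(0.0, hi))
        ref, var = gen_pfm_pair(rng, div, cfg.pfm_width)
        write_pfm(os.path.join(outdir, f"{vid}_ref.pfm"), ref)
        write_pfm(os.path.join(outdir, f"{vid}_snp.pfm"), var)
        truth.pfm_divergence[str(vid)] = div
        # paths are kept relative to the manifest's directory so a study
        # directory is relocatable and fixed-seed runs are byte-identical
        rows.append(
            {
                "pair_id": vid,
                "ref_path": f"{base}/{vid}_ref.pfm",
                "snp_path": f"{base}/{vid}_snp.pfm",
                "maf": maf,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# prediction scores

_SCORE_RANGES = {
    # method: (deleterious low, high), (benign low, high); margins keep draws
    # strictly clear of the decision boundaries
    "sift": ((0.0, 0.0499), (0.051, 1.0)),
    "polyphen2_hdiv": ((0.9501, 1.0), (0.0, 0.949)),
    "mutation_taster": ((0.9001, 1.0), (0.0, 0.899)),
    "fathmm": ((-7.0, -1.5001), (-1.499, 3.0)),
}


def gen_scores(
    cfg: SimConfig,
    variant_ids: Sequence[str],
    truth: GroundTruth,
    *,
    per_method_fraction: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Sample the four-method score table with planted deleterious sets.

    Each (variant, method) cell is missing with ``cfg.missing_score_rate``,
    otherwise deleterious with probability ``cfg.deleterious_fraction`` (or a
    per-method override).  Truth records, per variant, the exact set of
    methods whose written score crosses the threshold.
    """
    rng = cfg.rng("scores")
    fractions = {m: cfg.deleterious_fraction for m in METHODS}
    if per_method_fraction:
        fractions.update(per_method_fraction)
    rows = []
    for vid in variant_ids:
        row: dict[str, object] = {"variant_id": vid}
        flagged = []
        for m in METHODS:
            if rng.random() < cfg.missing_score_rate:
                row[m] = np.nan
                continue
            deleterious = rng.random() < fractions[m]
            lo, hi = _SCORE_RANGES[m][0 if deleterious else 1]
            row[m] = float(rng.uniform(lo, hi))
            if deleterious:
                flagged.append(m)
        truth.deleterious[str(vid)] = sorted(flagged)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# one-call study generation


def simulate_study(cfg: SimConfig, outdir: str) -> GroundTruth:
    """Generate and write every pipeline input under ``outdir``.

    Files: proteome.fa, variants.tsv, genotypes.vcf, panel.tsv, scores.tsv,
    pfms/ + pfm_manifest.tsv, truth.json.
    """
    import os

    os.makedirs(outdir, exist_ok=True)
    records, truth = gen_proteome(cfg)
    sequences = dict(records)
    write_fasta(os.path.join(outdir, "proteome.fa"), records)
    variants = gen_variant_table(cfg, truth, sequences)
    variants.to_csv(os.path.join(outdir, "variants.tsv"), sep="\t", index=False)
    samples, panel, geno = gen_cohort(cfg, variants, truth)
    write_vcf(os.path.join(outdir, "genotypes.vcf"), variants, samples, geno)
    write_panel(os.path.join(outdir, "panel.tsv"), panel)
    scores = gen_scores(cfg, list(variants["variant_id"]), truth)
    scores.to_csv(os.path.join(outdir, "scores.tsv"), sep="\t", index=False)
    manifest = gen_pfm_manifest(cfg, variants, truth, os.path.join(outdir, "pfms"))
    manifest.to_csv(os.path.join(outdir, "pfm_manifest.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "truth.json"), "w") as fh:
        fh.write(truth.to_json())
    return truth
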