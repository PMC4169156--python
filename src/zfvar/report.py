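"""Headline comparisons and pipeline orchestration.

The central contrast: are common variants (MAF >= 1%) depleted at
DNA-contacting finger positions relative to non-DNA-contacting positions?
The 2x2 table (class x common/rare) is tested with a two-sided Fisher exact
test — computed here by exact integer enumeration of the fixed-margin
hypergeometric distribution, summing tables no more probable than the
observed one — with the Pearson chi-square reported alongside.  The same
machinery compares per-class Hardy-Weinberg deviation rates.

The odds ratio is oriented (contacting & common) x (non-contacting & rare)
over (contacting & rare) x (non-contacting & common): depletion of common
variants at contacting positions gives OR < 1.

``run_pipeline`` wires the whole analysis together: simulate (or load) ->
scan -> map -> HWE -> KL -> enrichment tables, writing TSV outputs and a
deterministic reproducibility log.
"""

from __future__ import annotations

import hashlib
import math
import os
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import hwe as hwe_mod
from . import scan as scan_mod
from . import simulate as sim_mod
from . import specificity as spec_mod
from . import variants as var_mod

__all__ = [
    "ContingencyResult",
    "fisher_exact_2x2",
    "common_by_class_test",
    "deviation_rate_test",
    "maf_stratified_summary",
    "run_pipeline",
]


@dataclass
class ContingencyResult:
    table: np.ndarray  # rows: contacting / non_contacting; cols: common/rare
    odds_ratio: float  # inf when the denominator product is 0; nan when 0/0
    p_fisher: float
    p_chi2: float
    degenerate: bool = False


def fisher_exact_2x2(table: np.ndarray | list[list[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table, by exact enumeration.

    Conditions on the margins; sums hypergeometric probabilities of all
    tables whose probability does not exceed the observed table's.  All
    arithmetic is on integers, so ties are handled exactly.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = [math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    return float(Fraction(num, math.comb(n, c1)))


def _contingency(table: np.ndarray) -> ContingencyResult:
    t = np.asarray(table, dtype=np.int64)
    degenerate = bool((t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any())
    p_fisher = fisher_exact_2x2(t)
    if degenerate:
        p_chi2 = 1.0
    else:
        chi2, p_chi2, _, _ = stats.chi2_contingency(t, correction=False)
        p_chi2 = float(p_chi2)
    num = t[0, 0] * t[1, 1]
    den = t[0, 1] * t[1, 0]
    if den > 0:
        odds = float(num) / float(den)
    else:
        odds = float("nan") if num == 0 else float("inf")
    return ContingencyResult(
        table=t, odds_ratio=odds, p_fisher=p_fisher, p_chi2=p_chi2, degenerate=degenerate
    )


def common_by_class_test(variants: pd.DataFrame) -> ContingencyResult:
    """Test depletion of common variants at contacting positions.

    ``variants`` must carry position_class (restricted to contacting /
    non_contacting) and is_common columns.
    """
    sub = variants[variants["position_class"].isin(["contacting", "non_contacting"])]
    table = np.array(
        [
            [
                int(((sub["position_class"] == cls) & (sub["is_common"] == com)).sum())
                for com in (True, False)
            ]
            for cls in ("contacting", "non_contacting")
        ]
    )
    return _contingency(table)


def deviation_rate_test(
    variants: pd.DataFrame, summary: pd.DataFrame
) -> ContingencyResult:
    """Compare HWE-deviation rates between the two position classes.

    ``summary`` is the per-SNP deviation summary (snp_id, deviates);
    variants lacking a summary row count as not deviating (never tested).
    """
    dev = dict(zip(summary["snp_id"], summary["deviates"]))
    sub = variants[
        variants["position_class"].isin(["contacting", "non_contacting"])
    ].copy()
    sub["deviates"] = [bool(dev.get(v, False)) for v in sub["variant_id"]]
    table = np.array(
        [
            [
                int(((sub["position_class"] == cls) & (sub["deviates"] == s)).sum())
                for s in (True, False)
            ]
            for cls in ("contacting", "non_contacting")
        ]
    )
    return _contingency(table)


MAF_FLOOR = 1e-3


def maf_stratified_summary(
    variants: pd.DataFrame,
    flags: pd.DataFrame | None = None,
    kl: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-variant tidy table: MAF bin, prediction count, summed KL, class.

    MAF values below 0.001 are floored into a single "<=0.001" bin (very
    rare frequencies cannot be estimated accurately); other variants keep
    their numeric MAF as the bin value.
    """
    out = variants[["variant_id", "maf", "position_class"]].copy()
    out["maf_bin"] = [
        "<=0.001" if m < MAF_FLOOR else f"{m:.6g}" for m in out["maf"]
    ]
    if flags is not None and len(flags):
        nmeth = dict(zip(flags["variant_id"], flags["n_methods_deleterious"]))
        out["n_methods_deleterious"] = [
            int(nmeth.get(v, 0)) for v in out["variant_id"]
        ]
    if kl is not None and len(kl):
        summed = dict(zip(kl["pair_id"], kl["summed"]))
        out["summed_kl"] = [summed.get(v, float("nan")) for v in out["variant_id"]]
    return out


# ---------------------------------------------------------------------------
# pipeline


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_pipeline(
    outdir: str,
    *,
    sim_config: sim_mod.SimConfig | None = None,
    fasta: str | None = None,
    variants_tsv: str | None = None,
    vcf: str | None = None,
    panel_tsv: str | None = None,
    scores_tsv: str | None = None,
    pfm_manifest: str | None = None,
    alpha: float = 0.05,
    min_count: int = 5,
) -> dict[str, object]:
    """Run scan -> map -> HWE -> KL -> report end to end.

    With ``sim_config`` all inputs are first generated under
    ``outdir/inputs``; otherwise explicit paths must name them.  Outputs are
    TSVs under ``outdir`` plus a deterministic run log (parameters and input
    digests; no timestamps, so fixed-seed runs are byte-identical).
    Returns a summary dict of the headline numbers.
    """
    os.makedirs(outdir, exist_ok=True)
    if sim_config is not None:
        inputs = os.path.join(outdir, "inputs")
        sim_mod.simulate_study(sim_config, inputs)
        fasta = os.path.join(inputs, "proteome.fa")
        variants_tsv = os.path.join(inputs, "variants.tsv")
        vcf = os.path.join(inputs, "genotypes.vcf")
        panel_tsv = os.path.join(inputs, "panel.tsv")
        scores_tsv = os.path.join(inputs, "scores.tsv")
        pfm_manifest = os.path.join(inputs, "pfm_manifest.tsv")
    if not (fasta and variants_tsv):
        raise ValueError("need a proteome FASTA and a variant table (or sim_config)")

    from Bio import SeqIO

    records = [(r.id, str(r.seq)) for r in SeqIO.parse(fasta, "fasta")]
    fingers_by, arrays_by = scan_mod.scan_proteome(records)

    finger_rows = [
        {
            "protein_id": pid,
            "start": f.start,
            "end": f.end,
            "cys1": f.cys1_pos,
            "cys2": f.cys2_pos,
            "his1": f.his1_pos,
            "his2": f.his2_pos,
            "helix_map": ";".join(
                f"{lab}:{idx}:{aa}" for lab, (idx, aa) in sorted(f.helix_map.items())
            ),
        }
        for pid, fs in sorted(fingers_by.items())
        for f in fs
    ]
    pd.DataFrame(finger_rows).to_csv(
        os.path.join(outdir, "fingers.tsv"), sep="\t", index=False
    )
    array_rows = [
        {
            "protein_id": pid,
            "start": a.start,
            "end": a.end,
            "n_fingers": len(a.fingers),
        }
        for pid, arrs in sorted(arrays_by.items())
        for a in arrs
    ]
    pd.DataFrame(array_rows).to_csv(
        os.path.join(outdir, "arrays.tsv"), sep="\t", index=False
    )

    # restrict mapping to fingers inside assembled (>=3-finger) arrays,
    # the DNA-binding-competent subset
    array_fingers = {
        pid: [f for a in arrs for f in a.fingers] for pid, arrs in arrays_by.items()
    }
    raw_variants = pd.read_csv(variants_tsv, sep="\t")
    annotated = var_mod.annotate_variants(raw_variants, array_fingers)
    annotated.to_csv(
        os.path.join(outdir, "variants_annotated.tsv"), sep="\t", index=False
    )

    summary: dict[str, object] = {
        "n_proteins": len(records),
        "n_proteins_with_arrays": len(arrays_by),
        "n_arrays": sum(len(v) for v in arrays_by.values()),
        "n_variants": len(annotated),
        "n_contacting": int((annotated["position_class"] == "contacting").sum()),
        "n_non_contacting": int(
            (annotated["position_class"] == "non_contacting").sum()
        ),
        "n_common": int(annotated["is_common"].sum()),
    }

    missense = annotated[
        (annotated["effect"] == "missense")
        & annotated["position_class"].isin(["contacting", "non_contacting"])
    ]
    enr = common_by_class_test(missense)
    summary.update(
        {
            "common_by_class_table": enr.table.tolist(),
            "common_by_class_odds_ratio": enr.odds_ratio,
            "common_by_class_p_fisher": enr.p_fisher,
            "common_by_class_p_chi2": enr.p_chi2,
        }
    )

    hwe_df = dev_df = None
    if vcf and panel_tsv:
        panel = hwe_mod.read_panel(panel_tsv)
        counts = hwe_mod.genotype_counts(vcf, panel)
        hwe_df = hwe_mod.hwe_table(counts, min_count=min_count)
        hwe_df.to_csv(os.path.join(outdir, "hwe.tsv"), sep="\t", index=False)
        dev_df = hwe_mod.deviation_summary(hwe_df, alpha=alpha)
        dev_df.to_csv(os.path.join(outdir, "hwe_summary.tsv"), sep="\t", index=False)
        dev_test = deviation_rate_test(missense, dev_df)
        summary.update(
            {
                "n_snps_deviating": int(dev_df["deviates"].sum()),
                "n_snps_deviating_multiple": int(dev_df["deviates_in_multiple"].sum()),
                "deviation_rate_p_fisher": dev_test.p_fisher,
            }
        )

    flags_df = None
    if scores_tsv:
        scores = pd.read_csv(scores_tsv, sep="\t")
        flagged = var_mod.flag_score_table(scores)
        flags_df = pd.DataFrame(
            {
                "variant_id": [f.variant_id for f in flagged],
                "flags": [",".join(sorted(f.flags)) for f in flagged],
                "n_methods_deleterious": [f.n_methods_deleterious for f in flagged],
            }
        )
        flags_df.to_csv(os.path.join(outdir, "flags.tsv"), sep="\t", index=False)
        _overlap, by_n = var_mod.count_method_agreement(flagged)
        summary["n_deleterious_ge1"] = sum(v for k, v in by_n.items() if k >= 1)
        summary["n_deleterious_all4"] = by_n[4]

    kl_df = None
    if pfm_manifest and os.path.exists(pfm_manifest):
        manifest = pd.read_csv(pfm_manifest, sep="\t")
        kl_df = spec_mod.kl_manifest(
            manifest, base_dir=os.path.dirname(os.path.abspath(pfm_manifest))
        )
        kl_df.to_csv(os.path.join(outdir, "kl.tsv"), sep="\t", index=False)
        summary["n_dramatic_shifts"] = int(
            (kl_df["summed"] > spec_mod.DRAMATIC_THRESHOLD).sum()
        )

    maf_df = maf_stratified_summary(annotated, flags_df, kl_df)
    maf_df.to_csv(os.path.join(outdir, "maf_summary.tsv"), sep="\t", index=False)

    log = {
        "parameters": {"alpha": alpha, "min_count": min_count},
        "inputs": {
            name: _digest(path)
            for name, path in [
                ("fasta", fasta),
                ("variants", variants_tsv),
                ("vcf", vcf),
                ("panel", panel_tsv),
                ("scores", scores_tsv),
                ("pfm_manifest", pfm_manifest),
            ]
            if path and os.path.exists(path)
        },
        "summary": {
            k: v for k, v in summary.items() if not isinstance(v, list)
        },
    }
    if sim_config is not None:
        log["simulation"] = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in vars(sim_config).items()
        }
    with open(os.path.join(outdir, "run_log.yaml"), "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True, default_flow_style=False)
    return summary
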