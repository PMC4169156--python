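"""Contingency tests, MAF binning, and end-to-end pipeline behavior."""

import itertools
import json
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from conftest import fisher_oracle
from scipy import stats

from zfvar.report import (
    common_by_class_test,
    deviation_rate_test,
    fisher_exact_2x2,
    maf_stratified_summary,
    run_pipeline,
)
from zfvar.simulate import SimConfig


def test_fisher_balanced_table_no_association():
    assert fisher_exact_2x2([[10, 10], [10, 10]]) == pytest.approx(1.0)


def test_fisher_extreme_table_vs_enumeration():
    got = fisher_exact_2x2([[1, 9], [9, 1]])
    assert got == pytest.approx(float(fisher_oracle(1, 9, 9, 1)), abs=1e-15)


def test_fisher_exhaustive_small_tables():
    """Every 2x2 table with total <= 14 equals the Fraction enumeration."""
    for n in range(15):
        for a, b, c in itertools.product(range(n + 1), repeat=3):
            d = n - a - b - c
            if d < 0:
                continue
            got = fisher_exact_2x2([[a, b], [c, d]])
            assert got == pytest.approx(float(fisher_oracle(a, b, c, d)), abs=1e-12)


@pytest.mark.parametrize("trial", range(30))
def test_fisher_agrees_with_scipy(trial):
    """Independent cross-check against scipy's implementation."""
    rng = np.random.default_rng(500 + trial)
    t = rng.integers(0, 60, size=(2, 2))
    ours = fisher_exact_2x2(t)
    _, scipy_p = stats.fisher_exact(t, alternative="two-sided")
    assert ours == pytest.approx(float(scipy_p), abs=1e-7)


def _variants(classes, commons, deviates=None, vids=None):
    n = len(classes)
    df = pd.DataFrame(
        {
            "variant_id": vids or [f"v{i}" for i in range(n)],
            "maf": [0.2 if c else 0.002 for c in commons],
            "position_class": classes,
            "is_common": commons,
        }
    )
    return df


def test_common_by_class_orientation():
    """Depletion of common variants at contacting positions gives OR < 1."""
    df = _variants(
        ["contacting"] * 20 + ["non_contacting"] * 20,
        [True] * 2 + [False] * 18 + [True] * 10 + [False] * 10,
    )
    res = common_by_class_test(df)
    assert res.table.tolist() == [[2, 18], [10, 10]]
    assert res.odds_ratio < 1
    assert res.p_fisher == pytest.approx(
        float(fisher_oracle(2, 18, 10, 10)), abs=1e-12
    )


def test_common_by_class_degenerate_empty_class():
    df = _variants(["contacting"] * 10, [True] * 5 + [False] * 5)
    res = common_by_class_test(df)
    assert res.degenerate
    assert res.p_fisher == 1.0


def test_deviation_rate_equal_proportions():
    df = _variants(
        ["contacting"] * 10 + ["non_contacting"] * 10,
        [True] * 20,
    )
    summary = pd.DataFrame(
        {
            "snp_id": [f"v{i}" for i in range(20)],
            "deviates": [i % 5 == 0 for i in range(20)],
        }
    )
    res = deviation_rate_test(df, summary)
    assert res.table.sum() == 20
    assert res.p_fisher == pytest.approx(1.0)


def test_deviation_rate_no_deviants_degenerate():
    df = _variants(["contacting"] * 5 + ["non_contacting"] * 5, [True] * 10)
    summary = pd.DataFrame({"snp_id": ["v0"], "deviates": [False]})
    res = deviation_rate_test(df, summary)
    assert res.degenerate
    assert res.p_fisher == 1.0


def test_maf_bin_floor():
    df = _variants(["contacting"] * 3, [False, False, True])
    df["maf"] = [0.0005, 0.002, 0.2]
    out = maf_stratified_summary(df)
    assert list(out["maf_bin"]) == ["<=0.001", "0.002", "0.2"]


def test_maf_summary_empty_join():
    df = _variants(["contacting"], [True])
    out = maf_stratified_summary(df, flags=pd.DataFrame(), kl=pd.DataFrame())
    assert "n_methods_deleterious" not in out.columns
    assert len(out) == 1


PIPE_CFG = SimConfig(
    seed=3, n_proteins=30, n_planted_arrays=10, n_variants=60,
    n_individuals=40, populations=("P1", "P2"),
    inbreeding_f=0.3, f_snp_fraction=0.2,
)


@pytest.fixture(scope="module")
def pipeline_run(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("pipe")
    summary = run_pipeline(str(outdir), sim_config=PIPE_CFG)
    return outdir, summary


def test_pipeline_counts_match_ground_truth(pipeline_run):
    outdir, summary = pipeline_run
    truth = json.loads((outdir / "inputs" / "truth.json").read_text())
    ann = pd.read_csv(outdir / "variants_annotated.tsv", sep="\t")
    assert len(ann) == len(truth["variant_classes"])
    for vid, cls in zip(ann["variant_id"], ann["position_class"]):
        assert truth["variant_classes"][vid] == cls
    assert summary["n_arrays"] == len(truth["arrays"])


def test_pipeline_margins_conserved(pipeline_run):
    outdir, summary = pipeline_run
    table = np.array(summary["common_by_class_table"])
    ann = pd.read_csv(outdir / "variants_annotated.tsv", sep="\t")
    missense = ann[
        (ann["effect"] == "missense")
        & ann["position_class"].isin(["contacting", "non_contacting"])
    ]
    assert table.sum() == len(missense)
    assert table[0].sum() == (missense["position_class"] == "contacting").sum()
    assert table[:, 0].sum() == missense["is_common"].sum()


def test_pipeline_outputs_exist(pipeline_run):
    outdir, _ = pipeline_run
    for name in (
        "fingers.tsv", "arrays.tsv", "variants_annotated.tsv", "hwe.tsv",
        "hwe_summary.tsv", "flags.tsv", "kl.tsv", "maf_summary.tsv",
        "run_log.yaml",
    ):
        assert (outdir / name).exists(), name


def test_pipeline_missing_manifest_skips_kl(tmp_path):
    inputs = tmp_path / "in"
    from zfvar.simulate import simulate_study

    simulate_study(replace(PIPE_CFG, seed=9), str(inputs))
    (inputs / "pfm_manifest.tsv").unlink()
    out = tmp_path / "out"
    summary = run_pipeline(
        str(out),
        fasta=str(inputs / "proteome.fa"),
        variants_tsv=str(inputs / "variants.tsv"),
        vcf=str(inputs / "genotypes.vcf"),
        panel_tsv=str(inputs / "panel.tsv"),
        scores_tsv=str(inputs / "scores.tsv"),
        pfm_manifest=str(inputs / "pfm_manifest.tsv"),
    )
    assert "n_dramatic_shifts" not in summary
    assert (out / "variants_annotated.tsv").exists()
    assert not (out / "kl.tsv").exists()
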