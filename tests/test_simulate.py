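"""Synthetic study generator: determinism, planted truth, genotype model."""

import json
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from zfvar.scan import scan_proteome
from zfvar.simulate import (
    GroundTruth,
    SimConfig,
    gen_cohort,
    gen_genotypes,
    gen_pfm_pair,
    gen_proteome,
    gen_scores,
    gen_variant_table,
    genotype_probs,
    simulate_study,
    write_vcf,
)
from zfvar.variants import METHODS, flag_deleterious

SMALL = SimConfig(
    seed=11, n_proteins=20, n_planted_arrays=6, n_variants=40,
    n_individuals=30, populations=("P1", "P2"),
)


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(fingers_per_array=2)
    with pytest.raises(ValueError):
        SimConfig(n_proteins=5, n_planted_arrays=6)
    with pytest.raises(ValueError):
        SimConfig(maf_spectrum=(0.7,))
    with pytest.raises(ValueError):
        SimConfig(deleterious_fraction=1.5)


def test_proteome_planted_counts_and_determinism():
    records, truth = gen_proteome(SMALL)
    assert len(records) == SMALL.n_proteins
    assert len(truth.arrays) == SMALL.n_planted_arrays
    assert all(a["n_fingers"] == SMALL.fingers_per_array for a in truth.arrays)
    records2, _ = gen_proteome(SMALL)
    assert records == records2  # same seed, identical output
    records3, _ = gen_proteome(replace(SMALL, seed=12))
    assert records != records3


def test_proteome_nothing_planted():
    cfg = replace(SMALL, n_planted_arrays=0)
    records, truth = gen_proteome(cfg)
    assert truth.arrays == []
    assert len(records) == cfg.n_proteins


def test_decoys_preserve_composition():
    records, truth = gen_proteome(SMALL)
    planted = dict(records)[truth.arrays[0]["protein_id"]]
    decoy = [seq for pid, seq in records if pid.startswith("DECOY")][0]
    assert sorted(decoy) == sorted(planted)
    assert decoy != planted


def test_planted_arrays_fully_recoverable():
    """The scanner finds every planted array with exact boundaries."""
    records, truth = gen_proteome(SMALL)
    _fingers, arrays_by = scan_proteome(records)
    found = {
        (pid, a.start, a.end) for pid, arrs in arrays_by.items() for a in arrs
    }
    planted = {(a["protein_id"], a["start"], a["end"]) for a in truth.arrays}
    assert planted <= found


def test_genotype_probs_model():
    hr, het, ha = genotype_probs(0.3, 0.2)
    assert het == pytest.approx(2 * 0.7 * 0.3 * 0.8)
    assert ha == pytest.approx(0.09 + 0.21 * 0.2)
    assert hr + het + ha == pytest.approx(1.0)


def test_genotype_f_bounds():
    with pytest.raises(ValueError):
        genotype_probs(0.3, -0.6)  # below -q/p = -3/7
    with pytest.raises(ValueError):
        genotype_probs(0.0, 0.0)  # maf must be positive


def test_full_inbreeding_no_heterozygotes(rng):
    g = gen_genotypes(rng, 0.4, 1.0, 500)
    assert (g == 1).sum() == 0


def test_het_fraction_within_binomial_error(rng):
    """f=0.2, maf=0.3: het fraction within 3 SE of 2*0.3*0.7*0.8 = 0.336."""
    n = 10000
    g = gen_genotypes(rng, 0.3, 0.2, n)
    p_het = 0.336
    se = np.sqrt(p_het * (1 - p_het) / n)
    assert abs((g == 1).mean() - p_het) < 3 * se


def test_variant_table_planted_counts():
    records, truth = gen_proteome(SMALL)
    df = gen_variant_table(
        SMALL, truth, dict(records),
        n_contacting=10, n_non_contacting=10, n_unknown=0, n_silent=0, n_other=0,
    )
    assert len(df) == 20
    classes = pd.Series(truth.variant_classes)
    assert (classes == "contacting").sum() == 10
    assert (classes == "non_contacting").sum() == 10
    # planted ref amino acids match the sequence
    seqs = dict(records)
    for row in df.itertuples(index=False):
        assert seqs[row.protein_id][row.residue_pos - 1] == row.ref_aa


def test_variant_table_empty_truth():
    df = gen_variant_table(SMALL, GroundTruth(), {})
    assert df.empty


def test_unknown_position_class_is_unknown():
    records, truth = gen_proteome(SMALL)
    gen_variant_table(
        SMALL, truth, dict(records),
        n_contacting=0, n_non_contacting=0, n_unknown=5, n_silent=0, n_other=0,
    )
    assert set(truth.variant_classes.values()) == {"unknown"}
    assert set(truth.variant_labels.values()) == {"4"}


def test_scores_planted_fractions_extremes():
    truth = GroundTruth()
    vids = [f"v{i}" for i in range(50)]
    all_del = gen_scores(
        replace(SMALL, deleterious_fraction=1.0, missing_score_rate=0.0),
        vids, truth,
    )
    for row in all_del.itertuples(index=False):
        assert flag_deleterious(
            {m: getattr(row, m) for m in METHODS}
        ) == frozenset(METHODS)
    none_del = gen_scores(
        replace(SMALL, deleterious_fraction=0.0, missing_score_rate=0.0),
        vids, truth,
    )
    for row in none_del.itertuples(index=False):
        assert flag_deleterious({m: getattr(row, m) for m in METHODS}) == frozenset()


def test_scores_single_method_fraction_recovered():
    """25% planted for SIFT only: flag count within binomial error of 0.25."""
    truth = GroundTruth()
    vids = [f"v{i}" for i in range(2000)]
    cfg = replace(SMALL, deleterious_fraction=0.0, missing_score_rate=0.0)
    df = gen_scores(
        cfg, vids, truth, per_method_fraction={"sift": 0.25}
    )
    frac = (df["sift"] < 0.05).mean()
    se = np.sqrt(0.25 * 0.75 / len(vids))
    assert abs(frac - 0.25) < 3 * se
    assert (df["polyphen2_hdiv"] > 0.95).sum() == 0


def test_scores_truth_matches_written_flags():
    truth = GroundTruth()
    vids = [f"v{i}" for i in range(300)]
    df = gen_scores(SMALL, vids, truth)
    for row in df.itertuples(index=False):
        got = flag_deleterious({m: getattr(row, m) for m in METHODS})
        assert sorted(got) == truth.deleterious[row.variant_id]


def test_pfm_pair_columns_normalized(rng):
    ref, var = gen_pfm_pair(rng, 0.5, width=6)
    np.testing.assert_allclose(ref.sum(axis=0), 1.0, atol=1e-9)
    np.testing.assert_allclose(var.sum(axis=0), 1.0, atol=1e-9)
    ref0, var0 = gen_pfm_pair(rng, 0.0)
    np.testing.assert_allclose(ref0, var0, atol=1e-15)


def test_cohort_planted_f_bookkeeping():
    records, truth = gen_proteome(SMALL)
    df = gen_variant_table(SMALL, truth, dict(records))
    cfg = replace(SMALL, inbreeding_f=0.4, f_snp_fraction=0.25)
    samples, panel, geno = gen_cohort(cfg, df, truth)
    assert geno.shape == (len(samples), len(df))
    assert set(panel.values()) == set(SMALL.populations)
    fs = pd.Series(truth.planted_f)
    assert (fs == 0.4).sum() == round(0.25 * len(df))
    assert ((fs == 0.0) | (fs == 0.4)).all()


def test_vcf_round_trip(tmp_path):
    """The emitted VCF reads back to the same genotype tallies."""
    from zfvar.hwe import genotype_counts

    records, truth = gen_proteome(SMALL)
    df = gen_variant_table(SMALL, truth, dict(records))
    samples, panel, geno = gen_cohort(SMALL, df, truth)
    path = tmp_path / "g.vcf"
    write_vcf(str(path), df, samples, geno)
    counts = genotype_counts(str(path), panel)
    by = {(c.snp_id, c.population): c for c in counts}
    j = 3  # arbitrary SNP column
    vid = df["variant_id"].iloc[j]
    for pop in SMALL.populations:
        mask = np.array([panel[s] == pop for s in samples])
        col = geno[mask, j]
        c = by[(vid, pop)]
        assert (c.n_hom_ref, c.n_het, c.n_hom_alt) == (
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum()),
        )


def test_simulate_study_reproducible_files(tmp_path):
    """Same config + seed produces byte-identical study directories."""
    d1, d2 = tmp_path / "a", tmp_path / "b"
    simulate_study(SMALL, str(d1))
    simulate_study(SMALL, str(d2))
    names = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
    assert names  # wrote something
    for name in names:
        assert (d1 / name).read_bytes() == (d2 / name).read_bytes(), name
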