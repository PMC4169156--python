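# zfvar

Analysis toolkit for missense variation at the DNA-contacting positions of
C2H2 zinc finger transcription factors.

Cys₂-His₂ (C2H2) zinc fingers are the most abundant DNA-binding modules in
the human proteome. Within each ~23-residue finger, the recognition
α-helix contacts DNA mainly through the residues at helix positions −1, 2,
3 and 6, while positions C2 (β-turn), −2, 1 and 5 face away from the DNA.
A missense variant at a contacting position can, in principle, retarget the
transcription factor to different genes; a variant at a non-contacting
position of similar sequence diversity should not. `zfvar` implements the
full comparative analysis of these two position classes:

* **Finger and array detection** — a pattern scanner for C2H2 repeats
  (`C-x(2,4)-C-x(11,14)-H-x(3,5)-H`) that scores inter-finger linkers for
  identity to the canonical TGEKP linker and assembles arrays of ≥ 3
  fingers, the strongest sequence-level predictor of DNA binding. Helix
  numbering is anchored on the first conserved His (helix position 7).
* **Variant mapping** — classifies each protein-level substitution by
  position label and class (contacting {−1, 2, 3, 6}, non-contacting
  {C2, −2, 1, 5}, otherwise unknown), by coding effect
  (missense/silent/other via codon translation), and by frequency
  (common ⇔ MAF ≥ 1%).
* **Hardy-Weinberg deviation** — per population, genotype counts
  (n_AA, n_Aa, n_aa) are tested against the HWE expectation
  p², 2pq, q² with a 1-df Pearson χ² and an exact conditional test
  (enumeration over heterozygote counts given the allele counts, computed
  in exact integer arithmetic). The heterozygote-excess statistic
  D = (O_het − E_het)/2 gives the direction: D < 0 means a homozygote was
  favored. Pairs with any genotype category below 5 are skipped.
* **Binding-specificity change** — between the reference and variant
  finger's position frequency matrices R and S, the summed
  Kullback-Leibler distance D(R‖S) + D(S‖R) with
  D(R‖S) = Σᵢ Rᵢ ln(Rᵢ/Sᵢ); summed KL > 2.5 is called a dramatic shift.
* **Enrichment reporting** — the headline 2×2 contrast (position class ×
  common/rare) via a two-sided Fisher exact test (exact fixed-margin
  enumeration) with χ² alongside, deviation-rate comparison between
  classes, and MAF-stratified summaries of prediction flags
  (SIFT < 0.05, PolyPhen2-HDIV > 0.95, MutationTaster > 0.90,
  FATHMM < −1.5) and KL distances.
* **Synthetic studies** — a generator that plants finger arrays among
  shuffled decoys, draws genotypes under an inbreeding coefficient f
  (P(het) = 2pq(1−f)), plants variant position classes, MAF spectra,
  per-method deleteriousness and PFM divergence — so every stage can be
  validated against known ground truth.

## Worked example

Simulate a study and run the whole pipeline (scan → map → HWE → KL →
report) in one call:

```sh
zfvar run --seed 1 --out demo/
```

prints (stdout):

```
n_proteins              200
n_proteins_with_arrays  50
n_arrays                50
n_variants              200
n_contacting            100
n_non_contacting        80
n_common                98
common_by_class_table   [[39, 41], [37, 43]]
common_by_class_odds_ratio  1.1054713249835202
common_by_class_p_fisher    0.8742780458794807
common_by_class_p_chi2      0.7515290794442091
n_snps_deviating        28
n_snps_deviating_multiple   6
deviation_rate_p_fisher 0.6529803143183439
n_deleterious_ge1       62
n_deleterious_all4      0
n_dramatic_shifts       30
```

Reading this: the scanner recovered all 50 planted finger arrays among 200
proteins; of the 200 planted variants, 100 sit at DNA-contacting and 80 at
non-DNA-contacting tracked positions (the rest are at untracked positions).
The 2×2 table rows are contacting/non-contacting, columns common/rare; the
default simulation plants no depletion (odds ratio ≈ 1, Fisher p ≈ 0.87),
and no inbreeding, so HWE deviations are the per-population false-positive
background. 62 variants are flagged deleterious by at least one of the four
methods, none by all four; 30 PFM pairs exceed summed KL 2.5.

Per-stage outputs land in `demo/`: `fingers.tsv`, `arrays.tsv`,
`variants_annotated.tsv`, `hwe.tsv`, `hwe_summary.tsv`, `flags.tsv`,
`kl.tsv`, `maf_summary.tsv` and a deterministic `run_log.yaml` (fixed-seed
runs are byte-identical). The generated inputs, including the ground-truth
JSON, are under `demo/inputs/`. Each stage is also exposed separately:
`zfvar simulate`, `zfvar scan`, `zfvar map`, `zfvar hwe`, `zfvar kl`,
`zfvar enrich`.

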