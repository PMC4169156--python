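"""Per-population Hardy-Weinberg equilibrium tests and heterozygote excess.

For each biallelic SNP and population the module tallies genotypes, then
tests the fit of (hom_ref, het, hom_alt) counts to the Hardy-Weinberg
expectation p^2 : 2pq : q^2 with allele frequencies estimated from the same
sample.  Two tests are reported: the 1-df Pearson chi-square, and the exact
conditional test that enumerates all heterozygote counts compatible with the
observed allele counts and sums the probabilities of outcomes no more likely
than the observed one.  The exact test is computed in exact integer
arithmetic (big-int configuration weights, rational p-value), so it agrees
with brute-force enumeration to machine precision at any sample size.

The heterozygote-excess diagnostic D = (observed het - expected het) / 2 is
positive when heterozygotes are over-represented (suggesting overdominance)
and negative when a homozygote is favored.

Following common practice for sparse genotype tables, a SNP/population pair
is skipped when any genotype category holds fewer than five individuals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping

import pandas as pd
from scipy import stats

__all__ = [
    "GenotypeCounts",
    "HWEResult",
    "read_panel",
    "genotype_counts",
    "hwe_chi2",
    "hwe_exact",
    "het_excess_d",
    "apply_skip_rule",
    "hwe_test",
    "hwe_table",
    "deviation_summary",
]


@dataclass(frozen=True)
class GenotypeCounts:
    snp_id: str
    population: str
    n_hom_ref: int
    n_het: int
    n_hom_alt: int
    n_missing: int = 0

    @property
    def n(self) -> int:
        return self.n_hom_ref + self.n_het + self.n_hom_alt

    @property
    def alt_count(self) -> int:
        return 2 * self.n_hom_alt + self.n_het


@dataclass
class HWEResult:
    counts: GenotypeCounts
    p_hat: float
    q_hat: float
    expected_het: float
    chi2_stat: float
    p_chi2: float
    p_exact: float
    d_het_excess: float
    skipped: bool
    skip_reason: str = ""
    monomorphic: bool = False


def read_panel(path: str) -> dict[str, str]:
    """Read a sample→population panel TSV (sample, population, extra cols ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return dict(zip(df[0], df[1]))


def genotype_counts(
    vcf_path: str, panel: Mapping[str, str]
) -> list[GenotypeCounts]:
    """Tally genotypes per (SNP, population) from a biallelic-SNP VCF.

    Every sample in the VCF must appear in the panel; missing genotypes are
    counted in ``n_missing`` and excluded from tests.  A multiallelic record
    raises with the record named.
    """
    from cyvcf2 import VCF

    vcf = VCF(vcf_path, gts012=True)
    samples = vcf.samples
    absent = [s for s in samples if s not in panel]
    if absent:
        raise ValueError(f"samples absent from panel: {absent[:5]}")
    pops = sorted(set(panel[s] for s in samples))
    pop_idx: dict[str, list[int]] = {p: [] for p in pops}
    for i, s in enumerate(samples):
        pop_idx[panel[s]].append(i)

    out: list[GenotypeCounts] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multiallelic record {rec.ID or rec.CHROM + ':' + str(rec.POS)}"
            )
        # gts012: 0=hom_ref, 1=het, 2=hom_alt, 3=missing
        gt = rec.gt_types
        snp_id = rec.ID or f"{rec.CHROM}:{rec.POS}"
        for pop in pops:
            idx = pop_idx[pop]
            sub = gt[idx]
            out.append(
                GenotypeCounts(
                    snp_id=snp_id,
                    population=pop,
                    n_hom_ref=int((sub == 0).sum()),
                    n_het=int((sub == 1).sum()),
                    n_hom_alt=int((sub == 2).sum()),
                    n_missing=int((sub == 3).sum()),
                )
            )
    return out


def hwe_chi2(counts: GenotypeCounts) -> tuple[float, float, bool]:
    """Pearson 1-df chi-square against HWE expectations.

    Returns ``(chi2_stat, p_value, monomorphic)``.  Monomorphic SNPs get
    p = 1 by convention.  No continuity correction is applied.
    """
    n = counts.n
    if n < 1:
        raise ValueError("no genotyped individuals")
    q = counts.alt_count / (2 * n)
    p = 1.0 - q
    if q == 0.0 or q == 1.0:
        return 0.0, 1.0, True
    expected = (p * p * n, 2 * p * q * n, q * q * n)
    observed = (counts.n_hom_ref, counts.n_het, counts.n_hom_alt)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    return chi2, float(stats.chi2.sf(chi2, df=1)), False


def _het_weights(n: int, alt: int) -> tuple[range, list[int]]:
    """Integer weights of every heterozygote count compatible with (n, alt).

    The weight of het count h is the number of genotype configurations times
    2^h: n! / (n_AA! h! n_aa!) * 2^h, an exact integer.  Probabilities are
    weights normalized by their sum (the allele-count marginal cancels).
    """
    rare = min(alt, 2 * n - alt)
    hets = range(rare % 2, rare + 1, 2)
    weights = [
        math.comb(n, h) * math.comb(n - h, (alt - h) // 2) * (1 << h) for h in hets
    ]
    return hets, weights


def hwe_exact(counts: GenotypeCounts) -> float:
    """Exact conditional HWE test p-value.

    Conditions on the observed allele counts and sums, over all heterozygote
    counts of matching parity, the null probabilities that do not exceed the
    observed outcome's probability (ties included).  Evaluated in exact
    integer/rational arithmetic.
    """
    n = counts.n
    if n < 1:
        raise ValueError("no genotyped individuals")
    hets, weights = _het_weights(n, counts.alt_count)
    w_obs = weights[list(hets).index(counts.n_het)]
    num = sum(w for w in weights if w <= w_obs)
    return float(Fraction(num, sum(weights)))


def het_excess_d(counts: GenotypeCounts) -> float:
    """Heterozygote excess D = (observed het - 2*p*q*n) / 2."""
    n = counts.n
    if n < 1:
        raise ValueError("no genotyped individuals")
    q = counts.alt_count / (2 * n)
    p = 1.0 - q
    return (counts.n_het - 2.0 * p * q * n) / 2.0


def apply_skip_rule(counts: GenotypeCounts, min_count: int = 5) -> bool:
    """True when any genotype category holds fewer than ``min_count``."""
    return min(counts.n_hom_ref, counts.n_het, counts.n_hom_alt) < min_count


def hwe_test(counts: GenotypeCounts, *, min_count: int = 5) -> HWEResult:
    """Full per-(SNP, population) HWE evaluation with the skip rule."""
    n = counts.n
    if n < 1:
        return HWEResult(
            counts, float("nan"), float("nan"), float("nan"),
            float("nan"), float("nan"), float("nan"), float("nan"),
            skipped=True, skip_reason="no genotyped individuals",
        )
    q = counts.alt_count / (2 * n)
    p = 1.0 - q
    exp_het = 2.0 * p * q * n
    d = het_excess_d(counts)
    skipped = apply_skip_rule(counts, min_count)
    if skipped:
        return HWEResult(
            counts, p, q, exp_het, float("nan"), float("nan"), float("nan"), d,
            skipped=True,
            skip_reason=f"genotype category below {min_count}",
            monomorphic=(q in (0.0, 1.0)),
        )
    chi2, p_chi2, mono = hwe_chi2(counts)
    p_exact = hwe_exact(counts)
    return HWEResult(
        counts, p, q, exp_het, chi2, p_chi2, p_exact, d,
        skipped=False, monomorphic=mono,
    )


def hwe_table(
    counts: list[GenotypeCounts], *, min_count: int = 5
) -> pd.DataFrame:
    """Run :func:`hwe_test` over all count records and tabulate."""
    rows = []
    for c in counts:
        r = hwe_test(c, min_count=min_count)
        rows.append(
            {
                "snp_id": c.snp_id,
                "population": c.population,
                "n_hom_ref": c.n_hom_ref,
                "n_het": c.n_het,
                "n_hom_alt": c.n_hom_alt,
                "n_missing": c.n_missing,
                "q_hat": r.q_hat,
                "expected_het": r.expected_het,
                "chi2_stat": r.chi2_stat,
                "p_chi2": r.p_chi2,
                "p_exact": r.p_exact,
                "d_het_excess": r.d_het_excess,
                "skipped": r.skipped,
                "monomorphic": r.monomorphic,
            }
        )
    return pd.DataFrame(rows)


def deviation_summary(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-SNP summary of HWE deviation across populations.

    For each SNP: populations tested (not skipped), populations deviating
    (exact p < alpha), whether it deviates in more than one population, and
    the fraction of deviating (SNP, population) pairs with D < 0.
    """
    rows = []
    for snp_id, grp in results.groupby("snp_id", sort=True):
        tested = grp[~grp["skipped"]]
        dev = tested[tested["p_exact"] < alpha]
        n_dev = len(dev)
        rows.append(
            {
                "snp_id": snp_id,
                "n_populations_tested": len(tested),
                "n_populations_deviating": n_dev,
                "deviates": n_dev >= 1,
                "deviates_in_multiple": n_dev > 1,
                "frac_deviating_d_negative": (
                    float((dev["d_het_excess"] < 0).mean()) if n_dev else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)
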