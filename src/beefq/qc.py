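"""Marker quality control: missingness, minor allele frequency, exact HWE test.

Filters are applied in a fixed order — missing rate > 0.1, MAF < 0.01, exact
Hardy-Weinberg p < 1e-8 — and a SNP is attributed to the first filter it
fails. The HWE test is the exact conditional test (sum of the probabilities of
all heterozygote configurations no more probable than the observed one, given
the allele counts), which stays calibrated at the extreme 1e-8 threshold where
the chi-square approximation does not. It is computed on all animals pooled;
in a mixed-breed cohort the Wahlund effect produces heterozygote deficits, so
the report carries a pooled-test caveat.

Residual missing genotypes in surviving SNPs are mean-imputed per SNP so the
downstream model sees a complete matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix

DEFAULT_THRESHOLDS = (0.1, 0.01, 1e-8)  # max missing, min MAF, min HWE p

FILTER_ORDER = ("missing", "maf", "hwe")


class QCError(RuntimeError):
    pass


@dataclass
class QCReport:
    """Per-SNP statistics and removal bookkeeping for one QC pass."""

    per_snp: pd.DataFrame  # snp_id, missing_rate, maf, hwe_p, removed_by
    removed_counts: dict
    surviving_snp_ids: list
    notes: str = (
        "HWE computed on all animals pooled; mixed-breed cohorts show a "
        "Wahlund heterozygote deficit that can inflate removals."
    )

    def __post_init__(self) -> None:
        n_removed = int((self.per_snp["removed_by"] != "").sum())
        if sum(self.removed_counts.values()) != n_removed:
            raise ValueError("removal counts do not sum to removed SNPs")


def snp_missing_rate(geno: GenotypeMatrix) -> np.ndarray:
    """Fraction of animals with a missing call, per SNP."""
    if geno.n_animals < 1:
        raise ValueError("need at least one animal")
    return geno.missing_mask.mean(axis=0)


def genotype_counts(geno: GenotypeMatrix) -> np.ndarray:
    """(n_snps, 3) counts of codes 0, 1, 2 among non-missing animals."""
    counts = np.empty((geno.n_snps, 3), dtype=np.int64)
    for c in (0, 1, 2):
        counts[:, c] = (geno.codes == c).sum(axis=0)
    return counts


def snp_maf(geno: GenotypeMatrix) -> np.ndarray:
    """Minor allele frequency per SNP over non-missing animals (NaN if all missing)."""
    counts = genotype_counts(geno)
    n_called = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (2 * counts[:, 2] + counts[:, 1]) / (2 * n_called)
    maf = np.minimum(p, 1.0 - p)
    maf[n_called == 0] = np.nan
    return maf


def hwe_test(n0: int, n1: int, n2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count whose conditional probability does not exceed the
    observed configuration's (two-sided).
    """
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n0 + n1 + n2
    if n < 1:
        raise ValueError("need at least one genotyped animal")
    # work with the rarer allele; swap so that allele "a" has count na <= n_alleles/2
    na = 2 * n2 + n1
    if na > n:  # na out of 2n alleles
        n0, n2 = n2, n0
        na = 2 * n2 + n1

    # P(het = h | allele count na) ∝ 2^h * (2n)! ... computed in log space
    hets = np.arange(na % 2, na + 1, 2)
    hom_a = (na - hets) // 2
    hom_b = n - hets - hom_a
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hom_a + 1)
        - gammaln(hets + 1)
        - gammaln(hom_b + 1)
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets == n1][0]
    # tolerance guards ties against floating-point noise
    return min(float(probs[probs <= obs * (1 + 1e-12)].sum()), 1.0)


def hwe_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    counts = genotype_counts(geno)
    out = np.ones(geno.n_snps)
    for j, (n0, n1, n2) in enumerate(counts):
        tot = n0 + n1 + n2
        out[j] = np.nan if tot == 0 else hwe_test(int(n0), int(n1), int(n2))
    return out


def mean_impute(geno: GenotypeMatrix) -> np.ndarray:
    """Complete dosage matrix: missing entries replaced by the SNP mean dosage."""
    X = geno.dosage()
    col_mean = np.nanmean(X, axis=0)
    idx = np.where(np.isnan(X))
    X[idx] = col_mean[idx[1]]
    return X


def apply_qc(
    geno: GenotypeMatrix,
    thresholds: tuple = DEFAULT_THRESHOLDS,
) -> tuple[GenotypeMatrix, np.ndarray, QCReport]:
    """Filter SNPs and mean-impute the survivors.

    Returns ``(filtered GenotypeMatrix, complete imputed dosage matrix, report)``.
    A SNP is attributed to the first filter it fails in the fixed order
    missingness -> MAF -> HWE; thresholds are (max_missing, min_maf, min_hwe_p)
    with the missing rule strict > and the other two strict <.
    """
    max_missing, min_maf, min_hwe_p = thresholds
    miss = snp_missing_rate(geno)
    maf = snp_maf(geno)
    hwe_p = hwe_pvalues(geno)

    removed_by = np.full(geno.n_snps, "", dtype=object)
    fail_miss = miss > max_missing
    fail_maf = (~fail_miss) & (np.isnan(maf) | (maf < min_maf))
    fail_hwe = (~fail_miss) & (~fail_maf) & (np.isnan(hwe_p) | (hwe_p < min_hwe_p))
    removed_by[fail_miss] = "missing"
    removed_by[fail_maf] = "maf"
    removed_by[fail_hwe] = "hwe"

    keep = removed_by == ""
    if not keep.any():
        raise QCError("no SNPs survive quality control")

    per_snp = pd.DataFrame(
        {
            "snp_id": geno.snp_meta["snp_id"].to_numpy(),
            "missing_rate": miss,
            "maf": maf,
            "hwe_p": hwe_p,
            "removed_by": removed_by,
        }
    )
    report = QCReport(
        per_snp=per_snp,
        removed_counts={f: int((removed_by == f).sum()) for f in FILTER_ORDER},
        surviving_snp_ids=per_snp.loc[keep, "snp_id"].tolist(),
    )
    filtered = geno.subset_snps(np.where(keep)[0])
    X = mean_impute(filtered)
    return filtered, X, report
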