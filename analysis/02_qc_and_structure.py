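#!/usr/bin/env python
"""Marker QC and breed-structure covariates for the simulated cohort.

Applies the three filters (missing rate > 0.1, MAF < 0.01, exact HWE
p < 1e-8), mean-imputes the survivors, builds the VanRaden/GCTA GRM, and
writes its first four principal components (the breed proxies) and each
animal's heterozygosity to CSV.
"""

import argparse
from pathlib import Path

from beefq.io import read_plink, write_run_summary
from beefq.qc import apply_qc
from beefq.structure import compute_grm, structure_covariates, write_grm


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/structure"))
    ap.add_argument("--max-missing", type=float, default=0.1)
    ap.add_argument("--min-maf", type=float, default=0.01)
    ap.add_argument("--hwe-p", type=float, default=1e-8)
    args = ap.parse_args()

    geno = read_plink(args.cohort_dir / "cohort.bed")
    filtered, X, report = apply_qc(
        geno, thresholds=(args.max_missing, args.min_maf, args.hwe_p)
    )
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    report.per_snp.to_csv(out / "qc_report.csv", index=False)

    cov = structure_covariates(filtered, k=4)
    cov.to_frame().to_csv(out / "covariates.csv", index=False)
    write_grm(compute_grm(X), filtered.animal_ids, out / "cohort")

    write_run_summary(
        out / "run_summary.json",
        snps_in=geno.n_snps, snps_out=filtered.n_snps,
        removed=report.removed_counts, notes=report.notes,
        pc_variance_proportions=list(map(float, cov.variance_proportions)),
    )
    print(f"QC: {geno.n_snps} -> {filtered.n_snps} SNPs "
          f"(removed {report.removed_counts})")
    print("PC variance proportions:",
          [round(float(v), 4) for v in cov.variance_proportions])


if __name__ == "__main__":
    main()
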