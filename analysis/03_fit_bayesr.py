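#!/usr/bin/env python
"""Fit the full BayesR model (Model 1) for one eating-quality trait.

Writes the SNP-effect table (posterior mean effect per A1 copy, PIP, mean
mixture component), the fixed-effect estimates, the variance/h2 trace for
MCMC diagnostics, and the heritability summary.
"""

import argparse
from pathlib import Path

import pandas as pd

from beefq.bayesr import BayesRConfig, heritability_summary
from beefq.io import read_phenotypes, read_plink, write_run_summary
from beefq.qc import apply_qc
from beefq.strategies import TrainingData, project_pcs, train_model1
from beefq.structure import heterozygosity


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort-dir", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out-dir", type=Path, default=Path("results/fit"))
    ap.add_argument("--trait", default="tender",
                    choices=["tender", "juicy", "flavor", "overall", "mq4"])
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-iter", type=int, default=8_000)
    ap.add_argument("--burn-in", type=int, default=2_000)
    ap.add_argument("--thin", type=int, default=3)
    args = ap.parse_args()

    geno = read_plink(args.cohort_dir / "cohort.bed")
    phen = read_phenotypes(args.cohort_dir / "phenotypes.csv")
    filtered, X, _ = apply_qc(geno)

    keep = phen.observed(args.trait)
    Z = X[keep]
    pcs, _ = project_pcs(Z, Z, k=4)
    df = phen.data.loc[keep]
    data = TrainingData(
        y=phen.trait(args.trait)[keep],
        cg=df["cg"].to_numpy(),
        days_aged=df["days_aged"].to_numpy(float),
        carcass_weight=df["carcass_weight"].to_numpy(float),
        pcs=pcs,
        het=heterozygosity(filtered)[keep],
        Z=Z,
    )
    cfg = BayesRConfig(n_iter=args.n_iter, burn_in=args.burn_in,
                       thin=args.thin, seed=args.seed)
    post = train_model1(data, cfg)

    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "snp_id": filtered.snp_meta["snp_id"],
            "chrom": filtered.snp_meta["chrom"],
            "pos": filtered.snp_meta["pos"],
            "effect_per_a1": post.mean_g,
            "pip": post.pip,
            "mean_component": post.mean_component,
        }
    ).to_csv(out / f"snp_effects_{args.trait}.csv", index=False)
    pd.DataFrame(
        {"term": post.fixed_names, "estimate": post.mean_beta}
    ).to_csv(out / f"fixed_effects_{args.trait}.csv", index=False)
    pd.DataFrame(
        {
            "sigma_g2": post.sigma_g2_samples,
            "sigma_e2": post.sigma_e2_samples,
            "h2": post.h2_samples,
            **{f"pi{k + 1}": post.pi_samples[:, k] for k in range(4)},
        }
    ).to_csv(out / f"variance_trace_{args.trait}.csv", index=False)

    h2_mean, h2_sd = heritability_summary(post)
    write_run_summary(
        out / f"run_summary_{args.trait}.json",
        seed=args.seed, trait=args.trait, n_train=len(data.y),
        n_snps=filtered.n_snps, retained_samples=post.n_retained,
        h2_mean=h2_mean, h2_sd=h2_sd,
        mean_pi=list(map(float, post.mean_pi)),
    )
    print(f"{args.trait}: h2 = {h2_mean:.3f} +- {h2_sd:.3f} "
          f"({post.n_retained} retained samples, {filtered.n_snps} SNPs)")
    print(f"posterior mean pi: {[round(float(p), 4) for p in post.mean_pi]}")


if __name__ == "__main__":
    main()
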