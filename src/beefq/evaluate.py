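"""Cross-validated accuracy, strategy comparison, and PIP-based discovery.

Accuracy is the Pearson correlation between a fold's predictions and the raw
clipped phenotypes of its masked animals, averaged over the five folds, with
SE = SD / sqrt(k). Strategies are compared by a paired two-sided t-test on
the fold-level correlations (k - 1 degrees of freedom) and summarised by
compact letters: strategies connected through non-significant pairs share a
letter. Discovery reports rank SNPs by posterior inclusion probability and
list annotated genes within a 1 Mb window either side of each top SNP.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bayesr import BayesRConfig
from .io import GenotypeMatrix, PhenotypeTable
from .structure import heterozygosity
from .strategies import TrainingData, predict, project_pcs, train_model1, train_model5


class FoldError(ValueError):
    pass


@dataclass
class CVResult:
    """Five-fold cross-validation output for one trait."""

    fold_labels: np.ndarray            # (n,) fold index per animal
    per_fold: pd.DataFrame             # fold, strategy, trait, r
    summary: pd.DataFrame              # strategy, trait, mean_accuracy, se
    train_hashes: dict = field(default_factory=dict)   # fold -> sha256 of training y
    train_indices: dict = field(default_factory=dict)  # fold -> training animal indices
    flagged_folds: list = field(default_factory=list)  # folds with undefined r

    def accuracy(self, strategy: int) -> tuple[float, float]:
        row = self.summary[self.summary["strategy"] == strategy]
        if row.empty:
            raise KeyError(f"strategy {strategy} not evaluated")
        return float(row["mean_accuracy"].iloc[0]), float(row["se"].iloc[0])

    def fold_correlations(self, strategy: int) -> np.ndarray:
        sub = self.per_fold[self.per_fold["strategy"] == strategy]
        return sub.sort_values("fold")["r"].to_numpy()


def make_folds(n: int, k: int = 5, seed: int = 0,
               stratify_by=None) -> np.ndarray:
    """Random fold labels 0..k-1 with sizes differing by at most one.

    ``stratify_by`` (e.g. contemporary-group labels) spreads each stratum
    across folds so small groups cannot land entirely in one fold; plain
    random grouping is the default.
    """
    if n < k:
        raise FoldError(f"cannot split {n} animals into {k} folds")
    rng = np.random.default_rng(seed)
    labels = np.empty(n, dtype=np.int64)
    if stratify_by is None:
        for f, chunk in enumerate(np.array_split(rng.permutation(n), k)):
            labels[chunk] = f
        return labels
    strata = np.asarray(stratify_by)
    if len(strata) != n:
        raise FoldError("stratify_by length must equal n")
    start = 0  # rotate fold assignment across strata to keep sizes even
    for s in pd.unique(strata):
        idx = rng.permutation(np.where(strata == s)[0])
        labels[idx] = (start + np.arange(len(idx))) % k
        start = (start + len(idx)) % k
    return labels


def mean_and_se(fold_r: np.ndarray) -> tuple[float, float]:
    """Mean fold correlation and SE = SD / sqrt(k) (sample SD)."""
    fold_r = np.asarray(fold_r, float)
    k = len(fold_r)
    sd = float(np.std(fold_r, ddof=1)) if k > 1 else 0.0
    return float(fold_r.mean()), sd / np.sqrt(k)


def cross_validate(
    geno: GenotypeMatrix | np.ndarray,
    phenotypes: PhenotypeTable,
    trait: str,
    strategies: tuple = (1, 2, 3, 4),
    k: int = 5,
    seed: int = 0,
    config: BayesRConfig | None = None,
    pca_mode: str = "projection",
) -> CVResult:
    """Five-fold CV of the requested prediction strategies for one trait.

    All strategies share the same folds (and, for strategies 1-3, the same
    Model-1 fit per fold). Animals missing the analysed trait are dropped
    from training for that trait; validation correlations use only animals
    with an observed score. ``pca_mode`` is ``"projection"`` (training-only
    PCA, validation animals projected) or ``"joint"`` (PCA on all animals at
    once, mirroring a single-cohort analysis).
    """
    if pca_mode not in ("projection", "joint"):
        raise ValueError("pca_mode must be 'projection' or 'joint'")
    config = config or BayesRConfig(seed=seed)
    Z_all = geno.codes.astype(float) if isinstance(geno, GenotypeMatrix) else np.asarray(geno, float)
    n = Z_all.shape[0]
    df = phenotypes.data
    if len(df) != n:
        raise ValueError("phenotype table and genotypes disagree on animal count")

    y_all = phenotypes.trait(trait)
    observed = np.isfinite(y_all)
    cg_all = df["cg"].to_numpy()
    days_all = df["days_aged"].to_numpy(float)
    cw_all = df["carcass_weight"].to_numpy(float)
    if isinstance(geno, GenotypeMatrix):
        het_all = heterozygosity(geno)
    else:  # imputed dosages: count entries that round to the het code
        het_all = (np.rint(Z_all).astype(int) == 1).mean(axis=1)

    folds = make_folds(n, k=k, seed=seed)
    if pca_mode == "joint":
        pcs_joint, _ = project_pcs(Z_all, Z_all, k=4)

    needs_m1 = any(s in (1, 2, 3) for s in strategies)
    needs_m5 = 4 in strategies
    rows, train_hashes, train_indices, flagged = [], {}, {}, []
    for f in range(k):
        val = folds == f
        train = (~val) & observed
        idx_train = np.where(train)[0]
        idx_val = np.where(val & observed)[0]
        if len(idx_val) < 3:
            flagged.append(f)
            continue
        if pca_mode == "joint":
            pcs_train = pcs_joint[idx_train]
            pcs_val = pcs_joint[idx_val]
        else:
            pcs_train, pcs_val = project_pcs(
                Z_all[idx_train], Z_all[idx_val], k=4
            )
        data = TrainingData(
            y=y_all[idx_train],
            cg=cg_all[idx_train],
            days_aged=days_all[idx_train],
            carcass_weight=cw_all[idx_train],
            pcs=pcs_train,
            het=het_all[idx_train],
            Z=Z_all[idx_train],
        )
        train_hashes[f] = hashlib.sha256(
            np.ascontiguousarray(data.y).tobytes()
        ).hexdigest()
        train_indices[f] = idx_train

        fold_cfg = config.with_(seed=config.seed + 1000 * f)
        post_m1 = train_model1(data, fold_cfg) if needs_m1 else None
        post_m5 = train_model5(data, fold_cfg) if needs_m5 else None

        y_val = y_all[idx_val]
        Z_val = Z_all[idx_val]
        for s in strategies:
            post = post_m5 if s == 4 else post_m1
            pred = predict(
                s, post, Z_val,
                days_aged=days_all[idx_val],
                carcass_weight=cw_all[idx_val],
                pcs=pcs_val,
                het=het_all[idx_val],
            )
            if np.std(pred.y_hat) == 0 or np.std(y_val) == 0:
                flagged.append(f)
                r = np.nan
            else:
                r = float(np.corrcoef(pred.y_hat, y_val)[0, 1])
            rows.append({"fold": f, "strategy": s, "trait": trait, "r": r})

    per_fold = pd.DataFrame(rows)
    summary_rows = []
    for s in strategies:
        r_vals = per_fold.loc[
            (per_fold["strategy"] == s) & per_fold["r"].notna(), "r"
        ].to_numpy()
        mean, se = mean_and_se(r_vals)
        summary_rows.append(
            {"strategy": s, "trait": trait, "mean_accuracy": mean, "se": se}
        )
    return CVResult(
        fold_labels=folds,
        per_fold=per_fold,
        summary=pd.DataFrame(summary_rows),
        train_hashes=train_hashes,
        train_indices=train_indices,
        flagged_folds=sorted(set(flagged)),
    )


def compare_strategies(cv: CVResult, strategy_a: int, strategy_b: int):
    """Paired two-sided t-test on fold-level correlations.

    Returns ``(p_value, note)``. Identical fold correlations give p = 1 (no
    difference); a constant nonzero difference (zero variance) is degenerate
    and reported as significant (p = 0) with a warning note.
    """
    ra = cv.fold_correlations(strategy_a)
    rb = cv.fold_correlations(strategy_b)
    if len(ra) != len(rb):
        raise ValueError("strategies were not evaluated on identical folds")
    d = ra - rb
    if np.allclose(d, 0.0):
        return 1.0, "identical fold correlations"
    if np.std(d, ddof=1) == 0.0:
        return 0.0, "constant nonzero fold difference: zero variance, degenerate t"
    t = stats.ttest_rel(ra, rb)
    return float(t.pvalue), ""


def grouping_letters(cv: CVResult, alpha: float = 0.05) -> dict:
    """Compact letter display: strategies connected through non-significant
    pairwise differences share a letter; letters ordered by mean accuracy."""
    strategies = sorted(cv.summary["strategy"].tolist())
    parent = {s: s for s in strategies}

    def find(s):
        while parent[s] != s:
            parent[s] = parent[parent[s]]
            s = parent[s]
        return s

    for i, a in enumerate(strategies):
        for b in strategies[i + 1:]:
            p, _ = compare_strategies(cv, a, b)
            if p >= alpha:
                parent[find(a)] = find(b)
    groups = {}
    for s in strategies:
        groups.setdefault(find(s), []).append(s)
    ordered = sorted(
        groups.values(), key=lambda g: np.mean([cv.accuracy(s)[0] for s in g])
    )
    letters = {}
    for letter, group in zip("abcdefgh", ordered):
        for s in group:
            letters[s] = letter
    return letters


# ---------------------------------------------------------------------------
# Discovery
# ---------------------------------------------------------------------------

def pip_table(geno: GenotypeMatrix, pip: np.ndarray) -> pd.DataFrame:
    """One row per SNP: id, chromosome, position, PIP (Manhattan data)."""
    if len(pip) != geno.n_snps:
        raise ValueError("PIP length does not match SNP count")
    return pd.DataFrame(
        {
            "snp_id": geno.snp_meta["snp_id"].to_numpy(),
            "chrom": geno.snp_meta["chrom"].to_numpy(),
            "pos": geno.snp_meta["pos"].to_numpy(),
            "pip": np.asarray(pip, float),
        }
    )


def top_snps(table: pd.DataFrame, n: int = 20) -> pd.DataFrame:
    """Top-n SNPs by PIP; ties broken by (chromosome, position) so the
    ranking is deterministic."""
    out = table.sort_values(
        ["pip", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
    ).head(n)
    return out.reset_index(drop=True)


def nearest_genes(
    top: pd.DataFrame, annotation: pd.DataFrame, window: int = 1_000_000
) -> dict:
    """Genes whose interval overlaps [pos - window, pos + window] (inclusive)
    for each top SNP, nearest first (distance 0 when the SNP lies inside)."""
    ann_chroms = set(annotation["chrom"].astype(str))
    snp_chroms = set(top["chrom"].astype(str))
    unmatched = sorted(snp_chroms - ann_chroms)
    if unmatched:
        raise ValueError(
            f"chromosome labels absent from the annotation: {unmatched}"
        )
    out = {}
    for _, snp in top.iterrows():
        sub = annotation[annotation["chrom"].astype(str) == str(snp["chrom"])]
        lo, hi = snp["pos"] - window, snp["pos"] + window
        hit = sub[(sub["end"] >= lo) & (sub["start"] <= hi)].copy()
        dist = np.where(
            (hit["start"] <= snp["pos"]) & (snp["pos"] <= hit["end"]),
            0,
            np.minimum(
                np.abs(hit["start"] - snp["pos"]), np.abs(hit["end"] - snp["pos"])
            ),
        )
        hit["distance"] = dist
        hit = hit.sort_values(["distance", "start"], kind="mergesort")
        out[snp["snp_id"]] = list(hit["gene"])
    return out
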