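"""Breed-structure covariates: genomic relationship matrix, its leading
principal components, and the heterozygosity (heterosis) covariate.

The GRM follows the VanRaden method-1 / GCTA default: columns of the dosage
matrix are standardised with the sample allele frequency, ``G = W W' / m``.
Its first principal components act as breed-composition proxies in a
multi-breed cohort (in this system PC1 tracks *Bos indicus* content), and the
per-animal proportion of heterozygous loci is the covariate whose regression
slope estimates heterosis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeMatrix


@dataclass
class StructureCovariates:
    """Per-animal PC scores, variance proportions and heterozygosity."""

    pcs: np.ndarray                  # (n_animals, k), columns scaled by sqrt(eigenvalue)
    variance_proportions: np.ndarray  # (k,) eigenvalue / trace(G)
    heterozygosity: np.ndarray        # (n_animals,) in [0, 1]
    animal_ids: list[str]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"pc{i + 1}": self.pcs[:, i] for i in range(self.pcs.shape[1])}
        return pd.DataFrame({"animal_id": self.animal_ids, **cols,
                             "het": self.heterozygosity})


def _dosage_matrix(geno) -> np.ndarray:
    if isinstance(geno, GenotypeMatrix):
        if geno.missing_mask.any():
            raise ValueError("genotypes must be complete (run QC/imputation first)")
        return geno.codes.astype(np.float64)
    return np.asarray(geno, dtype=np.float64)


def compute_grm(geno) -> np.ndarray:
    """VanRaden/GCTA method-1 GRM from a complete dosage matrix.

    ``G = W W' / m`` with column j of W equal to ``(x_j - 2 p_j) / sqrt(2 p_j
    (1 - p_j))`` using the sample frequency ``p_j``; fixed SNPs (p of 0 or 1)
    carry no information and are excluded from the average.
    """
    X = _dosage_matrix(geno)
    p = X.mean(axis=0) / 2.0
    seg = (p > 0) & (p < 1)
    if not seg.any():
        raise ValueError("no segregating SNPs; GRM undefined")
    Xs = X[:, seg]
    ps = p[seg]
    W = (Xs - 2 * ps) / np.sqrt(2 * ps * (1 - ps))
    return (W @ W.T) / seg.sum()


def grm_pca(G: np.ndarray, k: int = 4):
    """Top-k principal components of the GRM.

    Returns ``(scores, variance_proportions)`` where scores are eigenvectors
    scaled by the square root of their eigenvalues and each variance
    proportion is eigenvalue / trace(G). PC signs are fixed by forcing the
    largest-magnitude loading positive so regression coefficients are
    reproducible across runs.
    """
    G = np.asarray(G, dtype=np.float64)
    n = G.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds the number of animals n={n}")
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("GRM must be symmetric")
    evals, evecs = np.linalg.eigh(G)
    order = np.argsort(evals)[::-1][:k]
    evals_k = np.clip(evals[order], 0.0, None)
    vecs = evecs[:, order]
    for j in range(vecs.shape[1]):
        i_max = np.argmax(np.abs(vecs[:, j]))
        if vecs[i_max, j] < 0:
            vecs[:, j] = -vecs[:, j]
    scores = vecs * np.sqrt(evals_k)
    trace = np.trace(G)
    var_prop = evals_k / trace if trace > 0 else np.zeros(k)
    return scores, var_prop


def heterozygosity(geno) -> np.ndarray:
    """Proportion of heterozygous (code 1) loci per animal."""
    if isinstance(geno, GenotypeMatrix):
        if geno.missing_mask.any():
            raise ValueError("genotypes must be complete")
        codes = geno.codes
    else:
        codes = np.asarray(geno)
    return (codes == 1).mean(axis=1)


def structure_covariates(geno, k: int = 4) -> StructureCovariates:
    """GRM -> PCA -> heterozygosity in one pass over complete genotypes."""
    G = compute_grm(geno)
    scores, var_prop = grm_pca(G, k=k)
    het = heterozygosity(geno)
    ids = geno.animal_ids if isinstance(geno, GenotypeMatrix) else [
        str(i) for i in range(len(het))
    ]
    return StructureCovariates(
        pcs=scores, variance_proportions=var_prop,
        heterozygosity=het, animal_ids=list(ids),
    )


def write_grm(G: np.ndarray, animal_ids, prefix) -> None:
    """GRM as a long-form CSV triplet (i, j, value) over the lower triangle."""
    import pathlib

    prefix = pathlib.Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n = G.shape[0]
    i_idx, j_idx = np.tril_indices(n)
    pd.DataFrame(
        {
            "id1": [animal_ids[i] for i in i_idx],
            "id2": [animal_ids[j] for j in j_idx],
            "grm": G[i_idx, j_idx],
        }
    ).to_csv(prefix.with_suffix(".grm.csv"), index=False)
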