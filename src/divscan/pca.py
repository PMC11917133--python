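"""Genotype PCA quick-look for population-structure inspection."""

from __future__ import annotations

import numpy as np

from .io import MISSING, VariantTable


def pca_quicklook(vt: VariantTable, k: int = 2, standardize: bool = True):
    """Top-k principal components of the sample genotype matrix.

    Missing genotypes are mean-imputed per site; columns (sites) are
    centered and, when ``standardize``, scaled by sqrt(p(1-p)) with p the
    alternate-allele frequency — the usual genotype-PCA normalization.
    Returns ``(coords, var_frac)``: sample coordinates (n_samples x k) and
    the fraction of total variance captured by each component.
    """
    if vt.n_samples < 2 or vt.n_sites < 2:
        raise ValueError("PCA needs >= 2 samples and >= 2 sites")
    X = vt.genotypes.T.astype(float)  # samples x sites
    miss = X == MISSING
    X[miss] = np.nan
    mean = np.nanmean(X, axis=0)
    mean = np.where(np.isnan(mean), 0.0, mean)
    inds = np.where(np.isnan(X))
    X[inds] = mean[inds[1]]
    X = X - mean
    if standardize:
        p = mean / 2.0
        scale = np.sqrt(np.clip(p * (1.0 - p), 1e-12, None))
        X = X / scale
    # SVD of the centered matrix: PCs are U * S
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    total = (S**2).sum()
    k = min(k, len(S))
    coords = U[:, :k] * S[:k]
    var_frac = (S[:k] ** 2) / total if total > 0 else np.zeros(k)
    return coords, var_frac
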