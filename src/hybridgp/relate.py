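"""Population structure and relatedness of the parental panel.

Three views of the same genotype matrix: the VanRaden genomic relationship
matrix (kinship), an identity-by-state co-ancestry distance, and principal
components of the centered codes.  All operate on a complete (imputed)
matrix coded -1/0/+1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markers import GenotypeMatrix


@dataclass
class PCAResult:
    """PC scores per line and percent variance explained per component.

    ``variance_explained`` covers the requested components only;
    ``variance_explained_all`` spans the full spectrum and sums to 100.
    """

    scores: pd.DataFrame
    variance_explained: np.ndarray
    variance_explained_all: np.ndarray


def vanraden_kinship(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Genomic relationship matrix G = ZZ' / (2 * sum p_k (1 - p_k)).

    Dosages M in {0, 1, 2} come from the -1/0/+1 codes; Z centers each
    marker by twice its observed alternate-allele frequency p_k.  The
    scaling makes the average diagonal approach 1 + F for inbreeding F.
    Frequencies come from the analyzed panel itself.
    """
    if genotypes.has_missing():
        raise ValueError("kinship requires a complete (imputed) matrix")
    dosage = genotypes.codes + 1.0
    p = dosage.mean(axis=0) / 2.0
    denom = 2.0 * float(np.sum(p * (1.0 - p)))
    if denom == 0.0:
        raise ValueError("all markers monomorphic: VanRaden denominator is zero")
    z = dosage - 2.0 * p
    k = (z @ z.T) / denom
    return pd.DataFrame(k, index=genotypes.lines, columns=genotypes.lines)


def coancestry_distance(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise distance = 1 - mean proportion of alleles shared per marker.

    With codes x, y in {-1, 0, +1}, shared-allele proportion at a marker is
    1 - |x - y| / 2 (identical homozygotes share both alleles, opposite
    homozygotes none, a het/hom pair one of two).  Distances lie in [0, 1].
    """
    if genotypes.has_missing():
        raise ValueError("co-ancestry distance requires a complete matrix")
    codes = genotypes.codes
    n, m = codes.shape
    # mean |x_i - x_j| / 2 over markers, via the pairwise L1 distance
    dist = np.zeros((n, n))
    for i in range(n):
        dist[i] = np.abs(codes - codes[i]).sum(axis=1) / (2.0 * m)
    return pd.DataFrame(dist, index=genotypes.lines, columns=genotypes.lines)


def pca_genotypes(genotypes: GenotypeMatrix, n_components: int) -> PCAResult:
    """Principal components of the column-centered genotype codes.

    Uses the singular value decomposition of the centered matrix (no
    scaling); percent variance explained is the squared singular value over
    the total.  Scores are defined up to a sign per component.
    """
    if genotypes.has_missing():
        raise ValueError("PCA requires a complete (imputed) matrix")
    n, m = genotypes.codes.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 lines")
    max_rank = min(n - 1, m)
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components must be in [1, {max_rank}] for {n} lines x {m} markers"
        )
    centered = genotypes.codes - genotypes.codes.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    total = float(np.sum(s**2))
    varexp_all = 100.0 * s**2 / total
    scores = (u * s)[:, :n_components]
    cols = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=genotypes.lines, columns=cols),
        variance_explained=varexp_all[:n_components],
        variance_explained_all=varexp_all,
    )
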