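"""Genomic and pedigree relationship matrices (additive and dominance).

The additive genomic matrix uses centred-dosage standardization with the
distinct diagonal estimator; the dominance genomic matrix uses the
(-2p^2, 2pq, -2q^2) covariate coding with a sum-of-(2pq)^2 denominator, so it
is mutually consistent with the dominance coding used in the association
scan.  Pedigree matrices use the tabular method.
"""

from __future__ import annotations

import numpy as np

from .data import UNKNOWN_PARENT, GenotypeMatrix, Pedigree, PedigreeError, RelationshipMatrix

__all__ = [
    "grm_additive",
    "grm_dominance",
    "pedigree_additive",
    "pedigree_dominance",
    "dominance_coding",
]


def _check_polymorphic(p: np.ndarray) -> None:
    bad = (p <= 0.0) | (p >= 1.0)
    if bad.any():
        raise ValueError(
            f"{int(bad.sum())} monomorphic variant(s) present; run QC "
            "(filter_variants) before building relationship matrices"
        )


def grm_additive(geno: GenotypeMatrix) -> RelationshipMatrix:
    """Variant-based additive relationship matrix.

    Off-diagonal: mean over variants of (x_j - 2p)(x_k - 2p) / 2p(1-p).
    Diagonal: 1 + mean of (x^2 - (1+2p)x + 2p^2) / 2p(1-p).
    Missing dosages are mean-imputed with 2p.
    """
    p = geno.allele_freq()
    _check_polymorphic(p)
    x = geno.imputed_dosages()
    m = geno.n_variants
    het = 2.0 * p * (1.0 - p)
    z = (x - 2.0 * p) / np.sqrt(het)
    G = z @ z.T / m
    diag = 1.0 + ((x**2 - (1.0 + 2.0 * p) * x + 2.0 * p**2) / het).mean(axis=1)
    np.fill_diagonal(G, diag)
    return RelationshipMatrix(values=G, ids=list(geno.samples), kind="G_additive")


def dominance_coding(x: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Per-variant dominance covariate: (-2p^2, 2pq, -2q^2) for x = (0,1,2).

    Non-integer (imputed) dosages are mapped through the quadratic that
    interpolates those three points.
    """
    q = 1.0 - p
    w = np.where(x == 0, -2.0 * p**2, np.where(x == 1, 2.0 * p * q, -2.0 * q**2))
    frac = (x % 1) != 0
    if frac.any():
        P = np.broadcast_to(p, x.shape)
        w = np.where(frac, -2 * P**2 + 2 * P * x - x**2 / 2, w)
    return w


def grm_dominance(geno: GenotypeMatrix) -> RelationshipMatrix:
    """Variant-based dominance relationship matrix.

    D_jk = sum_i w_ij w_ik / sum_i (2 p_i q_i)^2 with w the dominance coding.
    """
    p = geno.allele_freq()
    _check_polymorphic(p)
    x = geno.imputed_dosages()
    w = dominance_coding(x, p)
    denom = float(np.sum((2.0 * p * (1.0 - p)) ** 2))
    D = w @ w.T / denom
    return RelationshipMatrix(values=D, ids=list(geno.samples), kind="D_dominance")


def pedigree_additive(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method (with inbreeding)."""
    order = ped.topological_order()  # raises PedigreeError on cycles
    idx = {a: i for i, a in enumerate(order)}
    parent_map = dict(
        zip(ped.records["animal"], zip(ped.records["sire"], ped.records["dam"]))
    )
    n = len(order)
    A = np.zeros((n, n))
    for i, animal in enumerate(order):
        sire, dam = parent_map[animal]
        si = idx.get(sire, -1) if sire != UNKNOWN_PARENT else -1
        di = idx.get(dam, -1) if dam != UNKNOWN_PARENT else -1
        if si >= i or di >= i:
            raise PedigreeError(f"pedigree ordering failure at {animal!r}")
        a_sd = A[si, di] if (si >= 0 and di >= 0) else 0.0
        A[i, i] = 1.0 + 0.5 * a_sd
        contrib = np.zeros(i)
        if si >= 0:
            contrib += 0.5 * A[si, :i]
        if di >= 0:
            contrib += 0.5 * A[di, :i]
        A[i, :i] = contrib
        A[:i, i] = contrib
    # return in original record order
    rows = np.array([idx[a] for a in ped.animals])
    return RelationshipMatrix(
        values=A[np.ix_(rows, rows)], ids=ped.animals, kind="A_pedigree"
    )


def pedigree_dominance(ped: Pedigree, A: RelationshipMatrix) -> RelationshipMatrix:
    """Pedigree dominance relationships (non-inbred approximation).

    d_jk = 0.25 (a(s_j,s_k) a(d_j,d_k) + a(s_j,d_k) a(d_j,s_k)) when both
    parents of both animals are known; otherwise 0 off-diagonal.  Diagonal 1.
    """
    A = A.align(ped.animals)
    idx = {a: i for i, a in enumerate(ped.animals)}
    parent_map = dict(
        zip(ped.records["animal"], zip(ped.records["sire"], ped.records["dam"]))
    )
    n = len(ped.animals)
    D = np.eye(n)
    pa = []
    for a in ped.animals:
        s, d = parent_map[a]
        si = idx.get(s, -1) if s != UNKNOWN_PARENT else -1
        di = idx.get(d, -1) if d != UNKNOWN_PARENT else -1
        pa.append((si, di))
    Av = A.values
    for j in range(n):
        sj, dj = pa[j]
        if sj < 0 or dj < 0:
            continue
        for k in range(j + 1, n):
            sk, dk = pa[k]
            if sk < 0 or dk < 0:
                continue
            d_jk = 0.25 * (Av[sj, sk] * Av[dj, dk] + Av[sj, dk] * Av[dj, sk])
            D[j, k] = D[k, j] = d_jk
    return RelationshipMatrix(values=D, ids=ped.animals, kind="D_pedigree")
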