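"""Variant quality control, stratification PCs, and LD-based test counting.

Filters follow the usual sequence-panel rules: call rate > 0.95, minor allele
frequency > 0.05, and an exact Hardy-Weinberg test kept at p >= 1e-6.  The
effective number of independent variants (Meff) comes from windowed pairwise
r^2 pruning, plink ``--indep-pairwise`` style.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .data import GenotypeMatrix, RelationshipMatrix

__all__ = [
    "QCReport",
    "hwe_exact_test",
    "filter_variants",
    "pca_from_grm",
    "effective_n_variants",
]


@dataclass
class QCReport:
    """Bookkeeping of a variant-filter pass; removed + retained = input."""

    n_input: int = 0
    n_removed_call_rate: int = 0
    n_removed_maf: int = 0
    n_removed_hwe: int = 0
    n_retained: int = 0
    per_animal_call_rate: dict[str, float] = field(default_factory=dict)

    @property
    def n_removed(self) -> int:
        return self.n_removed_call_rate + self.n_removed_maf + self.n_removed_hwe

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_input": self.n_input,
                    "n_removed_call_rate": self.n_removed_call_rate,
                    "n_removed_maf": self.n_removed_maf,
                    "n_removed_hwe": self.n_removed_hwe,
                    "n_retained": self.n_retained,
                    "per_animal_call_rate": self.per_animal_call_rate,
                },
                fh,
                indent=1,
            )


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg test (no mid-p correction).

    Conditional on the observed allele counts, sums the probabilities of all
    heterozygote configurations whose probability does not exceed that of the
    observed configuration.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # count of the rarer allele
    # possible het counts share parity with n_rare
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    if len(hets) == 0:
        return 1.0

    # unnormalized log-probabilities of P(n_Aa = h | allele counts)
    from scipy.special import gammaln

    rare_hom = (n_rare - hets) // 2
    com_hom = n - hets - rare_hom
    logp = (
        hets * np.log(2.0)
        + gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_hom + 1)
        - gammaln(com_hom + 1)
    )
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    obs = np.flatnonzero(hets == n_Aa)
    if len(obs) == 0:  # het count inconsistent with allele parity
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = prob[obs[0]]
    return float(min(prob[prob <= p_obs * (1 + 1e-12)].sum(), 1.0))


def filter_variants(
    geno: GenotypeMatrix,
    call_rate_min: float = 0.95,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the call-rate / MAF / HWE filters, in that order of attribution.

    Call-rate and MAF comparisons are strict (``>``); the HWE keep rule is
    ``p >= hwe_p_min``.  Monomorphic variants never pass the MAF rule.
    """
    report = QCReport(n_input=geno.n_variants)
    cr = geno.call_rate()
    p = geno.allele_freq()
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(np.isnan(maf), 0.0, maf)

    fail_cr = ~(cr > call_rate_min)
    fail_maf = ~fail_cr & ~(maf > maf_min)

    keep = ~fail_cr & ~fail_maf
    fail_hwe = np.zeros(geno.n_variants, dtype=bool)
    d = geno.dosages
    for j in np.flatnonzero(keep):
        col = d[:, j]
        col = col[~np.isnan(col)]
        n_aa = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_AA = int((col == 2).sum())
        if hwe_exact_test(n_AA, n_het, n_aa) < hwe_p_min:
            fail_hwe[j] = True
    keep &= ~fail_hwe

    report.n_removed_call_rate = int(fail_cr.sum())
    report.n_removed_maf = int(fail_maf.sum())
    report.n_removed_hwe = int(fail_hwe.sum())
    report.n_retained = int(keep.sum())
    report.per_animal_call_rate = dict(
        zip(geno.samples, np.round(geno.sample_call_rate(), 6).tolist())
    )
    if report.n_retained == 0:
        warnings.warn("all variants removed by QC filters", UserWarning)
    return geno.subset_variants(keep), report


def pca_from_grm(
    G: RelationshipMatrix, n_components: int = 20
) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of a relationship matrix.

    Returns ``(scores, variance_explained)`` where scores are eigenvectors
    scaled by the square root of their eigenvalues (columns ordered by
    decreasing eigenvalue) and variance fractions are eigenvalue / trace.
    """
    if n_components > G.n:
        raise ValueError(
            f"n_components={n_components} exceeds matrix order {G.n}"
        )
    vals, vecs = np.linalg.eigh(G.values)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    trace = vals.sum()
    frac = vals / trace if trace > 0 else np.full_like(vals, np.nan)
    top = np.clip(vals[:n_components], 0.0, None)
    scores = vecs[:, :n_components] * np.sqrt(top)
    return scores, frac[:n_components]


def effective_n_variants(
    geno: GenotypeMatrix,
    r2_max: float = 0.5,
    window: int = 5000,
    step: int = 500,
    return_index: bool = False,
):
    """Meff: variants surviving windowed greedy pairwise r^2 pruning.

    Within each window (slid by ``step`` variants) every surviving pair with
    squared dosage correlation above ``r2_max`` loses its lower-MAF member
    (ties: the later variant is removed).  Missing dosages enter the
    correlations mean-imputed.
    """
    if window < step:
        raise ValueError("window must be >= step")
    m = geno.n_variants
    if m == 0:
        return (0, np.array([], dtype=int)) if return_index else 0
    x = geno.imputed_dosages()
    sd = x.std(axis=0)
    z = np.where(sd > 0, (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0), 0.0)
    p = geno.allele_freq()
    maf = np.minimum(p, 1 - p)
    alive = np.ones(m, dtype=bool)

    n = x.shape[0]
    for start in range(0, max(m - step, 0) + 1, step):
        idx = np.flatnonzero(alive[start : start + window]) + start
        if len(idx) < 2:
            continue
        zz = z[:, idx]
        r2 = (zz.T @ zz / n) ** 2
        local_alive = np.ones(len(idx), dtype=bool)
        for a in range(len(idx)):
            if not local_alive[a]:
                continue
            hits = np.flatnonzero(local_alive & (r2[a] > r2_max))
            for b in hits[hits > a]:
                if not local_alive[a]:
                    break
                if not local_alive[b]:
                    continue
                ia, ib = idx[a], idx[b]
                if maf[ia] < maf[ib] or (maf[ia] == maf[ib] and ia > ib):
                    local_alive[a] = False
                else:
                    local_alive[b] = False
        alive[idx[~local_alive]] = False

    surviving = np.flatnonzero(alive)
    if return_index:
        return int(len(surviving)), surviving
    return int(len(surviving))
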