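"""Single-variant association with simultaneous additive and dominance terms.

Each variant is tested by generalized least squares against the covariance
V = sigma_g^2 G + sigma_e^2 I fitted once under the null model, with the
centred additive coding (x - 2p) and the dominance coding
(-2p^2, 2pq, -2q^2) entering the design jointly.  Wald chi-square statistics
with 1 df per component; genomic inflation from the chi-square median;
Bonferroni and suggestive thresholds from the effective number of
independent variants.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import GenotypeMatrix, RelationshipMatrix
from .kinship import dominance_coding
from .varcomp import VarCompResult

__all__ = [
    "Thresholds",
    "thresholds_from_meff",
    "inflation_factor",
    "assoc_scan",
    "assign_tiers",
    "manhattan_export",
    "CHI2_1_MEDIAN",
]

#: median of the chi-square distribution with 1 df (lambda denominator)
CHI2_1_MEDIAN = float(stats.chi2.median(1))


@dataclass
class Thresholds:
    meff: int
    alpha: float
    p_bonf: float
    p_sug: float

    @property
    def neg_log10_bonf(self) -> float:
        return -math.log10(self.p_bonf)

    @property
    def neg_log10_sug(self) -> float:
        return -math.log10(self.p_sug)

    def printed(self, decimals: int = 2) -> tuple[float, float]:
        """-log10 thresholds truncated (not rounded) to ``decimals`` places,
        the convention used when such thresholds are quoted in reports."""
        f = 10.0**decimals
        return (
            math.floor(self.neg_log10_bonf * f) / f,
            math.floor(self.neg_log10_sug * f) / f,
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "meff": self.meff,
                    "alpha": self.alpha,
                    "p_bonf": self.p_bonf,
                    "p_sug": self.p_sug,
                    "neg_log10_bonf": self.neg_log10_bonf,
                    "neg_log10_sug": self.neg_log10_sug,
                },
                fh,
                indent=1,
            )


def thresholds_from_meff(meff: int, alpha: float = 0.05) -> Thresholds:
    """Bonferroni (alpha/Meff) and suggestive (1/Meff) thresholds."""
    if meff < 1:
        raise ValueError("meff must be >= 1")
    return Thresholds(
        meff=int(meff), alpha=alpha, p_bonf=alpha / meff, p_sug=1.0 / meff
    )


def inflation_factor(chisq: np.ndarray) -> float:
    """Genomic inflation: median observed chi-square / chi-square(1) median."""
    chisq = np.asarray(chisq, float)
    chisq = chisq[~np.isnan(chisq)]
    if chisq.size == 0:
        raise ValueError("empty chi-square vector")
    return float(np.median(chisq) / CHI2_1_MEDIAN)


def _whitener(G: np.ndarray, sigma_g2: float, sigma_e2: float) -> np.ndarray:
    """Matrix T with T' T = V^-1, via one spectral decomposition of G.

    G may be slightly indefinite (distinct-diagonal estimator); eigenvalues
    are clipped only when V itself would lose positive definiteness.
    """
    vals, vecs = np.linalg.eigh(G)
    d = sigma_g2 * vals + sigma_e2
    if d.min() <= 1e-10:
        d = sigma_g2 * np.clip(vals, 0.0, None) + sigma_e2
    return (vecs / np.sqrt(d)).T


def assoc_scan(
    y: np.ndarray,
    X: np.ndarray,
    geno: GenotypeMatrix,
    G: RelationshipMatrix | np.ndarray | None,
    varcomp: VarCompResult,
    method: str = "spectral",
) -> pd.DataFrame:
    """Scan all variants for additive and dominance effects.

    Variance components are held fixed at the null fit.  Per variant the
    design [X | x_a | x_d] is fitted by GLS on whitened data; the residual
    variance of the weighted fit rescales the coefficient covariance, so with
    sigma_g^2 = 0 the scan reduces exactly to OLS t-statistics.  Variants
    with a missing genotype class (x_d collinear with X and x_a) report only
    the additive test; monomorphic variants are skipped.
    """
    y = np.asarray(y, float).ravel()
    X = np.asarray(X, float)
    n = len(y)
    comp = varcomp.components
    sigma_g2 = comp[next(k for k in varcomp.names if k != "residual")]
    sigma_e2 = comp["residual"]

    Gv = G.values if isinstance(G, RelationshipMatrix) else G
    if Gv is None or sigma_g2 <= 0:
        T = np.eye(n) / math.sqrt(sigma_e2)
    elif method == "spectral":
        T = _whitener(Gv, sigma_g2, sigma_e2)
    elif method == "direct":
        V = sigma_g2 * Gv + sigma_e2 * np.eye(n)
        L = np.linalg.cholesky(V)
        T = np.linalg.inv(L)
    else:
        raise ValueError(f"unknown method {method!r}")

    ty = T @ y
    tX = T @ X
    p_all = geno.allele_freq()
    x_all = geno.imputed_dosages()
    TXA = T @ (x_all - 2.0 * p_all)
    TXD = T @ dominance_coding(x_all, p_all)
    # a variant needs all three genotype classes for a separable dominance term
    n_classes = np.stack(
        [(np.round(x_all) == c).any(axis=0) for c in (0.0, 1.0, 2.0)]
    ).sum(axis=0)

    rows = []
    chi2 = stats.chi2(1)
    for j in range(geno.n_variants):
        p = p_all[j]
        meta = geno.variants.iloc[j]
        out = dict(
            CHR=str(meta["chrom"]), BP=int(meta["pos"]), ID=meta.get("id", ""),
            FREQ=float(p),
            BETA_A=np.nan, SE_A=np.nan, CHI2_A=np.nan, P_A=np.nan,
            BETA_D=np.nan, SE_D=np.nan, CHI2_D=np.nan, P_D=np.nan,
            NOTE="",
        )
        if not (0.0 < p < 1.0):
            out["NOTE"] = "monomorphic"
            rows.append(out)
            continue
        use_dom = n_classes[j] >= 3
        for attempt in range(2):
            if use_dom:
                M = np.column_stack([tX, TXA[:, j], TXD[:, j]])
            else:
                M = np.column_stack([tX, TXA[:, j]])
            MtM = M.T @ M
            try:
                MtM_inv = np.linalg.inv(MtM)
                if np.linalg.cond(MtM) > 1e10:
                    raise np.linalg.LinAlgError
                break
            except np.linalg.LinAlgError:
                if use_dom:
                    use_dom = False  # retry without the dominance column
                else:
                    MtM_inv = None
                    break
        if MtM_inv is None:
            out["NOTE"] = "additive collinear"
            rows.append(out)
            continue
        if not use_dom:
            out["NOTE"] = "dominance collinear"
        beta = MtM_inv @ (M.T @ ty)
        resid = ty - M @ beta
        dof = n - M.shape[1]
        s2 = float(resid @ resid) / dof if dof > 0 else np.nan
        cov = s2 * MtM_inv
        ia = tX.shape[1]
        out["BETA_A"] = float(beta[ia])
        out["SE_A"] = float(np.sqrt(cov[ia, ia]))
        out["CHI2_A"] = (out["BETA_A"] / out["SE_A"]) ** 2
        out["P_A"] = float(chi2.sf(out["CHI2_A"]))
        if use_dom:
            idd = ia + 1
            out["BETA_D"] = float(beta[idd])
            out["SE_D"] = float(np.sqrt(cov[idd, idd]))
            out["CHI2_D"] = (out["BETA_D"] / out["SE_D"]) ** 2
            out["P_D"] = float(chi2.sf(out["CHI2_D"]))
        rows.append(out)
    return pd.DataFrame(rows)


def assign_tiers(assoc: pd.DataFrame, thresholds: Thresholds) -> pd.DataFrame:
    """Add TIER_A / TIER_D columns: none | suggestive | bonferroni."""

    def tier(p: float) -> str:
        if p != p:
            return "none"
        if p <= thresholds.p_bonf:
            return "bonferroni"
        if p <= thresholds.p_sug:
            return "suggestive"
        return "none"

    out = assoc.copy()
    out["TIER_A"] = out["P_A"].map(tier)
    out["TIER_D"] = out["P_D"].map(tier)
    return out


def manhattan_export(
    assoc: pd.DataFrame, thresholds: Thresholds, figure_path=None
) -> pd.DataFrame:
    """Cumulative genome coordinates and -log10 p per component.

    Returns the plot-data table; when ``figure_path`` is given, renders a
    two-panel Manhattan figure (additive top, dominance bottom) with
    horizontal lines at both thresholds.
    """
    df = assign_tiers(assoc, thresholds)
    chroms = list(dict.fromkeys(df["CHR"]))
    offset = 0
    cum = np.zeros(len(df))
    ticks = {}
    for c in chroms:
        mask = (df["CHR"] == c).to_numpy()
        bp = df.loc[mask, "BP"].to_numpy(float)
        cum[mask] = bp + offset
        ticks[c] = offset + (bp.max() + bp.min()) / 2.0
        offset += bp.max() + 1
    df["CUMPOS"] = cum
    with np.errstate(divide="ignore"):
        df["NEGLOG10_P_A"] = -np.log10(df["P_A"])
        df["NEGLOG10_P_D"] = -np.log10(df["P_D"])

    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 1, figsize=(10, 6), sharex=True)
        for ax, col, label in zip(
            axes, ["NEGLOG10_P_A", "NEGLOG10_P_D"], ["additive", "dominance"]
        ):
            for i, c in enumerate(chroms):
                sub = df[df["CHR"] == c]
                ax.scatter(
                    sub["CUMPOS"], sub[col], s=4,
                    color="#1f77b4" if i % 2 == 0 else "#ff7f0e",
                )
            ax.axhline(thresholds.neg_log10_bonf, color="red", ls="-", lw=0.8)
            ax.axhline(thresholds.neg_log10_sug, color="red", ls=":", lw=0.8)
            ax.set_ylabel(f"-log10 p ({label})")
        axes[1].set_xticks(list(ticks.values()))
        axes[1].set_xticklabels(list(ticks.keys()), fontsize=6)
        axes[1].set_xlabel("chromosome")
        fig.tight_layout()
        fig.savefig(figure_path, dpi=150)
        plt.close(fig)
    return df
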