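"""Breeding-value prediction and summaries.

BLUP of additive effects at fixed (REML) variance components, Pearson
correlations among per-trait EBVs with significance stars, and descriptive
trait statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .varcomp import MixedModelSpec, VarCompResult

__all__ = [
    "blup_solve",
    "ebv_correlations",
    "descriptive_stats",
    "CorrelationTable",
]


def blup_solve(spec: MixedModelSpec, varcomp: VarCompResult) -> pd.DataFrame:
    """BLUP of the additive random effect at the fitted variance components.

    Solves b = (X'V^-1 X)^-1 X'V^-1 y and g_hat = sigma_g^2 K V^-1 (y - Xb)
    with V assembled from all fitted components.  Returns a frame with one
    EBV per animal in the relationship matrix.
    """
    y, X = spec.y, spec.X
    n = len(y)
    comp = varcomp.components
    V = comp["residual"] * np.eye(n)
    for name, K in spec.random:
        V += comp[name] * K
    try:
        c = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        cond = np.linalg.cond(V)
        raise np.linalg.LinAlgError(
            f"mixed-model coefficient matrix not positive definite "
            f"(condition number {cond:.3g}); check variance components"
        ) from exc
    Vinv_y = cho_solve(c, y)
    Vinv_X = cho_solve(c, X)
    beta = np.linalg.solve(X.T @ Vinv_X, X.T @ Vinv_y)
    resid_w = cho_solve(c, y - X @ beta)
    add_name, add_K = spec.random[0]
    ebv = comp[add_name] * (add_K @ resid_w)
    ids = spec.ids if spec.ids is not None else [str(i) for i in range(n)]
    return pd.DataFrame({"animal": ids, "ebv": ebv})


@dataclass
class CorrelationTable:
    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame

    def formatted(self, decimals: int = 2) -> str:
        """Upper-triangle text table with significance stars."""
        traits = list(self.r.columns)
        lines = ["\t" + "\t".join(traits[1:])]
        for i, t in enumerate(traits[:-1]):
            cells = []
            for j in range(1, len(traits)):
                if j <= i:
                    cells.append("")
                else:
                    cells.append(
                        f"{self.r.iloc[i, j]:.{decimals}f}{self.stars.iloc[i, j]}"
                    )
            lines.append(t + "\t" + "\t".join(cells))
        return "\n".join(lines)


def _stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def ebv_correlations(ebvs: pd.DataFrame, animals=None) -> CorrelationTable:
    """Pearson correlations among EBV columns over phenotyped animals.

    ``ebvs``: frame indexed by animal with one column per trait.  Pairwise
    complete observations; two-sided t-test (n-2 df) against r = 0.
    """
    if animals is not None:
        ebvs = ebvs.loc[[a for a in animals if a in ebvs.index]]
    traits = list(ebvs.columns)
    k = len(traits)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = ebvs[[traits[i], traits[j]]].dropna()
            if len(pair) < 3:
                raise ValueError(
                    f"need >= 3 common animals for {traits[i]}/{traits[j]}"
                )
            a, b = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if np.std(a) == 0 or np.std(b) == 0:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            rr, pp = stats.pearsonr(a, b)
            r[i, j] = r[j, i] = rr
            p[i, j] = p[j, i] = pp
    rdf = pd.DataFrame(r, index=traits, columns=traits)
    pdf = pd.DataFrame(p, index=traits, columns=traits)
    sdf = pdf.map(lambda v: "" if v != v else _stars(v))
    np.fill_diagonal(sdf.values, "")
    return CorrelationTable(r=rdf, p=pdf, stars=sdf)


def descriptive_stats(
    traits: pd.DataFrame, trait_cols, group: str = "group"
) -> pd.DataFrame:
    """Per-trait, per-group mean, SD, min, max and CV = SD/mean."""
    rows = []
    for name in trait_cols:
        for label, sub in traits.groupby(group, sort=False):
            vals = sub[name].dropna().to_numpy(float)
            if len(vals) == 0:
                continue
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
            if mean == 0.0:
                cv = 0.0 if sd == 0.0 else np.nan  # undefined, flagged as NaN
            else:
                cv = sd / mean
            rows.append(
                dict(
                    trait=name, group=label, mean=mean, sd=sd,
                    min=float(vals.min()), max=float(vals.max()), cv=cv,
                )
            )
    return pd.DataFrame(rows)
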