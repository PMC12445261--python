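"""REML variance components with average-information updates.

Fits y = Xb + sum_k u_k + e with u_k ~ N(0, K_k sigma_k^2) and
e ~ N(0, I sigma_e^2) by restricted maximum likelihood.  Average-information
steps with monotone line search and an EM fallback; standard errors from the
inverse AI matrix; heritability ratios by the delta method; observed-scale
heritabilities of binary traits convertible to the liability scale.

When exactly one genomic matrix is present the model is rotated into the
eigenbasis of that matrix once, which makes each REML iteration O(n p^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import cho_factor, cho_solve

from .data import RelationshipMatrix

__all__ = [
    "MixedModelSpec",
    "VarCompResult",
    "build_design",
    "reml_fit",
    "heritability",
    "dominance_fraction",
    "liability_transform",
]


def build_design(
    table: pd.DataFrame,
    covariates: Sequence[str] = ("sex", "birth_type", "parity"),
    qcovariates: Sequence[str] = (),
    add_intercept: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effect design matrix: intercept + reference-coded class effects
    + continuous covariates.  Collinear columns are dropped."""
    cols: list[np.ndarray] = []
    names: list[str] = []
    if add_intercept:
        cols.append(np.ones(len(table)))
        names.append("intercept")
    for c in covariates:
        dummies = pd.get_dummies(table[c].astype("category"), prefix=c, drop_first=True)
        for name in dummies.columns:
            cols.append(dummies[name].to_numpy(float))
            names.append(str(name))
    for c in qcovariates:
        cols.append(table[c].to_numpy(float))
        names.append(str(c))
    X = np.column_stack(cols) if cols else np.empty((len(table), 0))
    # greedy rank pruning keeps the earliest independent columns
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
    return X[:, keep], [names[j] for j in keep]


@dataclass
class MixedModelSpec:
    """One single-trait mixed model: response, fixed design, random kernels."""

    y: np.ndarray
    X: np.ndarray
    random: list[tuple[str, np.ndarray]]  # (name, relationship matrix values)
    scale: str = "gaussian"  # gaussian | count-as-gaussian | binary-observed
    ids: Optional[list[str]] = None
    prevalence: Optional[float] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.y):
            raise ValueError("X must be n x p with n = len(y)")
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ValueError("fixed-effect design X is rank deficient")
        rnd = []
        for name, K in self.random:
            Kv = K.values if isinstance(K, RelationshipMatrix) else np.asarray(K, float)
            if Kv.shape != (len(self.y), len(self.y)):
                raise ValueError(f"random kernel {name!r} order mismatch with y")
            rnd.append((name, Kv))
        self.random = rnd
        if self.scale not in ("gaussian", "count-as-gaussian", "binary-observed"):
            raise ValueError(f"unknown trait scale {self.scale!r}")


@dataclass
class VarCompResult:
    """REML estimates; component order is (genomic terms..., residual)."""

    names: list[str]
    estimates: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    scale: str = "gaussian"
    prevalence: Optional[float] = None
    case_proportion: Optional[float] = None
    at_bound: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, float)
        self.se = np.asarray(self.se, float)
        if self.at_bound is None:
            self.at_bound = np.zeros(len(self.estimates), dtype=bool)

    @classmethod
    def from_components(
        cls,
        components: dict[str, float],
        se: Optional[dict[str, float]] = None,
        scale: str = "gaussian",
        prevalence: Optional[float] = None,
        case_proportion: Optional[float] = None,
    ) -> "VarCompResult":
        """Build a result from already-known variance components (e.g. for
        worked examples or external fits)."""
        names = list(components)
        est = np.array([components[k] for k in names], float)
        ses = np.array([(se or {}).get(k, np.nan) for k in names], float)
        return cls(
            names=names, estimates=est, se=ses, cov=np.diag(ses**2),
            loglik=np.nan, converged=True, n_iter=0, scale=scale,
            prevalence=prevalence, case_proportion=case_proportion,
        )

    @property
    def components(self) -> dict[str, float]:
        return dict(zip(self.names, self.estimates.tolist()))

    @property
    def sigma_p2(self) -> float:
        """Phenotypic variance: the sum of all fitted components."""
        return float(self.estimates.sum())

    def _index(self, name: str) -> int:
        return self.names.index(name)

    def ratio(self, name: str) -> tuple[float, float]:
        """Component / sigma_p2 with a delta-method standard error."""
        sp = self.sigma_p2
        if sp <= 0:
            raise ValueError("sigma_p2 <= 0; ratio undefined")
        i = self._index(name)
        r = self.estimates[i] / sp
        grad = np.full(len(self.estimates), -self.estimates[i] / sp**2)
        grad[i] += 1.0 / sp
        var = float(grad @ self.cov @ grad) if np.isfinite(self.cov).all() else np.nan
        return float(r), float(np.sqrt(var)) if var == var else np.nan

    def format_components(self, decimals: int = 2) -> dict[str, str]:
        """Printed-style components: bound-constrained zeros show as '<0.00'."""
        out = {}
        for name, est, bound in zip(self.names, self.estimates, self.at_bound):
            out[name] = "<0.00" if bound else f"{est:.{decimals}f}"
        return out


# ---------------------------------------------------------------------------
# internal REML state machinery
# ---------------------------------------------------------------------------


class _DenseModel:
    """Generic multi-kernel REML workspace (dense algebra)."""

    def __init__(self, y, X, Ks):
        self.y, self.X, self.Ks = y, X, Ks
        self.n, self.p = X.shape
        self.k = len(Ks) + 1  # + residual

    def state(self, theta):
        n = self.n
        V = theta[-1] * np.eye(n)
        for t, K in zip(theta[:-1], self.Ks):
            V += t * K
        try:
            c = cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            V[np.diag_indices(n)] += 1e-6 * np.trace(V) / n
            c = cho_factor(V, lower=True)
        logdet_v = 2.0 * np.log(np.diag(c[0])).sum()
        Vinv = cho_solve(c, np.eye(n))
        VinvX = Vinv @ self.X
        XtVX = self.X.T @ VinvX
        sign, logdet_x = np.linalg.slogdet(XtVX)
        P = Vinv - VinvX @ np.linalg.solve(XtVX, VinvX.T)
        Py = P @ self.y
        ll = -0.5 * (logdet_v + logdet_x + float(self.y @ Py))

        KPy = [K @ Py for K in self.Ks] + [Py]
        trPK = [float(np.sum(P * K)) for K in self.Ks] + [float(np.trace(P))]
        score = np.array(
            [
                -0.5 * (trPK[i] - float(Py @ KPy[i]))
                for i in range(self.k)
            ]
        )
        PKPy = [P @ v for v in KPy]
        AI = 0.5 * np.array(
            [[float(KPy[i] @ PKPy[j]) for j in range(self.k)] for i in range(self.k)]
        )
        return ll, score, AI, np.array([float(Py @ v) for v in KPy]), np.array(trPK)


class _SpectralModel:
    """Single genomic kernel + residual, rotated into the kernel eigenbasis."""

    def __init__(self, y, X, K):
        vals, vecs = np.linalg.eigh(K)
        self.lam = np.clip(vals, 0.0, None)
        self.y = vecs.T @ y
        self.X = vecs.T @ X
        self.n, self.p = self.X.shape
        self.k = 2

    def state(self, theta):
        d = theta[0] * self.lam + theta[1]
        d = np.maximum(d, 1e-12)
        w = 1.0 / d
        wX = w[:, None] * self.X
        XtWX = self.X.T @ wX
        cx = cho_factor(XtWX)
        beta_rhs = wX.T @ self.y

        def P_apply(u):
            wu = w * u
            return wu - wX @ cho_solve(cx, self.X.T @ wu)

        Py = P_apply(self.y)
        sign, logdet_x = np.linalg.slogdet(XtWX)
        ll = -0.5 * (np.log(d).sum() + logdet_x + float(self.y @ Py))

        kernels = [self.lam, np.ones(self.n)]
        XtWX_inv = cho_solve(cx, np.eye(self.p))
        score = np.empty(2)
        trPK = np.empty(2)
        yPKPy = np.empty(2)
        KPy = [c * Py for c in kernels]
        for i, c in enumerate(kernels):
            M = self.X.T @ ((w**2 * c)[:, None] * self.X)
            trPK[i] = float((w * c).sum() - np.sum(XtWX_inv * M))
            yPKPy[i] = float(Py @ KPy[i])
            score[i] = -0.5 * (trPK[i] - yPKPy[i])
        PKPy = [P_apply(v) for v in KPy]
        AI = 0.5 * np.array(
            [[float(KPy[i] @ PKPy[j]) for j in range(2)] for i in range(2)]
        )
        return ll, score, AI, yPKPy, trPK


def reml_fit(
    spec: MixedModelSpec,
    max_iter: int = 100,
    tol: float = 1e-8,
    algorithm: str = "ai-em",
    constrain: bool = True,
) -> VarCompResult:
    """AI-REML with EM fallback (``algorithm``: ``ai``, ``em`` or ``ai-em``).

    Components are constrained to a small positive bound when ``constrain``;
    estimates pinned at the bound are flagged.  Non-convergence returns the
    last iterate flagged ``converged=False``.
    """
    alg = algorithm.lower().replace("_", "-")
    alias = {"ai-with-em-fallback": "ai-em"}
    alg = alias.get(alg, alg)
    if alg not in ("ai", "em", "ai-em"):
        raise ValueError(f"unknown algorithm {algorithm!r}")

    y, X = spec.y, spec.X
    Ks = [K for _, K in spec.random]
    names = [name for name, _ in spec.random] + ["residual"]
    vary = float(np.var(y))
    if vary <= 0:
        raise ValueError("response has zero variance")
    bound = 1e-8 * vary if constrain else 1e-12 * vary

    model = _SpectralModel(y, X, Ks[0]) if len(Ks) == 1 else _DenseModel(y, X, Ks)
    k = len(Ks) + 1
    theta = np.full(k, vary / k)

    ll, score, AI, yPKPy, trPK = model.state(theta)
    converged = False
    n_done = 0
    for it in range(max_iter):
        n_done = it + 1
        # active set: a component pinned at the bound whose score pushes it
        # further negative stays fixed this iteration
        free = ~((theta <= bound * 1.5) & (score < 0.0))
        if not free.any():
            converged = True
            break
        use_ai = alg in ("ai", "ai-em") and (alg == "ai" or it >= 1)
        delta = np.zeros_like(theta)
        solved = False
        if use_ai:
            try:
                delta[free] = np.linalg.solve(
                    AI[np.ix_(free, free)], score[free]
                )
                solved = True
            except np.linalg.LinAlgError:
                if alg == "ai":
                    raise
        if not solved:  # EM step (guaranteed uphill)
            delta[free] = (theta**2 * (yPKPy - trPK) / model.n)[free]

        accepted = False
        step = 1.0
        for _ in range(8):
            cand = np.maximum(theta + step * delta, bound)
            cand_ll, c_score, c_AI, c_yPKPy, c_trPK = model.state(cand)
            if cand_ll >= ll - 1e-10:
                accepted = True
                break
            step *= 0.5
        if not accepted and alg != "em":
            delta = np.zeros_like(theta)
            delta[free] = (theta**2 * (yPKPy - trPK) / model.n)[free]
            cand = np.maximum(theta + delta, bound)
            cand_ll, c_score, c_AI, c_yPKPy, c_trPK = model.state(cand)

        change = np.max(np.abs(cand - theta))
        theta, ll, score, AI, yPKPy, trPK = (
            cand, cand_ll, c_score, c_AI, c_yPKPy, c_trPK,
        )
        if change < tol * max(vary, 1.0):
            converged = True
            break

    try:
        cov = np.linalg.inv(AI)
    except np.linalg.LinAlgError:
        cov = np.full((k, k), np.nan)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    case_prop = None
    prevalence = spec.prevalence
    if spec.scale == "binary-observed":
        case_prop = float(np.mean(y))
    return VarCompResult(
        names=names,
        estimates=theta,
        se=se,
        cov=cov,
        loglik=ll,
        converged=converged,
        n_iter=n_done,
        scale=spec.scale,
        prevalence=prevalence,
        case_proportion=case_prop,
        at_bound=theta <= bound * 1.5,
    )


def heritability(result: VarCompResult) -> tuple[float, float]:
    """h2 = additive component / phenotypic variance, delta-method SE.

    The additive component is the first non-residual component.
    """
    name = next(n for n in result.names if n != "residual")
    return result.ratio(name)


def dominance_fraction(result: VarCompResult) -> float:
    """Dominance share of phenotypic variance, as a percentage."""
    dom = [n for n in result.names if n.lower() in ("d", "dom", "dominance")]
    if not dom:
        raise ValueError("fit does not include a dominance component")
    r, _ = result.ratio(dom[0])
    return 100.0 * r


def liability_transform(h2_observed: float, K: float, P: Optional[float] = None) -> float:
    """Observed-scale to liability-scale heritability for a binary trait.

    h2_liab = h2_obs * [K(1-K)/z^2] * [K(1-K)/(P(1-P))] with z the standard
    normal density at the threshold Phi^-1(1-K).  With P = K (no case-control
    ascertainment) this reduces to h2_obs * K(1-K)/z^2.
    """
    if P is None:
        P = K
    if not (0.0 < K < 1.0) or not (0.0 < P < 1.0):
        raise ValueError("K and P must lie strictly inside (0, 1)")
    z = stats.norm.pdf(stats.norm.ppf(1.0 - K))
    factor = (K * (1.0 - K) / z**2) * (K * (1.0 - K) / (P * (1.0 - P)))
    return h2_observed * factor
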