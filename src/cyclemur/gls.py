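"""Generalized least squares with a joint phylogenetic-spatial correlation.

Closely related species resemble each other through descent, and species
living near one another resemble each other through shared environment.
A comparative regression must correct for both.  The error correlation is
modelled as a convex blend

    R = lambda_p * P  +  phi_s * S  +  (1 - lambda_p - phi_s) * I

where P is the phylogenetic correlation (shared root-to-MRCA path length as
a fraction of tree depth, from the maximum clade credibility tree of a
posterior sample), S is a spatial distance-decay correlation
S_ij = (1 - delta)^{D_ij} on range-centroid distances D normalised to the
study extent, and I is independent noise.  The three structure parameters —
total autocorrelation AC = lambda_p + phi_s, its phylogenetic share
prop_phylo = lambda_p / AC, and the decay delta (fractional loss of spatial
correlation per unit distance) — are estimated by maximum likelihood with a
derivative-free simplex on an unconstrained logistic reparameterisation,
profiling out the regression coefficients and the variance analytically.

Model comparison uses AICc with Akaike weights and relative likelihoods;
nested models are compared by likelihood-ratio tests.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, logit

from .errors import AlignmentError, DomainError

_JITTER = 1e-10  # diagonal guard for numerically semi-definite R


@dataclass
class CorrelationModel:
    """Weights of the convex correlation blend.

    lambda_p, phi_s in [0, 1) with lambda_p + phi_s <= 1; delta in [0, 1).
    """

    lambda_p: float
    phi_s: float
    delta: float

    def __post_init__(self) -> None:
        if not (0 <= self.lambda_p < 1 and 0 <= self.phi_s < 1):
            raise DomainError("lambda_p and phi_s must lie in [0, 1)")
        if self.lambda_p + self.phi_s > 1 + 1e-12:
            raise DomainError("lambda_p + phi_s must not exceed 1")
        if not 0 <= self.delta < 1:
            raise DomainError("delta must lie in [0, 1)")


@dataclass
class GLSFit:
    """A fitted GLS model with its autocorrelation-structure estimates."""

    beta: np.ndarray
    se: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df: int
    sigma2: float
    logLik: float
    n: int
    k: int
    model: CorrelationModel
    names: list[str] = field(default_factory=list)
    formula: str = ""
    aicc: float = math.nan
    degenerate: bool = False

    @property
    def AC(self) -> float:
        return self.model.lambda_p + self.model.phi_s

    @property
    def prop_phylo(self) -> float:
        return 0.0 if self.AC == 0 else self.model.lambda_p / self.AC

    @property
    def delta(self) -> float:
        return self.model.delta

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se, "t": self.t, "df": self.df, "p": self.p},
            index=self.names or [f"x{i}" for i in range(len(self.beta))],
        )


# ---------------------------------------------------------------------------
# tree operations


def _clade_keys(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial clades (tip-label sets) of a rooted tree."""
    keys: set[frozenset[str]] = set()
    for node in tree.preorder_internal_node_iter():
        tips = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(tips) < len(tree.leaf_nodes()) or node is tree.seed_node:
            keys.add(tips)
    # drop the root clade (all tips): frequency 1 in every tree, no signal
    all_tips = frozenset(lf.taxon.label for lf in tree.leaf_nodes())
    keys.discard(all_tips)
    return keys


def mcc_tree(trees: list[dendropy.Tree]) -> dendropy.Tree:
    """Maximum clade credibility tree of a posterior sample.

    Each tree is scored by the sum over its internal clades of the log of
    that clade's frequency in the sample; the highest-scoring tree wins,
    with ties resolved toward the first in input order.
    """
    if not trees:
        raise DomainError("empty tree sample")
    tip_sets = [frozenset(lf.taxon.label for lf in t.leaf_nodes()) for t in trees]
    if any(s != tip_sets[0] for s in tip_sets[1:]):
        raise DomainError("trees have mismatched tip sets")
    counts: dict[frozenset[str], int] = {}
    per_tree = []
    for t in trees:
        keys = _clade_keys(t)
        per_tree.append(keys)
        for k in keys:
            counts[k] = counts.get(k, 0) + 1
    m = len(trees)
    best_i, best_score = 0, -math.inf
    for i, keys in enumerate(per_tree):
        score = sum(math.log(counts[k] / m) for k in keys)
        if score > best_score + 1e-12:
            best_i, best_score = i, score
    return trees[best_i]


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    dm = {}
    for lf in tree.leaf_node_iter():
        dm[lf.taxon.label] = lf.distance_from_root()
    return dm


def phylo_correlation(
    tree: dendropy.Tree,
    labels: list[str] | None = None,
    *,
    ultrametric_tol: float = 1e-6,
) -> tuple[np.ndarray, list[str]]:
    """Phylogenetic correlation P from shared root-to-MRCA path lengths.

    P_ij = depth(MRCA(i, j)) / tree depth, P_ii = 1 — the Brownian-motion
    correlation on an ultrametric tree.  Non-ultrametric trees (beyond
    tolerance relative to depth) trigger a warning; the maximum tip depth
    is used as the depth.
    """
    depths = tip_depths(tree)
    T = max(depths.values())
    if T <= 0:
        raise DomainError("tree has zero depth")
    spread = max(depths.values()) - min(depths.values())
    if spread > ultrametric_tol * max(T, 1.0):
        import warnings

        warnings.warn(
            f"tree is not ultrametric (tip-depth spread {spread:.3g}); "
            "using max tip depth",
            stacklevel=2,
        )
    if labels is None:
        labels = sorted(depths)
    if len(set(labels)) != len(labels):
        raise DomainError("duplicate tip labels")
    missing = [l for l in labels if l not in depths]
    if missing:
        raise AlignmentError(f"labels absent from tree: {missing}")

    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    P = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        # on an ultrametric tree, patristic distance = 2 * (T - depth(MRCA))
        P[i, j] = P[j, i] = max(0.0, 1.0 - d / (2.0 * T))
    return P, labels


# ---------------------------------------------------------------------------
# spatial structure


def spatial_structure(centroids: np.ndarray) -> np.ndarray:
    """Pairwise Euclidean distances scaled by the maximum pair.

    The result lies in [0, 1]; "one unit of distance" is then the full
    study extent, which makes the fitted decay delta read as the fractional
    loss of spatial correlation across the whole study area.
    """
    pts = np.asarray(centroids, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise DomainError("need at least two centroids")
    D = np.hypot(pts[:, 0, None] - pts[None, :, 0], pts[:, 1, None] - pts[None, :, 1])
    dmax = D.max()
    if dmax == 0:
        raise DomainError("all centroids coincide")
    return D / dmax


def joint_correlation(
    P: np.ndarray,
    D: np.ndarray,
    model: CorrelationModel,
    *,
    unit_scale: float = 1.0,
) -> np.ndarray:
    """R = lambda_p P + phi_s S + (1 - lambda_p - phi_s) I.

    S_ij = (1 - delta)^(D_ij * unit_scale) with unit diagonal; with D
    max-normalised and unit_scale 1, delta = 0 gives compound symmetry
    (all-ones S) and delta -> 1 gives independence off the diagonal.
    """
    P = np.asarray(P, dtype=float)
    D = np.asarray(D, dtype=float)
    if P.shape != D.shape or P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise DomainError("P and D must be square matrices of the same size")
    n = P.shape[0]
    if model.delta == 0.0:
        S = np.ones_like(D)
    else:
        S = np.power(1.0 - model.delta, D * unit_scale)
    np.fill_diagonal(S, 1.0)
    R = model.lambda_p * P + model.phi_s * S + (1.0 - model.lambda_p - model.phi_s) * np.eye(n)
    return R


# ---------------------------------------------------------------------------
# likelihood


def gls_profile(
    y: np.ndarray, X: np.ndarray, R: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Profiled ML estimates for fixed correlation R.

    beta = (X' R^-1 X)^-1 X' R^-1 y;  sigma2 = e' R^-1 e / n (ML);
    logLik = -(n ln(2 pi sigma2) + ln|R| + n) / 2;
    SE columns from sigma2 (X' R^-1 X)^-1.

    A perfect fit (sigma2 underflowing) is floored and flagged by returning
    logLik inf-guarded; callers see sigma2 == floor.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if len(y) != n:
        raise DomainError("y and X have different numbers of rows")
    if np.linalg.matrix_rank(X) < p:
        # name the offending columns for the caller
        _, r = np.linalg.qr(X)
        dep = [j for j in range(p) if abs(r[j, j] if j < r.shape[0] else 0) < 1e-10]
        raise DomainError(f"design matrix is rank deficient (columns {dep})")
    L = np.linalg.cholesky(R + _JITTER * np.eye(n))
    logdetR = 2.0 * float(np.log(np.diag(L)).sum())
    yw = np.linalg.solve(L, y)
    Xw = np.linalg.solve(L, X)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    sigma2 = float(resid @ resid) / n
    sigma2 = max(sigma2, 1e-300)
    logLik = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdetR + n)
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(XtX)))
    return beta, se, sigma2, logLik


def _unpack(params: np.ndarray) -> CorrelationModel:
    ac = expit(params[0])
    prop = expit(params[1])
    delta = expit(params[2])
    return CorrelationModel(lambda_p=ac * prop, phi_s=ac * (1 - prop), delta=delta)


#: fixed multi-start design on the (AC, prop_phylo, delta) scale
_STARTS = [
    (0.05, 0.5, 0.1),
    (0.3, 0.2, 0.3),
    (0.3, 0.8, 0.3),
    (0.6, 0.2, 0.5),
    (0.6, 0.8, 0.5),
    (0.9, 0.5, 0.2),
    (0.9, 0.2, 0.8),
    (0.9, 0.8, 0.8),
]


def fit_ml(
    y: np.ndarray,
    X: np.ndarray,
    P: np.ndarray,
    D: np.ndarray,
    *,
    names: list[str] | None = None,
    formula: str = "",
    n_starts: int = 8,
    maxiter: int = 400,
) -> GLSFit:
    """Maximum-likelihood joint phylogenetic-spatial GLS.

    Maximises the profiled log-likelihood over (AC, prop_phylo, delta) via
    Nelder-Mead on logit-transformed coordinates, restarted from a fixed
    design of ``n_starts`` points (taken in order from an 8-point grid).
    Coefficient t-tests use df = n - #beta; AICc counts k = #beta + 3
    covariance parameters + 1 variance in every model so tables are
    internally comparable.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, pdim = X.shape

    def nll(params: np.ndarray) -> float:
        try:
            model = _unpack(params)
            R = joint_correlation(P, D, model)
            _, _, _, ll = gls_profile(y, X, R)
        except (np.linalg.LinAlgError, DomainError):
            return 1e12
        return -ll

    best = None
    for ac0, pr0, de0 in _STARTS[: max(1, min(n_starts, len(_STARTS)))]:
        x0 = np.array([logit(ac0), logit(pr0), logit(de0)])
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            options={"maxiter": maxiter, "xatol": 1e-5, "fatol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise DomainError("optimizer failed to converge from every start")

    model = _unpack(best.x)
    R = joint_correlation(P, D, model)
    beta, se, sigma2, logLik = gls_profile(y, X, R)
    df = n - pdim
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    k = pdim + 3 + 1
    fit = GLSFit(
        beta=beta, se=se, t=t, p=pvals, df=df, sigma2=sigma2, logLik=logLik,
        n=n, k=k, model=model,
        names=names or [f"x{i}" for i in range(pdim)], formula=formula,
        degenerate=sigma2 <= max(1e-290, 1e-20 * float(np.var(y))),
    )
    fit.aicc = aicc(logLik, k, n)
    return fit


# ---------------------------------------------------------------------------
# model selection and inference


def aicc(logLik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion."""
    if n <= k + 1:
        raise DomainError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * logLik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def akaike_table(aicc_values: np.ndarray, labels: list[str] | None = None) -> pd.DataFrame:
    """delta, Akaike weight w, and relative likelihood rLL from AICc values."""
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    rll = np.exp(-delta / 2.0)
    w = rll / rll.sum()
    df = pd.DataFrame(
        {
            "model": labels if labels is not None else [f"m{i}" for i in range(len(a))],
            "AICc": a,
            "delta": delta,
            "w": w,
            "rLL": rll,
        }
    )
    return df.sort_values("AICc", kind="stable").reset_index(drop=True)


def model_table(fits: list[GLSFit]) -> pd.DataFrame:
    """Comparison table sorted by AICc: delta, w, rLL, AC, phylo share, decay."""
    if not fits:
        raise DomainError("no fits to tabulate")
    base = akaike_table(
        np.array([f.aicc for f in fits]),
        labels=[f.formula or f"model{i}" for i, f in enumerate(fits)],
    )
    order = np.argsort([f.aicc for f in fits], kind="stable")
    base["AC"] = [fits[i].AC for i in order]
    base["phylo"] = [fits[i].prop_phylo for i in order]
    base["decay"] = [fits[i].delta for i in order]
    return base


def lrt(full: GLSFit, null: GLSFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fixed effects (same covariance family).

    chi2 = 2 (logLik_full - logLik_null), df = difference in #beta.
    A negative chi2 indicates an optimizer artefact; callers should refit.
    """
    if full.n != null.n:
        raise DomainError("models fit to different sample sizes")
    df = len(full.beta) - len(null.beta)
    if df < 0:
        raise DomainError("null model is not nested in the full model")
    if not set(null.names) <= set(full.names):
        raise DomainError(
            f"null terms {null.names} are not a subset of full terms {full.names}"
        )
    chi2 = 2.0 * (full.logLik - null.logLik)
    if chi2 < -1e-6:
        raise DomainError(
            f"negative LRT statistic ({chi2:.4g}); refit with more starts"
        )
    chi2 = max(chi2, 0.0)
    if df == 0:
        return chi2, 0, 1.0  # identical fixed effects: no test
    p = float(stats.chi2.sf(chi2, df))
    return chi2, df, p


def percent_effect(beta: float, form: str = "log-log") -> float:
    """Interpret a coefficient on an ln predictor as a percent effect.

    log-log (outcome also ln): 100 * (exp(beta) - 1), the percent change in
    the outcome per e-fold (~"100%") increase of the predictor.  linear-log
    (outcome already in percent units): beta itself, the percentage-point
    change per ln-unit of the predictor.
    """
    if form == "log-log":
        return 100.0 * (math.exp(beta) - 1.0)
    if form == "linear-log":
        return float(beta)
    raise DomainError(f"unknown form {form!r}")
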