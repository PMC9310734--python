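"""Distance-matrix construction and inference: Mantel tests, multiple matrix
regression with randomization (MMRR), and generalized dissimilarity
modelling (GDM) with monotone I-splines and permutation-based backward
elimination.

Permutation significance follows the standard convention for distance
matrices: rows and columns of one matrix are permuted jointly, the observed
statistic is compared with the permuted null, and p-values carry the +1
correction in numerator and denominator. All permutation streams are
seeded, so reported p-values are reproducible bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import nnls

from .geo import pairwise_haversine_km
from .matrices import DistanceMatrix
from .synthetic import LocalityTable

__all__ = [
    "MantelResult",
    "MMRRResult",
    "GDMModel",
    "geographic_distance_matrix",
    "environmental_distance_matrix",
    "normalize_fst",
    "mantel_test",
    "mmrr",
    "ispline_basis",
    "gdm_fit",
    "gdm_backward_elimination",
]


# ---------------------------------------------------------------------------
# matrix construction


def geographic_distance_matrix(
    points: LocalityTable | np.ndarray,
    labels: list[str] | None = None,
    log_transform: bool = False,
) -> DistanceMatrix:
    """Great-circle distance matrix (km) between locality centroids or
    individual coordinates; optional natural-log transform with zeros
    replaced by half the smallest positive distance."""
    if isinstance(points, LocalityTable):
        labels = points.names
        coords = points.centroids()
    else:
        coords = np.asarray(points, dtype=float)
        if labels is None:
            labels = [f"p{i}" for i in range(coords.shape[0])]
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 points")
    d = pairwise_haversine_km(coords[:, 0], coords[:, 1])
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2
    if log_transform:
        off = d[np.triu_indices_from(d, k=1)]
        positive = off[off > 0]
        if positive.size == 0:
            raise ValueError("all pairwise distances are zero; cannot log-transform")
        floor = positive.min() / 2.0
        if (off == 0).any():
            warnings.warn(
                f"{int((off == 0).sum())} zero distances replaced by {floor:.6g} km before log"
            )
        d = np.where(d == 0, floor, d)
        d = np.log(d)
        np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(labels), d, "IBD")


def environmental_distance_matrix(env: dict[str, np.ndarray] | np.ndarray,
                                  labels: list[str] | None = None) -> DistanceMatrix:
    """Euclidean distance on raw per-locality environmental vectors (kind IBE)."""
    if isinstance(env, dict):
        labels = list(env.keys())
        mat = np.asarray([env[k] for k in labels], dtype=float)
    else:
        mat = np.asarray(env, dtype=float)
        if labels is None:
            labels = [f"p{i}" for i in range(mat.shape[0])]
    if np.isnan(mat).any():
        raise ValueError("environmental vectors contain missing values")
    diff = mat[:, None, :] - mat[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return DistanceMatrix(list(labels), d, "IBE")


def normalize_fst(fst: DistanceMatrix) -> DistanceMatrix:
    """Linearized differentiation FST / (1 - FST)."""
    off = fst.values[~np.eye(fst.n, dtype=bool)]
    if np.any(off >= 1) or np.any(off < 0):
        raise ValueError("FST values must lie in [0, 1) to normalize")
    return fst.transform(lambda v: v / (1 - v))


# ---------------------------------------------------------------------------
# Mantel and MMRR


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    tail: str = "greater"

    @property
    def r_squared(self) -> float:
        return self.r**2


def _perm_indices(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    return np.stack([rng.permutation(n) for _ in range(n_perm)])


def mantel_test(
    X: DistanceMatrix,
    Y: DistanceMatrix,
    n_perm: int = 10000,
    standardize_by_mean: bool = False,
    tail: str = "greater",
    seed: int = 0,
) -> MantelResult:
    """Mantel permutation test of association between two distance matrices.

    r is the Pearson correlation of the lower triangles; the null permutes
    rows and columns of Y jointly. One-tailed (positive association) by
    default; ``tail="two-sided"`` compares |r|.
    """
    if X.labels != Y.labels:
        Y = Y.reorder(X.labels)
    n = X.n
    if n < 4:
        raise ValueError("Mantel test needs at least 4 labels")
    xv, yv = X.values.copy(), Y.values.copy()
    if standardize_by_mean:
        for v in (xv, yv):
            m = v[~np.eye(n, dtype=bool)].mean()
            if m != 0:
                v /= m
    il = np.tril_indices(n, k=-1)
    x = xv[il]
    if x.std() == 0 or yv[il].std() == 0:
        raise ValueError("constant distance matrix; Mantel r undefined")

    def corr(yperm: np.ndarray) -> float:
        y = yperm[il]
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(yv)
    rng = np.random.default_rng(seed)
    stat = abs(r_obs) if tail == "two-sided" else r_obs
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_p = corr(yv[np.ix_(perm, perm)])
        if (abs(r_p) if tail == "two-sided" else r_p) >= stat:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return MantelResult(r_obs, p, n_perm, tail)


@dataclass
class MMRRResult:
    predictor_names: list[str]
    coefficients: np.ndarray        # standardized betas, intercept last
    raw_coefficients: np.ndarray    # on the original distance scale
    r_squared: float
    t_statistics: np.ndarray
    coef_p: np.ndarray
    f_statistic: float
    overall_p: float
    n_perm: int


def _unfold(matrices: list[DistanceMatrix], labels: list[str]) -> np.ndarray:
    n = len(labels)
    il = np.tril_indices(n, k=-1)
    return np.column_stack([m.reorder(labels).values[il] for m in matrices])


def mmrr(
    Y: DistanceMatrix,
    X_list: list[DistanceMatrix],
    n_perm: int = 10000,
    seed: int = 0,
) -> MMRRResult:
    """Multiple regression on distance matrices with randomization.

    Lower triangles are unfolded and z-scored; OLS gives coefficients and
    R^2; significance comes from joint row/column permutations of Y,
    recomputing per-coefficient t and the overall F each time.
    """
    if not X_list:
        raise ValueError("need at least one predictor matrix")
    if Y.n < 5:
        raise ValueError("MMRR needs at least 5 labels")
    labels = Y.labels
    yfull = Y.values
    n = Y.n
    il = np.tril_indices(n, k=-1)
    Xraw = _unfold(X_list, labels)
    yraw = yfull[il]

    def zscore(a):
        sd = a.std(axis=0)
        if np.any(sd == 0):
            raise ValueError("constant predictor or response")
        return (a - a.mean(axis=0)) / sd

    Xz = zscore(Xraw)
    design = np.column_stack([Xz, np.ones(len(yraw))])
    cond = np.linalg.cond(design)
    if cond > 1e8:
        raise ValueError(f"collinear predictors (condition number {cond:.3g})")

    def fit(yvec):
        yz = (yvec - yvec.mean()) / yvec.std()
        beta, *_ = np.linalg.lstsq(design, yz, rcond=None)
        resid = yz - design @ beta
        dof = len(yz) - design.shape[1]
        sigma2 = resid @ resid / dof
        xtx_inv = np.linalg.inv(design.T @ design)
        se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 1e-300, None))
        t = beta / se
        ssr = ((design @ beta - yz.mean() * 0) ** 2).sum()  # yz has zero mean
        sst = (yz**2).sum()
        r2 = 1 - resid @ resid / sst
        k = Xz.shape[1]
        f = (r2 / k) / ((1 - r2) / dof) if r2 < 1 else np.inf
        return beta, t, r2, f

    beta_obs, t_obs, r2_obs, f_obs = fit(yraw)
    rng = np.random.default_rng(seed)
    t_exceed = np.zeros(len(beta_obs))
    f_exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yperm = yfull[np.ix_(perm, perm)][il]
        _, t_p, _, f_p = fit(yperm)
        t_exceed += np.abs(t_p) >= np.abs(t_obs)
        f_exceed += f_p >= f_obs
    coef_p = (1 + t_exceed) / (1 + n_perm)
    overall_p = (1 + f_exceed) / (1 + n_perm)

    # back-transform standardized betas to the raw distance scale
    y_sd, y_mean = yraw.std(), yraw.mean()
    x_sd = Xraw.std(axis=0)
    raw_beta = np.append(beta_obs[:-1] * y_sd / x_sd, 0.0)
    raw_beta[-1] = y_mean - (raw_beta[:-1] * Xraw.mean(axis=0)).sum()
    names = [m.kind or f"X{i}" for i, m in enumerate(X_list)]
    return MMRRResult(
        names, beta_obs, raw_beta, float(r2_obs), t_obs,
        coef_p, float(f_obs), float(overall_p), n_perm,
    )


# ---------------------------------------------------------------------------
# I-splines and GDM


def ispline_basis(x: np.ndarray, knots: np.ndarray, n_splines: int = 3) -> np.ndarray:
    """Order-2 monotone I-spline basis on [knots[0], knots[-1]].

    Built as suffix sums of degree-2 B-splines; each basis function rises
    from 0 at the lower boundary to 1 at the upper. Default knots sit at
    the 0/50/100 percentiles of the observed distances.
    """
    knots = np.asarray(knots, dtype=float)
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    if n_splines != len(knots):
        raise ValueError("n_splines must equal the number of knots (3 default)")
    t0, t2 = knots[0], knots[-1]
    interior = knots[1:-1]
    deg = 2
    tvec = np.concatenate([[t0] * (deg + 1), interior, [t2] * (deg + 1)])
    n_b = len(tvec) - deg - 1
    x = np.clip(np.asarray(x, dtype=float), t0, t2)
    B = np.column_stack([
        BSpline.basis_element(tvec[i : i + deg + 2], extrapolate=False)(x)
        for i in range(n_b)
    ])
    B = np.nan_to_num(B)
    # right boundary: the last B-spline is 1 at x == t2
    B[x == t2, -1] = 1.0
    # I_j = sum of B-splines j.. (suffix sums), dropping the constant first column
    I = np.cumsum(B[:, ::-1], axis=1)[:, ::-1]
    return np.clip(I[:, 1:], 0.0, 1.0)


def default_knots(x: np.ndarray) -> np.ndarray:
    q = np.quantile(np.asarray(x, dtype=float), [0.0, 0.5, 1.0])
    if q[1] <= q[0]:
        q[1] = (q[0] + q[2]) / 2
    if q[2] <= q[1]:
        raise ValueError("degenerate predictor: all distances equal")
    return q


@dataclass
class GDMModel:
    predictor_names: list[str]
    intercept: float
    coefficients: dict                 # name -> (n_splines,) non-negative
    knots: dict                        # name -> knot vector
    deviance_explained: float          # percent
    null_deviance: float
    deviance: float
    converged: bool
    importance: dict = field(default_factory=dict)   # name -> % deviance drop
    p_values: dict = field(default_factory=dict)
    elimination_history: list = field(default_factory=list)

    def transform(self, name: str, distances: np.ndarray) -> np.ndarray:
        """Fitted partial response f_k(d) = sum_j beta_kj I_j(d)."""
        basis = ispline_basis(distances, self.knots[name])
        return basis @ self.coefficients[name]

    def predict(self, predictor_distances: dict) -> np.ndarray:
        eta = self.intercept
        for name in self.predictor_names:
            eta = eta + self.transform(name, predictor_distances[name])
        return 1.0 - np.exp(-eta)


def _binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-10, 1 - 1e-10)
    yc = np.clip(y, 1e-10, 1 - 1e-10)
    return float(2 * np.sum(y * np.log(yc / mu) + (1 - y) * np.log((1 - yc) / (1 - mu))))


def _gdm_irls(y: np.ndarray, G: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Non-negative IRLS for the GDM link mu = 1 - exp(-eta), eta = b0 + G b."""
    design = np.column_stack([np.ones(len(y)), G])
    beta = np.zeros(design.shape[1])
    beta[0] = max(-np.log(1 - np.clip(y.mean(), 1e-6, 1 - 1e-6)), 1e-6)
    dev = _binomial_deviance(y, 1 - np.exp(-design @ beta))
    converged = False
    for _ in range(max_iter):
        eta = design @ beta
        mu = np.clip(1 - np.exp(-eta), 1e-10, 1 - 1e-10)
        dmu = 1 - mu                      # d mu / d eta = exp(-eta)
        var = mu * (1 - mu)
        w = np.clip(dmu**2 / var, 1e-10, None)
        z = eta + (y - mu) / np.clip(dmu, 1e-10, None)
        sw = np.sqrt(w)
        beta_new, _ = nnls(design * sw[:, None], z * sw)
        dev_new = _binomial_deviance(y, 1 - np.exp(-design @ beta_new))
        if dev_new > dev + 1e-10:
            # step-halve toward the previous iterate to keep deviance descending
            improved = False
            for frac in (0.5, 0.25, 0.1, 0.01):
                trial = beta + frac * (beta_new - beta)
                dev_trial = _binomial_deviance(y, 1 - np.exp(-design @ trial))
                if dev_trial <= dev:
                    beta_new, dev_new, improved = trial, dev_trial, True
                    break
            if not improved:
                break
        if abs(dev - dev_new) < tol * (abs(dev) + 1):
            beta, dev, converged = beta_new, dev_new, True
            break
        beta, dev = beta_new, dev_new
    return beta, dev, converged


def gdm_fit(
    Y: DistanceMatrix,
    predictors: list[DistanceMatrix],
    n_splines: int = 3,
    knots: dict | None = None,
) -> GDMModel:
    """Fit a generalized dissimilarity model.

    Response dissimilarities must lie in [0, 1); predicted dissimilarity is
    1 - exp(-eta) with eta a non-negative I-spline combination of predictor
    distances, fitted by iteratively reweighted non-negative least squares
    on the binomial deviance. Reports percent deviance explained against
    the intercept-only null.
    """
    if not predictors:
        raise ValueError("need at least one predictor")
    labels = Y.labels
    n = Y.n
    il = np.tril_indices(n, k=-1)
    y = Y.values[il]
    if np.any((y < 0) | (y >= 1)):
        raise ValueError("GDM response must lie in [0, 1)")
    names = [m.kind or f"X{i}" for i, m in enumerate(predictors)]
    xcols = {nm: m.reorder(labels).values[il] for nm, m in zip(names, predictors)}
    knots = dict(knots or {})
    for nm in names:
        knots.setdefault(nm, default_knots(xcols[nm]))
    G = np.hstack([ispline_basis(xcols[nm], knots[nm], n_splines) for nm in names])

    beta, dev, converged = _gdm_irls(y, G)
    b0_null, dev_null, _ = _gdm_irls(y, np.zeros((len(y), 0)))
    if not converged:
        warnings.warn("GDM IRLS did not converge", RuntimeWarning)
    explained = 100.0 * (1 - dev / dev_null) if dev_null > 0 else 0.0
    coefs = {
        nm: beta[1 + i * n_splines : 1 + (i + 1) * n_splines]
        for i, nm in enumerate(names)
    }
    return GDMModel(
        names, float(beta[0]), coefs, knots,
        float(max(explained, 0.0)), float(dev_null), float(dev), converged,
    )


def _permute_matrix(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    perm = rng.permutation(values.shape[0])
    return values[np.ix_(perm, perm)]


def gdm_importance(
    Y: DistanceMatrix,
    predictors: list[DistanceMatrix],
    n_perm: int = 500,
    seed: int = 0,
    n_splines: int = 3,
) -> tuple[GDMModel, dict, dict]:
    """Unique contribution and permutation p per predictor.

    A predictor's contribution is the mean drop in percent deviance
    explained when its matrix is row/column permuted and the model refit;
    p is the proportion of permutations in which the permuted model
    explains at least as much deviance as the observed one.
    """
    model = gdm_fit(Y, predictors, n_splines)
    rng = np.random.default_rng(seed)
    importance: dict[str, float] = {}
    p_values: dict[str, float] = {}
    names = [m.kind or f"X{i}" for i, m in enumerate(predictors)]
    for k, name in enumerate(names):
        drops = np.empty(n_perm)
        exceed = 0
        for b in range(n_perm):
            perm_list = list(predictors)
            pm = _permute_matrix(predictors[k].values, rng)
            pm = (pm + pm.T) / 2
            np.fill_diagonal(pm, 0.0)
            perm_list[k] = DistanceMatrix(predictors[k].labels, pm, predictors[k].kind)
            try:
                perm_model = gdm_fit(Y, perm_list, n_splines)
                de = perm_model.deviance_explained
            except ValueError:
                de = 0.0
            drops[b] = model.deviance_explained - de
            if de >= model.deviance_explained:
                exceed += 1
        importance[name] = float(drops.mean())
        p_values[name] = (1 + exceed) / (1 + n_perm)
    model.importance = importance
    model.p_values = p_values
    return model, importance, p_values


def gdm_backward_elimination(
    Y: DistanceMatrix,
    predictors: list[DistanceMatrix],
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
    n_splines: int = 3,
) -> GDMModel:
    """Backward elimination by permutation importance.

    Each round computes every remaining predictor's unique contribution and
    permutation p; if any retained predictor is non-significant, the least
    contributing one is dropped and the model refit, until all retained
    predictors are significant or one remains. The per-round tables are
    recorded in ``elimination_history``.
    """
    if len(predictors) < 2:
        model, imp, pv = gdm_importance(Y, predictors, n_perm, seed, n_splines)
        model.elimination_history = [
            {"retained": model.predictor_names, "importance": imp, "p": pv}
        ]
        return model
    rng = np.random.default_rng(seed)
    current = list(predictors)
    history = []
    model = None
    while True:
        round_seed = int(rng.integers(2**31 - 1))
        model, imp, pv = gdm_importance(Y, current, n_perm, round_seed, n_splines)
        history.append({
            "retained": list(model.predictor_names),
            "importance": dict(imp),
            "p": dict(pv),
        })
        if len(current) == 1 or all(p < alpha for p in pv.values()):
            break
        worst = min(imp, key=imp.get)
        names = [m.kind or f"X{i}" for i, m in enumerate(current)]
        current = [m for nm, m in zip(names, current) if nm != worst]
        if not current:
            warnings.warn("all predictors eliminated; intercept-only model")
            break
    model.elimination_history = history
    return model
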