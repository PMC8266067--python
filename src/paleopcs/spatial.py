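"""Spatial statistics: distance-band weights, Moran's I, spatial-error ML, IDW.

The spatial-error (simultaneous autoregressive) model is

    y = X beta + u,    u = lambda W u + eps,    eps ~ N(0, sigma^2 I)

with W a row-standardized great-circle distance-band weights matrix.  The
model is estimated by maximum likelihood, profiling the concentrated
log-likelihood over lambda with the log-determinant log|I - lambda W|
evaluated from the (dense) eigenvalues of W; lambda is constrained to the
interval bounded by the reciprocal extreme eigenvalues.  Assemblage counts
per time slice are a few hundred, so dense eigendecomposition is adequate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.spatial.distance
import scipy.stats
import statsmodels.api as sm

EARTH_RADIUS_KM = 6371.0088


def haversine_km(p1, p2) -> np.ndarray | float:
    """Great-circle distance in km between lon/lat points (degrees)."""
    lon1, lat1 = np.radians(np.asarray(p1, dtype=float)).T
    lon2, lat2 = np.radians(np.asarray(p2, dtype=float)).T
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def pairwise_haversine_km(points: np.ndarray) -> np.ndarray:
    """Full pairwise great-circle distance matrix for (lon, lat) rows."""
    pts = np.asarray(points, dtype=float)
    lon = np.radians(pts[:, 0])[:, None]
    lat = np.radians(pts[:, 1])[:, None]
    dlon = lon.T - lon
    dlat = lat.T - lat
    a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


class DistanceBandWeights:
    """Row-standardized binary distance-band spatial weights.

    Points within ``threshold_km`` great-circle distance are neighbors
    (adjacency 1); each row is then standardized to sum to one.  Points with
    no neighbor ("islands") keep a zero row and are flagged.
    """

    def __init__(self, points: np.ndarray, threshold_km: float,
                 metric: str = "haversine"):
        pts = np.asarray(points, dtype=float)
        if pts.shape[0] < 2:
            raise ValueError("need at least 2 points")
        if metric == "haversine":
            dist = pairwise_haversine_km(pts)
        elif metric == "euclidean":
            dist = scipy.spatial.distance.squareform(
                scipy.spatial.distance.pdist(pts))
        else:
            raise ValueError(f"unknown metric {metric!r}")
        adj = (dist <= threshold_km).astype(float)
        np.fill_diagonal(adj, 0.0)
        self.points = pts
        self.threshold_km = float(threshold_km)
        self.adjacency = adj
        self.cardinalities = adj.sum(axis=1).astype(int)
        self.islands = np.flatnonzero(self.cardinalities == 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            W = adj / adj.sum(axis=1, keepdims=True)
        W[np.isnan(W)] = 0.0
        self.W = W
        self.style = "row-standardized"

    @classmethod
    def from_matrix(cls, adjacency: np.ndarray) -> "DistanceBandWeights":
        """Build from a precomputed symmetric binary adjacency matrix."""
        obj = cls.__new__(cls)
        adj = np.asarray(adjacency, dtype=float)
        np.fill_diagonal(adj, 0.0)
        obj.points = None
        obj.threshold_km = np.nan
        obj.adjacency = adj
        obj.cardinalities = adj.sum(axis=1).astype(int)
        obj.islands = np.flatnonzero(obj.cardinalities == 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            W = adj / adj.sum(axis=1, keepdims=True)
        W[np.isnan(W)] = 0.0
        obj.W = W
        obj.style = "row-standardized"
        return obj

    @classmethod
    def lattice_rook(cls, nrow: int, ncol: int) -> "DistanceBandWeights":
        """Rook adjacency on a regular lattice (mainly for simulations)."""
        n = nrow * ncol
        adj = np.zeros((n, n))
        for r in range(nrow):
            for c in range(ncol):
                i = r * ncol + c
                if c + 1 < ncol:
                    adj[i, i + 1] = adj[i + 1, i] = 1
                if r + 1 < nrow:
                    adj[i, i + ncol] = adj[i + ncol, i] = 1
        return cls.from_matrix(adj)

    @property
    def n(self) -> int:
        return self.W.shape[0]

    @property
    def s0(self) -> float:
        return float(self.W.sum())

    def eigenvalues(self) -> np.ndarray:
        """Real eigenvalues of row-standardized W (via the symmetric similar
        matrix D^-1/2 A D^-1/2 on non-island rows)."""
        keep = np.flatnonzero(self.cardinalities > 0)
        A = self.adjacency[np.ix_(keep, keep)]
        d = A.sum(axis=1)
        if (d == 0).any():
            # dropping islands may create secondary islands; recurse once
            return DistanceBandWeights.from_matrix(A).eigenvalues()
        Dm = 1.0 / np.sqrt(d)
        S = A * Dm[:, None] * Dm[None, :]
        vals = scipy.linalg.eigvalsh(S)
        return vals

    def subset(self, keep: np.ndarray) -> "DistanceBandWeights":
        """Weights restricted to the given row indices (re-standardized)."""
        return DistanceBandWeights.from_matrix(
            self.adjacency[np.ix_(np.asarray(keep), np.asarray(keep))])

    def to_triplets(self) -> pd.DataFrame:
        i, j = np.nonzero(self.W)
        return pd.DataFrame({"i": i, "j": j, "w": self.W[i, j]})


# ------------------------------------------------------------------ Moran's I


@dataclass
class MoranResult:
    I: float
    expected_I: float
    var_norm: float
    z_norm: float
    p_norm: float
    p_perm: float | None
    n: int
    n_perm: int = 0
    perm_distribution: np.ndarray | None = field(default=None, repr=False)

    @property
    def significant(self) -> bool:
        return self.p_norm < 0.05


def morans_i(
    values: np.ndarray,
    weights: DistanceBandWeights,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    two_sided: bool = True,
) -> MoranResult:
    """Global Moran's I with analytic (normal) and permutation inference.

    I = (n/S0) * z'Wz / z'z with z the centered values.  The permutation
    p-value is computed from ``n_perm`` random relabelings; the analytic
    p-value uses the normality assumption.  Expectation under either null is
    -1/(n-1).
    """
    x = np.asarray(values, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("values must be finite")
    n = x.size
    if np.ptp(x) == 0:
        raise ValueError("Moran's I is undefined for a constant vector")
    W = weights.W
    S0 = W.sum()
    if S0 <= 0:
        raise ValueError("weights have no nonzero entries")
    z = x - x.mean()
    denom = z @ z

    def stat(zv: np.ndarray) -> float:
        return float(n / S0 * (zv @ (W @ zv)) / denom)

    I = stat(z)
    EI = -1.0 / (n - 1)

    # variance under the normality assumption
    S1 = 0.5 * ((W + W.T) ** 2).sum()
    S2 = ((W.sum(axis=1) + W.sum(axis=0)) ** 2).sum()
    var = (n**2 * S1 - n * S2 + 3 * S0**2) / ((n**2 - 1) * S0**2) - EI**2
    zscore = (I - EI) / np.sqrt(var)
    if two_sided:
        p_norm = 2 * scipy.stats.norm.sf(abs(zscore))
    else:
        p_norm = scipy.stats.norm.sf(zscore)

    p_perm = None
    perm = None
    if n_perm and n_perm > 0:
        rng = np.random.default_rng(seed)
        perm = np.empty(n_perm)
        for k in range(n_perm):
            perm[k] = stat(rng.permutation(z))
        if two_sided:
            extreme = np.abs(perm - EI) >= abs(I - EI) - 1e-15
        else:
            extreme = perm >= I - 1e-15
        p_perm = (1 + int(extreme.sum())) / (n_perm + 1)

    return MoranResult(I=I, expected_I=EI, var_norm=float(var),
                       z_norm=float(zscore), p_norm=float(p_norm),
                       p_perm=p_perm, n=n, n_perm=n_perm or 0,
                       perm_distribution=perm)


# ----------------------------------------------------------------------- OLS


def fit_ols(y: np.ndarray, X: np.ndarray | pd.DataFrame):
    """Ordinary least squares via statsmodels, with rank checking.

    ``X`` must already include a constant column if an intercept is wanted.
    Returns the statsmodels results object (params, resid, rsquared_adj,
    fvalue, f_pvalue, llf, ssr ... as usual).
    """
    Xa = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if Xa.ndim != 2:
        raise ValueError("design matrix must be 2-D")
    rank = np.linalg.matrix_rank(Xa)
    if rank < Xa.shape[1]:
        names = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(Xa.shape[1]))
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {Xa.shape[1]} "
            f"columns: {names})"
        )
    if y.size <= Xa.shape[1]:
        raise ValueError("need n > number of parameters")
    return sm.OLS(y, X).fit()


# ------------------------------------------------------------ SAR error model


class SpatialErrorResults:
    """Results of a maximum-likelihood spatial-error fit."""

    def __init__(self, model: "SpatialErrorModel", params: np.ndarray,
                 lam: float, sigma2: float, llf: float, llf_ols: float,
                 llf_null: float, bse: np.ndarray, converged: bool,
                 boundary: bool):
        self.model = model
        self.params = params
        self.lam = lam
        self.sigma2 = sigma2
        self.llf = llf
        self.llf_ols = llf_ols
        self.llf_null = llf_null
        self.bse = bse
        self.converged = converged
        self.boundary = boundary
        n = model.nobs
        A = np.eye(n) - lam * model.W
        u = model.endog - model.exog @ params
        #: response residuals (still spatially correlated by construction)
        self.resid_response = u
        #: innovations e = (I - lambda W) u; the whitened residuals used for
        #: spatial diagnostics
        self.resid = A @ u
        self.fittedvalues = model.endog - u
        self.df_model = model.exog.shape[1]
        # parameters: beta, lambda, sigma2
        self.k_params = self.df_model + 2
        self.aic = -2 * llf + 2 * (self.df_model + 1)  # sigma2 not counted, as in spdep
        self.nobs = n

    @property
    def pseudo_r2(self) -> float:
        """Nagelkerke pseudo-R-squared, 1 - (L0/L1)^(2/n) against the
        intercept-only non-spatial model."""
        n = self.nobs
        return float(1.0 - np.exp(2.0 / n * (self.llf_null - self.llf)))

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        q = scipy.stats.norm.ppf(1 - alpha / 2)
        lo = self.params - q * self.bse
        hi = self.params + q * self.bse
        return np.column_stack([lo, hi])

    @property
    def pvalues(self) -> np.ndarray:
        z = self.params / self.bse
        return 2 * scipy.stats.norm.sf(np.abs(z))

    def lr_test_vs_ols(self) -> tuple[float, float]:
        """Likelihood-ratio test of lambda = 0 (1 df chi-square)."""
        lr = 2 * (self.llf - self.llf_ols)
        return float(lr), float(scipy.stats.chi2.sf(lr, df=1))

    def moran_residuals(self, n_perm: int = 0,
                        seed: int | None = None) -> MoranResult:
        """Moran's I of the whitened residuals on the model's weights."""
        return morans_i(self.resid, self.model.weights, n_perm=n_perm, seed=seed)

    def summary(self) -> str:
        names = self.model.exog_names
        lines = [
            "Spatial Error Model (maximum likelihood)",
            "=" * 58,
            f"N obs: {self.nobs:>6d}    lambda: {self.lam: .4f}"
            f"    sigma2: {self.sigma2: .4f}",
            f"Log-likelihood: {self.llf: .3f}    AIC: {self.aic: .2f}"
            f"    pseudo-R2 (Nagelkerke): {self.pseudo_r2: .4f}",
            "-" * 58,
            f"{'':<18}{'coef':>10}{'std err':>10}{'z':>8}{'P>|z|':>10}",
        ]
        zs = self.params / self.bse
        for name, b, se, z, p in zip(names, self.params, self.bse, zs, self.pvalues):
            lines.append(f"{name:<18}{b:>10.4f}{se:>10.4f}{z:>8.2f}{p:>10.4g}")
        lines.append("=" * 58)
        return "\n".join(lines)


class SpatialErrorModel:
    """Maximum-likelihood spatial-error regression y = Xb + u, u = lam W u + e.

    Parameters
    ----------
    endog
        Response vector.
    exog
        Design matrix (include a constant column for an intercept).
    weights
        Row-standardized :class:`DistanceBandWeights`.  Rows with no
        neighbors are dropped (with their observations) when
        ``drop_islands`` is True, otherwise rejected.
    """

    def __init__(self, endog, exog, weights: DistanceBandWeights,
                 drop_islands: bool = True):
        y = np.asarray(endog, dtype=float)
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
        else:
            self.exog_names = [f"x{i}" for i in range(np.asarray(exog).shape[1])]
        X = np.asarray(exog, dtype=float)
        if y.size != X.shape[0] or y.size != weights.n:
            raise ValueError("endog, exog and weights must align")
        self.n_dropped_islands = 0
        if weights.islands.size:
            if not drop_islands:
                raise ValueError(
                    f"{weights.islands.size} observations have no neighbors")
            keep = np.setdiff1d(np.arange(y.size), weights.islands)
            # restriction can create new islands; iterate until stable
            while True:
                w2 = weights.subset(keep)
                if not w2.islands.size:
                    break
                keep = keep[np.setdiff1d(np.arange(keep.size), w2.islands)]
                if keep.size < X.shape[1] + 2:
                    raise ValueError("too few connected observations for SAR")
            self.n_dropped_islands = y.size - keep.size
            y, X, weights = y[keep], X[keep], w2
        if np.all(weights.W == 0):
            raise ValueError("all points are isolated; SAR not identifiable")
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError("design matrix is rank deficient")
        if y.size <= X.shape[1] + 1:
            raise ValueError("need n > number of parameters")
        self.endog = y
        self.exog = X
        self.weights = weights
        self.W = weights.W
        self.nobs = y.size
        self._eigs = weights.eigenvalues()

    def _profile(self, lam: float) -> tuple[float, np.ndarray, float]:
        """Concentrated log-likelihood and conditional beta, sigma2."""
        n = self.nobs
        A = np.eye(n) - lam * self.W
        ys = A @ self.endog
        Xs = A @ self.exog
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        e = ys - Xs @ beta
        sigma2 = float(e @ e) / n
        logdet = float(np.sum(np.log(np.abs(1.0 - lam * self._eigs))))
        llf = (-n / 2 * (np.log(2 * np.pi) + 1) - n / 2 * np.log(sigma2) + logdet)
        return llf, beta, sigma2

    def fit(self) -> SpatialErrorResults:
        emin, emax = self._eigs.min(), self._eigs.max()
        lo = 1.0 / emin if emin < 0 else -0.999
        hi = 1.0 / emax if emax > 0 else 0.999
        eps = 1e-6 * (hi - lo)
        res = scipy.optimize.minimize_scalar(
            lambda lam: -self._profile(lam)[0],
            bounds=(lo + eps, hi - eps), method="bounded",
            options={"xatol": 1e-8},
        )
        lam = float(res.x)
        llf, beta, sigma2 = self._profile(lam)
        llf0, beta0, s20 = self._profile(0.0)
        # intercept-only non-spatial log-likelihood for the pseudo-R2 baseline
        y = self.endog
        n = self.nobs
        s2n = float(np.var(y))
        llf_null = -n / 2 * (np.log(2 * np.pi) + 1) - n / 2 * np.log(s2n)
        # conditional-on-lambda covariance of beta
        A = np.eye(n) - lam * self.W
        Xs = A @ self.exog
        cov = sigma2 * np.linalg.inv(Xs.T @ Xs)
        bse = np.sqrt(np.diag(cov))
        boundary = lam - lo < 1e-4 * (hi - lo) or hi - lam < 1e-4 * (hi - lo)
        return SpatialErrorResults(
            model=self, params=beta, lam=lam, sigma2=sigma2, llf=llf,
            llf_ols=llf0, llf_null=llf_null, bse=bse,
            converged=bool(res.success), boundary=boundary,
        )


# ----------------------------------------------------------------------- IDW


def idw_interpolate(
    points: np.ndarray,
    values: np.ndarray,
    targets: np.ndarray,
    power: float = 2.0,
    max_neighbors: int | None = None,
    metric: str = "haversine",
) -> np.ndarray:
    """Inverse-distance-weighted interpolation; exact at data points.

    Weights are d^(-power); a target coinciding with a data point takes that
    point's value.  With ``max_neighbors`` only the nearest k points
    contribute.  Predictions are convex combinations of the data, hence
    bounded by the data range.
    """
    pts = np.asarray(points, dtype=float)
    vals = np.asarray(values, dtype=float)
    tg = np.asarray(targets, dtype=float)
    if pts.shape[0] == 0:
        raise ValueError("no data points")
    out = np.empty(tg.shape[0])
    for t in range(tg.shape[0]):
        if metric == "haversine":
            d = haversine_km(np.broadcast_to(tg[t], pts.shape), pts)
        else:
            d = np.sqrt(((pts - tg[t]) ** 2).sum(axis=1))
        d = np.atleast_1d(d)
        hit = d < 1e-12
        if hit.any():
            out[t] = vals[hit][0]
            continue
        if max_neighbors is not None and max_neighbors < d.size:
            idx = np.argpartition(d, max_neighbors)[:max_neighbors]
        else:
            idx = slice(None)
        w = d[idx] ** (-power)
        out[t] = (w * vals[idx]).sum() / w.sum()
    return out
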