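"""Testing the stationarity of PCS-climate relationships through time.

For one PCS metric (NRI or NTI) and one explanatory variable, three nested
model forms are fitted:

* stable_relationship:  PCS ~ x                (time neglected)
* stable_slope:         PCS ~ x + time         (intercepts vary by slice)
* changed_relationship: PCS ~ x * time         (intercepts and slopes vary)

Time enters as a categorical factor with one level per retained 1-ka slice
(reference level = the most recent slice).  Each form is fitted by OLS and by
the maximum-likelihood spatial-error model; the three forms are compared by
partial F-tests (OLS) or likelihood-ratio tests (SAR).  For SAR the
distance-band threshold is chosen, per variable, as the candidate distance
whose stable_relationship fit has the smallest |residual Moran's I|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from paleopcs.spatial import (
    DistanceBandWeights,
    MoranResult,
    SpatialErrorModel,
    SpatialErrorResults,
    fit_ols,
    morans_i,
)

log = logging.getLogger(__name__)

FORMS = ["stable_relationship", "stable_slope", "changed_relationship"]
DEFAULT_DISTANCES_KM = [120.0, 360.0, 480.0]
DEFAULT_MIN_SITES = 10


def exclude_sparse_periods(pcs: pd.DataFrame, min_sites: int = DEFAULT_MIN_SITES,
                           value_col: str | None = None) -> pd.DataFrame:
    """Drop every time slice with fewer than ``min_sites`` valid PCS rows."""
    df = pcs
    valid = df if value_col is None else df.loc[df[value_col].notna()]
    counts = valid.groupby("time_ka").size()
    drop = counts.index[counts < min_sites]
    keep_slices = counts.index[counts >= min_sites]
    if len(keep_slices) == 0:
        raise ValueError("all time slices fall below the minimum site count")
    if len(drop):
        log.info("excluding sparse slices (<%d sites): %s", min_sites, list(drop))
    return df.loc[df["time_ka"].isin(keep_slices)].copy()


def build_design(data: pd.DataFrame, variable: str, form: str,
                 metric: str = "nri",
                 time_encoding: str = "categorical",
                 ) -> tuple[np.ndarray, pd.DataFrame]:
    """Response vector and design matrix for one model form.

    Categorical time uses indicator columns for every slice except the
    reference (the most recent retained slice, i.e. the smallest ka value);
    the changed form adds x-by-indicator interactions.  Column counts are 2,
    1 + k, and 2k for the three forms, with k retained slices.
    """
    if form not in FORMS:
        raise ValueError(f"unknown form {form!r}")
    df = data.loc[data[metric].notna() & data[variable].notna()].copy()
    x = df[variable].to_numpy(dtype=float)
    y = df[metric].to_numpy(dtype=float)
    cols: dict[str, np.ndarray] = {"const": np.ones_like(x), variable: x}
    if form != "stable_relationship":
        if time_encoding == "categorical":
            times = np.sort(df["time_ka"].unique())
            if len(times) < 2:
                raise ValueError(f"{form} needs at least 2 time levels")
            for t in times[1:]:  # reference = most recent slice
                ind = (df["time_ka"] == t).to_numpy(dtype=float)
                cols[f"t{int(t)}"] = ind
                if form == "changed_relationship":
                    cols[f"{variable}:t{int(t)}"] = x * ind
        elif time_encoding == "continuous":
            tval = df["time_ka"].to_numpy(dtype=float)
            cols["time_ka"] = tval
            if form == "changed_relationship":
                cols[f"{variable}:time_ka"] = x * tval
        else:
            raise ValueError(f"unknown time encoding {time_encoding!r}")
    X = pd.DataFrame(cols, index=df.index)
    return y, X


@dataclass
class StationarityResults:
    """Fit of one (metric, variable, form, estimator) combination."""

    metric: str
    variable: str
    form: str
    estimator: str
    fit: object  # statsmodels OLSResults or SpatialErrorResults
    n: int
    distance_km: float | None = None
    moran: MoranResult | None = None
    times: np.ndarray | None = None

    @property
    def params(self) -> pd.Series:
        if self.estimator == "ols":
            return pd.Series(self.fit.params)
        return pd.Series(self.fit.params, index=self.fit.model.exog_names)

    @property
    def llf(self) -> float:
        return float(self.fit.llf)

    @property
    def rsquared(self) -> float:
        """Adjusted R-squared (OLS) or Nagelkerke pseudo-R-squared (SAR)."""
        if self.estimator == "ols":
            return float(self.fit.rsquared_adj)
        return float(self.fit.pseudo_r2)

    @property
    def resid(self) -> np.ndarray:
        return np.asarray(self.fit.resid)

    def summary(self) -> str:
        head = (f"{self.metric.upper()} ~ {self.variable} "
                f"[{self.form}, {self.estimator.upper()}"
                + (f", {self.distance_km:g} km]" if self.distance_km else "]"))
        body = self.fit.summary()
        return head + "\n" + str(body)


class StationarityModel:
    """One PCS-climate stationarity regression, statsmodels style.

    Parameters
    ----------
    data
        PCS table joined with the explanatory variables; must contain the
        metric column, the variable column and ``time_ka`` (plus
        ``cell_lon``/``cell_lat`` for the SAR estimator).
    metric, variable, form, estimator
        What to regress, which nested form, and 'ols' or 'sar'.
    weights / distance_km
        For SAR: either ready-made weights aligned with the (filtered) rows,
        or a distance threshold from which weights are built.
    """

    def __init__(self, data: pd.DataFrame, metric: str, variable: str,
                 form: str = "stable_relationship", estimator: str = "ols",
                 weights: DistanceBandWeights | None = None,
                 distance_km: float | None = None,
                 time_encoding: str = "categorical"):
        if estimator not in ("ols", "sar"):
            raise ValueError("estimator must be 'ols' or 'sar'")
        self.metric, self.variable = metric, variable
        self.form, self.estimator = form, estimator
        self.time_encoding = time_encoding
        mask = data[metric].notna() & data[variable].notna()
        self.data = data.loc[mask].copy()
        self.endog, self.exog = build_design(
            self.data, variable, form, metric, time_encoding)
        self.distance_km = distance_km
        if estimator == "sar":
            if weights is None:
                if distance_km is None:
                    raise ValueError("SAR needs weights or a distance_km")
                pts = self.data[["cell_lon", "cell_lat"]].to_numpy(dtype=float)
                weights = DistanceBandWeights(pts, distance_km)
            if weights.n != len(self.data):
                raise ValueError("weights do not align with the model rows")
        self.weights = weights

    def fit(self, moran_perm: int = 0, seed: int | None = None) -> StationarityResults:
        if self.estimator == "ols":
            res = fit_ols(self.endog, self.exog)
        else:
            res = SpatialErrorModel(self.endog, self.exog, self.weights).fit()
        moran = None
        if self.weights is not None:
            resid = np.asarray(res.resid)
            w = self.weights
            if self.estimator == "sar" and res.model.nobs != w.n:
                w = res.model.weights  # islands were dropped inside the model
            try:
                moran = morans_i(resid, w, n_perm=moran_perm, seed=seed)
            except ValueError:
                moran = None
        return StationarityResults(
            metric=self.metric, variable=self.variable, form=self.form,
            estimator=self.estimator, fit=res, n=len(self.endog),
            distance_km=self.distance_km, moran=moran,
            times=np.sort(self.data["time_ka"].unique()))


def select_weight_distance(stable_fits: dict[float, StationarityResults]) -> float:
    """Distance whose stable_relationship fit minimizes |residual Moran's I|.

    Ties are broken toward the smallest distance (sparser weights).
    """
    if not stable_fits:
        raise ValueError("no candidate fits")
    best, best_abs = None, np.inf
    for d in sorted(stable_fits):
        r = stable_fits[d]
        if r.moran is None:
            continue
        a = abs(r.moran.I)
        if a < best_abs - 1e-15:
            best, best_abs = d, a
    if best is None:
        raise ValueError("no candidate fit has a residual Moran's I")
    return best


def fit_model_set(data: pd.DataFrame, metric: str, variable: str,
                  estimator: str = "ols",
                  distances_km: list[float] = None,
                  time_encoding: str = "categorical",
                  ) -> dict:
    """Fit all three nested forms; for SAR, select the distance first.

    Returns ``{"fits": {form: StationarityResults}, "distance_km": float|None,
    "stable_by_distance": {...}}``.
    """
    distances_km = distances_km or DEFAULT_DISTANCES_KM
    out: dict = {"fits": {}, "distance_km": None, "stable_by_distance": {}}
    if estimator == "ols":
        pts = data.loc[data[metric].notna() & data[variable].notna(),
                       ["cell_lon", "cell_lat"]].to_numpy(dtype=float)
        for form in FORMS:
            m = StationarityModel(data, metric, variable, form, "ols")
            res = m.fit()
            # residual Moran diagnostics for OLS use each candidate distance;
            # record at the smallest for the summary table
            out["fits"][form] = res
        return out
    # SAR: choose distance on the stable form
    stable = {}
    for d in distances_km:
        try:
            m = StationarityModel(data, metric, variable,
                                  "stable_relationship", "sar", distance_km=d)
            stable[d] = m.fit()
        except ValueError as exc:
            log.warning("SAR stable fit failed at %g km: %s", d, exc)
    chosen = select_weight_distance(stable)
    out["stable_by_distance"] = stable
    out["distance_km"] = chosen
    out["fits"]["stable_relationship"] = stable[chosen]
    for form in FORMS[1:]:
        m = StationarityModel(data, metric, variable, form, "sar",
                              distance_km=chosen, time_encoding=time_encoding)
        out["fits"][form] = m.fit()
    return out


@dataclass
class ComparisonResult:
    estimator: str
    smaller: str
    larger: str
    statistic: float
    df: tuple
    p: float

    @property
    def rejects(self) -> bool:
        return self.p < 0.05


def compare_nested(fit_small: StationarityResults,
                   fit_large: StationarityResults) -> ComparisonResult:
    """Partial F-test (OLS) or likelihood-ratio chi-square test (SAR).

    The smaller design must be nested in the larger and fitted to the same
    rows.
    """
    if fit_small.estimator != fit_large.estimator:
        raise ValueError("cannot compare fits from different estimators")
    ks = FORMS.index(fit_small.form)
    kl = FORMS.index(fit_large.form)
    if ks >= kl:
        raise ValueError("fits are not nested in the expected order")
    if fit_small.n != fit_large.n:
        raise ValueError("fits use different observations")
    if fit_small.estimator == "ols":
        rss_s, rss_l = float(fit_small.fit.ssr), float(fit_large.fit.ssr)
        df_num = fit_large.fit.df_model - fit_small.fit.df_model
        df_den = fit_large.fit.df_resid
        tss = float(getattr(fit_large.fit, "centered_tss", 1.0)) or 1.0
        if rss_s <= 1e-12 * tss:  # both fits numerically perfect
            F = 0.0
        else:
            F = max(0.0, (rss_s - rss_l) / df_num / (rss_l / df_den))
        p = float(scipy.stats.f.sf(F, df_num, df_den))
        return ComparisonResult("ols", fit_small.form, fit_large.form,
                                F, (int(df_num), int(df_den)), p)
    lr = max(0.0, 2.0 * (fit_large.llf - fit_small.llf))
    df = fit_large.fit.df_model - fit_small.fit.df_model
    p = float(scipy.stats.chi2.sf(lr, df))
    return ComparisonResult("sar", fit_small.form, fit_large.form,
                            lr, (int(df),), p)


def select_form(fits: dict[str, StationarityResults],
                alpha: float = 0.05) -> tuple[str, list[ComparisonResult]]:
    """Sequential nested comparison: keep a larger form only when the test
    against the next smaller form rejects at ``alpha``."""
    comparisons = [
        compare_nested(fits["stable_relationship"], fits["stable_slope"]),
        compare_nested(fits["stable_slope"], fits["changed_relationship"]),
    ]
    if comparisons[1].p < alpha:
        selected = "changed_relationship"
    elif comparisons[0].p < alpha:
        selected = "stable_slope"
    else:
        selected = "stable_relationship"
    return selected, comparisons


def extract_time_coefficients(result: StationarityResults) -> pd.DataFrame:
    """Per-slice intercept and slope implied by a fitted form.

    For the changed form the reference slice uses the base intercept and
    slope; other slices add their indicator offset and interaction.  For the
    stable_slope form slopes are constant; for stable_relationship both are.
    """
    params = result.params
    variable = result.variable
    times = result.times
    base_int = params["const"]
    base_slope = params[variable]
    rows = []
    for t in times:
        it = base_int + params.get(f"t{int(t)}", 0.0)
        sl = base_slope + params.get(f"{variable}:t{int(t)}", 0.0)
        rows.append((int(t), float(it), float(sl)))
    return pd.DataFrame(rows, columns=["time_ka", "intercept", "slope"])


def geographic_trend(pcs: pd.DataFrame, metric: str, axis: str):
    """Pooled OLS of a PCS metric against longitude or latitude (per degree)."""
    coord = {"lon": "cell_lon", "lat": "cell_lat"}.get(axis, axis)
    df = pcs.loc[pcs[metric].notna(), [coord, metric]]
    X = pd.DataFrame({"const": np.ones(len(df)), coord: df[coord].to_numpy()})
    return fit_ols(df[metric].to_numpy(), X)


def equalize_sample_sizes(pcs: pd.DataFrame, n_per_slice: int,
                          seed: int | np.random.SeedSequence | None = None,
                          value_col: str = "nri",
                          on_small: str = "error") -> pd.DataFrame:
    """Random subsample of ``n_per_slice`` valid rows from every slice.

    Deterministic under a fixed seed.  Slices smaller than ``n_per_slice``
    raise (``on_small='error'``) or are dropped with a log entry
    (``on_small='drop'``).
    """
    rng = np.random.default_rng(seed)
    pieces = []
    for t, sl in pcs.loc[pcs[value_col].notna()].groupby("time_ka"):
        if len(sl) < n_per_slice:
            if on_small == "drop":
                log.info("dropping slice %s with %d < %d rows", t, len(sl),
                         n_per_slice)
                continue
            raise ValueError(f"slice {t} has {len(sl)} < {n_per_slice} rows")
        idx = rng.choice(len(sl), size=n_per_slice, replace=False)
        pieces.append(sl.iloc[np.sort(idx)])
    if not pieces:
        return pcs.iloc[0:0].copy()
    return pd.concat(pieces, ignore_index=True)
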