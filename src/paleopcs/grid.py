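"""Site quality filtering, 0.5-degree gridding, and climate collinearity screen.

Sites are fossil-pollen records with per-taxon relative abundances at 1-ka
time slices and a precomputed quality score in [0, 1].  Only sites with
quality strictly above the threshold (default 0.75) are kept.  Sites falling
in the same grid cell and slice have their abundances averaged (taxa absent
from a site count as zero, since relative abundances share a closed sum);
occurrence is abundance > 0.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SITE_COLUMNS = ["site_id", "lon", "lat", "time_ka", "quality", "taxon", "rel_abund"]
CLIMATE_VARIABLES = ["tmin", "tmax", "pmin", "pmax", "aet", "etr", "wdi"]

DEFAULT_RESOLUTION = 0.5
DEFAULT_QUALITY_THRESHOLD = 0.75
DEFAULT_R_THRESHOLD = 0.75


def filter_by_quality(sites: pd.DataFrame,
                      threshold: float = DEFAULT_QUALITY_THRESHOLD) -> pd.DataFrame:
    """Keep site records with quality strictly greater than ``threshold``.

    Records with a missing quality value are rejected with a warning.
    """
    if "quality" not in sites.columns:
        raise KeyError("sites table lacks a 'quality' column")
    missing = sites["quality"].isna()
    if missing.any():
        log.warning("dropping %d records with missing quality", int(missing.sum()))
    out = sites.loc[~missing & (sites["quality"] > threshold)].copy()
    kept = out.groupby("time_ka")["site_id"].nunique()
    log.info("quality filter >%s kept sites per slice: %s",
             threshold, kept.to_dict())
    return out


def assign_to_grid(lon: float, lat: float,
                   resolution: float = DEFAULT_RESOLUTION) -> tuple[float, float]:
    """Lower-left corner of the half-open grid cell containing (lon, lat).

    Cells are [corner, corner + resolution) in both axes, anchored at
    integer degrees.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    return (math.floor(lon / resolution) * resolution,
            math.floor(lat / resolution) * resolution)


def grid_sites(sites: pd.DataFrame,
               resolution: float = DEFAULT_RESOLUTION) -> pd.DataFrame:
    """Assign each site record to its grid cell and average within cells.

    Returns a long-format table with one row per (cell, slice, taxon):
    columns cell_lon, cell_lat, time_ka, taxon, rel_abund, occurrence,
    n_sites.  Averaging treats taxa missing from a co-located site as zero
    abundance and is invariant to site order.
    """
    df = sites.copy()
    res = float(resolution)
    df["cell_lon"] = np.floor(df["lon"] / res) * res
    df["cell_lat"] = np.floor(df["lat"] / res) * res

    records = []
    for (clon, clat, t), cell in df.groupby(["cell_lon", "cell_lat", "time_ka"]):
        site_ids = sorted(cell["site_id"].unique())
        n_sites = len(site_ids)
        # implicit zeros: mean over sites = sum of abundances / n_sites
        sums = cell.groupby("taxon")["rel_abund"].sum().sort_index()
        mean = sums / n_sites
        for taxon, ab in mean.items():
            records.append((clon, clat, t, taxon, ab, int(ab > 0), n_sites))
    out = pd.DataFrame(
        records,
        columns=["cell_lon", "cell_lat", "time_ka", "taxon",
                 "rel_abund", "occurrence", "n_sites"],
    )
    return out.sort_values(["time_ka", "cell_lat", "cell_lon", "taxon"],
                           ignore_index=True)


def occurrence_matrix(gridded: pd.DataFrame, time_ka: int,
                      taxa: list[str] | None = None,
                      drop_absent: bool = True) -> pd.DataFrame:
    """Binary cell-by-taxon matrix for one time slice.

    Row index is (cell_lon, cell_lat); columns are the supplied taxon list
    (e.g. the tree's tips) or the taxa observed in the slice.  With
    ``drop_absent`` taxa occurring nowhere in the slice are removed, so the
    null model randomizes only the slice's own taxon pool.
    """
    sl = gridded.loc[(gridded["time_ka"] == time_ka) & (gridded["occurrence"] > 0)]
    mat = (
        sl.pivot_table(index=["cell_lon", "cell_lat"], columns="taxon",
                       values="occurrence", aggfunc="max", fill_value=0)
    )
    if taxa is not None:
        extra = set(mat.columns) - set(taxa)
        if extra:
            raise KeyError(f"taxa not in the provided list: {sorted(extra)}")
        mat = mat.reindex(columns=taxa, fill_value=0)
    if drop_absent:
        mat = mat.loc[:, mat.sum(axis=0) > 0]
    return mat.astype(np.int8)


def screen_collinearity(climate: pd.DataFrame,
                        r_threshold: float = DEFAULT_R_THRESHOLD,
                        variables: list[str] | None = None,
                        ) -> tuple[list[str], pd.DataFrame]:
    """Greedy collinearity screen at |Pearson r| < threshold.

    While any pair exceeds the threshold, the variable involved in the
    largest number of offending pairs (ties: largest mean absolute
    correlation, then reverse variable order) is removed.  Returns the
    retained variables and the full correlation matrix.  Zero-variance
    variables are dropped with a warning.
    """
    variables = variables or [v for v in CLIMATE_VARIABLES if v in climate.columns]
    data = climate[variables].dropna()
    if len(data) < 2:
        raise ValueError("need at least 2 complete rows")
    keep = []
    for v in variables:
        if data[v].nunique() <= 1:
            log.warning("dropping zero-variance variable %s", v)
        else:
            keep.append(v)
    corr = data[keep].corr(method="pearson")
    retained = list(keep)
    while True:
        sub = corr.loc[retained, retained].abs()
        np.fill_diagonal(sub.values, 0.0)
        if (sub.values < r_threshold).all():
            break
        offend = (sub >= r_threshold).sum(axis=1)
        worst = offend[offend == offend.max()].index
        if len(worst) > 1:
            mean_abs = sub.loc[worst].mean(axis=1)
            worst = mean_abs[mean_abs == mean_abs.max()].index
        retained.remove(worst[-1])
    return retained, corr
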