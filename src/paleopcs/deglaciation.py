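"""Ice-sheet masks, time since deglaciation (DEGLAC), and PCS-DEGLAC summaries.

Time runs in ka BP on integer 1-ka slices, counting down toward the present
(0 ka).  A cell last glaciated at slice ``g`` is first ice-free at ``g - 1``
and its DEGLAC at slice ``t <= g - 1`` is the number of whole ka elapsed
since that first ice-free slice; cells never glaciated in the record accrue
DEGLAC from the record start.  DEGLAC is undefined while a cell is
glaciated and resets if a cell re-glaciates.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from paleopcs.spatial import fit_ols

log = logging.getLogger(__name__)


def align_ice_to_slices(layers: pd.DataFrame, slices: list[int]) -> pd.DataFrame:
    """Assign each native-age ice layer to the closest 1-ka slice.

    ``layers`` has columns cell_lon, cell_lat, age_ka, glaciated.  Each slice
    receives the layer of minimal |age difference|; exact half-way ties go to
    the younger layer.  Returns masks with a time_ka column.
    """
    ages = np.sort(layers["age_ka"].unique())
    out = []
    for t in slices:
        diffs = np.abs(ages - t)
        best = diffs.min()
        candidates = ages[diffs == best]
        chosen = candidates.min()  # tie -> younger layer
        if len(candidates) > 1:
            log.info("slice %s: tie between layers %s, using %s",
                     t, list(candidates), chosen)
        sel = layers.loc[layers["age_ka"] == chosen,
                         ["cell_lon", "cell_lat", "glaciated"]].copy()
        sel["time_ka"] = t
        out.append(sel)
    return pd.concat(out, ignore_index=True)


def reclassify_conflicts(masks: pd.DataFrame,
                         pollen_cells: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Make any glaciated (cell, slice) that holds a pollen assemblage ice-free.

    Such conflicts arise from temporal mismatch between ice reconstructions
    and the pollen record; the pollen data are trusted.  Returns the
    corrected masks and the conflict count.
    """
    keys = set(map(tuple, pollen_cells[["cell_lon", "cell_lat", "time_ka"]]
                   .drop_duplicates().itertuples(index=False)))
    out = masks.copy()
    mask_keys = list(map(tuple, out[["cell_lon", "cell_lat", "time_ka"]]
                         .itertuples(index=False)))
    conflict = np.array([k in keys for k in mask_keys]) & (out["glaciated"] == 1).to_numpy()
    n = int(conflict.sum())
    if n:
        log.info("reclassifying %d glaciated cells containing pollen as ice-free", n)
        out.loc[conflict, "glaciated"] = 0
    return out, n


def time_since_deglaciation(masks: pd.DataFrame,
                            record_start_ka: int | None = None) -> pd.DataFrame:
    """Per-(cell, slice) DEGLAC in whole ka.

    ``masks`` must cover every slice for every cell (columns cell_lon,
    cell_lat, time_ka, glaciated).  DEGLAC at slice t is t_first_free - t,
    where t_first_free is the first ice-free slice after the most recent
    glaciation (or ``record_start_ka`` for never-glaciated cells).  Returns
    masks with a ``deglac`` column (NaN while glaciated).
    """
    if record_start_ka is None:
        record_start_ka = int(masks["time_ka"].max())
    out = masks.copy()
    out["deglac"] = np.nan
    pieces = []
    for (_clon, _clat), cell in out.groupby(["cell_lon", "cell_lat"]):
        cell = cell.sort_values("time_ka", ascending=False).copy()
        t_first_free = None
        prev_glaciated = None
        deglac = []
        for _, row in cell.iterrows():
            t = row["time_ka"]
            if row["glaciated"]:
                if prev_glaciated is False:
                    log.info("re-glaciation at cell (%s, %s) slice %s",
                             _clon, _clat, t)
                t_first_free = None
                deglac.append(np.nan)
                prev_glaciated = True
            else:
                if t_first_free is None:
                    t_first_free = record_start_ka if prev_glaciated is None else t
                deglac.append(float(t_first_free - t))
                prev_glaciated = False
        cell["deglac"] = deglac
        pieces.append(cell)
    return pd.concat(pieces, ignore_index=True)


def deglac_heatmap(pcs: pd.DataFrame, ice: pd.DataFrame,
                   value_col: str = "nri") -> pd.DataFrame:
    """Mean PCS per (time slice, DEGLAC class) bin.

    Joins PCS rows to ice-free cells on (cell, slice); DEGLAC classes are
    whole ka.  Returns time_ka, deglac_ka, mean_value, n_cells.
    """
    joined = pcs.merge(ice.loc[ice["deglac"].notna()],
                       on=["cell_lon", "cell_lat", "time_ka"], how="inner")
    joined = joined.loc[joined[value_col].notna()]
    grp = joined.groupby(["time_ka", "deglac"])[value_col]
    out = grp.agg(mean_value="mean", n_cells="size").reset_index()
    out = out.rename(columns={"deglac": "deglac_ka"})
    out["deglac_ka"] = out["deglac_ka"].astype(int)
    return out.sort_values(["time_ka", "deglac_ka"], ignore_index=True)


def climate_residual_heatmap(pcs: pd.DataFrame, climate: pd.DataFrame,
                             ice: pd.DataFrame, value_col: str = "nri",
                             climate_vars: list[str] | None = None
                             ) -> pd.DataFrame:
    """DEGLAC heatmap of residual PCS after removing climate effects.

    A single pooled OLS of the PCS metric on all climate variables (plus an
    intercept) is fitted across every cell and slice; the heatmap then bins
    its residuals by (slice, DEGLAC class).
    """
    from paleopcs.grid import CLIMATE_VARIABLES

    climate_vars = climate_vars or [v for v in CLIMATE_VARIABLES
                                    if v in climate.columns]
    merged = pcs.merge(climate, on=["cell_lon", "cell_lat", "time_ka"],
                       how="inner")
    merged = merged.dropna(subset=[value_col] + climate_vars)
    X = merged[climate_vars].copy()
    X.insert(0, "const", 1.0)
    res = fit_ols(merged[value_col].to_numpy(), X)
    merged = merged.copy()
    merged["_resid"] = np.asarray(res.resid)
    return deglac_heatmap(merged, ice, value_col="_resid")
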