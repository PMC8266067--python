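"""NRI/NTI standardized effect sizes under the independent-swap null model.

Communities are binary presence/absence rows over a shared taxon set.  For
each assemblage the observed mean pairwise phylogenetic distance (MPD) and
mean nearest-taxon distance (MNTD) are compared to a null distribution
obtained by independent-swap randomization of the whole site-by-taxon matrix
— 2x2 checkerboard submatrix swaps that preserve every row sum (richness) and
column sum (taxon occurrence frequency) exactly.  The standardized effect
sizes are negated so that positive values mean phylogenetic clustering:

    NRI = -(MPD_obs - mean MPD_null) / sd MPD_null
    NTI = -(MNTD_obs - mean MNTD_null) / sd MNTD_null

Null defaults are 999 randomizations of 1000 trial swaps each, every run
starting from the observed matrix under an independent RNG substream.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_NULL_RUNS = 999
DEFAULT_TRIAL_SWAPS = 1000

try:  # numba accelerates the swap chain and per-row metrics when available
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def _njit(*args, **kwargs):
        def deco(f):
            return f
        return deco if not (args and callable(args[0])) else args[0]


@_njit(cache=False)
def _swap_kernel(M, rows, cols):  # pragma: no cover - exercised via wrapper
    for t in range(rows.shape[0]):
        r1, r2 = rows[t, 0], rows[t, 1]
        c1, c2 = cols[t, 0], cols[t, 1]
        if r1 == r2 or c1 == c2:
            continue
        a = M[r1, c1]
        if a == M[r2, c2] and a != M[r1, c2] and a == 1 - M[r2, c1]:
            M[r1, c1] = 1 - a
            M[r2, c2] = 1 - a
            M[r1, c2] = a
            M[r2, c1] = a


@_njit(cache=False)
def _row_metrics_kernel(M, D, out_mpd, out_mntd):  # pragma: no cover
    n, p = M.shape
    for i in range(n):
        k = 0
        for j in range(p):
            if M[i, j] == 1:
                k += 1
        if k < 2:
            out_mpd[i] = np.nan
            out_mntd[i] = np.nan
            continue
        idx = np.empty(k, dtype=np.int64)
        c = 0
        for j in range(p):
            if M[i, j] == 1:
                idx[c] = j
                c += 1
        total = 0.0
        sum_min = 0.0
        for a in range(k):
            mind = np.inf
            for b in range(k):
                if a == b:
                    continue
                d = D[idx[a], idx[b]]
                total += d
                if d < mind:
                    mind = d
            sum_min += mind
        out_mpd[i] = total / (k * (k - 1))
        out_mntd[i] = sum_min / k


def _as_binary(matrix: np.ndarray) -> np.ndarray:
    M = np.asarray(matrix)
    if not np.isin(M, (0, 1)).all():
        raise ValueError("occurrence matrix must be binary (0/1)")
    return M.astype(np.int8)


def mpd(presence: np.ndarray, D: np.ndarray) -> float:
    """Mean pairwise distance among present taxa; NaN when richness < 2."""
    idx = np.flatnonzero(presence)
    if idx.size < 2:
        return np.nan
    sub = D[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def mntd(presence: np.ndarray, D: np.ndarray) -> float:
    """Mean distance from each present taxon to its nearest present relative."""
    idx = np.flatnonzero(presence)
    if idx.size < 2:
        return np.nan
    sub = D[np.ix_(idx, idx)].astype(float)
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def _mpd_mntd_rows(M: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n = M.shape[0]
    out_mpd = np.empty(n)
    out_mntd = np.empty(n)
    if _HAVE_NUMBA:
        _row_metrics_kernel(np.ascontiguousarray(M, dtype=np.int8),
                            np.ascontiguousarray(D, dtype=np.float64),
                            out_mpd, out_mntd)
        return out_mpd, out_mntd
    for i in range(n):
        idx = np.flatnonzero(M[i])
        k = idx.size
        if k < 2:
            out_mpd[i] = np.nan
            out_mntd[i] = np.nan
            continue
        sub = D[np.ix_(idx, idx)]
        total = sub.sum()
        out_mpd[i] = total / (k * (k - 1))
        sub = sub + np.diag(np.full(k, np.inf))
        out_mntd[i] = sub.min(axis=1).mean()
    return out_mpd, out_mntd


def independent_swap(
    matrix: np.ndarray,
    n_trial_swaps: int = DEFAULT_TRIAL_SWAPS,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Randomize a binary matrix by attempted 2x2 checkerboard swaps.

    ``n_trial_swaps`` random (row pair, column pair) draws are attempted; a
    swap is applied only when the 2x2 submatrix is a checkerboard
    ([[1,0],[0,1]] or [[0,1],[1,0]]), so row and column sums are conserved
    exactly.  Deterministic under a fixed seed.
    """
    M = _as_binary(matrix).copy()
    nr, nc = M.shape
    if nr < 2 or nc < 2:
        return M
    rng = np.random.default_rng(seed)
    # draw all candidate quadruples up front so the numba and Python paths
    # consume identical random streams
    rows = rng.integers(0, nr, size=(n_trial_swaps, 2))
    cols = rng.integers(0, nc, size=(n_trial_swaps, 2))
    if _HAVE_NUMBA:
        _swap_kernel(M, rows, cols)
        return M
    for t in range(n_trial_swaps):
        r1, r2 = rows[t]
        c1, c2 = cols[t]
        if r1 == r2 or c1 == c2:
            continue
        a = M[r1, c1]
        if a == M[r2, c2] and a != M[r1, c2] and a == 1 - M[r2, c1]:
            M[r1, c1] = M[r2, c2] = 1 - a
            M[r1, c2] = M[r2, c1] = a
    return M


def null_taxa_shuffle(
    matrix: np.ndarray, n_trial_swaps: int = 0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Alternate null: permute taxon (column) labels; preserves row sums."""
    M = _as_binary(matrix).copy()
    rng = np.random.default_rng(seed)
    return M[:, rng.permutation(M.shape[1])]


def null_richness(
    matrix: np.ndarray, n_trial_swaps: int = 0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Alternate null: redraw each row uniformly at its observed richness."""
    M = _as_binary(matrix)
    rng = np.random.default_rng(seed)
    out = np.zeros_like(M)
    nc = M.shape[1]
    for i in range(M.shape[0]):
        k = int(M[i].sum())
        out[i, rng.choice(nc, size=k, replace=False)] = 1
    return out


_NULL_MODELS = {
    "independentswap": independent_swap,
    "taxa_shuffle": null_taxa_shuffle,
    "richness": null_richness,
}


def ses_pcs(
    matrix: np.ndarray | pd.DataFrame,
    D: np.ndarray | pd.DataFrame,
    n_runs: int = DEFAULT_NULL_RUNS,
    n_trial_swaps: int = DEFAULT_TRIAL_SWAPS,
    seed: int | np.random.SeedSequence | None = None,
    null_model: str = "independentswap",
    check_margins: bool = True,
) -> pd.DataFrame:
    """Standardized NRI/NTI for every row of an occurrence matrix.

    Parameters
    ----------
    matrix
        Binary assemblage-by-taxon matrix; a DataFrame's columns must match
        the labels of ``D``.
    D
        Patristic distance matrix over (a superset of) the matrix's taxa.
    n_runs, n_trial_swaps
        Number of null randomizations and trial swaps per randomization.
    seed
        Master seed; each null run uses an independent substream.
    null_model
        ``independentswap`` (default), ``taxa_shuffle`` or ``richness``.

    Returns
    -------
    DataFrame with columns richness, mpd, mntd, mpd_null_mean, mpd_null_sd,
    mntd_null_mean, mntd_null_sd, nri, nti.  Rows with richness < 2 or a
    zero null SD get missing SES values.
    """
    if null_model not in _NULL_MODELS:
        raise ValueError(f"unknown null model {null_model!r}")
    nullfun = _NULL_MODELS[null_model]

    index = None
    if isinstance(matrix, pd.DataFrame):
        if isinstance(D, pd.DataFrame):
            missing = set(matrix.columns) - set(D.index)
            if missing:
                raise KeyError(f"taxa absent from distance matrix: {sorted(missing)}")
            D = D.loc[matrix.columns, matrix.columns]
        index = matrix.index
        matrix = matrix.to_numpy()
    Dm = np.asarray(D, dtype=float)
    M = _as_binary(matrix)
    if Dm.shape[0] != M.shape[1]:
        raise ValueError("distance matrix does not match taxon count")

    obs_mpd, obs_mntd = _mpd_mntd_rows(M, Dm)
    row_sums = M.sum(axis=1)
    col_sums = M.sum(axis=0)

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_runs)
    null_mpd = np.empty((n_runs, M.shape[0]))
    null_mntd = np.empty((n_runs, M.shape[0]))
    for r in range(n_runs):
        Mn = nullfun(M, n_trial_swaps, np.random.default_rng(children[r]))
        if check_margins and null_model == "independentswap":
            assert (Mn.sum(axis=1) == row_sums).all()
            assert (Mn.sum(axis=0) == col_sums).all()
        null_mpd[r], null_mntd[r] = _mpd_mntd_rows(Mn, Dm)

    mpd_mean = null_mpd.mean(axis=0)
    mpd_sd = null_mpd.std(axis=0, ddof=1)
    mntd_mean = null_mntd.mean(axis=0)
    mntd_sd = null_mntd.std(axis=0, ddof=1)

    # a null SD at rounding-error scale means the null is degenerate
    mpd_tol = 1e-10 * np.maximum(1.0, np.abs(mpd_mean))
    mntd_tol = 1e-10 * np.maximum(1.0, np.abs(mntd_mean))
    with np.errstate(divide="ignore", invalid="ignore"):
        nri = -(obs_mpd - mpd_mean) / mpd_sd
        nti = -(obs_mntd - mntd_mean) / mntd_sd
    nri = np.where(mpd_sd > mpd_tol, nri, np.nan)
    nti = np.where(mntd_sd > mntd_tol, nti, np.nan)

    return pd.DataFrame(
        {
            "richness": row_sums,
            "mpd": obs_mpd,
            "mntd": obs_mntd,
            "mpd_null_mean": mpd_mean,
            "mpd_null_sd": mpd_sd,
            "mntd_null_mean": mntd_mean,
            "mntd_null_sd": mntd_sd,
            "nri": nri,
            "nti": nti,
            "null_runs": n_runs,
        },
        index=index,
    )


def enumerate_margin_preserving(matrix: np.ndarray) -> list[np.ndarray]:
    """All binary matrices with the given row and column sums (tiny inputs).

    Exhaustive oracle for the independent-swap null on matrices small enough
    to enumerate (used in tests; exponential in size).
    """
    M = _as_binary(matrix)
    nr, nc = M.shape
    if nr * nc > 25:
        raise ValueError("matrix too large to enumerate")
    row_sums = M.sum(axis=1)
    col_sums = tuple(M.sum(axis=0))
    out: list[np.ndarray] = []

    from itertools import combinations

    rows_choices = [list(combinations(range(nc), int(k))) for k in row_sums]

    def rec(i: int, current: list[tuple[int, ...]], remaining: np.ndarray) -> None:
        if i == nr:
            if not remaining.any():
                out.append(_rows_to_matrix(current, nc))
            return
        for choice in rows_choices[i]:
            new_rem = remaining.copy()
            ok = True
            for c in choice:
                new_rem[c] -= 1
                if new_rem[c] < 0:
                    ok = False
            if ok and new_rem.sum() <= (nr - i - 1) * nc:
                rec(i + 1, current + [choice], new_rem)

    rec(0, [], np.array(col_sums, dtype=int))
    return out


def _rows_to_matrix(rows: list[tuple[int, ...]], nc: int) -> np.ndarray:
    M = np.zeros((len(rows), nc), dtype=np.int8)
    for i, cols in enumerate(rows):
        M[i, list(cols)] = 1
    return M
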