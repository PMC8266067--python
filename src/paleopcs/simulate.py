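"""Synthetic input bundles: dated tree, climate history, retreating ice,
and communities assembled under known mechanisms.

The generator emulates the structure of a late-Quaternary pollen/climate/ice
study region: a birth-death phylogeny with a Brownian trait (so that
environmental filtering on the trait produces phylogenetic clustering by
construction), seven gridded climate variables built as latitudinal gradient
+ per-ka trend + spatially autocorrelated Gaussian noise, an ice margin
retreating poleward across 1-ka slices, and site assemblages admitted by one
of three mechanisms:

* ``filtering`` — admission probability proportional to
  exp(-(trait - optimum)^2 / (2 tau^2)) with optimum a linear function of a
  focal climate variable whose slope b(t) may change through time;
* ``neutral`` — uniform admission;
* ``limiting_similarity`` — sequential admission rejecting any taxon within
  trait distance delta of a current member.

Ground truth (mechanism, b(t), noise parameters) is recorded alongside the
generated files so parameter-recovery tests can compare against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from paleopcs.tree import Tree, write_tree
from paleopcs.grid import CLIMATE_VARIABLES


@dataclass
class Scenario:
    """Parameters of one synthetic study.

    Defaults are the 'small' preset: 20 taxa on a 10 x 10 grid of 0.5-degree
    cells over 8 1-ka slices, sized so the full pipeline runs end-to-end in
    minutes on one CPU while retaining every structural feature of the
    full-scale inputs.
    """

    n_taxa: int = 20
    birth: float = 1.0
    death: float = 0.0
    sigma2_bm: float = 1.0
    #: grid lower-left corner (lon, lat) and cell counts at `resolution`
    grid_origin: tuple[float, float] = (-85.0, 40.0)
    n_lon: int = 10
    n_lat: int = 10
    resolution: float = 0.5
    n_slices: int = 8  # slices n_slices-1 ... 0 ka BP
    #: climate: per-variable latitudinal gradient is built in; these control
    #: the temporal trend (units per ka toward the present), the spatial
    #: correlation range of the noise (km) and the noise SD
    climate_trend_per_ka: float = 0.5
    climate_range_km: float = 150.0
    climate_noise_sd: float = 1.0
    #: ice margin latitude per slice; by default a linear poleward retreat
    #: from mid-grid to above the grid.  The masks extend ``n_ice_preslices``
    #: slices before the assemblage record, as real ice reconstructions do,
    #: so that cells deglaciated at different pre-record times carry
    #: different DEGLAC values within the record's oldest slice.
    ice_margin_start_lat: float | None = None
    ice_margin_end_lat: float | None = None
    n_ice_preslices: int = 4
    mechanism: str = "filtering"
    tau: float = 1.0
    delta: float = 0.5
    #: slope linking the filtering optimum to the focal climate variable,
    #: per slice (ka value -> slope); a float means constant through time
    b_schedule: float | dict[int, float] = 1.0
    focal_variable: str = "tmin"
    richness_target: int = 8
    fraction_dated_nodes: float = 0.4
    seed: int = 0

    def slices(self) -> list[int]:
        return list(range(self.n_slices - 1, -1, -1))

    def b_at(self, t: int) -> float:
        if isinstance(self.b_schedule, dict):
            return float(self.b_schedule[t])
        return float(self.b_schedule)

    def margin_lat(self, t: int) -> float:
        lat0, nlat, res = self.grid_origin[1], self.n_lat, self.resolution
        start = (self.ice_margin_start_lat
                 if self.ice_margin_start_lat is not None
                 else lat0 + 0.5 * nlat * res)
        end = (self.ice_margin_end_lat
               if self.ice_margin_end_lat is not None
               else lat0 + (nlat + 2) * res)
        total = self.n_slices + self.n_ice_preslices
        if total == 1:
            return end
        frac = 1.0 - t / (total - 1)  # 0 at mask-record start, 1 at present
        return start + frac * (end - start)

    def ice_slices(self) -> list[int]:
        return list(range(self.n_slices - 1 + self.n_ice_preslices, -1, -1))

    @classmethod
    def small(cls, **overrides) -> "Scenario":
        return cls(**overrides)

    @classmethod
    def study_like(cls, **overrides) -> "Scenario":
        """A larger configuration mirroring the real study's proportions
        (96 taxa, 22 slices, wider grid); slow — not used by default tests."""
        defaults = dict(n_taxa=96, n_lon=24, n_lat=20, n_slices=22,
                        richness_target=15)
        defaults.update(overrides)
        return cls(**defaults)


# ------------------------------------------------------------------ phylogeny


def simulate_tree(n_taxa: int, birth: float = 1.0, death: float = 0.0,
                  seed: int | np.random.SeedSequence | None = None) -> Tree:
    """Ultrametric birth-death tree conditioned on ``n_taxa`` extant tips."""
    if not birth > death or death < 0:
        raise ValueError("need birth > death >= 0")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    import random as _random

    rng = _random.Random(int(ss.generate_state(1)[0]))
    dtree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth, death_rate=death, num_extant_tips=n_taxa,
        rng=rng, is_retain_extinct_tips=False,
    )
    for i, leaf in enumerate(dtree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
    tree = Tree.from_dendropy(dtree)
    # name internal nodes so node-age tables can reference them
    k = 0
    for node in tree.preorder():
        if not node.is_leaf:
            k += 1
            node.label = f"n{k}"
    tree.ages_from_edge_lengths()
    return tree


def withhold_node_ages(tree: Tree, fraction_dated: float,
                       seed: int | np.random.SeedSequence | None = None
                       ) -> pd.DataFrame:
    """Node-age table keeping the root and a random fraction of internal nodes.

    Emulates a partially dated topology (a minority of nodes with published
    ages) for exercising the BLADJ dating step.
    """
    rng = np.random.default_rng(seed)
    internals = [n for n in tree.preorder() if not n.is_leaf and n is not tree.root]
    n_keep = int(round(fraction_dated * len(internals)))
    keep = rng.choice(len(internals), size=n_keep, replace=False)
    rows = [(tree.root.label, tree.root.age)]
    rows += [(internals[i].label, internals[i].age) for i in sorted(keep)]
    return pd.DataFrame(rows, columns=["clade_name", "age_ma"])


def simulate_trait_bm(tree: Tree, sigma2: float = 1.0,
                      seed: int | np.random.SeedSequence | None = None
                      ) -> pd.Series:
    """Brownian-motion tip traits: increments N(0, sigma2 * branch length)."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    if not tree.is_fully_dated():
        raise ValueError("trait simulation needs a dated tree")
    rng = np.random.default_rng(seed)
    value = {id(tree.root): 0.0}
    out = {}
    for node in tree.preorder():
        if node is tree.root:
            continue
        bl = node.parent.age - node.age
        value[id(node)] = value[id(node.parent)] + rng.normal(
            0.0, np.sqrt(sigma2 * max(bl, 0.0)))
        if node.is_leaf:
            out[node.label] = value[id(node)]
    return pd.Series(out, name="trait")


# -------------------------------------------------------------------- climate


def _grid_cells(sc: Scenario) -> pd.DataFrame:
    lon0, lat0 = sc.grid_origin
    lons = lon0 + sc.resolution * np.arange(sc.n_lon)
    lats = lat0 + sc.resolution * np.arange(sc.n_lat)
    gg = np.array(np.meshgrid(lons, lats)).reshape(2, -1).T
    return pd.DataFrame(gg, columns=["cell_lon", "cell_lat"])


def _correlated_field(points_km: np.ndarray, range_km: float, sd: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Gaussian field with exponential correlation exp(-d / range)."""
    from paleopcs.spatial import pairwise_haversine_km

    d = pairwise_haversine_km(points_km)
    cov = sd**2 * np.exp(-d / range_km)
    cov[np.diag_indices_from(cov)] += 1e-8 * sd**2
    L = np.linalg.cholesky(cov)
    return L @ rng.standard_normal(cov.shape[0])


#: per-variable (base level at the grid origin, change per degree latitude)
_VARIABLE_GRADIENTS = {
    "tmin": (-10.0, -1.5),
    "tmax": (25.0, -1.0),
    "pmin": (30.0, 1.0),
    "pmax": (120.0, 3.0),
    "aet": (500.0, -8.0),
    "etr": (0.7, -0.01),
    "wdi": (0.3, 0.01),
}


def simulate_climate_history(sc: Scenario,
                             seed: int | np.random.SeedSequence | None = None
                             ) -> pd.DataFrame:
    """Seven climate variables per (cell, slice).

    Each variable is a latitudinal gradient plus a warming/wetting trend per
    ka toward the present plus a spatially correlated noise field that is
    independent across variables and slices.  The noise SD of each variable
    scales with that variable's systematic (gradient + trend) spread, so the
    shared latitudinal/temporal structure does not push pairwise Pearson
    correlations past the collinearity screen's threshold.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    cells = _grid_cells(sc)
    pts = cells[["cell_lon", "cell_lat"]].to_numpy()
    rows = []
    for t in sc.slices():
        age_from_present = t
        frame = cells.copy()
        frame["time_ka"] = t
        for var in CLIMATE_VARIABLES:
            base, grad = _VARIABLE_GRADIENTS[var]
            scale = 0.01 if var in ("etr", "wdi") else 1.0
            level = (base
                     + grad * (cells["cell_lat"] - sc.grid_origin[1])
                     - scale * sc.climate_trend_per_ka * age_from_present)
            lat_spread = abs(grad) * sc.n_lat * sc.resolution
            trend_spread = scale * sc.climate_trend_per_ka * (sc.n_slices - 1)
            sd = sc.climate_noise_sd * max(lat_spread + trend_spread,
                                           0.05 * abs(base))
            noise = _correlated_field(pts, sc.climate_range_km, sd, rng)
            vals = level.to_numpy() + noise
            if var == "etr":
                vals = np.clip(vals, 0.0, 1.0)
            frame[var] = vals
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


# ------------------------------------------------------------------------ ice


def simulate_ice_retreat(sc: Scenario) -> pd.DataFrame:
    """Cells glaciated iff latitude >= the slice's margin latitude.

    The margin moves poleward monotonically under the default schedule, so
    DEGLAC is well-defined with no resets.  Masks cover the pre-record
    slices as well (see :class:`Scenario`).
    """
    cells = _grid_cells(sc)
    rows = []
    for t in sc.ice_slices():
        frame = cells.copy()
        frame["time_ka"] = t
        frame["glaciated"] = (cells["cell_lat"] >= sc.margin_lat(t)).astype(int)
        rows.append(frame)
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------- communities


def assemble_communities(sc: Scenario, tree: Tree, traits: pd.Series,
                         climate: pd.DataFrame, ice: pd.DataFrame,
                         seed: int | np.random.SeedSequence | None = None
                         ) -> pd.DataFrame:
    """Site records (one site per ice-free cell and slice) under the scenario's
    assembly mechanism; abundances Dirichlet(1) over members, quality 1.0."""
    taxa = list(traits.index)
    if sc.richness_target > len(taxa):
        raise ValueError("richness target exceeds the taxon pool")
    if sc.mechanism not in ("filtering", "neutral", "limiting_similarity"):
        raise ValueError(f"unknown mechanism {sc.mechanism!r}")
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    trait_vals = traits.to_numpy()

    merged = climate.merge(ice, on=["cell_lon", "cell_lat", "time_ka"])
    merged = merged.loc[merged["glaciated"] == 0]
    # standardize the focal variable so the optimum scale is trait-like
    x = merged[sc.focal_variable]
    xstd = (x - x.mean()) / x.std()

    rows = []
    site_counter = 0
    for (idx, row), xs in zip(merged.iterrows(), xstd):
        t = int(row["time_ka"])
        members = _admit(sc, trait_vals, xs, t, rng)
        if members.size == 0:
            continue
        site_counter += 1
        abund = rng.dirichlet(np.ones(members.size))
        # site located at the cell center so it grids back to the same cell
        lon = row["cell_lon"] + sc.resolution / 2
        lat = row["cell_lat"] + sc.resolution / 2
        for m, ab in zip(members, abund):
            rows.append((f"s{site_counter}", lon, lat, t, 1.0, taxa[m], ab))
    return pd.DataFrame(rows, columns=["site_id", "lon", "lat", "time_ka",
                                       "quality", "taxon", "rel_abund"])


def _admit(sc: Scenario, traits: np.ndarray, x_std: float, t: int,
           rng: np.random.Generator) -> np.ndarray:
    n = traits.size
    k = min(sc.richness_target, n)
    if sc.mechanism == "neutral":
        return rng.choice(n, size=k, replace=False)
    if sc.mechanism == "filtering":
        optimum = sc.b_at(t) * x_std
        w = np.exp(-((traits - optimum) ** 2) / (2 * sc.tau**2))
        w = np.maximum(w, 1e-300)
        p = w / w.sum()
        return rng.choice(n, size=k, replace=False, p=p)
    # limiting similarity: random order, reject taxa too close to a member
    order = rng.permutation(n)
    members: list[int] = []
    for cand in order:
        if len(members) >= k:
            break
        if all(abs(traits[cand] - traits[m]) >= sc.delta for m in members):
            members.append(cand)
    return np.array(members, dtype=int)


# --------------------------------------------------------------------- bundle


def generate_fixture_bundle(sc: Scenario, out_dir: str | Path) -> dict:
    """Write sites.csv, climate.csv, ice.csv, tree.nwk, node_ages.csv and
    truth.json; byte-deterministic under the scenario's master seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(sc.seed)
    s_tree, s_trait, s_clim, s_comm, s_ages = ss.spawn(5)

    tree = simulate_tree(sc.n_taxa, sc.birth, sc.death, seed=s_tree)
    traits = simulate_trait_bm(tree, sc.sigma2_bm, seed=s_trait)
    climate = simulate_climate_history(sc, seed=s_clim)
    ice = simulate_ice_retreat(sc)
    sites = assemble_communities(sc, tree, traits, climate, ice, seed=s_comm)
    ages = withhold_node_ages(tree, sc.fraction_dated_nodes, seed=s_ages)

    write_tree(tree, out / "tree.nwk")
    ages.to_csv(out / "node_ages.csv", index=False, float_format="%.10g")
    sites.to_csv(out / "sites.csv", index=False, float_format="%.10g")
    climate.to_csv(out / "climate.csv", index=False, float_format="%.10g")
    ice.to_csv(out / "ice.csv", index=False)
    truth = {
        "scenario": {k: (v if not isinstance(v, dict)
                         else {str(kk): vv for kk, vv in v.items()})
                     for k, v in asdict(sc).items()},
        "mechanism": sc.mechanism,
        "b_schedule": ({str(t): sc.b_at(t) for t in sc.slices()}
                       if isinstance(sc.b_schedule, dict)
                       else sc.b_at(0)),
        "traits": {k: float(v) for k, v in traits.items()},
        "climate_noise": {"range_km": sc.climate_range_km,
                          "sd": sc.climate_noise_sd},
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {"tree": tree, "traits": traits, "climate": climate, "ice": ice,
            "sites": sites, "node_ages": ages, "truth": truth}
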