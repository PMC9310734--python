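"""Synthetic landscapes, occurrences, locality layouts and genotype likelihoods.

Every generator is a pure function of its seed, and each simulated dataset
carries the ground truth used to produce it, so downstream estimators
(SFS, FST, inbreeding, niche models, resistance distances) can be tested
for parameter recovery without any external downloads.

The genetic model is Balding–Nichols: per-site population allele
frequencies are Beta-distributed around an ancestral frequency with
variance governed by the target FST. Reads are Poisson-depth binomial
draws with a symmetric error rate, and genotype likelihoods are the exact
binomial read-sampling likelihoods, stored in beagle-normalized space
(max of the three values is 1 per individual and site).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .geo import haversine_km, pairwise_haversine_km
from .gl import GenotypeLikelihoodSet, write_beagle
from .raster import Raster, write_ascii_grid

__all__ = [
    "LandscapeBundle",
    "MetapopulationTruth",
    "LocalityTable",
    "SimulatedDataset",
    "generate_landscape",
    "generate_occurrences",
    "simulate_genotype_likelihoods",
    "place_localities",
    "spatial_population_frequencies",
]

BIOCLIM_NAMES = ("bio1", "bio2", "bio12", "bio15")
TEMPERATURE_LIKE = ("bio1", "bio2")
EPOCHS = ("current", "mid", "lgm")

# Past-climate offsets: additive (deg C) on temperature-like layers,
# multiplicative on precipitation-like layers.
DEFAULT_EPOCH_SHIFTS = {
    "current": (0.0, 1.0),
    "mid": (-1.0, 0.95),
    "lgm": (-4.0, 0.75),
}


# ---------------------------------------------------------------------------
# landscape


@dataclass
class LandscapeBundle:
    elevation: Raster
    bioclim: dict                      # name -> Raster (current climate)
    epochs: dict                       # epoch -> {name -> Raster}
    truth: dict                        # suitability-function parameters

    def true_suitability(self, epoch: str = "current") -> Raster:
        """Suitability in [0,1] from the generating Gaussian niche on bio1/bio12."""
        layers = self.epochs[epoch]
        t = self.truth
        z = (
            (layers["bio1"].values - t["t_opt"]) ** 2 / (2 * t["t_sd"] ** 2)
            + (layers["bio12"].values - t["p_opt"]) ** 2 / (2 * t["p_sd"] ** 2)
        )
        return self.elevation.with_values(np.exp(-z), name=f"suitability_{epoch}")


def _spectral_noise(rows: int, cols: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Zero-mean 1/f^exponent Gaussian field with unit standard deviation."""
    white = rng.standard_normal((rows, cols))
    f = np.fft.fft2(white)
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    freq = np.sqrt(fy**2 + fx**2)
    freq[0, 0] = 1.0
    amp = freq ** (-exponent)
    amp[0, 0] = 0.0
    field_ = np.real(np.fft.ifft2(f * amp))
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_landscape(
    shape: tuple[int, int] = (64, 64),
    extent: tuple[float, float, float, float] = (-79.0, -1.0, -78.0, 0.0),
    roughness: float = 1.2,
    seed: int = 0,
    epoch_shifts: dict | None = None,
) -> LandscapeBundle:
    """Generate an elevation raster plus four bioclimatic layers for three epochs.

    Elevation is spectral (1/f^roughness) noise rescaled to [0, 4000] m
    (``roughness=0`` yields a flat landscape); temperature decreases with
    elevation at a standard lapse rate, precipitation follows a west-east
    gradient, and past epochs apply the recorded additive/multiplicative
    shifts. The extent is (west, south, east, north) in degrees.
    """
    rows, cols = shape
    if rows < 8 or cols < 8:
        raise ValueError("grid must be at least 8x8")
    west, south, east, north = extent
    if not (-180 <= west < east <= 180 and -90 <= south < north <= 90):
        raise ValueError(f"invalid extent {extent}")
    if roughness < 0:
        raise ValueError("roughness must be >= 0")
    cell = (east - west) / cols
    cell_y = (north - south) / rows
    if abs(cell - cell_y) > 0.01 * cell:
        raise ValueError("extent/shape imply non-square cells (dx and dy differ > 1%)")

    rng = np.random.default_rng(seed)
    if roughness == 0:
        elev = np.full(shape, 1000.0)
    else:
        z = _spectral_noise(rows, cols, roughness, rng)
        z = z - z.min()
        elev = 4000.0 * z / z.max() if z.max() > 0 else np.full(shape, 1000.0)
    elevation = Raster(elev, west, north, cell, name="elevation")

    xnorm = np.linspace(0, 1, cols)[None, :] * np.ones((rows, 1))
    ynorm = np.linspace(0, 1, rows)[:, None] * np.ones((1, cols))
    # 6.5 C/km lapse rate; small seeded noise keeps layers from being exact
    # functions of elevation
    bio1 = 28.0 - 6.5 * elev / 1000.0 + 0.4 * rng.standard_normal(shape)
    bio2 = 9.0 + 1.5 * elev / 4000.0 + 0.3 * rng.standard_normal(shape)
    bio12 = 800.0 + 1800.0 * xnorm + 60.0 * rng.standard_normal(shape)
    bio15 = 30.0 + 40.0 * ynorm + 2.0 * rng.standard_normal(shape)
    current = {
        "bio1": elevation.with_values(bio1, "bio1"),
        "bio2": elevation.with_values(bio2, "bio2"),
        "bio12": elevation.with_values(np.clip(bio12, 0, None), "bio12"),
        "bio15": elevation.with_values(np.clip(bio15, 0, None), "bio15"),
    }
    shifts = dict(DEFAULT_EPOCH_SHIFTS, **(epoch_shifts or {}))
    epochs = {}
    for epoch in EPOCHS:
        add, mult = shifts[epoch]
        layers = {}
        for name, r in current.items():
            if name in TEMPERATURE_LIKE:
                layers[name] = r.with_values(r.values + add, name)
            else:
                layers[name] = r.with_values(r.values * mult, name)
        epochs[epoch] = layers

    # niche truth: optimum at mid-elevation temperature, moist end of the gradient
    truth = {
        "t_opt": float(28.0 - 6.5 * 1.8),  # ~1800 m optimum
        "t_sd": 3.0,
        "p_opt": 2100.0,
        "p_sd": 600.0,
        "roughness": roughness,
        "seed": seed,
        "epoch_shifts": {k: list(v) for k, v in shifts.items()},
    }
    return LandscapeBundle(elevation, current, epochs, truth)


def generate_occurrences(suitability: Raster, n: int, seed: int = 0) -> np.ndarray:
    """Sample n occurrence points (lon, lat) with cell probability proportional
    to suitability, jittered uniformly within the chosen cell."""
    vals = suitability.masked_values()
    weights = np.nan_to_num(vals, nan=0.0).ravel()
    if np.any(weights < 0) or np.any(weights > 1):
        raise ValueError("suitability values must lie in [0, 1]")
    total = weights.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample occurrences")
    rng = np.random.default_rng(seed)
    cells = rng.choice(weights.size, size=n, p=weights / total)
    rows_, cols_ = np.unravel_index(cells, suitability.shape)
    cell = suitability.cell_size
    jitter = rng.uniform(-0.5, 0.5, size=(n, 2)) * cell
    lon = suitability.west + (cols_ + 0.5) * cell + jitter[:, 0]
    lat = suitability.north - (rows_ + 0.5) * cell + jitter[:, 1]
    return np.column_stack([lon, lat])


# ---------------------------------------------------------------------------
# localities


@dataclass
class LocalityTable:
    individuals: pd.DataFrame   # columns: individual, locality, lon, lat
    localities: pd.DataFrame    # columns: locality, lon, lat (centroids)

    def __post_init__(self) -> None:
        cent = self.individuals.groupby("locality")[["lon", "lat"]].mean()
        ref = self.localities.set_index("locality")[["lon", "lat"]]
        if not np.allclose(cent.loc[ref.index].values, ref.values, atol=1e-9):
            raise ValueError("locality centroid must equal the mean of member coordinates")

    @property
    def names(self) -> list[str]:
        return list(self.localities["locality"])

    def members(self, locality: str) -> pd.DataFrame:
        return self.individuals[self.individuals["locality"] == locality]

    def centroids(self) -> np.ndarray:
        return self.localities[["lon", "lat"]].to_numpy()

    def write_sample_sheet(self, path: str | Path) -> None:
        self.individuals.to_csv(path, index=False)

    @classmethod
    def from_sample_sheet(cls, df: pd.DataFrame) -> "LocalityTable":
        cent = (
            df.groupby("locality", sort=False)[["lon", "lat"]].mean().reset_index()
        )
        return cls(df[["individual", "locality", "lon", "lat"]].copy(), cent)


def place_localities(
    raster: Raster,
    k: int = 5,
    min_sep_km: float = 20.0,
    near_pair_km: float = 12.0,
    n_ind_per_locality: int = 13,
    ind_scatter_km: float = 1.0,
    seed: int = 0,
    max_tries: int = 2000,
) -> LocalityTable:
    """Place k locality centroids on passable cells: exactly one pair of
    localities closer than near_pair_km, all other pairs farther than
    min_sep_km; individuals scattered within ind_scatter_km of the centroid.
    """
    if k < 3:
        raise ValueError("need at least 3 localities")
    rng = np.random.default_rng(seed)
    passable = np.argwhere(~raster.nodata_mask)
    if passable.shape[0] < k:
        raise ValueError("not enough passable cells for the requested localities")
    lons = raster.west + (passable[:, 1] + 0.5) * raster.cell_size
    lats = raster.north - (passable[:, 0] + 0.5) * raster.cell_size
    # margin keeps the individual scatter from flipping a pair across a threshold
    margin = 2.5 * ind_scatter_km

    for _ in range(max_tries):
        order = rng.permutation(len(lons))
        chosen: list[int] = []
        for idx in order:
            if len(chosen) == k - 1:
                break
            if all(
                haversine_km(lons[idx], lats[idx], lons[j], lats[j]) > min_sep_km + margin
                for j in chosen
            ):
                chosen.append(idx)
        if len(chosen) < k - 1:
            continue
        # attach the near-pair partner to a random base locality
        partner_of = int(rng.choice(chosen))
        d_all = haversine_km(lons[partner_of], lats[partner_of], lons, lats)
        lo, hi = 0.3 * near_pair_km, near_pair_km - margin
        cand = np.flatnonzero((d_all > lo) & (d_all < hi))
        good = [
            c for c in cand
            if all(
                haversine_km(lons[c], lats[c], lons[j], lats[j]) > min_sep_km + margin
                for j in chosen if j != partner_of
            )
        ]
        if not good:
            continue
        chosen.append(int(rng.choice(good)))
        break
    else:
        raise ValueError(
            f"could not place {k} localities with min_sep={min_sep_km} km and one "
            f"pair < {near_pair_km} km after {max_tries} tries"
        )

    rows = []
    cent_rows = []
    deg_per_km_lat = 1.0 / 111.195
    for li, idx in enumerate(chosen):
        name = f"L{li + 1}"
        clon, clat = lons[idx], lats[idx]
        deg_per_km_lon = deg_per_km_lat / max(math.cos(math.radians(clat)), 1e-6)
        r = ind_scatter_km * np.sqrt(rng.uniform(0, 1, n_ind_per_locality))
        theta = rng.uniform(0, 2 * np.pi, n_ind_per_locality)
        ind_lon = clon + r * np.cos(theta) * deg_per_km_lon
        ind_lat = clat + r * np.sin(theta) * deg_per_km_lat
        for ii in range(n_ind_per_locality):
            rows.append((f"{name}_i{ii}", name, ind_lon[ii], ind_lat[ii]))
        cent_rows.append((name, ind_lon.mean(), ind_lat.mean()))
    ind_df = pd.DataFrame(rows, columns=["individual", "locality", "lon", "lat"])
    loc_df = pd.DataFrame(cent_rows, columns=["locality", "lon", "lat"])
    return LocalityTable(ind_df, loc_df)


# ---------------------------------------------------------------------------
# genotype likelihoods


@dataclass
class MetapopulationTruth:
    """Ground-truth record sufficient to regenerate a simulated dataset exactly."""

    n_pops: int
    n_ind_per_pop: list[int]
    fst_target: float
    inbreeding_per_ind: list[float]
    ancestral_freqs: np.ndarray
    depth_mean: float = 8.0
    error_rate: float = 0.01
    seed: int = 0
    ancestral_known: bool = True

    def __post_init__(self) -> None:
        self.ancestral_freqs = np.asarray(self.ancestral_freqs, dtype=float)
        if not 0 <= self.fst_target < 1:
            raise ValueError("fst_target must be in [0, 1)")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be positive")
        if np.any((self.ancestral_freqs <= 0) | (self.ancestral_freqs >= 1)):
            raise ValueError("ancestral frequencies must lie in (0, 1)")
        if len(self.n_ind_per_pop) != self.n_pops:
            raise ValueError("n_ind_per_pop length must equal n_pops")
        n_ind = sum(self.n_ind_per_pop)
        if len(self.inbreeding_per_ind) != n_ind:
            raise ValueError("inbreeding_per_ind length must equal total individuals")

    @classmethod
    def default(
        cls,
        n_pops: int = 2,
        n_ind_per_pop: int | list[int] = 13,
        n_sites: int = 20000,
        fst_target: float = 0.1,
        inbreeding: float | list[float] = 0.0,
        depth_mean: float = 8.0,
        error_rate: float = 0.01,
        seed: int = 0,
        ancestral_known: bool = True,
    ) -> "MetapopulationTruth":
        if isinstance(n_ind_per_pop, int):
            n_ind_per_pop = [n_ind_per_pop] * n_pops
        n_ind = sum(n_ind_per_pop)
        if isinstance(inbreeding, (int, float)):
            inbreeding = [float(inbreeding)] * n_ind
        rng = np.random.default_rng(seed)
        anc = rng.uniform(0.05, 0.95, size=n_sites)
        return cls(
            n_pops, list(n_ind_per_pop), fst_target, list(inbreeding), anc,
            depth_mean, error_rate, seed, ancestral_known,
        )

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["ancestral_freqs"] = self.ancestral_freqs.tolist()
        Path(path).write_text(json.dumps(d))

    @classmethod
    def from_json(cls, path: str | Path) -> "MetapopulationTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass
class SimulatedDataset:
    gl: GenotypeLikelihoodSet
    true_genotypes: np.ndarray     # (n_sites, n_ind) dosages 0/1/2
    pop_labels: list[str]          # per individual
    pop_freqs: np.ndarray          # (n_sites, n_pops)
    truth: MetapopulationTruth

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_beagle(self.gl, outdir / "genolike.beagle")
        self.truth.to_json(outdir / "truth.json")


def balding_nichols_freqs(
    ancestral: np.ndarray, fst: float, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-population allele frequencies, Beta(p(1-F)/F, (1-p)(1-F)/F) around p.

    F=0 degenerates to the ancestral frequencies themselves.
    """
    p = np.asarray(ancestral, dtype=float)
    if fst == 0:
        return np.repeat(p[:, None], n_pops, axis=1)
    scale = (1.0 - fst) / fst
    a = p * scale
    b = (1.0 - p) * scale
    draws = rng.beta(a[:, None], b[:, None], size=(p.size, n_pops))
    return np.clip(draws, 1e-9, 1 - 1e-9)


def spatial_population_frequencies(
    distances_km: np.ndarray,
    ancestral: np.ndarray,
    sigma: float = 1.2,
    range_km: float = 40.0,
    seed: int = 0,
) -> np.ndarray:
    """Population frequencies whose divergence grows with pairwise distance.

    Logit-scale Gaussian field over populations with exponential-decay
    covariance sigma^2 * exp(-d / range_km); nearby populations share
    correlated deviations, so expected pairwise FST increases with distance.
    """
    d = np.asarray(distances_km, dtype=float)
    k = d.shape[0]
    cov = sigma**2 * np.exp(-d / range_km)
    cov[np.diag_indices(k)] += 1e-9
    chol = np.linalg.cholesky(cov)
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((ancestral.size, k)) @ chol.T
    p = expit(logit(np.asarray(ancestral))[:, None] + z)
    return np.clip(p, 1e-9, 1 - 1e-9)


def simulate_genotype_likelihoods(
    truth: MetapopulationTruth,
    pop_freqs: np.ndarray | None = None,
) -> SimulatedDataset:
    """Simulate genotypes, reads and beagle-normalized genotype likelihoods.

    ``pop_freqs`` (n_sites x n_pops) overrides the Balding–Nichols draw when
    population frequencies come from an explicit spatial model.
    """
    rng = np.random.default_rng(truth.seed)
    p_anc = truth.ancestral_freqs
    n_sites = p_anc.size
    if pop_freqs is None:
        pop_freqs = balding_nichols_freqs(p_anc, truth.fst_target, truth.n_pops, rng)
    else:
        pop_freqs = np.asarray(pop_freqs, dtype=float)
        if pop_freqs.shape != (n_sites, truth.n_pops):
            raise ValueError("pop_freqs must be (n_sites, n_pops)")

    pop_of_ind = np.repeat(np.arange(truth.n_pops), truth.n_ind_per_pop)
    n_ind = pop_of_ind.size
    f = np.asarray(truth.inbreeding_per_ind, dtype=float)

    p = pop_freqs[:, pop_of_ind]                       # (S, N)
    fpq = f[None, :] * p * (1 - p)
    prob0 = (1 - p) ** 2 + fpq
    prob1 = 2 * p * (1 - p) * (1 - f[None, :])
    u = rng.uniform(size=(n_sites, n_ind))
    genotypes = np.where(u < prob0, 0, np.where(u < prob0 + prob1, 1, 2)).astype(np.int8)

    depth = rng.poisson(truth.depth_mean, size=(n_sites, n_ind))
    e = truth.error_rate
    q_true = genotypes / 2.0 * (1 - e) + (1 - genotypes / 2.0) * e
    alt = rng.binomial(depth, q_true)

    # binomial read-sampling likelihoods for each genotype hypothesis;
    # the shared binomial coefficient cancels in the max-1 normalization
    gls = np.empty((n_sites, n_ind, 3))
    with np.errstate(divide="ignore", invalid="ignore"):
        for g in range(3):
            qg = g / 2.0 * (1 - e) + (1 - g / 2.0) * e
            loglik = alt * np.log(qg) + (depth - alt) * np.log1p(-qg)
            gls[..., g] = loglik
    gls = np.exp(gls - gls.max(axis=2, keepdims=True))
    gls[depth == 0] = 1.0   # zero depth: three equal likelihoods

    individuals = [
        f"P{pop_of_ind[i]}_i{i}" for i in range(n_ind)
    ]
    site_ids = [f"site_{s}" for s in range(n_sites)]
    polarization = "unfolded" if truth.ancestral_known else "folded"
    gl = GenotypeLikelihoodSet(individuals, site_ids, gls, polarization=polarization)
    labels = [f"P{k}" for k in pop_of_ind]
    return SimulatedDataset(gl, genotypes, labels, pop_freqs, truth)


def write_landscape(bundle: LandscapeBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_ascii_grid(bundle.elevation, outdir / "elevation.asc")
    for epoch, layers in bundle.epochs.items():
        for name, r in layers.items():
            write_ascii_grid(r, outdir / f"{name}_{epoch}.asc")
    (outdir / "suitability_truth.json").write_text(json.dumps(bundle.truth))
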