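"""Synthetic landscapes, virtual species, occurrences and climate scenarios.

The generator produces data with the statistical structure the modeling
pipeline assumes about its real inputs:

* bioclim-like predictor layers that are *spatially autocorrelated* and
  *mutually correlated* — each layer is a linear mix of a small number of
  shared smooth latent fields (Gaussian-kernel-smoothed white noise), so the
  inter-layer correlation structure is known from the mixing loadings;
* an elevation layer built from a deterministic component (plane or cone)
  plus a smooth random roughness term, optionally coupled into climate
  layers so that temperature-like variables track altitude;
* a virtual species whose true suitability is a product of unimodal
  (Gaussian) responses to a chosen subset of layers — the realized niche a
  correlative distribution model is supposed to approximate;
* seeded presence sampling proportional to suitability; and
* "future" layer sets formed by additive climate deltas plus a smooth
  per-GCM deviation field, mimicking coherent disagreement between general
  circulation models.

Everything is a pure function of its config (seeds included), so identical
configs give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.ndimage import gaussian_filter

from .grid import WGS84, Grid, PredictorStack
from .occurrences import OccurrenceSet

__all__ = [
    "ElevationParams",
    "LandscapeConfig",
    "VirtualSpeciesConfig",
    "ScenarioConfig",
    "ScenarioSet",
    "gen_landscape",
    "true_suitability",
    "sample_occurrences",
    "make_future_scenarios",
]


def smooth_field(shape: tuple[int, int], sigma: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Standardized (mean 0, sd 1) spatially autocorrelated random field.

    White noise smoothed with a Gaussian kernel of width *sigma* cells;
    sigma = 0 degenerates to white noise.
    """
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = gaussian_filter(z, sigma=sigma, mode="reflect")
    sd = z.std()
    if sd == 0:  # pathological tiny grids
        return np.zeros(shape)
    return (z - z.mean()) / sd


@dataclass
class ElevationParams:
    """Deterministic terrain + smooth roughness.

    ``plane``: base + gradient_ew·col + gradient_ns·row (meters per cell).
    ``cone``: peak of ``height`` m at the grid center decaying linearly to
    ``base`` at the corners — high-elevation area shrinks with altitude,
    the usual montane hypsography.
    """

    base: float = 200.0
    shape: Literal["plane", "cone"] = "plane"
    gradient_ew: float = 5.0
    gradient_ns: float = 0.0
    height: float = 1500.0
    roughness_sd: float = 30.0
    roughness_range: float = 3.0


@dataclass
class LandscapeConfig:
    n_rows: int = 100
    n_cols: int = 100
    cell_size_deg: float = 1.0 / 12.0  # 5 arcmin
    origin_lon: float = 10.0
    origin_lat: float = 50.0
    layer_names: list[str] = field(
        default_factory=lambda: ["bio_2", "bio_4", "bio_10", "bio_11",
                                 "bio_12", "bio_17", "bio_18", "bio_19"])
    n_latent_fields: int = 4
    autocorrelation_range: float = 6.0  # cells
    layer_loadings: np.ndarray | None = None  # (n_layers, n_latent)
    layer_elev_coupling: np.ndarray | None = None  # (n_layers,), weight on standardized elevation
    layer_means: np.ndarray | None = None
    layer_sds: np.ndarray | None = None
    elevation_params: ElevationParams = field(default_factory=ElevationParams)
    seed: int = 0

    def resolved(self) -> "LandscapeConfig":
        """Fill unset array fields with defaults of the right shape."""
        n = len(self.layer_names)
        cfg = LandscapeConfig(**{**self.__dict__})
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x10AD]))
        if cfg.layer_loadings is None:
            cfg.layer_loadings = rng.uniform(-1, 1, size=(n, self.n_latent_fields))
        cfg.layer_loadings = np.atleast_2d(np.asarray(cfg.layer_loadings, dtype=float))
        if cfg.layer_elev_coupling is None:
            cfg.layer_elev_coupling = np.zeros(n)
        cfg.layer_elev_coupling = np.asarray(cfg.layer_elev_coupling, dtype=float)
        if cfg.layer_means is None:
            cfg.layer_means = np.zeros(n)
        if cfg.layer_sds is None:
            cfg.layer_sds = np.ones(n)
        cfg.layer_means = np.asarray(cfg.layer_means, dtype=float)
        cfg.layer_sds = np.asarray(cfg.layer_sds, dtype=float)
        return cfg

    def validate(self) -> None:
        if self.n_rows < 8 or self.n_cols < 8:
            raise ValueError("grid must be at least 8x8")
        if not self.cell_size_deg > 0:
            raise ValueError("cell_size_deg must be positive")
        n = len(self.layer_names)
        if self.layer_loadings is not None:
            loadings = np.atleast_2d(np.asarray(self.layer_loadings))
            if loadings.shape != (n, self.n_latent_fields):
                raise ValueError(
                    f"layer_loadings shape {loadings.shape} != "
                    f"({n}, {self.n_latent_fields})")


@dataclass
class VirtualSpeciesConfig:
    """Gaussian-response virtual species."""

    response_vars: list[str]
    mu: dict[str, float]  # optimum, layer units
    sigma: dict[str, float]  # niche breadth, layer units
    n_presences: int = 300
    sampling: Literal["weighted", "bernoulli"] = "weighted"
    species: str = "Virtualis exempli"
    seed: int = 0

    def validate(self) -> None:
        for v in self.response_vars:
            if v not in self.mu or v not in self.sigma:
                raise ValueError(f"missing mu/sigma for response var {v!r}")
            if not self.sigma[v] > 0:
                raise ValueError(f"sigma must be positive for {v!r}")


@dataclass
class ScenarioConfig:
    """Additive climate deltas plus per-GCM smooth deviations."""

    rcp_label: str = "RCP45"
    deltas: dict[str, float] = field(default_factory=dict)
    gcm_noise_sd: float = 0.0
    gcm_noise_range: float = 6.0  # cells; smoothness of per-GCM deviation
    n_gcms: int = 3
    seed: int = 0

    def validate(self, topo_layers=("altitude", "slope")) -> None:
        if self.n_gcms < 1:
            raise ValueError("n_gcms must be >= 1")
        for name in self.deltas:
            if name in topo_layers:
                raise ValueError(
                    f"delta specified for topographic layer {name!r}; "
                    "terrain does not change between time slices")


@dataclass
class ScenarioSet:
    """Per-GCM future stacks for one forcing pathway."""

    rcp_label: str
    gcms: dict[str, PredictorStack]


# ---------------------------------------------------------------------------


def gen_landscape(config: LandscapeConfig) -> PredictorStack:
    """Generate the synthetic predictor stack (climate layers + altitude).

    Each climate layer is ``loadings @ latent_fields (+ coupling · std
    elevation)``, standardized and rescaled to the configured mean/sd; a
    zero mixing row yields a constant layer at its mean. Slope is *not*
    generated here — derive it with :func:`sdmrange.predictors.compute_slope`
    so synthetic terrain passes through the same code path as real DEMs.
    """
    config.validate()
    cfg = config.resolved()
    shape = (cfg.n_rows, cfg.n_cols)
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    # terrain first: climate layers may be coupled to it
    ep = cfg.elevation_params
    rows, cols = np.mgrid[0:cfg.n_rows, 0:cfg.n_cols]
    if ep.shape == "cone":
        cr, cc = (cfg.n_rows - 1) / 2.0, (cfg.n_cols - 1) / 2.0
        dist = np.hypot(rows - cr, cols - cc)
        elev = ep.base + ep.height * np.clip(1.0 - dist / max(cr, cc), 0.0, None)
    else:
        elev = ep.base + ep.gradient_ew * cols + ep.gradient_ns * rows
    if ep.roughness_sd > 0:
        elev = elev + ep.roughness_sd * smooth_field(shape, ep.roughness_range, rng)
    elev_sd = elev.std()
    std_elev = (elev - elev.mean()) / elev_sd if elev_sd > 0 else np.zeros(shape)

    latents = np.stack([smooth_field(shape, cfg.autocorrelation_range, rng)
                        for _ in range(cfg.n_latent_fields)])

    layers: dict[str, Grid] = {}
    for i, name in enumerate(cfg.layer_names):
        mix = np.tensordot(cfg.layer_loadings[i], latents, axes=1)
        mix = mix + cfg.layer_elev_coupling[i] * std_elev
        sd = mix.std()
        if sd > 0:
            vals = (mix - mix.mean()) / sd * cfg.layer_sds[i] + cfg.layer_means[i]
        else:
            vals = np.full(shape, cfg.layer_means[i])
        layers[name] = Grid(vals, np.zeros(shape, bool),
                            cfg.origin_lon, cfg.origin_lat, cfg.cell_size_deg)
    layers["altitude"] = Grid(elev, np.zeros(shape, bool),
                              cfg.origin_lon, cfg.origin_lat, cfg.cell_size_deg)
    return PredictorStack(layers)


def true_suitability(stack: PredictorStack, sp: VirtualSpeciesConfig) -> Grid:
    """S(x) = prod_v exp(-(E_v(x) - mu_v)^2 / (2 sigma_v^2)), in [0, 1]."""
    sp.validate()
    missing = [v for v in sp.response_vars if v not in stack]
    if missing:
        raise KeyError(f"response vars not in stack: {missing}")
    template = stack.template
    suit = np.ones(template.shape)
    for v in sp.response_vars:
        e = stack[v].values
        suit *= np.exp(-((e - sp.mu[v]) ** 2) / (2.0 * sp.sigma[v] ** 2))
    mask = stack.combined_nodata()
    suit = np.where(mask, np.nan, suit)
    return Grid(suit, mask, template.origin_lon, template.origin_lat,
                template.cell_size, template.crs)


def sample_occurrences(suit: Grid, sp: VirtualSpeciesConfig) -> OccurrenceSet:
    """Draw presence records at cell centers, seeded.

    ``weighted``: *n_presences* distinct cells, probability proportional to
    suitability.  ``bernoulli``: visit cells in random order, accept each
    with probability equal to its suitability, until *n_presences* accepted
    (cells may be revisited across passes, so near-degenerate surfaces
    still terminate).
    """
    sp.validate()
    rng = np.random.default_rng(np.random.SeedSequence([sp.seed, 2]))
    valid = ~suit.nodata_mask
    if not valid.any():
        raise ValueError("suitability map has no valid cells")
    if sp.n_presences == 0:
        return OccurrenceSet.from_arrays(sp.species, np.array([]), np.array([]))

    rows, cols = np.nonzero(valid)
    weights = suit.values[rows, cols].astype(float)
    weights = np.clip(weights, 0.0, None)
    if weights.sum() <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample presences")

    if sp.sampling == "weighted":
        n_support = int((weights > 0).sum())
        if sp.n_presences > n_support:
            raise ValueError(f"n_presences={sp.n_presences} exceeds the "
                             f"{n_support} cells with positive suitability")
        idx = rng.choice(len(rows), size=sp.n_presences, replace=False,
                         p=weights / weights.sum())
    else:  # bernoulli
        accepted: list[int] = []
        p = np.clip(weights, 0.0, 1.0)
        while len(accepted) < sp.n_presences:
            order = rng.permutation(len(rows))
            accept = rng.random(len(rows)) < p[order]
            accepted.extend(order[accept][: sp.n_presences - len(accepted)])
        idx = np.array(accepted)

    lon, lat = suit.cell_center(rows[idx], cols[idx])
    return OccurrenceSet.from_arrays(sp.species, lon, lat,
                                     uncertainty_km=0.0, source="synthetic")


def make_future_scenarios(stack: PredictorStack, sc: ScenarioConfig) -> ScenarioSet:
    """Future per-GCM stacks: present + delta + smooth per-GCM deviation.

    Topographic layers (altitude, slope) are copied unchanged — terrain is
    static over the projection horizon.
    """
    sc.validate()
    unknown = [k for k in sc.deltas if k not in stack]
    if unknown:
        raise KeyError(f"delta layers not in stack: {unknown}")
    template = stack.template
    topo = {"altitude", "slope"}
    gcms: dict[str, PredictorStack] = {}
    for g in range(sc.n_gcms):
        rng = np.random.default_rng(np.random.SeedSequence([sc.seed, 3, g]))
        layers: dict[str, Grid] = {}
        for name, grid in stack.layers.items():
            if name in topo:
                layers[name] = grid.copy()
                continue
            vals = grid.values + sc.deltas.get(name, 0.0)
            if sc.gcm_noise_sd > 0:
                vals = vals + sc.gcm_noise_sd * smooth_field(
                    template.shape, sc.gcm_noise_range, rng)
            layers[name] = grid.copy(values=vals)
        gcms[f"GCM{g + 1}"] = PredictorStack(layers)
    return ScenarioSet(rcp_label=sc.rcp_label, gcms=gcms)
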