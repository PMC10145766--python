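"""Bundled virtual-species case study.

A single seeded synthetic landscape exercised by the test suite, the demo
configuration and the results-reproduction script: a 100x100-cell montane
landscape (conical hypsography, so high-elevation area shrinks with
altitude) with three informative climate layers — summer temperature
(bio_10, strongly coupled to elevation), annual precipitation (bio_12) and
temperature seasonality (bio_4) — plus three pure-noise climate layers
(bio_2, bio_17, bio_19), and a cool-wet montane virtual species with
Gaussian responses to the three informative layers.

Two future scenarios bracket the qualitative outcomes of interest:

* ``warming`` — summer warming (+2.5 degC) with mild drying; finding the
  species' thermal optimum then requires higher altitude, where the conical
  terrain offers less area, so the suitable envelope both shifts uphill and
  shrinks (a range loser);
* ``wettening`` — cooler, wetter conditions that move more of the landscape
  toward the species' precipitation optimum, expanding the envelope (a
  range winner).

Every quantity is a pure function of the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seeds import child_seed
from .grid import Grid, PredictorStack
from .occurrences import OccurrenceSet
from .synth import (ElevationParams, LandscapeConfig, ScenarioConfig,
                    ScenarioSet, VirtualSpeciesConfig, gen_landscape,
                    make_future_scenarios, sample_occurrences,
                    true_suitability)

__all__ = ["CaseStudy", "demo_case", "demo_landscape_config",
           "demo_species_config", "INFORMATIVE_VARS", "NOISE_VARS"]

INFORMATIVE_VARS = ["bio_10", "bio_12", "bio_4"]
NOISE_VARS = ["bio_2", "bio_17", "bio_19"]
CLIMATE_VARS = INFORMATIVE_VARS + NOISE_VARS


def demo_landscape_config(seed: int = 0, n_rows: int = 100,
                          n_cols: int = 100) -> LandscapeConfig:
    # one private latent field per climate layer; bio_10 additionally rides
    # on standardized elevation (lapse-rate-like negative coupling)
    loadings = np.zeros((6, 6))
    loadings[0, 0] = 0.4   # bio_10: mostly elevation-driven (see coupling)
    loadings[1, 1] = 1.0   # bio_12
    loadings[2, 2] = 1.0   # bio_4
    loadings[3, 3] = 1.0   # bio_2  (noise for this species)
    loadings[4, 4] = 1.0   # bio_17 (noise)
    loadings[5, 5] = 1.0   # bio_19 (noise)
    coupling = np.array([-0.85, 0.0, 0.0, 0.0, 0.0, 0.0])
    return LandscapeConfig(
        n_rows=n_rows, n_cols=n_cols,
        cell_size_deg=1.0 / 12.0, origin_lon=10.0, origin_lat=50.0,
        layer_names=CLIMATE_VARS,
        n_latent_fields=6,
        autocorrelation_range=6.0,
        layer_loadings=loadings,
        layer_elev_coupling=coupling,
        # bio_10 degC, bio_12 mm, bio_4 (sd x 100), bio_2 degC, bio_17/19 mm
        layer_means=np.array([16.0, 900.0, 6000.0, 9.0, 150.0, 220.0]),
        layer_sds=np.array([4.0, 250.0, 1500.0, 2.0, 60.0, 80.0]),
        elevation_params=ElevationParams(
            base=100.0, shape="cone", height=1800.0,
            roughness_sd=40.0, roughness_range=3.0),
        seed=child_seed(seed, "landscape"),
    )


def demo_species_config(seed: int = 0, n_presences: int = 300) -> VirtualSpeciesConfig:
    # cool-wet montane species: below-average summer temperature, above-
    # average precipitation, slightly low seasonality
    return VirtualSpeciesConfig(
        response_vars=INFORMATIVE_VARS,
        mu={"bio_10": 12.0, "bio_12": 1100.0, "bio_4": 5500.0},
        sigma={"bio_10": 2.5, "bio_12": 250.0, "bio_4": 1000.0},
        n_presences=n_presences,
        sampling="weighted",
        species="Virtualis montana",
        seed=child_seed(seed, "species"),
    )


def warming_scenario(seed: int = 0, n_gcms: int = 3) -> ScenarioConfig:
    return ScenarioConfig(
        rcp_label="RCP85",
        deltas={"bio_10": 2.5, "bio_12": -100.0},
        gcm_noise_sd=0.3, gcm_noise_range=6.0, n_gcms=n_gcms,
        seed=child_seed(seed, "scenario-warming"),
    )


def wettening_scenario(seed: int = 0, n_gcms: int = 3) -> ScenarioConfig:
    return ScenarioConfig(
        rcp_label="RCP45",
        deltas={"bio_10": -1.0, "bio_12": 150.0},
        gcm_noise_sd=0.3, gcm_noise_range=6.0, n_gcms=n_gcms,
        seed=child_seed(seed, "scenario-wettening"),
    )


@dataclass
class CaseStudy:
    stack: PredictorStack            # six climate layers + altitude
    suitability: Grid                # the species' true suitability
    occurrences: OccurrenceSet       # 300 seeded presence records
    species: VirtualSpeciesConfig
    scenarios: dict[str, ScenarioSet]  # 'warming' (shrink) / 'wettening' (expand)
    seed: int

    @property
    def informative_vars(self) -> list[str]:
        return list(INFORMATIVE_VARS)

    @property
    def noise_vars(self) -> list[str]:
        return list(NOISE_VARS)


def demo_case(seed: int = 0, n_rows: int = 100, n_cols: int = 100,
              n_presences: int = 300, n_gcms: int = 3) -> CaseStudy:
    """Materialize the full bundled case study for one master seed."""
    land = demo_landscape_config(seed, n_rows=n_rows, n_cols=n_cols)
    stack = gen_landscape(land)
    sp = demo_species_config(seed, n_presences=n_presences)
    suit = true_suitability(stack, sp)
    occ = sample_occurrences(suit, sp)
    scenarios = {
        "warming": make_future_scenarios(stack, warming_scenario(seed, n_gcms)),
        "wettening": make_future_scenarios(stack, wettening_scenario(seed, n_gcms)),
    }
    return CaseStudy(stack=stack, suitability=suit, occurrences=occ,
                     species=sp, scenarios=scenarios, seed=seed)
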