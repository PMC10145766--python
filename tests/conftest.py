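"""Shared fixtures: small grids and the session-scoped niche-recovery run."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import sdmrange as sr
from sdmrange.fixtures import CLIMATE_VARS, CaseStudy, demo_case
from sdmrange.predictors import crop_study_area

MASTER_SEED = 1


def make_grid(values, origin_lon=0.0, origin_lat=10.0, cell_size=0.1,
              nodata_mask=None) -> sr.Grid:
    values = np.asarray(values, dtype=float)
    if nodata_mask is None:
        nodata_mask = np.zeros(values.shape, dtype=bool)
    return sr.Grid(values, nodata_mask, origin_lon, origin_lat, cell_size)


@pytest.fixture(scope="session")
def case() -> CaseStudy:
    """The bundled 100x100 virtual-species case study (3 informative + 3
    noise climate layers, 300 presences, conical terrain, two scenarios)."""
    return demo_case(seed=MASTER_SEED)


@dataclass
class ModeledCase:
    case: CaseStudy
    stack: sr.PredictorStack        # cropped to the study area
    area0: sr.StudyArea             # on the full template (for cropping more stacks)
    area: sr.StudyArea
    runs: list[sr.ModelRun]
    tables: list[sr.TrainingTable]
    maps: list[sr.Grid]
    ensemble: "sr.EnsembleResult"
    threshold: float
    present_binary: sr.Grid


@pytest.fixture(scope="session")
def modeled(case: CaseStudy) -> ModeledCase:
    """Reduced-settings ensemble on the bundled case: 2 pseudoabsence sets
    x 3 replicates of a 150-tree random forest on the six climate layers."""
    area0 = sr.build_study_area(case.occurrences, 2.5, case.stack.template)
    stack = sr.crop_mask(case.stack, area0)
    area = crop_study_area(area0)
    pa_sets = sr.sample_pseudoabsences(area, case.occurrences, n=1000,
                                       n_sets=2, seed=11)
    runs, tables = sr.run_models(stack, case.occurrences, pa_sets,
                                 CLIMATE_VARS, "RF", n_replicates=3,
                                 params={"n_estimators": 150}, seed=7)
    maps = [sr.predict_map(r, stack) for r in runs]
    ens = sr.ensemble_maps(maps, runs, auc_min=0.8)
    thr = sr.ensemble_mtss_threshold(runs, tables, ens.contributing)
    present_binary = sr.mtss_binarize(ens.map, thr)
    return ModeledCase(case=case, stack=stack, area0=area0, area=area, runs=runs,
                       tables=tables, maps=maps, ensemble=ens, threshold=thr,
                       present_binary=present_binary)
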