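"""Spatial projection, AUC-gated ensembling, MTSS binarization, and
range-change / elevation-shift accounting.

The ensemble suitability map is the unweighted per-cell mean over the model
runs whose test AUC clears the gate (0.8 by convention).  The ensemble's
own MTSS threshold is derived from its predictions on the pooled test
partitions of the contributing runs, then applied to the present and every
future projection.  Per-GCM binary futures within one forcing pathway are
combined by cell-wise averaging with a majority (mean >= 0.5) rule.

Range change between a present and a future binary map follows the
loss/stable/gain/never transition semantics:

    pct_loss   = 100 * loss / (loss + stable)
    pct_gain   = 100 * gain / (loss + stable)
    pct_change = pct_gain - pct_loss

i.e. percentages are relative to the present suitable area.  The elevation
summary compares the altitude distribution of presently suitable cells with
that of cells suitable in the future (stable plus gain).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import Grid, PredictorStack
from .modeling import ModelRun, TrainingTable, mtss_threshold

__all__ = [
    "EnsembleResult",
    "RangeChange",
    "ElevationSummary",
    "predict_map",
    "ensemble_maps",
    "ensemble_mtss_threshold",
    "mtss_binarize",
    "combine_binary",
    "range_change",
    "elevation_shift",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (matches conventional table formatting)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def predict_map(run: ModelRun, stack: PredictorStack) -> Grid:
    """Project one fitted run over a predictor stack.

    Valid cells get the model's suitability in [0, 1]; a cell where any
    predictor is nodata is nodata.
    """
    missing = [v for v in run.predictor_names if v not in stack]
    if missing:
        raise KeyError(f"stack is missing predictor layers {missing}")
    template = stack.template
    nodata = stack.combined_nodata()
    rows, cols = np.nonzero(~nodata)
    out = np.zeros(template.shape)
    if len(rows):
        X = stack.to_table(rows, cols, run.predictor_names)
        out[rows, cols] = run.predict_suitability(X)
    return Grid(out, nodata.copy(), template.origin_lon, template.origin_lat,
                template.cell_size, template.crs)


@dataclass
class EnsembleResult:
    map: Grid
    n_contributing: int
    n_total: int
    contributing: list[int]  # indices into the input lists


def ensemble_maps(maps: list[Grid], runs: list[ModelRun],
                  auc_min: float = 0.8) -> EnsembleResult:
    """Unweighted mean of the maps whose run AUC exceeds the gate."""
    if len(maps) != len(runs):
        raise ValueError("one run per map required")
    passing = [i for i, r in enumerate(runs)
               if r.evaluation is not None and r.evaluation.auc > auc_min]
    if not passing:
        raise ValueError(f"no model run passes the AUC > {auc_min} gate")
    template = maps[0]
    for m in maps[1:]:
        if not m.aligned_with(template):
            raise ValueError("suitability maps are not aligned")
    stackd = np.stack([maps[i].masked() for i in passing])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-nodata cells
        mean = np.nanmean(stackd, axis=0)
    mask = np.all([maps[i].nodata_mask for i in passing], axis=0) | ~np.isfinite(mean)
    mean = np.where(mask, 0.0, mean)
    return EnsembleResult(
        map=Grid(mean, mask, template.origin_lon, template.origin_lat,
                 template.cell_size, template.crs),
        n_contributing=len(passing), n_total=len(maps), contributing=passing)


def ensemble_mtss_threshold(runs: list[ModelRun], tables: list[TrainingTable],
                            contributing: list[int]) -> float:
    """MTSS threshold of the ensemble on the pooled test partitions.

    For every contributing run's test rows, the *ensemble* prediction (mean
    over contributing models) is scored; the threshold maximizing
    sensitivity + specificity over the pooled rows is returned.
    """
    scores, labels = [], []
    models = [runs[i] for i in contributing]
    for i in contributing:
        test = tables[i].part("test")
        X = test[tables[i].predictor_names]
        ens = np.mean([m.predict_suitability(X) for m in models], axis=0)
        scores.append(ens)
        labels.append(test["response"].to_numpy())
    thr, _, _ = mtss_threshold(np.concatenate(scores), np.concatenate(labels))
    return thr


def mtss_binarize(suitability: Grid, threshold: float) -> Grid:
    """Binary map: 1 where suitability >= threshold, nodata preserved."""
    vals = (suitability.values >= threshold).astype(float)
    vals[suitability.nodata_mask] = 0.0
    return suitability.copy(values=vals)


def combine_binary(maps: list[Grid]) -> Grid:
    """Cell-wise average of binary maps, re-binarized by majority.

    The mean of the member maps is taken per cell and a cell counts suitable
    when the mean is >= 0.5 (inclusive: exact ties count suitable).  Used to
    merge the per-GCM futures within one forcing pathway.
    """
    if not maps:
        raise ValueError("need at least one binary map")
    template = maps[0]
    for m in maps[1:]:
        if not m.aligned_with(template):
            raise ValueError("binary maps are not aligned")
    mean = np.mean([m.values for m in maps], axis=0)
    mask = np.any([m.nodata_mask for m in maps], axis=0)
    vals = (mean >= 0.5).astype(float)
    vals[mask] = 0.0
    return Grid(vals, mask, template.origin_lon, template.origin_lat,
                template.cell_size, template.crs)


@dataclass
class RangeChange:
    """Loss/stable/gain/never transition counts and derived percentages.

    Percentages are relative to the present suitable area (loss + stable)
    and reported to one decimal, rounding half away from zero; pct_change is
    rounded after differencing the unrounded percentages.
    """

    loss_cells: int
    stable_cells: int
    gain_cells: int
    never_cells: int

    @property
    def present_cells(self) -> int:
        return self.loss_cells + self.stable_cells

    @property
    def future_cells(self) -> int:
        return self.stable_cells + self.gain_cells

    @property
    def pct_loss(self) -> float:
        return round_half_away(100.0 * self.loss_cells / self.present_cells)

    @property
    def pct_gain(self) -> float:
        return round_half_away(100.0 * self.gain_cells / self.present_cells)

    @property
    def pct_change(self) -> float:
        raw = 100.0 * (self.gain_cells - self.loss_cells) / self.present_cells
        return round_half_away(raw)

    @classmethod
    def from_counts(cls, loss: int, stable: int, gain: int,
                    never: int = 0) -> "RangeChange":
        return cls(loss_cells=int(loss), stable_cells=int(stable),
                   gain_cells=int(gain), never_cells=int(never))

    def as_dict(self) -> dict:
        return {
            "loss_cells": self.loss_cells, "stable_cells": self.stable_cells,
            "gain_cells": self.gain_cells, "never_cells": self.never_cells,
            "pct_loss": self.pct_loss, "pct_gain": self.pct_gain,
            "pct_change": self.pct_change,
        }


def range_change(present: Grid, future: Grid) -> RangeChange:
    """Transition accounting between two aligned binary maps.

    loss = 1→0, stable = 1→1, gain = 0→1, never = 0→0 over the shared valid
    cells; the four counts partition the valid cells.
    """
    if not present.aligned_with(future):
        raise ValueError("binary maps are not aligned")
    if not np.array_equal(present.nodata_mask, future.nodata_mask):
        raise ValueError("binary maps have different valid masks")
    valid = ~present.nodata_mask
    p = present.values[valid] > 0.5
    f = future.values[valid] > 0.5
    rc = RangeChange(
        loss_cells=int((p & ~f).sum()),
        stable_cells=int((p & f).sum()),
        gain_cells=int((~p & f).sum()),
        never_cells=int((~p & ~f).sum()),
    )
    assert rc.loss_cells + rc.stable_cells == int(p.sum())
    assert rc.stable_cells + rc.gain_cells == int(f.sum())
    assert (rc.loss_cells + rc.stable_cells + rc.gain_cells + rc.never_cells
            == int(valid.sum()))
    return rc


@dataclass
class ElevationSummary:
    """Altitude distribution of suitable cells, present vs future."""

    present_mean: float
    future_mean: float
    present_q1: float
    present_median: float
    present_q3: float
    future_q1: float
    future_median: float
    future_q3: float

    @property
    def shift(self) -> float:
        return self.future_mean - self.present_mean

    def as_dict(self) -> dict:
        return {
            "present_mean": self.present_mean, "future_mean": self.future_mean,
            "present_q1": self.present_q1, "present_median": self.present_median,
            "present_q3": self.present_q3, "future_q1": self.future_q1,
            "future_median": self.future_median, "future_q3": self.future_q3,
            "shift": self.shift,
        }


def elevation_shift(present: Grid, future: Grid, elevation: Grid) -> ElevationSummary:
    """Compare the altitude of presently vs future-suitable cells.

    Future-suitable means suitable in the future map (the union of stable
    and gain cells).  Means and quartiles are over the elevation values of
    the respective suitable cells; shift = future mean - present mean.
    """
    for g in (future, elevation):
        if not present.aligned_with(g):
            raise ValueError("maps and elevation are not aligned")
    valid = ~(present.nodata_mask | future.nodata_mask | elevation.nodata_mask)
    p = (present.values > 0.5) & valid
    f = (future.values > 0.5) & valid
    if not p.any() or not f.any():
        raise ValueError("no suitable cells in the present or future map")
    ep = elevation.values[p]
    ef = elevation.values[f]
    pq1, pmed, pq3 = np.percentile(ep, [25, 50, 75])
    fq1, fmed, fq3 = np.percentile(ef, [25, 50, 75])
    return ElevationSummary(
        present_mean=float(ep.mean()), future_mean=float(ef.mean()),
        present_q1=float(pq1), present_median=float(pmed), present_q3=float(pq3),
        future_q1=float(fq1), future_median=float(fmed), future_q3=float(fq3),
    )
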