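"""Predictor preparation: alignment, terrain slope, masking, collinearity
filtering, and GCM selection.

Collinearity control follows the common two-step practice: variance
inflation factors diagnose overall multicollinearity, then an iterative
pairwise-correlation filter drops, from each offending pair, the variable
with the higher mean absolute correlation against everything still in play,
until no pair exceeds the threshold.  An explicit keep-list protects
variables the analyst wants retained on ecological grounds.

GCM selection mirrors ensemble-comparison practice: each candidate climate
model is summarized by its study-area mean change in two diagnostic
variables; candidates closest (Euclidean) to the across-candidate ensemble
mean are selected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .grid import M_PER_DEG, Grid, PredictorStack
from .occurrences import StudyArea

__all__ = [
    "GcmCandidate",
    "CorSelectResult",
    "align_stack",
    "compute_slope",
    "crop_mask",
    "sample_cells",
    "multicollinearity_vif",
    "cor_select",
    "select_gcms",
]


@dataclass
class GcmCandidate:
    """One general circulation model's future predictor stack."""

    name: str
    future_stack: PredictorStack


def _resample_bilinear(layer: Grid, template: Grid) -> Grid:
    """Bilinear resampling of one grid onto the template's cell centers."""
    src_lat = layer.origin_lat - (np.arange(layer.n_rows) + 0.5) * layer.cell_size
    src_lon = layer.origin_lon + (np.arange(layer.n_cols) + 0.5) * layer.cell_size
    vals = layer.values.copy()
    vals[layer.nodata_mask] = np.nan
    # latitude axis is descending; flip so the interpolator sees ascending coords
    interp = RegularGridInterpolator(
        (src_lat[::-1], src_lon), vals[::-1, :],
        method="linear", bounds_error=False, fill_value=np.nan)
    lon_mesh, lat_mesh = template.lon_lat_mesh()
    out = interp(np.column_stack([lat_mesh.ravel(), lon_mesh.ravel()]))
    out = out.reshape(template.shape)
    mask = ~np.isfinite(out) | template.nodata_mask
    out = np.where(mask, 0.0, out)
    return Grid(out, mask, template.origin_lon, template.origin_lat,
                template.cell_size, template.crs)


def align_stack(layers: dict[str, Grid], template: Grid) -> PredictorStack:
    """Resample every layer onto the template grid (bilinear).

    Layers already on the template grid are passed through bit-identically.
    Nodata propagates: an output cell touching any nodata source cell, or
    falling outside the source extent, is nodata.
    """
    out: dict[str, Grid] = {}
    for name, layer in layers.items():
        if layer.crs is None:
            raise ValueError(f"layer {name!r} has no CRS defined")
        if layer.aligned_with(template):
            out[name] = layer
            continue
        res = _resample_bilinear(layer, template)
        if res.nodata_mask.all():
            raise ValueError(f"layer {name!r} has no overlap with the template")
        out[name] = res
    return PredictorStack(out)


def compute_slope(elevation: Grid) -> Grid:
    """Terrain slope in degrees from elevation in meters (Horn's 3x3 method).

    Degree spacing is converted to meters with 111,320 m per degree of
    latitude and a cos(latitude) correction for longitude.  Edge cells and
    cells with any nodata neighbor are nodata.
    """
    if elevation.n_rows < 3 or elevation.n_cols < 3:
        raise ValueError("elevation grid must be at least 3x3")
    z = elevation.values
    bad = elevation.nodata_mask

    # 3x3 shifted views over the interior
    def s(dr: int, dc: int) -> np.ndarray:
        return z[1 + dr : z.shape[0] - 1 + dr, 1 + dc : z.shape[1] - 1 + dc]

    def sbad(dr: int, dc: int) -> np.ndarray:
        return bad[1 + dr : z.shape[0] - 1 + dr, 1 + dc : z.shape[1] - 1 + dc]

    _, lat_mesh = elevation.lon_lat_mesh()
    dy_m = elevation.cell_size * M_PER_DEG
    dx_m = elevation.cell_size * M_PER_DEG * np.cos(np.radians(lat_mesh[1:-1, 1:-1]))

    # Horn kernel: weights 1,2,1 along each edge of the 3x3 window
    dzdx = ((s(-1, 1) + 2 * s(0, 1) + s(1, 1))
            - (s(-1, -1) + 2 * s(0, -1) + s(1, -1))) / (8.0 * dx_m)
    dzdy = ((s(1, -1) + 2 * s(1, 0) + s(1, 1))
            - (s(-1, -1) + 2 * s(-1, 0) + s(-1, 1))) / (8.0 * dy_m)
    slope_int = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))

    any_bad = np.zeros_like(slope_int, dtype=bool)
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            any_bad |= sbad(dr, dc)

    out = np.full(z.shape, np.nan)
    out[1:-1, 1:-1] = np.where(any_bad, np.nan, slope_int)
    mask = ~np.isfinite(out)
    out = np.where(mask, 0.0, out)
    return Grid(out, mask, elevation.origin_lon, elevation.origin_lat,
                elevation.cell_size, elevation.crs)


def crop_mask(stack: PredictorStack, area: StudyArea) -> PredictorStack:
    """Set cells outside the study area to nodata and trim to its bbox."""
    template = stack.template
    if not area.mask.aligned_with(template):
        raise ValueError("study area is not aligned with the stack")
    keep = area.bool_mask
    if not keep.any():
        raise ValueError("study area mask has no cells")
    rows = np.nonzero(keep.any(axis=1))[0]
    cols = np.nonzero(keep.any(axis=0))[0]
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    new_origin_lon = template.origin_lon + c0 * template.cell_size
    new_origin_lat = template.origin_lat - r0 * template.cell_size
    out: dict[str, Grid] = {}
    for name, g in stack.layers.items():
        vals = g.values[r0:r1, c0:c1].copy()
        mask = g.nodata_mask[r0:r1, c0:c1] | ~keep[r0:r1, c0:c1]
        vals[mask] = 0.0
        out[name] = Grid(vals, mask, new_origin_lon, new_origin_lat,
                         g.cell_size, g.crs)
    return PredictorStack(out)


def crop_study_area(area: StudyArea) -> StudyArea:
    """Trim a study area to its own mask bbox (companion to crop_mask).

    Cell indices on the returned mask match a stack cropped with the same
    area, so downstream sampling can index either consistently.
    """
    keep = area.bool_mask
    if not keep.any():
        raise ValueError("study area mask has no cells")
    rows = np.nonzero(keep.any(axis=1))[0]
    cols = np.nonzero(keep.any(axis=0))[0]
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    g = area.mask
    mask = Grid(g.values[r0:r1, c0:c1].copy(), g.nodata_mask[r0:r1, c0:c1].copy(),
                g.origin_lon + c0 * g.cell_size, g.origin_lat - r0 * g.cell_size,
                g.cell_size, g.crs)
    return StudyArea(mask=mask, buffer_deg=area.buffer_deg)


def sample_cells(stack: PredictorStack, max_n: int = 10_000,
                 seed: int = 0, names: list[str] | None = None) -> pd.DataFrame:
    """Seeded random sample of <= max_n valid cells as a variables table."""
    names = names or stack.names
    valid = ~stack.combined_nodata()
    rows, cols = np.nonzero(valid)
    if len(rows) == 0:
        raise ValueError("stack has no valid cells")
    if len(rows) > max_n:
        idx = np.random.default_rng(seed).choice(len(rows), max_n, replace=False)
        rows, cols = rows[idx], cols[idx]
    return pd.DataFrame(stack.to_table(rows, cols, names), columns=names)


def multicollinearity_vif(table: pd.DataFrame) -> dict[str, float]:
    """Variance inflation factor per variable: VIF_j = 1 / (1 - R2_j).

    R2_j is from the least-squares regression of variable j on all others
    (with intercept).  Perfect collinearity is reported as ``inf`` rather
    than silently clipped.
    """
    if table.shape[1] < 2:
        raise ValueError("need at least two variables")
    if table.shape[0] <= table.shape[1]:
        raise ValueError("need more rows than variables")
    X = table.to_numpy(dtype=float)
    names = list(table.columns)
    vifs: dict[str, float] = {}
    for j, name in enumerate(names):
        y = X[:, j]
        others = np.delete(X, j, axis=1)
        A = np.column_stack([np.ones(len(y)), others])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot == 0:
            vifs[name] = np.inf
            continue
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        vifs[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


@dataclass
class CorSelectResult:
    selected: list[str]
    dropped: list[str]
    reasons: dict[str, str]
    max_remaining_r: float

    def report(self) -> pd.DataFrame:
        rows = [{"variable": v, "kept": True, "reason": ""} for v in self.selected]
        rows += [{"variable": v, "kept": False, "reason": self.reasons[v]}
                 for v in self.dropped]
        return pd.DataFrame(rows)


def cor_select(table: pd.DataFrame, threshold: float = 0.8,
               keep_list: list[str] | None = None) -> CorSelectResult:
    """Iterative pairwise-correlation filtering at |r| >= threshold.

    While any remaining pair has |Pearson r| >= threshold, the pair with the
    largest |r| is examined and the member with the higher mean absolute
    correlation against all remaining variables is dropped; keep-list
    members are protected (their partner is dropped instead).  Errors out if
    the keep-list itself is internally correlated above the threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    keep_list = list(keep_list or [])
    missing = [k for k in keep_list if k not in table.columns]
    if missing:
        raise ValueError(f"keep_list variables not in table: {missing}")

    corr = table.corr(method="pearson").abs()
    kl = [k for k in table.columns if k in keep_list]
    if len(kl) >= 2:
        sub = corr.loc[kl, kl].to_numpy()
        iu = np.triu_indices(len(kl), k=1)
        if (sub[iu] >= threshold).any():
            raise ValueError("keep_list variables are mutually correlated above "
                             "the threshold; resolve the keep_list first")

    remaining = list(table.columns)
    dropped: list[str] = []
    reasons: dict[str, str] = {}
    while True:
        sub = corr.loc[remaining, remaining].to_numpy().copy()
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        worst = sub[i, j]
        if worst < threshold:
            break
        a, b = remaining[i], remaining[j]
        if a in keep_list and b in keep_list:  # guarded above; defensive
            raise ValueError("keep_list pair above threshold")
        if a in keep_list:
            victim, partner = b, a
        elif b in keep_list:
            victim, partner = a, b
        else:
            # mean |r| against everything else still remaining
            mean_a = sub[i].sum() / (len(remaining) - 1)
            mean_b = sub[j].sum() / (len(remaining) - 1)
            victim, partner = (a, b) if mean_a >= mean_b else (b, a)
        remaining.remove(victim)
        dropped.append(victim)
        reasons[victim] = (f"|r|={worst:.3f} with {partner} "
                           f">= threshold {threshold}")

    if len(remaining) >= 2:
        sub = corr.loc[remaining, remaining].to_numpy().copy()
        np.fill_diagonal(sub, 0.0)
        max_r = float(sub.max())
    else:
        max_r = 0.0
    return CorSelectResult(selected=remaining, dropped=dropped,
                           reasons=reasons, max_remaining_r=max_r)


def select_gcms(candidates: list[GcmCandidate], present: PredictorStack,
                variables: tuple[str, str], area: StudyArea, k: int,
                standardize: bool = False) -> list[tuple[str, float]]:
    """Rank GCM candidates by distance to the candidate-ensemble mean change.

    For each candidate, the study-area mean delta (future - present) of the
    two diagnostic variables is computed; candidates are ranked by Euclidean
    distance to the across-candidate mean of those deltas (raw units by
    default; ``standardize`` z-scores each delta axis first).  Returns the
    ``k`` closest as (name, distance), ranked; distance ties break on name
    so the result is invariant to candidate order.
    """
    if k > len(candidates):
        raise ValueError("k exceeds the number of candidates")
    if area.n_cells == 0:
        raise ValueError("empty study area")
    rows, cols = area.valid_cells()
    deltas = np.zeros((len(candidates), 2))
    for ci, cand in enumerate(candidates):
        for vi, var in enumerate(variables):
            if var not in cand.future_stack or var not in present:
                raise KeyError(f"variable {var!r} missing from a stack")
            diff = cand.future_stack[var].values - present[var].values
            deltas[ci, vi] = diff[rows, cols].mean()
    if standardize:
        sd = deltas.std(axis=0)
        sd[sd == 0] = 1.0
        space = (deltas - deltas.mean(axis=0)) / sd
        center = np.zeros(2)
    else:
        space = deltas
        center = deltas.mean(axis=0)
    dist = np.linalg.norm(space - center, axis=1)
    order = sorted(range(len(candidates)),
                   key=lambda i: (dist[i], candidates[i].name))
    return [(candidates[i].name, float(dist[i])) for i in order[:k]]
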