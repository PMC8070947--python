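"""The E-S-A vulnerability index on raster stacks.

The pipeline standardizes each raw indicator layer against its standard value
(RC = C/S for negative indicators, S/C for positive ones), aggregates the
standardized layers into element scores by Delphi weights (RB = sum RC_i W_i),
averages the elements into the three objectives with equal weights
(RE = (RB1+RB2)/2, RS = (RB3+RB4)/2, RA = (RB5+...+RB8)/4), and combines the
objectives into the island ecological vulnerability index as their geometric
mean, IEVI = (RE * RS * RA)^(1/3). The IEVI is reported in five classes:
non-vulnerable (<= 0.6), near (0.6-0.7], slight (0.7-0.9], moderate (0.9-1.0],
severe (> 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (
    CLASS_LABELS,
    DEFAULT_CLASS_BREAKS,
    OBJECTIVE_ELEMENTS,
    IndexConfig,
    IndicatorSpec,
    warn_weight_renormalization,
)
from .grid import CategoricalRaster, Grid, Raster, RegionMask, require_aligned


class DataError(ValueError):
    """Input data violate a precondition of the index computation."""


def constant_raster(value: float, grid: Grid, domain: RegionMask | None = None) -> Raster:
    """Materialize an island-wide-constant (uniform) indicator over the domain."""
    values = np.full(grid.shape, float(value))
    valid = domain.member.copy() if domain is not None else np.ones(grid.shape, bool)
    if domain is not None:
        require_aligned(grid, domain.grid)
        values[~valid] = np.nan
    return Raster(grid, values, valid)


def standardize(raw: Raster, spec: IndicatorSpec, domain: RegionMask) -> Raster:
    """Single-factor score RC for one indicator.

    For a negative indicator RC = C/S (larger raw value -> more vulnerable);
    for a positive indicator RC = S/C. With ``standard_rule='regional_mean'``
    the standard value S is the mean of the raw layer over the valid cells of
    the study domain.
    """
    require_aligned(raw.grid, domain.grid)
    valid = raw.valid & domain.member
    if spec.standard_rule == "regional_mean":
        if not valid.any():
            raise DataError(f"{spec.id}: no valid cells in domain to take the regional mean")
        s = float(raw.values[valid].mean())
    else:
        s = float(spec.standard_value)  # validated positive at config time
    if s == 0:
        raise DataError(f"{spec.id}: standard value is zero")
    out = np.full(raw.grid.shape, np.nan)
    c = raw.values
    if spec.polarity == "negative":
        out[valid] = c[valid] / s
    else:
        if np.any(c[valid] <= 0):
            raise DataError(
                f"{spec.id}: positive indicator has nonpositive raw values; S/C undefined"
            )
        out[valid] = s / c[valid]
    return Raster(raw.grid, out, valid)


def aggregate_element(standardized: list[tuple[Raster, float]], element_id: str = "?") -> Raster:
    """Weighted sum of standardized indicator layers within one element.

    Printed weight tables are rounded, so per-element sums may be slightly off
    1 (e.g. 1.01); weights are renormalized to sum exactly 1 (with a warning)
    before summation. Sums further than 0.02 from 1 are rejected.
    """
    if not standardized:
        raise DataError("aggregate_element needs at least one layer")
    grids = [r.grid for r, _ in standardized]
    require_aligned(*grids)
    total = sum(w for _, w in standardized)
    if abs(total - 1.0) > 0.02:
        raise DataError(f"element {element_id}: weights sum to {total:.3f}, outside tolerance")
    warn_weight_renormalization(element_id, total)
    valid = np.logical_and.reduce([r.valid for r, _ in standardized])
    acc = np.full(grids[0].shape, np.nan)
    acc[valid] = sum(r.values[valid] * (w / total) for r, w in standardized)
    return Raster(grids[0], acc, valid)


_OBJECTIVE_ARITY = {name: len(elems) for name, elems in OBJECTIVE_ELEMENTS.items()}


def aggregate_objective(elements: list[Raster], objective: str) -> Raster:
    """Equal-weight mean of the element layers under one objective.

    Exposure and sensitivity each average exactly two element layers,
    adaptability four; the equal weights are structural and not configurable.
    """
    if objective not in _OBJECTIVE_ARITY:
        raise DataError(f"unknown objective {objective!r}")
    n = _OBJECTIVE_ARITY[objective]
    if len(elements) != n:
        raise DataError(f"{objective} aggregates exactly {n} element layers, got {len(elements)}")
    require_aligned(*[r.grid for r in elements])
    valid = np.logical_and.reduce([r.valid for r in elements])
    acc = np.full(elements[0].grid.shape, np.nan)
    acc[valid] = sum(r.values[valid] for r in elements) / n
    return Raster(elements[0].grid, acc, valid)


def compute_ievi(re_: Raster, rs: Raster, ra: Raster) -> Raster:
    """Per-cell geometric mean of the three objective layers."""
    require_aligned(re_.grid, rs.grid, ra.grid)
    valid = re_.valid & rs.valid & ra.valid
    for name, r in (("exposure", re_), ("sensitivity", rs), ("adaptability", ra)):
        if np.any(r.values[valid] < 0):
            raise DataError(f"{name} layer has negative values at valid cells")
    out = np.full(re_.grid.shape, np.nan)
    out[valid] = np.cbrt(re_.values[valid] * rs.values[valid] * ra.values[valid])
    return Raster(re_.grid, out, valid)


def classify_ievi(
    ievi: Raster, breaks: tuple[float, ...] = DEFAULT_CLASS_BREAKS
) -> CategoricalRaster:
    """Map the IEVI layer onto the five vulnerability classes.

    Intervals are left-open/right-closed: class 1 is (-inf, b1], class k is
    (b_{k-1}, b_k], the top class (b_last, inf).
    """
    if list(breaks) != sorted(breaks) or len(set(breaks)) != len(breaks):
        raise DataError("class breaks must be strictly increasing")
    levels = np.searchsorted(np.asarray(breaks), ievi.values, side="left") + 1
    levels = np.where(ievi.valid, levels, 1).astype(np.int32)
    return CategoricalRaster(
        ievi.grid, levels, len(breaks) + 1, ievi.valid.copy(), labels=dict(CLASS_LABELS)
    )


def class_area_fractions(classes: CategoricalRaster, domain: RegionMask) -> pd.DataFrame:
    """Share of the study domain occupied by each vulnerability class.

    Returns a frame with one row per state (state, label, cells, fraction);
    fractions are over valid domain cells and sum to 1.
    """
    require_aligned(classes.grid, domain.grid)
    sel = classes.valid & domain.member
    n = int(sel.sum())
    if n == 0:
        raise DataError("no valid cells inside the domain")
    counts = np.bincount(classes.levels[sel], minlength=classes.n_states + 1)[1:]
    labels = classes.labels or {}
    return pd.DataFrame(
        {
            "state": np.arange(1, classes.n_states + 1),
            "label": [labels.get(s, str(s)) for s in range(1, classes.n_states + 1)],
            "cells": counts,
            "fraction": counts / n,
        }
    )


@dataclass
class AssessmentResult:
    """All layers produced by a full index run."""

    rc: dict[str, Raster]
    rb: dict[str, Raster]
    objectives: dict[str, Raster]  # keys: exposure, sensitivity, adaptability
    ievi: Raster
    classes: CategoricalRaster
    fractions: pd.DataFrame


def assess(
    raw: dict[str, Raster | float],
    cfg: IndexConfig,
    domain: RegionMask,
) -> AssessmentResult:
    """Run the whole index pipeline on a stack of raw indicator layers.

    ``raw`` maps indicator id to either a raster or a scalar (for uniform
    indicators, materialized as a constant layer over the domain).
    """
    rc: dict[str, Raster] = {}
    for spec in cfg.indicators:
        if spec.id not in raw:
            raise DataError(f"missing raw layer for indicator {spec.id}")
        layer = raw[spec.id]
        if not isinstance(layer, Raster):
            layer = constant_raster(float(layer), domain.grid, domain)
        rc[spec.id] = standardize(layer, spec, domain)
    rb: dict[str, Raster] = {}
    for eid, specs in cfg.by_element().items():
        rb[eid] = aggregate_element([(rc[s.id], s.weight) for s in specs], eid)
    objectives = {
        name: aggregate_objective([rb[e] for e in elems if e in rb], name)
        for name, elems in OBJECTIVE_ELEMENTS.items()
    }
    ievi = compute_ievi(
        objectives["exposure"], objectives["sensitivity"], objectives["adaptability"]
    )
    classes = classify_ievi(ievi, cfg.class_breaks)
    fractions = class_area_fractions(classes, domain)
    return AssessmentResult(rc, rb, objectives, ievi, classes, fractions)
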