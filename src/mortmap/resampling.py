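"""Polygon-referenced observations -> population-weighted pseudo-points.

The geostatistical likelihood is point-referenced, but some survey clusters
are only located to an administrative polygon.  Each such observation is
replaced by up to ``k_points`` cell-centre pseudo-points sampled (without
replacement by default) proportional to the polygon's under-5 population in
the observation's year; entrants and deaths are split across the points with
weights proportional to the selected cells' population, normalised to sum to
one, so totals are conserved exactly and every pseudo-point keeps the parent's
empirical ratio Y/n.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .histories import OBS_COLUMNS
from .synthetic import AdminTessellation, GridDefinition, PopulationSurface

logger = logging.getLogger(__name__)

RESAMPLED_COLUMNS = OBS_COLUMNS + ["parent_observation_id"]


def resample_polygon_observations(
    obs: pd.DataFrame,
    population: PopulationSurface,
    admin: AdminTessellation,
    grid: GridDefinition,
    k_points: int = 10,
    seed: int = 0,
    with_replacement: bool = False,
) -> pd.DataFrame:
    """Replace polygon-referenced rows with weighted pseudo-point rows.

    Point-referenced rows pass through unchanged (weight and counts intact),
    with ``parent_observation_id`` equal to their own ``obs_id``.  Rows whose
    polygon has zero total population raise, naming the polygon.
    """
    if k_points < 1:
        raise ValueError(f"k_points must be >= 1, got {k_points}")
    if obs.empty:
        out = obs.copy()
        out["parent_observation_id"] = pd.Series(dtype=object)
        return out

    rng = np.random.default_rng(seed)
    has_poly = obs["polygon_id"].notna() & (obs["polygon_id"].astype(str) != "")
    points = obs.loc[~has_poly].copy()
    if points["x"].isna().any() or points["y"].isna().any():
        raise ValueError("point-referenced observations must carry coordinates")
    points["parent_observation_id"] = points["obs_id"]

    poly_rows = obs.loc[has_poly]
    frames = [points]
    centres = grid.cell_centres()
    for _, row in poly_rows.iterrows():
        unit = admin.by_id(str(row["polygon_id"]))
        t = int(grid.year_index(int(row["year"])))
        pop = population.under5[t, unit.cells]
        total = pop.sum()
        if total <= 0:
            raise ValueError(
                f"polygon {row['polygon_id']!r} has zero under-5 population in "
                f"year {row['year']}; cannot resample observation {row['obs_id']}"
            )
        populated = pop > 0
        cand_cells = unit.cells[populated]
        cand_pop = pop[populated]
        k = min(k_points, len(cand_cells)) if not with_replacement else k_points
        if not with_replacement and len(cand_cells) <= k_points:
            chosen = np.arange(len(cand_cells))
        else:
            chosen = rng.choice(
                len(cand_cells), size=k, replace=with_replacement,
                p=cand_pop / cand_pop.sum(),
            )
        cells = cand_cells[chosen]
        w = cand_pop[chosen].astype(float)
        w = w / w.sum()
        sub = pd.DataFrame({c: np.repeat(row[c], len(cells)) for c in OBS_COLUMNS})
        sub["x"] = centres[cells, 0]
        sub["y"] = centres[cells, 1]
        sub["polygon_id"] = ""
        sub["entrants"] = float(row["entrants"]) * w
        sub["deaths"] = float(row["deaths"]) * w
        sub["parent_observation_id"] = row["obs_id"]
        frames.append(sub)

    out = pd.concat(frames, ignore_index=True)
    out = out.sort_values(["parent_observation_id"], kind="stable").reset_index(drop=True)
    out["obs_id"] = np.arange(len(out))
    if has_poly.any():
        logger.info(
            "resampled %d polygon observation(s) into pseudo-points (k=%d)",
            int(has_poly.sum()), k_points,
        )
    return out[RESAMPLED_COLUMNS]
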