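"""Artificial resource landscapes for the central-place-forager simulator.

A landscape is a 100 x 100 grid of prey abundance (g of catchable prey per
fishing hour) on 10 x 10 km cells with the breeding island at the grid centre.
Construction:

1. a stationary Gaussian random field whose correlation scale grows with the
   aggregation level (``aggreg``), built by Gaussian smoothing of white noise;
2. zero masks over the island plateau (distance <= 50 km) and beyond the
   500 km foraging limit, plus an accessibility gradient rising linearly
   from 0 at the plateau edge to 1 at the configured distance-to-resource
   ``dist``, applied as an abundance attenuation (the near zone is poor);
3. truncation of the field at zero (negative values become zero abundance),
   so roughly half of the accessible annulus carries resource, in smooth
   blobs whose size grows with the aggregation level;
4. normalisation so the mean over the accessible annulus (plateau edge to
   500 km) equals the abundance level ``abund`` in g h^-1; the mean over the
   non-zero cells alone (AvgEnv, which controls the fishing threshold) is
   correspondingly higher and is recorded per map.

Coordinates are 0-based row-major; the island is cell (50, 50) and distances
are measured centre-to-centre in km.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .params import Params

AGGREG_LEVELS = (0, 1, 2, 3, 4, 6, 8, 10)
ABUND_LEVELS = (90, 180, 270, 360)
DIST_LEVELS = tuple(range(100, 501, 50))

#: steepness of the accessibility attenuation between the plateau edge and
#: the distance-to-resource; >1 keeps the inner zone below profitability so
#: foraging concentrates beyond ``dist`` (see docs/methods.md)
GRADIENT_EXPONENT = 0.15

#: Gaussian smoothing sigma per aggregation level, in cells: sigma = KAPPA * a.
#: Calibrated against the published patch counts at the extreme aggregation
#: levels (see docs/methods.md).
SIGMA_PER_LEVEL = 0.45


@dataclass(frozen=True)
class MapConfig:
    """Factor levels identifying one landscape draw."""

    aggreg: int = 3
    abund: float = 180.0
    dist: float = 150.0
    rep_map: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.aggreg not in AGGREG_LEVELS:
            raise ValueError(f"aggreg must be one of {AGGREG_LEVELS}")
        if self.dist <= 50 or self.dist > 500:
            raise ValueError("dist must lie in (50, 500] km")
        if self.abund <= 0:
            raise ValueError("abund must be positive")


@dataclass
class ResourceMap:
    """Generated landscape: abundance values plus geometry metadata."""

    values: np.ndarray                  # (100, 100) g h^-1
    config: MapConfig
    cell_km: float = 10.0
    island: tuple = (50, 50)
    dist_field: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.dist_field is None:
            self.dist_field = build_distance_field(self.island, self.cell_km,
                                                   self.values.shape[0])

    @property
    def avg_env(self) -> float:
        return avg_env(self.values)

    @property
    def island_xy_km(self) -> tuple:
        i, j = self.island
        return ((i + 0.5) * self.cell_km, (j + 0.5) * self.cell_km)

    # ---------------------------------------------------------------- I/O
    def save(self, path) -> None:
        """Write the grid as headerless CSV plus a JSON sidecar."""
        path = Path(path)
        np.savetxt(path, self.values, delimiter=",", fmt="%.6g")
        meta = {
            "aggreg": self.config.aggreg,
            "abund": self.config.abund,
            "dist": self.config.dist,
            "rep_map": self.config.rep_map,
            "seed": self.config.seed,
            "cell_km": self.cell_km,
            "island": list(self.island),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path) -> "ResourceMap":
        path = Path(path)
        values = np.loadtxt(path, delimiter=",")
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            cfg = MapConfig(meta["aggreg"], meta["abund"], meta["dist"],
                            meta.get("rep_map", 1), meta.get("seed", 0))
            return cls(values, cfg, meta.get("cell_km", 10.0),
                       tuple(meta.get("island", (50, 50))))
        return cls(values, MapConfig())


@dataclass
class PatchStats:
    n_patches: int
    mean_patch_size: float


# ---------------------------------------------------------------------------
def build_distance_field(island=(50, 50), cell_km=10.0, n=100) -> np.ndarray:
    """Euclidean centre-to-centre distance (km) of every cell to the island."""
    idx = np.arange(n)
    di = (idx[:, None] - island[0]) * cell_km
    dj = (idx[None, :] - island[1]) * cell_km
    return np.hypot(di, dj)


def apply_masks(raw_field, dist_field, dist, rng=None, plateau_km=50.0,
                d_max_km=500.0, mode="value"):
    """Zero the plateau and the far field; attenuate the near field.

    The accessibility gradient runs linearly from 0 at the plateau edge to 1
    at ``dist``; cells between ``dist`` and the 500 km limit keep weight 1.
    With ``mode='value'`` (default) the gradient scales cell abundance, so
    the near zone is present but poor; with ``mode='retention'`` it is the
    probability of keeping the cell at full value (Bernoulli per cell, using
    ``rng``).
    """
    if dist <= plateau_km or dist > d_max_km:
        raise ValueError("dist must lie in (plateau, d_max]")
    out = np.asarray(raw_field, dtype=float).copy()
    out[(dist_field <= plateau_km) | (dist_field > d_max_km)] = 0.0
    grad_zone = (dist_field > plateau_km) & (dist_field < dist)
    p_keep = (dist_field - plateau_km) / (dist - plateau_km)
    if mode == "value":
        out[grad_zone] *= p_keep[grad_zone] ** GRADIENT_EXPONENT
    elif mode == "retention":
        if rng is None or isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        drop = grad_zone & (rng.random(out.shape) >= p_keep)
        out[drop] = 0.0
    else:
        raise ValueError("mode must be 'value' or 'retention'")
    return out


def generate_field(config: MapConfig, params: Params | None = None) -> ResourceMap:
    """Draw one landscape; deterministic given (config, seed)."""
    params = params or Params()
    n = params.n_cells
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed),
                                                        int(config.rep_map)]))
    dist_field = build_distance_field((n // 2, n // 2), params.cell_km, n)
    for attempt in range(10):
        g = rng.standard_normal((n, n))
        sigma = SIGMA_PER_LEVEL * config.aggreg
        if sigma > 0:
            g = ndimage.gaussian_filter(g, sigma, mode="wrap")
            g /= g.std()
        weight = apply_masks(np.ones_like(g), dist_field, config.dist, rng,
                             params.plateau_km, params.d_max_km)
        if (weight > 0).sum() == 0:
            continue
        vals = np.clip(g, 0.0, None) * weight
        nz = vals > 0
        if nz.sum() > 0:
            # the abundance level fixes the map's total prey budget:
            # grid-wide mean = abund, all of it carried by the annulus
            vals *= config.abund / vals.mean()
            rmap = ResourceMap(vals, config, params.cell_km, (n // 2, n // 2),
                               dist_field)
            return rmap
        warnings.warn("degenerate all-zero field after masking; redrawing")
    raise RuntimeError("could not generate a non-degenerate map")


def avg_env(values) -> float:
    """AvgEnv: arithmetic mean of the strictly positive cells (g h^-1)."""
    values = np.asarray(values)
    nz = values > 0
    if not nz.any():
        raise ValueError("map has no non-zero cells")
    return float(values[nz].mean())


def patch_statistics(values, threshold: float = 55.0) -> PatchStats:
    """Connected components (4-neighbourhood) of cells above ``threshold``.

    The default threshold is the fishing-profitability abundance (1.5 map
    units, about 55 g h^-1).
    """
    values = np.asarray(values)
    mask = values > threshold
    labels, n = ndimage.label(mask)  # default structure = 4-neighbourhood
    if n == 0:
        return PatchStats(0, 0.0)
    sizes = np.bincount(labels.ravel())[1:]
    return PatchStats(int(n), float(sizes.mean()))
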