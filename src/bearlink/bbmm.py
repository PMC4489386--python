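"""Two-fix Brownian bridge movement model.

The utilization distribution (UD) between two consecutive fixes a (at time 0)
and b (at time T, hours) is the time average over t in (0, T) of a circular
bivariate normal centred on the straight-line interpolation

    mu(t) = a + (t/T) (b - a)

with variance

    sigma^2(t) = T * a(1-a) * sig1^2 + (1-a)^2 * sig2^2 + a^2 * sig2^2,
    a = t / T,

where sig1 (m h^-1/2) is the Brownian motion smoothing parameter — larger for
fast, tortuous movement — and sig2 (m) is the GPS location-error standard
deviation. The time integral is discretized by a midpoint rule; per-cell mass
is density at the cell centre times cell area, with no renormalization: the
grid must be large enough that edge truncation stays below ``MASS_EPS``.

sig1 is estimated per animal by the alternate-fix ("odd point") likelihood:
every odd-indexed interior fix is treated as an observation of the bridge
between its two neighbours, and the summed log transition density is
maximized over a search interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime
from typing import Sequence

import numpy as np
import shapely
from scipy.optimize import minimize_scalar
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union

from .telemetry import GpsFix, Trajectory

__all__ = [
    "BridgeParams",
    "UDGrid",
    "IsoplethPolygon",
    "Sig1Estimate",
    "bridge_sigma2",
    "bridge_density_at",
    "bridge_density",
    "estimate_sig1",
    "isopleth_polygon",
    "backward_ellipses",
]

MASS_EPS = 1e-3


class TruncationError(ValueError):
    """The grid clips more than MASS_EPS of probability mass."""


class DegenerateUDError(ValueError):
    """The UD carries no mass (cannot contour)."""


@dataclass(frozen=True)
class BridgeParams:
    """Variance components of the bridge: sig1 in m h^-1/2, sig2 in m."""

    sig1: float
    sig2: float = 5.0

    def __post_init__(self) -> None:
        if not self.sig1 > 0:
            raise ValueError("sig1 must be > 0")
        if self.sig2 < 0:
            raise ValueError("sig2 must be >= 0")


@dataclass
class UDGrid:
    """Gridded probability masses; origin is the lower-left cell corner."""

    origin: tuple[float, float]
    cell_size: tuple[float, float]
    values: np.ndarray  # shape (ny, nx), row 0 = southernmost

    def total_mass(self) -> float:
        return float(self.values.sum())

    def x_centers(self) -> np.ndarray:
        x0, _ = self.origin
        dx, _ = self.cell_size
        return x0 + dx * (np.arange(self.values.shape[1]) + 0.5)

    def y_centers(self) -> np.ndarray:
        _, y0 = self.origin
        _, dy = self.cell_size
        return y0 + dy * (np.arange(self.values.shape[0]) + 0.5)

    def write_ascii_grid(self, path) -> None:
        """ESRI ASCII grid (text raster) of per-cell mass."""
        dx, dy = self.cell_size
        if abs(dx - dy) > 1e-9:
            raise ValueError("ASCII grid requires square cells")
        ny, nx = self.values.shape
        with open(path, "w") as fh:
            fh.write(f"ncols {nx}\nnrows {ny}\n")
            fh.write(f"xllcorner {self.origin[0]}\nyllcorner {self.origin[1]}\n")
            fh.write(f"cellsize {dx}\nNODATA_value -9999\n")
            for row in self.values[::-1]:  # ASCII grids run north to south
                fh.write(" ".join(f"{v:.10e}" for v in row) + "\n")


@dataclass
class IsoplethPolygon:
    """Cumulative-mass contour region of a UD."""

    level: float
    geometry: Polygon | MultiPolygon
    attained_mass: float

    @property
    def area(self) -> float:
        return float(self.geometry.area)

    def to_wkt(self) -> str:
        return self.geometry.wkt

    def to_geojson_feature(self) -> dict:
        from shapely.geometry import mapping

        return {
            "type": "Feature",
            "geometry": mapping(self.geometry),
            "properties": {
                "level": self.level,
                "attained_mass": self.attained_mass,
            },
        }


def bridge_sigma2(
    t: np.ndarray | float, T: float, sig1: float, sig2: float
) -> np.ndarray | float:
    """Pointwise variance sigma^2(t) of the bridge (m^2); t, T in hours."""
    a = np.asarray(t, dtype=float) / T
    return T * a * (1.0 - a) * sig1**2 + ((1.0 - a) ** 2 + a**2) * sig2**2


def _midpoint_nodes(T: float, n: int) -> np.ndarray:
    return (np.arange(n) + 0.5) * (T / n)


def bridge_density_at(
    points: np.ndarray,
    fix_a: GpsFix,
    fix_b: GpsFix,
    params: BridgeParams,
    time_steps: int = 100,
) -> np.ndarray:
    """Time-averaged bridge density (m^-2) at arbitrary probe points.

    ``points`` is (n, 2). Midpoint rule over ``time_steps`` nodes — the same
    quadrature as :func:`bridge_density`, exposed for probing and testing.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    T = (fix_b.timestamp - fix_a.timestamp).total_seconds() / 3600.0
    if T <= 0:
        raise ValueError("fix_b must be strictly later than fix_a")
    ts = _midpoint_nodes(T, time_steps)
    al = ts / T
    mx = fix_a.x + al * (fix_b.x - fix_a.x)  # (k,)
    my = fix_a.y + al * (fix_b.y - fix_a.y)
    s2 = np.asarray(bridge_sigma2(ts, T, params.sig1, params.sig2))
    s2 = np.maximum(s2, 1e-12)
    dx = points[:, 0][:, None] - mx[None, :]  # (n, k)
    dy = points[:, 1][:, None] - my[None, :]
    dens = np.exp(-(dx**2 + dy**2) / (2.0 * s2[None, :])) / (2.0 * np.pi * s2[None, :])
    return dens.mean(axis=1)


def bridge_density(
    fix_a: GpsFix,
    fix_b: GpsFix,
    params: BridgeParams,
    cell: float = 10.0,
    time_steps: int = 100,
    margin_sds: float = 6.0,
    grid_origin: tuple[float, float] | None = None,
    grid_shape: tuple[int, int] | None = None,
    check_truncation: bool = True,
) -> UDGrid:
    """Two-fix bridge UD on a square-cell grid.

    By default the grid is sized to cover both fixes with a margin of
    ``margin_sds`` times the maximum positional SD, which keeps edge
    truncation below ``MASS_EPS``. Raises :class:`TruncationError` when an
    explicitly supplied grid clips more mass than that;
    ``check_truncation=False`` skips the check (useful for needle-thin
    degenerate bridges whose mass a cell-centre quadrature cannot capture).
    """
    T = (fix_b.timestamp - fix_a.timestamp).total_seconds() / 3600.0
    if T <= 0:
        raise ValueError("fix_b must be strictly later than fix_a")
    ts = _midpoint_nodes(T, time_steps)
    s2 = np.asarray(bridge_sigma2(ts, T, params.sig1, params.sig2))
    s2 = np.maximum(s2, 1e-12)
    max_sd = float(np.sqrt(s2.max()))

    if grid_origin is None or grid_shape is None:
        margin = margin_sds * max_sd + cell
        x_lo = min(fix_a.x, fix_b.x) - margin
        x_hi = max(fix_a.x, fix_b.x) + margin
        y_lo = min(fix_a.y, fix_b.y) - margin
        y_hi = max(fix_a.y, fix_b.y) + margin
        # snap origin to the cell lattice so translated grids align
        x0 = np.floor(x_lo / cell) * cell
        y0 = np.floor(y_lo / cell) * cell
        nx = int(np.ceil((x_hi - x0) / cell))
        ny = int(np.ceil((y_hi - y0) / cell))
    else:
        x0, y0 = grid_origin
        ny, nx = grid_shape

    xc = x0 + cell * (np.arange(nx) + 0.5)
    yc = y0 + cell * (np.arange(ny) + 0.5)
    al = ts / T
    mx = fix_a.x + al * (fix_b.x - fix_a.x)
    my = fix_a.y + al * (fix_b.y - fix_a.y)

    vals = np.zeros((ny, nx))
    # separable circular gaussian: accumulate outer(gy_k, gx_k) over nodes
    for k in range(time_steps):
        inv2s = 1.0 / (2.0 * s2[k])
        gx = np.exp(-((xc - mx[k]) ** 2) * inv2s)
        gy = np.exp(-((yc - my[k]) ** 2) * inv2s)
        vals += np.outer(gy, gx) / (2.0 * np.pi * s2[k])
    vals *= cell * cell / time_steps

    total = vals.sum()
    if check_truncation and total < 1.0 - MASS_EPS:
        raise TruncationError(
            f"grid clips {1.0 - total:.4f} of UD mass (> {MASS_EPS}); "
            "enlarge the grid extent"
        )
    return UDGrid(origin=(float(x0), float(y0)), cell_size=(cell, cell), values=vals)


@dataclass
class Sig1Estimate:
    value: float
    log_likelihood: float
    n_triples: int
    at_boundary: bool = False


def _triple_arrays(trajectory: Trajectory, sig2: float):
    """Per-odd-fix quantities for the alternate-fix likelihood.

    Returns (d2, w, Tab) where for each valid triple (i-1, i, i+1):
    d2 = squared distance of fix i from the interpolated mean, w = a(1-a)*T
    scaling of the sig1^2 term, and the fixed sig2 contribution.
    """
    fixes = trajectory.fixes
    flags = trajectory.gap_flags
    d2, w, s2fix = [], [], []
    for i in range(1, len(fixes) - 1, 2):
        if flags[i - 1] or flags[i]:
            continue
        a, m, b = fixes[i - 1], fixes[i], fixes[i + 1]
        T = (b.timestamp - a.timestamp).total_seconds() / 3600.0
        t = (m.timestamp - a.timestamp).total_seconds() / 3600.0
        if T <= 0 or not (0 < t < T):
            continue
        al = t / T
        mx = a.x + al * (b.x - a.x)
        my = a.y + al * (b.y - a.y)
        d2.append((m.x - mx) ** 2 + (m.y - my) ** 2)
        w.append(T * al * (1.0 - al))
        s2fix.append(((1.0 - al) ** 2 + al**2) * sig2**2)
    return np.array(d2), np.array(w), np.array(s2fix)


def estimate_sig1(
    trajectory: Trajectory,
    sig2: float = 5.0,
    search_interval: tuple[float, float] = (0.1, 1000.0),
) -> Sig1Estimate:
    """Maximum-likelihood sig1 from alternate-fix bridge transition densities.

    Deterministic: a dense coarse scan over the interval followed by bounded
    scalar refinement (resolution well below 0.01 map units). A maximum at an
    interval boundary is flagged, not raised.
    """
    lo, hi = search_interval
    if not (0 < lo < hi):
        raise ValueError("search interval must satisfy 0 < lo < hi")
    d2, w, s2fix = _triple_arrays(trajectory, sig2)
    if len(d2) < 3:
        raise ValueError(
            "need at least 3 gap-free consecutive triples to estimate sig1"
        )

    def nll(sig1: float) -> float:
        s2 = w * sig1**2 + s2fix
        s2 = np.maximum(s2, 1e-12)
        # bivariate circular normal log density, constants dropped
        return float(np.sum(np.log(s2) + d2 / (2.0 * s2)))

    grid = np.geomspace(lo, hi, 400)
    vals = np.array([nll(g) for g in grid])
    j = int(np.argmin(vals))
    b_lo = grid[max(j - 1, 0)]
    b_hi = grid[min(j + 1, len(grid) - 1)]
    if b_lo == b_hi:
        best = b_lo
    else:
        res = minimize_scalar(
            nll, bounds=(b_lo, b_hi), method="bounded", options={"xatol": 1e-4}
        )
        best = float(res.x)
    tol = max(1e-3, (hi - lo) * 1e-4)
    at_boundary = best <= lo + tol or best >= hi - tol
    return Sig1Estimate(
        value=best,
        log_likelihood=-nll(best),
        n_triples=len(d2),
        at_boundary=at_boundary,
    )


def isopleth_polygon(
    ud: UDGrid, level: float = 0.75, simplify: bool = False
) -> IsoplethPolygon:
    """Smallest cell set, by descending mass, whose cumulative mass reaches
    ``level``; returned as polygon(s) traced along outer cell boundaries.

    With ``simplify`` a single pass of topology-preserving simplification at
    one cell width is applied (off by default: exact boundaries reproduce).
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    flat = ud.values.ravel()
    total = flat.sum()
    if total <= 0 or np.count_nonzero(flat) == 0:
        raise DegenerateUDError("UD carries no mass")
    order = np.argsort(flat)[::-1]
    csum = np.cumsum(flat[order])
    k = int(np.searchsorted(csum, level * min(total, 1.0)) + 1)
    k = min(k, len(flat))
    sel = order[:k]
    attained = float(csum[k - 1])

    ny, nx = ud.values.shape
    rows, cols = np.unravel_index(sel, (ny, nx))
    dx, dy = ud.cell_size
    x0, y0 = ud.origin
    xmin = x0 + cols * dx
    ymin = y0 + rows * dy
    boxes = shapely.box(xmin, ymin, xmin + dx, ymin + dy)
    geom = unary_union(boxes)
    if simplify:
        geom = geom.simplify(min(dx, dy), preserve_topology=True)
    if geom.is_empty:
        raise DegenerateUDError("isopleth geometry is empty")
    return IsoplethPolygon(level=level, geometry=geom, attained_mass=attained)


@dataclass
class BackwardEllipses:
    """Per-step 75% regions behind a departure fix, plus skip audit."""

    polygons: list[IsoplethPolygon]
    step_end_lags_h: list[float]
    skipped_gaps: int = 0


def backward_ellipses(
    trajectory: Trajectory,
    departure_index: int,
    window: tuple[float, float],
    params: BridgeParams,
    level: float = 0.75,
    cell: float = 10.0,
    time_steps: int = 100,
    max_lookback_h: float = 24.0,
) -> BackwardEllipses:
    """Isopleths of every consecutive-fix bridge whose step ends within
    ``window`` = (h_from, h_to) hours before the departure fix.

    A step qualifies when its end lag lies in [h_from, h_to] and its start is
    within ``max_lookback_h`` of departure (the collar's 12 prior 2-h fixes).
    Steps across flagged gaps are skipped and counted, never bridged.
    """
    h_from, h_to = window
    if not (0 <= h_from < h_to <= max_lookback_h):
        raise ValueError("window must satisfy 0 <= h_from < h_to <= lookback")
    fixes = trajectory.fixes
    dep_t = fixes[departure_index].timestamp
    polys: list[IsoplethPolygon] = []
    lags: list[float] = []
    skipped = 0
    for i in range(departure_index):
        a, b = fixes[i], fixes[i + 1]
        end_lag = (dep_t - b.timestamp).total_seconds() / 3600.0
        start_lag = (dep_t - a.timestamp).total_seconds() / 3600.0
        if not (h_from <= end_lag <= h_to and start_lag <= max_lookback_h):
            continue
        if trajectory.gap_flags[i]:
            skipped += 1
            continue
        ud = bridge_density(a, b, params, cell=cell, time_steps=time_steps)
        polys.append(isopleth_polygon(ud, level=level))
        lags.append(end_lag)
    if not polys:
        warnings.warn(
            f"no eligible bridge steps in window {window} before fix "
            f"{departure_index}",
            stacklevel=2,
        )
    return BackwardEllipses(polygons=polys, step_end_lags_h=lags, skipped_gaps=skipped)
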