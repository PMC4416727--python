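"""Correlated disaster fields on a ring-space x year lattice.

Disaster events are placed on a lattice of ``x_extent`` ring locations by
``t_extent`` years.  Events come in clusters: cluster centers are uniform on
the lattice, and each cluster contributes a batch of distinct cells drawn
from a discretized bivariate Gaussian centered on its mode.  The standard
deviations ``sigma_x`` (locations) and ``sigma_t`` (years) control the
correlation length of the resulting point pattern: large sigmas approach a
uniform sprinkling of events, small sigmas concentrate events into tight
spatial columns, temporal bands, or compact blobs.

Coordinate conventions used everywhere in this package: locations are
0-based (``0 .. x_extent-1``) and live on a ring, years are 1-based
(``1 .. t_extent``) and do not wrap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SCENARIO_LABELS",
    "SigmaPair",
    "Scenario",
    "DisasterField",
    "scenario_sigmas",
    "sample_cluster_centers",
    "sample_cluster_events",
    "generate_disaster_field",
    "realized_event_count",
]

SCENARIO_LABELS = ("none", "spatial", "temporal", "spatiotemporal")

#: default Gaussian widths at the weakest correlation level (p = 1)
BASE_SIGMA_X = 64.0
BASE_SIGMA_T = 32.0


@dataclass(frozen=True)
class SigmaPair:
    """Standard deviations of the event clusters.

    ``sigma_x`` is measured in ring-location units, ``sigma_t`` in years.
    """

    sigma_x: float
    sigma_t: float

    def __post_init__(self) -> None:
        for name in ("sigma_x", "sigma_t"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be strictly positive and finite, got {v}")


@dataclass(frozen=True)
class Scenario:
    """A correlation scenario: which axes correlate and how strongly.

    ``level`` is the correlation-strength index p >= 1; each increment halves
    the relevant sigma(s), so p = 1 is the weakest (near-uniform) setting.
    """

    label: str
    level: int = 1

    def __post_init__(self) -> None:
        if self.label not in SCENARIO_LABELS:
            raise ValueError(
                f"unknown scenario label {self.label!r}; expected one of {SCENARIO_LABELS}"
            )
        if self.level < 1:
            raise ValueError(f"correlation level must be >= 1, got {self.level}")


def scenario_sigmas(
    scenario: Scenario,
    base_sigma_x: float = BASE_SIGMA_X,
    base_sigma_t: float = BASE_SIGMA_T,
) -> SigmaPair:
    """Map a correlation scenario to Gaussian widths.

    The correlated axis is narrowed geometrically, ``sigma = 2**-(p-1) * base``;
    the uncorrelated axis stays at its weakest (p = 1) base value.  For the
    ``none`` scenario both axes stay at base regardless of ``level``.
    """
    if base_sigma_x <= 0 or base_sigma_t <= 0:
        raise ValueError("base sigmas must be strictly positive")
    p = scenario.level
    shrink = 2.0 ** -(p - 1)
    if scenario.label == "none":
        return SigmaPair(base_sigma_x, base_sigma_t)
    if scenario.label == "spatial":
        return SigmaPair(base_sigma_x * shrink, base_sigma_t)
    if scenario.label == "temporal":
        return SigmaPair(base_sigma_x, base_sigma_t * shrink)
    # spatiotemporal
    return SigmaPair(base_sigma_x * shrink, base_sigma_t * shrink)


@dataclass
class DisasterField:
    """Realized disaster events on the (location, year) lattice.

    ``occupancy`` has shape ``(x_extent, t_extent)``; ``occupancy[x, t-1] == 1``
    means the node at ring location ``x`` is struck in year ``t``.  ``events``
    lists the distinct occupied cells as ``(year, location)`` pairs; duplicates
    produced by overlapping clusters collapse onto a single cell.
    """

    occupancy: np.ndarray
    events: list[tuple[int, int]]
    centers: list[tuple[int, int]]
    n_total: int
    m_clusters: int
    sigmas: SigmaPair
    scenario: Scenario | None = None
    seed_info: str | None = None

    @property
    def x_extent(self) -> int:
        return self.occupancy.shape[0]

    @property
    def t_extent(self) -> int:
        return self.occupancy.shape[1]

    def validate(self) -> None:
        occ = set()
        for year, loc in self.events:
            if not (1 <= year <= self.t_extent and 0 <= loc < self.x_extent):
                raise ValueError(f"event ({year}, {loc}) off the lattice")
            occ.add((year, loc))
        if len(occ) != len(self.events):
            raise ValueError("duplicate cells in event list")
        mat = {(t + 1, x) for x, t in zip(*np.nonzero(self.occupancy))}
        if mat != occ:
            raise ValueError("occupancy matrix and event list disagree")

    def to_csv(self, out_dir: str | Path, prefix: str = "field") -> None:
        """Write occupancy matrix, events table and a JSON sidecar."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savetxt(out / f"{prefix}_occupancy.csv", self.occupancy, fmt="%d", delimiter=",")
        with open(out / f"{prefix}_events.csv", "w") as fh:
            fh.write("year,location\n")
            for year, loc in sorted(self.events):
                fh.write(f"{year},{loc}\n")
        meta = {
            "scenario": self.scenario.label if self.scenario else None,
            "level": self.scenario.level if self.scenario else None,
            "sigma_x": self.sigmas.sigma_x,
            "sigma_t": self.sigmas.sigma_t,
            "n_total": self.n_total,
            "m_clusters": self.m_clusters,
            "x_extent": self.x_extent,
            "t_extent": self.t_extent,
            "seed": self.seed_info,
        }
        with open(out / f"{prefix}_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)


def sample_cluster_centers(
    m: int, x_extent: int, t_extent: int, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Draw ``m`` cluster modes uniformly and independently over the lattice.

    Returns ``(year, location)`` pairs; modes may coincide.
    """
    if m < 1:
        raise ValueError("need at least one cluster")
    if x_extent < 1 or t_extent < 1:
        raise ValueError("lattice extents must be positive")
    years = rng.integers(1, t_extent + 1, size=m)
    locs = rng.integers(0, x_extent, size=m)
    return [(int(t), int(x)) for t, x in zip(years, locs)]


def _nearest_cells(
    center: tuple[int, int], x_extent: int, t_extent: int
) -> np.ndarray:
    """All lattice cells ordered by squared distance to the center.

    Spatial distance is measured around the ring; ties break on (year,
    location) order so the fill-in is deterministic.
    """
    cy, cx = center
    years = np.arange(1, t_extent + 1)
    locs = np.arange(x_extent)
    dy = (years[:, None] - cy) ** 2
    dx_lin = np.abs(locs[None, :] - cx)
    dx = np.minimum(dx_lin, x_extent - dx_lin) ** 2
    dist = dy + dx
    flat = [(dist[i, j], years[i], locs[j]) for i in range(t_extent) for j in range(x_extent)]
    flat.sort()
    return np.array([(t, x) for _, t, x in flat], dtype=int)


def sample_cluster_events(
    center: tuple[int, int],
    sigmas: SigmaPair,
    n_events: int,
    x_extent: int,
    t_extent: int,
    rng: np.random.Generator,
    max_draws: int = 10_000,
    exhaustion: str = "truncate",
) -> list[tuple[int, int]]:
    """Sample distinct lattice cells around one cluster mode.

    Continuous draws from an axis-aligned bivariate normal centered on
    ``center`` are rounded to the nearest cell; the location wraps around the
    ring, while draws with a year outside ``[1, t_extent]`` are rejected and
    redrawn so the in-window temporal profile stays Gaussian.  Sampling
    repeats until ``n_events`` distinct cells accumulate or ``max_draws``
    draws are spent.

    When the draw budget runs out (very narrow sigmas concentrate all mass on
    a handful of cells) the behaviour depends on ``exhaustion``:

    - ``"truncate"`` (default): return the distinct cells found so far.  In
      the sigma -> 0 limit each cluster then collapses onto its mode alone.
    - ``"spill"``: top up with the unused cells nearest to the mode, so the
      requested count is always met.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    if n_events > x_extent * t_extent:
        raise ValueError("n_events exceeds the lattice size")
    if exhaustion not in ("truncate", "spill"):
        raise ValueError(f"unknown exhaustion policy {exhaustion!r}")
    cy, cx = center
    chosen: dict[tuple[int, int], None] = {}
    draws = 0
    while len(chosen) < n_events and draws < max_draws:
        batch = min(max(4 * (n_events - len(chosen)), 16), max_draws - draws)
        ts = rng.normal(cy, sigmas.sigma_t, size=batch)
        xs = rng.normal(cx, sigmas.sigma_x, size=batch)
        draws += batch
        years = np.rint(ts).astype(int)
        locs = np.rint(xs).astype(int) % x_extent
        ok = (years >= 1) & (years <= t_extent)
        for year, loc in zip(years[ok], locs[ok]):
            chosen[(int(year), int(loc))] = None
            if len(chosen) == n_events:
                break
    if len(chosen) < n_events and exhaustion == "spill":
        for year, loc in _nearest_cells(center, x_extent, t_extent):
            cell = (int(year), int(loc))
            if cell not in chosen:
                chosen[cell] = None
            if len(chosen) == n_events:
                break
    return list(chosen)


def generate_disaster_field(
    scenario: Scenario | SigmaPair,
    n_total: int = 500,
    m_clusters: int = 40,
    x_extent: int = 100,
    t_extent: int = 50,
    rng: np.random.Generator | None = None,
    count_sd: float = 1.0,
    mixture: bool = False,
) -> DisasterField:
    """Generate one disaster field.

    ``m_clusters`` modes are placed uniformly on the lattice; each cluster's
    event count is drawn from Normal(``n_total / m_clusters``, ``count_sd**2``)
    rounded to the nearest non-negative integer, and that many distinct cells
    are sampled around the mode.  Cells struck by more than one cluster
    collapse to a single occupied cell, so the realized event count can fall
    slightly below ``n_total`` when clusters overlap.

    With ``mixture=True`` events are instead drawn one at a time from the
    global M-modal mixture (a uniformly chosen cluster per event) without
    replacement across the whole field.
    """
    if rng is None:
        rng = np.random.default_rng()
    if m_clusters < 1:
        raise ValueError("need at least one cluster")
    if n_total < m_clusters:
        raise ValueError("n_total must be >= m_clusters")
    if isinstance(scenario, SigmaPair):
        sigmas = scenario
        scen = None
    else:
        sigmas = scenario_sigmas(scenario)
        scen = scenario

    centers = sample_cluster_centers(m_clusters, x_extent, t_extent, rng)
    mean_count = n_total / m_clusters
    counts = np.rint(rng.normal(mean_count, count_sd, size=m_clusters)).astype(int)
    counts = np.clip(counts, 0, x_extent * t_extent)

    occupancy = np.zeros((x_extent, t_extent), dtype=np.uint8)
    events: dict[tuple[int, int], None] = {}
    if mixture:
        target = int(counts.sum())
        draws = 0
        while len(events) < target and draws < 100 * target:
            c = centers[rng.integers(m_clusters)]
            cell_list = sample_cluster_events(c, sigmas, 1, x_extent, t_extent, rng)
            draws += 1
            if not cell_list:
                continue
            cell = cell_list[0]
            if cell not in events:
                events[cell] = None
    else:
        for center, count in zip(centers, counts):
            if count <= 0:
                continue
            for cell in sample_cluster_events(
                center, sigmas, int(count), x_extent, t_extent, rng
            ):
                events[cell] = None
    for year, loc in events:
        occupancy[loc, year - 1] = 1
    return DisasterField(
        occupancy=occupancy,
        events=list(events),
        centers=centers,
        n_total=n_total,
        m_clusters=m_clusters,
        sigmas=sigmas,
        scenario=scen,
    )


def realized_event_count(field: DisasterField) -> int:
    """Number of occupied lattice cells (== length of the event list)."""
    return int(field.occupancy.sum())
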