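"""Need-based gift-giving (Osotua) herd dynamics.

Each node of the support network holds a cattle herd.  Year by year, herds
grow by a small random percentage, disasters destroy a random fraction of
the herds they strike, and nodes whose herd has fallen below the minimum
sustainable size of 64 cattle ask one randomly chosen living partner for
exactly the amount that would restore them to 64.  A partner gives what is
asked — but only if doing so leaves its own herd at or above 64; otherwise
it gives nothing.  A node is eliminated after two consecutive year-ends
below the threshold.

The within-year order of operations is growth, then disaster loss, then
requests and gifts, then the survival check — so a successful gift, which
restores the recipient exactly to the threshold, prevents that year from
counting against it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .disaster import DisasterField
from .network import SpatialNetwork

__all__ = [
    "SimParams",
    "AgentState",
    "GiftEvent",
    "SimResult",
    "annual_growth",
    "disaster_loss",
    "gift_amount",
    "process_requests",
    "update_survival",
    "run_simulation",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the herd dynamics.

    All herd quantities are in head of cattle; rates are yearly fractions.
    ``threshold`` is the minimum sustainable herd size, ``death_lag`` the
    number of consecutive below-threshold year-ends that eliminates a node.
    """

    t_years: int = 50
    initial_herd: float = 70.0
    threshold: float = 64.0
    growth_mean: float = 0.03
    growth_sd: float = 0.03
    loss_mean: float = 0.30
    loss_sd: float = 0.10
    death_lag: int = 2
    retries: int = 0  # additional partners asked after a refusal
    check_pre_gift: bool = False  # survival check on the pre-gift herd

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if self.initial_herd < self.threshold:
            raise ValueError("initial herd must be at least the threshold")
        if not 0.0 <= self.loss_mean <= 1.0:
            raise ValueError("loss_mean must lie in [0, 1]")
        if self.growth_sd < 0 or self.loss_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.t_years < 1 or self.death_lag < 1:
            raise ValueError("t_years and death_lag must be >= 1")


@dataclass
class AgentState:
    """Mutable per-node state: herd size, alive flag, below-threshold streak."""

    herd: np.ndarray
    alive: np.ndarray
    below_count: np.ndarray

    @classmethod
    def initial(cls, n: int, params: SimParams) -> "AgentState":
        return cls(
            herd=np.full(n, float(params.initial_herd)),
            alive=np.ones(n, dtype=bool),
            below_count=np.zeros(n, dtype=int),
        )

    @property
    def n(self) -> int:
        return self.herd.shape[0]


class GiftEvent(NamedTuple):
    year: int
    giver: int
    receiver: int
    amount: float


@dataclass
class SimResult:
    """Observables of one 50-year run."""

    survival_rate: float
    surviving_herds: np.ndarray
    effective_disasters: int
    gifts: list[GiftEvent]
    gifts_per_year: np.ndarray
    alive: np.ndarray

    def gifts_to_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("year,giver,receiver,amount\n")
            for g in self.gifts:
                fh.write(f"{g.year},{g.giver},{g.receiver},{g.amount:.6f}\n")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "survival_rate": self.survival_rate,
            "surviving_herds": [float(h) for h in self.surviving_herds],
            "effective_disasters": self.effective_disasters,
            "gifts_per_year": [int(c) for c in self.gifts_per_year],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def annual_growth(
    herd: np.ndarray | float, params: SimParams, rng: np.random.Generator
) -> np.ndarray | float:
    """Multiply herd(s) by 1 + g, g ~ Normal(growth_mean, growth_sd²), g >= -1."""
    g = rng.normal(params.growth_mean, params.growth_sd, size=np.shape(herd) or None)
    g = np.maximum(g, -1.0)
    return herd * (1.0 + g)


def disaster_loss(
    herd: np.ndarray | float, params: SimParams, rng: np.random.Generator
) -> np.ndarray | float:
    """Multiply herd(s) by 1 - l, l ~ Normal(loss_mean, loss_sd²) clipped to [0, 1]."""
    l = rng.normal(params.loss_mean, params.loss_sd, size=np.shape(herd) or None)
    l = np.clip(l, 0.0, 1.0)
    return herd * (1.0 - l)


def gift_amount(giver_herd: float, request: float, threshold: float) -> float:
    """All-or-nothing giving rule.

    The full request is granted iff it leaves the giver at or above the
    threshold; partial gifts never happen.
    """
    if request <= 0:
        raise ValueError("request must be positive")
    return request if giver_herd - request >= threshold else 0.0


def process_requests(
    state: AgentState,
    net: SpatialNetwork | Sequence[np.ndarray],
    params: SimParams,
    rng: np.random.Generator,
    year: int = 0,
) -> list[GiftEvent]:
    """One year's round of requests, mutating ``state.herd`` in place.

    Every living node below the threshold asks one uniformly chosen living
    partner for exactly (threshold - herd); refusals are final unless
    ``params.retries`` allows asking further (distinct) partners.  Needy
    nodes are processed in a fresh uniformly random order each year, since a
    giver near the threshold can serve only some of several askers.  The
    step conserves total cattle.
    """
    neighbors = net.neighbor_lists() if isinstance(net, SpatialNetwork) else net
    herd, alive = state.herd, state.alive
    thr = params.threshold
    gifts: list[GiftEvent] = []
    needy = np.flatnonzero(alive & (herd < thr))
    if needy.size == 0:
        return gifts
    for i in rng.permutation(needy):
        nbrs = neighbors[i]
        if nbrs.size == 0:
            continue
        live = nbrs[alive[nbrs]]
        if live.size == 0:
            continue
        request = thr - herd[i]
        n_ask = min(1 + params.retries, live.size)
        partners = (
            live[[rng.integers(live.size)]]
            if n_ask == 1
            else rng.choice(live, size=n_ask, replace=False)
        )
        for j in partners:
            amount = gift_amount(herd[j], request, thr)
            if amount > 0:
                herd[j] -= amount
                herd[i] = thr
                gifts.append(GiftEvent(int(year), int(j), int(i), float(amount)))
                break
    return gifts


def update_survival(state: AgentState, params: SimParams) -> None:
    """Year-end survival check, mutating ``state`` in place.

    A living node's streak grows by one if its herd is below the threshold,
    else resets to zero; reaching ``death_lag`` eliminates the node.
    """
    alive = state.alive
    below = alive & (state.herd < params.threshold)
    state.below_count[below] += 1
    state.below_count[alive & ~below] = 0
    died = alive & (state.below_count >= params.death_lag)
    state.alive[died] = False


def run_simulation(
    field: DisasterField,
    net: SpatialNetwork | None,
    params: SimParams | None = None,
    rng: np.random.Generator | None = None,
    record_gifts: bool = True,
) -> SimResult:
    """Run the full multi-year simulation on one field and one network.

    ``net=None`` simulates unconnected nodes (one per ring location): the
    no-insurance benchmark.  Each year applies growth to living nodes, then
    the disaster losses scheduled for that year, then the request/gift round
    (skipped without a network), then the survival check.  An *effective*
    disaster is a scheduled event that strikes a node still alive that year.
    """
    if params is None:
        params = SimParams()
    if rng is None:
        rng = np.random.default_rng()
    n = net.n if net is not None else field.x_extent
    if net is not None and net.n != field.x_extent:
        raise ValueError(
            f"network has {net.n} nodes but the field has {field.x_extent} locations"
        )
    t_years = min(params.t_years, field.t_extent)
    if params.t_years > field.t_extent:
        raise ValueError("disaster field is shorter than the simulation horizon")

    spatial = net.spatial_index if net is not None else np.arange(n)
    hits = field.occupancy[spatial, :t_years].astype(bool)  # (n, T)
    neighbors = net.neighbor_lists() if net is not None else None

    state = AgentState.initial(n, params)
    herd, alive = state.herd, state.alive
    # pre-drawn per-(node, year) growth and loss percentages; a node's draw is
    # simply ignored in years it is dead or unhit
    growth = np.maximum(
        rng.normal(params.growth_mean, params.growth_sd, size=(t_years, n)), -1.0
    )
    losses = np.clip(
        rng.normal(params.loss_mean, params.loss_sd, size=(t_years, n)), 0.0, 1.0
    )

    effective = 0
    gifts: list[GiftEvent] = []
    gifts_per_year = np.zeros(t_years, dtype=int)
    for t in range(t_years):
        herd[alive] *= 1.0 + growth[t, alive]
        struck = alive & hits[:, t]
        effective += int(struck.sum())
        herd[struck] *= 1.0 - losses[t, struck]
        if params.check_pre_gift:
            pre_gift_below = alive & (herd < params.threshold)
        if net is not None:
            year_gifts = process_requests(state, neighbors, params, rng, year=t + 1)
            gifts_per_year[t] = len(year_gifts)
            if record_gifts:
                gifts.extend(year_gifts)
        if params.check_pre_gift:
            state.below_count[alive & pre_gift_below] += 1
            state.below_count[alive & ~pre_gift_below] = 0
            died = alive & (state.below_count >= params.death_lag)
            state.alive[died] = False
        else:
            update_survival(state, params)

    surviving = herd[alive]
    return SimResult(
        survival_rate=float(alive.sum()) / n,
        surviving_herds=surviving.copy(),
        effective_disasters=effective,
        gifts=gifts,
        gifts_per_year=gifts_per_year,
        alive=alive.copy(),
    )
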