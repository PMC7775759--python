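"""Monte-Carlo simulator of the transmission dynamics on a square lattice.

Languages occupy the cells of an L x L lattice with periodic boundaries;
each carries one binary feature value.  A single event picks a random cell
and then, with probability 1-q, performs a vertical event (spontaneous
gain with probability p_I if absent, spontaneous loss with probability p_E
if present) or, with probability q, a horizontal event: the cell copies
the value of a uniformly chosen von Neumann neighbor, miscopying absence
as presence with probability p_I' and presence as absence with probability
p_E'.  This is an asymmetric noisy two-state voter model; its stationary
(rho, sigma) statistics are given in closed form in :mod:`.theory`.

One *sweep* is defined as L^2 events.  The event loop is compiled with
numba; reproducibility is guaranteed by drawing each kernel seed from the
state's own seeded numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import FeatureParams
from . import theory

__all__ = [
    "LatticeState", "SummaryStats", "init_lattice", "step_event",
    "run_sweeps", "lattice_frequency", "lattice_isogloss_density",
    "estimate_stationary_summary",
]

_SEED_MAX = 2 ** 31 - 1


@dataclass
class LatticeState:
    """Binary field on an L x L periodic lattice plus its RNG."""

    values: np.ndarray          # int8, shape (L, L), entries in {0, 1}
    rng: np.random.Generator
    events_elapsed: int = 0

    @property
    def side_length(self) -> int:
        return self.values.shape[0]


@dataclass
class SummaryStats:
    """The (rho, sigma) summary-statistic pair with standard errors."""

    rho: float
    sigma: float
    n_basis: int
    rho_se: float = float("nan")
    sigma_se: float = float("nan")


def init_lattice(L: int, seed: int | np.random.Generator) -> LatticeState:
    """Random initial lattice: each cell present independently w.p. 1/2."""
    if L < 2:
        raise ValueError(f"lattice side length must be >= 2, got {L!r}")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    values = (rng.random((L, L)) < 0.5).astype(np.int8)
    return LatticeState(values=values, rng=rng)


@njit(cache=True)
def _run_events(values, L, n_events,
                p_iv, p_ev, p_ih, p_eh, q, seed):  # pragma: no cover
    np.random.seed(seed)
    for _ in range(n_events):
        i = np.random.randint(0, L)
        j = np.random.randint(0, L)
        if np.random.random() < q:
            # horizontal: copy a von Neumann neighbor, with errors
            d = np.random.randint(0, 4)
            if d == 0:
                ni, nj = (i + 1) % L, j
            elif d == 1:
                ni, nj = (i - 1) % L, j
            elif d == 2:
                ni, nj = i, (j + 1) % L
            else:
                ni, nj = i, (j - 1) % L
            if values[ni, nj] == 0:
                values[i, j] = 1 if np.random.random() < p_ih else 0
            else:
                values[i, j] = 0 if np.random.random() < p_eh else 1
        else:
            # vertical: spontaneous gain / loss
            if values[i, j] == 0:
                if np.random.random() < p_iv:
                    values[i, j] = 1
            else:
                if np.random.random() < p_ev:
                    values[i, j] = 0


def _advance(state: LatticeState, params: FeatureParams, n_events: int) -> None:
    if n_events <= 0:
        return
    kernel_seed = int(state.rng.integers(0, _SEED_MAX))
    _run_events(state.values, state.side_length, n_events,
                params.p_ingress_vertical, params.p_egress_vertical,
                params.p_ingress_horizontal, params.p_egress_horizontal,
                params.q_horizontal_rate, kernel_seed)
    state.events_elapsed += n_events


def step_event(state: LatticeState, params: FeatureParams) -> LatticeState:
    """Apply a single update event in place; at most one cell changes."""
    _advance(state, params, 1)
    return state


def run_sweeps(state: LatticeState, params: FeatureParams,
               n_sweeps: int) -> LatticeState:
    """Apply n_sweeps * L^2 events in place."""
    if n_sweeps < 0:
        raise ValueError("n_sweeps must be >= 0")
    _advance(state, params, n_sweeps * state.side_length ** 2)
    return state


def lattice_frequency(state: LatticeState) -> float:
    """Feature frequency rho: fraction of cells where the feature is present."""
    return float(np.mean(state.values))


def lattice_isogloss_density(state: LatticeState) -> float:
    """Isogloss density sigma: fraction of disagreeing lattice bonds.

    Bonds are the 2 L^2 von Neumann nearest-neighbor pairs of the periodic
    lattice; invariant under global complementation of the field.
    """
    v = state.values
    horiz = v != np.roll(v, -1, axis=1)
    vert = v != np.roll(v, -1, axis=0)
    return float((horiz.sum() + vert.sum()) / (2 * v.size))


def estimate_stationary_summary(
    params: FeatureParams,
    L: int = 100,
    burn_in: int = 5000,
    n_samples: int = 20,
    spacing: int = 10,
    n_replicas: int = 5,
    seed: int = 0,
) -> SummaryStats:
    """Stationary (rho, sigma) by time-averaged simulation.

    Each of ``n_replicas`` independent lattices (seeded seed + r) is burnt
    in for ``burn_in`` sweeps, then sampled ``n_samples`` times at
    ``spacing``-sweep intervals.  Standard errors are computed between
    replica means (ddof=1), which absorbs within-replica autocorrelation.
    """
    if burn_in < 1 or n_samples < 1 or n_replicas < 1:
        raise ValueError("burn_in, n_samples and n_replicas must be >= 1")
    tau = theory.temperature_from_params(params)
    if tau < 0.01:
        import warnings
        warnings.warn(
            f"tau={tau:.2g} is below the validated mixing range (>= 0.01); "
            "coarsening is slow and the default burn-in may be insufficient",
            stacklevel=2)
    rho_means = np.empty(n_replicas)
    sigma_means = np.empty(n_replicas)
    for r in range(n_replicas):
        state = init_lattice(L, seed + r)
        run_sweeps(state, params, burn_in)
        rhos = np.empty(n_samples)
        sigmas = np.empty(n_samples)
        for s in range(n_samples):
            if s > 0:
                run_sweeps(state, params, spacing)
            rhos[s] = lattice_frequency(state)
            sigmas[s] = lattice_isogloss_density(state)
        rho_means[r] = rhos.mean()
        sigma_means[r] = sigmas.mean()
    rho_se = float(rho_means.std(ddof=1) / np.sqrt(n_replicas)) \
        if n_replicas > 1 else float("nan")
    sigma_se = float(sigma_means.std(ddof=1) / np.sqrt(n_replicas)) \
        if n_replicas > 1 else float("nan")
    return SummaryStats(rho=float(rho_means.mean()),
                        sigma=float(sigma_means.mean()),
                        n_basis=L * L, rho_se=rho_se, sigma_se=sigma_se)
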