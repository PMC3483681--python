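"""Stochastic mucus creation, growth, propagation, scarring and treatment
dynamics on the binary airway tree.

Each airway can acquire a chronic mucus/biofilm colonization; once colonized
its mucus volume grows linearly at rate ``v_c`` until the airway is full.  A
full airway seeds infection in its parent and children (overflow) and makes
everything distal to it reversibly nonfunctional.  Mucus that persists longer
than ``T_s`` months starts scarring the wall at rate ``v_s``; when scarring
reaches the threshold ``S_star`` the airway is irreversibly remodeled.
Treatment fires when the functional volume drops to a fraction ``alpha`` of
its last post-treatment baseline; it clears mucus from and removes every
undamaged colonization, but airways whose scarring has begun are reinfected
instantaneously -- treatment cannot clear them, so damaged coverage is lost
for good and the post-treatment baseline ratchets downward over life.

State is piecewise linear between switching events, so all updates are exact
closed-form ramps on a fixed monthly grid -- no ODE solver is involved.

The per-airway logical variables are, for infected site ``i`` with airway
volume ``V_i``::

    F_i = H(M_i - V_i)            filled (reversibly nonfunctional)
    O_i = H(#blocked ancestors)   shut by a plugged/remodeled ancestor
    R_i = H(S_i - S_star)         remodeled (irreversible)

with ``H`` the Heaviside step, taken as 1 at 0 so that "reaching" a
threshold counts as crossing it.

The fraction of accessible alveoli (leaves with no filled/remodeled airway
on their root path) serves as the forced-vital-capacity proxy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .geometry import AirwayTree, GeometryError, merge_intervals

__all__ = [
    "SimParams",
    "InfectionSite",
    "DiseaseState",
    "FvcTrajectory",
    "heaviside",
    "sample_colonizations",
    "colonize",
    "step_mucus",
    "step_scarring",
    "propagate_overflow",
    "functional_volume",
    "check_treatment",
    "apply_treatment",
    "apply_remodeling",
    "step",
    "simulate",
]


def heaviside(x: float) -> int:
    """Unit step: 0 for negative arguments, 1 for zero or positive ones."""
    return 0 if x < 0 else 1


@dataclass(frozen=True)
class SimParams:
    """Model constants and simulation controls.

    Attributes
    ----------
    P_c
        Colonization probability density per unit airway surface per unit
        time (mm^-2 month^-1).
    v_c
        Mucus volume growth rate in a colonized airway (mm^3/month).
    T_s
        Delay from colonization to scarring onset (months).
    v_s
        Scarring accrual rate (scar-units/month); the remodeling threshold
        ``S_star`` defines the scar unit.
    S_star
        Scarring threshold at which an airway is irreversibly remodeled.
    alpha
        Exacerbation threshold: treatment fires when the functional volume
        falls to ``alpha`` times the last post-treatment baseline.
    dt
        Time step (months).
    horizon
        Number of steps per run (600 monthly steps = ages 0-50).
    seed
        Base RNG seed; replicate ``r`` uses ``seed + r``.
    bronchiole_gen_min
        First generation whose airways count as bronchioles and are exposed
        to direct environmental colonization.  Proximal cartilaginous airways
        (generations below this) are only ever infected by overflow from a
        filled neighbour.  The default, 10, is where airway diameters drop
        to ~1 mm in the Weibel tree; the distal generations hold >99.5% of
        the total surface, so the expected colonization rate is essentially
        ``P_c`` times the total airway surface either way.
    """

    P_c: float = 6.0e-6
    v_c: float = 11.0
    T_s: float = 7.0
    v_s: float = 0.023
    S_star: float = 1.0
    alpha: float = 0.94
    dt: float = 1.0
    horizon: int = 600
    seed: int = 0
    bronchiole_gen_min: int = 10

    def __post_init__(self):
        for name in ("P_c", "v_c", "T_s", "v_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.S_star <= 0:
            raise ValueError("S_star must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.horizon < 1:
            raise ValueError("horizon must be at least 1")

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)


@dataclass
class InfectionSite:
    """Dynamic state of one colonized airway (inspection/toy-scale view)."""

    airway_index: int
    t_i: float
    M_i: float = 0.0
    S_i: float = 0.0


class DiseaseState:
    """Sparse dynamic disease state over an :class:`AirwayTree`.

    Only colonized airways carry state, held in parallel arrays; a dense
    boolean mask provides O(1) infection membership over the whole tree.
    Blocked (filled or remodeled) subtrees are tracked as a merged union of
    leaf-index intervals so the accessible-alveoli count is exact and cheap.
    """

    def __init__(self, tree: AirwayTree, params: SimParams,
                 rng: np.random.Generator | None = None):
        self.tree = tree
        self.params = params
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)
        self.time = 0.0
        n_slots = 1 << tree.n_generations
        self.infected_mask = np.zeros(n_slots, dtype=bool)
        self.infected_per_gen = np.zeros(tree.n_generations, dtype=np.int64)
        self.idx = np.empty(0, dtype=np.int64)
        self.gen = np.empty(0, dtype=np.int64)
        self.t_i = np.empty(0, dtype=np.float64)
        self.M = np.empty(0, dtype=np.float64)
        self.S = np.empty(0, dtype=np.float64)
        self.filled = np.empty(0, dtype=bool)
        self.remodeled = np.empty(0, dtype=bool)
        # merged, disjoint, sorted half-open leaf intervals under F ∪ R
        self._blk_lo = np.empty(0, dtype=np.int64)
        self._blk_hi = np.empty(0, dtype=np.int64)
        self.V_L_star = 1.0
        self._newly_filled = np.empty(0, dtype=np.int64)
        self.events: list[tuple[float, str, int]] = []

    # -- bookkeeping --------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.idx.size

    def seed_site(self, airway_index: int, t_i: float | None = None) -> None:
        """Plant a colonization by hand (used for worked examples/tests)."""
        self.tree.validate_index(airway_index)
        self._add_sites(np.array([airway_index], dtype=np.int64),
                        self.time if t_i is None else t_i)

    def _add_sites(self, new_idx: np.ndarray, t_i: float) -> None:
        if new_idx.size == 0:
            return
        if np.any(self.infected_mask[new_idx]):
            raise ValueError("airway already colonized")
        self.infected_mask[new_idx] = True
        gens = self.tree.generation_of(new_idx)
        np.add.at(self.infected_per_gen, gens, 1)
        n = new_idx.size
        self.idx = np.concatenate([self.idx, new_idx])
        self.gen = np.concatenate([self.gen, gens])
        self.t_i = np.concatenate([self.t_i, np.full(n, t_i)])
        self.M = np.concatenate([self.M, np.zeros(n)])
        self.S = np.concatenate([self.S, np.zeros(n)])
        self.filled = np.concatenate([self.filled, np.zeros(n, dtype=bool)])
        self.remodeled = np.concatenate([self.remodeled, np.zeros(n, dtype=bool)])

    def _add_blocked(self, nodes: np.ndarray) -> None:
        if nodes.size == 0:
            return
        lo, hi = self.tree.leaf_spans(nodes)
        self._blk_lo, self._blk_hi = merge_intervals(
            np.concatenate([self._blk_lo, lo]),
            np.concatenate([self._blk_hi, hi]),
        )

    def _rebuild_blocked(self) -> None:
        nodes = self.idx[self.filled | self.remodeled]
        if nodes.size == 0:
            self._blk_lo = np.empty(0, dtype=np.int64)
            self._blk_hi = np.empty(0, dtype=np.int64)
        else:
            lo, hi = self.tree.leaf_spans(nodes)
            self._blk_lo, self._blk_hi = merge_intervals(lo, hi)

    def blocked_alveoli(self) -> int:
        return int(np.sum(self._blk_hi - self._blk_lo))

    # -- inspection helpers (toy-tree scale) --------------------------------

    def sites(self) -> dict[int, InfectionSite]:
        return {
            int(k): InfectionSite(int(k), float(t), float(m), float(s))
            for k, t, m, s in zip(self.idx, self.t_i, self.M, self.S)
        }

    @property
    def F(self) -> set[int]:
        return set(int(k) for k in self.idx[self.filled])

    @property
    def R(self) -> set[int]:
        return set(int(k) for k in self.idx[self.remodeled])

    def O(self) -> set[int]:
        """Airways shut by a filled/remodeled ancestor (exhaustive walk)."""
        blocked = self.F | self.R
        out = set()
        for k in range(1, self.tree.total_airways + 1):
            if any(a in blocked for a in self.tree.ancestors(k)) :
                out.add(k)
        return out


@dataclass
class FvcTrajectory:
    """Percent functional volume per month, per replicate.

    ``values`` has shape (n_replicates, n_months); the dispersion is the
    root-mean-square deviation from the pointwise mean with divisor equal to
    the number of replicates.
    """

    months: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.months.size:
            raise ValueError("values and months lengths differ")

    @property
    def n_replicates(self) -> int:
        return self.values.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.values.mean(axis=0)

    @property
    def se(self) -> np.ndarray:
        dev = self.values - self.mean
        return np.sqrt(np.mean(dev * dev, axis=0))

    def at_ages(self, ages: Sequence[int]) -> np.ndarray:
        """Replicate-mean percent at integer ages (years); requires dt = 1."""
        months = np.asarray(ages, dtype=int) * 12
        if months.max() >= self.months.size:
            raise ValueError("trajectory shorter than requested ages")
        return self.mean[months]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "month": self.months,
                "mean_fvc_pct": self.mean,
                "se_fvc_pct": self.se,
                "n_replicates": self.n_replicates,
            }
        )


# -- single-site operations (the semantics the vectorized core mirrors) -----

def step_mucus(site: InfectionSite, filled: bool, params: SimParams,
               dt: float, V_i: float, t_now: float | None = None) -> InfectionSite:
    """Advance one site's mucus ramp over ``(t_now - dt, t_now]``.

    Growth runs at ``v_c`` while the airway is colonized and not yet full,
    capped at the airway volume ``V_i``.
    """
    if t_now is None:
        t_now = site.t_i + dt
    if filled:
        return site
    window = max(0.0, t_now - max(t_now - dt, site.t_i))
    M = min(V_i, site.M_i + params.v_c * window)
    return InfectionSite(site.airway_index, site.t_i, M, site.S_i)


def step_scarring(site: InfectionSite, remodeled: bool, params: SimParams,
                  dt: float, t_now: float) -> InfectionSite:
    """Advance one site's scarring ramp to time ``t_now``.

    Scarring accrues at ``v_s`` once mucus has been present for ``T_s``
    months and freezes when the airway is remodeled.
    """
    if remodeled:
        return site
    S = params.v_s * max(0.0, t_now - site.t_i - params.T_s)
    return InfectionSite(site.airway_index, site.t_i, site.M_i, S)


def check_treatment(V_L: float, V_L_star: float, alpha: float) -> bool:
    """Exacerbation rule: treat when ``V_L <= alpha * V_L_star``."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return V_L <= alpha * V_L_star


# -- colonization ------------------------------------------------------------

def sample_colonizations(rng: np.random.Generator, tree: AirwayTree,
                         infected_mask: np.ndarray,
                         infected_per_gen: np.ndarray,
                         P_c: float, dt: float,
                         gen_min: int = 0) -> np.ndarray:
    """Draw the airways newly colonized during one step.

    Every uninfected airway ``i`` of generation ``gen_min`` or deeper
    independently acquires a colonization with probability
    ``P(Pois(λ_i) ≥ 1) = 1 - exp(-λ_i)``, ``λ_i = P_c·A_i·dt``.  Sampling is
    aggregated per generation -- a Binomial total placed uniformly among
    that generation's uninfected airways -- which is distributionally
    identical to the per-airway draw.
    """
    chosen: list[np.ndarray] = []
    for g in range(gen_min, tree.n_generations):
        n_total = 1 << g
        n_uninf = int(n_total - infected_per_gen[g])
        if n_uninf == 0:
            continue
        lam = P_c * tree.airway_surface_mm2[g] * dt
        p = -np.expm1(-lam)
        k = int(rng.binomial(n_uninf, p))
        if k == 0:
            continue
        lo, hi = 1 << g, 1 << (g + 1)
        if n_uninf < n_total // 8 or n_total <= 4096:
            # generation small or mostly infected: enumerate the open airways
            free = np.flatnonzero(~infected_mask[lo:hi]) + lo
            picked = rng.choice(free, size=k, replace=False)
        else:
            # rejection sampling; draws are iid uniform, so keeping the
            # first k distinct uninfected candidates (in draw order) is a
            # uniformly random k-subset
            picked = np.empty(0, dtype=np.int64)
            while picked.size < k:
                need = k - picked.size
                cand = rng.integers(lo, hi, size=2 * need + 8)
                _, first = np.unique(cand, return_index=True)
                cand = cand[np.sort(first)]  # dedupe, draw order preserved
                cand = cand[~infected_mask[cand]]
                if picked.size:
                    cand = cand[~np.isin(cand, picked)]
                picked = np.concatenate([picked, cand[: k - picked.size]])
        chosen.append(picked)
    if not chosen:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(chosen)


def colonize(state: DiseaseState, params: SimParams, tree: AirwayTree) -> DiseaseState:
    """Seed new colonizations for the current step (t_i = current time)."""
    new = sample_colonizations(state.rng, tree, state.infected_mask,
                               state.infected_per_gen, params.P_c, params.dt,
                               gen_min=params.bronchiole_gen_min)
    state._add_sites(new, state.time)
    return state


# -- vectorized per-step phases ----------------------------------------------

def _update_mucus(state: DiseaseState, params: SimParams, tree: AirwayTree) -> None:
    grow = ~state.filled
    if not np.any(grow):
        state._newly_filled = np.empty(0, dtype=np.int64)
        return
    V = tree.airway_volume_mm3[state.gen[grow]]
    M = np.minimum(V, state.M[grow] + params.v_c * params.dt)
    state.M[grow] = M
    just_filled = np.flatnonzero(grow)[M >= V]
    state.filled[just_filled] = True
    state._newly_filled = np.sort(state.idx[just_filled])
    state._add_blocked(state._newly_filled)


def propagate_overflow(state: DiseaseState, tree: AirwayTree) -> DiseaseState:
    """Newly filled airways colonize their parent and children (once per step)."""
    nf = state._newly_filled  # sorted
    state._newly_filled = np.empty(0, dtype=np.int64)
    if nf.size == 0:
        return state
    # children first: interleaving 2k, 2k+1 of a sorted k keeps sort order
    kids = np.empty(2 * nf.size, dtype=np.int64)
    kids[0::2] = nf << 1
    kids[1::2] = (nf << 1) + 1
    kids = kids[kids <= tree.total_airways]
    kids = kids[~state.infected_mask[kids]]
    state._add_sites(kids, state.time)
    # parents: duplicates (both children filled) are adjacent after >> 1;
    # the mask now includes the new child sites, so no cross-duplication
    parents = nf >> 1
    if parents.size > 1:
        keep = np.empty(parents.size, dtype=bool)
        keep[0] = True
        np.not_equal(parents[1:], parents[:-1], out=keep[1:])
        parents = parents[keep]
    parents = parents[parents >= 1]
    parents = parents[~state.infected_mask[parents]]
    state._add_sites(parents, state.time)
    return state


def _update_scarring(state: DiseaseState, params: SimParams, t_now: float) -> None:
    live = ~state.remodeled
    state.S[live] = params.v_s * np.maximum(0.0, t_now - state.t_i[live] - params.T_s)


def apply_remodeling(state: DiseaseState, params: SimParams, tree: AirwayTree) -> DiseaseState:
    """Airways whose scarring reached ``S_star`` become permanently nonfunctional."""
    new = ~state.remodeled & (state.S >= params.S_star)
    if np.any(new):
        state.remodeled[new] = True
        nodes = state.idx[new]
        state._add_blocked(nodes)
        state.events.append((state.time, "remodeled", int(new.sum())))
    return state


def functional_volume(state: DiseaseState, tree: AirwayTree) -> float:
    """Fraction of alveoli reachable through unblocked airways, in [0, 1]."""
    return 1.0 - state.blocked_alveoli() / tree.n_alveoli


def apply_treatment(state: DiseaseState, params: SimParams,
                    tree: AirwayTree | None = None) -> DiseaseState:
    """Clear undamaged colonizations; rebase the FVC baseline.

    Mucus is cleared from every airway whose wall is still undamaged, and
    those airways revert to the uninfected state.  Airways whose scarring
    has begun (mucus present for at least ``T_s`` months, the threshold
    counting as crossed when reached) cannot be cleared: they are
    reinfected instantaneously, keeping their colonization time, mucus
    load and filled status, so a plugged scarred airway never re-triggers
    overflow and stays plugged through treatment.  Remodeled subtrees are
    untouched.  The new baseline ``V_L_star`` therefore excludes all
    damaged coverage -- treatment recovers only the losses caused by
    undamaged disease.
    """
    tree = tree if tree is not None else state.tree
    scar_begun = (state.time - state.t_i >= params.T_s) & (params.v_s > 0)
    keep = scar_begun | state.remodeled
    dropped = state.idx[~keep]
    if dropped.size:
        state.infected_mask[dropped] = False
        np.subtract.at(state.infected_per_gen, state.gen[~keep], 1)
    for name in ("idx", "gen", "t_i", "M", "S", "filled", "remodeled"):
        setattr(state, name, getattr(state, name)[keep])
    state._rebuild_blocked()
    state.V_L_star = functional_volume(state, tree)
    state.events.append((state.time, "treatment", int(dropped.size)))
    return state


def step(state: DiseaseState, params: SimParams, tree: AirwayTree) -> DiseaseState:
    """One time step: colonize → grow/fill → overflow → scar → remodel → treat."""
    t_next = state.time + params.dt
    colonize(state, params, tree)
    _update_mucus(state, params, tree)
    propagate_overflow(state, tree)
    _update_scarring(state, params, t_next)
    apply_remodeling(state, params, tree)
    state.time = t_next
    V_L = functional_volume(state, tree)
    if check_treatment(V_L, state.V_L_star, params.alpha):
        apply_treatment(state, params, tree)
    return state


def simulate(params: SimParams, tree: AirwayTree, n_replicates: int = 100,
             progress: bool = False) -> FvcTrajectory:
    """Run independent replicates from a healthy lung at t = 0.

    Replicate ``r`` uses its own generator seeded ``params.seed + r``, so the
    output is bit-reproducible and individual replicates can be re-run in
    isolation.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be at least 1")
    months = np.arange(params.horizon + 1) * params.dt
    values = np.empty((n_replicates, params.horizon + 1))
    for r in range(n_replicates):
        rng = np.random.default_rng(params.seed + r)
        state = DiseaseState(tree, params, rng)
        values[r, 0] = 100.0
        for s in range(params.horizon):
            step(state, params, tree)
            values[r, s + 1] = 100.0 * functional_volume(state, tree)
    return FvcTrajectory(months=months, values=values)
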