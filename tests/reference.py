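"""Naive per-airway reference implementation of the disease dynamics.

Deliberately simple and slow: dense python dictionaries over every airway,
explicit root-to-leaf path walks for accessibility, no interval
bookkeeping, no vectorization.  Shares only the colonization *sampler*
with the package (so both consume the random stream identically); every
other rule -- growth, fill, overflow, scarring, remodeling, treatment --
is re-implemented independently for state-for-state comparison.
"""

from __future__ import annotations

import numpy as np

from cflung.geometry import AirwayTree
from cflung.model import SimParams, sample_colonizations


class NaiveDiseaseModel:
    def __init__(self, tree: AirwayTree, params: SimParams,
                 rng: np.random.Generator):
        self.tree = tree
        self.params = params
        self.rng = rng
        self.time = 0.0
        self.t_i: dict[int, float] = {}
        self.M: dict[int, float] = {}
        self.S: dict[int, float] = {}
        self.filled: set[int] = set()
        self.remodeled: set[int] = set()
        self.V_L_star = 1.0

    # -- helpers ------------------------------------------------------------

    def _volume(self, k: int) -> float:
        g = int(np.floor(np.log2(k)))
        return float(self.tree.airway_volume_mm3[g])

    def _infect(self, k: int, t: float) -> None:
        assert k not in self.t_i
        self.t_i[k] = t
        self.M[k] = 0.0
        self.S[k] = 0.0

    def shut(self) -> set[int]:
        blocked = self.filled | self.remodeled
        out = set()
        for k in range(1, self.tree.total_airways + 1):
            a = k // 2
            while a >= 1:
                if a in blocked:
                    out.add(k)
                    break
                a //= 2
        return out

    def functional_volume(self) -> float:
        blocked = self.filled | self.remodeled
        lo = self.tree.leaf_lo
        accessible = 0
        for leaf in range(lo, 2 * lo):
            k = leaf
            ok = True
            while k >= 1:
                if k in blocked:
                    ok = False
                    break
                k //= 2
            accessible += ok
        return accessible / self.tree.n_alveoli

    # -- one step, same phase order as the package --------------------------

    def step(self) -> None:
        p = self.params
        t0 = self.time
        t1 = t0 + p.dt

        # colonization (shared sampler => identical stream consumption)
        n_slots = 1 << self.tree.n_generations
        mask = np.zeros(n_slots, dtype=bool)
        mask[list(self.t_i)] = True
        per_gen = np.zeros(self.tree.n_generations, dtype=np.int64)
        for k in self.t_i:
            per_gen[int(np.floor(np.log2(k)))] += 1
        new = sample_colonizations(self.rng, self.tree, mask, per_gen,
                                   p.P_c, p.dt, p.bronchiole_gen_min)
        for k in new:
            self._infect(int(k), t0)

        # mucus growth with cap; collect this step's fills
        newly = []
        for k in list(self.t_i):
            if k in self.filled:
                continue
            V = self._volume(k)
            self.M[k] = min(V, self.M[k] + p.v_c * p.dt)
            if self.M[k] >= V:
                self.filled.add(k)
                newly.append(k)

        # overflow, once per step: children of the new fills, then parents
        for k in sorted(newly):
            for c in (2 * k, 2 * k + 1):
                if c <= self.tree.total_airways and c not in self.t_i:
                    self._infect(c, t0)
        for k in sorted(newly):
            a = k // 2
            if a >= 1 and a not in self.t_i:
                self._infect(a, t0)

        # scarring ramp (frozen once remodeled)
        for k in self.t_i:
            if k not in self.remodeled:
                self.S[k] = p.v_s * max(0.0, t1 - self.t_i[k] - p.T_s)

        # remodeling threshold
        for k in self.t_i:
            if k not in self.remodeled and self.S[k] >= p.S_star:
                self.remodeled.add(k)

        self.time = t1

        # treatment: clears undamaged sites only; damaged keep everything
        V_L = self.functional_volume()
        if V_L <= p.alpha * self.V_L_star:
            for k in list(self.t_i):
                damaged = (t1 - self.t_i[k] >= p.T_s and p.v_s > 0) \
                    or (k in self.remodeled)
                if not damaged:
                    del self.t_i[k], self.M[k], self.S[k]
                    self.filled.discard(k)
            self.V_L_star = self.functional_volume()
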