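"""Synthetic inputs: random measurement batteries, feasible flux vectors
with noisy read-outs, and small hand-verified toy networks.

The toy networks double as oracles: their elementary modes are enumerated by
an exhaustive support-subset search (feasible only for tiny networks), which
is independent of the double-description implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .model import MetabolicModel, loads_model
from .possibilistic import MeasurementSet, shape_measurement

__all__ = [
    "RandomBatterySpec",
    "BATTERY_1",
    "BATTERY_2",
    "random_battery",
    "sample_feasible_flux",
    "perturb_measurements",
    "toy_networks",
    "brute_force_ems",
]


# ---------------------------------------------------------------------------
# random rejection batteries

@dataclass
class RandomBatterySpec:
    """Uniform sampling bounds for each measured quantity."""

    bounds: dict[str, tuple[float, float]]
    n_datasets: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_datasets < 1:
            raise ValueError("n_datasets must be >= 1")
        for q, (lo, hi) in self.bounds.items():
            if lo > hi:
                raise ValueError(f"invalid bounds for {q!r}: {lo} > {hi}")


#: every quantity free in [0, 10] mol kg-1 h-1 (mu in Cmol kg-1 h-1)
BATTERY_1 = {
    "mu": (0.0, 10.0),
    "q_glu": (0.0, 10.0),
    "q_gly": (0.0, 10.0),
    "q_met": (0.0, 10.0),
    "q_et": (0.0, 10.0),
    "our": (0.0, 10.0),
    "cpr": (0.0, 10.0),
}

#: bounds shaped to the physiological ranges spanned by the literature data
BATTERY_2 = {
    "mu": (1.5, 6.0),
    "q_glu": (0.0, 2.0),
    "q_gly": (0.0, 2.7),
    "q_met": (0.0, 2.7),
    "q_et": (0.0, 0.1),
    "our": (2.1, 7.2),
    "cpr": (1.5, 4.0),
}


def random_battery(spec: RandomBatterySpec) -> list[dict[str, float]]:
    """Draw ``n_datasets`` random measurement dictionaries within the bounds."""
    rng = np.random.default_rng(spec.seed)
    out = []
    quantities = list(spec.bounds)
    for _ in range(spec.n_datasets):
        row = {}
        for q in quantities:
            lo, hi = spec.bounds[q]
            row[q] = float(rng.uniform(lo, hi))
        out.append(row)
    return out


# ---------------------------------------------------------------------------
# ground-truth flux sampling and noisy read-outs

def sample_feasible_flux(
    model: MetabolicModel, seed: int, ems=None, scale: float = 1.0
) -> np.ndarray:
    """Random exactly-feasible flux vector: Dirichlet mixture of the EMs.

    Modes are combined with Dirichlet(1) weights, so the result satisfies
    N v = 0 and all irreversibility constraints by construction.
    """
    if ems is None:
        from .ems import enumerate_ems

        ems = enumerate_ems(model)
    if len(ems) == 0:
        raise ValueError("model has no elementary modes")
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(np.ones(len(ems)))
    v = np.zeros(model.n_reactions)
    for wi, mode in zip(w, ems):
        v += wi * mode.flux
    return scale * v


def perturb_measurements(
    v: np.ndarray,
    model: MetabolicModel,
    rel_noise: float,
    seed: int,
    **shape_kwargs,
) -> MeasurementSet:
    """Read exchange fluxes of ``v`` with multiplicative uniform noise.

    Each measured quantity is multiplied by an independent factor drawn from
    [1 - rel_noise, 1 + rel_noise] and shaped into a possibilistic
    measurement with the default band parameters.
    """
    if rel_noise < 0:
        raise ValueError("rel_noise must be >= 0")
    rng = np.random.default_rng(seed)
    ms = MeasurementSet()
    for q, (j, sign) in model.exchange_map.items():
        true = sign * v[j]
        factor = rng.uniform(1.0 - rel_noise, 1.0 + rel_noise)
        ms.add(
            shape_measurement(j, true * factor, sign=sign, quantity=q, **shape_kwargs)
        )
    return ms


# ---------------------------------------------------------------------------
# exhaustive EM oracle (tiny networks only)

def brute_force_ems(model: MetabolicModel, max_reactions: int = 12) -> list[np.ndarray]:
    """Enumerate EMs by testing every support subset (exponential; tiny nets).

    A support set S is elementary iff the nullspace of N restricted to S is
    one-dimensional, its generator has full support on S, and the generator
    (or its negation, when every active reaction is reversible) satisfies
    the irreversibility signs.
    """
    n = model.n_reactions
    if n > max_reactions:
        raise ValueError("brute force oracle limited to tiny networks")
    N = model.N
    rev = model.reversible
    found: list[np.ndarray] = []
    supports: list[frozenset[int]] = []
    for k in range(1, n + 1):
        for S in combinations(range(n), k):
            Ssub = np.asarray(S)
            # support minimality: no previously found EM support inside S
            sset = frozenset(S)
            if any(sup <= sset for sup in supports):
                continue
            sub = N[:, Ssub] if N.size else np.zeros((0, len(S)))
            # nullspace of the restricted matrix
            u, s, vt = np.linalg.svd(sub) if sub.size else (None, np.array([]), None)
            rank = int(np.sum(s > 1e-10))
            if len(S) - rank != 1:
                continue
            if sub.size:
                gen = vt[-1]
            else:
                gen = np.ones(len(S))
            if np.any(np.abs(gen) < 1e-10):
                continue  # generator not fully supported on S
            v = np.zeros(n)
            v[Ssub] = gen
            irrev_active = [j for j in S if not rev[j]]
            if irrev_active:
                signs = np.sign(v[irrev_active])
                if np.all(signs > 0):
                    pass
                elif np.all(signs < 0):
                    v = -v
                else:
                    continue
            else:
                first = min(S)
                if v[first] < 0:
                    v = -v
            found.append(v / np.max(np.abs(v)))
            supports.append(sset)
    return found


# ---------------------------------------------------------------------------
# toy network library

_TOYS = {
    "chain": """
[metabolites]
Xa\texternal\t1
Xb\texternal\t1
A\tinternal\t1
B\tinternal\t1
[reactions]
t1\tXa -> A\t
t2\tA -> B\t
t3\tB -> Xb\t
""",
    "branch": """
[metabolites]
Xa\texternal\t1
Xb\texternal\t1
Xc\texternal\t1
A\tinternal\t1
B\tinternal\t1
C\tinternal\t1
[reactions]
t1\tXa -> A\t
t2\tA -> B\t
t3\tB -> Xb\t
t4\tA -> C\t
t5\tC -> Xc\t
""",
    "reversible_cycle": """
[metabolites]
Xa\texternal\t1
Xb\texternal\t1
A\tinternal\t1
B\tinternal\t1
C\tinternal\t1
[reactions]
t1\tXa -> A\t
t2\tA <-> B\t
t3\tB <-> C\t
t4\tC <-> A\t
t5\tB -> Xb\t
""",
    "diamond_futile": """
[metabolites]
Xa\texternal\t2
Xb\texternal\t2
A\tinternal\t2
B\tinternal\t2
C\tinternal\t2
[reactions]
t1\tXa -> A\t
t2\tA -> B\t
t3\tA <-> C\t
t4\tB -> C\t
t5\tC -> B\t
t6\tB -> Xb\t
""",
    "substrate_choice": """
[metabolites]
Xa\texternal\t2
Xc\texternal\t3
Xp\texternal\t1
Xq\texternal\t1
A\tinternal\t2
C\tinternal\t3
P\tinternal\t1
[reactions]
t1\tXa -> A\t
t2\tXc -> C\t
t3\tA -> 2 P\t
t4\tC -> 3 P\t
t5\tP -> Xp\t
t6\tP -> Xq\t
""",
}


def toy_networks() -> dict[str, tuple[MetabolicModel, list[np.ndarray]]]:
    """Hand-sized toy models paired with their oracle-enumerated EM sets."""
    out = {}
    for name, text in _TOYS.items():
        model = loads_model(text)
        out[name] = (model, brute_force_ems(model))
    return out
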