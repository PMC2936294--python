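"""Elementary flux mode enumeration, classification and carbon yields.

Elementary modes (EMs) are the support-minimal steady-state flux
distributions of a metabolic network; every feasible steady state is a
non-negative combination of EMs without cancellation across reversible
fluxes.  Enumeration uses the tableau double-description method on the flux
cone after splitting reversible reactions into forward/backward pairs, with
futile two-cycle artifacts removed and split pairs re-fused afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import MetabolicModel, check_steady_state

__all__ = [
    "ElementaryMode",
    "EMSet",
    "EnumerationCapError",
    "enumerate_ems",
    "classify_ems",
    "em_yield",
    "max_yield_per_category",
]

SUBSTRATES = ("glucose", "glycerol", "methanol")

_ZERO_TOL = 1e-9  # coefficients below this (after scaling) are zero


class EnumerationCapError(RuntimeError):
    """Raised when the intermediate ray count exceeds the configured cap."""


@dataclass
class ElementaryMode:
    """One elementary mode in canonical scaling."""

    flux: np.ndarray
    support: frozenset[int] = field(init=False)
    macroreaction: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.support = frozenset(np.flatnonzero(np.abs(self.flux) > _ZERO_TOL).tolist())

    @property
    def substrates(self) -> frozenset[str]:
        return frozenset(
            s for s in SUBSTRATES if self.macroreaction.get(s, 0.0) > _ZERO_TOL
        )

    @property
    def produces_biomass(self) -> bool:
        return self.macroreaction.get("biomass", 0.0) > _ZERO_TOL

    @property
    def produces_ethanol(self) -> bool:
        return self.macroreaction.get("ethanol", 0.0) > _ZERO_TOL


@dataclass
class EMSet:
    modes: list[ElementaryMode]

    def __len__(self) -> int:
        return len(self.modes)

    def __iter__(self):
        return iter(self.modes)

    def __getitem__(self, i: int) -> ElementaryMode:
        return self.modes[i]


# ---------------------------------------------------------------------------
# double description

def _extreme_rays(Nsplit: np.ndarray, cap: int) -> np.ndarray:
    """Extreme rays of {x >= 0 : Nsplit @ x = 0} (rows of the result)."""
    m, n = Nsplit.shape
    rays = np.eye(n)
    resid = Nsplit.T.copy()  # residual balance of each ray for each constraint
    remaining = list(range(m))

    while remaining:
        # cheapest constraint first keeps intermediate ray counts small
        costs = []
        for k in remaining:
            col = resid[:, k]
            npos = int(np.sum(col > _ZERO_TOL))
            nneg = int(np.sum(col < -_ZERO_TOL))
            costs.append(npos * nneg - (npos + nneg))
        k = remaining.pop(int(np.argmin(costs)))

        col = resid[:, k]
        zero = np.abs(col) <= _ZERO_TOL
        pos = np.flatnonzero(col > _ZERO_TOL)
        neg = np.flatnonzero(col < -_ZERO_TOL)

        keep_rays = [rays[zero]]
        keep_resid = [resid[zero]]
        if pos.size and neg.size:
            support = np.abs(rays) > _ZERO_TOL
            new_rays = []
            new_resid = []
            for i in pos:
                for j in neg:
                    comb_support = support[i] | support[j]
                    # adjacency: no third ray's support inside the union
                    inside = ~np.any(support & ~comb_support, axis=1)
                    inside[i] = inside[j] = False
                    if np.any(inside):
                        continue
                    w_i, w_j = -col[j], col[i]
                    r = w_i * rays[i] + w_j * rays[j]
                    b = w_i * resid[i] + w_j * resid[j]
                    scale = np.max(np.abs(r))
                    new_rays.append(r / scale)
                    new_resid.append(b / scale)
            if new_rays:
                keep_rays.append(np.asarray(new_rays))
                keep_resid.append(np.asarray(new_resid))
        rays = np.vstack(keep_rays)
        resid = np.vstack(keep_resid)
        if rays.shape[0] > cap:
            raise EnumerationCapError(
                f"intermediate ray count {rays.shape[0]} exceeds cap {cap}"
            )
        # clean numerical dust so support tests stay exact
        rays[np.abs(rays) <= _ZERO_TOL] = 0.0
        resid[np.abs(resid) <= _ZERO_TOL] = 0.0
    return rays


def _canonical_scale(v: np.ndarray, model: MetabolicModel) -> np.ndarray:
    """Scale so total substrate consumption is 1 mol, else max |coeff| = 1."""
    total = 0.0
    for s in SUBSTRATES:
        if s not in model.exchange_map:
            continue
        j, sign = model.exchange_map[s]
        total += max(0.0, sign * v[j])
    if total > _ZERO_TOL:
        return v / total
    return v / np.max(np.abs(v))


def _macroreaction(v: np.ndarray, model: MetabolicModel) -> dict[str, float]:
    macro = {}
    for q, (j, sign) in model.exchange_map.items():
        macro[q] = float(sign * v[j])
    return macro


def enumerate_ems(
    model: MetabolicModel, cap: int = 200_000, tol: float = 1e-8
) -> EMSet:
    """Enumerate all elementary flux modes of ``model``.

    Reversible reactions are split into forward/backward pairs, extreme rays
    of the resulting pointed cone are computed by double description, futile
    two-cycles are dropped and split pairs re-fused.  A mode whose reversible
    fluxes can all be negated without touching an irreversible flux is
    reported once, with the canonical sign making its first non-zero entry
    positive.

    Raises
    ------
    EnumerationCapError
        if the intermediate ray count exceeds ``cap`` (never silently
        truncates).
    """
    if model.n_reactions == 0:
        raise ValueError("model has no reactions")
    N = model.N
    n = model.n_reactions
    rev = model.reversible

    # column map: irreversible -> one column; reversible -> (fwd, bwd)
    cols = []
    for j in range(n):
        cols.append((j, +1.0))
        if rev[j]:
            cols.append((j, -1.0))
    Nsplit = np.column_stack([s * N[:, j] for j, s in cols])

    rays = _extreme_rays(Nsplit, cap)

    modes: list[np.ndarray] = []
    seen: set[tuple] = set()
    for x in rays:
        v = np.zeros(n)
        for (j, s), xi in zip(cols, x):
            v[j] += s * xi
        v[np.abs(v) <= _ZERO_TOL] = 0.0
        if not np.any(v):
            continue  # futile two-cycle artifact of the split
        # canonical sign for fully-reversible modes
        active_irrev = np.flatnonzero((np.abs(v) > _ZERO_TOL) & ~rev)
        if active_irrev.size == 0:
            first = np.flatnonzero(np.abs(v) > _ZERO_TOL)[0]
            if v[first] < 0:
                v = -v
        v = _canonical_scale(v, model)
        key = tuple(np.round(v / np.max(np.abs(v)), 9))
        if key in seen:
            continue
        seen.add(key)
        ok, resid = check_steady_state(model, v, tol=max(tol, 1e-7))
        if not ok:  # pragma: no cover - guards numerical failure
            raise RuntimeError(f"enumerated ray violates steady state: {resid}")
        modes.append(v)

    modes.sort(key=lambda v: (len(np.flatnonzero(v)), tuple(np.round(v, 9))))
    ems = [ElementaryMode(v, _macroreaction(v, model)) for v in modes]
    return EMSet(ems)


# ---------------------------------------------------------------------------
# classification and yields

def classify_ems(ems: EMSet, model: MetabolicModel) -> dict[str, int]:
    """Count modes per category (growth / no growth, ethanol, substrate use)."""
    counts = {
        "total": len(ems),
        "no_biomass": 0,
        "ethanol": 0,
    }
    for mode in ems:
        if not mode.produces_biomass:
            counts["no_biomass"] += 1
        if mode.produces_ethanol:
            counts["ethanol"] += 1
        label = "+".join(sorted(mode.substrates)) or "none"
        grow = "growth" if mode.produces_biomass else "no-growth"
        counts[f"{label}|{grow}"] = counts.get(f"{label}|{grow}", 0) + 1
    return counts


def em_yield(
    mode: ElementaryMode, model: MetabolicModel, basis: str = "per-mol-substrate"
) -> float:
    """Biomass carbon yield of a mode.

    ``per-mol-substrate``: Cmol biomass per total mol of carbon substrates
    consumed (Table-style units, Cmol DW mol^-1).  ``per-Cmol-substrate``:
    Cmol biomass per Cmol of substrate carbon (bounded by 1).
    """
    macro = mode.macroreaction
    present = [s for s in SUBSTRATES if s in model.exchange_map]
    mol = sum(max(0.0, macro.get(s, 0.0)) for s in present)
    cmol = sum(
        max(0.0, macro.get(s, 0.0)) * model.carbon_per_mol(s) for s in present
    )
    if mol <= _ZERO_TOL:
        raise ValueError("mode consumes no carbon substrate; yield undefined")
    biomass = max(0.0, macro.get("biomass", 0.0))
    if basis == "per-mol-substrate":
        return biomass / mol
    if basis == "per-Cmol-substrate":
        return biomass / cmol
    raise ValueError(f"unknown basis {basis!r}")


def max_yield_per_category(
    ems: EMSet, model: MetabolicModel
) -> dict[frozenset[str], tuple[float, int]]:
    """Maximum per-mol growth yield for each substrate combination.

    Returns ``{substrate set: (max yield, index of the arg-max mode)}``;
    combinations with no growth mode are absent.  Ties break to the lowest
    mode index.
    """
    best: dict[frozenset[str], tuple[float, int]] = {}
    for i, mode in enumerate(ems):
        if not mode.produces_biomass or not mode.substrates:
            continue
        y = em_yield(mode, model, "per-mol-substrate")
        key = mode.substrates
        if key not in best or y > best[key][0] + _ZERO_TOL:
            best[key] = (y, i)
    return best
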