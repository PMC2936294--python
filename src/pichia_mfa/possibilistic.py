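"""Possibilistic metabolic flux analysis.

Each measurement ``w`` of a model flux is relaxed into
``w = v + eps1 - mu1 + eps2 - mu2`` with ``eps2, mu2`` bounded (the fully
possible band) and ``eps1, mu1`` penalized linearly through the cost
``J = alpha·eps1 + beta·mu1``.  A candidate flux state has possibility
``pi = exp(-J)``; the most possible state, the consistency degree
``pi(v_mp)``, and per-flux possibility intervals are all linear programs
over the constraint set {N·v = 0, D·v >= 0} plus the measurement relaxations.

With the default shaping, deviations within +/-5% of the measured value are
fully possible and a +/-20% deviation has possibility 0.1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linprog

from .model import MetabolicModel

__all__ = [
    "SolverError",
    "PossibilisticMeasurement",
    "MeasurementSet",
    "ConsistencyResult",
    "FluxIntervalEstimate",
    "shape_measurement",
    "measurement_possibility",
    "max_possibility",
    "flux_interval",
    "minimal_full_band",
    "estimate_excluded_flux",
    "DEFAULT_FULL_BAND",
    "DEFAULT_REF_BAND",
    "DEFAULT_REF_POSSIBILITY",
    "DEFAULT_ZERO_FLOOR",
]

DEFAULT_FULL_BAND = 0.05
DEFAULT_REF_BAND = 0.20
DEFAULT_REF_POSSIBILITY = 0.1
#: scale floor for zero-valued measurements, mol kg-1 h-1
DEFAULT_ZERO_FLOOR = 0.05


class SolverError(RuntimeError):
    """LP solver did not return an optimum; carries the solver status."""


@dataclass
class PossibilisticMeasurement:
    """One measured flux with its possibility distribution parameters.

    The measured quantity equals ``sign * v[reaction_index]``; ``eps2_max``
    and ``mu2_max`` bound the fully possible band and ``alpha``/``beta``
    (units 1/flux) set the exponential decay of possibility beyond it.
    """

    reaction_index: int
    w_m: float
    eps2_max: float
    mu2_max: float
    alpha: float
    beta: float
    sign: float = 1.0
    quantity: str = ""

    def __post_init__(self) -> None:
        if self.eps2_max < 0 or self.mu2_max < 0:
            raise ValueError("band half-widths must be non-negative")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("slope weights must be non-negative")

    def possibility_of(self, value: float) -> float:
        """Possibility of the flux taking ``value`` under this measurement."""
        dev = value - self.w_m
        if dev >= 0:
            excess = max(0.0, dev - self.mu2_max)
            return math.exp(-self.beta * excess)
        excess = max(0.0, -dev - self.eps2_max)
        return math.exp(-self.alpha * excess)


class MeasurementSet:
    """Ordered collection of possibilistic measurements."""

    def __init__(self, measurements=()):
        self._items: list[PossibilisticMeasurement] = list(measurements)

    def add(self, m: PossibilisticMeasurement) -> None:
        self._items.append(m)

    def drop(self, quantity: str) -> "MeasurementSet":
        """Copy of the set without the measurements of ``quantity``."""
        return MeasurementSet([m for m in self._items if m.quantity != quantity])

    def widen(self, factor: float) -> "MeasurementSet":
        """Copy with bands scaled up and slopes scaled down by ``factor``."""
        return MeasurementSet(
            [
                replace(
                    m,
                    eps2_max=m.eps2_max * factor,
                    mu2_max=m.mu2_max * factor,
                    alpha=m.alpha / factor,
                    beta=m.beta / factor,
                )
                for m in self._items
            ]
        )

    def __iter__(self):
        return iter(self._items)

    def __len__(self) -> int:
        return len(self._items)

    def __getitem__(self, i: int) -> PossibilisticMeasurement:
        return self._items[i]


@dataclass
class ConsistencyResult:
    """Outcome of the maximum-possibility LP."""

    pi: float
    J_min: float
    v_mp: np.ndarray
    band_to_full: float | None = None


@dataclass
class FluxIntervalEstimate:
    """[lower, upper] flux range with conditional possibility >= gamma."""

    reaction_index: int
    gamma: float
    lower: float
    upper: float
    most_possible: float
    empty: bool = False


def shape_measurement(
    reaction_index: int,
    w_m: float,
    full_band: float = DEFAULT_FULL_BAND,
    ref_band: float = DEFAULT_REF_BAND,
    ref_possibility: float = DEFAULT_REF_POSSIBILITY,
    zero_floor: float = DEFAULT_ZERO_FLOOR,
    sign: float = 1.0,
    quantity: str = "",
) -> PossibilisticMeasurement:
    """Build the default symmetric possibility distribution for a measurement.

    The fully possible band is ``+/- full_band`` (relative), and a relative
    deviation of ``ref_band`` has possibility ``ref_possibility``; zero-valued
    measurements use ``zero_floor`` as the reference scale.
    """
    if not 0 < full_band < ref_band:
        raise ValueError("need 0 < full_band < ref_band")
    if not 0 < ref_possibility < 1:
        raise ValueError("ref_possibility must lie in (0, 1)")
    scale = max(abs(w_m), zero_floor)
    half = full_band * scale
    slope = -math.log(ref_possibility) / ((ref_band - full_band) * scale)
    return PossibilisticMeasurement(
        reaction_index=reaction_index,
        w_m=w_m,
        eps2_max=half,
        mu2_max=half,
        alpha=slope,
        beta=slope,
        sign=sign,
        quantity=quantity,
    )


def measurement_possibility(m: PossibilisticMeasurement, value: float) -> float:
    """Possibility of ``value`` under a single measurement distribution."""
    return m.possibility_of(value)


# ---------------------------------------------------------------------------
# LP assembly

def _assemble(model: MetabolicModel, meas: MeasurementSet):
    """Shared constraint blocks: variables are [v, (eps1, mu1, eps2, mu2)*K]."""
    n = model.n_reactions
    K = len(meas)
    nvar = n + 4 * K
    N = model.N
    m_rows = N.shape[0]

    A_eq = np.zeros((m_rows + K, nvar))
    b_eq = np.zeros(m_rows + K)
    A_eq[:m_rows, :n] = N
    bounds: list[tuple[float | None, float | None]] = [
        (None, None) if r else (0.0, None) for r in model.reversible
    ]
    for k, m in enumerate(meas):
        row = m_rows + k
        A_eq[row, m.reaction_index] = m.sign
        off = n + 4 * k
        A_eq[row, off + 0] = 1.0  # eps1
        A_eq[row, off + 1] = -1.0  # mu1
        A_eq[row, off + 2] = 1.0  # eps2
        A_eq[row, off + 3] = -1.0  # mu2
        b_eq[row] = m.w_m
        bounds += [
            (0.0, None),
            (0.0, None),
            (0.0, m.eps2_max),
            (0.0, m.mu2_max),
        ]

    cost = np.zeros(nvar)
    for k, m in enumerate(meas):
        off = n + 4 * k
        cost[off + 0] = m.alpha
        cost[off + 1] = m.beta
    return cost, A_eq, b_eq, bounds, n, nvar


def _solve(c, A_ub, b_ub, A_eq, b_eq, bounds):
    res = linprog(
        c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs"
    )
    return res


def max_possibility(
    model: MetabolicModel, meas: MeasurementSet, compute_full_band: bool = False,
    zero_floor: float = DEFAULT_ZERO_FLOOR,
) -> ConsistencyResult:
    """Most possible flux vector and consistency degree pi = exp(-J_min)."""
    cost, A_eq, b_eq, bounds, n, _ = _assemble(model, meas)
    res = _solve(cost, None, None, A_eq, b_eq, bounds)
    if res.status != 0:
        raise SolverError(f"max-possibility LP failed: {res.message}")
    J = max(0.0, float(res.fun))
    out = ConsistencyResult(pi=math.exp(-J), J_min=J, v_mp=res.x[:n].copy())
    if compute_full_band:
        out.band_to_full = minimal_full_band(model, meas, zero_floor=zero_floor)
    return out


def flux_interval(
    model: MetabolicModel,
    meas: MeasurementSet,
    reaction_index: int,
    gamma: float,
    conditional: bool = False,
    _cache: ConsistencyResult | None = None,
) -> FluxIntervalEstimate:
    """Possibility interval of one flux: min/max v_i subject to J <= -ln(gamma).

    With ``conditional=True`` the cost budget is measured relative to the
    optimum (J - J_min <= -ln gamma), i.e. the interval of values with
    conditional possibility >= gamma; the default uses the absolute budget.
    """
    if not 0 < gamma < 1:
        raise ValueError("gamma must lie in (0, 1)")
    mp = _cache if _cache is not None else max_possibility(model, meas)
    budget = -math.log(gamma) + (mp.J_min if conditional else 0.0)
    if mp.J_min > budget + 1e-9:
        return FluxIntervalEstimate(
            reaction_index, gamma, math.nan, math.nan,
            float(mp.v_mp[reaction_index]), empty=True,
        )
    cost, A_eq, b_eq, bounds, n, nvar = _assemble(model, meas)
    A_ub = cost[None, :]
    b_ub = np.array([budget])
    lo = hi = None
    for sense in (+1.0, -1.0):
        c = np.zeros(nvar)
        c[reaction_index] = sense
        res = _solve(c, A_ub, b_ub, A_eq, b_eq, bounds)
        if res.status == 3:  # unbounded flux at this budget
            val = -math.inf if sense > 0 else math.inf
        elif res.status != 0:
            raise SolverError(f"interval LP failed: {res.message}")
        else:
            val = sense * float(res.fun) if sense > 0 else -float(res.fun)
        if sense > 0:
            lo = float(res.fun) if res.status == 0 else -math.inf
        else:
            hi = -float(res.fun) if res.status == 0 else math.inf
    return FluxIntervalEstimate(
        reaction_index, gamma, lo, hi, float(mp.v_mp[reaction_index])
    )


def minimal_full_band(
    model: MetabolicModel,
    meas: MeasurementSet,
    zero_floor: float = DEFAULT_ZERO_FLOOR,
) -> float:
    """Smallest uniform relative band b making the measurements fully
    consistent: exists v with N·v = 0, D·v >= 0 and
    |sign·v_i - w_i| <= b·max(|w_i|, zero_floor) for every measurement."""
    n = model.n_reactions
    K = len(meas)
    nvar = n + 1  # v plus the band fraction b
    N = model.N
    A_eq = np.zeros((N.shape[0], nvar))
    A_eq[:, :n] = N
    b_eq = np.zeros(N.shape[0])
    A_ub = np.zeros((2 * K, nvar))
    b_ub = np.zeros(2 * K)
    for k, m in enumerate(meas):
        scale = max(abs(m.w_m), zero_floor)
        A_ub[2 * k, m.reaction_index] = m.sign
        A_ub[2 * k, n] = -scale
        b_ub[2 * k] = m.w_m
        A_ub[2 * k + 1, m.reaction_index] = -m.sign
        A_ub[2 * k + 1, n] = -scale
        b_ub[2 * k + 1] = -m.w_m
    bounds = [(None, None) if r else (0.0, None) for r in model.reversible]
    bounds.append((0.0, None))
    c = np.zeros(nvar)
    c[n] = 1.0
    res = _solve(c, A_ub, b_ub, A_eq, b_eq, bounds)
    if res.status != 0:
        raise SolverError(f"minimal-band LP failed: {res.message}")
    return max(0.0, float(res.fun))


def estimate_excluded_flux(
    model: MetabolicModel,
    meas: MeasurementSet,
    target_index: int,
    gammas=(0.8, 0.5, 0.1),
    conditional: bool = False,
) -> tuple[float, list[FluxIntervalEstimate]]:
    """Most possible value and gamma-intervals of a non-measured flux.

    ``meas`` must not constrain ``target_index`` directly (leave-one-out
    prediction); intervals are returned for each level in ``gammas``.
    """
    if any(m.reaction_index == target_index for m in meas):
        raise ValueError("target flux is in the measurement set; drop it first")
    mp = max_possibility(model, meas)
    intervals = [
        flux_interval(model, meas, target_index, g, conditional=conditional, _cache=mp)
        for g in gammas
    ]
    return float(mp.v_mp[target_index]), intervals
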