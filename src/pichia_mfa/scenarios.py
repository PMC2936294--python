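"""Literature datasets for *P. pastoris* cultures and their conversion to
possibilistic measurement sets.

Eleven published datasets (glucose, glycerol, methanol and mixed feeds)
are shipped as a fixture table; each row carries the biomass growth rate mu
(Cmol kg-1 h-1), substrate uptake and ethanol production rates, the gas
exchange rates OUR and CPR (mol kg-1 h-1), and the specific protein
productivity q_p (mg g-1 h-1).  Protein productivity is not mapped onto the
model by default: the network does not account for resources devoted to
recombinant-protein production.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .ems import EMSet, max_yield_per_category
from .model import MetabolicModel
from .possibilistic import (
    DEFAULT_ZERO_FLOOR,
    MeasurementSet,
    shape_measurement,
)

__all__ = [
    "Scenario",
    "load_scenarios",
    "to_measurements",
    "experimental_yield",
    "yield_vs_theoretical",
    "MEASURED_QUANTITIES",
]

_DATA = Path(__file__).parent / "data" / "table2_scenarios.tsv"

#: scenario field -> exchange_map quantity
MEASURED_QUANTITIES = {
    "mu": "biomass",
    "q_glu": "glucose",
    "q_gly": "glycerol",
    "q_met": "methanol",
    "q_et": "ethanol",
    "our": "o2",
    "cpr": "co2",
}


@dataclass(frozen=True)
class Scenario:
    """One published dataset (rates per kg dry weight per hour)."""

    id: str
    source: str
    mu: float
    q_glu: float
    q_gly: float
    q_met: float
    q_et: float
    our: float
    cpr: float
    q_p: float

    def quantity(self, field: str) -> float:
        return getattr(self, field)


def load_scenarios(path: str | Path = _DATA) -> list[Scenario]:
    """Read the shipped dataset table (or a user table in the same layout)."""
    out = []
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        f = line.split("\t")
        out.append(
            Scenario(
                id=f[0],
                source=f[1],
                mu=float(f[2]),
                q_glu=float(f[3]),
                q_gly=float(f[4]),
                q_met=float(f[5]),
                q_et=float(f[6]),
                our=float(f[7]),
                cpr=float(f[8]),
                q_p=float(f[9]),
            )
        )
    ids = [s.id for s in out]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate scenario id in table")
    return out


def to_measurements(
    s: Scenario,
    model: MetabolicModel,
    include_qp: bool = False,
    zero_floor: float = DEFAULT_ZERO_FLOOR,
    **shape_kwargs,
) -> MeasurementSet:
    """Map a scenario's measured quantities onto model fluxes.

    Every mapped column becomes one possibilistic measurement (zero-valued
    ones included -- they constrain the fermentative fluxes); ``q_p`` is
    skipped unless ``include_qp`` and the model maps a protein efflux.
    """
    ms = MeasurementSet()
    for field, quantity in MEASURED_QUANTITIES.items():
        if quantity not in model.exchange_map:
            raise KeyError(f"model exchange map lacks {quantity!r}")
        j, sign = model.exchange_map[quantity]
        ms.add(
            shape_measurement(
                j,
                s.quantity(field),
                sign=sign,
                quantity=quantity,
                zero_floor=zero_floor,
                **shape_kwargs,
            )
        )
    if include_qp:
        if "protein" not in model.exchange_map:
            raise KeyError("include_qp requires a protein efflux in the model")
        j, sign = model.exchange_map["protein"]
        ms.add(
            shape_measurement(
                j, s.q_p, sign=sign, quantity="protein",
                zero_floor=zero_floor, **shape_kwargs,
            )
        )
    return ms


def experimental_yield(s: Scenario) -> float:
    """Growth yield mu / total substrate uptake, Cmol DW per mol substrate."""
    uptake = s.q_glu + s.q_gly + s.q_met
    if uptake <= 0:
        raise ValueError(f"scenario {s.id} has no substrate uptake")
    return s.mu / uptake


def yield_vs_theoretical(
    s: Scenario, ems: EMSet, model: MetabolicModel
) -> dict[str, object]:
    """Compare a scenario's yield with the max EM yield of its substrate mix."""
    substrates = frozenset(
        name
        for field, name in (("q_glu", "glucose"), ("q_gly", "glycerol"), ("q_met", "methanol"))
        if s.quantity(field) > 0
    )
    table = max_yield_per_category(ems, model)
    theo = table.get(substrates, (float("nan"), -1))[0]
    exp = experimental_yield(s)
    return {
        "id": s.id,
        "substrates": substrates,
        "experimental": exp,
        "theoretical_max": theo,
        "violated": bool(exp > theo + 1e-9),
    }
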