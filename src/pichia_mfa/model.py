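"""Constraint-based metabolic model container and reaction-table I/O.

A model is the feasible set  {v : N·v = 0, D·v >= 0}  where ``N`` is the
stoichiometric matrix over the *internal* (balanced) metabolites and ``D``
selects the irreversible reactions.  Models are read from and written to a
plain tab-separated reaction table with three sections::

    [metabolites]   id, role (internal|external), carbon atoms, name
    [reactions]     id, equation ("2 A + B -> C", "<->" if reversible), note
    [exchange]      measurable quantity, reaction id, sign

The ``[exchange]`` section maps measurable culture quantities (glucose,
glycerol, methanol, ethanol, O2, CO2, biomass) onto model fluxes with a sign
convention of *uptakes and production rates positive*.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ModelFormatError",
    "MetabolicModel",
    "load_model",
    "loads_model",
    "save_model",
    "dumps_model",
    "degrees_of_freedom",
    "measurement_rank",
    "check_steady_state",
    "pichia_model_path",
    "load_pichia_model",
]


class ModelFormatError(ValueError):
    """Raised when a reaction-table file violates the format contract."""


_ARROW_RE = re.compile(r"(<->|->)")
_DATA_DIR = Path(__file__).parent / "data"


@dataclass
class MetabolicModel:
    """Stoichiometric model with irreversibility flags and exchange mapping.

    Attributes
    ----------
    reaction_ids : list of str
        Ordered reaction identifiers (1-based numbering = list position + 1).
    metabolite_ids : list of str
        All declared compounds, internal ones first is *not* required.
    internal : dict
        metabolite id -> bool, True if balanced at steady state.
    carbon : dict
        metabolite id -> carbon atoms per mole (biomass: 1 per Cmol).
    stoichiometry : list of dict
        Per reaction, metabolite id -> signed coefficient.
    reversible : ndarray of bool
        Per reaction; irreversible reactions must carry non-negative flux.
    exchange_map : dict
        quantity name -> (reaction index, sign).  Signed flux = measured
        quantity when positive means uptake (substrates, O2) or production
        (CO2, ethanol, biomass).
    notes : dict
        reaction id -> free-text annotation.
    """

    reaction_ids: list[str]
    metabolite_ids: list[str]
    internal: dict[str, bool]
    carbon: dict[str, float]
    stoichiometry: list[dict[str, float]]
    reversible: np.ndarray
    exchange_map: dict[str, tuple[int, float]] = field(default_factory=dict)
    notes: dict[str, str] = field(default_factory=dict)

    # -- derived structure -------------------------------------------------
    @property
    def n_reactions(self) -> int:
        return len(self.reaction_ids)

    @property
    def internal_metabolites(self) -> list[str]:
        return [m for m in self.metabolite_ids if self.internal[m]]

    @property
    def N(self) -> np.ndarray:
        """Stoichiometric matrix restricted to internal metabolites (m x n)."""
        rows = self.internal_metabolites
        idx = {m: i for i, m in enumerate(rows)}
        N = np.zeros((len(rows), self.n_reactions))
        for j, coeffs in enumerate(self.stoichiometry):
            for met, c in coeffs.items():
                if self.internal[met]:
                    N[idx[met], j] = c
        return N

    @property
    def irreversible_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.reversible)

    def reaction_index(self, rid: str) -> int:
        try:
            return self.reaction_ids.index(rid)
        except ValueError:
            raise KeyError(f"unknown reaction id {rid!r}") from None

    def carbon_per_mol(self, quantity: str) -> float:
        """Carbon atoms transported per unit flux of an exchanged quantity."""
        j, _sign = self.exchange_map[quantity]
        ext = [m for m in self.stoichiometry[j] if not self.internal[m]]
        if not ext:
            return 0.0
        # exchange reactions touch exactly one external species of interest
        return max(self.carbon[m] for m in ext)

    def validate(self) -> None:
        if self.n_reactions == 0:
            raise ModelFormatError("model declares no reactions")
        if len(set(self.reaction_ids)) != self.n_reactions:
            raise ModelFormatError("duplicate reaction id")
        if len(set(self.metabolite_ids)) != len(self.metabolite_ids):
            raise ModelFormatError("duplicate metabolite id")
        for rid, coeffs in zip(self.reaction_ids, self.stoichiometry):
            if not coeffs:
                raise ModelFormatError(f"reaction {rid} touches no metabolite")
            for met in coeffs:
                if met not in self.internal:
                    raise ModelFormatError(
                        f"reaction {rid} references undeclared metabolite {met!r}"
                    )
        for q, (j, sign) in self.exchange_map.items():
            if not 0 <= j < self.n_reactions:
                raise ModelFormatError(f"exchange entry {q!r} -> bad index {j}")
            if sign not in (-1.0, 1.0):
                raise ModelFormatError(f"exchange entry {q!r} has sign {sign}")


# ---------------------------------------------------------------------------
# equation parsing / formatting

def _parse_side(text: str) -> list[tuple[float, str]]:
    terms = []
    text = text.strip()
    if not text:
        return terms
    for part in text.split("+"):
        part = part.strip()
        if not part:
            raise ModelFormatError(f"empty term in equation side {text!r}")
        tokens = part.split()
        if len(tokens) == 1:
            terms.append((1.0, tokens[0]))
        elif len(tokens) == 2:
            try:
                coeff = float(tokens[0])
            except ValueError:
                raise ModelFormatError(f"bad coefficient in term {part!r}") from None
            terms.append((coeff, tokens[1]))
        else:
            raise ModelFormatError(f"cannot parse term {part!r}")
    return terms


def parse_equation(eq: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 A + B -> C"`` into ({A: -2, B: -1, C: 1}, reversible)."""
    m = _ARROW_RE.search(eq)
    if m is None:
        raise ModelFormatError(f"equation {eq!r} lacks an arrow")
    reversible = m.group(1) == "<->"
    lhs, rhs = eq[: m.start()], eq[m.end():]
    coeffs: dict[str, float] = {}
    for c, met in _parse_side(lhs):
        coeffs[met] = coeffs.get(met, 0.0) - c
    for c, met in _parse_side(rhs):
        coeffs[met] = coeffs.get(met, 0.0) + c
    coeffs = {m_: c for m_, c in coeffs.items() if c != 0.0}
    return coeffs, reversible


def _format_coeff(c: float) -> str:
    if c == int(c):
        return "" if c == 1 else f"{int(c)} "
    return f"{c:g} "


def format_equation(coeffs: Mapping[str, float], reversible: bool) -> str:
    lhs = [f"{_format_coeff(-c)}{m}" for m, c in coeffs.items() if c < 0]
    rhs = [f"{_format_coeff(c)}{m}" for m, c in coeffs.items() if c > 0]
    arrow = "<->" if reversible else "->"
    return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}".strip()


# ---------------------------------------------------------------------------
# reader / writer

def loads_model(text: str) -> MetabolicModel:
    section = None
    met_ids: list[str] = []
    internal: dict[str, bool] = {}
    carbon: dict[str, float] = {}
    rxn_ids: list[str] = []
    stoich: list[dict[str, float]] = []
    rev: list[bool] = []
    notes: dict[str, str] = {}
    exchange: dict[str, tuple[int, float]] = {}
    pending_exchange: list[tuple[str, str, float]] = []

    for raw in text.splitlines():
        line = raw.split("#", 1)[0].rstrip()
        if not line.strip():
            continue
        if line.strip().startswith("["):
            section = line.strip().strip("[]").lower()
            continue
        fields = [f.strip() for f in line.split("\t")]
        if section == "metabolites":
            if len(fields) < 3:
                raise ModelFormatError(f"bad metabolite line: {raw!r}")
            mid, role, carb = fields[0], fields[1].lower(), float(fields[2])
            if mid in internal:
                raise ModelFormatError(f"duplicate metabolite {mid!r}")
            if role not in ("internal", "external"):
                raise ModelFormatError(f"bad role {role!r} for {mid!r}")
            met_ids.append(mid)
            internal[mid] = role == "internal"
            carbon[mid] = carb
        elif section == "reactions":
            if len(fields) < 2:
                raise ModelFormatError(f"bad reaction line: {raw!r}")
            rid, eq = fields[0], fields[1]
            if rid in rxn_ids:
                raise ModelFormatError(f"duplicate reaction id {rid!r}")
            coeffs, is_rev = parse_equation(eq)
            rxn_ids.append(rid)
            stoich.append(coeffs)
            rev.append(is_rev)
            if len(fields) >= 3 and fields[2]:
                notes[rid] = fields[2]
        elif section == "exchange":
            if len(fields) < 3:
                raise ModelFormatError(f"bad exchange line: {raw!r}")
            pending_exchange.append((fields[0], fields[1], float(fields[2])))
        else:
            raise ModelFormatError(f"content outside a known section: {raw!r}")

    rid_to_idx = {rid: i for i, rid in enumerate(rxn_ids)}
    for qty, rid, sign in pending_exchange:
        if rid not in rid_to_idx:
            raise ModelFormatError(f"exchange {qty!r} references unknown reaction {rid!r}")
        exchange[qty] = (rid_to_idx[rid], sign)

    model = MetabolicModel(
        reaction_ids=rxn_ids,
        metabolite_ids=met_ids,
        internal=internal,
        carbon=carbon,
        stoichiometry=stoich,
        reversible=np.asarray(rev, dtype=bool),
        exchange_map=exchange,
        notes=notes,
    )
    model.validate()
    return model


def load_model(path: str | Path) -> MetabolicModel:
    """Read a model from a reaction-table file (see module docstring)."""
    return loads_model(Path(path).read_text())


def dumps_model(model: MetabolicModel) -> str:
    lines = ["[metabolites]"]
    for m in model.metabolite_ids:
        role = "internal" if model.internal[m] else "external"
        lines.append(f"{m}\t{role}\t{model.carbon[m]:g}")
    lines.append("")
    lines.append("[reactions]")
    for rid, coeffs, is_rev in zip(
        model.reaction_ids, model.stoichiometry, model.reversible
    ):
        eq = format_equation(coeffs, bool(is_rev))
        note = model.notes.get(rid, "")
        lines.append(f"{rid}\t{eq}\t{note}".rstrip())
    if model.exchange_map:
        lines.append("")
        lines.append("[exchange]")
        for qty, (j, sign) in model.exchange_map.items():
            lines.append(f"{qty}\t{model.reaction_ids[j]}\t{sign:g}")
    return "\n".join(lines) + "\n"


def save_model(model: MetabolicModel, path: str | Path) -> None:
    Path(path).write_text(dumps_model(model))


# ---------------------------------------------------------------------------
# structural properties

def _rank(M: np.ndarray) -> int:
    if M.size == 0:
        return 0
    s = np.linalg.svd(M, compute_uv=False)
    tol = max(M.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    return int(np.sum(s > tol))


def degrees_of_freedom(model: MetabolicModel) -> int:
    """Number of free flux directions: n - rank(N)."""
    return model.n_reactions - _rank(model.N)


def measurement_rank(
    model: MetabolicModel, measured: Iterable[int] | Sequence[Sequence[float]]
) -> int:
    """Independent constraints a measured-flux set adds beyond N·v = 0.

    ``measured`` is either a set of reaction indices (selector rows) or a
    matrix of measurement functionals (rows of coefficients over fluxes).
    Returns rank([N; E]) - rank(N); dependencies such as the closed carbon
    balance over the exchange fluxes lower the added rank.
    """
    n = model.n_reactions
    measured = list(measured)
    if measured and np.isscalar(measured[0]):
        E = np.zeros((len(measured), n))
        for r, j in enumerate(measured):
            E[r, int(j)] = 1.0
    else:
        E = np.asarray(measured, dtype=float).reshape(-1, n)
    N = model.N
    return _rank(np.vstack([N, E])) - _rank(N)


def check_steady_state(
    model: MetabolicModel, v: np.ndarray, tol: float = 1e-8
) -> tuple[bool, float]:
    """Test N·v = 0 and irreversibility within ``tol``; returns (ok, residual)."""
    if tol <= 0:
        raise ValueError("tol must be positive")
    v = np.asarray(v, dtype=float)
    if v.shape != (model.n_reactions,):
        raise ValueError(
            f"flux vector has shape {v.shape}, expected ({model.n_reactions},)"
        )
    resid = float(np.max(np.abs(model.N @ v))) if model.N.size else 0.0
    irrev_viol = 0.0
    idx = model.irreversible_indices
    if idx.size:
        irrev_viol = float(max(0.0, np.max(-v[idx])))
    return (resid <= tol and irrev_viol <= tol), max(resid, irrev_viol)


# ---------------------------------------------------------------------------
# shipped P. pastoris model

def pichia_model_path() -> Path:
    """Path of the shipped *P. pastoris* central-carbon reaction table."""
    return _DATA_DIR / "pichia_pastoris.tsv"


def load_pichia_model() -> MetabolicModel:
    """Load the shipped 44-reaction *P. pastoris* model."""
    return load_model(pichia_model_path())
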