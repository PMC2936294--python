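"""End-to-end validation study: elementary-mode census and yields,
per-dataset consistency (phi, pi, minimal full-consistency band),
experimental-vs-theoretical yields, leave-one-out growth prediction,
per-flux interval estimates and sign patterns, and random rejection
batteries.  Deterministic given the configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path


from .ems import classify_ems, enumerate_ems, max_yield_per_category
from .model import MetabolicModel, load_model, load_pichia_model
from .possibilistic import (
    DEFAULT_FULL_BAND,
    DEFAULT_REF_BAND,
    DEFAULT_REF_POSSIBILITY,
    DEFAULT_ZERO_FLOOR,
    MeasurementSet,
    estimate_excluded_flux,
    max_possibility,
    minimal_full_band,
    shape_measurement,
)
from .scenarios import (
    MEASURED_QUANTITIES,
    Scenario,
    experimental_yield,
    load_scenarios,
    to_measurements,
    yield_vs_theoretical,
)
from .synthetic import BATTERY_1, BATTERY_2, RandomBatterySpec, random_battery
from .wls import WlsSpec, wls_residual

__all__ = ["ValidationConfig", "ValidationReport", "run_validation", "flux_sign_report"]

#: splitting-node fluxes reported in the per-scenario sign table
SIGN_REPORT_FLUXES = ("v2", "v3", "v4", "v21", "v22", "v23", "v32", "v33", "v34")


@dataclass
class ValidationConfig:
    full_band: float = DEFAULT_FULL_BAND
    ref_band: float = DEFAULT_REF_BAND
    ref_possibility: float = DEFAULT_REF_POSSIBILITY
    zero_floor: float = DEFAULT_ZERO_FLOOR
    rel_sd: float = 0.10
    gammas: tuple[float, ...] = (0.8, 0.5, 0.1)
    conditional_intervals: bool = True
    battery_n: int = 500
    seed: int = 12345
    run_batteries: bool = True

    @classmethod
    def from_file(cls, path: str | Path) -> "ValidationConfig":
        """Read a key = value config file (unknown keys rejected)."""
        cfg = cls()
        fields = set(cfg.__dataclass_fields__)
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            if key not in fields:
                raise KeyError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.strip().lower() in ("1", "true", "yes"))
            elif isinstance(current, tuple):
                setattr(cfg, key, tuple(float(x) for x in value.split(",")))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            else:
                setattr(cfg, key, float(value))
        return cfg


@dataclass
class ValidationReport:
    em_counts: dict
    max_yields: dict
    scenarios: list[dict]
    growth_prediction: list[dict]
    flux_signs: list[dict]
    battery_rejection: dict

    def to_json(self) -> str:
        return json.dumps(
            {
                "em_counts": self.em_counts,
                "max_yields": self.max_yields,
                "scenarios": self.scenarios,
                "growth_prediction": self.growth_prediction,
                "flux_signs": self.flux_signs,
                "battery_rejection": self.battery_rejection,
            },
            indent=2,
            sort_keys=True,
        )


def _shape_kwargs(cfg: ValidationConfig) -> dict:
    return dict(
        full_band=cfg.full_band,
        ref_band=cfg.ref_band,
        ref_possibility=cfg.ref_possibility,
        zero_floor=cfg.zero_floor,
    )


def _battery_rejection(
    model: MetabolicModel, bounds: dict, cfg: ValidationConfig, seed: int
) -> float:
    rows = random_battery(
        RandomBatterySpec(bounds, n_datasets=cfg.battery_n, seed=seed)
    )
    n_reject = 0
    for row in rows:
        ms = MeasurementSet()
        for field_, q in MEASURED_QUANTITIES.items():
            j, sign = model.exchange_map[q]
            ms.add(
                shape_measurement(
                    j, row[field_], sign=sign, quantity=q, **_shape_kwargs(cfg)
                )
            )
        if max_possibility(model, ms).pi < 0.1:
            n_reject += 1
    return n_reject / len(rows)


def flux_sign_report(
    model: MetabolicModel,
    scenarios: list[Scenario],
    cfg: ValidationConfig | None = None,
    fluxes: tuple[str, ...] = SIGN_REPORT_FLUXES,
    tol: float = 1e-6,
) -> list[dict]:
    """Sign (+/-/0) of the most-possible value of selected fluxes, per
    scenario; the classic glycolysis / pentose-phosphate / methanol
    splitting nodes by default."""
    cfg = cfg or ValidationConfig()
    idx = {f: model.reaction_index(f) for f in fluxes}
    out = []
    for s in scenarios:
        ms = to_measurements(s, model, zero_floor=cfg.zero_floor)
        v = max_possibility(model, ms).v_mp
        row = {"id": s.id}
        for f, j in idx.items():
            x = v[j]
            row[f] = "0" if abs(x) <= tol else ("+" if x > 0 else "-")
        out.append(row)
    return out


def run_validation(
    model_path: str | Path | None = None,
    scenarios_path: str | Path | None = None,
    config: ValidationConfig | None = None,
    out_dir: str | Path | None = None,
) -> ValidationReport:
    """Run the full study and (optionally) write TSV/JSON reports."""
    cfg = config or ValidationConfig()
    model = load_model(model_path) if model_path else load_pichia_model()
    scenarios = load_scenarios(scenarios_path) if scenarios_path else load_scenarios()

    ems = enumerate_ems(model)
    counts = classify_ems(ems, model)
    maxy = max_yield_per_category(ems, model)
    max_yields = {
        "+".join(sorted(k)): {"yield": y, "mode": i} for k, (y, i) in maxy.items()
    }

    scen_rows = []
    growth_rows = []
    jbio = model.exchange_map["biomass"][0]
    for s in scenarios:
        ms = to_measurements(s, model, zero_floor=cfg.zero_floor, **{
            k: v for k, v in _shape_kwargs(cfg).items() if k != "zero_floor"
        })
        mp = max_possibility(model, ms)
        band = minimal_full_band(model, ms, zero_floor=cfg.zero_floor)
        phi = wls_residual(
            model, ms, WlsSpec(rel_sd=cfg.rel_sd, zero_floor=cfg.zero_floor)
        ).phi
        yrec = yield_vs_theoretical(s, ems, model)
        scen_rows.append(
            {
                "id": s.id,
                "phi": round(phi, 4),
                "pi": round(mp.pi, 4),
                "band_to_full": round(band, 4),
                "yield_exp": round(yrec["experimental"], 4),
                "yield_theo_max": round(yrec["theoretical_max"], 4),
                "yield_violated": yrec["violated"],
            }
        )
        ms_nomu = ms.drop("biomass")
        vmp, intervals = estimate_excluded_flux(
            model, ms_nomu, jbio, gammas=cfg.gammas,
            conditional=cfg.conditional_intervals,
        )
        row = {"id": s.id, "mu_measured": s.mu, "mu_estimate": round(vmp, 4)}
        for g, iv in zip(cfg.gammas, intervals):
            row[f"lo_{g:g}"] = round(iv.lower, 4)
            row[f"hi_{g:g}"] = round(iv.upper, 4)
        g_last = cfg.gammas[-1]
        row["measured_inside"] = bool(
            row[f"lo_{g_last:g}"] - 1e-9 <= s.mu <= row[f"hi_{g_last:g}"] + 1e-9
        )
        growth_rows.append(row)

    signs = flux_sign_report(model, scenarios, cfg)

    battery = {}
    if cfg.run_batteries:
        battery["battery1_reject_fraction"] = _battery_rejection(
            model, BATTERY_1, cfg, cfg.seed
        )
        battery["battery2_reject_fraction"] = _battery_rejection(
            model, BATTERY_2, cfg, cfg.seed + 1
        )

    report = ValidationReport(
        em_counts=counts,
        max_yields=max_yields,
        scenarios=scen_rows,
        growth_prediction=growth_rows,
        flux_signs=signs,
        battery_rejection=battery,
    )
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _tsv(path: Path, rows: list[dict]) -> None:
    if not rows:
        path.write_text("")
        return
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for r in rows:
        lines.append("\t".join(str(r[c]) for c in cols))
    path.write_text("\n".join(lines) + "\n")


def _write_report(report: ValidationReport, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    _tsv(out_dir / "table2_consistency.tsv", report.scenarios)
    _tsv(out_dir / "growth_prediction.tsv", report.growth_prediction)
    _tsv(out_dir / "flux_signs.tsv", report.flux_signs)
    yield_rows = [
        {"substrates": k, "max_yield": round(v["yield"], 4), "mode": v["mode"]}
        for k, v in sorted(report.max_yields.items())
    ]
    _tsv(out_dir / "table1_yields.tsv", yield_rows)
    (out_dir / "report.json").write_text(report.to_json())
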