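"""Pipeline orchestration: correct -> quench -> bind -> thermo -> classify -> report.

``run_pipeline`` executes the full titration analysis and returns a
:class:`PipelineReport` whose JSON form validates against
:class:`ReportSchema` (a pydantic model; its JSON Schema is exported by
:func:`report_json_schema`).  ``render_table`` prints the per-temperature
summary in the conventional scaled units (K_sv x10^4 L/mol, K_q x10^12
L/mol/s, K_A x10^4 L/mol, dH and dG in kJ/mol, dS in J/mol/K).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import __version__ as _version
from .binding import BindingFit, classify_strength, fit_double_log
from .data_model_io import (
    AbsorbanceRecord,
    TitrationSeries,
    load_titration,
)
from .errors import QuenchBindError, StageError
from .inner_filter import correct_series
from .quenching import (
    DEFAULT_TAU0,
    MechanismCall,
    QuenchingFit,
    classify_mechanism,
    fit_stern_volmer,
)
from .thermodynamics import ThermoConstants, VantHoffFit, fit_vant_hoff

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineOptions:
    """Everything tunable about a pipeline run; echoed into provenance."""

    tau0: float = DEFAULT_TAU0
    constrain_intercept: bool = False
    skip_ife: bool = False  # analyse observed intensities, log the choice
    paper_faithful: bool = False  # 2.303 instead of ln 10 in thermodynamics
    ka_override: Mapping[float, float] | None = None  # skip binding, use published K_A
    seed: int | None = None  # recorded when the input is synthetic


@dataclass(frozen=True)
class PipelineReport:
    quenching: tuple[QuenchingFit, ...]
    binding: tuple[BindingFit, ...]
    mechanism: MechanismCall
    vant_hoff: VantHoffFit | None
    provenance: dict


class _QuenchingModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ksv: float
    intercept: float
    kq: float
    tau0: float
    r_squared: float
    temperature: float
    n_points: int
    used_corrected: bool
    mechanism: str | None = None


class _BindingModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    ka: float
    n: float
    r_squared: float
    temperature: float
    n_points: int
    strength_band: str


class _MechanismModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    label: str
    kq_rule: str
    corroboration: list[str]


class _VantHoffModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    delta_h: float
    delta_s: float
    r_squared: float
    gibbs_by_temp: dict[str, float]
    force_label: str
    spontaneous: bool
    exothermic: bool


class ReportSchema(BaseModel):
    """Published schema of the pipeline's JSON report."""

    model_config = ConfigDict(extra="forbid")
    provenance: dict
    quenching: list[_QuenchingModel]
    binding: list[_BindingModel]
    mechanism: _MechanismModel
    vant_hoff: _VantHoffModel | None


def report_json_schema() -> dict:
    """JSON Schema of the report, for external validators."""
    return ReportSchema.model_json_schema()


def report_to_dict(report: PipelineReport) -> dict:
    d = {
        "provenance": dict(report.provenance),
        "quenching": [dataclasses.asdict(f) for f in report.quenching],
        "binding": [dataclasses.asdict(f) for f in report.binding],
        "mechanism": {
            "label": report.mechanism.label,
            "kq_rule": report.mechanism.kq_rule,
            "corroboration": list(report.mechanism.corroboration),
        },
        "vant_hoff": None,
    }
    if report.vant_hoff is not None:
        vh = dataclasses.asdict(report.vant_hoff)
        vh["gibbs_by_temp"] = {str(t): g for t, g in report.vant_hoff.gibbs_by_temp.items()}
        d["vant_hoff"] = vh
    ReportSchema.model_validate(d)
    return d


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False

    return _Ctx()


def _load_absorbance_csv(path: str | Path) -> dict[float, list[AbsorbanceRecord]]:
    df = pd.read_csv(path)
    recs: dict[float, list[AbsorbanceRecord]] = {}
    for temp, grp in df.groupby("temperature_K", sort=True):
        grp = grp.sort_values("quencher_conc_M")
        recs[float(temp)] = [
            AbsorbanceRecord(
                a_ex=float(r["a_ex"]),
                a_em=float(r["a_em"]),
                d_ex=float(r.get("d_ex", 1.0)),
                d_em=float(r.get("d_em", 1.0)),
            )
            for _, r in grp.iterrows()
        ]
    return recs


def run_pipeline(
    titration: str | Path | Sequence[TitrationSeries],
    absorbance: str | Path | Mapping[float, Sequence[AbsorbanceRecord]] | None = None,
    options: PipelineOptions | None = None,
) -> PipelineReport:
    """Run the full analysis on a titration table.

    ``titration`` is a long-format CSV path or already-validated series.
    ``absorbance`` supplies per-point absorbance records keyed by
    temperature (CSV path or mapping); without it, and unless
    ``options.skip_ife``, the run proceeds on observed intensities and the
    report records that no correction was applied.
    """
    opts = options or PipelineOptions()

    with _stage("data_model_io"):
        if isinstance(titration, (str, Path)):
            series = load_titration(titration)
            source = str(titration)
        else:
            series = list(titration)
            source = "<in-memory>"
            if not series:
                raise QuenchBindError("empty titration input")
            for s in series:
                s.validate()

    with _stage("inner_filter"):
        abs_by_temp: Mapping[float, Sequence[AbsorbanceRecord]] | None
        if isinstance(absorbance, (str, Path)):
            abs_by_temp = _load_absorbance_csv(absorbance)
        else:
            abs_by_temp = absorbance
        ife_applied = abs_by_temp is not None and not opts.skip_ife
        corrected = []
        for s in series:
            if ife_applied:
                corrected.append(correct_series(s, abs_by_temp[s.temperature]))
            else:
                corrected.append(correct_series(s, no_ife=True))
        series = corrected

    with _stage("quenching"):
        qfits = [
            fit_stern_volmer(s, constrain_intercept=opts.constrain_intercept, tau0=opts.tau0)
            for s in series
        ]

    with _stage("binding"):
        if opts.ka_override is not None:
            ka_by_temp = {float(t): float(k) for t, k in opts.ka_override.items()}
            bfits = []
        else:
            bfits = [fit_double_log(s) for s in series]
            ka_by_temp = {f.temperature: f.ka for f in bfits}

    with _stage("thermodynamics"):
        constants = (
            ThermoConstants.paper_faithful() if opts.paper_faithful else ThermoConstants()
        )
        vh = fit_vant_hoff(ka_by_temp, constants) if len(ka_by_temp) >= 2 else None
        if vh is None:
            logger.info("single temperature: van't Hoff analysis skipped")

    with _stage("classification"):
        mech = classify_mechanism(qfits, ka_by_temp=ka_by_temp or None)
        qfits = [dataclasses.replace(f, mechanism=mech.label) for f in qfits]

    provenance = {
        "software": f"quenchbind {_version}",
        "input": source,
        "ife_applied": ife_applied,
        "log_base_mode": "2.303" if opts.paper_faithful else "ln10",
        "options": {
            "tau0": opts.tau0,
            "constrain_intercept": opts.constrain_intercept,
            "skip_ife": opts.skip_ife,
            "paper_faithful": opts.paper_faithful,
            "ka_override": (
                None
                if opts.ka_override is None
                else {str(t): v for t, v in opts.ka_override.items()}
            ),
            "seed": opts.seed,
        },
    }
    return PipelineReport(
        quenching=tuple(qfits),
        binding=tuple(bfits),
        mechanism=mech,
        vant_hoff=vh,
        provenance=provenance,
    )


def report_rows(report: PipelineReport) -> list[dict]:
    """Per-temperature summary rows in SI units (the result-CSV layout)."""
    q_by_t = {f.temperature: f for f in report.quenching}
    b_by_t = {f.temperature: f for f in report.binding}
    ka_over = report.provenance["options"].get("ka_override") or {}
    temps = sorted(set(q_by_t) | set(b_by_t) | {float(t) for t in ka_over})
    vh = report.vant_hoff
    rows = []
    for t in temps:
        q = q_by_t.get(t)
        b = b_by_t.get(t)
        rows.append(
            {
                "temperature_K": t,
                "ksv_L_per_mol": q.ksv if q else None,
                "kq_L_per_mol_s": q.kq if q else None,
                "ka_L_per_mol": b.ka if b else (float(ka_over.get(str(t))) if str(t) in ka_over else None),
                "n_sites": b.n if b else None,
                "delta_h_J_per_mol": vh.delta_h if vh else None,
                "delta_s_J_per_mol_K": vh.delta_s if vh else None,
                "delta_g_J_per_mol": vh.gibbs_by_temp.get(t) if vh else None,
            }
        )
    return rows


def _fmt(value: float | None, scale: float, sig_figs: int) -> str:
    if value is None:
        return "-"
    return f"{value / scale:.{sig_figs}g}"


def render_table(report: PipelineReport, sig_figs: int = 3) -> str:
    """Fixed-column text table in the conventional scaled units."""
    header = (
        "T (K)",
        "K_sv (x10^4 L/mol)",
        "K_q (x10^12 L/mol/s)",
        "K_A (x10^4 L/mol)",
        "n",
        "dH (kJ/mol)",
        "dS (J/mol/K)",
        "dG (kJ/mol)",
    )
    scales = (1.0, 1e4, 1e12, 1e4, 1.0, 1e3, 1.0, 1e3)
    lines = ["\t".join(header)]
    for row in report_rows(report):
        vals = (
            row["temperature_K"],
            row["ksv_L_per_mol"],
            row["kq_L_per_mol_s"],
            row["ka_L_per_mol"],
            row["n_sites"],
            row["delta_h_J_per_mol"],
            row["delta_s_J_per_mol_K"],
            row["delta_g_J_per_mol"],
        )
        lines.append("\t".join(_fmt(v, s, sig_figs) for v, s in zip(vals, scales)))
    return "\n".join(lines)


def write_report(report: PipelineReport, base_path: str | Path) -> None:
    """Serialise the report: ``<base>.json`` (full) and ``<base>.csv`` (rows)."""
    from .data_model_io import RESULT_COLUMNS

    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    full = report_to_dict(report)
    base.with_suffix(".json").write_text(json.dumps(full, indent=2, default=float))
    pd.DataFrame(report_rows(report), columns=RESULT_COLUMNS).to_csv(
        base.with_suffix(".csv"), index=False
    )
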