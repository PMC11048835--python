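"""Synthetic titration generator with known ground truth.

Emulates the study design the analysis assumes: a 10 uM protein titrated
with ligand at molar ratios 0-10 (grid 0,1,2,3,4,5,6,8,10), read at 290,
300 and 310 K.  Quenching is purely static: the ground-state complex makes
the quenched fraction

    (F_0 - F)/F = (K_A [Q]_free)^n,

with K_A(T) generated from van't Hoff parameters (dH, dS), the free-ligand
concentration solved self-consistently against depletion by the protein,
Beer-Lambert inner-filter attenuation applied from ligand molar
absorptivities, and multiplicative Gaussian noise applied last.  Each
reported intensity is the mean of ``replicates`` noisy readings, matching
the triplicate measurement protocol typical of these titrations.

Because the generator is exactly the model family the analysis fits, a
zero-noise simulation is an inverse crime: the pipeline must recover the
true parameters to numerical precision, which is the intended oracle.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_model_io import (
    AbsorbanceRecord,
    EmissionSpectrum,
    TitrationPoint,
    TitrationSeries,
    titration_to_frame,
)
from .errors import SolverError, ValidationError
from .inner_filter import attenuation_exponent, records_from_epsilons
from .thermodynamics import ThermoConstants


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters and noise model for synthetic titrations.

    Defaults are the study conditions: 1e-5 M protein, the 0-10 molar-ratio
    grid, 290/300/310 K, and van't Hoff parameters (dH=-1368 J/mol,
    dS=85.72 J/mol/K) chosen so K_A(290 K) ~ 5.29e4 L/mol with a weakly
    decreasing K_A(T) (static-quenching regime).  ``ka_true`` overrides the
    van't Hoff generation with explicit per-temperature constants.
    ``eps_ex``/``eps_em`` of 0 disable the inner-filter effect.
    """

    protein_conc: float = 1e-5  # mol/L
    molar_ratios: tuple[float, ...] = (0, 1, 2, 3, 4, 5, 6, 8, 10)
    temperatures: tuple[float, ...] = (290.0, 300.0, 310.0)
    delta_h_true: float = -1368.0  # J/mol
    delta_s_true: float = 85.72  # J mol^-1 K^-1
    ka_true: Mapping[float, float] | None = None  # direct override, L/mol
    n_true: float = 1.19  # binding sites
    f0: float = 1000.0  # unquenched intensity, a.u.
    eps_ex: float = 0.0  # ligand molar absorptivity at excitation, L mol^-1 cm^-1
    eps_em: float = 0.0  # at emission
    d_ex: float = 1.0  # cm
    d_em: float = 1.0  # cm
    noise_sd: float = 0.0  # relative (multiplicative Gaussian) noise per reading
    replicates: int = 3  # readings averaged per point (triplicate protocol)
    seed: int = 0
    # optional dilution bookkeeping of the 500 uM-stock titration design
    track_dilution: bool = False
    stock_conc: float = 5e-4  # mol/L ligand stock
    initial_volume_l: float = 4e-3  # L of protein solution titrated

    def validate(self) -> None:
        if not (self.protein_conc > 0 and self.f0 > 0):
            raise ValidationError("protein_conc and f0 must be > 0")
        if not (self.d_ex > 0 and self.d_em > 0):
            raise ValidationError("path lengths must be > 0")
        if self.noise_sd < 0 or self.eps_ex < 0 or self.eps_em < 0:
            raise ValidationError("noise_sd and absorptivities must be >= 0")
        if self.replicates < 1:
            raise ValidationError("replicates must be >= 1")
        r = self.molar_ratios
        if len(r) < 2 or r[0] != 0 or any(b <= a for a, b in zip(r, r[1:])):
            raise ValidationError("molar_ratios must start at 0 and strictly increase")
        if self.n_true <= 0:
            raise ValidationError("n_true must be > 0")


@dataclass(frozen=True)
class SimulationResult:
    """Series, paired per-point absorbance records, and the truth manifest."""

    series: tuple[TitrationSeries, ...]
    absorbances: tuple[tuple[AbsorbanceRecord, ...], ...]  # aligned with series
    manifest: dict


def ka_at_temperature(
    delta_h: float, delta_s: float, t: float, constants: ThermoConstants | None = None
) -> float:
    """Binding constant from van't Hoff parameters:
    K_A = 10^(-dH/(c R T) + dS/(c R)), c = ln 10."""
    if not t > 0:
        raise ValidationError(f"temperature must be > 0 K, got {t}")
    c = constants or ThermoConstants()
    return 10.0 ** (-delta_h / (c.decadic * c.r_gas * t) + delta_s / (c.decadic * c.r_gas))


def solve_free_ligand(
    q_total: float,
    p: float,
    ka: float,
    n: float,
    *,
    tol: float = 1e-12,
    max_iter: int = 200,
    damping: float = 0.5,
) -> tuple[float, float]:
    """Self-consistent free-ligand concentration under protein depletion.

    Solves Q_free = Q_total - p*theta with the bound fraction
    theta = (K_A Q_free)^n / (1 + (K_A Q_free)^n) by damped fixed-point
    iteration to |dQ_free|/Q_total <= tol.  Returns (q_free, theta).
    """
    if q_total < 0 or p < 0 or ka < 0 or n <= 0:
        raise ValidationError(
            f"need q_total, p, ka >= 0 and n > 0; got {q_total}, {p}, {ka}, {n}"
        )
    if q_total == 0 or ka == 0:
        return q_total, 0.0
    q_free = q_total
    for _ in range(max_iter):
        x = (ka * q_free) ** n
        theta = x / (1.0 + x)
        target = max(q_total - p * theta, 1e-30)
        step = target - q_free
        if abs(step) / q_total <= tol:
            return target, theta
        q_free = q_free + damping * step
    raise SolverError(
        f"free-ligand iteration did not converge (q_total={q_total}, p={p}, "
        f"ka={ka}, n={n})"
    )


def true_ka_by_temp(config: SimulationConfig) -> dict[float, float]:
    """Ground-truth K_A at each configured temperature."""
    if config.ka_true is not None:
        return {float(t): float(config.ka_true[t]) for t in config.temperatures}
    return {
        float(t): ka_at_temperature(config.delta_h_true, config.delta_s_true, t)
        for t in config.temperatures
    }


def _concentrations(config: SimulationConfig, ratio: float) -> tuple[float, float]:
    """(q_total, protein_conc) for one molar ratio, optionally tracking the
    dilution caused by adding ligand stock to the cuvette."""
    if not config.track_dilution:
        return ratio * config.protein_conc, config.protein_conc
    n_protein = config.protein_conc * config.initial_volume_l  # mol
    n_ligand = ratio * n_protein
    v_added = n_ligand / config.stock_conc
    v_total = config.initial_volume_l + v_added
    return n_ligand / v_total, n_protein / v_total


def simulate_titration(config: SimulationConfig) -> SimulationResult:
    """Generate noisy observed titrations with paired absorbance records.

    Deterministic in ``config.seed``: one child random stream per
    temperature, so adding a temperature does not perturb the others.
    """
    config.validate()
    ka_by_t = true_ka_by_temp(config)
    streams = np.random.SeedSequence(config.seed).spawn(len(config.temperatures))
    all_series: list[TitrationSeries] = []
    all_abs: list[tuple[AbsorbanceRecord, ...]] = []
    for t, ss in zip(config.temperatures, streams):
        rng = np.random.default_rng(ss)
        ka = ka_by_t[float(t)]
        points = []
        q_totals = []
        for ratio in config.molar_ratios:
            q_total, p_conc = _concentrations(config, ratio)
            q_free, _theta = solve_free_ligand(q_total, p_conc, ka, config.n_true)
            x = (ka * q_free) ** config.n_true if q_free > 0 else 0.0
            f_true = config.f0 / (1.0 + x)
            rec = AbsorbanceRecord(
                a_ex=config.eps_ex * q_total * config.d_ex,
                a_em=config.eps_em * q_total * config.d_em,
                d_ex=config.d_ex,
                d_em=config.d_em,
            )
            f_att = f_true * 10.0 ** (-attenuation_exponent(rec))
            readings = f_att * (
                1.0 + config.noise_sd * rng.standard_normal(config.replicates)
            )
            f_obs = float(np.mean(readings))
            if f_obs <= 0:
                raise SolverError(
                    f"noise drove intensity non-positive at ratio {ratio}, T={t} K; "
                    "noise_sd too large for this signal"
                )
            points.append(TitrationPoint(quencher_conc=q_total, f_obs=f_obs))
            q_totals.append(q_total)
        series = TitrationSeries(
            temperature=float(t),
            protein_conc=_concentrations(config, 0)[1],
            points=points,
        )
        series.validate()
        all_series.append(series)
        all_abs.append(
            tuple(
                records_from_epsilons(
                    q_totals, config.eps_ex, config.eps_em, config.d_ex, config.d_em
                )
            )
        )
    manifest = {
        "model": "static quenching, (F0-F)/F = (KA*Qfree)^n with ligand depletion",
        "config": {
            k: (dict(v) if isinstance(v, Mapping) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "ka_true_by_temperature": {str(t): ka for t, ka in ka_by_t.items()},
    }
    return SimulationResult(
        series=tuple(all_series), absorbances=tuple(all_abs), manifest=manifest
    )


def write_simulation(result: SimulationResult, out_dir: str | Path) -> dict[str, Path]:
    """Write titration CSV, absorbance CSV and ground-truth manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "titration": out / "titration.csv",
        "absorbance": out / "absorbance.csv",
        "manifest": out / "manifest.json",
    }
    titration_to_frame(result.series).to_csv(paths["titration"], index=False)
    rows = []
    for s, recs in zip(result.series, result.absorbances):
        for p, rec in zip(s.points, recs):
            rows.append(
                {
                    "temperature_K": s.temperature,
                    "quencher_conc_M": p.quencher_conc,
                    "a_ex": rec.a_ex,
                    "a_em": rec.a_em,
                    "d_ex": rec.d_ex,
                    "d_em": rec.d_em,
                }
            )
    pd.DataFrame(rows).to_csv(paths["absorbance"], index=False)
    paths["manifest"].write_text(json.dumps(result.manifest, indent=2))
    return paths


def gaussian_band(
    center_nm: float = 330.0,
    width_nm: float = 25.0,
    amplitude: float = 1000.0,
    grid: Sequence[float] | None = None,
) -> EmissionSpectrum:
    """A single Gaussian emission band on a 290-450 nm grid.

    Only used to exercise fixed-wavelength intensity extraction; no attempt
    at realistic protein lineshapes.
    """
    w = np.asarray(grid if grid is not None else np.arange(290.0, 450.5, 1.0))
    i = amplitude * np.exp(-0.5 * ((w - center_nm) / width_nm) ** 2)
    return EmissionSpectrum(wavelengths=tuple(w), intensities=tuple(i))


def simulate_assay_tables(
    seed: int, noise_sd: float = 0.0, n_curve_points: int = 8
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Deterministic assay fixture tables with embedded ground truth.

    The Folin-Ciocalteu calibration points are drawn from the reference line
    y = 9.935 x + 0.1077 (absorbance vs mg/mL) with optional multiplicative
    noise on the absorbances; the remaining tables carry plain record
    columns for the calculators.  Returns (tables, truth).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    slope_true, intercept_true = 9.935, 0.1077
    conc = np.linspace(0.0, 0.1, n_curve_points)
    absorb = slope_true * conc + intercept_true
    if noise_sd > 0:
        absorb = absorb * (1.0 + noise_sd * rng.standard_normal(len(absorb)))
    tables = {
        "standard_curve": pd.DataFrame({"conc_mg_ml": conc, "absorbance": absorb}),
        "grafting": pd.DataFrame(
            {"c_sample_mg_ml": [0.824, 0.347, 0.1682], "c_reactant_mg_ml": [1.0, 1.0, 1.0]}
        ),
        "dpph": pd.DataFrame({"a0": [0.8, 0.8], "a1": [0.05, 0.0], "a2": [0.65, 0.4]}),
        "solubility": pd.DataFrame({"soluble": [7.5, 10.0], "total": [10.0, 10.0]}),
        "foam": pd.DataFrame({"v0_ml": [15.0], "v_ml": [30.0], "v30_ml": [22.5]}),
        "emulsion": pd.DataFrame(
            {
                "a0": [0.5],
                "a10": [0.4],
                "df": [100.0],
                "l_m": [0.01],
                "phi": [0.25],
                "c_g_ml": [0.001],
            }
        ),
        "digestion": pd.DataFrame({"c_digesta": [0.6], "c_initial": [0.8]}),
    }
    truth = {
        "standard_curve": {"slope": slope_true, "intercept": intercept_true},
        "grafting_pct": [82.4, 34.7, 16.82],
        "dpph_pct_blank_corrected": [25.0, 50.0],
        "solubility_pct": [75.0, 100.0],
        "foam_fe_fs_pct": [200.0, 150.0],
        "emulsion_esi_min": 50.0,
        "digestion_pct": 75.0,
    }
    return tables, truth
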