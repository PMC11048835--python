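"""Domain types for fluorescence titrations and the tabular I/O they share.

A titration experiment is stored long-format: one row per (temperature,
quencher concentration) with the observed emission intensity at the analysis
wavelength.  Each temperature's rows form a :class:`TitrationSeries`; the
zero-quencher row is mandatory and defines ``F_0``, so the provenance of the
reference intensity stays in the data rather than in metadata.

All concentrations are mol/L internally; temperatures are kelvin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

#: canonical long-format column names (logical name -> CSV header)
DEFAULT_SCHEMA: dict[str, str] = {
    "temperature": "temperature_K",
    "protein_conc": "protein_conc_M",
    "quencher_conc": "quencher_conc_M",
    "f_obs": "f_obs",
    "f_cor": "f_cor",  # optional on input
}

#: result-table column order, mirroring the conventional per-temperature
#: summary (K_sv, K_q, K_A, n, then the thermodynamic block)
RESULT_COLUMNS = [
    "temperature_K",
    "ksv_L_per_mol",
    "kq_L_per_mol_s",
    "ka_L_per_mol",
    "n_sites",
    "delta_h_J_per_mol",
    "delta_s_J_per_mol_K",
    "delta_g_J_per_mol",
]


@dataclass(frozen=True)
class TitrationPoint:
    """One titration point: quencher concentration and emission intensity."""

    quencher_conc: float  # [Q], mol/L
    f_obs: float  # observed intensity, arbitrary units
    f_cor: float | None = None  # inner-filter-corrected intensity

    def validate(self) -> None:
        if not self.quencher_conc >= 0:
            raise ValidationError(f"quencher_conc must be >= 0, got {self.quencher_conc}")
        if not self.f_obs > 0:
            raise ValidationError(f"f_obs must be > 0, got {self.f_obs}")
        if self.f_cor is not None and not self.f_cor > 0:
            raise ValidationError(f"f_cor must be > 0 when set, got {self.f_cor}")

    @property
    def intensity(self) -> float:
        """Corrected intensity when available, observed otherwise."""
        return self.f_obs if self.f_cor is None else self.f_cor


@dataclass(frozen=True)
class TitrationSeries:
    """An ordered single-temperature titration.

    Invariants: points sorted by strictly increasing ``quencher_conc``, the
    first point at ``quencher_conc == 0`` (it defines ``F_0``), and
    ``protein_conc > 0``.
    """

    temperature: float  # K
    protein_conc: float  # [P], mol/L
    points: tuple[TitrationPoint, ...]

    def __post_init__(self):
        object.__setattr__(self, "points", tuple(self.points))

    def validate(self) -> None:
        if not self.protein_conc > 0:
            raise ValidationError(f"protein_conc must be > 0, got {self.protein_conc}")
        if not self.temperature > 0:
            raise ValidationError(f"temperature must be > 0 K, got {self.temperature}")
        if len(self.points) == 0:
            raise ValidationError("series has no points")
        for p in self.points:
            p.validate()
        q = [p.quencher_conc for p in self.points]
        if q[0] != 0:
            raise ValidationError(
                f"series at T={self.temperature} K lacks a zero-quencher point (F_0)"
            )
        if any(b <= a for a, b in zip(q, q[1:])):
            raise ValidationError(
                f"quencher_conc not strictly increasing in series at T={self.temperature} K"
            )

    @property
    def f0(self) -> float:
        """Reference intensity of the zero-quencher point (corrected if set)."""
        return self.points[0].intensity

    @property
    def quencher_concs(self) -> np.ndarray:
        return np.array([p.quencher_conc for p in self.points])

    @property
    def intensities(self) -> np.ndarray:
        return np.array([p.intensity for p in self.points])

    @property
    def is_corrected(self) -> bool:
        return all(p.f_cor is not None for p in self.points)

    def with_points(self, points: Sequence[TitrationPoint]) -> "TitrationSeries":
        return replace(self, points=tuple(points))


@dataclass(frozen=True)
class AbsorbanceRecord:
    """Absorbances and path lengths at excitation/emission wavelengths."""

    a_ex: float
    a_em: float
    d_ex: float = 1.0  # cm, standard cuvette
    d_em: float = 1.0  # cm

    def validate(self) -> None:
        if self.a_ex < 0 or self.a_em < 0:
            raise ValidationError(f"absorbances must be >= 0, got {self.a_ex}, {self.a_em}")
        if not (self.d_ex > 0 and self.d_em > 0):
            raise ValidationError(f"path lengths must be > 0, got {self.d_ex}, {self.d_em}")


@dataclass(frozen=True)
class EmissionSpectrum:
    """An emission scan on a strictly increasing wavelength grid (nm)."""

    wavelengths: tuple[float, ...]
    intensities: tuple[float, ...]

    def __post_init__(self):
        object.__setattr__(self, "wavelengths", tuple(self.wavelengths))
        object.__setattr__(self, "intensities", tuple(self.intensities))

    def validate(self) -> None:
        if len(self.wavelengths) != len(self.intensities):
            raise ValidationError("wavelengths and intensities differ in length")
        w = self.wavelengths
        if any(b <= a for a, b in zip(w, w[1:])):
            raise ValidationError("wavelengths must be strictly increasing")


def intensity_at_analysis_wavelength(spectrum: EmissionSpectrum, wavelength: float) -> float:
    """Linearly interpolate the spectrum at the analysis wavelength.

    The analysis wavelength is held fixed across a titration (conventionally
    the emission maximum of the zero-quencher scan) so that peak shifts on
    binding are not conflated with quenching.
    """
    spectrum.validate()
    w = spectrum.wavelengths
    if not (w[0] <= wavelength <= w[-1]):
        raise ValidationError(
            f"wavelength {wavelength} nm outside spectrum range [{w[0]}, {w[-1]}] nm"
        )
    return float(np.interp(wavelength, w, spectrum.intensities))


def _require_columns(df: pd.DataFrame, schema: Mapping[str, str], keys: Sequence[str]) -> None:
    missing = [schema[k] for k in keys if schema[k] not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}; found {list(df.columns)}")


def load_titration(
    path: str | Path, schema: Mapping[str, str] | None = None
) -> list[TitrationSeries]:
    """Read a long-format titration CSV into validated per-temperature series.

    Parameters
    ----------
    path
        CSV with one row per titration point (UTF-8, '.' decimal).
    schema
        Logical-name -> column-header mapping overriding
        :data:`DEFAULT_SCHEMA`.

    Returns
    -------
    One :class:`TitrationSeries` per distinct temperature, sorted by
    temperature.  Each series must contain a zero-quencher row.
    """
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    df = pd.read_csv(path)
    _require_columns(df, sch, ["temperature", "protein_conc", "quencher_conc", "f_obs"])

    has_fcor = sch["f_cor"] in df.columns
    series: list[TitrationSeries] = []
    for temp, grp in df.groupby(sch["temperature"], sort=True):
        grp = grp.sort_values(sch["quencher_conc"])
        pconc = grp[sch["protein_conc"]].unique()
        if len(pconc) != 1:
            raise ValidationError(
                f"multiple protein concentrations {pconc.tolist()} at T={temp} K"
            )
        pts = []
        for _, row in grp.iterrows():
            fcor = row[sch["f_cor"]] if has_fcor else None
            if fcor is not None and (isinstance(fcor, float) and math.isnan(fcor)):
                fcor = None
            pts.append(
                TitrationPoint(
                    quencher_conc=float(row[sch["quencher_conc"]]),
                    f_obs=float(row[sch["f_obs"]]),
                    f_cor=None if fcor is None else float(fcor),
                )
            )
        qs = [p.quencher_conc for p in pts]
        if len(set(qs)) != len(qs):
            raise ValidationError(f"duplicate quencher_conc values at T={temp} K")
        if not any(q == 0 for q in qs):
            raise ValidationError(f"no zero-quencher row (F_0) for temperature {temp} K")
        s = TitrationSeries(temperature=float(temp), protein_conc=float(pconc[0]), points=pts)
        s.validate()
        series.append(s)
    return series


def titration_to_frame(
    series: Sequence[TitrationSeries], schema: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Flatten series back to the long-format table (inverse of loading)."""
    sch = dict(DEFAULT_SCHEMA)
    if schema:
        sch.update(schema)
    rows = []
    for s in series:
        for p in s.points:
            rows.append(
                {
                    sch["temperature"]: s.temperature,
                    sch["protein_conc"]: s.protein_conc,
                    sch["quencher_conc"]: p.quencher_conc,
                    sch["f_obs"]: p.f_obs,
                    sch["f_cor"]: p.f_cor,
                }
            )
    df = pd.DataFrame(rows)
    if df[sch["f_cor"]].isna().all():
        df = df.drop(columns=[sch["f_cor"]])
    return df


def write_results(results, path: str | Path, meta: Mapping | None = None) -> None:
    """Write pipeline results as a JSON report plus a summary CSV.

    ``results`` is a sequence of per-temperature row mappings using
    :data:`RESULT_COLUMNS` keys (extra keys are preserved in the JSON).
    ``path`` is a base path; ``<base>.json`` and ``<base>.csv`` are written.
    """
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    rows = [dict(r) for r in results]
    report = {"meta": dict(meta) if meta else {}, "rows": rows}
    base.with_suffix(".json").write_text(json.dumps(report, indent=2, default=float))
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(base.with_suffix(".csv"), index=False)


def read_results(path: str | Path) -> dict:
    """Read back a JSON report written by :func:`write_results`."""
    return json.loads(Path(path).with_suffix(".json").read_text())
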