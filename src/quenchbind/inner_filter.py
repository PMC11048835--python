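"""Inner-filter effect (IFE) correction for fluorescence titrations.

When the titrant absorbs at the excitation or emission wavelength, the
observed fluorescence is attenuated beyond any true quenching.  The standard
multiplicative correction restores the signal from the absorbances measured
at both wavelengths:

    F_cor = F_obs * 10^((A_ex * d_ex + A_em * d_em) / 2)

with the positive exponent so that correction always increases an attenuated
observed signal (F_cor >= F_obs for non-negative absorbances).  Path lengths
default to a 1 cm cuvette.
"""

from __future__ import annotations

import logging
from typing import Sequence

from .data_model_io import AbsorbanceRecord, TitrationPoint, TitrationSeries
from .errors import PairingError, ValidationError

logger = logging.getLogger(__name__)


def attenuation_exponent(abs_rec: AbsorbanceRecord) -> float:
    """Decadic exponent (A_ex*d_ex + A_em*d_em)/2 of the IFE attenuation."""
    abs_rec.validate()
    return (abs_rec.a_ex * abs_rec.d_ex + abs_rec.a_em * abs_rec.d_em) / 2.0


def correction_factor(abs_rec: AbsorbanceRecord) -> float:
    """Multiplicative factor 10^((A_ex d_ex + A_em d_em)/2), always >= 1."""
    return 10.0 ** attenuation_exponent(abs_rec)


def correct_point(f_obs: float, abs_rec: AbsorbanceRecord) -> float:
    """Inner-filter-correct one observed intensity."""
    if not f_obs > 0:
        raise ValidationError(f"f_obs must be > 0, got {f_obs}")
    return f_obs * correction_factor(abs_rec)


def correct_series(
    series: TitrationSeries,
    abs_recs: Sequence[AbsorbanceRecord] | None = None,
    *,
    no_ife: bool = False,
) -> TitrationSeries:
    """Return a copy of ``series`` with ``f_cor`` populated for every point.

    ``abs_recs`` pairs one absorbance record with each titration point, in
    order.  With ``no_ife=True`` the correction is declared unnecessary and
    ``f_cor`` is set equal to ``f_obs`` (logged, so the report records that
    uncorrected intensities were analysed).

    F_0 is implicitly recomputed: the zero-quencher point is corrected like
    any other, and downstream stages read ``series.f0`` from it.
    """
    series.validate()
    if no_ife:
        logger.info(
            "IFE correction skipped at T=%s K; corrected intensities equal observed",
            series.temperature,
        )
        points = [
            TitrationPoint(p.quencher_conc, p.f_obs, f_cor=p.f_obs) for p in series.points
        ]
        return series.with_points(points)
    if abs_recs is None:
        raise PairingError("abs_recs required unless no_ife=True")
    if len(abs_recs) != len(series.points):
        raise PairingError(
            f"{len(abs_recs)} absorbance records for {len(series.points)} points "
            f"at T={series.temperature} K"
        )
    points = [
        TitrationPoint(p.quencher_conc, p.f_obs, f_cor=correct_point(p.f_obs, rec))
        for p, rec in zip(series.points, abs_recs)
    ]
    return series.with_points(points)


def beer_lambert_absorbance(epsilon: float, conc: float, path_cm: float = 1.0) -> float:
    """A = eps * c * d for a single absorbing species (shared with the simulator)."""
    if epsilon < 0 or conc < 0 or path_cm <= 0:
        raise ValidationError(
            f"need epsilon, conc >= 0 and path > 0; got {epsilon}, {conc}, {path_cm}"
        )
    return epsilon * conc * path_cm


def records_from_epsilons(
    quencher_concs: Sequence[float],
    eps_ex: float,
    eps_em: float,
    d_ex: float = 1.0,
    d_em: float = 1.0,
) -> list[AbsorbanceRecord]:
    """Build per-point absorbance records from ligand molar absorptivities."""
    return [
        AbsorbanceRecord(
            a_ex=beer_lambert_absorbance(eps_ex, q, d_ex),
            a_em=beer_lambert_absorbance(eps_em, q, d_em),
            d_ex=d_ex,
            d_em=d_em,
        )
        for q in quencher_concs
    ]
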