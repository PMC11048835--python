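"""Double-logarithm binding analysis for static quenching.

For a ground-state complex, the quenched fraction obeys

    log10((F_0 - F) / F) = n log10 K_A + n log10 [Q]_free

where [Q]_free = [Q] - [P](F_0 - F)/F_0 corrects the total quencher
concentration for the amount sequestered by the protein (ligand depletion).
The slope of the double-log regression is the binding-site number n and the
binding constant is K_A = 10^(intercept / n).  All logarithms are decadic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data_model_io import TitrationSeries
from .errors import DepletionError, InsufficientDataError, ValidationError
from .errors import DepletionWarning

#: K_A bands (L/mol) for qualitative binding strength
STRONG_BAND = (1e5, 1e7)
WEAK_MODERATE_BAND = (1e2, 1e4)


@dataclass(frozen=True)
class BindingFit:
    """Double-log binding fit at one temperature."""

    ka: float  # L/mol
    n: float  # binding sites
    r_squared: float
    temperature: float  # K
    n_points: int
    strength_band: str


def free_ligand(q: float, p: float, f0: float, f: float) -> float:
    """Free-quencher concentration [Q] - [P](F_0 - F)/F_0.

    Raises :class:`DepletionError` when the depletion term exhausts the
    quencher (non-positive result), which signals an inconsistent point.
    """
    if not f0 > 0:
        raise ValidationError(f"f0 must be > 0, got {f0}")
    if not (0 < f <= f0):
        raise ValidationError(f"need 0 < f <= f0, got f={f}, f0={f0}")
    if q < 0 or p < 0:
        raise ValidationError(f"concentrations must be >= 0, got q={q}, p={p}")
    q_free = q - p * (f0 - f) / f0
    if q_free <= 0:
        raise DepletionError(
            f"free ligand non-positive (q={q}, p={p}, bound fraction={(f0 - f) / f0:.3f})"
        )
    return q_free


def fit_double_log(series: TitrationSeries) -> BindingFit:
    """Fit log10((F_0-F)/F) against log10([Q]_free) for K_A and n.

    Points with no quenching (F >= F_0) or a non-positive free-ligand term
    are dropped with a warning; early titration points are often
    noise-dominated and should not abort the fit.  The zero-quencher point
    never enters the regression (the left side is undefined there).
    """
    series.validate()
    f0 = series.f0
    p = series.protein_conc
    xs, ys = [], []
    for pt in series.points:
        if pt.quencher_conc == 0:
            continue
        f = pt.intensity
        if f >= f0:
            warnings.warn(
                f"point [Q]={pt.quencher_conc:g} at T={series.temperature} K shows no "
                "quenching (F >= F_0); dropped from binding fit",
                DepletionWarning,
                stacklevel=2,
            )
            continue
        try:
            qf = free_ligand(pt.quencher_conc, p, f0, f)
        except DepletionError as exc:
            warnings.warn(
                f"point [Q]={pt.quencher_conc:g} at T={series.temperature} K dropped: {exc}",
                DepletionWarning,
                stacklevel=2,
            )
            continue
        xs.append(np.log10(qf))
        ys.append(np.log10((f0 - f) / f))
    if len(xs) < 3:
        raise InsufficientDataError(
            f"only {len(xs)} usable points for binding fit at T={series.temperature} K"
        )
    res = stats.linregress(xs, ys)
    n = float(res.slope)
    if n <= 0:
        raise ValidationError(
            f"non-positive fitted site number n={n:.3g} at T={series.temperature} K"
        )
    ka = float(10.0 ** (res.intercept / n))
    r2 = float(res.rvalue**2)
    return BindingFit(
        ka=ka,
        n=n,
        r_squared=r2,
        temperature=series.temperature,
        n_points=len(xs),
        strength_band=classify_strength(ka),
    )


def classify_strength(ka: float) -> str:
    """Band a binding constant: strong (1e5-1e7 L/mol), weak-to-moderate
    (1e2-1e4), intermediate in the gap; out-of-range values map to the
    nearest band with a warning."""
    if not ka > 0:
        raise ValidationError(f"ka must be > 0, got {ka}")
    if STRONG_BAND[0] <= ka <= STRONG_BAND[1]:
        return "strong"
    if WEAK_MODERATE_BAND[0] <= ka <= WEAK_MODERATE_BAND[1]:
        return "weak-to-moderate"
    if WEAK_MODERATE_BAND[1] < ka < STRONG_BAND[0]:
        return "intermediate"
    if ka > STRONG_BAND[1]:
        warnings.warn(f"K_A={ka:.3g} above the strong band", stacklevel=2)
        return "strong"
    warnings.warn(f"K_A={ka:.3g} below the weak-to-moderate band", stacklevel=2)
    return "weak-to-moderate"
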