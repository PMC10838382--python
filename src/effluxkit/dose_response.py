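"""Sigmoidal (four-parameter logistic) concentration-response analysis.

Viability assays report a raw signal (fluorescence or colony count) per
well; dividing by the mean untreated-control signal gives the
treated-over-control fraction T/C, the effect measure used throughout.
A 4PL curve

    f(c) = bottom + (top - bottom) / (1 + (c / ic50)**hill)

is fitted to the T/C values in log10-concentration space.  The reported
IC50 is the *relative* IC50: the concentration at the inflection point,
halfway between the fitted top and bottom plateaus.  When the fitted
midpoint falls outside the tested concentration range the estimate is
censored and reported as a bound (e.g. "> 30 uM"), mirroring how
inactive single agents are tabulated.

Resistance and sensitization are quantified as ratios of relative IC50s
(fold change); a resistant line divided by its parental line gives the
relative resistance.

All concentrations are molar internally; I/O helpers convert from
nM / uM columns (see :mod:`effluxkit.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseData",
    "FourPLFit",
    "ResistanceRatio",
    "InsufficientDataError",
    "InvalidPlateError",
    "FitFailureError",
    "CensoredIC50Error",
    "four_pl",
    "tc_fraction",
    "fit_dose_response",
    "ic50_ratio",
]


class InsufficientDataError(ValueError):
    """Fewer than four distinct concentrations were supplied."""


class InvalidPlateError(ValueError):
    """Control wells are missing or their mean signal is not positive."""


class FitFailureError(RuntimeError):
    """The least-squares fit did not converge from any starting point."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class CensoredIC50Error(ValueError):
    """A censored IC50 was used where a point estimate is required.

    Callers should report a bound (e.g. ``"> 30 uM"``) instead of a fold
    change when either IC50 in a ratio is censored.
    """


# Multi-start grid over the Hill slope; sigmoid fits are prone to local
# minima when initialised far from the true steepness.
_HILL_STARTS = (0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4PL parameters on the T/C scale.

    ``censored`` is ``"none"`` for an interior estimate, ``"above_max"``
    when the midpoint was not reached within the tested range (ic50_rel
    then holds the highest tested concentration, to be read as a lower
    bound), or ``"below_min"`` symmetrically.
    """

    top: float
    bottom: float
    ic50_rel: float
    hill: float
    censored: str = "none"
    rss: float = float("nan")

    def __post_init__(self):
        if self.censored not in ("none", "above_max", "below_min"):
            raise ValueError(f"invalid censoring flag {self.censored!r}")
        if self.bottom > self.top + 1e-12:
            raise ValueError("bottom plateau exceeds top plateau")
        if self.censored == "none":
            if not self.ic50_rel > 0:
                raise ValueError("ic50_rel must be positive")
            if not (math.isfinite(self.hill) and self.hill != 0):
                raise ValueError("hill must be finite and nonzero")

    def predict(self, conc) -> np.ndarray | float:
        return four_pl(conc, self.top, self.bottom, self.ic50_rel, self.hill)

    def format_ic50(self, unit: str = "nM", decimals: int = 4) -> str:
        """IC50 with censoring comparator, e.g. ``"> 30.0000"`` (in ``unit``)."""
        scale = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "nM": 1e-9}[unit]
        value = self.ic50_rel / scale
        prefix = {"none": "", "above_max": "> ", "below_min": "< "}[self.censored]
        return f"{prefix}{value:.{decimals}f}"


@dataclass
class DoseResponseData:
    """One concentration-response series plus its untreated controls.

    ``points`` are (concentration [M], raw signal, replicate id) tuples;
    replicates at the same concentration are averaged on the T/C scale
    before fitting.
    """

    assay_id: str
    cell_line: str
    drug: str
    points: list[tuple[float, float, int]]
    controls: list[float]
    meta: dict = field(default_factory=dict)

    def validate(self) -> None:
        conc = np.array([p[0] for p in self.points], dtype=float)
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if len(np.unique(conc)) < 4:
            raise InsufficientDataError(
                f"{self.assay_id}/{self.cell_line}/{self.drug}: "
                f"{len(np.unique(conc))} distinct concentrations < 4"
            )
        if len(self.controls) < 1:
            raise InvalidPlateError("at least one untreated control well required")


@dataclass(frozen=True)
class ResistanceRatio:
    """Fold change between two relative IC50s (numerator / denominator)."""

    numerator_ic50: float
    denominator_ic50: float

    @property
    def fold(self) -> float:
        return self.numerator_ic50 / self.denominator_ic50

    @property
    def fold_1dp(self) -> float:
        """Fold rounded to one decimal, the convention used in result tables."""
        return round(self.fold, 1)


def four_pl(conc, top: float, bottom: float, ic50: float, hill: float):
    """Evaluate the 4PL curve at ``conc`` (molar, strictly positive).

    Decreasing in concentration when ``hill > 0`` and ``top > bottom``;
    ``f(ic50) = (top + bottom) / 2`` (the relative-IC50 definition) and
    ``f -> top`` as ``conc -> 0``.
    """
    c = np.asarray(conc, dtype=float)
    if np.any(c <= 0):
        raise ValueError("concentration must be strictly positive")
    out = bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)
    return float(out) if np.isscalar(conc) else out


def tc_fraction(treated_signal: float, control_signals: Sequence[float]) -> float:
    """Treated-over-control fraction: signal / mean(untreated controls).

    Values above 1 (stimulation) are preserved; clipping to [0, 1] is a
    display concern handled by the synergy heat-map export.
    """
    controls = np.asarray(control_signals, dtype=float)
    if controls.size == 0 or controls.mean() <= 0:
        raise InvalidPlateError("control mean must be positive")
    return float(treated_signal) / float(controls.mean())


def _log10_model(logc, top, bottom, logic50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - logic50)))


def fit_dose_response(data: DoseResponseData, min_span: float = 0.2) -> FourPLFit:
    """Unweighted least-squares 4PL fit in log10(concentration) space.

    Replicate wells at the same concentration are averaged on the T/C
    scale first.  Initialisation: top/bottom from the observed extremes,
    IC50 from linear interpolation of the midpoint crossing, with a
    multi-start over Hill slopes; parameters are bounded to keep
    plateaus and midpoint near the data (partial curves otherwise drive
    plateaus to infinity).

    A response whose observed span is below ``min_span`` (no real curve
    within the tested range), or whose fitted midpoint lies outside the
    tested range, is returned censored with the boundary concentration,
    never as a spurious interior IC50.
    """
    data.validate()
    conc = np.array([p[0] for p in data.points], dtype=float)
    signal = np.array([p[1] for p in data.points], dtype=float)
    tc = np.array([tc_fraction(s, data.controls) for s in signal])

    # average replicates per distinct concentration
    uconc = np.unique(conc)
    tc_mean = np.array([tc[conc == c].mean() for c in uconc])
    logc = np.log10(uconc)
    cmin, cmax = float(uconc[0]), float(uconc[-1])

    hi, lo = float(tc_mean.max()), float(tc_mean.min())
    if hi - lo < min_span:
        # Flat response: no concentration-dependence resolvable.
        censored = "above_max" if tc_mean.mean() >= 0.5 else "below_min"
        boundary = cmax if censored == "above_max" else cmin
        rss = float(((tc_mean - tc_mean.mean()) ** 2).sum())
        return FourPLFit(top=hi, bottom=lo, ic50_rel=boundary, hill=1.0,
                         censored=censored, rss=rss)

    # bounds scaled to the observed top of the response
    b_lo = np.array([0.5 * hi, -0.1 * hi, np.log10(cmin / 100.0), 0.1])
    b_hi = np.array([1.2 * hi, 0.5 * hi, np.log10(cmax * 100.0), 10.0])

    mid = 0.5 * (hi + lo)
    logic50_0 = _midpoint_crossing(logc, tc_mean, mid)
    p0_base = np.array([hi, lo, logic50_0, 1.0])
    p0_base = np.clip(p0_base, b_lo + 1e-9, b_hi - 1e-9)

    def residuals(p):
        return _log10_model(logc, p[0], p[1], p[2], p[3]) - tc_mean

    best = None
    failures = []
    for h0 in _HILL_STARTS:
        p0 = p0_base.copy()
        p0[3] = h0
        try:
            sol = least_squares(residuals, p0, bounds=(b_lo, b_hi), method="trf")
        except Exception as exc:  # pragma: no cover - scipy raises rarely here
            failures.append(str(exc))
            continue
        if not sol.success:
            failures.append(sol.message)
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[1]:
            best = (sol.x, rss)
    if best is None:
        raise FitFailureError(
            f"4PL fit failed for {data.assay_id}/{data.cell_line}/{data.drug}",
            diagnostics={"messages": failures, "n_points": len(uconc)},
        )

    (top, bottom, logic50, hill), rss = best
    ic50 = 10.0 ** logic50
    censored = "none"
    if ic50 > cmax:
        censored, ic50 = "above_max", cmax
    elif ic50 < cmin:
        censored, ic50 = "below_min", cmin
    return FourPLFit(top=float(top), bottom=float(bottom), ic50_rel=float(ic50),
                     hill=float(hill), censored=censored, rss=rss)


def _midpoint_crossing(logc: np.ndarray, tc_mean: np.ndarray, mid: float) -> float:
    """log10 concentration where the interpolated response crosses ``mid``."""
    for i in range(len(logc) - 1):
        y0, y1 = tc_mean[i], tc_mean[i + 1]
        if (y0 - mid) * (y1 - mid) <= 0 and y0 != y1:
            frac = (mid - y0) / (y1 - y0)
            return float(logc[i] + frac * (logc[i + 1] - logc[i]))
    return float(logc.mean())


def ic50_ratio(ic50_num, ic50_den) -> ResistanceRatio:
    """Relative resistance / fold sensitization from two relative IC50s.

    Accepts molar concentrations or :class:`FourPLFit` objects (which
    must be uncensored).  ``ic50_ratio(a, b).fold * ic50_ratio(b, a).fold
    == 1`` exactly.
    """
    num = _uncensored_value(ic50_num, "numerator")
    den = _uncensored_value(ic50_den, "denominator")
    if num <= 0 or den <= 0:
        raise ValueError("IC50s must be positive")
    return ResistanceRatio(numerator_ic50=num, denominator_ic50=den)


def _uncensored_value(x, which: str) -> float:
    if isinstance(x, FourPLFit):
        if x.censored != "none":
            raise CensoredIC50Error(
                f"{which} IC50 is censored ({x.censored}); report a bound "
                "on the fold change instead of a point estimate"
            )
        return x.ic50_rel
    return float(x)
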