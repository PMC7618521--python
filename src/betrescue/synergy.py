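"""ZIP (zero interaction potency) synergy scoring of dose-response matrices.

The ZIP model takes Bliss independence on the inhibition scale as the
zero-interaction reference — y_zip(a, b) = yA(a) + yB(b) - yA(a)*yB(b) with
inhibitions as fractions — but evaluates both the reference and the observed
response through four-parameter logistic (4PL) fits, so that dose-response
shape (potency shift) rather than single noisy wells drives the score.  The
delta surface is (observed - expected) in percentage points over the
combination wells; its mean is the summary score.  Scores above +10 are called
synergistic, below -10 antagonistic, in between additive.

Scheduling mode (BETi-first, concomitant, p300i-first) is carried as metadata
only: the scoring is identical per mode, and any biology of scheduling enters
through the measured matrices themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "MODES",
    "HillParams",
    "HillFit",
    "DoseMatrix",
    "SynergyResult",
    "hill_curve",
    "fit_hill",
    "bliss_expectation",
    "zip_delta",
    "classify_synergy",
    "compare_modes",
]

MODES = ("BETi_first", "concomitant", "p300i_first")

_BOUNDS = {  # 4PL parameter bounds on the percent-inhibition scale
    "bottom": (-5.0, 20.0),
    "top": (50.0, 110.0),
    "ec50": (1e-9, 1e9),
    "slope": (0.2, 10.0),
}


@dataclass(frozen=True)
class HillParams:
    """Four-parameter logistic: bottom, top (%), EC50 (dose units), slope."""

    bottom: float = 0.0
    top: float = 100.0
    ec50: float = 1.0
    slope: float = 1.0


def hill_curve(doses, params: HillParams) -> np.ndarray:
    """4PL response at each dose; the zero dose returns ``bottom``."""
    d = np.asarray(doses, dtype=float)
    with np.errstate(divide="ignore"):
        log_ratio = params.slope * (np.log(params.ec50) - np.log(np.maximum(d, 1e-300)))
    ratio = np.exp(np.clip(log_ratio, -700, 700))
    ratio = np.where(d > 0, ratio, np.inf)
    return params.bottom + (params.top - params.bottom) / (1.0 + ratio)


@dataclass
class HillFit:
    """A fitted monotherapy curve; ``method`` is '4pl', 'flat' or 'isotonic'."""

    params: HillParams | None
    method: str = "4pl"
    flagged: bool = False
    _doses: np.ndarray | None = None
    _values: np.ndarray | None = None

    def predict(self, doses) -> np.ndarray:
        d = np.asarray(doses, dtype=float)
        if self.method == "4pl":
            return hill_curve(d, self.params)
        if self.method == "flat":
            return np.full_like(d, self._values.mean())
        return np.interp(d, self._doses, self._values)  # isotonic


def _fit_4pl(doses, values, fixed_bottom: float | None = None):
    """curve_fit wrapper; raises on failure."""
    d = np.asarray(doses, float)
    y = np.asarray(values, float)
    nz = d[d > 0]
    ec50_init = float(np.exp(np.mean(np.log(nz))))
    lo_t, hi_t = _BOUNDS["top"]
    top_init = float(np.clip(y.max(), lo_t + 1e-6, hi_t - 1e-6))
    if fixed_bottom is None:
        lo_b, hi_b = _BOUNDS["bottom"]
        def f(x, bottom, top, ec50, slope):
            return hill_curve(x, HillParams(bottom, top, ec50, slope))
        p0 = [float(np.clip(y.min(), lo_b, hi_b)), top_init, ec50_init, 1.0]
        bounds = (
            [lo_b, lo_t, _BOUNDS["ec50"][0], _BOUNDS["slope"][0]],
            [hi_b, hi_t, _BOUNDS["ec50"][1], _BOUNDS["slope"][1]],
        )
        popt, _ = curve_fit(f, d, y, p0=p0, bounds=bounds, maxfev=20000)
        return HillParams(*popt)
    def g(x, top, ec50, slope):
        return hill_curve(x, HillParams(fixed_bottom, top, ec50, slope))
    p0 = [max(top_init, fixed_bottom + 1.0), ec50_init, 1.0]
    bounds = (
        [lo_t, _BOUNDS["ec50"][0], _BOUNDS["slope"][0]],
        [hi_t, _BOUNDS["ec50"][1], _BOUNDS["slope"][1]],
    )
    popt, _ = curve_fit(g, d, y, p0=p0, bounds=bounds, maxfev=20000)
    return HillParams(fixed_bottom, *popt)


def fit_hill(doses, inhibition) -> HillFit:
    """Least-squares 4PL fit of a monotherapy dose-response.

    Bounds: bottom in [-5, 20], top in [50, 110], slope in [0.2, 10], EC50 > 0
    (initialized at the geometric mean of nonzero doses).  Degenerate flat data
    yield a flagged constant fit; non-convergence falls back to monotone
    isotonic interpolation, flagged.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(inhibition, dtype=float)
    if len(d) < 4 or (d == 0).sum() == 0:
        raise ValueError("need >=4 dose levels including a zero dose")
    if y.max() - y.min() < 1e-6:
        return HillFit(None, method="flat", flagged=True, _doses=d, _values=y)
    try:
        return HillFit(_fit_4pl(d, y))
    except RuntimeError:
        from sklearn.isotonic import IsotonicRegression

        order = np.argsort(d)
        iso = IsotonicRegression(increasing=True).fit(d[order], y[order])
        return HillFit(
            None, method="isotonic", flagged=True,
            _doses=d[order], _values=iso.predict(d[order]),
        )


def bliss_expectation(y_a, y_b) -> np.ndarray:
    """Bliss-independent combined inhibition (percent scale)."""
    y_a = np.asarray(y_a, float)
    y_b = np.asarray(y_b, float)
    return y_a + y_b - y_a * y_b / 100.0


@dataclass
class DoseMatrix:
    """Percent-inhibition grid; row/column 0 are the vehicle doses.

    ``inhibition[i, j]`` is the response at (doses_a[i], doses_b[j]).
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray
    mode: str = "concomitant"
    readout_day: float = 5.0

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, float)
        self.doses_b = np.asarray(self.doses_b, float)
        self.inhibition = np.asarray(self.inhibition, float)
        if self.doses_a[0] != 0 or self.doses_b[0] != 0:
            raise ValueError("dose grids must start with the zero (vehicle) dose")
        if (np.diff(self.doses_a) <= 0).any() or (np.diff(self.doses_b) <= 0).any():
            raise ValueError("doses must be strictly increasing")
        if self.inhibition.shape != (len(self.doses_a), len(self.doses_b)):
            raise ValueError("inhibition grid does not match dose lists")


@dataclass
class SynergyResult:
    """ZIP delta surface and summary for one dose matrix."""

    delta_surface: pd.DataFrame
    mean_delta: float
    max_window_delta: float
    call: str
    hill_fit_a: HillFit
    hill_fit_b: HillFit
    mode: str
    flags: list[str] = field(default_factory=list)


def classify_synergy(score: float) -> str:
    """> +10 synergistic, < -10 antagonistic, else additive."""
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    if score > 10:
        return "synergistic"
    if score < -10:
        return "antagonistic"
    return "additive"


def zip_delta(matrix: DoseMatrix) -> SynergyResult:
    """ZIP delta surface, mean score and most-synergistic-area score.

    Monotherapy curves come from 4PL fits to the zero-dose row/column.  The
    observed response at each combination well is the average of two
    potency-shifted 4PL re-fits: along the well's row (drug A varying, bottom
    pinned to the fitted monotherapy response of drug B at that row's dose)
    and along its column (roles swapped).  delta = observed - Bliss
    expectation of the fitted monotherapies, in percentage points.
    ``max_window_delta`` is the largest mean over 3x3 sub-windows of the combo
    grid (the whole grid when smaller).
    """
    da, db = matrix.doses_a, matrix.doses_b
    fit_a = fit_hill(da, matrix.inhibition[:, 0])
    fit_b = fit_hill(db, matrix.inhibition[0, :])
    flags = []
    if fit_a.flagged:
        flags.append("monotherapy_A_fit_flagged")
    if fit_b.flagged:
        flags.append("monotherapy_B_fit_flagged")

    ya = fit_a.predict(da)
    yb = fit_b.predict(db)
    expected = bliss_expectation(ya[:, None], yb[None, :])

    na, nb = len(da) - 1, len(db) - 1  # combo grid size
    if na < 1 or nb < 1:
        raise ValueError("need at least one nonzero dose per drug")

    row_fit = np.full((na, nb), np.nan)
    col_fit = np.full((na, nb), np.nan)
    for j in range(1, nb + 1):  # fit along drug A at fixed b_j
        try:
            p = _fit_4pl(da, matrix.inhibition[:, j], fixed_bottom=float(yb[j]))
            row_fit[:, j - 1] = hill_curve(da[1:], p)
        except RuntimeError:
            row_fit[:, j - 1] = matrix.inhibition[1:, j]
            flags.append(f"row_fit_fallback_b{j}")
    for i in range(1, na + 1):  # fit along drug B at fixed a_i
        try:
            p = _fit_4pl(db, matrix.inhibition[i, :], fixed_bottom=float(ya[i]))
            col_fit[i - 1, :] = hill_curve(db[1:], p)
        except RuntimeError:
            col_fit[i - 1, :] = matrix.inhibition[i, 1:]
            flags.append(f"col_fit_fallback_a{i}")

    observed = (row_fit + col_fit) / 2.0
    delta = observed - expected[1:, 1:]
    mean_delta = float(delta.mean())

    if na >= 3 and nb >= 3:
        windows = [
            delta[i:i + 3, j:j + 3].mean()
            for i in range(na - 2)
            for j in range(nb - 2)
        ]
        max_window = float(max(windows))
    else:
        max_window = mean_delta
        flags.append("combo_grid_smaller_than_3x3_window")

    surface = pd.DataFrame(delta, index=da[1:], columns=db[1:])
    surface.index.name, surface.columns.name = "dose_a", "dose_b"
    return SynergyResult(
        delta_surface=surface,
        mean_delta=mean_delta,
        max_window_delta=max_window,
        call=classify_synergy(mean_delta),
        hill_fit_a=fit_a,
        hill_fit_b=fit_b,
        mode=matrix.mode,
        flags=flags,
    )


def compare_modes(results: list[SynergyResult]) -> pd.DataFrame:
    """Tabulate per-mode ZIP summaries, ordered by mean delta (descending).

    Ties in mean delta break by the canonical mode order (BETi_first,
    concomitant, p300i_first); duplicate mode labels are an error.
    """
    if len(results) < 1:
        raise ValueError("no synergy results supplied")
    modes = [r.mode for r in results]
    if len(set(modes)) != len(modes):
        raise ValueError(f"duplicate mode labels: {modes}")
    rank = {m: i for i, m in enumerate(MODES)}
    table = pd.DataFrame(
        {
            "mode": modes,
            "mean_delta": [r.mean_delta for r in results],
            "max_window_delta": [r.max_window_delta for r in results],
            "call": [r.call for r in results],
        }
    )
    table["_rank"] = table["mode"].map(lambda m: rank.get(m, len(MODES)))
    table = (
        table.sort_values(["mean_delta", "_rank"], ascending=[False, True], kind="mergesort")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return table
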