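"""Dose-response (4PL/IC50) fitting and stiffness-response metrics.

``fit_ic50`` estimates the IC50 of an MTT-style viability table with the
four-parameter logistic model. ``cv_percent`` quantifies how much a drug
softened a cell line: the default mode is the relative change of the mean
Young's modulus between control and treated populations (in %), with the
treated population's dispersion (100·sd/mean) as an alternative reading.
``per_component_cv`` applies the relative-change metric separately to the
softer and stiffer subpopulations of bimodal lines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .errors import InvalidConfigError, NoIC50Error
from .popmodel import MixtureFit, StiffnessPopulation


def four_pl(conc, top: float, bottom: float, ic50: float, hill: float):
    """Four-parameter logistic: v(c) = bottom + (top−bottom)/(1+(c/ic50)^hill).

    With hill > 0 the curve decreases from ``top`` (no drug) to ``bottom``
    (saturating dose); v(IC50) is the midpoint (top+bottom)/2.
    """
    c = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


@dataclass
class ViabilityTable:
    """Replicate-averaged viability (percent of untreated) per dose."""

    concentrations: np.ndarray
    viability: np.ndarray
    line_id: str = ""

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.viability = np.asarray(self.viability, dtype=float)
        if self.concentrations.shape != self.viability.shape:
            raise InvalidConfigError("concentrations and viability must match")
        if np.any(self.concentrations <= 0):
            raise InvalidConfigError("concentrations must be positive (µM)")
        if np.any(np.diff(self.concentrations) <= 0):
            raise InvalidConfigError("concentrations must be strictly increasing")
        if not np.all(np.isfinite(self.viability)):
            raise InvalidConfigError("viability must be finite")


@dataclass
class DoseResponseFit:
    """4PL parameters; IC50 in µM."""

    ic50: float
    hill: float
    top: float
    bottom: float
    rss: float
    converged: bool
    line_id: str = ""


@dataclass
class ResponseMetrics:
    """Stiffness response of one line to treatment.

    ``cv_percent`` follows the requested mode; both readings are always
    stored (``cv_relative_change``, ``cv_treated_dispersion``).
    """

    line_id: str
    mean_E_control: float
    mean_E_treated: float
    cv_percent: float
    cv_mode: str
    cv_relative_change: float
    cv_treated_dispersion: float
    per_component_cv: tuple[float, float] | None = None


def fit_ic50(
    table: ViabilityTable,
    top: float = 100.0,
    free_top: bool = False,
    bottom_bounds: tuple[float, float] = (0.0, 50.0),
    flat_range: float = 10.0,
) -> DoseResponseFit:
    """Least-squares 4PL fit on log-concentration; returns the IC50 in µM.

    Default parameterization fixes top = 100 (viability normalized to the
    untreated control) and lets bottom float within ``bottom_bounds``;
    ``free_top=True`` releases the top asymptote too.

    Raises
    ------
    NoIC50Error
        If viability increases with dose (Spearman ρ > 0) or spans less
        than ``flat_range`` percentage points (flat curve): no midpoint
        is resolvable.
    """
    c = table.concentrations
    v = table.viability
    if c.size < 5:
        raise InvalidConfigError("need >= 5 concentrations for a 4PL fit")
    if float(np.ptp(v)) < flat_range:
        raise NoIC50Error("viability curve is flat; no IC50")
    rho = stats.spearmanr(c, v).statistic
    if rho > 0:
        raise NoIC50Error("viability increases with concentration; no IC50")

    logc = np.log10(c)

    def model_fixed(lc, bottom, log_ic50, hill):
        return four_pl(10.0**lc, top, bottom, 10.0**log_ic50, hill)

    def model_free(lc, top_, bottom, log_ic50, hill):
        return four_pl(10.0**lc, top_, bottom, 10.0**log_ic50, hill)

    # midpoint crossing as IC50 start value
    b0 = float(np.clip(v.min(), *bottom_bounds))
    mid = (top + b0) / 2.0
    below = np.nonzero(v <= mid)[0]
    lic0 = logc[below[0]] if below.size else float(np.median(logc))
    span = (logc.min() - 2.0, logc.max() + 2.0)
    try:
        if free_top:
            popt, _ = optimize.curve_fit(
                model_free, logc, v,
                p0=[float(v.max()), b0, lic0, 1.0],
                bounds=([0.0, bottom_bounds[0], span[0], 0.05],
                        [200.0, bottom_bounds[1], span[1], 20.0]),
                maxfev=20000,
            )
            top_hat, bottom_hat, lic, hill = popt
        else:
            popt, _ = optimize.curve_fit(
                model_fixed, logc, v,
                p0=[b0, lic0, 1.0],
                bounds=([bottom_bounds[0], span[0], 0.05],
                        [bottom_bounds[1], span[1], 20.0]),
                maxfev=20000,
            )
            bottom_hat, lic, hill = popt
            top_hat = top
    except RuntimeError as exc:
        raise NoIC50Error(f"4PL fit did not converge: {exc}") from exc

    pred = four_pl(c, top_hat, bottom_hat, 10.0**lic, hill)
    rss = float(np.sum((v - pred) ** 2))
    ic50 = float(10.0**lic)
    converged = bool(np.isfinite(ic50) and ic50 > 0 and bottom_hat <= top_hat)
    return DoseResponseFit(
        ic50=ic50, hill=float(hill), top=float(top_hat), bottom=float(bottom_hat),
        rss=rss, converged=converged, line_id=table.line_id,
    )


def cv_percent(
    control: StiffnessPopulation,
    treated: StiffnessPopulation,
    mode: str = "relative-change",
) -> ResponseMetrics:
    """Stiffness-response metric CV% of a treated vs control population.

    ``relative-change`` (default): 100·(mean_control − mean_treated)/
    mean_control, floored at 0 — the extent to which treatment softened
    the line. ``treated-dispersion``: 100·sd/mean of the treated per-cell
    moduli. Both values are computed and stored regardless of mode.
    """
    if control.n_cells == 0 or treated.n_cells == 0:
        raise InvalidConfigError("both populations must be non-empty")
    mc = float(np.mean(control.cell_moduli))
    mt = float(np.mean(treated.cell_moduli))
    rel = max(0.0, 100.0 * (mc - mt) / mc)
    disp = 100.0 * float(np.std(treated.cell_moduli, ddof=1)) / mt
    if mode == "relative-change":
        chosen = rel
    elif mode == "treated-dispersion":
        chosen = disp
    else:
        raise InvalidConfigError(f"unknown cv mode {mode!r}")
    return ResponseMetrics(
        line_id=control.line_id,
        mean_E_control=mc,
        mean_E_treated=mt,
        cv_percent=chosen,
        cv_mode=mode,
        cv_relative_change=rel,
        cv_treated_dispersion=disp,
    )


def per_component_cv(control: MixtureFit, treated: MixtureFit) -> tuple[float, float]:
    """Relative change (%) of the softer and stiffer component means.

    Components are rank-matched (softer↔softer, stiffer↔stiffer); both
    fits must be bimodal. Returns (softer_cv, stiffer_cv).
    """
    if control.classification != "Bimodal" or treated.classification != "Bimodal":
        raise InvalidConfigError("per_component_cv requires two Bimodal fits")
    out = []
    for idx_c, idx_t in (
        (control.softer_index, treated.softer_index),
        (control.stiffer_index, treated.stiffer_index),
    ):
        mc = control.means[idx_c]
        mt = treated.means[idx_t]
        out.append(100.0 * (mc - mt) / mc)
    return (out[0], out[1])
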