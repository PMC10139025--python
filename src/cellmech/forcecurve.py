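"""Hertz-model analysis of AFM force–displacement curves.

Turns raw approach curves (piezo extension z in µm, cantilever deflection
in nm) into per-curve Young's moduli and per-cell stiffness values:

1. ``correct_baseline`` — remove tilt/offset of the non-contact segment;
2. ``detect_contact_point`` — piecewise flat + Hertz model scan over
   candidate contact points, minimizing total residual sum of squares;
3. ``fit_hertz`` — least-squares estimate of E on the indentation window
   0 < δ ≤ 500 nm with the contact point held fixed;
4. ``aggregate_cell`` — per-cell stiffness from ≥ 5 converged curves.

Indentation follows the standard AFM convention δ = (z − z_c) − d, i.e.
piezo travel past contact minus cantilever deflection; force F = k·d.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FitError, InsufficientDataError, NoContactError, ProcessingError
from .physics import ProbeSpec, hertz_prefactor

logger = logging.getLogger(__name__)

MAX_INDENT_NM = 500.0
MIN_INDENT_NM = 100.0  # curves never reaching this depth are rejected
MIN_CURVE_POINTS = 50
MIN_FIT_POINTS = 10
MIN_CURVES_PER_CELL = 5


@dataclass
class ForceCurve:
    """One AFM approach (indentation) record.

    ``z`` is piezo extension in µm, strictly increasing toward the cell;
    ``deflection`` is cantilever deflection in nm. ``truth`` optionally
    carries generator ground truth (keys ``E_kPa``, ``contact_z_um``).
    """

    z: np.ndarray
    deflection: np.ndarray
    probe: ProbeSpec
    cell_id: str = ""
    curve_id: str = ""
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.deflection = np.asarray(self.deflection, dtype=float)
        if self.z.shape != self.deflection.shape:
            raise ProcessingError("z and deflection must have equal length")
        if self.z.size < MIN_CURVE_POINTS:
            raise ProcessingError(
                f"curve needs >= {MIN_CURVE_POINTS} points, got {self.z.size}"
            )
        if not np.all(np.diff(self.z) > 0):
            raise ProcessingError("z must be strictly increasing (approach)")

    @property
    def force(self) -> np.ndarray:
        """Cantilever force in nN (k · d)."""
        return self.probe.spring_constant * self.deflection


@dataclass
class HertzFit:
    """Result of a single-curve Hertz fit."""

    contact_z: float
    youngs_modulus: float
    max_indentation_used: float
    rss: float
    n_fit_points: int
    converged: bool
    cell_id: str = ""
    curve_id: str = ""


@dataclass
class CellStiffness:
    """Per-cell stiffness aggregated over its converged curve fits."""

    cell_id: str
    per_curve_moduli: list[float] = field(default_factory=list)
    aggregate_modulus: float = float("nan")
    n_curves: int = 0


def correct_baseline(curve: ForceCurve, fraction: float = 0.3) -> ForceCurve:
    """Subtract a straight line fitted on the pre-contact region.

    The first ``fraction`` of points (assumed free of contact) defines the
    baseline; the fitted line is removed from the whole curve so that the
    pre-contact deflection is centered on zero.
    """
    n_base = int(round(fraction * curve.z.size))
    if n_base < 20:
        raise ProcessingError(
            f"baseline region has {n_base} points; need >= 20"
        )
    coeff = np.polyfit(curve.z[:n_base], curve.deflection[:n_base], 1)
    corrected = curve.deflection - np.polyval(coeff, curve.z)
    return ForceCurve(
        z=curve.z.copy(),
        deflection=corrected,
        probe=curve.probe,
        cell_id=curve.cell_id,
        curve_id=curve.curve_id,
        truth=curve.truth,
    )


def _piecewise_rss(curve: ForceCurve, zc: float, prefactor: float):
    """Total RSS (in force units) of flat-baseline + Hertz split at ``zc``.

    Returns (rss, E). The Hertz segment modulus is the closed-form
    least-squares solution of F = E·A·δ^{3/2}; points at or before the
    candidate contact (δ ≤ 0) count toward the baseline residual.
    """
    d = curve.deflection
    f = curve.force
    delta = (curve.z - zc) * 1e3 - d
    post = (curve.z > zc) & (delta > 0)
    rss_base = float(np.sum(f[~post] ** 2))
    x = prefactor * delta[post] ** 1.5
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        return rss_base + float(np.sum(f[post] ** 2)), 0.0
    e_hat = float(np.dot(f[post], x) / sxx)
    resid = f[post] - e_hat * x
    return rss_base + float(np.dot(resid, resid)), e_hat


def detect_contact_point(
    curve: ForceCurve,
    min_improvement: float = 0.02,
    coarse_step: int | None = None,
) -> float:
    """Locate the z position where deflection departs from baseline.

    Scans candidate contact positions with a two-segment model — flat
    zero baseline before contact, Hertz force law after — and returns the
    z minimizing the total residual sum of squares. A coarse scan (every
    ``coarse_step`` grid points, default n/100) is refined to single-point
    resolution and then to a continuous sub-grid position by golden-
    section search between the neighbouring grid nodes.

    Raises
    ------
    NoContactError
        If no candidate reduces the flat-only RSS by at least
        ``min_improvement`` (relative), or the best Hertz modulus is not
        positive — i.e. the curve shows no indentation.
    """
    n = curve.z.size
    pref = hertz_prefactor(curve.probe)
    f = curve.force
    rss_flat = float(np.dot(f, f))
    if rss_flat == 0.0:
        raise NoContactError("deflection identically zero: no contact")

    lo, hi = 5, n - MIN_FIT_POINTS
    if coarse_step is None:
        coarse_step = max(1, n // 100)
    candidates = list(range(lo, hi, coarse_step))

    def best_of(indices):
        best = (np.inf, 0.0, None)
        for i in indices:
            rss, e = _piecewise_rss(curve, float(curve.z[i]), pref)
            if rss < best[0]:
                best = (rss, e, i)
        return best

    rss_c, _, i_c = best_of(candidates)
    if i_c is None:
        raise NoContactError("no candidate contact index available")
    refine = range(max(lo, i_c - coarse_step), min(hi, i_c + coarse_step + 1))
    rss_best, e_best, i_best = best_of(refine)

    if e_best <= 0.0 or rss_best > (1.0 - min_improvement) * rss_flat:
        raise NoContactError(
            "no contact point improves on the flat model "
            f"(best relative RSS {rss_best / rss_flat:.3f})"
        )

    # continuous sub-grid refinement between the flanking grid nodes
    from scipy.optimize import minimize_scalar

    z_lo = float(curve.z[max(i_best - 1, 0)])
    z_hi = float(curve.z[min(i_best + 1, n - 1)])
    res = minimize_scalar(
        lambda zc: _piecewise_rss(curve, zc, pref)[0],
        bounds=(z_lo, z_hi),
        method="bounded",
        options={"xatol": (z_hi - z_lo) * 1e-6},
    )
    if res.fun <= rss_best:
        return float(res.x)
    return float(curve.z[i_best])


def fit_hertz(
    curve: ForceCurve,
    contact_z: float,
    max_indent: float = MAX_INDENT_NM,
) -> HertzFit:
    """Least-squares Hertz fit of E with the contact point held fixed.

    The fit uses only points with indentation 0 < δ ≤ ``max_indent`` nm
    (default 500 nm, within the linear-elastic regime for cells). E is the
    single free parameter of F = A·E·δ^{3/2}, solved in closed form.
    """
    d = curve.deflection
    delta = (curve.z - contact_z) * 1e3 - d
    window = (delta > 0) & (delta <= max_indent)
    n_pts = int(window.sum())
    if n_pts < MIN_FIT_POINTS:
        raise FitError(f"only {n_pts} points in the fit window (need >= {MIN_FIT_POINTS})")
    max_delta = float(delta[window].max())
    if max_delta < MIN_INDENT_NM:
        raise FitError(
            f"curve reaches only {max_delta:.0f} nm indentation (< {MIN_INDENT_NM:.0f} nm)"
        )
    x = hertz_prefactor(curve.probe) * delta[window] ** 1.5
    f = curve.force[window]
    e_hat = float(np.dot(f, x) / np.dot(x, x))
    resid = f - e_hat * x
    return HertzFit(
        contact_z=float(contact_z),
        youngs_modulus=e_hat,
        max_indentation_used=max_delta,
        rss=float(np.dot(resid, resid)),
        n_fit_points=n_pts,
        converged=e_hat > 0.0,
        cell_id=curve.cell_id,
        curve_id=curve.curve_id,
    )


def aggregate_cell(
    fits: Sequence[HertzFit],
    cell_id: str,
    method: str = "mean",
) -> CellStiffness:
    """Aggregate converged per-curve moduli into one per-cell stiffness.

    Arithmetic mean by default (median available); requires at least five
    converged fits, mirroring the ≥ 5 indentations-per-cell protocol.
    """
    moduli = [f.youngs_modulus for f in fits if f.converged]
    if len(moduli) < MIN_CURVES_PER_CELL:
        raise InsufficientDataError(
            f"cell {cell_id}: {len(moduli)} converged fits (< {MIN_CURVES_PER_CELL})"
        )
    agg = float(np.median(moduli)) if method == "median" else float(np.mean(moduli))
    return CellStiffness(
        cell_id=cell_id,
        per_curve_moduli=[float(m) for m in moduli],
        aggregate_modulus=agg,
        n_curves=len(moduli),
    )


def process_curve(curve: ForceCurve, max_indent: float = MAX_INDENT_NM) -> HertzFit:
    """Baseline-correct, detect contact and Hertz-fit a single curve."""
    corrected = correct_baseline(curve)
    zc = detect_contact_point(corrected)
    return fit_hertz(corrected, zc, max_indent=max_indent)


def process_cells(
    cells: Sequence[tuple[str, Sequence[ForceCurve]]],
    max_indent: float = MAX_INDENT_NM,
    method: str = "mean",
) -> pd.DataFrame:
    """Run the full pipeline on many cells; return the per-cell table.

    Cells with fewer than five converged curves are excluded with a
    logged reason. Columns: cell_id, n_curves, E_kPa_mean, E_kPa_sd.
    """
    rows = []
    for cell_id, curves in cells:
        fits = []
        for curve in curves:
            try:
                fits.append(process_curve(curve, max_indent=max_indent))
            except (ProcessingError, FitError) as exc:
                logger.info("cell %s curve %s dropped: %s", cell_id, curve.curve_id, exc)
        try:
            agg = aggregate_cell(fits, cell_id, method=method)
        except InsufficientDataError as exc:
            logger.warning("cell excluded: %s", exc)
            continue
        rows.append(
            {
                "cell_id": agg.cell_id,
                "n_curves": agg.n_curves,
                "E_kPa_mean": agg.aggregate_modulus,
                "E_kPa_sd": float(np.std(agg.per_curve_moduli, ddof=1)),
            }
        )
    return pd.DataFrame(rows, columns=["cell_id", "n_curves", "E_kPa_mean", "E_kPa_sd"])


def read_curve_tsv(tsv_path: str | Path, sidecar_path: str | Path | None = None) -> ForceCurve:
    """Read a curve written by :func:`cellmech.simgen.write_curve_tsv`.

    The TSV has columns ``z_um`` and ``deflection_nm``; the JSON sidecar
    (default: same stem with ``.json``) holds the probe metadata and any
    ground truth.
    """
    tsv_path = Path(tsv_path)
    if sidecar_path is None:
        sidecar_path = tsv_path.with_suffix(".json")
    table = pd.read_csv(tsv_path, sep="\t")
    meta = json.loads(Path(sidecar_path).read_text())
    probe = ProbeSpec(**meta["probe"])
    return ForceCurve(
        z=table["z_um"].to_numpy(),
        deflection=table["deflection_nm"].to_numpy(),
        probe=probe,
        cell_id=meta.get("cell_id", ""),
        curve_id=meta.get("curve_id", ""),
        truth=meta.get("truth"),
    )
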