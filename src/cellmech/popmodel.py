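"""Stiffness-distribution deconvolution: unimodal vs bimodal cell lines.

A cell line's per-cell Young's moduli are modeled as one or two Gaussian
components. The two fits are compared by BIC with guards (minimum
component weight, minimum separation in pooled-SD units) to decide
whether the line is mechanically homogeneous ("Gaussian") or carries two
subpopulations with distinct stiffness ("Bimodal"). Maximum-likelihood EM
is the default; a histogram peak-fit mode (least-squares Gaussian peaks on
a Freedman–Diaconis histogram) is provided as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from sklearn.mixture import GaussianMixture

from .errors import FitError, InsufficientDataError, InvalidConfigError

MIN_CELLS_FOR_FIT = 20


@dataclass
class StiffnessPopulation:
    """Per-cell Young's moduli of one cell line under one condition."""

    line_id: str
    cell_moduli: np.ndarray
    condition: str = "control"

    def __post_init__(self) -> None:
        self.cell_moduli = np.asarray(self.cell_moduli, dtype=float)
        if np.any(self.cell_moduli <= 0):
            raise InvalidConfigError("all cell moduli must be positive (kPa)")

    @property
    def n_cells(self) -> int:
        return int(self.cell_moduli.size)


@dataclass
class ComponentFit:
    """Parameters and score of a k-component Gaussian fit."""

    k: int
    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    log_likelihood: float
    bic: float


@dataclass
class MixtureFit:
    """Selected mixture model plus the unimodal/bimodal classification."""

    n_components: int
    means: list[float]
    sds: list[float]
    weights: list[float]
    model_scores: dict = field(default_factory=dict)
    classification: str = "Gaussian"
    softer_index: int | None = None
    stiffer_index: int | None = None
    line_id: str = ""
    condition: str = "control"


@dataclass
class PatternTransition:
    """Change of distribution pattern between two conditions."""

    transition: str
    label_changed: bool
    component_changes: list[dict] = field(default_factory=list)


def fit_components(
    pop: StiffnessPopulation,
    k: int,
    method: str = "ml",
    seed: int = 0,
    n_init: int = 10,
) -> ComponentFit:
    """Fit a k-component Gaussian model to the per-cell moduli.

    ``method='ml'`` (default) runs EM with k-means initialization and
    ``n_init`` restarts; score is the log-likelihood and BIC. The
    ``'histogram'`` mode instead least-squares-fits k Gaussian peaks to a
    Freedman–Diaconis density histogram (score = histogram RSS stored in
    place of the likelihood-based BIC), mirroring figure-style peak
    deconvolution.
    """
    if k not in (1, 2):
        raise InvalidConfigError("k must be 1 or 2")
    if pop.n_cells < MIN_CELLS_FOR_FIT:
        raise InsufficientDataError(
            f"{pop.n_cells} cells < {MIN_CELLS_FOR_FIT} required for distribution fitting"
        )
    x = pop.cell_moduli
    if method == "ml":
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            init_params="kmeans",
            random_state=seed,
            max_iter=500,
        ).fit(x.reshape(-1, 1))
        if not gm.converged_:
            raise FitError(f"EM did not converge for k={k}")
        order = np.argsort(gm.means_.ravel())
        means = gm.means_.ravel()[order]
        sds = np.sqrt(gm.covariances_.reshape(-1)[order])
        weights = gm.weights_[order]
        ll = float(gm.score(x.reshape(-1, 1)) * x.size)
        return ComponentFit(
            k=k, means=means, sds=sds, weights=weights,
            log_likelihood=ll, bic=float(gm.bic(x.reshape(-1, 1))),
        )
    if method == "histogram":
        return _fit_histogram_peaks(x, k)
    raise InvalidConfigError(f"unknown method {method!r}")


def _fit_histogram_peaks(x: np.ndarray, k: int) -> ComponentFit:
    """Least-squares Gaussian peak fit on a Freedman–Diaconis histogram."""
    counts, edges = np.histogram(x, bins="fd", density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(c, *params):
        out = np.zeros_like(c)
        for j in range(k):
            amp, mu, sig = params[3 * j : 3 * j + 3]
            out = out + amp * np.exp(-((c - mu) ** 2) / (2 * sig**2))
        return out

    # initialize at the k tallest separated histogram modes
    bin_width = float(edges[1] - edges[0])
    order = np.argsort(counts)[::-1]
    peaks: list[tuple[float, float]] = []
    min_sep = float(np.ptp(x)) / (2 * k)
    for i in order:
        c = float(centers[i])
        if all(abs(c - mu) > min_sep for mu, _ in peaks):
            peaks.append((c, float(counts[i])))
        if len(peaks) == k:
            break
    if len(peaks) < k:
        peaks = [
            (float(q), float(counts.max()))
            for q in np.quantile(x, np.linspace(0.25, 0.75, k))
        ]
    peaks.sort()
    sig0 = float(np.std(x)) / (2 * k)
    p0, lower, upper = [], [], []
    for mu0, amp0 in peaks:
        p0 += [amp0, mu0, sig0]
        lower += [0.0, float(x.min()), bin_width / 2]
        upper += [10.0 * float(counts.max()), float(x.max()), float(np.ptp(x))]
    try:
        popt, _ = optimize.curve_fit(
            model, centers, counts, p0=p0, bounds=(lower, upper), maxfev=50000
        )
    except RuntimeError as exc:  # pragma: no cover - rare
        raise FitError(f"histogram peak fit failed: {exc}") from exc
    amps = popt[0::3]
    means = popt[1::3]
    sds = popt[2::3]
    # area under each Gaussian peak approximates the component weight
    areas = amps * sds * np.sqrt(2 * np.pi)
    weights = areas / areas.sum()
    order = np.argsort(means)
    rss = float(np.sum((model(centers, *popt) - counts) ** 2))
    return ComponentFit(
        k=k, means=means[order], sds=sds[order], weights=weights[order],
        log_likelihood=-rss, bic=rss,
    )


def classify_pattern(
    pop: StiffnessPopulation,
    bic_threshold: float = 2.0,
    min_weight: float = 0.1,
    min_separation: float = 1.0,
    seed: int = 0,
) -> MixtureFit:
    """Label a stiffness distribution Gaussian (unimodal) or Bimodal.

    The two-component model is accepted only when all hold:

    - BIC(k=2) < BIC(k=1) − ``bic_threshold``;
    - both mixture weights ≥ ``min_weight``;
    - |μ₂ − μ₁| > ``min_separation`` × pooled SD
      (pooled SD = sqrt of the weight-averaged component variance).

    The guards suppress spurious bimodality driven by heavy tails or a
    handful of outlying cells. Decisions are scale-invariant (kPa vs Pa).
    """
    fit1 = fit_components(pop, 1, seed=seed)
    fit2 = fit_components(pop, 2, seed=seed)
    pooled_sd = float(np.sqrt(np.sum(fit2.weights * fit2.sds**2)))
    separation = float(abs(fit2.means[1] - fit2.means[0]))
    accept2 = (
        fit2.bic < fit1.bic - bic_threshold
        and np.all(fit2.weights >= min_weight)
        and separation > min_separation * pooled_sd
    )
    scores = {
        "bic_1": fit1.bic,
        "bic_2": fit2.bic,
        "loglik_1": fit1.log_likelihood,
        "loglik_2": fit2.log_likelihood,
    }
    if accept2:
        return MixtureFit(
            n_components=2,
            means=[float(m) for m in fit2.means],
            sds=[float(s) for s in fit2.sds],
            weights=[float(w) for w in fit2.weights],
            model_scores=scores,
            classification="Bimodal",
            softer_index=0,
            stiffer_index=1,
            line_id=pop.line_id,
            condition=pop.condition,
        )
    return MixtureFit(
        n_components=1,
        means=[float(fit1.means[0])],
        sds=[float(fit1.sds[0])],
        weights=[1.0],
        model_scores=scores,
        classification="Gaussian",
        line_id=pop.line_id,
        condition=pop.condition,
    )


def peak_ratio(fit: MixtureFit) -> float:
    """Stiffer-over-softer mean modulus ratio of a bimodal fit (≥ 1)."""
    if fit.classification != "Bimodal" or fit.n_components != 2:
        raise InvalidConfigError("peak_ratio requires a Bimodal fit")
    softer = fit.means[fit.softer_index]
    stiffer = fit.means[fit.stiffer_index]
    return stiffer / softer


def compare_conditions(control: MixtureFit, treated: MixtureFit) -> PatternTransition:
    """Report the pattern transition (e.g. Bimodal→Gaussian) between
    conditions and, when both fits have the same number of components,
    the rank-matched per-component mean/SD/weight changes."""
    transition = f"{control.classification}→{treated.classification}"
    changes: list[dict] = []
    if control.n_components == treated.n_components:
        for r in range(control.n_components):
            changes.append(
                {
                    "rank": r,
                    "mean_control": control.means[r],
                    "mean_treated": treated.means[r],
                    "delta_mean": treated.means[r] - control.means[r],
                    "delta_sd": treated.sds[r] - control.sds[r],
                    "delta_weight": treated.weights[r] - control.weights[r],
                }
            )
    return PatternTransition(
        transition=transition,
        label_changed=control.classification != treated.classification,
        component_changes=changes,
    )
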