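"""Synthetic inputs with known ground truth for every pipeline stage.

Generates Hertzian indentation curves with instrument noise, per-cell
stiffness populations (unimodal or two-component mixtures), four-parameter
logistic viability tables, elliptical cell masks with configurable radial
fluorescence patterns, and log-normal expression tables with housekeeping
genes. Every generator takes an explicit seed and stores its ground truth
so recovery can be tested quantitatively.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .doseresponse import four_pl
from .errors import GenerationError, InvalidConfigError
from .forcecurve import ForceCurve
from .physics import ProbeSpec, hertz_prefactor

__all__ = [
    "ProbeSpec",
    "CurveSimConfig",
    "PopulationSpec",
    "SimulatedCell",
    "sample_cell_moduli",
    "gen_force_curve",
    "gen_population",
    "gen_viability",
    "gen_cell_image",
    "gen_expression_table",
    "write_curve_tsv",
]

HOUSEKEEPING_GENES = ("HPRT1", "HMBS", "PPIB")


@dataclass(frozen=True)
class CurveSimConfig:
    """Ground-truth parameters of one simulated indentation curve.

    ``noise_sd`` is additive Gaussian deflection noise in nm. The default
    0.25 nm is the thermal noise limit of the soft lever,
    √(k_BT/k) ≈ 0.23 nm for k = 0.08 N/m at 310 K; real instruments add
    detector noise on top, so the parameter is exposed.
    ``baseline_slope`` is residual optical tilt in nm of deflection per
    µm of piezo travel.
    """

    true_modulus: float = 0.5       # kPa
    contact_z: float = 5.0          # µm
    z_range: tuple[float, float] = (3.5, 6.0)
    n_points: int = 1000            # ~2.5 nm spacing: kHz-rate sampling at 2 µm/s
    noise_sd: float = 0.25          # nm
    baseline_slope: float = 0.0     # nm per µm
    baseline_offset: float = 0.0    # nm
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_modulus <= 0:
            raise InvalidConfigError("true_modulus must be positive (kPa)")
        if self.n_points < 50:
            raise InvalidConfigError("n_points must be >= 50")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        lo, hi = self.z_range
        if not (lo < self.contact_z < hi):
            raise InvalidConfigError(
                f"z_range {self.z_range} must contain contact_z={self.contact_z}"
            )


@dataclass(frozen=True)
class PopulationSpec:
    """Gaussian (mixture) description of a cell line's stiffness.

    One component reproduces a unimodal line; two components (weights
    summing to 1) a bimodal line with softer and stiffer subpopulations.
    """

    component_means: tuple[float, ...]    # kPa
    component_sds: tuple[float, ...]      # kPa
    component_weights: tuple[float, ...] = (1.0,)
    n_cells: int = 100
    curves_per_cell: int = 5

    def __post_init__(self) -> None:
        k = len(self.component_means)
        if not 1 <= k <= 2:
            raise InvalidConfigError("1 or 2 mixture components supported")
        if len(self.component_sds) != k or len(self.component_weights) != k:
            raise InvalidConfigError("means, sds and weights must have equal length")
        if abs(sum(self.component_weights) - 1.0) > 1e-9:
            raise InvalidConfigError("component_weights must sum to 1")
        if any(m <= 0 for m in self.component_means) or any(
            s < 0 for s in self.component_sds
        ):
            raise InvalidConfigError("component means must be > 0 and sds >= 0")
        if self.curves_per_cell < 5:
            raise InvalidConfigError("curves_per_cell must be >= 5")
        if self.n_cells < 1:
            raise InvalidConfigError("n_cells must be >= 1")


@dataclass
class SimulatedCell:
    """One synthetic cell: its true modulus, mixture label and curves."""

    cell_id: str
    true_modulus: float
    component: int
    curves: list[ForceCurve] = field(default_factory=list)


def _solve_deflection(travel_nm: np.ndarray, modulus: float, probe: ProbeSpec) -> np.ndarray:
    """Deflection d solving k·d = A·E·(s − d)^{3/2} for piezo travel s.

    Vectorized damped Newton iteration; the equation is monotone in d so
    convergence from d = 0 is unconditional.
    """
    a_e = hertz_prefactor(probe) * modulus
    k = probe.spring_constant
    d = np.zeros_like(travel_nm)
    for _ in range(100):
        gap = np.clip(travel_nm - d, 0.0, None)
        g = k * d - a_e * gap**1.5
        gprime = k + 1.5 * a_e * np.sqrt(gap)
        step = g / gprime
        d = np.clip(d - step, 0.0, travel_nm)
        if np.max(np.abs(step)) < 1e-12:
            break
    return d


def gen_force_curve(
    config: CurveSimConfig,
    probe: ProbeSpec | None = None,
    rng: np.random.Generator | None = None,
    cell_id: str = "",
    curve_id: str = "",
) -> ForceCurve:
    """Simulate one approach curve under the Hertz spherical-contact model.

    Pre-contact deflection is baseline offset plus tilt plus noise; past
    contact the deflection solves the implicit force balance
    k·d = (4/3)·E/(1−ν²)·√R·δ^{3/2} with δ = piezo travel − d. The curve
    is truncated where the noiseless force exceeds the probe's trigger
    force. Ground truth (E, contact z) is stored on the returned curve.
    """
    probe = probe or ProbeSpec()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    z = np.linspace(config.z_range[0], config.z_range[1], config.n_points)
    travel = np.clip((z - config.contact_z) * 1e3, 0.0, None)
    d_contact = _solve_deflection(travel, config.true_modulus, probe)

    force_true = probe.spring_constant * d_contact
    over = np.nonzero(force_true > probe.trigger_force)[0]
    if over.size:
        z = z[: over[0]]
        d_contact = d_contact[: over[0]]

    deflection = (
        d_contact
        + config.baseline_offset
        + config.baseline_slope * (z - z[0])
        + rng.normal(0.0, config.noise_sd, size=z.size)
        if config.noise_sd > 0
        else d_contact + config.baseline_offset + config.baseline_slope * (z - z[0])
    )
    return ForceCurve(
        z=z,
        deflection=deflection,
        probe=probe,
        cell_id=cell_id,
        curve_id=curve_id,
        truth={"E_kPa": config.true_modulus, "contact_z_um": config.contact_z},
    )


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float) -> float:
    """One positive draw from N(mean, sd²); rejection with 100 attempts."""
    if sd == 0.0:
        return mean
    for _ in range(100):
        x = rng.normal(mean, sd)
        if x > 0:
            return float(x)
    raise GenerationError(
        f"no positive draw from N({mean}, {sd}^2) in 100 attempts"
    )


def sample_cell_moduli(
    spec: PopulationSpec,
    n_cells: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw per-cell moduli and component labels from the mixture.

    Components are chosen by the spec weights; within a component the
    modulus is a positive-truncated Gaussian draw. Returns (moduli kPa,
    component indices).
    """
    components = rng.choice(
        len(spec.component_means), size=n_cells, p=list(spec.component_weights)
    )
    moduli = np.array(
        [
            _truncated_normal(
                rng, spec.component_means[c], spec.component_sds[c]
            )
            for c in components
        ]
    )
    return moduli, components


def gen_population(
    spec: PopulationSpec,
    probe: ProbeSpec | None = None,
    seed: int = 0,
    within_cell_cv: float = 0.10,
    curve_config: CurveSimConfig | None = None,
) -> list[SimulatedCell]:
    """Simulate a cell line: per-cell moduli from a truncated-positive
    Gaussian mixture, ``curves_per_cell`` noisy curves per cell.

    Within a cell, curve-to-curve true moduli vary with coefficient of
    variation ``within_cell_cv`` (local membrane/cytoskeleton
    heterogeneity); draws are truncated to stay positive.
    """
    probe = probe or ProbeSpec()
    base = curve_config or CurveSimConfig()
    rng = np.random.default_rng(seed)
    moduli, components = sample_cell_moduli(spec, spec.n_cells, rng)
    cells: list[SimulatedCell] = []
    for i, (cell_e, comp) in enumerate(zip(moduli, components)):
        cell = SimulatedCell(cell_id=f"cell{i:04d}", true_modulus=float(cell_e), component=int(comp))
        for j in range(spec.curves_per_cell):
            curve_e = _truncated_normal(rng, cell_e, within_cell_cv * cell_e)
            cfg = CurveSimConfig(
                true_modulus=curve_e,
                contact_z=base.contact_z,
                z_range=base.z_range,
                n_points=base.n_points,
                noise_sd=base.noise_sd,
                baseline_slope=base.baseline_slope,
                baseline_offset=base.baseline_offset,
            )
            cell.curves.append(
                gen_force_curve(
                    cfg, probe, rng=rng, cell_id=cell.cell_id, curve_id=f"curve{j}"
                )
            )
        cells.append(cell)
    return cells


def gen_viability(
    ic50: float,
    hill: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
    top: float = 100.0,
    bottom: float = 0.0,
) -> pd.DataFrame:
    """Four-parameter-logistic viability table for an MTT-style assay.

    Viability (percent of untreated) follows the 4PL with the given IC50
    (µM) and Hill slope, plus additive Gaussian noise, clipped to
    [0, 110]. Columns: ``concentration_uM``, ``viability_pct``.
    """
    if ic50 <= 0:
        raise InvalidConfigError("ic50 must be positive (µM)")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise InvalidConfigError("concentrations must be positive (µM)")
    rng = np.random.default_rng(seed)
    v = four_pl(conc, top=top, bottom=bottom, ic50=ic50, hill=hill)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=conc.size)
    v = np.clip(v, 0.0, 110.0)
    return pd.DataFrame({"concentration_uM": conc, "viability_pct": v})


def gen_cell_image(
    axes: tuple[float, float] = (60.0, 30.0),
    intensity_profile: str = "uniform",
    size: tuple[int, int] = (256, 256),
    noise_sd: float = 0.0,
    seed: int = 0,
    angle_deg: float = 0.0,
    background: float = 100.0,
    amplitude: float = 1000.0,
    profile_width: float = 0.35,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic fluorescence image of one elliptical cell plus its mask.

    ``axes`` are the ellipse semi-axes in pixels (major, minor); the
    intensity field inside the mask follows the requested radial pattern
    in the normalized elliptical radius ρ ∈ [0, 1]:

    - ``uniform``: background + amplitude everywhere in the mask;
    - ``center-weighted``: Gaussian blob exp(−ρ²/(2w²)) peaking at the
      centroid (w = ``profile_width``);
    - ``periphery-weighted``: exp(−(1−ρ)²/(2w²)) peaking at the rim.

    Returns (image float64, mask bool). The ellipse is centered on the
    image center and rotated by ``angle_deg``.
    """
    h, w = size
    a, b = axes
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    if a >= min(h, w) / 2 or b >= min(h, w) / 2:
        raise InvalidConfigError("ellipse axes must fit in the image")
    yy, xx = np.mgrid[0:h, 0:w]
    th = np.deg2rad(angle_deg)
    u = (xx - cx) * np.cos(th) + (yy - cy) * np.sin(th)
    v = -(xx - cx) * np.sin(th) + (yy - cy) * np.cos(th)
    rho = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    mask = rho <= 1.0

    image = np.full(size, background, dtype=float)
    if intensity_profile == "uniform":
        image[mask] += amplitude
    elif intensity_profile == "center-weighted":
        image[mask] += amplitude * np.exp(-(rho[mask] ** 2) / (2 * profile_width**2))
    elif intensity_profile == "periphery-weighted":
        image[mask] += amplitude * np.exp(
            -((1.0 - rho[mask]) ** 2) / (2 * profile_width**2)
        )
    else:
        raise InvalidConfigError(f"unknown intensity_profile {intensity_profile!r}")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, size=size)
        image = np.clip(image, 0.0, None)
    return image, mask


def gen_expression_table(
    n_genes: int = 100,
    group_effects: dict[str, float] | None = None,
    n_reps: int = 5,
    seed: int = 0,
    base_log2_mean: float = 6.0,
    log2_sd: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series]:
    """Log-normal expression table with three housekeeping genes.

    Rows are genes (``GENE0001`` ... plus HPRT1, HMBS, PPIB), columns are
    samples split evenly into groups A and B (``n_reps`` each).
    ``group_effects`` maps gene name → fold change of group B over group A
    (housekeeping genes always carry fold change 1). Returns the linear-
    scale table and a sample → group Series.
    """
    if n_genes < 1:
        raise InvalidConfigError("n_genes must be >= 1")
    group_effects = group_effects or {}
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:04d}" for i in range(1, n_genes + 1)] + list(HOUSEKEEPING_GENES)
    samples = [f"A{r+1}" for r in range(n_reps)] + [f"B{r+1}" for r in range(n_reps)]
    groups = pd.Series(["A"] * n_reps + ["B"] * n_reps, index=samples, name="group")

    gene_base = rng.normal(base_log2_mean, 1.0, size=len(genes))
    log2 = rng.normal(0.0, log2_sd, size=(len(genes), len(samples))) + gene_base[:, None]
    for g, fold in group_effects.items():
        if g in HOUSEKEEPING_GENES or g not in genes:
            continue
        i = genes.index(g)
        log2[i, n_reps:] += np.log2(fold)
    table = pd.DataFrame(2.0**log2, index=pd.Index(genes, name="gene"), columns=samples)
    return table, groups


def write_curve_tsv(curve: ForceCurve, tsv_path: str | Path) -> Path:
    """Write a curve as TSV (z_um, deflection_nm) + JSON sidecar.

    The sidecar (same stem, ``.json``) stores the probe metadata, the ids
    and any generator ground truth; ``forcecurve.read_curve_tsv`` round-
    trips it.
    """
    tsv_path = Path(tsv_path)
    pd.DataFrame({"z_um": curve.z, "deflection_nm": curve.deflection}).to_csv(
        tsv_path, sep="\t", index=False
    )
    meta = {
        "probe": {
            "spring_constant": curve.probe.spring_constant,
            "bead_radius": curve.probe.bead_radius,
            "poisson_ratio": curve.probe.poisson_ratio,
            "trigger_force": curve.probe.trigger_force,
            "indent_velocity": curve.probe.indent_velocity,
        },
        "cell_id": curve.cell_id,
        "curve_id": curve.curve_id,
        "truth": curve.truth,
    }
    sidecar = tsv_path.with_suffix(".json")
    sidecar.write_text(json.dumps(meta, indent=1))
    return tsv_path


def write_image_tiff(image: np.ndarray, mask: np.ndarray, stem: str | Path) -> tuple[Path, Path]:
    """Write image as 16-bit grayscale TIFF and mask as 8-bit 0/255 TIFF."""
    stem = Path(stem)
    img_path = stem.with_suffix(".tif")
    mask_path = stem.with_name(stem.name + "_mask").with_suffix(".tif")
    tifffile.imwrite(img_path, np.clip(image, 0, 65535).astype(np.uint16))
    tifffile.imwrite(mask_path, (mask.astype(np.uint8) * 255))
    return img_path, mask_path
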