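"""Synthetic spheroid images and dose-structured screening tables.

The generator emulates the statistical structure a label-free spheroid
screen produces: one roughly circular object per brightfield frame, and
per-feature dose responses that follow four-parameter logistic curves in
feature-specific directions (size-like features shrink with dose, shape
irregularity measures such as form factor rise), with lognormal
multiplicative replicate noise, triplicate structure, and occasional gross
outliers.  Every dataset carries a machine-readable truth record (true
IC50s, injected outlier positions) so recovery and QC tests can score
themselves.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .plate_io import DEFAULT_FILENAME_PATTERN, FeatureTable, parse_filename

#: Ten-point half-log dose ladder up to 10 uM, plus the zero-dose control.
DEFAULT_CONCENTRATIONS_NM = [0.0] + [round(10_000 / 10 ** (k / 2), 4) for k in range(9, -1, -1)]


@dataclass(frozen=True)
class ImageSpec:
    """Parameters of one synthetic brightfield spheroid frame."""

    width: int = 256
    height: int = 256
    radius: float = 50.0
    boundary_roughness: float = 0.0  # amplitude of radial perturbation, [0, 1)
    texture_grain: float = 0.0  # speckle disc radius in px; 0 = uniform interior
    fg_intensity: float = 0.8
    bg_intensity: float = 0.1
    noise_sd: float = 0.0
    polarity: str = "bright"  # bright object on dark bg, or "dark"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width < 4 or self.height < 4:
            raise ValueError("image must be at least 4x4 px")
        if not 0 < self.radius < min(self.width, self.height) / 2:
            raise ValueError("radius must be positive and < half the smaller image side")
        if not 0 <= self.boundary_roughness < 1:
            raise ValueError("boundary_roughness must be in [0, 1)")
        for name in ("fg_intensity", "bg_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0 or self.texture_grain < 0:
            raise ValueError("noise_sd and texture_grain must be >= 0")
        if self.polarity not in ("bright", "dark"):
            raise ValueError("polarity must be 'bright' or 'dark'")


@dataclass
class SpheroidImage:
    """A rendered frame plus the analytic truth about its object."""

    image: np.ndarray  # float grayscale in [0, 1]
    true_area: float  # px^2, from the continuous boundary
    true_perimeter: float  # px
    boundary_radii: np.ndarray  # r(theta) on the dense theta grid
    spec: ImageSpec


def _radial_profile(spec: ImageSpec, rng: np.random.Generator, n_theta: int = 4096):
    """Continuous boundary r(theta) with a few random Fourier roughness modes."""
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    if spec.boundary_roughness > 0:
        modes = np.arange(3, 9)
        amps = rng.uniform(0.3, 1.0, size=modes.size)
        phases = rng.uniform(0, 2 * np.pi, size=modes.size)
        s = np.sum(amps[:, None] * np.cos(modes[:, None] * theta[None, :] + phases[:, None]), axis=0)
        s /= np.max(np.abs(s))
        r = spec.radius * (1 + spec.boundary_roughness * s)
    else:
        r = np.full_like(theta, spec.radius)
    return theta, r


def make_spheroid_image(spec: ImageSpec) -> SpheroidImage:
    """Render one spheroid-like object with analytically known geometry.

    The object boundary is a star-convex radial profile around the image
    centre; its continuous area and perimeter are integrated from the
    profile and returned for oracle tests.  Identical specs (same seed)
    yield bit-identical images.
    """
    rng = np.random.default_rng(spec.seed)
    theta, r = _radial_profile(spec, rng)
    # Continuous geometry: A = 1/2 int r^2 dtheta, P = int sqrt(r^2 + r'^2) dtheta.
    dtheta = 2 * np.pi / theta.size
    true_area = 0.5 * np.sum(r**2) * dtheta
    dr = np.gradient(r, dtheta, edge_order=2)
    true_perimeter = float(np.sum(np.sqrt(r**2 + dr**2)) * dtheta)

    cy, cx = (spec.height - 1) / 2.0, (spec.width - 1) / 2.0
    yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
    ang = np.arctan2(yy - cy, xx - cx) % (2 * np.pi)
    rad = np.hypot(yy - cy, xx - cx)
    r_at = np.interp(ang.ravel(), theta, r, period=2 * np.pi).reshape(ang.shape)
    inside = rad <= r_at

    img = np.full((spec.height, spec.width), spec.bg_intensity, dtype=float)
    img[inside] = spec.fg_intensity
    if spec.texture_grain > 0:
        amp = 0.5 * abs(spec.fg_intensity - spec.bg_intensity)
        n_spots = max(8, int(true_area / (8 * math.pi * spec.texture_grain**2)))
        for _ in range(n_spots):
            a = rng.uniform(0, 2 * np.pi)
            rr = math.sqrt(rng.uniform(0, 1)) * spec.radius * 0.8
            sy, sx = cy + rr * math.sin(a), cx + rr * math.cos(a)
            spot = np.hypot(yy - sy, xx - sx) <= spec.texture_grain
            img[spot & inside] += amp
    if spec.noise_sd > 0:
        img += rng.normal(0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    if spec.polarity == "dark":
        img = 1.0 - img
    return SpheroidImage(img, float(true_area), true_perimeter, r, spec)


def write_image_tiff(si: SpheroidImage, path) -> None:
    """Write the frame as 16-bit grayscale TIFF with a JSON truth sidecar."""
    data = np.round(si.image * 65535).astype(np.uint16)
    tifffile.imwrite(path, data)
    sidecar = Path(path).with_suffix(".truth.json")
    sidecar.write_text(
        json.dumps(
            {"true_area_px2": si.true_area, "true_perimeter_px": si.true_perimeter,
             "spec": asdict(si.spec)},
            indent=2,
        )
    )


# ---------------------------------------------------------------------------
# Dose-structured tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureSpec:
    """Dose behaviour of one morphometric feature.

    ``top``/``bottom`` are fractions of the control value; for a decreasing
    feature the zero-dose asymptote is ``top`` (anchored at 1), for an
    increasing feature it is ``bottom`` (anchored at 1).  ``base_scale``
    sets the raw magnitude so features span realistic, heterogeneous scales.
    """

    name: str
    direction: str  # "decreasing" | "increasing"
    true_ic50: float = 500.0  # nM
    hill: float = 1.2
    top: float = 1.0
    bottom: float = 0.2
    base_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.direction not in ("decreasing", "increasing"):
            raise ValueError("direction must be 'decreasing' or 'increasing'")
        if self.true_ic50 <= 0:
            raise ValueError("true_ic50 must be > 0")
        if self.hill <= 0:
            raise ValueError("hill must be > 0")
        if self.direction == "decreasing" and not self.bottom < self.top:
            raise ValueError("decreasing feature needs bottom < top")
        if self.direction == "increasing" and not self.top > self.bottom:
            raise ValueError("increasing feature needs top > bottom")

    def expected(self, conc_nM: np.ndarray | float) -> np.ndarray:
        """Expected fraction-of-control response at the given dose(s)."""
        c = np.asarray(conc_nM, dtype=float)
        if self.direction == "decreasing":
            near, far = self.top, self.bottom
        else:
            near, far = self.bottom, self.top
        with np.errstate(divide="ignore"):
            ratio = np.where(c > 0, c / self.true_ic50, 0.0)
        val = far + (near - far) / (1 + ratio**self.hill)
        return np.where(c == 0, near, val)


def default_feature_specs(true_ic50: float = 500.0, hill: float = 1.2) -> list[FeatureSpec]:
    """Six shape descriptors with mixed response directions."""
    return [
        FeatureSpec("AreaShape_Area", "decreasing", true_ic50, hill, top=1.0, bottom=0.2,
                    base_scale=1.5e5),
        FeatureSpec("AreaShape_Perimeter", "decreasing", true_ic50, hill, top=1.0, bottom=0.45,
                    base_scale=1.4e3),
        FeatureSpec("AreaShape_FormFactor", "increasing", true_ic50, hill, top=1.7, bottom=1.0,
                    base_scale=0.5),
        FeatureSpec("AreaShape_Compactness", "increasing", true_ic50, hill, top=1.6, bottom=1.0,
                    base_scale=1.15),
        FeatureSpec("AreaShape_Solidity", "decreasing", true_ic50, hill, top=1.0, bottom=0.6,
                    base_scale=0.97),
        FeatureSpec("AreaShape_MedianRadius", "decreasing", true_ic50, hill, top=1.0, bottom=0.3,
                    base_scale=2.1e2),
    ]


@dataclass
class DoseScenario:
    """One cell line x compound titration with triplicates and known truth."""

    cell_line: str = "HCT116"
    compound: str = "DrugA"
    concentrations: list[float] = field(default_factory=lambda: list(DEFAULT_CONCENTRATIONS_NM))
    n_replicates: int = 3
    feature_specs: list[FeatureSpec] = field(default_factory=default_feature_specs)
    noise_cv: float = 10.0  # percent
    outlier_rate: float = 0.0  # probability per triplicate
    fluor_ic50: float = 500.0  # nM, viability-readout midpoint
    fluor_hill: float = 1.2
    fluor_bottom: float = 0.1  # fraction of control RFU
    fluor_scale: float = 5.0e4  # control-level RFU
    seed: int = 0

    def __post_init__(self) -> None:
        concs = list(self.concentrations)
        if sum(1 for c in concs if c == 0) != 1:
            raise ValueError("concentrations must include exactly one zero (control)")
        if any(c < 0 for c in concs):
            raise ValueError("concentrations must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must be in [0, 1]")
        if self.fluor_ic50 <= 0:
            raise ValueError("fluor_ic50 must be > 0")


@dataclass
class DoseTables:
    """Generated screen: feature table, fluorescence table, truth record."""

    features: FeatureTable
    fluorescence: pd.DataFrame
    truth: dict


def _lognormal_factors(rng: np.random.Generator, cv_percent: float, size) -> np.ndarray:
    """Multiplicative lognormal noise with unit mean and the given CV."""
    if cv_percent == 0:
        return np.ones(size)
    cv = cv_percent / 100.0
    sigma = math.sqrt(math.log(1 + cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=size)


def make_dose_tables(scn: DoseScenario) -> DoseTables:
    """Generate feature and fluorescence tables for one titration.

    Expected values follow 4PL curves (fraction-of-control, per
    :class:`FeatureSpec`); replicates get lognormal multiplicative noise at
    ``noise_cv``; with probability ``outlier_rate`` one replicate of a
    triplicate is multiplied by a factor drawn uniformly from [3, 5] and
    recorded in the truth record.
    """
    rng = np.random.default_rng(scn.seed)
    concs = sorted(scn.concentrations)
    reps = list(range(1, scn.n_replicates + 1))
    outliers: list[dict] = []

    rows = []
    for c in concs:
        for r in reps:
            rows.append({"cell_line": scn.cell_line, "compound": scn.compound,
                         "concentration_nM": float(c), "replicate": r})
    df = pd.DataFrame(rows)

    for fs in scn.feature_specs:
        expected = fs.expected(df["concentration_nM"].to_numpy()) * fs.base_scale
        noisy = expected * _lognormal_factors(rng, scn.noise_cv, len(df))
        df[fs.name] = noisy

    # Outlier injection: per (feature, concentration) triplicate.
    for fs in scn.feature_specs:
        for c in concs:
            if rng.random() < scn.outlier_rate:
                rep = int(rng.integers(1, scn.n_replicates + 1))
                factor = float(rng.uniform(3, 5))
                sel = (df["concentration_nM"] == c) & (df["replicate"] == rep)
                df.loc[sel, fs.name] *= factor
                outliers.append({"table": "features", "feature": fs.name,
                                 "concentration_nM": float(c), "replicate": rep,
                                 "factor": factor})

    # Fluorescence (viability) table: decreasing 4PL in RFU.
    fl_rows = []
    for c in concs:
        ratio = (c / scn.fluor_ic50) ** scn.fluor_hill if c > 0 else 0.0
        exp_frac = scn.fluor_bottom + (1 - scn.fluor_bottom) / (1 + ratio)
        vals = exp_frac * scn.fluor_scale * _lognormal_factors(rng, scn.noise_cv, scn.n_replicates)
        if rng.random() < scn.outlier_rate:
            rep = int(rng.integers(0, scn.n_replicates))
            factor = float(rng.uniform(3, 5))
            vals[rep] *= factor
            outliers.append({"table": "fluorescence", "feature": "RFU",
                             "concentration_nM": float(c), "replicate": rep + 1,
                             "factor": factor})
        for r, v in zip(reps, vals):
            fl_rows.append({"cell_line": scn.cell_line, "compound": scn.compound,
                            "concentration_nM": float(c), "replicate": r, "rfu": float(v)})
    fluor = pd.DataFrame(fl_rows)

    truth = {
        "cell_line": scn.cell_line,
        "compound": scn.compound,
        "feature_ic50_nM": {fs.name: fs.true_ic50 for fs in scn.feature_specs},
        "feature_direction": {fs.name: fs.direction for fs in scn.feature_specs},
        "fluor_ic50_nM": scn.fluor_ic50,
        "outliers": outliers,
        "seed": scn.seed,
    }
    ft = FeatureTable(df, provenance="native", extra={"truth": truth})
    return DoseTables(features=ft, fluorescence=fluor, truth=truth)


def make_screen(scenarios: list[DoseScenario]) -> DoseTables:
    """Concatenate several titrations (cell line x compound panels)."""
    parts = [make_dose_tables(s) for s in scenarios]
    feat = pd.concat([p.features.data for p in parts], ignore_index=True)
    fluor = pd.concat([p.fluorescence for p in parts], ignore_index=True)
    truth = {"panels": [p.truth for p in parts]}
    return DoseTables(FeatureTable(feat, provenance="native", extra={"truth": truth}),
                      fluor, truth)


DEFAULT_NAME_TEMPLATE = "{cell_line}_{compound}_{conc}nM_r{replicate}.tif"


def _fmt_conc(c: float) -> str:
    s = f"{c:.4f}".rstrip("0").rstrip(".")
    return s if s else "0"


def make_plate_filenames(scn: DoseScenario, template: str = DEFAULT_NAME_TEMPLATE) -> list[str]:
    """File names for every well of the scenario; round-trip losslessly
    through :func:`spheromet.plate_io.parse_filename`."""
    needed = ("{cell_line}", "{compound}", "{conc}", "{replicate}")
    missing = [p for p in needed if p not in template]
    if missing:
        raise ValueError(f"filename template lacks placeholders: {missing}")
    names = []
    for c in sorted(scn.concentrations):
        for r in range(1, scn.n_replicates + 1):
            names.append(template.format(cell_line=scn.cell_line, compound=scn.compound,
                                         conc=_fmt_conc(c), replicate=r))
    # Sanity: the default template must parse back with the default pattern.
    if template == DEFAULT_NAME_TEMPLATE:
        for n in names:
            parse_filename(n, DEFAULT_FILENAME_PATTERN)
    return names
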