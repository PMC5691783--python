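"""Synthetic-data generators with known ground truth.

The original reflectance spectra and photographs were never deposited, so
every input the pipeline needs is emulated here with seeded randomness:

* viewer sensitivity fixtures (visual-pigment nomogram templates for a
  UVS-type passerine; the curves are generator parameters, not measured
  blue-tit data),
* dowel reflectance spectra — flat achromatic series of graded luminance,
  a brown ramp, a green bump, and brown<->green paint mixtures,
* larval cohorts whose responses follow a configurable polynomial reaction
  norm with individual noise (and optional box effects), with larval
  spectra reconstructed so the visual-model summary matches the simulated
  response,
* specialiser-mixture cohorts for the heterogeneous-environment experiment,
* synthetic calibrated-photography fixtures with an 18% grey patch.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import polynomial as P

from . import photo
from .illuminants import d65
from .spectra import Spectrum, StandardGrid
from .stats import ResponseRecord
from .visual_model import (DEFAULT_DENSITIES, DEFAULT_WEBER, ReceptorSet,
                           quantum_catch)

__all__ = [
    "ViewerFixtureSpec",
    "DowelSpec",
    "CohortSpec",
    "DEFAULT_LUMINANCE_NORM",
    "make_sensitivity_set",
    "make_dowel_spectrum",
    "default_dowels",
    "relative_luminance",
    "dowel_greenness",
    "solve_blend",
    "simulate_cohort",
    "simulate_heterogeneous_cohort",
    "make_synthetic_image",
    "scaled_norm_coefficients",
]

#: Cubic luminance reaction norm, raw coefficients (ascending powers) of
#: f(x) = 0.5 + 0.3(x-0.5) + 4(x-0.5)^3 on relative luminance x in [0, 1]:
#: steep near the extremes, shallow at intermediate luminance.
DEFAULT_LUMINANCE_NORM = (-0.15, 3.3, -6.0, 4.0)


# ---------------------------------------------------------------------------
# Viewer fixture
# ---------------------------------------------------------------------------

@dataclass
class ViewerFixtureSpec:
    """Parameters of a generated receptor set.

    Default lambda-max values approximate a UVS passerine (371/448/503/563 nm
    single cones, 563 nm double cone); they are fixture choices, not
    species measurements.
    """

    lambda_max: dict[str, float] = field(default_factory=lambda: {
        "UV": 371.0, "SW": 448.0, "MW": 503.0, "LW": 563.0})
    dd_lambda_max: float | None = 563.0
    bandwidth: float = 40.0                 # Gaussian shape only
    densities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES))
    base_weber: float = DEFAULT_WEBER
    dd_weber: float = DEFAULT_WEBER
    shape: str = "nomogram"                 # "nomogram" | "gaussian"


def _govardovskii_a1(wl: np.ndarray, lmax: float) -> np.ndarray:
    """A1 visual-pigment absorbance template (alpha + beta band)."""
    x = lmax / wl
    a = 0.8795 + 0.0459 * np.exp(-((lmax - 300.0) ** 2) / 11940.0)
    alpha = 1.0 / (np.exp(69.7 * (a - x)) + np.exp(28.0 * (0.922 - x))
                   + np.exp(-14.9 * (1.104 - x)) + 0.674)
    lmb = 189.0 + 0.315 * lmax
    b = -40.5 + 0.195 * lmax
    beta = 0.26 * np.exp(-(((wl - lmb) / b) ** 2))
    return alpha + beta


def make_sensitivity_set(spec: ViewerFixtureSpec,
                         grid: StandardGrid | None = None) -> ReceptorSet:
    """Generate smooth unimodal receptor sensitivities, peak-normalised to 1."""
    grid = grid or StandardGrid()
    wl = grid.wavelengths
    lmaxes = dict(spec.lambda_max)
    if spec.dd_lambda_max is not None:
        lmaxes["DD"] = spec.dd_lambda_max
    sens = {}
    for name, lm in lmaxes.items():
        if not grid.start <= lm <= grid.stop:
            raise ValueError(
                f"receptor '{name}': lambda_max {lm} outside the grid")
        if spec.shape == "nomogram":
            curve = _govardovskii_a1(wl, lm)
        elif spec.shape == "gaussian":
            if spec.bandwidth <= 0:
                raise ValueError("bandwidth must be positive")
            curve = np.exp(-(((wl - lm) / spec.bandwidth) ** 2))
        else:
            raise ValueError(f"unknown sensitivity shape '{spec.shape}'")
        sens[name] = Spectrum(wl, curve / curve.max(), name=name)
    return ReceptorSet(sens, densities=dict(spec.densities),
                       base_weber=spec.base_weber, dd_weber=spec.dd_weber,
                       name="synthetic-viewer")


# ---------------------------------------------------------------------------
# Dowel spectra
# ---------------------------------------------------------------------------

@dataclass
class DowelSpec:
    """One dowel treatment's reflectance recipe."""

    kind: str                     # achromatic | brown | green | mixture
    code: str = ""
    level: float | None = None    # achromatic reflectance
    mix: float | None = None      # mixture weight of green (0 = brown)

    def __post_init__(self) -> None:
        if self.kind == "achromatic":
            if self.level is None or not 0.0 <= self.level <= 1.0:
                raise ValueError(
                    f"dowel '{self.code}': level must be in [0, 1]")
        elif self.kind == "mixture":
            if self.mix is None or not 0.0 <= self.mix <= 1.0:
                raise ValueError(
                    f"dowel '{self.code}': mix must be in [0, 1]")
        elif self.kind not in ("brown", "green"):
            raise ValueError(f"unknown dowel kind '{self.kind}'")


def _green_curve(wl: np.ndarray) -> np.ndarray:
    # low baseline + bump centred near 550 nm (leaf-green paint proxy)
    return 0.06 + 0.30 * np.exp(-(((wl - 550.0) / 45.0) ** 2))


def _brown_curve(wl: np.ndarray) -> np.ndarray:
    # monotone rise toward the red end (brown paint proxy); amplitude set so
    # the brown and green endmembers are approximately luminance-matched
    # (near-zero achromatic JND) while clearly differing in colour, matching
    # the isoluminant design of the colour experiment
    return 0.05 + 0.50 / (1.0 + np.exp(-(wl - 585.0) / 45.0))


def make_dowel_spectrum(spec: DowelSpec,
                        grid: StandardGrid | None = None) -> Spectrum:
    grid = grid or StandardGrid()
    wl = grid.wavelengths
    if spec.kind == "achromatic":
        vals = np.full(wl.size, float(spec.level))
    elif spec.kind == "green":
        vals = _green_curve(wl)
    elif spec.kind == "brown":
        vals = _brown_curve(wl)
    else:
        w = float(spec.mix)
        vals = w * _green_curve(wl) + (1.0 - w) * _brown_curve(wl)
    return Spectrum(wl, np.clip(vals, 0.0, 1.0), name=spec.code or spec.kind)


def default_dowels(experiment: str) -> dict[str, DowelSpec]:
    """Default treatment sets per experiment.

    luminance: flat greys Bl/BW1/BW2/BW3/Wh at graded reflectance;
    colour: isoluminant brown (IB) vs green (IG); colour-luminance: paint
    mixtures Br/BG1/BG2/BG3/Gr; heterogeneous: the Br and Gr endpoints
    (mixing happens at the cohort level, not in the paint).
    """
    if experiment == "luminance":
        levels = {"Bl": 0.05, "BW1": 0.15, "BW2": 0.30, "BW3": 0.50,
                  "Wh": 0.80}
        return {c: DowelSpec("achromatic", code=c, level=v)
                for c, v in levels.items()}
    if experiment == "colour":
        return {"IB": DowelSpec("brown", code="IB"),
                "IG": DowelSpec("green", code="IG")}
    if experiment == "colour-luminance":
        mixes = {"Br": 0.0, "BG1": 0.25, "BG2": 0.50, "BG3": 0.75,
                 "Gr": 1.0}
        return {c: DowelSpec("mixture", code=c, mix=w)
                for c, w in mixes.items()}
    if experiment == "heterogeneous":
        return {"Br": DowelSpec("brown", code="Br"),
                "Gr": DowelSpec("green", code="Gr")}
    raise ValueError(f"unknown experiment '{experiment}'")


# ---------------------------------------------------------------------------
# Stimulus summaries and inverse-summary spectra
# ---------------------------------------------------------------------------

def relative_luminance(reflectance: Spectrum, receptors: ReceptorSet,
                       illuminant: Spectrum | None = None,
                       grid: StandardGrid | None = None) -> float:
    """Double-cone catch relative to a perfect white reflector (in [0, 1])."""
    grid = grid or StandardGrid()
    illuminant = illuminant if illuminant is not None else d65(grid)
    q = quantum_catch(reflectance, illuminant, receptors, grid=grid)
    white = Spectrum(grid.wavelengths, np.ones(len(grid)), name="white")
    qw = quantum_catch(white, illuminant, receptors, grid=grid)
    return q.dd / qw.dd


def dowel_greenness(reflectance: Spectrum, receptors: ReceptorSet,
                    illuminant: Spectrum | None = None,
                    grid: StandardGrid | None = None) -> float:
    """Chromatic greenness MW/(MW+LW) of a stimulus."""
    from .visual_model import greenness_chromatic

    grid = grid or StandardGrid()
    illuminant = illuminant if illuminant is not None else d65(grid)
    q = quantum_catch(reflectance, illuminant, receptors, grid=grid)
    return greenness_chromatic(q)


def solve_blend(end_low: Spectrum, end_high: Spectrum, summary_fn,
                target: float, tol: float = 1e-9) -> tuple[float, Spectrum]:
    """Find the convex blend of two endmember spectra whose summary statistic
    equals ``target``, by monotone bisection on the blend weight.

    Targets outside the achievable range are clamped to the nearest
    endmember.  Returns (weight, blended spectrum).
    """
    wl = end_low.wavelengths

    def blend(w: float) -> Spectrum:
        return Spectrum(wl, (1 - w) * end_low.values + w * end_high.values)

    s_lo, s_hi = summary_fn(blend(0.0)), summary_fn(blend(1.0))
    sign = 1.0 if s_hi >= s_lo else -1.0
    lo_val, hi_val = min(s_lo, s_hi), max(s_lo, s_hi)
    if target <= lo_val:
        w = 0.0 if sign > 0 else 1.0
        return w, blend(w)
    if target >= hi_val:
        w = 1.0 if sign > 0 else 0.0
        return w, blend(w)
    a, b = 0.0, 1.0
    while b - a > tol:
        m = 0.5 * (a + b)
        if sign * (summary_fn(blend(m)) - target) < 0:
            a = m
        else:
            b = m
    w = 0.5 * (a + b)
    return w, blend(w)


def scaled_norm_coefficients(x_lo: float, x_hi: float,
                             unit_coeffs) -> np.ndarray:
    """Map a polynomial defined on the unit interval to raw stimulus scale.

    Given f(u) with u = (x - x_lo)/(x_hi - x_lo), returns the ascending raw
    coefficients of f as a polynomial in x.
    """
    span = x_hi - x_lo
    if span == 0:
        raise ValueError("x_lo and x_hi must differ")
    base = np.array([-x_lo / span, 1.0 / span])
    out = np.zeros(1)
    for k, c in enumerate(unit_coeffs):
        term = c * (P.polypow(base, k) if k else np.ones(1))
        out = P.polyadd(out, term)
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Design and noise parameters of a simulated rearing cohort.

    Defaults follow the study design: 25 larvae per replicate box, three
    boxes per treatment; specialist greenness components 38% vs 56% with
    SD 3 (six generator-SDs apart).  ``seed`` is mandatory.
    """

    seed: int
    n_per_box: int = 25
    boxes_per_treatment: int = 3
    norm_coefficients: tuple = DEFAULT_LUMINANCE_NORM
    noise_sd: float = 0.05
    box_sd: float = 0.0
    p_green: float | None = None
    green_mean: float = 56.0
    brown_mean: float = 38.0
    component_sd: float = 3.0

    def __post_init__(self) -> None:
        if self.n_per_box < 1 or self.boxes_per_treatment < 1:
            raise ValueError("n_per_box and boxes_per_treatment must be >= 1")
        if self.noise_sd < 0 or self.box_sd < 0 or self.component_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.p_green is not None and not 0.0 <= self.p_green <= 1.0:
            raise ValueError(f"p_green must be in [0, 1], got {self.p_green}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _luminance_endmembers(grid: StandardGrid) -> tuple[Spectrum, Spectrum]:
    wl = grid.wavelengths
    return (Spectrum(wl, np.full(wl.size, 0.01), name="black"),
            Spectrum(wl, np.full(wl.size, 0.98), name="white"))


def simulate_cohort(
    dowels: dict[str, DowelSpec],
    cohort: CohortSpec,
    receptors: ReceptorSet,
    stimulus_kind: str = "luminance",
    illuminant: Spectrum | None = None,
    grid: StandardGrid | None = None,
    make_spectra: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[list[ResponseRecord], dict[str, Spectrum]]:
    """Simulate a reaction-norm rearing experiment.

    For each treatment the dowel's stimulus summary (relative double-cone
    luminance or chromatic greenness) is computed; each larva's true
    response is the cohort's polynomial reaction norm at that stimulus plus
    a box-level offset and independent Gaussian noise.  When
    ``make_spectra`` is true, a reflectance spectrum is reconstructed for
    each larva by blending two endmember spectra so that its visual-model
    summary equals the simulated response (bisection, tol 1e-9; responses
    outside the achievable summary range clamp to an endmember).
    """
    if stimulus_kind not in ("luminance", "greenness"):
        raise ValueError("stimulus_kind must be 'luminance' or 'greenness'")
    grid = grid or StandardGrid()
    illuminant = illuminant if illuminant is not None else d65(grid)
    rng = rng if rng is not None else cohort.rng()

    if stimulus_kind == "luminance":
        def summary(s: Spectrum) -> float:
            return relative_luminance(s, receptors, illuminant, grid)
        ends = _luminance_endmembers(grid)
    else:
        def summary(s: Spectrum) -> float:
            return dowel_greenness(s, receptors, illuminant, grid)
        ends = (make_dowel_spectrum(DowelSpec("brown"), grid),
                make_dowel_spectrum(DowelSpec("green"), grid))

    records: list[ResponseRecord] = []
    spectra: dict[str, Spectrum] = {}
    for code in sorted(dowels):
        x = summary(make_dowel_spectrum(dowels[code], grid))
        true_mean = float(P.polyval(x, np.asarray(cohort.norm_coefficients)))
        for b in range(cohort.boxes_per_treatment):
            box = f"{code}-b{b + 1}"
            box_off = rng.normal(0.0, cohort.box_sd) if cohort.box_sd > 0 else 0.0
            noise = rng.normal(0.0, cohort.noise_sd, size=cohort.n_per_box)
            for i in range(cohort.n_per_box):
                sid = f"{box}-l{i + 1}"
                resp = true_mean + box_off + noise[i]
                records.append(ResponseRecord(sid, code, box, x, resp))
                if make_spectra:
                    _, sp = solve_blend(ends[0], ends[1], summary, resp)
                    sp.name = sid
                    spectra[sid] = sp
    return records, spectra


def simulate_heterogeneous_cohort(
    p_green: float,
    cohort: CohortSpec,
    treatment_code: str | None = None,
    rng: np.random.Generator | None = None,
) -> list[ResponseRecord]:
    """Simulate one heterogeneous-environment treatment.

    Each larva independently specialises on green with probability
    ``p_green`` (brown otherwise) and draws its photographic greenness (%)
    from that component's normal distribution — a two-component specialiser
    mixture with no intermediate component.  The stimulus value recorded is
    the green-dowel proportion.
    """
    if not 0.0 <= p_green <= 1.0:
        raise ValueError(f"p_green must be in [0, 1], got {p_green}")
    rng = rng if rng is not None else cohort.rng()
    code = treatment_code or f"H{int(round(100 * p_green)):03d}"
    records = []
    for b in range(cohort.boxes_per_treatment):
        box = f"{code}-b{b + 1}"
        is_green = rng.random(cohort.n_per_box) < p_green
        vals = np.where(is_green, cohort.green_mean, cohort.brown_mean)
        vals = vals + rng.normal(0.0, cohort.component_sd,
                                 size=cohort.n_per_box)
        for i in range(cohort.n_per_box):
            records.append(ResponseRecord(f"{box}-l{i + 1}", code, box,
                                          p_green, float(vals[i])))
    return records


# ---------------------------------------------------------------------------
# Photographic fixtures
# ---------------------------------------------------------------------------

def make_synthetic_image(
    true_rgbs,
    cast=(1.0, 1.0, 1.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    shape: tuple[int, int] = (96, 150),
) -> tuple[np.ndarray, photo.RoiSet, dict]:
    """Build a linear-light photograph fixture with known ground truth.

    Six specimen patches at the given true linear RGB values and one grey
    patch of true reflectance 0.18 are painted on a dark background; a
    global per-channel gain ``cast`` (the unknown illuminant/camera balance
    the calibration must undo) and optional Gaussian pixel noise are then
    applied.  Returns (image, RoiSet, ground-truth dict).
    """
    true_rgbs = np.asarray(true_rgbs, dtype=float)
    if true_rgbs.shape != (6, 3):
        raise ValueError("true_rgbs must have shape (6, 3)")
    cast = np.asarray(cast, dtype=float)
    if cast.shape != (3,) or np.any(cast <= 0):
        raise ValueError("cast must be 3 positive per-channel gains")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")

    h, w = shape
    img = np.full((h, w, 3), 0.05)
    grey = photo.Roi(4, 4, 24, 24)
    img[grey.slice()] = photo.GREY_REFLECTANCE

    rois = {}
    pw, ph = 28, 26
    for i, label in enumerate(photo.SEGMENT_LABELS):
        r, c = divmod(i, 3)
        r0 = 30 + r * (ph + 4)
        c0 = 4 + c * (pw + 4)
        roi = photo.Roi(r0, c0, r0 + ph, c0 + pw)
        rois[label] = roi
        img[roi.slice()] = true_rgbs[i]
    roiset = photo.RoiSet(specimen=rois, grey=grey)
    roiset.check_bounds((h, w))

    img = img * cast
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
        img = np.clip(img, 0.0, None)

    truth = {
        "rgbs": {lab: true_rgbs[i].tolist()
                 for i, lab in enumerate(photo.SEGMENT_LABELS)},
        "greenness": {lab: photo.greenness_rgb(true_rgbs[i])
                      for i, lab in enumerate(photo.SEGMENT_LABELS)},
        "specimen_greenness": float(np.mean(
            [photo.greenness_rgb(v) for v in true_rgbs])),
        "cast": cast.tolist(),
    }
    return img, roiset, truth
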