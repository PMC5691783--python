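"""Receptor-noise-limited avian visual model.

Computes cone quantum catches for a stimulus under an illuminant, and from
those the chromatic and achromatic discriminability between two stimuli in
just-noticeable-difference (JND) units, following the receptor-noise-limited
model of tetrachromatic colour discrimination.  The viewer defaults to a
blue tit (*Cyanistes caeruleus*)-like tetrachromat with relative cone
densities UV = 0.3704, SW = 0.7111, MW = 0.9926, LW = 1.0 and a base Weber
fraction of 0.05; luminance discrimination uses the double (dorsal) cone.

A chromatic "greenness" summary, the opponency ratio MW/(MW+LW), is also
provided.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

import numpy as np
import yaml

from .spectra import Spectrum, StandardGrid

logger = logging.getLogger(__name__)

__all__ = [
    "SINGLE_CONES",
    "ReceptorSet",
    "QuantumCatchVector",
    "WeberVector",
    "DiscriminabilityCategory",
    "DiscriminabilityResult",
    "quantum_catch",
    "weber_fractions",
    "chromatic_jnd",
    "achromatic_jnd",
    "discriminability_category",
    "discriminability",
    "greenness_chromatic",
]

#: Canonical single-cone order used throughout (short to long wavelength
#: would be UV, SW, MW, LW; this fixed order defines vector layouts).
SINGLE_CONES = ("UV", "SW", "MW", "LW")

#: Relative cone densities of the blue tit retina.
DEFAULT_DENSITIES = {"UV": 0.3704, "SW": 0.7111, "MW": 0.9926, "LW": 1.0}

#: Base Weber fraction of the most abundant cone.
DEFAULT_WEBER = 0.05


@dataclass
class ReceptorSet:
    """A viewer: receptor sensitivities, relative densities and noise.

    ``sensitivities`` maps receptor name -> sensitivity Spectrum on the
    canonical grid; it must contain the four single cones and may contain
    the double cone "DD" for luminance modelling.
    """

    sensitivities: dict[str, Spectrum]
    densities: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DENSITIES))
    base_weber: float = DEFAULT_WEBER
    dd_weber: float = DEFAULT_WEBER
    name: str = "viewer"

    def __post_init__(self) -> None:
        missing = [c for c in SINGLE_CONES if c not in self.sensitivities]
        if missing:
            raise ValueError(f"receptor set missing single cones: {missing}")
        for rname, spec in self.sensitivities.items():
            if np.any(spec.values < 0):
                raise ValueError(f"receptor '{rname}': negative sensitivity")
        for rname in SINGLE_CONES:
            eta = self.densities.get(rname)
            if eta is None or not 0 < eta <= 1:
                raise ValueError(
                    f"receptor '{rname}': density must be in (0, 1], got {eta}")
        if max(self.densities[c] for c in SINGLE_CONES) != 1.0:
            raise ValueError("reference receptor must have density 1.0")
        if self.base_weber <= 0 or self.dd_weber <= 0:
            raise ValueError("Weber fractions must be positive")

    @property
    def has_double_cone(self) -> bool:
        return "DD" in self.sensitivities

    @classmethod
    def from_yaml(cls, path) -> "ReceptorSet":
        """Load a viewer definition (receptor -> sensitivity table path or
        lambda-max spec, densities, Weber fractions) from YAML."""
        from . import synthetic  # local import to avoid a cycle

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        if "lambda_max" in cfg:
            spec = synthetic.ViewerFixtureSpec(
                lambda_max=cfg["lambda_max"],
                dd_lambda_max=cfg.get("dd_lambda_max"),
                densities=cfg.get("densities", dict(DEFAULT_DENSITIES)),
                base_weber=cfg.get("base_weber", DEFAULT_WEBER),
                dd_weber=cfg.get("dd_weber", DEFAULT_WEBER),
                shape=cfg.get("shape", "nomogram"),
            )
            return synthetic.make_sensitivity_set(spec)
        raise ValueError(f"{path}: viewer file needs a 'lambda_max' mapping")


@dataclass
class QuantumCatchVector:
    """Relative photon catches per receptor for one stimulus."""

    catches: dict[str, float]
    stimulus: str = ""

    def __getitem__(self, receptor: str) -> float:
        return self.catches[receptor]

    def single_cone_array(self) -> np.ndarray:
        return np.array([self.catches[c] for c in SINGLE_CONES])

    @property
    def dd(self) -> float:
        if "DD" not in self.catches:
            raise KeyError(
                f"stimulus '{self.stimulus}': no double-cone (DD) catch; "
                "viewer lacks a DD sensitivity curve")
        return self.catches["DD"]


@dataclass
class WeberVector:
    """Noise-scaled Weber fraction per receptor (e_i)."""

    fractions: dict[str, float]

    def __getitem__(self, receptor: str) -> float:
        return self.fractions[receptor]

    def single_cone_array(self) -> np.ndarray:
        return np.array([self.fractions[c] for c in SINGLE_CONES])


class DiscriminabilityCategory(str, enum.Enum):
    INDISCRIMINABLE = "indiscriminable"
    GOOD_CONDITIONS_ONLY = "good-conditions-only"
    DISCRIMINABLE = "discriminable"


@dataclass
class DiscriminabilityResult:
    chromatic_jnd: float
    achromatic_jnd: float | None
    chromatic_category: DiscriminabilityCategory
    achromatic_category: DiscriminabilityCategory | None


def quantum_catch(
    reflectance: Spectrum,
    illuminant: Spectrum,
    receptors: ReceptorSet,
    grid: StandardGrid | None = None,
    floor: bool = False,
) -> QuantumCatchVector:
    """Receptor quantum catches Q_i = sum_lambda R*I*S_i*dlambda.

    All spectra must live on the canonical grid.  A zero catch is an error
    (the discriminability metric takes logs); pass ``floor=True`` to replace
    catches below 1e-6 x the maximum catch with that floor instead.
    """
    grid = grid or StandardGrid()
    for nm, sp in (("reflectance", reflectance), ("illuminant", illuminant)):
        if not sp.on_grid(grid):
            raise ValueError(f"{nm} spectrum is not on the canonical grid")
    prod = reflectance.values * illuminant.values
    catches = {}
    for rname, sens in receptors.sensitivities.items():
        if not sens.on_grid(grid):
            raise ValueError(f"receptor '{rname}' sensitivity not on grid")
        catches[rname] = float(np.sum(prod * sens.values) * grid.step)
    qmax = max(catches.values())
    zeroish = [r for r, q in catches.items() if q <= 0]
    if zeroish:
        if not floor or qmax <= 0:
            raise ValueError(
                f"zero quantum catch for receptor(s) {zeroish} on stimulus "
                f"'{reflectance.name}'; the JND metric takes logs — "
                "pass floor=True to apply a small-catch floor"
            )
        eps = 1e-6 * qmax
        for r in zeroish:
            catches[r] = eps
        logger.info("quantum_catch: floored %d receptor catch(es) at %.3g",
                    len(zeroish), eps)
    return QuantumCatchVector(catches, stimulus=reflectance.name)


def weber_fractions(receptors: ReceptorSet) -> WeberVector:
    """Per-receptor Weber fractions from relative cone densities.

    Neural-noise scaling: e_i = nu / sqrt(eta_i / eta_max), so the most
    abundant cone has e = nu and rarer cones are noisier.  The double cone,
    if present, gets the configured achromatic Weber fraction.
    """
    etas = {c: receptors.densities[c] for c in SINGLE_CONES}
    eta_max = max(etas.values())
    fr = {c: receptors.base_weber / np.sqrt(eta / eta_max)
          for c, eta in etas.items()}
    if receptors.has_double_cone:
        fr["DD"] = receptors.dd_weber
    return WeberVector(fr)


def _check_positive_catches(q: QuantumCatchVector) -> np.ndarray:
    arr = q.single_cone_array()
    if np.any(arr <= 0):
        raise ValueError(
            f"stimulus '{q.stimulus}': non-positive single-cone catch")
    return arr


def chromatic_jnd(
    a: QuantumCatchVector, b: QuantumCatchVector, w: WeberVector
) -> float:
    """Chromatic distance (JND) between two stimuli.

    Tetrachromat receptor-noise formula on log catch ratios
    ``df_i = ln(Q_i^a / Q_i^b)``::

        dS^2 = sum_pairs (e_k e_l)^2 (df_i - df_j)^2
               / sum_triples (e_i e_j e_k)^2

    where for each receptor pair (i, j) the weight uses the complementary
    pair (k, l), and the denominator sums over all receptor triples.  The
    result is symmetric and invariant to a common intensity scaling of
    either stimulus.
    """
    qa = _check_positive_catches(a)
    qb = _check_positive_catches(b)
    e = w.single_cone_array()
    df = np.log(qa / qb)

    idx = range(4)
    num = 0.0
    for i in idx:
        for j in idx:
            if j <= i:
                continue
            k, l = [r for r in idx if r not in (i, j)]
            num += (e[k] * e[l]) ** 2 * (df[i] - df[j]) ** 2
    den = 0.0
    for i in idx:
        trip = [r for r in idx if r != i]
        den += np.prod(e[trip]) ** 2
    return float(np.sqrt(num / den))


def achromatic_jnd(
    a: QuantumCatchVector,
    b: QuantumCatchVector,
    receptors: ReceptorSet | None = None,
    dd_weber: float | None = None,
) -> float:
    """Luminance distance (JND) from double-cone catches.

    dL = |ln(Q_DD^a / Q_DD^b)| / e_DD.
    """
    if dd_weber is None:
        if receptors is None:
            raise ValueError("supply receptors or dd_weber")
        dd_weber = receptors.dd_weber
    qa, qb = a.dd, b.dd
    if qa <= 0 or qb <= 0:
        raise ValueError("non-positive double-cone catch")
    return float(abs(np.log(qa / qb)) / dd_weber)


def discriminability_category(jnd: float) -> DiscriminabilityCategory:
    """Categorise a JND: <1 indiscriminable; 1-3 discriminable only under
    good viewing conditions; >3 discriminable."""
    if jnd < 0:
        raise ValueError(f"JND must be non-negative, got {jnd}")
    if jnd < 1.0:
        return DiscriminabilityCategory.INDISCRIMINABLE
    if jnd <= 3.0:
        return DiscriminabilityCategory.GOOD_CONDITIONS_ONLY
    return DiscriminabilityCategory.DISCRIMINABLE


def discriminability(
    a: QuantumCatchVector,
    b: QuantumCatchVector,
    receptors: ReceptorSet,
) -> DiscriminabilityResult:
    """Chromatic and (if DD catches exist) achromatic JNDs with categories."""
    w = weber_fractions(receptors)
    ds = chromatic_jnd(a, b, w)
    dl = cat_l = None
    if "DD" in a.catches and "DD" in b.catches:
        dl = achromatic_jnd(a, b, receptors)
        cat_l = discriminability_category(dl)
    return DiscriminabilityResult(ds, dl, discriminability_category(ds), cat_l)


def greenness_chromatic(q: QuantumCatchVector) -> float:
    """Chromatic greenness: the opponency ratio MW/(MW+LW), in [0, 1]."""
    mw, lw = q.catches["MW"], q.catches["LW"]
    if mw < 0 or lw < 0 or mw + lw <= 0:
        raise ValueError("MW and LW catches must be positive")
    return float(mw / (mw + lw))
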