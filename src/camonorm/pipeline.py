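"""End-to-end orchestration of the four rearing experiments.

Each experiment maps to one stage chain:

* ``colour`` — two isoluminant treatments: greenness, colour-space
  coordinates, pairwise JND matrices, nested ANOVA.
* ``luminance`` — five-step achromatic gradient: double-cone luminance,
  polynomial reaction-norm fits with order selection, reference curves,
  one-way ANOVA, achromatic JND matrix.
* ``colour-luminance`` — five-step brown-to-green gradient: chromatic
  greenness fits, one-way ANOVA, chromatic JND matrix.
* ``heterogeneous`` — five green:brown mixture ratios scored through the
  calibrated-photograph pathway: RGB greenness, one-way ANOVA,
  Brown-Forsythe variance test, and the drop-most-variable retest.

All randomness flows from the config seed; a rerun with the same config
writes byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import photo, stats, synthetic
from .colour_space import relative_catches, tetra_coordinates
from .illuminants import get_illuminant
from .spectra import SpecimenSpectra, Spectrum, StandardGrid, average_specimen
from .stats import (ModelSelection, ResponseRecord, records_to_frame)
from .visual_model import (QuantumCatchVector, ReceptorSet, WeberVector,
                           achromatic_jnd, chromatic_jnd,
                           discriminability_category, greenness_chromatic,
                           quantum_catch, weber_fractions)

logger = logging.getLogger(__name__)

__all__ = ["ExperimentConfig", "RunReport", "run_experiment", "jnd_matrix",
           "write_report", "EXPERIMENTS"]

EXPERIMENTS = ("colour", "luminance", "colour-luminance", "heterogeneous")

_FLOAT_FMT = "%.10g"


@dataclass
class ExperimentConfig:
    """Validated configuration of one experiment run."""

    experiment: str
    seed: int
    out_dir: str | None = None
    illuminant: str = "d65"
    alpha: float = 0.05
    orders: tuple = (1, 2, 3, 4)
    n_per_box: int | None = None
    boxes_per_treatment: int | None = None
    noise_sd: float | None = None
    viewer: synthetic.ViewerFixtureSpec = field(
        default_factory=synthetic.ViewerFixtureSpec)

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(
                f"unknown experiment '{self.experiment}'; "
                f"choose from {EXPERIMENTS}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if any(o < 1 for o in self.orders):
            raise ValueError("polynomial orders must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        viewer = cfg.pop("viewer", None)
        obj = cls(**cfg)
        if viewer:
            obj.viewer = synthetic.ViewerFixtureSpec(**viewer)
        return obj

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (output location
        excluded, so identical runs hash identically wherever written)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir", None)
        blob = yaml.safe_dump(_to_jsonable(d), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All result tables of one experiment run, plus provenance."""

    experiment: str
    tables: dict[str, pd.DataFrame]
    results: dict
    provenance: dict


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and np.isinf(obj):
        return "inf"
    if isinstance(obj, Path):
        return str(obj)
    return obj


def _test_to_dict(res: stats.GroupTestResult) -> dict:
    return _to_jsonable({
        "method": res.method,
        "statistic": res.statistic,
        "df": list(res.df),
        "p_value": res.p_value,
        "degenerate": res.degenerate,
        "note": res.note,
    })


def jnd_matrix(
    catches: dict[str, QuantumCatchVector],
    w: WeberVector,
    mode: str = "chromatic",
    dd_weber: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise JND matrix over labelled stimuli, with categories.

    Returns (jnd DataFrame, category DataFrame), symmetric with zero
    diagonal.
    """
    if len(catches) < 2:
        raise ValueError("need >= 2 stimuli")
    if mode not in ("chromatic", "achromatic"):
        raise ValueError("mode must be 'chromatic' or 'achromatic'")
    if mode == "achromatic":
        dd = dd_weber if dd_weber is not None else w.fractions.get("DD")
        if dd is None:
            raise ValueError("achromatic mode needs a DD Weber fraction")
    labels = list(catches)
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if mode == "chromatic":
                v = chromatic_jnd(catches[labels[i]], catches[labels[j]], w)
            else:
                v = achromatic_jnd(catches[labels[i]], catches[labels[j]],
                                   dd_weber=dd)
            mat[i, j] = mat[j, i] = v
    jnd = pd.DataFrame(mat, index=labels, columns=labels)
    cats = jnd.map(lambda v: discriminability_category(v).value)
    for lab in labels:
        cats.loc[lab, lab] = "self"
    return jnd, cats


# ---------------------------------------------------------------------------
# Stage helpers
# ---------------------------------------------------------------------------

def _treatment_mean_spectra(records, spectra, grid) -> dict[str, Spectrum]:
    """Average larval spectra within each treatment (averaging before
    catches, consistent with specimen-level spectral averaging)."""
    by_trt: dict[str, list[Spectrum]] = {}
    for r in records:
        if r.specimen_id in spectra:
            by_trt.setdefault(r.treatment_code, []).append(
                spectra[r.specimen_id])
    return {
        t: average_specimen(
            SpecimenSpectra(f"mean-{t}", t, "all", sp), grid)
        for t, sp in sorted(by_trt.items())
    }


def _fit_and_select(records, orders, alpha):
    fits = stats.fit_polynomials(records, orders=orders)
    comparisons = (stats.compare_nested_fits(fits)
                   if len(fits) > 1 else None)
    selection = (stats.select_best(fits, alpha=alpha)
                 if len(fits) > 1 else None)
    fit_rows = [{
        "order": f.order, "r2": f.r2, "adj_r2": f.adj_r2, "rss": f.rss,
        **{f"beta_{i}": c for i, c in enumerate(f.coefficients)},
    } for f in fits]
    return fits, comparisons, selection, pd.DataFrame(fit_rows)


def _reference_table(records) -> pd.DataFrame:
    df = records_to_frame(records)
    means = df.groupby("treatment").agg(stimulus=("stimulus", "mean"),
                                        response=("response", "mean"))
    lo = means.loc[means["stimulus"].idxmin()]
    hi = means.loc[means["stimulus"].idxmax()]
    grid_x = np.linspace(lo["stimulus"], hi["stimulus"], 101)
    return stats.reference_responses(
        grid_x, (lo["stimulus"], lo["response"]),
        (hi["stimulus"], hi["response"]))


# ---------------------------------------------------------------------------
# Experiment chains
# ---------------------------------------------------------------------------

def _run_gradient(cfg: ExperimentConfig, grid, receptors, ill, rng):
    """Shared chain for the luminance and colour-luminance gradients."""
    is_lum = cfg.experiment == "luminance"
    dowels = synthetic.default_dowels(cfg.experiment)
    specs = {c: synthetic.make_dowel_spectrum(d, grid)
             for c, d in dowels.items()}

    if is_lum:
        stim = {c: synthetic.relative_luminance(s, receptors, ill, grid)
                for c, s in specs.items()}
        coeffs = synthetic.DEFAULT_LUMINANCE_NORM
        noise = cfg.noise_sd if cfg.noise_sd is not None else 0.05
        kind = "luminance"
    else:
        stim = {c: synthetic.dowel_greenness(s, receptors, ill, grid)
                for c, s in specs.items()}
        # quadratic response on the dowel greenness span: compressed at the
        # brown end, accelerating toward green
        lo, hi = min(stim.values()), max(stim.values())
        unit_quad = [0.0, 0.35, 0.65]   # f(0)=0, f(1)=1, convex
        coeffs = tuple(np.asarray(
            synthetic.scaled_norm_coefficients(lo, hi, unit_quad)) * (hi - lo)
            + np.array([lo, 0.0, 0.0]))
        noise = cfg.noise_sd if cfg.noise_sd is not None else 0.012
        kind = "greenness"

    cohort = synthetic.CohortSpec(
        seed=cfg.seed,
        n_per_box=cfg.n_per_box or 25,
        boxes_per_treatment=cfg.boxes_per_treatment or 3,
        norm_coefficients=coeffs,
        noise_sd=noise,
    )
    records, spectra = synthetic.simulate_cohort(
        dowels, cohort, receptors, stimulus_kind=kind, illuminant=ill,
        grid=grid, make_spectra=True, rng=rng)

    fits, comparisons, selection, fit_tbl = _fit_and_select(
        records, cfg.orders, cfg.alpha)
    df = records_to_frame(records)
    anova = stats.one_way_anova(
        {t: g["response"].to_numpy() for t, g in df.groupby("treatment")})

    mean_larvae = _treatment_mean_spectra(records, spectra, grid)
    stimuli = {f"dowel:{c}": s for c, s in specs.items()}
    stimuli.update({f"larvae:{c}": s for c, s in mean_larvae.items()})
    catches = {k: quantum_catch(s, ill, receptors, grid=grid)
               for k, s in stimuli.items()}
    w = weber_fractions(receptors)
    mode = "achromatic" if is_lum else "chromatic"
    jnd, cats = jnd_matrix(catches, w, mode=mode)

    summary = df.groupby("treatment").agg(
        n=("response", "size"), stimulus=("stimulus", "mean"),
        mean_response=("response", "mean"), sd_response=("response", "std"))

    tables = {
        "responses": df,
        "treatment_summary": summary.reset_index(),
        "polynomial_fits": fit_tbl,
        "fit_comparisons": comparisons,
        "reference_curves": _reference_table(records),
        f"jnd_{mode}": jnd.reset_index(names="stimulus"),
        f"jnd_{mode}_category": cats.reset_index(names="stimulus"),
    }
    results = {
        "selected_order": selection.order if selection else None,
        "selection_rationale": selection.rationale if selection else "",
        "anova": _test_to_dict(anova),
        "true_norm_coefficients": list(coeffs),
    }
    return tables, results


def _run_colour(cfg: ExperimentConfig, grid, receptors, ill, rng):
    dowels = synthetic.default_dowels("colour")
    specs = {c: synthetic.make_dowel_spectrum(d, grid)
             for c, d in dowels.items()}
    stim = {c: synthetic.dowel_greenness(s, receptors, ill, grid)
            for c, s in specs.items()}
    centre = float(np.mean(list(stim.values())))
    # larvae shift 70% of the way from a neutral centre to their dowel
    coeffs = (0.3 * centre, 0.7)
    cohort = synthetic.CohortSpec(
        seed=cfg.seed,
        n_per_box=cfg.n_per_box or 25,
        boxes_per_treatment=cfg.boxes_per_treatment or 5,
        norm_coefficients=coeffs,
        noise_sd=cfg.noise_sd if cfg.noise_sd is not None else 0.012,
    )
    records, spectra = synthetic.simulate_cohort(
        dowels, cohort, receptors, stimulus_kind="greenness", illuminant=ill,
        grid=grid, make_spectra=True, rng=rng)
    df = records_to_frame(records)

    nested = stats.nested_anova(records)

    mean_larvae = _treatment_mean_spectra(records, spectra, grid)
    stimuli = {f"dowel:{c}": s for c, s in specs.items()}
    stimuli.update({f"larvae:{c}": s for c, s in mean_larvae.items()})
    catches = {k: quantum_catch(s, ill, receptors, grid=grid)
               for k, s in stimuli.items()}
    w = weber_fractions(receptors)
    jnd_c, cats_c = jnd_matrix(catches, w, mode="chromatic")
    jnd_a, cats_a = jnd_matrix(catches, w, mode="achromatic")

    tetra_rows = []
    for k, q in catches.items():
        p = tetra_coordinates(relative_catches(q))
        tetra_rows.append({"stimulus": k, "x": p.x, "y": p.y, "z": p.z,
                           "greenness": greenness_chromatic(q)})

    summary = df.groupby("treatment").agg(
        n=("response", "size"), stimulus=("stimulus", "mean"),
        mean_greenness=("response", "mean"), sd=("response", "std"))

    tables = {
        "responses": df,
        "treatment_summary": summary.reset_index(),
        "tetra_coordinates": pd.DataFrame(tetra_rows),
        "jnd_chromatic": jnd_c.reset_index(names="stimulus"),
        "jnd_chromatic_category": cats_c.reset_index(names="stimulus"),
        "jnd_achromatic": jnd_a.reset_index(names="stimulus"),
        "jnd_achromatic_category": cats_a.reset_index(names="stimulus"),
    }
    results = {
        "nested_anova": _test_to_dict(nested),
        "dowel_greenness": _to_jsonable(stim),
        "dowel_chromatic_jnd": float(
            jnd_c.loc["dowel:IB", "dowel:IG"]),
        "dowel_achromatic_jnd": float(
            jnd_a.loc["dowel:IB", "dowel:IG"]),
    }
    return tables, results


def _run_heterogeneous(cfg: ExperimentConfig, grid, receptors, ill, rng):
    p_levels = {"H000": 0.0, "H030": 0.3, "H050": 0.5, "H070": 0.7,
                "H100": 1.0}
    cohort = synthetic.CohortSpec(
        seed=cfg.seed,
        n_per_box=cfg.n_per_box or 25,
        boxes_per_treatment=cfg.boxes_per_treatment or 3,
    )
    true_records: list[ResponseRecord] = []
    for code in sorted(p_levels):
        true_records.extend(synthetic.simulate_heterogeneous_cohort(
            p_levels[code], cohort, treatment_code=code, rng=rng))

    # photographic pathway: each larva becomes a synthetic photograph with
    # an unknown colour cast; measured greenness comes from calibration +
    # ROI extraction, not from the generator's number directly
    cast = (1.3, 1.0, 0.8)
    measured: list[ResponseRecord] = []
    for rec in true_records:
        g = rec.response
        roi_g = np.clip(g + rng.normal(0.0, 0.5, size=6), 1.0, 99.0)
        rgbs = np.stack([[(100.0 - gg) / 2.0, gg, (100.0 - gg) / 2.0]
                         for gg in roi_g]) * 0.004
        img, rois, _ = synthetic.make_synthetic_image(
            rgbs, cast=cast, noise_sd=0.0)
        cal = photo.calibrate_image(img, rois, source=rec.specimen_id)
        means = photo.extract_roi_means(cal, rois)
        measured.append(ResponseRecord(
            rec.specimen_id, rec.treatment_code, rec.replicate_box,
            rec.stimulus, photo.specimen_greenness(means)))

    df = records_to_frame(measured)
    groups = {t: g["response"].to_numpy() for t, g in df.groupby("treatment")}
    anova = stats.one_way_anova(groups)
    lev = stats.levene_test(groups)
    lev_drop = stats.drop_most_variable_and_retest(groups)

    summary = df.groupby("treatment").agg(
        n=("response", "size"), p_green=("stimulus", "mean"),
        mean_greenness=("response", "mean"),
        var_greenness=("response", "var"),
        median_greenness=("response", "median"))

    tables = {
        "responses": df,
        "treatment_summary": summary.reset_index(),
        "group_stats": lev.groups.reset_index(),
    }
    results = {
        "anova": _test_to_dict(anova),
        "levene": _test_to_dict(lev),
        "levene_after_drop": _test_to_dict(lev_drop),
        "mean_greenness_by_p": _to_jsonable(
            summary.sort_values("p_green")["mean_greenness"].to_dict()),
        "monotone_in_p_green": bool(
            summary.sort_values("p_green")["mean_greenness"]
            .is_monotonic_increasing),
    }
    return tables, results


def run_experiment(cfg: ExperimentConfig) -> RunReport:
    """Run one experiment chain end to end and return its report.

    If ``cfg.out_dir`` is set the report is also written there as CSV
    tables plus a ``report.json``.
    """
    grid = StandardGrid()
    receptors = synthetic.make_sensitivity_set(cfg.viewer, grid)
    ill = get_illuminant(cfg.illuminant, grid)
    rng = np.random.default_rng(cfg.seed)
    logger.info("run_experiment: %s (seed=%d, hash=%s)",
                cfg.experiment, cfg.seed, cfg.config_hash())

    if cfg.experiment == "colour":
        tables, results = _run_colour(cfg, grid, receptors, ill, rng)
    elif cfg.experiment in ("luminance", "colour-luminance"):
        tables, results = _run_gradient(cfg, grid, receptors, ill, rng)
    else:
        tables, results = _run_heterogeneous(cfg, grid, receptors, ill, rng)

    from . import __version__
    report = RunReport(
        experiment=cfg.experiment,
        tables={k: v for k, v in tables.items() if v is not None},
        results=results,
        provenance={"config_hash": cfg.config_hash(), "seed": cfg.seed,
                    "experiment": cfg.experiment, "version": __version__},
    )
    if cfg.out_dir:
        write_report(report, cfg.out_dir)
    return report


def write_report(report: RunReport, out_dir) -> None:
    """Write the report deterministically: one CSV per table + report.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in sorted(report.tables):
        report.tables[name].to_csv(out / f"{name}.csv", index=False,
                                   float_format=_FLOAT_FMT)
    payload = {"experiment": report.experiment,
               "results": _to_jsonable(report.results),
               "provenance": report.provenance}
    with open(out / "report.json", "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
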