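"""End-to-end orchestration: simulate -> calibrate -> build -> fit -> contrast -> niche.

Each stage reads and writes plain CSV/JSON artifacts in a run directory, so
any stage can be inspected, replaced, or resumed. A single master seed
derives one independent stream per stage (hash-split on the stage name), so
re-running one stage never perturbs another.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import contrast as ct
from . import covariates as cov
from . import encounters as enc
from . import occupancy as occ
from . import synthetic as syn
from ._util import stage_seed
from .calibration import calibrate

log = logging.getLogger("owlbaci")

#: Species-to-analysis-unit mapping: small species at ARU level, the large
#: great horned owl at hexagon level.
SPECIES_LEVEL = {"flammulated": "aru", "pygmy": "aru", "great_horned": "hexagon"}


@dataclass
class RunConfig:
    seed: int = 1
    extent: tuple = (24_000.0, 24_000.0)
    cell_size: float = 20.0
    n_hex: int = 60
    seasons: tuple = (2018, 2021, 2022, 2023)
    species: tuple = ("flammulated",)
    models: tuple = ("fire_tc", "fire_td", "bo_tc", "bo_td", "int_tc", "int_td")
    truth_model: str = "bo_tc"
    fires: tuple = (
        {"year": 2020, "center": (8000.0, 8000.0), "radius": 6000.0, "severity_frac": 0.49},
        {"year": 2021, "center": (17000.0, 16000.0), "radius": 8000.0, "severity_frac": 0.56},
    )
    n_removals: int | None = None  # default: TruthParams (12), capped at n_hex // 3
    calibration_target: float = 0.01
    calibration_n_hours: int = 84
    chains: int = 4
    iters: int = 2600
    burn: int = 1300
    ci_level: float = 0.85
    overlap_threshold: float = 0.15

    @classmethod
    def from_yaml(cls, path):
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        bad = [m for m in cfg.models if m not in occ.MODEL_COLUMNS]
        if bad:
            raise ValueError(f"unknown model ids in config: {bad}")
        if cfg.truth_model not in occ.MODEL_COLUMNS:
            raise ValueError(f"unknown truth_model {cfg.truth_model!r}")
        return cfg

    def validate(self):
        bad = [m for m in self.models if m not in occ.MODEL_COLUMNS]
        if bad:
            raise ValueError(f"unknown model ids in config: {bad}")
        for s in self.species:
            if s not in SPECIES_LEVEL:
                raise ValueError(f"unknown species {s!r}")


def _done(outdir: Path, *names) -> bool:
    return all((outdir / n).exists() for n in names)


def stage_simulate(cfg: RunConfig, outdir: Path, resume=True):
    if resume and _done(outdir, "detections.csv", "deployments.csv", "sites.csv"):
        log.info("simulate: artifacts present, skipping")
        return
    fire_specs = [syn.FireSpec(f["year"], tuple(f["center"]), f["radius"], f["severity_frac"])
                  for f in cfg.fires]
    land = syn.simulate_landscape(cfg.extent, cfg.cell_size, fire_specs,
                                  seed=stage_seed(cfg.seed, "landscape"))
    design = syn.simulate_survey(land, cfg.n_hex, cfg.seasons,
                                 seed=stage_seed(cfg.seed, "survey"))
    truth = syn.TruthParams(seed=stage_seed(cfg.seed, "detections"))
    truth.n_removals = cfg.n_removals if cfg.n_removals is not None \
        else min(truth.n_removals, max(1, cfg.n_hex // 3))
    frames = []
    for sp in cfg.species:
        det, info = syn.simulate_detections(
            design, land, truth, cfg.truth_model, species=sp,
            level=SPECIES_LEVEL[sp], seed=stage_seed(cfg.seed, f"detections:{sp}"))
        frames.append(det)
        info["covariates"].to_csv(outdir / f"covariates_{sp}.csv", index=False)
    detections = pd.concat(frames).drop_duplicates().sort_values("timestamp")
    syn.write_outputs(outdir, land, design, detections, info)
    log.info("simulate: wrote %d detection events", len(detections))


def stage_calibrate(cfg: RunConfig, outdir: Path, resume=True):
    if resume and _done(outdir, "calibration.json"):
        return
    out = {}
    for sp in cfg.species:
        streams = syn.simulate_scores(
            syn.SpeciesScoreProfile(), n_hours=3000,
            seed=stage_seed(cfg.seed, f"scores:{sp}"))
        pool = syn.validation_sample(streams)
        res = calibrate(pool, target=cfg.calibration_target,
                        n_hours=cfg.calibration_n_hours)
        out[sp] = {
            "selected_threshold": res.selected,
            "target": res.target,
            "n_hours": res.n_hours,
            "table": res.as_table().to_dict(orient="records"),
        }
        log.info("calibrate[%s]: threshold %.2f", sp, res.selected)
    (outdir / "calibration.json").write_text(json.dumps(out, indent=1))


def stage_build(cfg: RunConfig, outdir: Path, resume=True):
    need = [f"history_{sp}.csv" for sp in cfg.species]
    if resume and _done(outdir, *need):
        return
    detections = pd.read_csv(outdir / "detections.csv", parse_dates=["timestamp"])
    deployments = pd.read_csv(outdir / "deployments.csv", parse_dates=["start", "end"])
    sites = pd.read_csv(outdir / "sites.csv")
    inv_hist = enc.build_history(detections, deployments, sites, "barred_owl", level="aru")
    invader = enc.invader_covariate(inv_hist)
    invader.to_csv(outdir / "invader.csv", index=False)
    for sp in cfg.species:
        hist = enc.build_history(detections, deployments, sites, sp,
                                 level=SPECIES_LEVEL[sp])
        hist.to_csv(outdir / f"history_{sp}.csv")
        covs = pd.read_csv(outdir / f"covariates_{sp}.csv")
        covs = covs.merge(invader, on=["hexagon", "season"], how="left").fillna({"invader": 0})
        # screen distinct predictors (nested pairs like burn/allpostburn are
        # structurally correlated and appear jointly in the equations)
        cov.predictor_correlations(
            covs, ["allpostburn", "allpostlethal", "elevation", "ruggedness", "seral_frac"])
        covs.to_csv(outdir / f"covariates_{sp}.csv", index=False)
        log.info("build[%s]: %d unit-season rows", sp, len(hist.df))


def stage_fit(cfg: RunConfig, outdir: Path, resume=True):
    results = {}
    for sp, model in itertools.product(cfg.species, cfg.models):
        tag = f"{sp}_{model}"
        if resume and _done(outdir, f"draws_{tag}.csv", f"summary_{tag}.json"):
            continue
        hist = pd.read_csv(outdir / f"history_{sp}.csv")
        covs = pd.read_csv(outdir / f"covariates_{sp}.csv")
        design = occ.build_design(model, covs, hist)
        draws = occ.sample_posterior(
            design, chains=cfg.chains, iters=cfg.iters, burn=cfg.burn,
            seed=stage_seed(cfg.seed, f"fit:{tag}"))
        gof = occ.mb_gof(draws, design, n_rep=100,
                         seed=stage_seed(cfg.seed, f"gof:{tag}"))
        summary = draws.summary(cfg.ci_level)
        rhat = draws.rhat()
        payload = {
            "summary": summary.to_dict(orient="records"),
            "rhat": {k: v for k, v in rhat.items()},
            "gof_p": gof["p_value"],
        }
        (outdir / f"summary_{tag}.json").write_text(json.dumps(payload, indent=1))
        flat = pd.DataFrame(draws.stacked("beta"), columns=draws.psi_cols)
        flat.to_csv(outdir / f"draws_{tag}.csv", index=False)
        results[tag] = payload
        log.info("fit[%s]: max rhat %.3f, GOF p %.2f", tag,
                 max(rhat.values()), gof["p_value"])
    return results


class _DrawsView:
    """Minimal draws interface over a saved beta-draw table."""

    def __init__(self, df):
        self.psi_cols = list(df.columns)
        self._beta = df.to_numpy()

    def stacked(self, name):
        assert name == "beta"
        return self._beta


def stage_contrast(cfg: RunConfig, outdir: Path, resume=True):
    if resume and _done(outdir, "contrasts.json"):
        return
    out = {}
    for sp, model in itertools.product(cfg.species, cfg.models):
        if "site_type" not in occ.MODEL_COLUMNS[model]:
            continue
        path = outdir / f"draws_{sp}_{model}.csv"
        if not path.exists():
            continue
        draws = _DrawsView(pd.read_csv(path))
        res = ct.removal_contrasts(draws, model)
        out[f"{sp}_{model}"] = {
            k: {"overlap": v.overlap, "meaningful": v.overlap < cfg.overlap_threshold}
            for k, v in res.items()
        }
    (outdir / "contrasts.json").write_text(json.dumps(out, indent=1))


def stage_niche(cfg: RunConfig, outdir: Path, resume=True):
    if resume and _done(outdir, "niche.json"):
        return
    detections = pd.read_csv(outdir / "detections.csv", parse_dates=["timestamp"])
    sites = pd.read_csv(outdir / "sites.csv")
    removals = pd.read_csv(outdir / "removals.csv") if (outdir / "removals.csv").exists() else None
    first = min(cfg.seasons)
    # habitat conditions per ARU from the first species' covariate table
    covs = pd.read_csv(outdir / f"covariates_{cfg.species[0]}.csv")
    base = covs.drop_duplicates("unit")[["unit", "hexagon", "elevation", "ruggedness", "seral_frac"]]
    el, _, _ = cov.standardize(base["elevation"])
    ru, _, _ = cov.standardize(base["ruggedness"])
    base = base.assign(elevation_z=el, ruggedness_z=ru)
    axes = ["elevation_z", "ruggedness_z", "seral_frac"]

    def det_points(species):
        d = detections[(detections.species == species)
                       & (detections.timestamp.dt.year == first)]
        units = d["aru_id"].unique()
        return base[base["unit"].isin(units)]

    species_pts = {sp: det_points(sp) for sp in cfg.species}
    inv_pts = det_points("barred_owl")
    out = {"pairs": {}, "occurrence": {}}
    inv_hex = set(inv_pts["hexagon"])
    if removals is not None and len(removals):
        # removal locations stand in for additional invader occurrence records
        arus = sites.rename(columns={"aru_id": "unit"})
        for _, r in removals.iterrows():
            d2 = (arus.x - r.x) ** 2 + (arus.y - r.y) ** 2
            inv_hex.add(arus.loc[d2.idxmin(), "hexagon"])
    inv_base = base[base["hexagon"].isin(inv_hex)]

    for ax, ay in itertools.combinations(axes, 2):
        pair = {}
        try:
            e_inv = ct.standard_ellipse(inv_base[[ax, ay]].to_numpy(), species="invader")
            pair["invader"] = {"area": e_inv.area}
            for sp, pts in species_pts.items():
                if len(pts) < 3:
                    continue
                e_sp = ct.standard_ellipse(pts[[ax, ay]].to_numpy(), species=sp)
                inter, frac = ct.ellipse_overlap(e_inv, e_sp)
                pair[sp] = {"area": e_sp.area, "overlap_frac": frac}
        except ValueError as err:
            pair["error"] = str(err)
        out["pairs"][f"{ax}|{ay}"] = pair

    occ_y = base["hexagon"].isin(inv_hex).astype(int).to_numpy()
    if occ_y.min() != occ_y.max():
        fit = ct.fit_occurrence_logistic(occ_y, base[axes], level=cfg.ci_level)
        out["occurrence"] = {
            "coefficients": fit.params.to_dict(),
            "flagged": fit.flagged,
            "ame": {a: ct.average_marginal_effect(fit, a) for a in axes},
        }
    (outdir / "niche.json").write_text(json.dumps(out, indent=1))


STAGES = {
    "simulate": stage_simulate,
    "calibrate": stage_calibrate,
    "build": stage_build,
    "fit": stage_fit,
    "contrast": stage_contrast,
    "niche": stage_niche,
}


def run(cfg: RunConfig, outdir, stages=None, resume=True) -> Path:
    """Execute the pipeline (or a subset of stages) into ``outdir``."""
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(asdict(cfg)))
    for name in stages or STAGES:
        log.info("stage %s (seed %d)", name, stage_seed(cfg.seed, name))
        try:
            STAGES[name](cfg, outdir, resume=resume)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
    return outdir
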