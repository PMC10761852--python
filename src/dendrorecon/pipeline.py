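"""Config-driven end-to-end driver: simulate/read -> crossdate ->
chronology -> climate response -> transfer fit + validation ->
reconstruction -> variability, with persisted intermediates and a
machine-readable report."""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chronology import build_chronology, pca_sites, truncate_by_eps
from .climate_response import bootstrap_corrfun, moving_corr, seascorr, seasonalize
from .crossdating import crossdate_collection
from .reconstruction import fit_transfer, loocv, reconstruct, split_sample
from .rwl_io import read_climate_table, read_rwl, write_climate_table, write_rwl
from .synthetic import (ClimateSimConfig, ForestSimConfig, default_study_conditions,
                        simulate_climate, simulate_forest)
from .types import pool
from .variability import extremes_per_century, find_extremes, find_periods, mtm_spectrum, morlet_wavelet

DEFAULT_CONFIG = {
    "seed": 1,
    "simulate": {"enabled": True, "n_years": 719, "first_year": 1300,
                 "r_target": 0.73, "cycles": [[2.7, 0.35], [8.2, 0.35]],
                 "n_sites": 3, "trees_per_site": 8},
    "inputs": {"rwl": [], "climate": None},
    "detrend": {"prewhiten": True, "max_ar_order": 3, "fallback": "mean"},
    "eps": {"threshold": 0.85, "window": 50, "overlap": 25, "min_overlap": 30},
    "season": {"variable": "prcp", "months": [2, 3, 4, 5, 6], "aggregation": "sum"},
    "calibration": {"start": 1965, "end": 2018, "split_year": None},
    "response": {"nboot": 200, "seascorr_nsim": 200, "enabled": True},
    "spectral": {"nw": 2.0, "k_tapers": 3},
    "extremes": {"k_years": 1.5, "k_periods": 1.0, "cutoff": 10, "min_len": 2},
}


def _merge(base: dict, over: dict) -> dict:
    out = dict(base)
    for k, v in (over or {}).items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | None = None, overrides: dict | None = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path:
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    sim_on = cfg["simulate"].get("enabled", False)
    has_inputs = bool(cfg["inputs"]["rwl"]) or cfg["inputs"]["climate"]
    if sim_on and has_inputs:
        raise ValueError("config must use either a simulate block or input paths, not both")
    if not sim_on and not has_inputs:
        raise ValueError("config needs either a simulate block or input paths")
    return cfg


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return None if np.isnan(o) else float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(type(o))


def run_pipeline(cfg: dict, out_dir: str | None = None) -> dict:
    """Execute the full workflow and return the run report (a dict).

    Intermediates (chronology, reconstruction, spectra, catalogs) are
    written as TSV under ``out_dir`` when given.  Fully deterministic
    under the config seeds.
    """
    seed = int(cfg["seed"])
    report: dict = {"version": __version__,
                    "config_hash": hashlib.sha256(
                        json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16],
                    "seed": seed}
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return wrap

    # --- data -------------------------------------------------------------
    truth = None
    if cfg["simulate"].get("enabled"):
        sim = cfg["simulate"]
        ccfg, fcfg = default_study_conditions(
            seed=seed, n_years=int(sim["n_years"]), first_year=int(sim["first_year"]),
            r_target=float(sim["r_target"]),
            cycles=[tuple(c) for c in sim["cycles"]],
            n_sites=int(sim["n_sites"]), trees_per_site=int(sim["trees_per_site"]))
        climate, _ctruth = stage("simulate")(lambda: simulate_climate(ccfg))
        sites, truth = stage("simulate")(lambda: simulate_forest(fcfg, climate))
        report["simulate"] = {"beta": fcfg.beta, "gamma": fcfg.gamma,
                              "n_sites": fcfg.n_sites, "n_series": sum(len(s) for s in sites)}
        if out_dir:
            for s in sites:
                write_rwl(s, os.path.join(out_dir, f"{s.site_id.lower()}.rwl"))
            write_climate_table(climate, os.path.join(out_dir, "climate_prcp.csv"), "prcp")
    else:
        sites = [read_rwl(p) for p in cfg["inputs"]["rwl"]]
        climate = read_climate_table(**cfg["inputs"]["climate"])

    # --- crossdating ------------------------------------------------------
    composite = pool(sites)
    reports = stage("crossdate")(lambda: crossdate_collection(composite))
    report["crossdating"] = {
        "n_series": len(reports),
        "n_flagged_segments": int(sum(r.n_flagged for r in reports)),
        "mean_overall_r": float(np.mean([r.overall_r for r in reports])),
        "mean_glk": float(np.mean([r.glk for r in reports])),
    }
    if out_dir:
        pd.concat([r.to_frame() for r in reports]).to_csv(
            os.path.join(out_dir, "crossdating.tsv"), sep="\t", index=False)

    # --- chronologies -----------------------------------------------------
    dt = cfg["detrend"]
    ep = cfg["eps"]
    build = lambda coll: build_chronology(
        coll, prewhiten_series=dt["prewhiten"], max_ar_order=dt["max_ar_order"],
        fallback=dt["fallback"], rbar_window=ep["window"], rbar_overlap=ep["overlap"],
        min_overlap=ep["min_overlap"])
    site_chrons = [stage("chronology")(lambda c=c: build(c)) for c in sites]
    chron = stage("chronology")(lambda: build(composite))
    trunc_year = stage("chronology")(lambda: truncate_by_eps(chron, ep["threshold"]))
    kind = "residual" if dt["prewhiten"] else "standard"
    ch_series = chron.series(kind)
    # prewhitening drops each series' first p years; the reliable span
    # cannot start before the chronology actually exists
    trunc_year = max(trunc_year, int(ch_series.dropna().index.min()))
    report["chronology"] = {**chron.stats, "first_year": int(chron.years[0]),
                            "last_year": int(chron.years[-1]),
                            "truncation_year": int(trunc_year),
                            "eps_threshold": ep["threshold"]}
    if len(site_chrons) >= 2:
        fractions, _, _ = pca_sites(site_chrons)
        report["chronology"]["pc1_variance_pct"] = float(100 * fractions[0])
    if out_dir:
        chron.to_frame().to_csv(os.path.join(out_dir, "chronology.tsv"), sep="\t")
        pd.DataFrame(chron.rbar_windows,
                     columns=["start", "end", "rbar", "eps", "n"]).to_csv(
            os.path.join(out_dir, "running_stats.tsv"), sep="\t", index=False)

    # --- climate response -------------------------------------------------
    se = cfg["season"]
    target = seasonalize(climate, se["variable"], se["months"], se["aggregation"])
    if cfg["response"].get("enabled", True):
        resp = cfg["response"]
        cf = stage("respond")(lambda: bootstrap_corrfun(
            ch_series, climate, [se["variable"], "tmean"], nboot=int(resp["nboot"]),
            seed=seed + 10))
        sc = stage("respond")(lambda: seascorr(
            ch_series, climate, nsim=int(resp["seascorr_nsim"]), seed=seed + 11))
        report["response"] = {
            var: {lab: {"r": float(row["r"]), "significant": bool(row["significant"])}
                  for lab, row in f.table.iterrows()} for var, f in cf.items()}
        if out_dir:
            sc.to_csv(os.path.join(out_dir, "seascorr.tsv"), sep="\t", index=False)
            for var, f in cf.items():
                f.table.to_csv(os.path.join(out_dir, f"corrfun_{var}.tsv"), sep="\t")

    # --- transfer model + validation -------------------------------------
    cal = cfg["calibration"]
    span = (int(cal["start"]), int(cal["end"]))
    model = stage("reconstruct")(lambda: fit_transfer(ch_series, target.values, span))
    cv = stage("reconstruct")(lambda: loocv(ch_series, target.values, span))
    split = stage("reconstruct")(lambda: split_sample(
        ch_series, target.values, cal.get("split_year"), span))
    report["calibration"] = {"slope": model.slope, "intercept": model.intercept,
                             "span": span, **model.stats}
    report["validation"] = {"loocv": cv.to_dict(), "split_sample": split}

    # --- reconstruction ---------------------------------------------------
    recon = stage("reconstruct")(lambda: reconstruct(model, ch_series, trunc_year))
    report["reconstruction"] = {
        "first_year": int(recon.years[0]), "last_year": int(recon.years[-1]),
        "n_years": len(recon.years), "mean_mm": recon.mean, "sd_mm": recon.sd,
        "rmse_mm": recon.rmse, "n_negative": int(len(recon.negative_years))}
    if truth is not None:
        joint = pd.concat([recon.series(),
                           pd.Series(truth.fj_precip, index=truth.years, name="truth")],
                          axis=1).dropna()
        pre = joint.loc[:span[0] - 1]
        report["truth_recovery"] = {
            "r_full": float(joint.corr().iloc[0, 1]),
            "r_precalibration": float(pre.corr().iloc[0, 1]) if len(pre) > 30 else None,
            "true_beta": truth.beta, "true_gamma": truth.gamma}
    if out_dir:
        recon.to_frame().to_csv(os.path.join(out_dir, "reconstruction.tsv"), sep="\t")

    # --- variability ------------------------------------------------------
    ex = cfg["extremes"]
    rs = recon.series()
    catalog = stage("variability")(lambda: find_extremes(rs, k=ex["k_years"]))
    wet_p, dry_p, lp = stage("variability")(lambda: find_periods(
        rs, cutoff=ex["cutoff"], k=ex["k_periods"], min_len=ex["min_len"]))
    century = (stage("variability")(lambda: extremes_per_century(rs, k=ex["k_years"]))
               if len(rs) >= 200 else None)
    spec = stage("variability")(lambda: mtm_spectrum(
        rs, nw=cfg["spectral"]["nw"], k_tapers=cfg["spectral"]["k_tapers"]))
    wav = stage("variability")(lambda: morlet_wavelet(rs))
    report["variability"] = {
        "n_extreme_wet": len(catalog.wet_years), "n_extreme_dry": len(catalog.dry_years),
        "wettest_years": catalog.wet_years[:10], "driest_years": catalog.dry_years[:10],
        "wet_periods": wet_p, "dry_periods": dry_p,
        "century_pct_extreme": (century["pct_extreme"].round(2).tolist()
                                if century is not None else None),
        "significant_periods_yr_95": [round(p, 2) for p in spec.peaks95 if p < 50],
        "significant_periods_yr_99": [round(p, 2) for p in spec.peaks99 if p < 50],
        "wavelet_n_signif_cells": int(wav.signif95[wav.coi_mask()].sum()),
    }
    if out_dir:
        spec.to_frame().to_csv(os.path.join(out_dir, "spectrum.tsv"), sep="\t", index=False)
        lp.to_frame().to_csv(os.path.join(out_dir, "lowpass.tsv"), sep="\t")
        pd.DataFrame([{"kind": "wet", "start": a, "end": b, "length": b - a + 1}
                      for a, b in wet_p] +
                     [{"kind": "dry", "start": a, "end": b, "length": b - a + 1}
                      for a, b in dry_p]).to_csv(
            os.path.join(out_dir, "periods.tsv"), sep="\t", index=False)
        if century is not None:
            century.to_csv(os.path.join(out_dir, "centuries.tsv"), sep="\t", index=False)
        with open(os.path.join(out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, default=_json_default, sort_keys=True)
    return report
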