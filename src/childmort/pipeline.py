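"""End-to-end reproducible pipeline: simulate -> estimate -> smooth -> assess.

A single YAML configuration drives every stage; one seed propagates to all
stochastic steps; a JSON manifest records per-stage durations and SHA-256
hashes of the written artifacts so a rerun can be checked bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as cio
from .direct import direct_estimates
from .graphs import make_lattice_adjacency, write_edge_list
from .indirect import calibrate_coefficients, indirect_estimates, parity_ratios
from .records import aggregate_sbh, records_to_frame
from .simulate import SimConfig, SurveySpec, sample_true_surface, simulate_survey
from .smoother import MCMCConfig, SpaceTimeSmoother
from .targets import assess_all, inequality_series
from .validation import make_calibration_corpus

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Validated pipeline configuration (see ``RunConfig.from_yaml``)."""

    out_dir: Path
    seed: int
    sim: SimConfig
    rows: int
    cols: int
    mcmc: MCMCConfig
    calibration_surveys: int = 25
    calibration_women: int = 1200
    crossval_fraction: float = 0.0  # 0 disables the cross-validation stage
    arr_window: tuple = (2000, 2013)

    @classmethod
    def from_dict(cls, cfg: dict, out_dir=None) -> "RunConfig":
        sim_cfg = dict(cfg["sim"])
        rows, cols = int(sim_cfg.pop("rows")), int(sim_cfg.pop("cols"))
        seed = int(cfg.get("seed", 0))
        surveys = tuple(
            SurveySpec(year=int(s["year"]),
                       counties=s.get("counties") or
                       make_lattice_adjacency(rows, cols).node_ids,
                       women_per_county=int(s["women_per_county"]),
                       collects_cbh=bool(s.get("collects_cbh", True)),
                       collects_sbh=bool(s.get("collects_sbh", True)))
            for s in sim_cfg.pop("surveys"))
        sim = SimConfig(K=rows * cols,
                        year_range=tuple(sim_cfg.pop("year_range")),
                        surveys=surveys, seed=seed, **sim_cfg)
        mcmc_cfg = dict(cfg.get("mcmc", {}))
        mcmc = MCMCConfig(iterations=int(mcmc_cfg.get("iterations", 110_000)),
                          burn_in=int(mcmc_cfg.get("burn_in", 10_000)),
                          thin=int(mcmc_cfg.get("thin", 10)), seed=seed)
        out = Path(out_dir if out_dir is not None else cfg["out_dir"])
        cal = cfg.get("calibration", {})
        return cls(out_dir=out, seed=seed, sim=sim, rows=rows, cols=cols,
                   mcmc=mcmc,
                   calibration_surveys=int(cal.get("n_surveys", 25)),
                   calibration_women=int(cal.get("women_per_survey", 1200)),
                   crossval_fraction=float(cfg.get("crossval_fraction", 0.0)),
                   arr_window=tuple(cfg.get("arr_window", (2000, 2013))))

    @classmethod
    def from_yaml(cls, path, out_dir=None) -> "RunConfig":
        return cls.from_dict(cio.load_yaml(path), out_dir=out_dir)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages, writing artifacts and a manifest to
    ``config.out_dir``.  Returns the output directory.

    Stages whose preconditions are not met by the configured study window
    (goal assessment needs years 1990-2013; the inequality ratio needs at
    least 10 counties) are skipped with a log entry rather than failing.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"seed": config.seed, "stages": []}

    def stage(name):
        class _Stage:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                self_inner.outputs = []
                return self_inner

            def add(self_inner, path):
                self_inner.outputs.append(Path(path))

            def __exit__(self_inner, exc_type, exc, tb):
                if exc_type is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
                    return False
                manifest["stages"].append({
                    "stage": name,
                    "duration_s": round(time.perf_counter() - self_inner.t0, 3),
                    "outputs": {str(p.relative_to(out)): _sha256(p)
                                for p in self_inner.outputs}})
                return False
        return _Stage()

    # 1. graph + latent truth --------------------------------------------
    with stage("simulate") as st:
        graph = make_lattice_adjacency(config.rows, config.cols)
        write_edge_list(graph, out / "adjacency.txt")
        st.add(out / "adjacency.txt")
        surface = sample_true_surface(config.sim, graph)
        truth = pd.DataFrame(
            [(c, int(y), surface.Q[k, t])
             for k, c in enumerate(surface.county_ids)
             for t, y in enumerate(surface.years)],
            columns=["county_id", "year", "true_q5"])
        truth.to_csv(out / "true_surface.csv", index=False)
        st.add(out / "true_surface.csv")

        records_by_survey = {}
        for idx, spec in enumerate(config.sim.surveys):
            records = simulate_survey(config.sim, surface, idx)
            records_by_survey[idx] = records
            sid = f"s{idx}"
            if spec.collects_cbh:
                cio.write_cbh_csv(records, out / f"cbh_{sid}.csv", survey_id=sid)
                st.add(out / f"cbh_{sid}.csv")
            if spec.collects_sbh:
                tables = []
                by_county = {}
                for w in records:
                    by_county.setdefault(w.county_id, []).append(w)
                for county, recs in sorted(by_county.items()):
                    for grouping in ("MA", "TFB"):
                        tables.append(aggregate_sbh(recs, grouping, county_id=county))
                cio.write_sbh_csv(tables, out / f"sbh_{sid}.csv")
                st.add(out / f"sbh_{sid}.csv")

    # 2. calibration ------------------------------------------------------
    with stage("calibrate") as st:
        corpus, _ = make_calibration_corpus(
            config.calibration_surveys, config.calibration_women,
            seed=config.seed + 90_001)
        coeffs = {}
        for grouping in ("MA", "TFB"):
            cohort, period, dist = calibrate_coefficients(corpus, grouping=grouping)
            coeffs[grouping] = (cohort, period, dist)
            cohort.to_csv(out / f"coeff_cohort_{grouping}.csv")
            period.to_csv(out / f"coeff_period_{grouping}.csv")
            dist.to_frame().to_csv(out / f"empirical_dist_{grouping}.csv", index=False)
            for f in (f"coeff_cohort_{grouping}.csv", f"coeff_period_{grouping}.csv",
                      f"empirical_dist_{grouping}.csv"):
                st.add(out / f)

    # 3. estimation -------------------------------------------------------
    with stage("estimate") as st:
        rows_all = []
        for idx, spec in enumerate(config.sim.surveys):
            sid = f"s{idx}"
            records = records_by_survey[idx]
            by_county = {}
            for w in records:
                by_county.setdefault(w.county_id, []).append(w)
            for county, recs in sorted(by_county.items()):
                frame = records_to_frame(recs)
                if spec.collects_cbh:
                    d = direct_estimates(frame, by_county=False)
                    for _, r in d.iterrows():
                        rows_all.append((sid, "direct", county, int(r["year"]),
                                         r["q5"], r["n_women"]))
                if spec.collects_sbh:
                    sbh_ma = aggregate_sbh(recs, "MA", county_id=county)
                    ratios = parity_ratios(sbh_ma)
                    for grouping in ("MA", "TFB"):
                        sbh = (sbh_ma if grouping == "MA"
                               else aggregate_sbh(recs, "TFB", county_id=county))
                        cohort, period, dist = coeffs[grouping]
                        est = indirect_estimates(sbh, cohort, period, dist, ratios)
                        for _, r in est.iterrows():
                            rows_all.append((sid, r["method"], county,
                                             int(r["year"]), r["q5"], r["n_women"]))
        estimates = pd.DataFrame(rows_all, columns=[
            "survey_id", "method", "county_id", "year", "q5", "n"])
        lo, hi = config.sim.year_range
        keep = (estimates["q5"].between(1e-6, 1 - 1e-6)
                & estimates["year"].between(lo, hi) & (estimates["n"] >= 3))
        dropped = int((~keep).sum())
        if dropped:
            logger.info("estimate stage: dropped %d unusable estimate rows", dropped)
        estimates = estimates[keep].reset_index(drop=True)
        estimates.to_csv(out / "estimates.csv", index=False)
        st.add(out / "estimates.csv")

    # 4. smoothing --------------------------------------------------------
    with stage("fit") as st:
        model = SpaceTimeSmoother(estimates, graph, years=config.sim.year_range)
        results = model.fit(config.mcmc)
        summary = results.summary_frame()
        summary.to_csv(out / "posterior_summary.csv", index=False)
        st.add(out / "posterior_summary.csv")
        (out / "model_summary.txt").write_text(results.summary() + "\n")
        st.add(out / "model_summary.txt")

    # 5. cross-validation (optional) --------------------------------------
    if config.crossval_fraction > 0:
        with stage("crossval") as st:
            cv = model.cross_validate(config.mcmc,
                                      holdout_fraction=config.crossval_fraction,
                                      seed=config.seed + 17)
            pd.DataFrame([{"rmse": cv["rmse"], "bias": cv["bias"],
                           "n_heldout": cv["n_heldout"]}]).to_csv(
                out / "crossval.csv", index=False)
            st.add(out / "crossval.csv")

    # 6. targets and inequality -------------------------------------------
    with stage("assess") as st:
        years_present = set(summary["year"])
        needed = {1990, 2000, *config.arr_window}
        if needed <= years_present:
            assess = assess_all(summary, arr_window=config.arr_window)
            assess.to_csv(out / "target_assessment.csv", index=False)
            st.add(out / "target_assessment.csv")
        else:
            logger.info("assess stage: study window lacks years %s; "
                        "goal assessment skipped", sorted(needed - years_present))
        if graph.n_nodes >= 10:
            ineq = inequality_series(summary)
            ineq.to_csv(out / "inequality.csv", index=False)
            st.add(out / "inequality.csv")
        else:
            logger.info("assess stage: fewer than 10 counties; "
                        "inequality ratio skipped")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
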