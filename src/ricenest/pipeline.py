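"""End-to-end pipeline driver.

Runs the full chain on a synthetic landscape: simulate → terrain evidence →
probabilistic classification → Bayesian refinement → accuracy assessment →
point-pattern analysis (univariate CSR tests for nests and habitat points,
bivariate independence test between them) → nest clustering, buffer-area
levels and the group-difference test battery. Every stage writes plain
CSV/TIFF artifacts with provenance headers; all randomness flows from the
config seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import accuracy as acc
from . import clusters as cl
from . import refine as rf
from . import ripley as rp
from . import synth, terrain
from .grids import DEFAULT_SCHEME, PointPattern
from .io import RunConfig, write_csv, write_points, write_points_geojson, write_raster

__all__ = ["run_pipeline"]


def _stage_seeds(seed: int, n: int = 16) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Run every stage; returns the machine-readable run summary.

    Outputs land in ``out_dir``; any stage failure aborts with the stage
    name and cause. Deterministic for a fixed config (byte-identical CSVs).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme = DEFAULT_SCHEME
    rngs = _stage_seeds(config.seed)
    summary: dict = {"seed": config.seed, "config": config.digest()}
    config.to_yaml(out / "run.yaml")

    stage = "simulate"
    try:
        dem = synth.generate_dem(
            config.nrows, config.ncols, config.cell_size, config.relief_range,
            config.smoothness, config.hypsometric_exponent, seed=rngs[0],
        )
        terr = terrain.classify_terrain_position(dem, config.terrain_radius)
        elev = terrain.classify_elevation(dem, list(config.elevation_breaks))
        truth = synth.generate_true_landcover(dem, terr.grid, scheme, seed=rngs[1])
        bands = synth.generate_band_stack(
            truth, noise_sd=config.noise_sd, scheme=scheme, n_bands=config.n_bands, seed=rngs[2]
        )
        plots = synth.generate_sample_plots(
            truth, config.n_plots, config.plot_size_m, scheme, seed=rngs[3]
        )
        focal = scheme.code(config.focal_class)
        habitat = truth.like((truth.values == focal).astype(np.uint8))
        nests = synth.generate_nest_pattern(
            habitat, config.n_parents, config.offspring_mean, config.sigma_m,
            config.association, rngs[4],
        )
        write_raster(dem, out / "dem.tif")
        write_raster(truth, out / "truth.tif")
        write_raster(terr.grid, out / "terrain.tif")
        write_raster(elev.grid, out / "elevation.tif")
        for i, b in enumerate(bands):
            write_raster(b, out / f"band_{i}.tif")
        write_csv(
            pd.DataFrame({"x": plots.x, "y": plots.y,
                          "true_class": [scheme.names[c] for c in plots.true_class],
                          "split": plots.split}),
            out / "plots.csv", config.provenance(stage),
        )
        write_points(nests, out / "nests.csv", header=config.provenance(stage))
        write_points_geojson(nests, out / "nests.geojson")
        summary["n_nests"] = nests.n
        summary["n_plots"] = plots.n
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    stage = "classify"
    try:
        model = rf.fit_base_classifier(plots, bands, scheme, seed=int(rngs[5].integers(2**31)))
        rules = rf.predict_rule_stack(model, bands)
        base_map = rf.relabel_max_posterior(rules)
        write_raster(base_map, out / "base_map.tif")
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    stage = "refine"
    try:
        table = rf.estimate_rule_table([terr, elev], truth, plots, scheme)
        table.to_csv(out / "rules.csv")
        post = rf.evaluate_evidence(rules, [terr, elev], table)
        refined_map = rf.relabel_max_posterior(post)
        write_raster(refined_map, out / "refined_map.tif")
        summary["n_flagged_cells"] = post.n_flagged
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    stage = "assess"
    try:
        test = plots.half("test")
        idx = [truth.cell_index(x, y) for x, y in zip(test.x, test.y)]
        ref = test.true_class.astype(int)
        pred_base = np.array([base_map.values[r, c] for r, c in idx], dtype=int)
        pred_ref = np.array([refined_map.values[r, c] for r, c in idx], dtype=int)
        rows = []
        for name, pred in (("base", pred_base), ("refined", pred_ref)):
            m = acc.accuracy_metrics(acc.confusion_matrix(ref, pred, scheme))
            rows.append({"map": name, "overall": m.overall, "kappa": m.kappa,
                         **{f"producers_{k}": v for k, v in m.producers.items()},
                         **{f"users_{k}": v for k, v in m.users.items()}})
            summary[f"{name}_overall"] = m.overall
            summary[f"{name}_kappa"] = m.kappa
        mc = acc.mcnemar_test(pred_ref == ref, pred_base == ref)
        summary["mcnemar"] = {"chi2": mc.statistic, "p": mc.p_value, "b": mc.b, "c": mc.c}
        write_csv(pd.DataFrame(rows), out / "accuracy.csv", config.provenance(stage))
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    stage = "ppa"
    try:
        rice = cl.raster_class_to_points(refined_map, focal)
        write_points(rice, out / "rice_points.csv", header=config.provenance(stage))
        uni_r = rp.univariate_radii(config.uni_rmax, config.uni_step)
        biv_r = rp.bivariate_radii(config.biv_rmax, config.biv_step)
        envs = {}
        if nests.n >= 2:
            envs["nests_univariate"] = rp.csr_envelope(
                nests, uni_r, config.nsim, config.alpha, rngs[6]
            )
        if rice.n >= 2:
            envs["rice_univariate"] = rp.csr_envelope(
                rice, uni_r, config.nsim, config.alpha, rngs[7]
            )
        if nests.n >= 1 and rice.n >= 1:
            envs["bivariate"] = rp.independence_envelope(
                nests, rice, biv_r, config.nsim, config.alpha, rngs[8]
            )
        for name, env in envs.items():
            write_csv(
                pd.DataFrame({"r": env.radii, "L": env.observed_L, "lo": env.lower,
                              "hi": env.upper, "verdict": env.verdicts}),
                out / f"{name}_L.csv", config.provenance(stage),
            )
            summary[f"{name}_above"] = int(np.sum(env.verdicts == "above"))
            summary[f"{name}_inside"] = int(np.sum(env.verdicts == "inside"))
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    stage = "cluster"
    try:
        areas = cl.buffer_class_area(refined_map, nests, config.buffer_radius, focal)
        nest_clusters = cl.ward_cluster(nests.points, config.k_nests)
        level_clusters = cl.ward_cluster(areas.area_ha, config.n_levels)
        frame = areas.to_frame()
        frame["cluster"] = nest_clusters.labels
        frame["area_level"] = level_clusters.labels
        write_csv(frame, out / "buffers.csv", config.provenance(stage))
        write_points_geojson(
            nests, out / "clusters.geojson",
            {"cluster": nest_clusters.labels, "area_ha": areas.area_ha,
             "area_level": level_clusters.labels},
        )
        grouped = {g: areas.area_ha[nest_clusters.labels == g] for g in range(1, config.k_nests + 1)}
        gt = cl.group_tests(grouped, config.alpha)
        summary["kruskal"] = {"H": gt.kruskal_h, "p": gt.kruskal_p}
        summary["area_by_cluster_ha"] = {
            str(g): {"mean": float(v.mean()), "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0}
            for g, v in grouped.items()
        }
        write_csv(gt.pairwise, out / "pairwise_mannwhitney.csv", config.provenance(stage))
        # per-cluster bivariate association, then ANOVA over pooled L12 values
        biv_r = rp.bivariate_radii(config.biv_rmax, config.biv_step)
        l12_groups = {}
        cluster_rows = []
        for g in range(1, config.k_nests + 1):
            sub = nests.points[nest_clusters.labels == g]
            if len(sub) < 1 or rice.n < 1:
                continue
            env = rp.independence_envelope(
                PointPattern(sub, nests.window, allow_duplicates=True), rice, biv_r,
                config.nsim, config.alpha, rngs[9 + g % 6],
            )
            l12_groups[g] = env.observed_L
            for r, L, lo, hi, v in zip(env.radii, env.observed_L, env.lower, env.upper, env.verdicts):
                cluster_rows.append({"cluster": g, "r": r, "L": L, "lo": lo, "hi": hi, "verdict": v})
        write_csv(pd.DataFrame(cluster_rows), out / "cluster_L12.csv", config.provenance(stage))
        if len(l12_groups) >= 2:
            an = cl.envelope_anova(l12_groups, config.alpha)
            summary["anova"] = {"F": an.f, "p": an.p}
            write_csv(an.tukey, out / "tukey.csv", config.provenance(stage))
    except Exception as e:
        raise RuntimeError(f"stage {stage!r} failed: {e}") from e

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=float)
    return summary
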