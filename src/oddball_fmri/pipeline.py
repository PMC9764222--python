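"""End-to-end orchestration: simulate → fit → detect → test → compare → report.

A :class:`PipelineConfig` fixes the cohort (participants, runs), the
acquisition (TR, tSNR), the labelled voxel grid, the generative profile
of each ROI, the statistical thresholds, and a single global seed that
fans out deterministically into per-stage child seeds.  The report
bundle mirrors the study's outputs: an SSA cluster table, a
predictability comparison table, SSAi and posterior-probability maps,
Bayes-factor histograms, and a machine-readable summary.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import pickle
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import bms, design, expectation, glm, simulate, ssa

logger = logging.getLogger("oddball_fmri")

__all__ = ["PipelineConfig", "run_pipeline"]

DEFAULT_PROFILES = {name: {"model": "h2", "gain": simulate.DEFAULT_GAIN,
                           "slope_sign": -1, "baseline": 1.0}
                    for name in simulate.DEFAULT_ROI_NAMES}


@dataclass(frozen=True)
class PipelineConfig:
    """Complete, serialisable description of one synthetic study.

    Defaults follow the pure-tone arm of the emulated study: 19
    participants, 4 runs, TR 1.6 s, tSNR 50.
    """

    n_participants: int = 19
    n_runs: int = 4
    stimulus_kind: str = "pure_tone"        # or "fm_sweep"
    tr: float = 1.6
    grid_shape: tuple[int, ...] = (20, 20, 10)
    roi_block: tuple[int, ...] = (5, 5, 4)
    roi_profiles: dict = field(default_factory=lambda: dict(DEFAULT_PROFILES))
    tsnr: float | None = 50.0
    ar1: float = 0.3
    alpha: float = 0.05
    pairwise_family_size: int | None = None     # None -> 6 x n SSA regions
    null_rate: float = 0.10
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        d["roi_block"] = list(self.roi_block)
        return json.dumps(d, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["grid_shape"] = tuple(d["grid_shape"])
        d["roi_block"] = tuple(d["roi_block"])
        return cls(**d)

    def digest(self) -> str:
        return hashlib.sha1(self.to_json().encode()).hexdigest()[:12]

    def child_seed(self, *tags) -> int:
        """Deterministic per-stage seed derived from the global seed."""
        h = hashlib.sha1(("/".join(map(str, tags)) +
                          f"#{self.seed}").encode()).digest()
        return int.from_bytes(h[:4], "little") % (2 ** 31)

    def stimuli(self):
        return (design.default_pure_tones() if self.stimulus_kind == "pure_tone"
                else design.default_fm_sweeps())

    def grid(self) -> simulate.VoxelGrid:
        spec = simulate.default_roi_spec(self.grid_shape, self.roi_block,
                                         names=tuple(self.roi_profiles))
        return simulate.make_roi_grid(spec)

    def profiles(self) -> dict[str, simulate.GenerativeProfile]:
        return {name: simulate.GenerativeProfile(**spec)
                for name, spec in self.roi_profiles.items()}

    def noise_spec(self) -> simulate.NoiseSpec:
        return simulate.NoiseSpec(tsnr=self.tsnr, ar1=self.ar1)


def _timed(stage):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") \
                    from exc
            logger.info("stage %-15s %6.1f s", stage, time.perf_counter() - t0)
            return out
        return wrapper
    return deco


@dataclass
class CohortData:
    grid: simulate.VoxelGrid
    schedules: list               # [participant][run] RunSchedule
    bold: list                    # [participant][run] BOLDRun


@_timed("simulate")
def simulate_cohort(config: PipelineConfig) -> CohortData:
    """Generate schedules and synthetic BOLD runs for the whole cohort."""
    grid = config.grid()
    profiles = config.profiles()
    noise = config.noise_spec()
    params = design.RunParams(null_rate=config.null_rate)
    stimuli = config.stimuli()
    schedules, bold = [], []
    for s in range(config.n_participants):
        sch_row, bold_row = [], []
        for r in range(config.n_runs):
            schedule = design.build_run(
                params, seed=config.child_seed("design", s, r),
                stimuli=stimuli, run_index=r)
            run = simulate.simulate_run(
                schedule, grid, profiles, noise, tr=config.tr,
                seed=config.child_seed("noise", s, r))
            sch_row.append(schedule)
            bold_row.append(run)
        schedules.append(sch_row)
        bold.append(bold_row)
    return CohortData(grid=grid, schedules=schedules, bold=bold)


@_timed("fit-glm")
def fit_cohort(config: PipelineConfig, cohort: CohortData) -> glm.BetaMaps:
    """First-level GLM per run; standardised condition betas per cohort."""
    run_betas = []
    for s in range(config.n_participants):
        row = []
        for r in range(config.n_runs):
            schedule = cohort.schedules[s][r]
            run = cohort.bold[s][r]
            events = design.event_table(schedule)
            X = glm.build_design_matrix(events, config.tr, run.n_volumes)
            row.append(glm.fit_glm(run, X))
        run_betas.append(row)
    maps = glm.BetaMaps.from_runs(run_betas, cohort.grid)
    return glm.standardize_betas(maps)


@_timed("detect-ssa")
def detect_ssa(config: PipelineConfig, maps: glm.BetaMaps,
               grid: simulate.VoxelGrid) -> dict:
    """Voxel-wise SSA conjunction, clusters, and the SSAi map."""
    p_adapt = ssa.voxelwise_contrast_test(maps, "adaptation")
    p_dev = ssa.voxelwise_contrast_test(maps, "deviant_detection")
    result = ssa.ssa_conjunction(p_adapt, p_dev, maps.roi_labels,
                                 maps.roi_names, alpha=config.alpha)
    mask_vol = ssa.to_volume(result.significant_mask.astype(float),
                             maps.coords, grid.shape, fill=0.0) > 0
    p_vol = ssa.to_volume(result.p_ssa, maps.coords, grid.shape, fill=1.0)
    clusters = ssa.extract_clusters(mask_vol, grid.labels, p_vol,
                                    grid.roi_names)
    ssai = ssa.ssai_map(maps)
    return {"contrast": result, "clusters": clusters, "ssai": ssai}


def _region_masks(config: PipelineConfig, maps: glm.BetaMaps,
                  contrast: ssa.ContrastResult) -> dict[str, np.ndarray]:
    """SSA regions: significant voxels within each FWE-significant ROI."""
    regions = {}
    for name in contrast.significant_rois:
        lab = next(l for l, n in maps.roi_names.items() if n == name)
        sel = (maps.roi_labels == lab) & contrast.significant_mask
        if sel.any():
            regions[name] = sel
    return regions


@_timed("stats")
def expectation_stats(config: PipelineConfig, maps: glm.BetaMaps,
                      contrast: ssa.ContrastResult) -> dict:
    """Classical, mixed-model, and correlational predictability analyses."""
    regions = _region_masks(config, maps, contrast)
    family = config.pairwise_family_size or \
        len(expectation.PAIRWISE_CONTRASTS) * max(1, len(regions))
    avg = maps.run_average()                       # (S, C, V)
    dev_idx = [maps.condition_index(c) for c in ("dev4", "dev5", "dev6")]
    out = {"regions": {}, "n_regions": len(regions)}
    for name, sel in regions.items():
        means = pd.DataFrame(
            {cond: avg[:, maps.condition_index(cond), :][:, sel].mean(axis=1)
             for cond in maps.conditions})
        comparisons = expectation.pairwise_tests(means, family_size=family)

        rows = []
        S, R = maps.n_participants, maps.n_runs
        vox = np.flatnonzero(sel)
        for cond, p in expectation.PREDICTABILITY_CODES.items():
            c = maps.condition_index(cond)
            block = maps.betas[:, :, c, :][:, :, vox]      # (S, R, v)
            for s in range(S):
                for r in range(R):
                    rows.append(pd.DataFrame({
                        "beta": block[s, r], "predictability": p,
                        "participant": s, "run": r, "voxel": vox}))
        lmm = expectation.fit_lmm(pd.concat(rows, ignore_index=True),
                                  n_rois=max(1, len(regions)),
                                  alpha=config.alpha)
        spearman = expectation.spearman_predictability(
            avg[:, dev_idx, :][:, :, vox])
        out["regions"][name] = {"pairwise": comparisons, "lmm": lmm,
                                "spearman": spearman}
    return out


@_timed("compare-models")
def compare_models(config: PipelineConfig, cohort: CohortData) -> dict:
    """Per-voxel log-evidence for h1 and h2 and group posterior maps."""
    runs_data = [[b.data for b in row] for row in cohort.bold]
    evidence = bms.evidence_for_cohort(runs_data, cohort.schedules,
                                       config.tr, cohort.grid)
    posterior = bms.group_maps(evidence)
    return {"evidence": evidence, "posterior": posterior}


def _comparison_frame(stats_out: dict) -> pd.DataFrame:
    rows = []
    for roi, block in stats_out["regions"].items():
        for c in block["pairwise"]:
            rows.append({"roi": roi, "contrast": c.contrast,
                         "statistic": c.statistic, "p_raw": c.p_raw,
                         "p_holm": c.p_holm, "n": c.n_participants})
    return pd.DataFrame(rows)


def _lmm_frame(stats_out: dict) -> pd.DataFrame:
    rows = []
    for roi, block in stats_out["regions"].items():
        m = block["lmm"]
        rows.append({"roi": roi, "intercept": m.intercept, "slope": m.slope,
                     "ci_low": m.slope_ci[0], "ci_high": m.slope_ci[1],
                     "dof": m.dof, "p": m.slope_p,
                     "p_bonferroni": m.slope_p_corrected,
                     "converged": m.converged, "singular": m.singular})
    return pd.DataFrame(rows)


def _k_histogram(posterior: bms.PosteriorMaps, bins: int = 40) -> pd.DataFrame:
    lnk = posterior.log_bayes_factor
    counts, edges = np.histogram(lnk, bins=bins)
    return pd.DataFrame({"lnK_low": edges[:-1], "lnK_high": edges[1:],
                         "count": counts})


def _summary(config: PipelineConfig, detect_out, stats_out, compare_out) -> dict:
    contrast: ssa.ContrastResult = detect_out["contrast"]
    posterior: bms.PosteriorMaps = compare_out["posterior"]
    ssai = detect_out["ssai"].ssai
    signal_rois = [n for n, spec in config.roi_profiles.items()
                   if spec.get("model", "null") != "null"]
    frac = posterior.fraction_favoring("h2")
    signal_fracs = [frac[n] for n in signal_rois if n in frac]
    lmm_rows = _lmm_frame(stats_out).to_dict("records") \
        if stats_out["regions"] else []
    return {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_significant_voxels": int(contrast.significant_mask.sum()),
        "significant_rois": contrast.significant_rois,
        "peak_p": contrast.peak_p,
        "n_clusters": len(detect_out["clusters"]),
        "ssai_median": (float(np.nanmedian(ssai))
                        if np.isfinite(ssai).any() else None),
        "pct_voxels_favoring_h2": 100.0 * float(
            (posterior.expected_posterior[:, 1] > 0.5).mean()),
        "pct_signal_voxels_favoring_h2": (
            100.0 * float(np.mean(signal_fracs)) if signal_fracs else None),
        "fraction_favoring_h2_by_roi": frac,
        "lmm": lmm_rows,
        "n_ssa_regions": stats_out["n_regions"],
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None,
                 use_cache: bool = True) -> dict:
    """Run every stage and return (and optionally write) the report bundle.

    With ``outdir`` set, intermediate cohort data are cached under a
    directory keyed by the config digest and reused on repeated calls;
    tables are written as TSV and the summary as JSON.
    """
    cohort = None
    cache_file = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cache_dir = outdir / f"cache-{config.digest()}"
        cache_dir.mkdir(exist_ok=True)
        cache_file = cache_dir / "cohort.pkl"
        if use_cache and cache_file.exists():
            with open(cache_file, "rb") as fh:
                cohort = pickle.load(fh)
            logger.info("stage %-15s cached", "simulate")
    if cohort is None:
        cohort = simulate_cohort(config)
        if cache_file is not None:
            with open(cache_file, "wb") as fh:
                pickle.dump(cohort, fh)

    maps = fit_cohort(config, cohort)
    detect_out = detect_ssa(config, maps, cohort.grid)
    stats_out = expectation_stats(config, maps, detect_out["contrast"])
    compare_out = compare_models(config, cohort)
    summary = _summary(config, detect_out, stats_out, compare_out)

    report = {
        "summary": summary,
        "cluster_table": ssa.cluster_table(detect_out["clusters"]),
        "comparison_table": _comparison_frame(stats_out),
        "lmm_table": _lmm_frame(stats_out),
        "k_histogram": _k_histogram(compare_out["posterior"]),
        "roi_model_summary": compare_out["posterior"].roi_summary("h2"),
        "beta_maps": maps,
        "contrast": detect_out["contrast"],
        "ssai": detect_out["ssai"],
        "posterior": compare_out["posterior"],
        "stats": stats_out,
    }
    if outdir is not None:
        report["cluster_table"].to_csv(outdir / "clusters.tsv", sep="\t",
                                       index=False)
        report["comparison_table"].to_csv(outdir / "comparisons.tsv",
                                          sep="\t", index=False)
        report["lmm_table"].to_csv(outdir / "lmm.tsv", sep="\t", index=False)
        report["k_histogram"].to_csv(outdir / "k_histogram.tsv", sep="\t",
                                     index=False)
        report["roi_model_summary"].to_csv(outdir / "roi_model_summary.tsv",
                                           sep="\t", index=False)
        (outdir / "summary.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True))
        (outdir / "config.json").write_text(config.to_json())
    return report
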