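"""End-to-end orchestration: simulate -> seed -> track -> metrics -> analyze.

One master seed deterministically derives every stage and per-subject seed
(via ``numpy.random.SeedSequence``), so a rerun with the same configuration
reproduces all outputs bit-exactly; a manifest records parameters, derived
seeds, stage counts and file checksums.
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

from lingtract.exceptions import InputError
from lingtract.io import CohortTable, save_cohort, save_volume
from lingtract.metrics import CommonalityMap, commonality, hemispheric_volumes, tract_li
from lingtract.outcomes import (
    MixedModelFit,
    PredictionEvaluation,
    RegressionFit,
    decline_scores,
    evaluate_prediction,
    fit_mixed_model,
    fit_regression,
    pearson_r,
    seizure_outcome_test,
    to_long,
)
from lingtract.seeds import build_seed, homotopic_peak
from lingtract.synthetic import (
    CohortSpec,
    PhantomSpec,
    make_cohort,
    make_phantom,
    phantom_spec_for_subject,
)
from lingtract.tracking import OrientationField, TrackingParams, binarize, track

logger = logging.getLogger("lingtract.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    seed_k: int = 100
    binarize_threshold: float = 0.01
    timepoints: tuple[str, ...] = ("4mo", "12mo")
    loo: bool = False
    z_transform: bool = False
    master_seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        from lingtract.synthetic import BundleSpec

        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            ph = dict(d["phantom"])
            if "bundle_specs" in ph:
                ph["bundle_specs"] = tuple(
                    BundleSpec(**b) if isinstance(b, dict) else b for b in ph["bundle_specs"]
                )
            for key in ("grid_shape", "voxel_size"):
                if key in ph:
                    ph[key] = tuple(ph[key])
            d["phantom"] = PhantomSpec(**ph)
        if "cohort" in d and isinstance(d["cohort"], dict):
            co = dict(d["cohort"])
            for key in ("li_asymmetry_range", "gnt_pre_range", "education_probs"):
                if key in co:
                    co[key] = tuple(co[key])
            d["cohort"] = CohortSpec(**co)
        if "tracking" in d and isinstance(d["tracking"], dict):
            d["tracking"] = TrackingParams(**d["tracking"])
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineReport:
    """All outputs of one pipeline run."""

    cohort: CohortTable
    correlations: pd.DataFrame
    regressions: dict[str, RegressionFit]
    predictions: dict[str, PredictionEvaluation]
    mixed_models: dict[str, MixedModelFit]
    fisher_p: dict[str, float]
    commonality_maps: dict[str, CommonalityMap]
    manifest: dict


def _child_seed(ss: np.random.SeedSequence) -> int:
    # keep derived seeds below 2**31 for portability
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _zscore(v: pd.Series | np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = np.nanstd(v, ddof=1)
    return (v - np.nanmean(v)) / sd if sd > 0 else v - np.nanmean(v)


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineReport:
    """Run every stage on a synthetic cohort and assemble the report bundle.

    Per subject: build a phantom (surgery-side bundle radii scaled by a
    drawn asymmetry factor), construct the seed from the activation peak and
    its homotopic correlate, track from both seeds, binarize and union the
    tract maps, and extract hemispheric volumes. The cohort generator then
    plants naming decline on the computed ipsilateral volumes, and the
    statistics layer produces correlations, regression + prediction tables,
    mixed models and the seizure-outcome test.
    """
    master = np.random.SeedSequence(config.master_seed)
    ss_subjects, ss_cohort, ss_asym = master.spawn(3)
    rng_asym = np.random.default_rng(ss_asym)

    n = config.cohort.n_subjects
    lo, hi = config.cohort.li_asymmetry_range
    asymmetry = rng_asym.uniform(lo, hi, n)
    sides = np.where(rng_asym.random(n) < config.cohort.p_left, "left", "right")

    records = []
    masks_by_side: dict[str, list[np.ndarray]] = {"left": [], "right": []}
    subject_seeds = ss_subjects.spawn(n)
    for i in range(n):
        ss_i = subject_seeds[i]
        phantom_seed = _child_seed(ss_i)
        track_seed_a = _child_seed(ss_i)
        track_seed_b = _child_seed(ss_i)
        spec_i = phantom_spec_for_subject(
            config.phantom, sides[i], float(asymmetry[i]), phantom_seed
        )
        tissue, fld, peak_left, _ = make_phantom(spec_i)
        seed_ipsi = build_seed(peak_left, tissue, k=config.seed_k)
        peak_homotopic = homotopic_peak(peak_left, tissue)
        seed_contra = build_seed(peak_homotopic, tissue, k=config.seed_k)
        tract_a = track(
            seed_ipsi, fld, tissue,
            dataclasses.replace(config.tracking, seed=track_seed_a),
            keep_streamlines=False,
        )
        tract_b = track(
            seed_contra, fld, tissue,
            dataclasses.replace(config.tracking, seed=track_seed_b),
            keep_streamlines=False,
        )
        mask = binarize(tract_a, config.binarize_threshold) | binarize(
            tract_b, config.binarize_threshold
        )
        vols = hemispheric_volumes(mask, tissue, sides[i])
        masks_by_side[sides[i]].append(mask)
        records.append(
            {
                "surgery_side": sides[i],
                "asymmetry": float(asymmetry[i]),
                "v_surg_norm": vols.v_surg_norm,
                "v_contralat_norm": vols.v_contralat_norm,
                "tract_li": tract_li(vols.v_surg, vols.v_contralat),
                "n_accepted_ipsi": tract_a.n_accepted,
                "n_accepted_contra": tract_b.n_accepted,
            }
        )
        logger.info(
            "subject %d/%d side=%s accepted=%d/%d v_surg=%.0f",
            i + 1, n, sides[i], tract_a.n_accepted, tract_b.n_accepted,
            vols.v_surg_norm,
        )

    volumes = pd.DataFrame(records)
    cohort_spec = dataclasses.replace(config.cohort, seed=_child_seed(ss_cohort))
    cohort = make_cohort(cohort_spec, volumes=volumes)

    # ---------------- statistics -----------------
    scores = decline_scores(cohort)
    corr_rows = []
    for predictor in ("v_surg_norm", "tract_li"):
        for tp in config.timepoints:
            x = cohort.df[predictor]
            y = scores[f"decline_{tp}"]
            yv = _zscore(y) if config.z_transform else y
            r, p = pearson_r(x, yv)
            corr_rows.append(
                {"predictor": predictor, "timepoint": tp, "r": r, "p": p,
                 "n": int((x.notna() & y.notna()).sum())}
            )
    correlations = pd.DataFrame(corr_rows)

    regressions: dict[str, RegressionFit] = {}
    predictions: dict[str, PredictionEvaluation] = {}
    for tp in config.timepoints:
        fit = fit_regression(cohort, "v_surg_norm", timepoint=tp)
        regressions[tp] = fit
        predictions[tp] = evaluate_prediction(fit, loo=config.loo)

    long_df = to_long(cohort, value_cols=("v_surg_norm", "tract_li"))
    if config.z_transform:
        long_df = long_df.assign(decline=_zscore(long_df["decline"]))
    mixed_models = {
        pred: fit_mixed_model(long_df, pred) for pred in ("v_surg_norm", "tract_li")
    }

    fisher_p = {tp: seizure_outcome_test(cohort, timepoint=tp) for tp in config.timepoints}

    commonality_maps = {
        side: commonality(masks) for side, masks in masks_by_side.items() if masks
    }

    manifest: dict = {
        "config": config.to_dict(),
        "master_seed": config.master_seed,
        "n_subjects": n,
        "stage_counts": {
            "seed_voxels": config.seed_k,
            "streamlines_per_seed": config.tracking.n_streamlines,
            "accepted_ipsi": [r["n_accepted_ipsi"] for r in records],
            "accepted_contra": [r["n_accepted_contra"] for r in records],
        },
        "files": {},
    }

    report = PipelineReport(
        cohort=cohort,
        correlations=correlations,
        regressions=regressions,
        predictions=predictions,
        mixed_models=mixed_models,
        fisher_p=fisher_p,
        commonality_maps=commonality_maps,
        manifest=manifest,
    )

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        save_cohort(cohort, out / "cohort.csv")
        correlations.to_csv(out / "correlations.csv", index=False)
        summary = report_summary(report)
        (out / "report.json").write_text(json.dumps(summary, indent=2))
        from lingtract.io import VolumeGrid

        for side, cmap in commonality_maps.items():
            # all subjects share the phantom grid geometry
            save_volume(
                VolumeGrid(cmap.value, np.asarray(tissue.labels.affine)),
                out / f"commonality_{side}.nii.gz",
            )
        for f in sorted(out.iterdir()):
            if f.name != "manifest.json":
                manifest["files"][f.name] = _sha256(f)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


def report_summary(report: PipelineReport) -> dict:
    """JSON-serialisable digest of a pipeline report."""
    out: dict = {
        "correlations": report.correlations.to_dict(orient="records"),
        "regressions": {},
        "predictions": {},
        "mixed_models": {},
        "fisher_p": report.fisher_p,
    }
    for tp, fit in report.regressions.items():
        out["regressions"][tp] = {
            "f_stat": fit.f_stat,
            "df": [fit.df_model, fit.df_resid],
            "p": fit.f_pvalue,
            "r2": fit.r2,
            "adj_r2": fit.adj_r2,
            "coefficients": fit.params.to_dict(),
            "coefficient_p": fit.pvalues.to_dict(),
        }
    for tp, ev in report.predictions.items():
        sens, spec = ev.rounded()
        out["predictions"][tp] = {
            "tp": ev.tp, "fp": ev.fp, "fn": ev.fn, "tn": ev.tn,
            "sensitivity_pct": None if np.isnan(sens) else sens,
            "specificity_pct": None if np.isnan(spec) else spec,
        }
    for pred, mm in report.mixed_models.items():
        out["mixed_models"][pred] = {
            "chi2": mm.chi2, "df": mm.chi2_df, "p": mm.p,
            "marginal_r2": mm.marginal_r2,
            "fixed_effects": mm.fe_params.to_dict(),
            "random_intercept_var": mm.random_intercept_var,
        }
    return out
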