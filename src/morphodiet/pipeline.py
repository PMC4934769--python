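"""Study-shaped analysis pipeline: from landmark/isotope inputs to a report bundle.

``run_full_analysis`` executes, in order: Procrustes superimposition with
semi-landmark sliding; per-group size summaries and ANOVA; the per-phase
wild/domestic admixture screen; the allometry permutation test and pooled
within-group correction; MANOVA; CVA with cross-validated dimensionality
selection (scores, confidence ellipses and per-axis shape changes);
Mahalanobis distances and the unrooted NJ phenogram; and on the isotope
side the weaning filter, diet classification, per-phase ANOVA, delta13C
mixture selection and the isotope-by-M3-size cross-table.  Every artifact is
written as CSV/JSON/Newick under the output directory and a manifest records
all constants and the seed, so reruns with the same config are
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import isotope_diet, model_clustering, shape_statistics, synthetic_data
from .isotope_diet import DietEndmemberModel
from .procrustes_core import SlidingSpec, cyclic_neighbors, gpa_align, slide_semilandmarks
from .tps_io import read_isotope_csv, read_tps

__all__ = ["RunConfig", "run_full_analysis", "PipelineError"]

logger = logging.getLogger("morphodiet")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage tag."""


@dataclass
class RunConfig:
    """Configuration of a full analysis run.

    Either file inputs (``tps_path`` and/or ``isotope_csv``) or the synthetic
    presets (``synthetic_shapes`` / ``synthetic_isotopes``) feed the two
    analysis arms; a missing arm is skipped.  All thresholds default to the
    endmember model's values; the seed is mandatory.
    """

    seed: int
    outdir: str | Path = "morphodiet_out"
    tps_path: str | None = None
    tps_sidecar: str | None = None
    isotope_csv: str | None = None
    synthetic_shapes: bool = False
    synthetic_isotopes: bool = False
    group_key: str = "phase"
    n_perm: int = 1000
    g_max: int = 3
    n_boot: int = 50
    m3_cutoff: float = 37.9
    min_dental_stage: int = 10
    strict_weaning: bool = False
    slide: bool = True
    allometry_alpha: float = 0.05
    endmember: dict = field(default_factory=dict)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "seed" not in data:
            raise ValueError("config must set a seed")
        return cls(**data)

    def endmember_model(self) -> DietEndmemberModel:
        return DietEndmemberModel(**self.endmember)


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n",
        encoding="utf-8",
    )


def _write_csv(path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


# ---------------------------------------------------------------------------
# Shape arm
# ---------------------------------------------------------------------------

@_stage("shapes")
def _run_shape_stage(config: RunConfig, outdir: Path, rng: np.random.Generator) -> dict:
    if config.tps_path:
        configs = read_tps(config.tps_path, sidecar=config.tps_sidecar)
    else:
        configs, _ = synthetic_data.simulate_shape_dataset(
            synthetic_data.default_shape_spec(seed=config.seed)
        )
    groups = np.array([c.meta.get(config.group_key, "unknown") for c in configs])
    shapes = gpa_align(configs)
    if config.slide and shapes.semi_indices:
        spec = SlidingSpec(
            semi_indices=shapes.semi_indices,
            neighbors=cyclic_neighbors(shapes.semi_indices),
        )
        shapes = slide_semilandmarks(shapes, spec)

    # (1) size summary + ANOVA
    summary = shape_statistics.size_summary(shapes.centroid_sizes, groups)
    _write_csv(outdir / "size_summary.csv", summary.table)
    _write_json(
        outdir / "size_anova.json",
        {"F": summary.anova_F, "p": summary.anova_p},
    )

    # (2) admixture screen per group
    screen = model_clustering.admixture_screen(
        shapes, groups, seed=int(rng.integers(0, 2**31 - 1))
    )
    _write_json(outdir / "admixture_screen.json", screen)

    # (3) allometry test and correction
    allo = shape_statistics.test_allometry(
        shapes, n_perm=config.n_perm, seed=int(rng.integers(0, 2**31 - 1))
    )
    correction = shape_statistics.remove_allometry(shapes, groups)
    use_corrected = allo.p_value <= config.allometry_alpha
    _write_json(
        outdir / "allometry.json",
        {
            "pct_variance_predicted": allo.pct_variance_predicted,
            "p_value": allo.p_value,
            "n_perm": allo.n_perm,
            "corrected_variables_used": bool(use_corrected),
        },
    )
    if use_corrected:
        vars_full = correction.residuals
        groups_used = groups[correction.keep_mask]
        flat = shapes.flat()[correction.keep_mask]
    else:
        flat = shapes.flat()
        vars_full = flat - flat.mean(axis=0)
        groups_used = groups

    # (4-6) PCA -> PC count -> CVA -> MANOVA -> NJ
    pca = shape_statistics.shape_pca(vars_full)
    n_pc = shape_statistics.select_pc_count(
        pca.scores,
        groups_used,
        n_boot=config.n_boot,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    cva_res = shape_statistics.cva(
        pca.scores, groups_used, n_pc=n_pc, shape_coords=flat
    )
    manova = shape_statistics.manova_test(pca.scores[:, :n_pc], groups_used)
    _write_json(outdir / "manova.json", manova)

    scores_df = pd.DataFrame(
        cva_res.scores,
        columns=[f"CV{i + 1}" for i in range(cva_res.scores.shape[1])],
    )
    scores_df.insert(0, "group", groups_used)
    scores_df.insert(0, "specimen_id", [i for i, keep in zip(shapes.ids, (correction.keep_mask if use_corrected else np.ones(len(shapes.ids), bool))) if keep])
    _write_csv(outdir / "cva_scores.csv", scores_df)

    ellipse_rows = []
    if cva_res.scores.shape[1] >= 2:
        for g in pd.unique(groups_used):
            pts = cva_res.scores[groups_used == g][:, :2]
            if pts.shape[0] < 3:
                continue
            ell = shape_statistics.confidence_ellipse(pts, level=0.9)
            ellipse_rows.append(
                {
                    "group": g,
                    "center_x": ell.center[0],
                    "center_y": ell.center[1],
                    "semi_major": ell.semi_axes[0],
                    "semi_minor": ell.semi_axes[1],
                    "angle_rad": ell.angle,
                    "level": ell.level,
                    "degenerate": ell.degenerate,
                }
            )
    _write_csv(outdir / "cva_ellipses.csv", pd.DataFrame(ellipse_rows))

    axis_df = pd.DataFrame(
        cva_res.axis_shape_changes,
        columns=[f"CV{i + 1}" for i in range(cva_res.scores.shape[1])],
    )
    _write_csv(outdir / "cva_axis_shapes.csv", axis_df)

    maha = cva_res.mahalanobis
    maha_out = maha.reset_index(names="group")
    _write_csv(outdir / "mahalanobis.csv", maha_out)
    newick = shape_statistics.nj_phenogram(maha.values, list(maha.index))
    (outdir / "phenogram.nwk").write_text(newick + "\n", encoding="utf-8")

    return {
        "n_specimens": shapes.n_specimens,
        "n_pc_used": n_pc,
        "cv_accuracy": cva_res.cv_accuracy,
        "allometry_p": allo.p_value,
        "anova_F": summary.anova_F,
        "manova_pillai": manova["pillai"],
    }


# ---------------------------------------------------------------------------
# Isotope arm
# ---------------------------------------------------------------------------

@_stage("isotopes")
def _run_isotope_stage(config: RunConfig, outdir: Path, rng: np.random.Generator) -> dict:
    model = config.endmember_model()
    if config.isotope_csv:
        records = read_isotope_csv(config.isotope_csv)
    else:
        records, _ = synthetic_data.simulate_isotope_dataset(
            synthetic_data.xwg_isotope_spec(seed=config.seed)
        )
    records = isotope_diet.filter_weaned(
        records, min_stage=config.min_dental_stage, strict=config.strict_weaning
    )
    if not records:
        raise ValueError("no isotope records left after weaning filter")

    # (7) classification + per-phase mixture + phase ANOVA
    rows = []
    for r in records:
        cls = isotope_diet.classify_d13C(r, model)
        m3_class = (
            isotope_diet.classify_M3(r.M3_length, cutoff=config.m3_cutoff)
            if r.M3_length is not None
            else ""
        )
        rows.append(
            {
                "specimen_id": r.specimen_id,
                "phase": r.phase,
                "taxon": r.taxon,
                "d13C": r.d13C,
                "d15N": r.d15N,
                "d13C_category": cls.d13C_category,
                "millet_fraction_indicative": cls.millet_fraction_indicative,
                "M3_length": r.M3_length if r.M3_length is not None else "",
                "M3_size_class": m3_class,
            }
        )
    class_df = pd.DataFrame(rows)

    mixture_report = {}
    phases = pd.unique(class_df["phase"])
    for ph in phases:
        sub = [r for r in records if r.phase == ph]
        if len(sub) < 5:
            mixture_report[str(ph)] = {"skipped": True, "n": len(sub)}
            continue
        fit = isotope_diet.cluster_d13C(
            sub,
            G_range=range(1, config.g_max + 1),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        mixture_report[str(ph)] = {
            "skipped": False,
            "n": len(sub),
            "best_G": fit.G,
            "family": fit.family,
            "loglik": fit.loglik,
            "df": fit.df,
            "bic": fit.bic,
            "means": fit.means.ravel().tolist(),
            "bic_table": fit.table.to_dict(orient="records"),
        }
        labels = {r.specimen_id: int(a) for r, a in zip(sub, fit.assignments)}
        class_df.loc[class_df["phase"] == ph, "d13C_cluster"] = [
            labels[s] for s in class_df.loc[class_df["phase"] == ph, "specimen_id"]
        ]
    if "d13C_cluster" in class_df.columns:
        class_df["d13C_cluster"] = class_df["d13C_cluster"].astype("Int64")
    _write_csv(outdir / "isotope_classification.csv", class_df)
    _write_json(outdir / "isotope_mixture.json", mixture_report)

    anova = {
        "d13C": isotope_diet.phase_comparison(records, "d13C"),
        "d15N": isotope_diet.phase_comparison(records, "d15N"),
    }
    _write_json(outdir / "isotope_phase_anova.json", anova)

    # (8) isotope category x M3 size class cross-table
    with_m3 = class_df[class_df["M3_size_class"] != ""]
    if len(with_m3):
        crosstab = (
            pd.crosstab(with_m3["d13C_category"], with_m3["M3_size_class"])
            .reset_index()
        )
    else:
        crosstab = pd.DataFrame(columns=["d13C_category"])
    _write_csv(outdir / "isotope_m3_crosstab.csv", crosstab)

    return {
        "n_records": len(records),
        "phases": [str(p) for p in phases],
        "anova_d13C_F": anova["d13C"]["anova_F"],
        "anova_d15N_F": anova["d15N"]["anova_F"],
    }


def run_full_analysis(config: RunConfig) -> dict:
    """Run both analysis arms and write the report bundle plus manifest.

    Returns a summary dict with the paths written and headline statistics.
    Stage failures raise :class:`PipelineError` tagged with the stage name;
    artifacts from completed stages are retained.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    shape_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
    iso_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))

    report: dict = {"outdir": str(outdir)}
    do_shapes = bool(config.tps_path) or config.synthetic_shapes
    do_isotopes = bool(config.isotope_csv) or config.synthetic_isotopes
    if not do_shapes and not do_isotopes:
        raise ValueError("config enables neither shape nor isotope inputs")

    if do_shapes:
        report["shapes"] = _run_shape_stage(config, outdir, shape_rng)
    if do_isotopes:
        report["isotopes"] = _run_isotope_stage(config, outdir, iso_rng)

    manifest = {
        "seed": config.seed,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "endmember_model": config.endmember_model().to_dict(),
        "collagen_ranges": {
            e: isotope_diet.endmember_collagen_range(config.endmember_model(), e)
            for e in ("c3", "millet_seed", "millet_leaf")
        },
        "stages_run": [k for k in ("shapes", "isotopes") if k in report],
    }
    _write_json(outdir / "manifest.json", manifest)
    report["manifest"] = manifest
    return report
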