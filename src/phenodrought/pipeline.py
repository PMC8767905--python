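"""End-to-end orchestration: simulate -> extract -> gravimetrics ->
indices -> analyze, plus reproduction of the packaged published tables.

Each stage reads only the previous stage's outputs (CSV on disk when run
through `run_pipeline`), logs timestamped progress lines, and everything
is content-addressed in a final manifest so a fixed seed gives
byte-identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis, cohort as cohort_mod, datasets, gravimetric, imaging, indices, render

logger = logging.getLogger("phenodrought")

__all__ = ["RunConfig", "run_pipeline", "reproduce_published_tables", "extract_traits_from_images"]


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    cohort: cohort_mod.CohortConfig = None  # type: ignore[assignment]
    selection_k: int = 9
    flat_tol_pct: float = 10.0
    wu_kappa_g_per_cm2: float = 0.2  # biomass proxy: kappa * PSA
    render_images: bool = True
    #: genotypes to render (images are a validation artifact; rendering the
    #: whole cohort at every stage is deliberately opt-in)
    n_render_genotypes: int = 2
    min_segment_size: int = 25
    version: str = "0.1.0"

    def __post_init__(self):
        if self.cohort is None:
            self.cohort = cohort_mod.CohortConfig(seed=self.seed)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        raw = dict(raw)
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            sub = raw["cohort"]
            sub_known = {f.name for f in dataclasses.fields(cohort_mod.CohortConfig)}
            sub_unknown = set(sub) - sub_known
            if sub_unknown:
                raise ValueError(f"unknown cohort configuration keys: {sorted(sub_unknown)}")
            if "anchors" in sub and isinstance(sub["anchors"], dict):
                sub["anchors"] = cohort_mod.TraitAnchors(
                    **{k: tuple(v) if isinstance(v, list) else v for k, v in sub["anchors"].items()}
                )
            if "pot" in sub and isinstance(sub["pot"], dict):
                sub["pot"] = gravimetric.PotGeometry(**sub["pot"])
            for key in ("stage_days", "yp_range", "rdy_range", "tau_range", "tillers_range"):
                if key in sub and isinstance(sub[key], list):
                    sub[key] = tuple(sub[key])
            raw["cohort"] = cohort_mod.CohortConfig(**sub)
        return cls(**raw)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load YAML (or JSON — valid YAML is a superset) configuration."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw or {})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def extract_traits_from_images(
    image_sets: dict[str, render.ImageSet],
    min_segment_size: int = 25,
) -> pd.DataFrame:
    """PSA and mean NIR per rendered image set, via the imaging pipeline.

    Registration is refit from each set's control points rather than taken
    from the renderer, so the whole chain (segmentation, area, affine,
    NIR lookup) is exercised.
    """
    rows = []
    for key, image_set in image_sets.items():
        affine = imaging.register_nir(image_set.control_points_nir, image_set.control_points_rgb)
        masks = {
            view: imaging.segment_plant(
                image_set.rgb[view], image_set.px_per_cm, view, min_segment_size
            )
            for view in ("SV0", "SV120", "SV240")
        }
        psa = imaging.psa_from_views(masks)
        nir_values = []
        for view in ("SV0", "SV120", "SV240"):
            try:
                nir_values.append(
                    imaging.mean_nir_intensity(image_set.nir[view], masks[view], affine)
                )
            except ValueError:
                pass  # empty plant in this view
        rows.append(
            {
                "key": key,
                "PSA": psa,
                "NIR": float(np.mean(nir_values)) if nir_values else np.nan,
                "registration_rms": affine.residual_rms,
            }
        )
    return pd.DataFrame(rows)


def extract_traits_from_dir(
    images_dir: str | Path, min_segment_size: int = 25
) -> pd.DataFrame:
    """Extract PSA/NIR from a directory of `<key>_<view>_{rgb,nir}.png`.

    Expects the `image_meta.json` written next to the images (pixel scale
    and control points per image set).
    """
    import imageio.v3 as iio

    images_dir = Path(images_dir)
    meta_path = images_dir / "image_meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing image metadata: {meta_path}")
    meta = json.loads(meta_path.read_text())
    sets: dict[str, render.ImageSet] = {}
    for key, m in meta.items():
        rgb = {
            v: iio.imread(images_dir / f"{key}_{v}_rgb.png")
            for v in ("SV0", "SV120", "SV240", "top")
            if (images_dir / f"{key}_{v}_rgb.png").exists()
        }
        nir = {
            v: iio.imread(images_dir / f"{key}_{v}_nir.png")
            for v in ("SV0", "SV120", "SV240")
            if (images_dir / f"{key}_{v}_nir.png").exists()
        }
        sets[key] = render.ImageSet(
            rgb=rgb,
            nir=nir,
            px_per_cm=float(m["px_per_cm"]),
            control_points_nir=np.asarray(m["control_points_nir"], float),
            control_points_rgb=np.asarray(m["control_points_rgb"], float),
            true_affine=None,  # type: ignore[arg-type]  # unknown when reading from disk
        )
    return extract_traits_from_images(sets, min_segment_size)


def _log_stage(name: str, t0: float) -> None:
    logger.info("%s  stage=%s  elapsed=%.2fs", time.strftime("%H:%M:%S"), name, time.time() - t0)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute all stages; returns the run directory.

    Writes the synthetic dataset, the water budget, the recomputed index
    table, stage changes / scores / correlations, a run log and a
    checksummed manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    t0 = time.time()
    try:
        ccfg = dataclasses.replace(config.cohort, seed=config.seed)
        genotypes = cohort_mod.make_cohort(ccfg)
        yields = cohort_mod.simulate_yields(genotypes, ccfg)
        traj = cohort_mod.simulate_trajectories(genotypes, ccfg)
        pots = cohort_mod.simulate_pot_weights(genotypes, traj, ccfg)

        images = {}
        if config.render_images:
            stressed = traj[traj["treatment"] == "stressed"]
            for gi, g in enumerate(genotypes[: config.n_render_genotypes]):
                for stage in ("I", "III", "V"):
                    sub = stressed[(stressed["genotype"] == g.id) & (stressed["stage"] == stage)]
                    psa = float(sub[sub["trait"] == "PSA"]["value"].iloc[0])
                    nir = float(sub[sub["trait"] == "NIR"]["value"].iloc[0])
                    # keep the rendered plant within the test canvas
                    scale = 200.0 / ccfg.anchors.psa_base_range[1]
                    images[f"{g.id}_stressed_{stage}"] = render.render_views(
                        psa * scale,
                        rolling=0.3 if stage == "III" else 0.0,
                        nir_level=int(round(nir)),
                        seed=ccfg.seed + 1000 * gi + ord(stage[0]),
                    )
        cohort_mod.write_dataset(out / "dataset", genotypes, yields, traj, pots, ccfg, images)
        _log_stage("simulate", t0)

        if images:
            extracted = extract_traits_from_images(images, config.min_segment_size)
            extracted.to_csv(out / "extracted_traits.csv", index=False)
        _log_stage("extract", t0)

        budget = gravimetric.water_budget(pots, ccfg.pot)
        budget.to_csv(out / "water_budget.csv", index=False)
        _log_stage("gravimetrics", t0)

        table, constants = indices.index_table(yields)
        table.to_csv(out / "indices.csv", index=False)
        (out / "cohort_constants.json").write_text(
            json.dumps(dataclasses.asdict(constants), indent=2)
        )
        _log_stage("indices", t0)

        changes = analysis.stage_changes(traj)
        changes.to_csv(out / "stage_changes.csv", index=False)
        scores = analysis.composite_tolerance_score(changes, k=config.selection_k)
        scores.to_csv(out / "scores.csv", index=False)
        responses = table[["genotype", "Yp", "Ys", "SSI_calc", "STI_calc", "TOL_diff_calc"]]
        corr = analysis.stagewise_correlation(traj, responses)
        corr.to_csv(out / "correlations.csv", index=False)
        _log_stage("analyze", t0)

        _plot_trajectories(out, traj)
        _write_report(out, yields, scores, corr, config)
        artifacts = sorted(
            p for p in out.rglob("*") if p.is_file() and p.suffix in {".csv", ".json", ".png", ".md"}
        )
        manifest = {
            "seed": config.seed,
            "files": {
                str(p.relative_to(out)): hashlib.sha256(p.read_bytes()).hexdigest()
                for p in artifacts
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        _log_stage("manifest", t0)
    except Exception:
        logger.exception("pipeline failed")
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out


def _plot_trajectories(out: Path, traj: pd.DataFrame) -> None:
    """Cohort-mean stage trajectories per trait, stressed vs unstressed."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    stages = ["I", "II", "III", "IV", "V"]
    fig, axes = plt.subplots(1, 4, figsize=(14, 3.2))
    for ax, trait in zip(axes, ("PSA", "WU", "TR", "NIR")):
        for treatment, style in (("stressed", "-o"), ("unstressed", "--s")):
            sub = traj[(traj["trait"] == trait) & (traj["treatment"] == treatment)]
            means = sub.groupby("stage")["value"].mean().reindex(stages)
            ax.plot(stages, means, style, label=treatment)
        ax.set_title(trait)
        ax.set_xlabel("stage")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "trajectories.png", dpi=100)
    plt.close(fig)


def _write_report(out: Path, yields, scores, corr, config: RunConfig) -> None:
    selected = scores[scores["selected"]].sort_values("composite_rank")
    lines = [
        "# Drought phenomics run report",
        "",
        f"Seed: {config.seed}; cohort: {len(yields)} genotypes.",
        "",
        f"## Selected genotypes (top {config.selection_k} composite ranks)",
        "",
        selected[["genotype", "composite", "composite_rank"]].to_markdown(index=False),
        "",
        "## Cohort-mean trajectories",
        "",
        "![trajectories](trajectories.png)",
        "",
        "## Stage-wise trait vs yield/index correlations (stressed)",
        "",
        corr[corr["significant"]].to_markdown(index=False),
        "",
    ]
    (out / "report.md").write_text("\n".join(lines))


def reproduce_published_tables(ratio_tol: float = 0.07, gram_tol: float = 0.1) -> dict:
    """Recompute every derivable cell and count of the packaged tables.

    Returns a report dict with per-cell mismatches and the published
    check-comparison counts. Tolerances: gram-scale cells +-0.1 g (the
    tables' own 1-dp yield rounding), ratio cells +-0.07 (half the printed
    unit plus the same rounding allowance).
    """
    report: dict = {}

    field = datasets.field_yield_table()
    table, constants = indices.index_table(field)
    mismatches = []
    printed_to_calc = {
        "TOL": ("TOL_diff_calc", gram_tol),
        "MP": ("MP_calc", gram_tol),
        "GMP": ("GMP_calc", gram_tol),
        "SSI": ("SSI_calc", ratio_tol),
        "STI": ("STI_calc", ratio_tol),
        "YI": ("YI_calc", ratio_tol),
        "YSI": ("YSI_calc", ratio_tol),
    }
    for printed, (calc, tol) in printed_to_calc.items():
        dev = (table[printed] - table[calc]).abs()
        for idx in dev.index[dev > tol + 1e-9]:
            mismatches.append(
                {
                    "table": "field",
                    "genotype": table.loc[idx, "genotype"],
                    "column": printed,
                    "printed": float(table.loc[idx, printed]),
                    "recomputed": float(table.loc[idx, calc]),
                }
            )
    counts = indices.compare_to_checks(
        table,
        datasets.RP_ID,
        datasets.DP_ID,
        indices=("TOL_diff", "SSI", "STI", "MP", "YI"),
        printed_columns={"TOL_diff": "TOL"},
    )
    report["field"] = {
        "constants": dataclasses.asdict(constants),
        "rp_ssi": float(table.loc[table["role"] == "RP", "SSI_calc"].iloc[0]),
        "dp_ssi": float(table.loc[table["role"] == "DP", "SSI_calc"].iloc[0]),
        "dp_sti": float(table.loc[table["role"] == "DP", "STI_calc"].iloc[0]),
        "counts": counts.to_dict("records"),
        "tol_summary": indices.summarize_index(table, "TOL_diff"),
        "mismatches": mismatches,
    }

    pot = datasets.pot_yield_table()
    pot_table, _ = indices.index_table(pot)
    pot_mismatches = []
    for printed, calc, tol in (("RDY", "RDY_calc", 0.01), ("RT", "RT_calc", 1.0)):
        dev = (pot_table[printed] - pot_table[calc]).abs()
        for idx in dev.index[dev > tol + 1e-9]:
            pot_mismatches.append(
                {
                    "table": "pot",
                    "genotype": pot_table.loc[idx, "genotype"],
                    "column": printed,
                    "printed": float(pot_table.loc[idx, printed]),
                    "recomputed": float(pot_table.loc[idx, calc]),
                }
            )
    pot_counts = indices.compare_to_checks(
        pot_table, datasets.RP_ID, datasets.DP_ID, indices=("RDY", "RT")
    )
    nil_rdy = pot_table.loc[pot_table["role"] == "NIL", "RDY_calc"]
    dp_rdy = float(pot_table.loc[pot_table["role"] == "DP", "RDY_calc"].iloc[0])
    report["pot"] = {
        "nil_mean_rdy": float(nil_rdy.mean()),
        "n_rdy_better_than_rp": int(
            (nil_rdy < pot_table.loc[pot_table["role"] == "RP", "RDY_calc"].iloc[0]).sum()
        ),
        "n_rdy_above_dp": int((nil_rdy > dp_rdy).sum()),
        "counts": pot_counts.to_dict("records"),
        "mismatches": pot_mismatches,
    }
    return report
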