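"""Pipeline orchestration: simulate -> quantify -> voxelwise -> overlap -> associate.

Each stage reads its inputs from the run directory and persists its outputs
there, so stages are individually re-runnable from intermediates.
:func:`run_pipeline` chains all stages and writes ``report.json`` with the
headline numbers (occupancy per category and age, Dice coefficients,
percent changes, standardized differences, correlations and regressions).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .association import (
    anova_tukey,
    fit_regression,
    pearson,
    standardized_difference_series,
)
from .config import PipelineConfig, config_hash
from .core import ImageVolume, RegionAtlas, load_atlas, load_volume, save_atlas, save_volume
from .overlap import (
    CategoryMap,
    combine_categories,
    dice_binary,
    dice_continuous,
    occupancy,
    transition_flows,
)
from .phantom import build_atlas, simulate_cohort, write_cohort
from .quantify import percent_change, summarize_groups, suvr_table
from .voxelstats import BinaryMap, TScoreMap, fdr_binarize, smooth_volume, voxelwise_ttest

__all__ = [
    "run_pipeline",
    "stage_simulate",
    "stage_quantify",
    "stage_voxelwise",
    "stage_overlap",
    "stage_associate",
    "load_run_atlas",
]

log = logging.getLogger(__name__)

BIOMARKER_MEASURES = ("sTREM2", "total_Abeta", "IL_1b", "IL_6", "KC_GRO")
IMAGING_MEASURES = ("suvr_tspo", "suvr_amyloid")


def _setup_run_logging(outdir: Path) -> None:
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logging.getLogger("dualpet").addHandler(handler)


def load_run_atlas(outdir: str | Path) -> RegionAtlas:
    outdir = Path(outdir)
    return load_atlas(outdir / "atlas.nii.gz", outdir / "atlas_regions.json")


def stage_simulate(config: PipelineConfig, outdir: str | Path):
    """Build the atlas and simulate + persist the phantom cohort."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    atlas = build_atlas(config.grid)
    save_atlas(atlas, outdir / "atlas.nii.gz", outdir / "atlas_regions.json")
    design = replace(config.design, seed=config.seed)
    cohort = simulate_cohort(design, config.params, atlas)
    write_cohort(cohort, outdir)
    log.info("simulated %d images, %d biomarker rows", len(cohort.manifest), len(cohort.biomarkers))
    return atlas, cohort


def _image_loader(outdir: Path):
    def get_image(row: pd.Series) -> ImageVolume:
        return load_volume(outdir / row["path"])

    return get_image


def stage_quantify(outdir: str | Path, target_voi: str = "target_forebrain") -> pd.DataFrame:
    """SUVR endpoints per subject x tracer plus group summaries."""
    outdir = Path(outdir)
    atlas = load_run_atlas(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    table = suvr_table(manifest, atlas, _image_loader(outdir), target_voi=target_voi)
    table.to_csv(outdir / "suvr_table.csv", index=False)

    summaries = []
    for tracer in sorted(table["tracer"].unique()):
        sub = table[table["tracer"] == tracer].rename(columns={"suvr": f"suvr_{tracer}"})
        s = summarize_groups(sub, f"suvr_{tracer}")
        summaries.append(s)
    biomarkers = pd.read_csv(outdir / "biomarkers.csv")
    for m in BIOMARKER_MEASURES:
        if m in biomarkers.columns:
            summaries.append(summarize_groups(biomarkers, m))
    pd.concat(summaries, ignore_index=True).to_csv(outdir / "group_summaries.csv", index=False)
    return table


def stage_voxelwise(
    outdir: str | Path, q: float = 0.05, fwhm_mm: float = 0.0
) -> list[dict]:
    """TG-vs-WT t-maps and FDR-binarized maps per tracer and age."""
    outdir = Path(outdir)
    atlas = load_run_atlas(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    loader = _image_loader(outdir)
    stats_dir = outdir / "stats"
    stats_dir.mkdir(exist_ok=True)

    sidecars = []
    for tracer in sorted(manifest["tracer"].unique()):
        for age in sorted(manifest["age_months"].unique()):
            sel = manifest[(manifest["tracer"] == tracer) & (manifest["age_months"] == age)]
            groups = {}
            for genotype in ("TG", "WT"):
                imgs = [loader(r) for _, r in sel[sel["genotype"] == genotype].iterrows()]
                if fwhm_mm > 0:
                    imgs = [smooth_volume(im, fwhm_mm) for im in imgs]
                groups[genotype] = imgs
            tmap = voxelwise_ttest(
                groups["TG"], groups["WT"], atlas.brain_mask, tracer=tracer, age_months=age
            )
            bmap = fdr_binarize(tmap, q)
            tag = f"{tracer}_{age:04.1f}m"
            # NaN outside the brain mask is the map's missing-value convention,
            # so write it directly rather than through ImageVolume.
            nib.save(
                nib.Nifti1Image(tmap.t.astype(np.float32), atlas.grid.affine),
                str(stats_dir / f"tmap_{tag}.nii.gz"),
            )
            nib.save(
                nib.Nifti1Image(bmap.elevated.astype(np.uint8), atlas.grid.affine),
                str(stats_dir / f"binmap_{tag}.nii.gz"),
            )
            sidecar = {
                "tracer": tracer,
                "age_months": float(age),
                "df": tmap.df,
                "q": q,
                "fwhm_mm": fwhm_mm,
                "t_threshold": bmap.t_threshold if np.isfinite(bmap.t_threshold) else None,
                "n_significant": bmap.n_significant,
                "n_degenerate": tmap.n_degenerate,
            }
            (stats_dir / f"stats_{tag}.json").write_text(json.dumps(sidecar, indent=2))
            sidecars.append(sidecar)
            log.info(
                "%s %.1f m: %d significant voxels (t >= %s)",
                tracer, age, bmap.n_significant, f"{bmap.t_threshold:.2f}",
            )
    return sidecars


def _load_stat_maps(outdir: Path, tracer: str, age: float) -> tuple[TScoreMap, BinaryMap]:
    atlas = load_run_atlas(outdir)
    tag = f"{tracer}_{age:04.1f}m"
    stats_dir = outdir / "stats"
    sidecar = json.loads((stats_dir / f"stats_{tag}.json").read_text())
    t = np.asarray(nib.load(str(stats_dir / f"tmap_{tag}.nii.gz")).dataobj, dtype=float)
    elevated = np.asarray(nib.load(str(stats_dir / f"binmap_{tag}.nii.gz")).dataobj).astype(bool)
    mask = atlas.brain_mask
    from scipy import stats as sps

    p = np.full(mask.shape, np.nan)
    p[mask] = sps.t.sf(t[mask], sidecar["df"])
    tmap = TScoreMap(
        t=t, p_one_sided=p, df=sidecar["df"], mask=mask, tracer=tracer, age_months=age
    )
    thr = sidecar["t_threshold"]
    bmap = BinaryMap(
        elevated=elevated,
        t_threshold=float("inf") if thr is None else float(thr),
        q=sidecar["q"],
        n_significant=sidecar["n_significant"],
        mask=mask,
        tracer=tracer,
        age_months=age,
    )
    return tmap, bmap


def stage_overlap(outdir: str | Path) -> dict:
    """Category maps, %-occupancy, Dice coefficients and inter-age flows."""
    outdir = Path(outdir)
    atlas = load_run_atlas(outdir)
    manifest = pd.read_csv(outdir / "manifest.csv")
    ages = sorted(manifest["age_months"].unique())
    mask = atlas.brain_mask

    occ_rows, dice_rows, cats = [], [], {}
    for age in ages:
        t_tspo, b_tspo = _load_stat_maps(outdir, "tspo", age)
        t_amy, b_amy = _load_stat_maps(outdir, "amyloid", age)
        cat = combine_categories(b_tspo, b_amy, mask, age_months=age)
        cats[age] = cat
        nib.save(
            nib.Nifti1Image(cat.codes.astype(np.uint8), atlas.grid.affine),
            str(outdir / "stats" / f"categories_{age:04.1f}m.nii.gz"),
        )
        _save_category_slice_png(cat, outdir / "stats" / f"categories_{age:04.1f}m.png")
        occ = occupancy(cat)
        occ_rows.append(
            {
                "age_months": age,
                "neither_pct": occ.percent[0],
                "tspo_only_pct": occ.percent[1],
                "amyloid_only_pct": occ.percent[2],
                "both_pct": occ.percent[3],
                "tspo_total_pct": occ.tspo_total,
                "amyloid_total_pct": occ.amyloid_total,
            }
        )
        dice_rows.append(
            {
                "age_months": age,
                "dice_binary": dice_binary(b_tspo, b_amy),
                "dice_continuous": dice_continuous(t_tspo, t_amy, mask),
            }
        )

    flow_rows = []
    for a_from, a_to in zip(ages, ages[1:]):
        flow = transition_flows(cats[a_from], cats[a_to], mask)
        for tracer, vals in flow.per_tracer.items():
            flow_rows.append({"age_from": a_from, "age_to": a_to, "tracer": tracer, **vals})

    occ_df = pd.DataFrame(occ_rows)
    dice_df = pd.DataFrame(dice_rows)
    flows_df = pd.DataFrame(flow_rows)
    occ_df.to_csv(outdir / "occupancy.csv", index=False)
    dice_df.to_csv(outdir / "dice.csv", index=False)
    flows_df.to_csv(outdir / "transitions.csv", index=False)
    return {"occupancy": occ_df, "dice": dice_df, "transitions": flows_df}


def _save_category_slice_png(cat: CategoryMap, path: Path) -> None:
    # Simple mid-sagittal slice rendering of the 4-category overlap code.
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    sl = cat.codes[cat.codes.shape[0] // 2, :, :].T
    fig, ax = plt.subplots(figsize=(4, 3))
    cmap = ListedColormap(["black", "green", "red", "blue"])
    ax.imshow(sl, origin="lower", cmap=cmap, vmin=0, vmax=3, interpolation="nearest")
    ax.set_title(f"overlap categories, {cat.age_months} m")
    ax.axis("off")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def stage_associate(outdir: str | Path) -> dict:
    """Biomarker associations: correlations, regressions, ANOVA, timelines."""
    outdir = Path(outdir)
    suvr = pd.read_csv(outdir / "suvr_table.csv")
    biomarkers = pd.read_csv(outdir / "biomarkers.csv")

    wide = suvr.pivot_table(
        index=["subject_id", "genotype", "age_months"], columns="tracer", values="suvr"
    ).reset_index()
    wide = wide.rename(columns={"tspo": "suvr_tspo", "amyloid": "suvr_amyloid"})
    merged = wide.merge(
        biomarkers.drop(columns=["genotype", "age_months"]), on="subject_id", how="inner"
    )

    assoc_rows = []
    for genotype in ("TG", "WT"):
        sub = merged[merged["genotype"] == genotype]
        for x, y in [
            ("suvr_tspo", "sTREM2"),
            ("suvr_amyloid", "sTREM2"),
            ("total_Abeta", "sTREM2"),
        ]:
            r, p = pearson(sub[x], sub[y])
            assoc_rows.append(
                {
                    "kind": "pearson", "genotype": genotype, "outcome": y,
                    "predictors": x, "estimate": r, "p": p, "n": len(sub),
                    "r_squared": r**2, "adj_r_squared": np.nan,
                    "f_statistic": np.nan, "df_model": np.nan, "df_resid": np.nan,
                }
            )

    tg = merged[merged["genotype"] == "TG"]
    regressions = {}
    for predictor in ("suvr_tspo", "suvr_amyloid"):
        res = fit_regression(tg, "sTREM2", [predictor, "age_months"])
        regressions[predictor] = res
        assoc_rows.append(
            {
                "kind": "regression", "genotype": "TG", "outcome": "sTREM2",
                "predictors": "+".join(res.predictors), "estimate": res.beta[predictor],
                "p": res.p_values[predictor], "n": res.df_resid + res.df_model + 1,
                "r_squared": res.r_squared, "adj_r_squared": res.adj_r_squared,
                "f_statistic": res.f_statistic, "df_model": res.df_model,
                "df_resid": res.df_resid,
            }
        )
    pd.DataFrame(assoc_rows).to_csv(outdir / "associations.csv", index=False)

    # One-way ANOVA across TG age groups with Tukey post-hoc, per measure.
    anova_rows = []
    for measure in (*IMAGING_MEASURES, *BIOMARKER_MEASURES):
        if measure not in merged.columns:
            continue
        res = anova_tukey(tg[measure].to_numpy(), tg["age_months"].to_numpy())
        anova_rows.append(
            {
                "measure": measure, "type": "omnibus", "f": res.f, "p": res.p,
                "df_between": res.df_between, "df_within": res.df_within,
                "group_a": "", "group_b": "", "p_adj": np.nan,
            }
        )
        for _, pw in res.pairwise.iterrows():
            anova_rows.append(
                {
                    "measure": measure, "type": "tukey", "f": np.nan, "p": np.nan,
                    "df_between": np.nan, "df_within": np.nan,
                    "group_a": pw.group_a, "group_b": pw.group_b, "p_adj": pw.p_adj,
                }
            )
    pd.DataFrame(anova_rows).to_csv(outdir / "anova.csv", index=False)

    # Standardized-difference timelines against linearly-aging WT anchors.
    # For the total-Abeta assay the two youngest TG groups share a pooled SD:
    # the pre-onset group's degenerately small spread would otherwise distort
    # the standardized difference.
    summaries = pd.read_csv(outdir / "group_summaries.csv")
    std_rows = []
    for measure in (*IMAGING_MEASURES, "sTREM2", "total_Abeta"):
        per = summaries[summaries["measure"] == measure]
        tg_sum = per[per["genotype"] == "TG"][["age_months", "mean", "sd", "n"]]
        wt_sum = per[per["genotype"] == "WT"].sort_values("age_months")
        if tg_sum.empty or len(wt_sum) < 2:
            continue
        anchors = (
            (float(wt_sum.iloc[0]["age_months"]), float(wt_sum.iloc[0]["mean"])),
            (float(wt_sum.iloc[-1]["age_months"]), float(wt_sum.iloc[-1]["mean"])),
        )
        pool = None
        if measure == "total_Abeta":
            tg_ages = sorted(tg_sum["age_months"])
            if len(tg_ages) >= 2:
                pool = (tg_ages[0], tg_ages[1])
        series = standardized_difference_series(tg_sum, anchors, measure=measure, pool_ages=pool)
        for _, row in series.table.iterrows():
            std_rows.append({"measure": measure, **row.to_dict()})
    std_df = pd.DataFrame(std_rows)
    std_df.to_csv(outdir / "std_differences.csv", index=False)

    return {
        "associations": pd.DataFrame(assoc_rows),
        "anova": pd.DataFrame(anova_rows),
        "std_differences": std_df,
        "regressions": regressions,
        "merged": merged,
    }


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Run every stage and write ``report.json`` in the run directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_run_logging(outdir)
    config.to_yaml(outdir / "config_resolved.yaml")

    try:
        stage = "simulate"
        stage_simulate(config, outdir)
        stage = "quantify"
        stage_quantify(outdir, target_voi=config.target_voi)
        stage = "voxelwise"
        sidecars = stage_voxelwise(outdir, q=config.q, fwhm_mm=config.fwhm_mm)
        stage = "overlap"
        overlap_res = stage_overlap(outdir)
        stage = "associate"
        assoc_res = stage_associate(outdir)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    report = _build_report(config, outdir, sidecars, overlap_res, assoc_res)
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    return outdir


def _build_report(config, outdir: Path, sidecars, overlap_res, assoc_res) -> dict:
    occ = overlap_res["occupancy"].set_index("age_months")
    dice = overlap_res["dice"].set_index("age_months")
    summaries = pd.read_csv(outdir / "group_summaries.csv")

    pct_changes = {}
    ages = sorted(occ.index)
    for measure in (*IMAGING_MEASURES, *BIOMARKER_MEASURES):
        per = summaries[(summaries["measure"] == measure) & (summaries["genotype"] == "TG")]
        if per.empty:
            continue
        per = per.set_index("age_months")["mean"]
        base_age = min(per.index)
        pct_changes[measure] = {
            f"{base_age:g}_vs_{a:g}m": percent_change(float(per[a]), float(per[base_age]))
            for a in per.index
            if a != base_age
        }

    std = assoc_res["std_differences"]
    std_out = {
        m: {f"{row.age_months:g}m": row.d for _, row in std[std["measure"] == m].iterrows()}
        for m in std["measure"].unique()
    }

    correlations = {}
    for _, row in assoc_res["associations"].iterrows():
        if row["kind"] == "pearson":
            key = f"{row.genotype}:{row.outcome}~{row.predictors}"
            correlations[key] = {"R": row.estimate, "p": row.p, "n": int(row.n)}

    regressions = {}
    for predictor, res in assoc_res["regressions"].items():
        regressions[f"sTREM2~{predictor}+age"] = {
            "beta": res.beta,
            "p": res.p_values,
            "r_squared": res.r_squared,
            "adj_r_squared": res.adj_r_squared,
            "f_statistic": res.f_statistic,
            "df": [res.df_model, res.df_resid],
        }

    return {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config_hash": config_hash(config),
        "n_per_group": config.design.n_per_group,
        "ages_months": list(ages),
        "q_fdr": config.q,
        "occupancy_pct": {f"{a:g}m": occ.loc[a].to_dict() for a in occ.index},
        "dice": {f"{a:g}m": dice.loc[a].to_dict() for a in dice.index},
        "transitions": overlap_res["transitions"].to_dict(orient="records"),
        "voxelwise": sidecars,
        "percent_change_tg": pct_changes,
        "standardized_differences": std_out,
        "correlations": correlations,
        "regressions": regressions,
    }
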