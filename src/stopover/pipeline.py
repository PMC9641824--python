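"""End-to-end orchestration: simulate -> segment -> prep -> community ->
differential abundance -> associations, with a reproducibility manifest.

Stages communicate through plain-text files in the run directory so each can
be re-run and inspected independently; outputs are byte-reproducible for a
fixed configuration (the manifest records seeds and a config hash, never
wall-clock state).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import community_metrics as metrics
from . import diff_abundance as da
from . import movement
from . import synthetic_data as synth
from .community_prep import AsvTable, PrepConfig, prep_ladder
from .morphometrics import smi_by_sex

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "simulate": {
        "n_females": 36,
        "n_males": 18,
        "condition_date_slope": -3.0,
        "n_tracks": 12,
        "track": {
            "n_migratory_days": 8,
            "daily_step_km": 150.0,
            "fix_interval_min": 30.0,
            "endpoint_mix": {"arrival": 0.56, "death": 0.32, "loss": 0.12},
        },
        "community": {
            "n_taxa": 150,
            "dispersion": 50.0,
            "depth_range": [14523, 76393],
            "n_controls": 3,
            "n_contaminants": 5,
            "n_offenders": 4,
            "sex_lfc": 2.0,
            "n_sex_taxa": 5,
            "date_evenness_slope": -0.03,
            "condition_taxon_slope": -1.0,
        },
    },
    "segmentation": {
        "migratory_total_km": 40.0,
        "migratory_beeline_km": 19.0,
        "arrival_longdist_km": 50.0,
        "arrival_turn_deg": 100.0,
        "subsample_interval_min": 60.0,
        "arrival_lookahead_days": 5,
        "death_acc_epsilon": 0.01,
        "death_window_h": 24.0,
        "death_displacement_km": 0.5,
    },
    "prep": {"decontam_threshold": 0.5, "min_depth": 10000, "rarefaction_seed": 999},
    "metrics": {"n_permutations": 999, "metrics": ["unifrac", "wunifrac", "jaccard", "bray"]},
    "da": {"rank": "Genus", "prevalence_min": 0.10, "q_threshold": 0.01, "w_percentile": 0.85},
    "analyses": {"h1_sex": True, "h2_date": True, "h3_condition_survival": True},
    "stratify_by_sex": True,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending path."""


def _merge(default, override, path=""):
    if not isinstance(override, dict):
        return override
    out = dict(default)
    for key, val in override.items():
        if key not in default:
            raise ValueError(f"unknown config key {path + key!r}")
        if isinstance(default[key], dict):
            out[key] = _merge(default[key], val, path + key + ".")
        else:
            out[key] = val
    return out


def validate_config(source) -> dict:
    """Load and schema-check a run configuration (path, mapping, or None).

    Unknown keys and out-of-range thresholds raise ``ValueError``; defaults
    are filled in and echoed back.
    """
    if source is None:
        raw: dict = {}
    elif isinstance(source, dict):
        raw = source
    else:
        raw = yaml.safe_load(Path(source).read_text()) or {}
    cfg = _merge(DEFAULT_CONFIG, raw)
    seg = cfg["segmentation"]
    for key, val in seg.items():
        if val <= 0:
            raise ValueError(f"segmentation.{key} must be > 0")
    if not 0 < cfg["prep"]["decontam_threshold"] < 1:
        raise ValueError("prep.decontam_threshold must lie in (0, 1)")
    if cfg["prep"]["min_depth"] <= 0:
        raise ValueError("prep.min_depth must be > 0")
    for key in ("prevalence_min", "q_threshold", "w_percentile"):
        if not 0 < cfg["da"][key] < 1:
            raise ValueError(f"da.{key} must lie in (0, 1)")
    if cfg["simulate"]["n_tracks"] > cfg["simulate"]["n_females"] + cfg["simulate"]["n_males"]:
        raise ValueError("simulate.n_tracks exceeds the number of individuals")
    return cfg


def dump_config(cfg: dict) -> str:
    return yaml.safe_dump(cfg, sort_keys=True)


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]


def _seg_config(cfg: dict) -> movement.SegmentationConfig:
    return movement.SegmentationConfig(**cfg["segmentation"])


def _endpoint_plan(mix: dict, n: int) -> list[str]:
    counts = {k: int(round(v * n)) for k, v in mix.items()}
    while sum(counts.values()) < n:
        counts["arrival"] = counts.get("arrival", 0) + 1
    order = []
    for k in ("arrival", "death", "loss"):
        order += [k] * counts.get(k, 0)
    return order[:n]


def stage_simulate(cfg: dict, outdir: Path) -> dict:
    seed = int(cfg["seed"])
    sim = cfg["simulate"]
    meta = synth.simulate_metadata(
        sim["n_females"], sim["n_males"], seed=seed + 1,
        condition_date_slope=sim["condition_date_slope"],
    )
    meta = smi_by_sex(meta)
    trk = sim["track"]
    plan = _endpoint_plan(trk["endpoint_mix"], sim["n_tracks"])
    all_fixes = []
    for i, endpoint in enumerate(plan):
        scn = synth.TrackScenario(
            seed=seed * 1000 + i,
            n_migratory_days=trk["n_migratory_days"],
            daily_step_km=trk["daily_step_km"],
            fix_interval_min=trk["fix_interval_min"],
            endpoint=endpoint,
        )
        fixes, _ = synth.simulate_track(scn)
        fixes["individual_id"] = meta["id"].iloc[i]
        all_fixes.append(fixes)
    fixes = pd.concat(all_fixes, ignore_index=True)
    com = sim["community"]
    taxa = [f"ASV{i + 1:04d}" for i in range(com["n_taxa"])]
    rng = np.random.default_rng(seed + 7)
    sex_taxa = {t: com["sex_lfc"] for t in rng.choice(taxa[: com["n_taxa"] - com["n_contaminants"]],
                                                      size=com["n_sex_taxa"], replace=False)}
    scn = synth.CommunityScenario(
        seed=seed + 2,
        n_samples=len(meta),
        n_taxa=com["n_taxa"],
        dispersion=com["dispersion"],
        depth_range=tuple(com["depth_range"]),
        n_controls=com["n_controls"],
        n_contaminants=com["n_contaminants"],
        n_offenders=com["n_offenders"],
        sex_effect_taxa=sex_taxa,
        date_evenness_slope=com["date_evenness_slope"],
        condition_taxon=taxa[0],
        condition_taxon_slope=com["condition_taxon_slope"],
    )
    table, taxonomy, newick, truth = synth.simulate_community(scn, meta)
    synth.write_dataset(outdir / "data", fixes=fixes, metadata=meta, table=table,
                        newick=newick, truth=truth)
    return {"n_individuals": len(meta), "n_tracks": len(plan), "n_fixes": len(fixes),
            "n_samples": table.counts.shape[0], "n_taxa": table.counts.shape[1]}


def stage_segment(cfg: dict, outdir: Path) -> dict:
    seg_cfg = _seg_config(cfg)
    fixes = movement.read_fixes(outdir / "data" / "gps_fixes.csv")
    seg_rows, summary_rows = [], []
    for ind, track in fixes.groupby("individual_id", sort=True):
        segments = movement.segment_track(track, seg_cfg)
        outcome = movement.detect_endpoint(segments, track, seg_cfg)
        capture = (float(track["lat"].iloc[0]), float(track["lon"].iloc[0]))
        summary = movement.migration_summary(segments, outcome, capture)
        seg = segments.copy()
        seg.insert(0, "individual_id", ind)
        seg_rows.append(seg)
        summary_rows.append(
            {
                "individual_id": ind,
                "endpoint": outcome.endpoint,
                "endpoint_date": outcome.endpoint_date,
                "survived": outcome.endpoint == "arrival",
                **dataclasses.asdict(summary),
            }
        )
    pd.concat(seg_rows, ignore_index=True).to_csv(outdir / "segments.tsv", sep="\t", index=False)
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "track_summary.tsv", sep="\t", index=False)
    return {"n_tracks": len(summary_rows), "n_days": sum(len(s) for s in seg_rows)}


def _read_asv(outdir: Path) -> tuple[AsvTable, str]:
    data = outdir / "data"
    counts = pd.read_csv(data / "asv_table.tsv", sep="\t", index_col=0)
    taxonomy = pd.read_csv(data / "taxonomy.tsv", sep="\t", index_col=0).fillna("")
    controls = pd.read_csv(data / "controls.tsv", sep="\t", index_col=0)["is_control"]
    newick = (data / "tree.nwk").read_text().strip()
    return AsvTable(counts, taxonomy, controls.astype(bool)), newick


def stage_prep(cfg: dict, outdir: Path) -> dict:
    table, _ = _read_asv(outdir)
    prep_cfg = PrepConfig(**cfg["prep"])
    rare, log = prep_ladder(table, prep_cfg)
    rare.counts.to_csv(outdir / "rarefied_table.tsv", sep="\t")
    (outdir / "prep_log.json").write_text(json.dumps(log, sort_keys=True, indent=1) + "\n")
    return log


def stage_community(cfg: dict, outdir: Path) -> dict:
    seed = int(cfg["seed"])
    nperm = int(cfg["metrics"]["n_permutations"])
    rare = pd.read_csv(outdir / "rarefied_table.tsv", sep="\t", index_col=0)
    _, newick = _read_asv(outdir)
    meta = pd.read_csv(outdir / "data" / "metadata.csv").set_index("sample_id")
    meta = meta.loc[[s for s in rare.index if s in meta.index]]
    rare = rare.loc[meta.index]
    alpha = metrics.alpha_table(rare, newick)
    alpha["shannon_log10"] = metrics.transform_alpha(alpha["shannon"], "shannon")
    alpha["faith_pd_inv"] = metrics.transform_alpha(alpha["faith_pd"], "faith_pd")
    alpha.to_csv(outdir / "alpha.tsv", sep="\t")
    perm_rows, disp_rows = [], []
    for i, metric in enumerate(cfg["metrics"]["metrics"]):
        dist = metrics.beta_distance(rare, metric, tree=newick)
        pd.DataFrame(dist.data, index=dist.ids, columns=dist.ids).to_csv(
            outdir / f"dist_{metric}.tsv", sep="\t"
        )
        if cfg["analyses"]["h1_sex"]:
            res = metrics.permanova(
                dist, meta.reset_index(), ["sex", "age_class"],
                n_perm=nperm, mode="margin", seed=seed + 10 + i,
            )
            res.insert(0, "metric", metric)
            res.insert(1, "analysis", "sex_age")
            perm_rows.append(res)
            disp = metrics.dispersion_test(dist, meta["sex"], n_perm=nperm, seed=seed + 30 + i)
            disp_rows.append({"metric": metric, "analysis": "sex", "F": disp["F"], "p": disp["p"]})
        fem = meta["sex"] == "female"
        if cfg["stratify_by_sex"] and fem.sum() >= 5:
            dist_f = dist.filter([s for s, f in zip(meta.index, fem) if f])
            meta_f = meta.loc[fem]
            for term, flag in (("smi_g", "h3_condition_survival"), ("capture_date", "h2_date")):
                if not cfg["analyses"][flag]:
                    continue
                res = metrics.permanova(
                    dist_f, meta_f.reset_index(), [term],
                    n_perm=nperm, mode="margin", seed=seed + 50 + i,
                )
                res.insert(0, "metric", metric)
                res.insert(1, "analysis", f"female_{term}")
                perm_rows.append(res)
    pd.concat(perm_rows, ignore_index=True).to_csv(outdir / "permanova.tsv", sep="\t", index=False)
    pd.DataFrame(disp_rows).to_csv(outdir / "dispersion.tsv", sep="\t", index=False)
    return {"n_samples": len(rare), "n_metrics": len(cfg["metrics"]["metrics"])}


def stage_da(cfg: dict, outdir: Path) -> dict:
    rare = pd.read_csv(outdir / "rarefied_table.tsv", sep="\t", index_col=0)
    table, _ = _read_asv(outdir)
    taxonomy = table.taxonomy.loc[table.taxonomy.index.isin(rare.columns)]
    meta = pd.read_csv(outdir / "data" / "metadata.csv").set_index("sample_id").loc[rare.index]
    da_cfg = da.DaConfig(
        prevalence_min=cfg["da"]["prevalence_min"],
        q_threshold=cfg["da"]["q_threshold"],
        w_percentile=cfg["da"]["w_percentile"],
    )
    rank = cfg["da"]["rank"]
    rows = []
    if cfg["analyses"]["h1_sex"] and meta["sex"].nunique() == 2:
        res = da.differential_abundance(rare, taxonomy, meta["sex"], rank, da_cfg)
        res.insert(0, "analysis", "sex")
        rows.append(res)
    fem = meta["sex"] == "female"
    if cfg["stratify_by_sex"] and fem.sum() >= 8:
        for col, flag in (("capture_date", "h2_date"), ("smi_g", "h3_condition_survival")):
            if not cfg["analyses"][flag]:
                continue
            res = da.differential_abundance(
                rare.loc[fem], taxonomy, meta.loc[fem, col], rank, da_cfg
            )
            res.insert(0, "analysis", f"female_{col}")
            rows.append(res)
    out = pd.concat(rows).reset_index()
    out.to_csv(outdir / "differential_abundance.tsv", sep="\t", index=False)
    return {"n_results": len(out), "n_selected": int(out["selected"].sum())}


def stage_associate(cfg: dict, outdir: Path) -> dict:
    meta = pd.read_csv(outdir / "data" / "metadata.csv")
    summary = pd.read_csv(outdir / "track_summary.tsv", sep="\t")
    merged = meta.merge(summary, left_on="id", right_on="individual_id", how="left")
    alpha = pd.read_csv(outdir / "alpha.tsv", sep="\t", index_col=0)
    tests: list[assoc.TestResult] = []
    # demographic family: condition by age per sex, capture date by sex/age, survival
    for sex, grp in merged.groupby("sex"):
        juv = grp.loc[grp["age_class"] == "juvenile", "smi_g"]
        adu = grp.loc[grp["age_class"] == "adult", "smi_g"]
        if len(juv) >= 2 and len(adu) >= 2:
            tests.append(assoc.welch_t(juv, adu, name=f"smi_juv_vs_adult_{sex}"))
        surv = grp.dropna(subset=["survived"])
        a = surv.loc[surv["survived"] == True, "smi_g"]  # noqa: E712
        b = surv.loc[surv["survived"] == False, "smi_g"]  # noqa: E712
        if len(a) >= 2 and len(b) >= 2:
            tests.append(assoc.welch_t(a, b, name=f"smi_surv_vs_dead_{sex}"))
    srh = assoc.scheirer_ray_hare(merged, "capture_date", "sex", "age_class")
    for term, res in srh.items():
        tests.append(dataclasses.replace(res, name=f"capture_date_srh_{term}"))
    resolved = merged.dropna(subset=["endpoint"])
    resolved = resolved[resolved["endpoint"].isin(["arrival", "death"])]
    if len(resolved) >= 4 and resolved["sex"].nunique() == 2:
        tab = pd.crosstab(resolved["sex"], resolved["survived"])
        if tab.shape == (2, 2) and (tab.sum(0) > 0).all() and (tab.sum(1) > 0).all():
            tests.append(assoc.chi_square_2x2(tab.to_numpy(), name="survival_by_sex"))
    tests = assoc.adjust_family(tests, family="demographic")
    # migration correlations
    surv = merged[merged["endpoint"] == "arrival"]
    if len(surv) >= 3:
        tests.append(assoc.pearson_cor(surv["capture_date"], surv["post_eilat_distance_km"],
                                       name="date_vs_posteilat"))
    # model sets: capture date ~ condition / age, per sex
    model_rows = []
    formulas = [
        "capture_date ~ 1",
        "capture_date ~ smi_g",
        "capture_date ~ smi_g + age_class",
        "capture_date ~ smi_g * age_class",
    ]
    for sex, grp in merged.groupby("sex"):
        if len(grp) >= 8 and grp["age_class"].nunique() == 2:
            ms = assoc.fit_model_set(grp, "capture_date", formulas)
            ms.insert(0, "analysis", f"capture_date_models_{sex}")
            model_rows.append(ms)
    # alpha-diversity associations (females)
    fem = merged[merged["sex"] == "female"].set_index("sample_id")
    common = [s for s in fem.index if s in alpha.index]
    if len(common) >= 5:
        al = alpha.loc[common]
        fm = fem.loc[common]
        tests.append(assoc.alpha_association(al["shannon_log10"], fm["smi_g"],
                                             name="shannon_vs_smi_female"))
        tests.append(assoc.alpha_association(al["shannon_log10"], fm["capture_date"],
                                             name="shannon_vs_date_female"))
        survf = fm.dropna(subset=["survived"])
        if survf["survived"].nunique() == 2 and survf["survived"].value_counts().min() >= 2:
            tests.append(assoc.alpha_association(
                al.loc[survf.index, "shannon_log10"], survf["survived"].map({True: "alive", False: "dead"}),
                kind="welch", name="shannon_vs_survival_female"))
    rows = [
        {
            "name": t.name,
            "statistic": t.statistic,
            "df": t.df,
            "p": t.p,
            "p_adj": t.p_adj,
            "direction": t.direction,
            "extra": json.dumps(t.extra, sort_keys=True, default=str),
        }
        for t in tests
    ]
    pd.DataFrame(rows).to_csv(outdir / "associations.tsv", sep="\t", index=False)
    if model_rows:
        pd.concat(model_rows, ignore_index=True).to_csv(
            outdir / "model_selection.tsv", sep="\t", index=False
        )
    return {"n_tests": len(rows), "n_model_sets": len(model_rows)}


STAGES = [
    ("simulate", stage_simulate),
    ("segment", stage_segment),
    ("prep", stage_prep),
    ("community", stage_community),
    ("da", stage_da),
    ("associate", stage_associate),
]


def run_pipeline(config, outdir) -> dict:
    """Execute all stages in order; returns (and writes) the run manifest."""
    cfg = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": config_hash(cfg), "seed": cfg["seed"], "stages": {}}
    for name, fn in STAGES:
        t0 = time.monotonic()
        try:
            manifest["stages"][name] = fn(cfg, outdir)
        except Exception as exc:  # noqa: BLE001
            raise StageError(f"stage {name!r} failed in {outdir}: {exc}") from exc
        print(f"[stopover] stage {name}: {time.monotonic() - t0:.1f}s", file=sys.stderr)
    (outdir / "config.yaml").write_text(dump_config(cfg))
    (outdir / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1) + "\n")
    return manifest
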