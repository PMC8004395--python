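"""End-to-end pipeline orchestration.

Runs the full synthetic-cohort analysis in dependency order: food database
and diaries -> energy screen -> food tree, UniFrac and diet PCoA -> diet
quality -> metagenome, subspecies calling and JSD PCoA -> co-inertia with
held-out prediction -> functional (CAZy / hydrogenase) analysis.  Every
output table is written under one results directory together with a manifest
of the parameters and seeds that produced it; the same config reproduces
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as dio
from .diet_quality import (
    filter_implausible_energy,
    fsanps_diet_index,
    load_default_grids,
    meal_quality_profile,
    score_food_db,
)
from .food_tree import (
    build_food_tree,
    diet_profiles,
    meat_plant_log2ratio,
    unifrac_matrix,
)
from .function_analysis import (
    aggregate_families,
    cazotype_enterotype_assoc,
    cazotype_partition,
    correlation_network,
    lda_scores,
)
from .msp_subspecies import (
    msp_core_abundance,
    subspecies_abundance,
    subspecies_partition_all,
)
from .ordination import (
    coinertia,
    jsd_distance,
    pc_regression,
    pcoa,
    pcoa_project,
    project_single_block,
)
from .synthetic_data import (
    gen_clinical,
    gen_diaries,
    gen_food_db,
    gen_function_profiles,
    gen_msp_metagenome,
)

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

log = logging.getLogger("dietmg")


@dataclass
class PipelineConfig:
    """All pipeline knobs with their literature defaults.

    Detection median 2, accessory quantile band 2.5-97.5%, silhouette floor
    0.25, correlation threshold |rho| = 0.4, 7 retained co-inertia axes,
    5 regression components and the 800-4500 kcal/day energy screen.
    """

    seed: int = 42
    n_subjects: int = 60
    n_items: int = 120
    n_nutrients: int = 8
    gradient_sd: float = 1.0
    subspecies_spec: list = field(default_factory=lambda: [[15, 15], [12, 12, 12], [15, 15], [12, 12]])
    subspecies_coupling: float = 1.0
    abundance_coupling: float = 0.5
    clinical_effects: dict = field(
        default_factory=lambda: {
            "severity_quality": 1.0,
            "gas_meat": 1.0,
            "gas_quality": 0.3,
        }
    )
    clinical_noise_sd: float = 0.5
    energy_kcal_min: float = 800.0
    energy_kcal_max: float = 4500.0
    detection_median: float = 2.0
    quantile_band: tuple = (2.5, 97.5)
    silhouette_floor: float = 0.25
    k_max: int = 4
    n_boot: int = 100
    rho_threshold: float = 0.4
    n_axes: int = 7
    reg_k: int = 5
    train_frac: float = 2 / 3
    stages: dict = field(
        default_factory=lambda: {"diet": True, "metagenome": True, "coupling": True, "functions": True}
    )

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = PipelineConfig(**raw)
        if isinstance(cfg.quantile_band, list):
            cfg.quantile_band = tuple(cfg.quantile_band)
        return cfg


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute all enabled stages and write their tables under ``outdir``.

    Returns a dict of in-memory results; raises a clear error when a stage's
    upstream dependency is disabled.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    res: dict = {}
    stages = config.stages
    seed = config.seed

    if stages.get("diet", True):
        t = time.time()
        food_db = gen_food_db(config.n_items, config.n_nutrients, seed=seed)
        diaries, truth = gen_diaries(
            food_db, config.n_subjects, config.gradient_sd, seed=seed + 1
        )
        diaries, energy_report = filter_implausible_energy(
            diaries, food_db, config.energy_kcal_min, config.energy_kcal_max
        )
        tree = build_food_tree(food_db, seed=seed + 2)
        profiles = diet_profiles(diaries, tree)
        diet_dm = unifrac_matrix(profiles, tree)
        diet_pcoa = pcoa(diet_dm)
        grids = load_default_grids()
        scored = score_food_db(food_db, grids)
        per_subject = []
        for subj, d in diaries.groupby("subject"):
            per_subject.append(
                {
                    "subject": subj,
                    "meat_plant_log2ratio": meat_plant_log2ratio(d, tree),
                    "fsanps_di": fsanps_diet_index(
                        d, scored["score"], food_db["energy_kcal"]
                    ),
                    "main_meal_quality_ratio": meal_quality_profile(
                        d, scored["class"]
                    )["ratio"],
                }
            )
        diet_vars = pd.DataFrame(per_subject).set_index("subject")
        res.update(
            food_db=food_db,
            diaries=diaries,
            truth=truth,
            tree=tree,
            diet_dm=diet_dm,
            diet_pcoa=diet_pcoa,
            diet_vars=diet_vars,
            energy_report=energy_report,
            item_scores=scored,
        )
        dio.write_table(food_db, out / "food_db.tsv")
        dio.write_table(diaries, out / "diaries.tsv", index=False)
        dio.write_table(diet_vars, out / "diet_variables.tsv")
        dio.write_distance(diet_dm, out / "diet_unifrac.tsv")
        dio.write_table(diet_pcoa.coords, out / "diet_pcoa.tsv")
        tree.write_newick(out / "food_tree.nwk")
        log.info("diet stage done in %.1fs", time.time() - t)

    if stages.get("metagenome", True):
        t = time.time()
        truth = res.get("truth")
        gene_counts, catalog, truth = gen_msp_metagenome(
            config.n_subjects,
            len(config.subspecies_spec),
            config.subspecies_spec,
            seed=seed + 3,
            truth=truth,
            subspecies_coupling=config.subspecies_coupling,
            abundance_coupling=config.abundance_coupling,
        )
        core_ab = msp_core_abundance(gene_counts, catalog)
        partitions = subspecies_partition_all(
            gene_counts,
            catalog,
            k_max=config.k_max,
            n_boot=config.n_boot,
            seed=seed + 4,
            silhouette_floor=config.silhouette_floor,
        )
        sub_ab = subspecies_abundance(partitions, core_ab)
        mgs_dm = jsd_distance(sub_ab.T)
        mgs_pcoa = pcoa(mgs_dm)
        clinical = gen_clinical(
            truth, config.clinical_effects, config.clinical_noise_sd, seed=seed + 5
        )
        part_rows = [
            {
                "msp": msp,
                "sample": s,
                "subspecies": int(lab),
                "k": part.k,
                "silhouette": part.silhouette.get(part.k, np.nan),
                "stability": part.stability.get(int(lab), np.nan),
            }
            for msp, part in partitions.items()
            for s, lab in part.labels.items()
        ]
        res.update(
            gene_counts=gene_counts,
            catalog=catalog,
            truth=truth,
            core_abundance=core_ab,
            partitions=partitions,
            subspecies_ab=sub_ab,
            mgs_dm=mgs_dm,
            mgs_pcoa=mgs_pcoa,
            clinical=clinical,
        )
        dio.write_gene_counts(gene_counts, out / "gene_counts.tsv")
        dio.write_catalog(catalog, out / "msp_catalog.tsv")
        dio.write_table(core_ab, out / "msp_abundance.tsv")
        dio.write_table(sub_ab, out / "subspecies_abundance.tsv")
        dio.write_table(pd.DataFrame(part_rows), out / "subspecies_partition.tsv", index=False)
        dio.write_distance(mgs_dm, out / "mgs_jsd.tsv")
        dio.write_table(clinical, out / "clinical.tsv")
        log.info("metagenome stage done in %.1fs", time.time() - t)

    if stages.get("coupling", True):
        if "diet_pcoa" not in res or "mgs_pcoa" not in res:
            raise RuntimeError(
                "coupling stage needs the diet and metagenome stages; enable them in the config"
            )
        t = time.time()
        subjects = list(res["diet_vars"].index)
        n_train = max(int(round(config.train_frac * len(subjects))), 3)
        train, test = subjects[:n_train], subjects[n_train:]
        diet_dm, mgs_dm = res["diet_dm"], res["mgs_dm"]
        diet_tr = pcoa(diet_dm.filter(train))
        mgs_tr = pcoa(mgs_dm.filter(train))
        model = coinertia(diet_tr.coords, mgs_tr.coords, n_axes=config.n_axes)
        clinical = res["clinical"]
        gas = np.log2(
            (clinical["h2_ppm"] + 1.0) / (clinical["ch4_ppm"] + 1.0)
        ).rename("log2_h2_ch4")
        targets = {
            "log2_h2_ch4": gas,
            "severity": clinical["severity_group"].astype(float),
            "meat_plant": res["diet_vars"]["meat_plant_log2ratio"],
        }
        k = min(config.reg_k, model.n_axes)
        preds = {}
        diet_d_test = pd.DataFrame(
            diet_dm.filter(subjects).data, index=subjects, columns=subjects
        ).loc[test, train]
        diet_test_coords = pcoa_project(diet_tr, diet_d_test)
        test_scores = project_single_block(model, diet_test_coords, "diet")
        for name, y in targets.items():
            reg = pc_regression(model.x_scores, y.loc[train], k=k, response=name)
            r, p = reg.score(test_scores, y)
            preds[name] = {"train_r": reg.train_r, "test_r": r, "test_p": p}
        pred_tbl = pd.DataFrame(preds).T
        res.update(coinertia=model, predictions=pred_tbl, gas_ratio=gas)
        dio.write_table(model.x_scores, out / "coinertia_diet_scores.tsv")
        dio.write_table(model.y_scores, out / "coinertia_mgs_scores.tsv")
        dio.write_table(pred_tbl, out / "predictions.tsv")
        (out / "coinertia_rv.txt").write_text(f"{model.rv:.6f}\n")
        log.info("coupling stage done (RV=%.3f) in %.1fs", model.rv, time.time() - t)

    if stages.get("functions", True):
        if "clinical" not in res:
            raise RuntimeError("functions stage needs the metagenome stage")
        t = time.time()
        clinical = res["clinical"]
        gas = res.get("gas_ratio")
        if gas is None:
            gas = np.log2((clinical["h2_ppm"] + 1.0) / (clinical["ch4_ppm"] + 1.0))
        z = (gas - gas.mean()) / gas.std()
        # planted CAZotypes follow the enterotypes with 75% fidelity, so the
        # recovered partition should associate with them
        rng_f = np.random.default_rng(seed + 8)
        ent = clinical["enterotype"]
        caz_truth = ent.where(
            rng_f.random(len(ent)) < 0.75,
            other=pd.Series(rng_f.integers(1, 4, size=len(ent)), index=ent.index),
        )
        fx = gen_function_profiles(
            len(clinical),
            seed=seed + 6,
            sample_ids=list(clinical.index),
            gas_latent=z,
            cazotype_labels=caz_truth,
        )
        cazy = aggregate_families(fx["gene_counts"], fx["cazy_map"], "CAZy")
        hyd = aggregate_families(fx["gene_counts"], fx["hydrogenase_map"], "hydrogenase")
        net = correlation_network(cazy, hyd, threshold=config.rho_threshold)
        cazotypes, fit = cazotype_partition(cazy, k_range=range(1, 5), seed=seed + 7)
        if cazotypes.nunique() >= 2 and ent.nunique() >= 2:
            chi2, df, p = cazotype_enterotype_assoc(cazotypes, ent)
        else:
            log.warning("cazotype or enterotype partition has one level; chi2 skipped")
            chi2, df, p = np.nan, 0, np.nan
        sev_labels = clinical["severity_group"].map(
            {1: "control", 4: "severe"}
        ).dropna()
        lda = lda_scores(hyd.loc[sev_labels.index], sev_labels)
        res.update(
            function_profiles=fx,
            cazy=cazy,
            hydrogenase=hyd,
            network=net,
            cazotypes=cazotypes,
            cazotype_fit=fit,
            cazotype_enterotype=(chi2, df, p),
            lda=lda,
        )
        dio.write_table(cazy, out / "cazy_families.tsv")
        dio.write_table(hyd, out / "hydrogenase_groups.tsv")
        net.write_edgelist(out / "function_network.tsv")
        dio.write_table(lda, out / "lda_scores.tsv", index=False)
        cazotypes.to_frame().to_csv(out / "cazotypes.tsv", sep="\t")
        log.info("functions stage done in %.1fs", time.time() - t)

    manifest = {
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "package": "dietmg",
        "stages_run": [s for s, on in stages.items() if on],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return res


def validate_inputs(paths: dict) -> dict:
    """Schema-check pipeline input files; returns {'failures': [...],
    'warnings': [...], 'counts': {...}} without raising."""
    failures, warns, counts = [], [], {}
    food_db = diaries = gene_counts = catalog = None
    if "food_db" in paths:
        try:
            food_db = dio.read_table(paths["food_db"])
            counts["food_items"] = len(food_db)
            for col in ("level2", "level3", "level4", "energy_kcal", "is_drink"):
                if col not in food_db.columns:
                    failures.append(f"food_db: missing column {col!r}")
        except Exception as e:  # noqa: BLE001
            failures.append(f"food_db: unreadable ({e})")
    if "diaries" in paths:
        try:
            diaries = pd.read_csv(paths["diaries"], sep="\t")
            counts["diary_rows"] = len(diaries)
            for col in ("subject", "day", "meal", "item", "grams"):
                if col not in diaries.columns:
                    failures.append(f"diaries: missing column {col!r}")
            if food_db is not None and "item" in diaries.columns:
                unknown = sorted(set(diaries["item"]) - set(food_db.index))
                if unknown:
                    failures.append(f"diaries: unknown food ids {unknown[:5]}")
            if "grams" in diaries.columns and (diaries["grams"] <= 0).any():
                failures.append("diaries: non-positive grams")
        except Exception as e:  # noqa: BLE001
            failures.append(f"diaries: unreadable ({e})")
    if "gene_counts" in paths:
        try:
            gene_counts = dio.read_gene_counts(paths["gene_counts"])
            counts["genes"], counts["samples"] = gene_counts.shape
            if (gene_counts.to_numpy() < 0).any():
                failures.append("gene_counts: negative values")
        except Exception as e:  # noqa: BLE001
            failures.append(f"gene_counts: unreadable ({e})")
    if "catalog" in paths:
        try:
            catalog = dio.read_catalog(paths["catalog"])
            counts["msps"] = len(catalog.msp_ids)
            if gene_counts is not None:
                all_genes = set(gene_counts.index)
                missing = [
                    g
                    for msp in catalog.msp_ids
                    for g in catalog.core(msp) + catalog.accessory(msp)
                    if g not in all_genes
                ]
                if missing:
                    warns.append(
                        f"catalog: {len(missing)} genes absent from the count matrix"
                    )
        except Exception as e:  # noqa: BLE001
            failures.append(f"catalog: unreadable ({e})")
    return {"failures": failures, "warnings": warns, "counts": counts}
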