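"""Synthetic cohort generators with planted statistical structure.

Every pipeline input — food composition table, 4-day diet diaries, gene
counts with an MSP catalog, functional annotation maps and a clinical table —
can be generated here with known ground truth, so each downstream stage is
testable without the deposited cohort data.  The planted structure mirrors
the study design: a latent meat<->plant gradient and a food-quality gradient
per subject drive both the diaries and (optionally) the metagenome, the
quality gradient drives symptom severity, and a gas-metabolism latent couples
one hydrogenase group to animal-carbohydrate CAZy families and to the
exhaled H2/CH4 ratio.

All draws flow from one seeded ``numpy.random.Generator`` per call; the same
seed reproduces byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diet_quality import load_default_grids, score_food_db
from .msp_subspecies import MSPCatalog

__all__ = [
    "SyntheticTruth",
    "gen_food_db",
    "gen_diaries",
    "gen_msp_metagenome",
    "gen_clinical",
    "gen_function_profiles",
]

LEVEL2_CLASSES = ("animal-based", "plant-based", "alcohol", "fats", "others")

#: level-2 class -> (share of items, level-3 group names)
_HIERARCHY = {
    "animal-based": (0.30, ["meat", "dairy", "fish", "egg"]),
    "plant-based": (0.35, ["vegetables", "fruit", "grains", "legumes"]),
    "alcohol": (0.08, ["beer_wine", "spirits"]),
    "fats": (0.10, ["oils", "spreads"]),
    "others": (0.17, ["sweets", "beverages", "mixed_dishes"]),
}

_CORE_NUTRIENTS = [
    "protein_g",
    "fat_g",
    "carb_g",
    "fiber_g",
    "sugars_g",
    "saturated_fat_g",
    "fructose_g",
]


@dataclass
class SyntheticTruth:
    """Ground truth recorded by the generators, exactly as used.

    ``subject_latents`` holds the per-subject meat/plant and quality scores;
    ``subspecies_labels`` maps msp id -> Series (sample -> planted subspecies,
    NaN where the MSP is undetected); ``coupling_effects`` records the effect
    sizes linking latents to severity and exhaled gases.
    """

    subject_latents: pd.DataFrame
    subspecies_labels: dict = field(default_factory=dict)
    coupling_effects: dict = field(default_factory=dict)
    seed: int = 0
    extras: dict = field(default_factory=dict)


def gen_food_db(n_items: int, n_nutrients: int = 8, seed: int = 0) -> pd.DataFrame:
    """Generate a food composition table with a 4-level hierarchy.

    Each item carries a level-2 class (animal-based / plant-based / alcohol /
    fats / others), level-3 and level-4 category labels, per-100 g nutrients,
    energy, a drink flag and a fruit/vegetable percentage.  Within every
    level-4 category holding enough items, nutrient compositions are drawn
    from 2-3 distinct Dirichlet components, so nutrient-based mixture models
    can recover subcategories.  ``n_nutrients`` below the named core set of
    7 is floored to it; larger values append generic micro-nutrient columns.
    """
    if n_items < 10 or n_nutrients < 4:
        raise ValueError("need n_items >= 10 and n_nutrients >= 4")
    rng = np.random.default_rng(seed)
    n_cols = max(n_nutrients, len(_CORE_NUTRIENTS))
    extra_cols = [f"micronutrient_{i:02d}" for i in range(n_cols - len(_CORE_NUTRIENTS))]

    # allocate items to the hierarchy (every level-2 class non-empty)
    shares = np.array([_HIERARCHY[c][0] for c in LEVEL2_CLASSES])
    alloc = np.maximum(np.round(shares * n_items).astype(int), 1)
    while alloc.sum() > n_items:
        alloc[np.argmax(alloc)] -= 1
    while alloc.sum() < n_items:
        alloc[np.argmin(alloc)] += 1

    records = []
    item_no = 0
    for cls, n_cls in zip(LEVEL2_CLASSES, alloc):
        groups = _HIERARCHY[cls][1]
        g_idx = rng.integers(0, len(groups), size=n_cls)
        for gi in range(len(groups)):
            n_g = int((g_idx == gi).sum())
            if n_g == 0:
                continue
            n_l4 = max(1, min(1 + n_g // 5, 3))
            l4_idx = rng.integers(0, n_l4, size=n_g)
            for li in range(n_l4):
                n_cat = int((l4_idx == li).sum())
                if n_cat == 0:
                    continue
                l3 = f"{cls}:{groups[gi]}"
                l4 = f"{l3}:c{li + 1}"
                records.extend(
                    _gen_category_items(
                        rng, cls, l3, l4, n_cat, extra_cols, item_no
                    )
                )
                item_no += n_cat
    db = pd.DataFrame(records).set_index("item")
    db.index.name = "item"
    return db


def _gen_category_items(rng, cls, l3, l4, n_cat, extra_cols, item_no):
    """Items of one level-4 category, drawn from >=2 Dirichlet nutrient
    components when the category is large enough."""
    n_comp = 1 if n_cat < 4 else int(rng.integers(2, 4))
    # macro-slot base compositions: protein, fat, carb, fiber + extras
    n_slots = 4 + len(extra_cols)
    bases = rng.dirichlet(np.full(n_slots, 0.8), size=n_comp)
    sat_frac = rng.uniform(0.1, 0.8, size=n_comp)
    sugar_frac = rng.uniform(0.05, 0.9, size=n_comp)
    fruct_frac = rng.uniform(0.1, 0.9, size=n_comp)
    sodium_mu = rng.uniform(np.log(20), np.log(900), size=n_comp)
    is_drink_cat = (
        cls == "alcohol"
        or "beverages" in l3
        or (cls == "plant-based" and rng.random() < 0.08)
    )
    comp_of = rng.integers(0, n_comp, size=n_cat)
    if n_comp > 1:  # ensure every component represented
        comp_of[rng.choice(n_cat, size=n_comp, replace=False)] = np.arange(n_comp)
    out = []
    for j in range(n_cat):
        c = comp_of[j]
        w = rng.dirichlet(bases[c] * 400.0)
        total = rng.uniform(3.0, 15.0) if is_drink_cat else rng.uniform(20.0, 95.0)
        protein, fat, carb, fiber = (w[:4] * total).tolist()
        extras = w[4:] * total * 0.1
        sugars = carb * sugar_frac[c]
        mono = sugars * rng.uniform(0.3, 0.9)
        fructose = mono * fruct_frac[c]
        kcal = 4.0 * (protein + carb) + 9.0 * fat + 2.0 * fiber
        if cls == "alcohol":
            kcal += rng.uniform(20, 60)  # ethanol energy
        fv = 0.0
        if cls == "plant-based":
            fv = 90.0 if ("vegetables" in l3 or "fruit" in l3) else rng.uniform(0, 60)
        rec = {
            "item": f"F{item_no + j:04d}",
            "level2": cls,
            "level3": l3,
            "level4": l4,
            "nutrient_component": int(c),
            "protein_g": protein,
            "fat_g": fat,
            "carb_g": carb,
            "fiber_g": fiber,
            "sugars_g": sugars,
            "saturated_fat_g": fat * sat_frac[c],
            "fructose_g": fructose,
            "monosaccharides_g": mono,
            "sodium_mg": float(np.exp(sodium_mu[c] + rng.normal(0, 0.3))),
            "energy_kcal": max(kcal, 5.0),
            "is_drink": bool(is_drink_cat),
            "fruit_veg_pct": fv,
        }
        for name, v in zip(extra_cols, extras):
            rec[name] = v
        out.append(rec)
    return out


def gen_diaries(
    food_db: pd.DataFrame,
    n_subjects: int,
    gradient_sd: float = 1.0,
    seed: int = 0,
    quality_sd: float = 1.0,
    meat_tilt: float = 1.0,
    quality_tilt: float = 0.8,
    target_kcal=(2200.0, 300.0),
):
    """Generate 4-day diet diaries tilted by per-subject latent gradients.

    Each subject draws a meat/plant score (SD ``gradient_sd``) tilting item
    choice toward animal- or plant-based classes, and a quality score (SD
    ``quality_sd``) tilting choice toward high- or low-FSA-NPS items.  Days
    hold three main meals plus 0-2 snacks; grams are log-normal, then each
    day is rescaled to a plausible energy total (normal around
    ``target_kcal``, clipped well inside the 800-4500 kcal/day screen).

    Returns ``(diaries, truth)``.
    """
    if len(food_db) == 0:
        raise ValueError("food_db is empty")
    if n_subjects < 4:
        raise ValueError("need n_subjects >= 4")
    rng = np.random.default_rng(seed)
    items = food_db.index.to_numpy()
    level2 = food_db["level2"].to_numpy()
    tilt_dir = np.where(
        level2 == "animal-based", 1.0, np.where(level2 == "plant-based", -1.0, 0.0)
    )
    scores = score_food_db(food_db, load_default_grids())["score"].to_numpy(float)
    z = (scores - scores.mean()) / (scores.std() or 1.0)
    kcal100 = food_db["energy_kcal"].to_numpy()

    mp = rng.normal(0.0, gradient_sd, size=n_subjects)
    qual = rng.normal(0.0, quality_sd, size=n_subjects)
    subjects = [f"S{i:03d}" for i in range(n_subjects)]

    rows = []
    for si, subj in enumerate(subjects):
        logit = meat_tilt * mp[si] * tilt_dir + quality_tilt * qual[si] * z
        w = np.exp(logit - logit.max())
        w /= w.sum()
        for day in range(1, 5):
            meals = [("breakfast", True), ("lunch", True), ("dinner", True)]
            meals += [(f"snack{i+1}", False) for i in range(rng.binomial(2, 0.5))]
            day_rows = []
            for meal, is_main in meals:
                n_it = int(rng.integers(3, 7)) if is_main else int(rng.integers(1, 3))
                n_it = min(n_it, len(items))
                chosen = rng.choice(len(items), size=n_it, replace=False, p=w)
                grams = np.exp(rng.normal(np.log(60.0), 0.5, size=n_it))
                for ci, g in zip(chosen, grams):
                    day_rows.append(
                        {
                            "subject": subj,
                            "day": day,
                            "meal": meal,
                            "is_main": is_main,
                            "item": items[ci],
                            "grams": float(g),
                            "_idx": ci,
                        }
                    )
            day_kcal = sum(r["grams"] * kcal100[r["_idx"]] / 100.0 for r in day_rows)
            target = float(
                np.clip(rng.normal(*target_kcal), 1200.0, 3800.0)
            )
            scale = target / day_kcal
            for r in day_rows:
                r["grams"] *= scale
                del r["_idx"]
            rows.extend(day_rows)
    diaries = pd.DataFrame(rows)
    truth = SyntheticTruth(
        subject_latents=pd.DataFrame(
            {"meat_plant_score": mp, "quality_score": qual}, index=subjects
        ),
        coupling_effects={"meat_tilt": meat_tilt, "quality_tilt": quality_tilt},
        seed=seed,
    )
    return diaries, truth


def _normalize_blocks(subspecies_spec, n_msp):
    """Accept per-MSP accessory block sizes (ints) or explicit disjoint gene
    index lists; return list of per-MSP block-size lists."""
    if len(subspecies_spec) != n_msp:
        raise ValueError("subspecies_spec must have one entry per MSP")
    sizes = []
    for blocks in subspecies_spec:
        if all(np.isscalar(b) for b in blocks):
            bs = [int(b) for b in blocks]
            if any(b <= 0 for b in bs):
                raise ValueError("block sizes must be positive")
        else:
            seen = set()
            bs = []
            for b in blocks:
                b = set(b)
                if b & seen:
                    raise ValueError("accessory gene blocks must be disjoint")
                seen |= b
                bs.append(len(b))
        sizes.append(bs)
    return sizes


def gen_msp_metagenome(
    n_samples: int,
    n_msp: int,
    subspecies_spec,
    seed: int = 0,
    n_core: int = 40,
    n_shared_accessory: int = 8,
    undetected_frac: float = 0.1,
    truth: SyntheticTruth | None = None,
    subspecies_coupling: float = 0.0,
    abundance_coupling: float = 0.0,
    sample_ids=None,
):
    """Gene coverage matrix + MSP catalog with planted subspecies.

    Per detected sample and MSP, one planted subspecies is chosen; its
    accessory-block genes get coverage inside the sample's core-coverage
    band while other blocks stay at (or near) zero.  About
    ``undetected_frac`` of sample x MSP pairs get median core coverage <= 2
    (undetected).  With ``truth`` given, subspecies choice and MSP abundance
    are tilted by the subjects' meat/plant and quality latents so the
    metagenome covaries with diet.

    Returns ``(gene_counts, catalog, truth)`` with planted labels and the
    detection bookkeeping stored on the truth object.
    """
    block_sizes = _normalize_blocks(subspecies_spec, n_msp)
    if n_core < 10:
        raise ValueError("each MSP needs >= 10 core genes")
    rng = np.random.default_rng(seed)
    if truth is not None:
        sample_ids = list(truth.subject_latents.index)
        n_samples = len(sample_ids)
        mp = truth.subject_latents["meat_plant_score"].to_numpy()
        qual = truth.subject_latents["quality_score"].to_numpy()
    else:
        if sample_ids is None:
            sample_ids = [f"S{i:03d}" for i in range(n_samples)]
        mp = np.zeros(n_samples)
        qual = np.zeros(n_samples)
        truth = SyntheticTruth(
            subject_latents=pd.DataFrame(
                {"meat_plant_score": mp, "quality_score": qual}, index=sample_ids
            ),
            seed=seed,
        )

    members = {}
    gene_rows = []
    gene_index = []
    detected_tbl = {}
    for m in range(n_msp):
        msp = f"msp{m:03d}"
        blocks = block_sizes[m]
        core_genes = [f"{msp}_core_{i:03d}" for i in range(n_core)]
        acc_blocks = [
            [f"{msp}_acc{b}_{i:03d}" for i in range(sz)]
            for b, sz in enumerate(blocks, start=1)
        ]
        shared = [f"{msp}_accS_{i:03d}" for i in range(n_shared_accessory)]
        accessory = [g for blk in acc_blocks for g in blk] + shared
        members[msp] = {"core": core_genes, "accessory": accessory}

        detected = rng.random(n_samples) >= undetected_frac
        k = len(blocks)
        dirs = np.linspace(-1.0, 1.0, k) if k > 1 else np.zeros(1)
        logits = subspecies_coupling * np.outer(mp, dirs)
        probs = np.exp(logits - logits.max(axis=1, keepdims=True))
        probs /= probs.sum(axis=1, keepdims=True)
        sub = np.array([rng.choice(k, p=probs[i]) for i in range(n_samples)])
        v_m = rng.normal(0, abundance_coupling) if abundance_coupling else 0.0
        w_m = rng.normal(0, abundance_coupling / 2) if abundance_coupling else 0.0
        level = np.exp(rng.normal(np.log(12.0), 0.6, size=n_samples) + v_m * mp + w_m * qual)
        level = np.maximum(level, 3.0)

        cov = np.zeros((n_core + len(accessory), n_samples))
        n_acc = len(accessory)
        for s in range(n_samples):
            if not detected[s]:
                lo = rng.uniform(0.0, 1.0)
                cov[:n_core, s] = lo * rng.random(n_core) * (rng.random(n_core) < 0.5)
                continue
            c = level[s]
            cov[:n_core, s] = np.maximum(rng.normal(c, 0.12 * c, size=n_core), 0.1)
            row = n_core
            for b, blk in enumerate(acc_blocks):
                nb = len(blk)
                if b == sub[s]:
                    cov[row : row + nb, s] = np.maximum(
                        rng.normal(c, 0.12 * c, size=nb), 0.1
                    )
                row += nb
            pres = rng.random(len(shared)) < 0.5
            cov[row : row + len(shared), s] = pres * np.maximum(
                rng.normal(c, 0.12 * c, size=len(shared)), 0.1
            )
        gene_rows.append(cov)
        gene_index.extend(core_genes + accessory)
        labels = pd.Series(
            np.where(detected, sub + 1, np.nan), index=sample_ids, name=msp
        )
        truth.subspecies_labels[msp] = labels
        detected_tbl[msp] = pd.Series(detected, index=sample_ids)

    gene_counts = pd.DataFrame(
        np.vstack(gene_rows), index=gene_index, columns=sample_ids
    )
    catalog = MSPCatalog(members=members)
    truth.extras["detected"] = pd.DataFrame(detected_tbl)
    truth.coupling_effects.update(
        {
            "subspecies_coupling": subspecies_coupling,
            "abundance_coupling": abundance_coupling,
        }
    )
    return gene_counts, catalog, truth


def gen_clinical(
    truth: SyntheticTruth,
    effects: dict | None = None,
    noise_sd: float = 0.5,
    seed: int = 0,
    subjects=None,
) -> pd.DataFrame:
    """Clinical table driven by the planted latents.

    Severity group (1 = healthy ... 4 = severe) is a quantile-binned monotone
    function of ``severity_quality x quality + severity_meat x meat_plant``
    plus noise, with cohort-like group proportions.  The log2 H2/CH4 ratio
    follows the linear model ``gas_meat x meat_plant + gas_quality x quality``
    plus noise; exhaled CH4 (ppm) is log-normal and H2 = CH4 x 2^ratio.
    """
    effects = dict(effects or {})
    latents = truth.subject_latents
    if subjects is not None:
        unknown = set(subjects) - set(latents.index)
        if unknown:
            raise KeyError(f"unknown subjects: {sorted(unknown)[:5]}")
        latents = latents.loc[list(subjects)]
    rng = np.random.default_rng(seed)
    n = len(latents)
    mp = latents["meat_plant_score"].to_numpy()
    qual = latents["quality_score"].to_numpy()

    sev_lat = (
        effects.get("severity_quality", 0.0) * qual
        + effects.get("severity_meat", 0.0) * mp
        + rng.normal(0, max(noise_sd, 1e-9), size=n)
    )
    # healthy / mild / moderate / severe split close to the cohort profile
    cuts = np.quantile(sev_lat, [0.27, 0.40, 0.66])
    severity = np.searchsorted(cuts, sev_lat, side="right") + 1

    log2_ratio = (
        effects.get("gas_meat", 0.0) * mp
        + effects.get("gas_quality", 0.0) * qual
        + rng.normal(0, max(noise_sd, 1e-9), size=n)
    )
    ch4 = np.exp(rng.normal(np.log(15.0), 0.5, size=n))
    h2 = ch4 * np.power(2.0, log2_ratio)

    truth.coupling_effects.update({f"clinical_{k}": v for k, v in effects.items()})
    return pd.DataFrame(
        {
            "severity_group": severity,
            "h2_ppm": h2,
            "ch4_ppm": ch4,
            "bmi": 22.0 + rng.normal(0, 2.5, size=n),
            "age": rng.integers(20, 66, size=n),
            "sex": rng.choice(["F", "M"], size=n, p=[0.65, 0.35]),
            "enterotype": rng.integers(1, 4, size=n),
        },
        index=latents.index,
    )


def gen_function_profiles(
    n_samples: int,
    seed: int = 0,
    n_cazy: int = 60,
    n_animal: int = 8,
    coupling: float = 0.8,
    noise_sd: float = 0.35,
    genes_per_family: int = 3,
    severity_coupling: float = 1.5,
    sample_ids=None,
    gas_latent=None,
    n_cazotypes: int = 0,
    cazotype_labels=None,
    cazotype_sep: float = 1.2,
):
    """Gene counts + annotation maps with a planted function coupling.

    A per-sample gas-metabolism latent drives the hydrogenase group
    ``hyd_FeFe_A3`` and ``n_animal`` CAZy families of the
    ``animal carbohydrates`` substrate class (log-linear with slope
    ``coupling``); all other families are independent log-normal noise.
    Severity labels (severe vs control) are tilted by the same latent with
    slope ``severity_coupling``, so the A3-like group is enriched in the
    severe class.  Family abundances are expanded into ``genes_per_family``
    genes each, with two-column annotation maps returned for re-aggregation.

    With ``n_cazotypes`` (or explicit ``cazotype_labels``, e.g. enterotype
    assignments), sample clusters get distinct marker-family profiles so
    mixture clustering of the CAZy table can recover them.

    Returns a dict with ``gene_counts``, ``cazy_map``, ``hydrogenase_map``,
    ``substrate_map``, ``labels``, ``gas_latent``, ``cazotype_truth`` (or
    None) and the planted ``coupled_pairs``.
    """
    rng = np.random.default_rng(seed)
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(n_samples)]
    n_samples = len(sample_ids)
    g = np.asarray(gas_latent, dtype=float) if gas_latent is not None else rng.normal(
        size=n_samples
    )

    cazy_families = [f"GH{i + 1}" if i % 2 == 0 else f"CBM{i + 1}" for i in range(n_cazy)]
    animal = cazy_families[:n_animal]
    substrate = {}
    for i, fam in enumerate(cazy_families):
        if fam in animal:
            substrate[fam] = "animal carbohydrates"
        else:
            substrate[fam] = ["plant cell wall", "peptidoglycan", "other"][i % 3]
    hyd_groups = [
        "hyd_FeFe_A1",
        "hyd_FeFe_A2",
        "hyd_FeFe_A3",
        "hyd_FeFe_A4",
        "hyd_FeFe_B",
        "hyd_FeFe_C1",
        "hyd_FeFe_C2",
        "hyd_NiFe_4a",
        "hyd_NiFe_4e",
        "hyd_NiFe_1d",
        "hyd_Fe",
        "hyd_NiFe_3b",
    ]

    def family_matrix(families, coupled):
        # the coupled families sit ~1.5 log-units below the bulk, so their
        # swings barely move the universe total and compositional closure
        # does not induce spurious correlations elsewhere
        base = np.where(
            np.isin(families, list(coupled)),
            rng.normal(0.7, 0.3, size=len(families)),
            rng.normal(3.2, 0.5, size=len(families)),
        )
        log_ab = base[None, :] + rng.normal(0, noise_sd, size=(n_samples, len(families)))
        for j, fam in enumerate(families):
            if fam in coupled:
                log_ab[:, j] += coupling * g
        return np.exp(log_ab)

    cazy_ab = family_matrix(cazy_families, set(animal))
    hyd_ab = family_matrix(hyd_groups, {"hyd_FeFe_A3"})

    # optional planted CAZotypes: distinct marker-family profiles per sample
    # cluster, drawn from (or tilted toward) given labels such as enterotypes
    caz_truth = None
    if cazotype_labels is not None or n_cazotypes:
        if cazotype_labels is not None:
            caz_truth = pd.Series(cazotype_labels).reindex(sample_ids).to_numpy()
            n_cazotypes = len(np.unique(caz_truth))
        else:
            caz_truth = rng.integers(1, n_cazotypes + 1, size=n_samples)
        marker_start = n_animal
        per_type = 4
        for t in range(n_cazotypes):
            cols = slice(
                marker_start + t * per_type, marker_start + (t + 1) * per_type
            )
            mask = np.asarray(caz_truth) == np.unique(caz_truth)[t]
            cazy_ab[mask, cols] *= np.exp(cazotype_sep)
        caz_truth = pd.Series(caz_truth, index=sample_ids, name="cazotype_truth")

    gene_rows, gene_names, cazy_map, hyd_map = [], [], {}, {}
    for fams, ab, amap, tag in (
        (cazy_families, cazy_ab, cazy_map, "cz"),
        (hyd_groups, hyd_ab, hyd_map, "hy"),
    ):
        for j, fam in enumerate(fams):
            split = rng.dirichlet(np.ones(genes_per_family))
            for k in range(genes_per_family):
                gid = f"{tag}_{fam}_{k}"
                gene_names.append(gid)
                amap[gid] = fam
                gene_rows.append(ab[:, j] * split[k])
    gene_counts = pd.DataFrame(
        np.vstack(gene_rows), index=gene_names, columns=sample_ids
    )

    p_sev = 1.0 / (1.0 + np.exp(-(severity_coupling * g)))
    labels = pd.Series(
        np.where(rng.random(n_samples) < p_sev, "severe", "control"),
        index=sample_ids,
    )
    return {
        "gene_counts": gene_counts,
        "cazy_map": pd.Series(cazy_map, name="family"),
        "hydrogenase_map": pd.Series(hyd_map, name="family"),
        "substrate_map": pd.Series(substrate, name="substrate"),
        "labels": labels,
        "gas_latent": pd.Series(g, index=sample_ids),
        "cazotype_truth": caz_truth,
        "coupled_pairs": [("hyd_FeFe_A3", fam) for fam in animal],
    }
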