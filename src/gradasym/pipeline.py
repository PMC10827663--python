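"""End-to-end orchestration over a directory layout.

A study directory holds: ``phenotype.csv``, ``parcellation.tsv``,
``template.txt`` (reference gradients), ``fc/sub-*.txt`` (full Fisher-z
connectomes), and the stage outputs (aligned gradients, tidy asymmetry
tables, statistics tables). Every writer uses a fixed float format so
outputs are byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthetic as syn
from .asymmetry import intersubject_similarity, network_mean, subject_asymmetry
from .config import PipelineConfig
from .connectome import split_blocks
from .decoding import decode
from .gradients import GradientTemplate, align_subject
from .harmonization import combat_fit_transform
from .io_core import (
    CohortTable,
    ParcellationScheme,
    load_parcellation,
    load_phenotype,
    read_matrix,
    write_matrix,
)
from .stats import group_pipeline

FLOAT_FMT = "%.12g"


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def full_matrix(blocks, scheme: ParcellationScheme) -> np.ndarray:
    """Assemble a full connectome from homolog-ordered hemispheric blocks."""
    n = scheme.n_parcels
    li, ri = scheme.left_indices, scheme.right_indices
    fc = np.zeros((n, n))
    fc[np.ix_(li, li)] = blocks.LL
    fc[np.ix_(li, ri)] = blocks.LR
    fc[np.ix_(ri, li)] = blocks.RL
    fc[np.ix_(ri, ri)] = blocks.RR
    return fc


def simulate_study(
    out_dir: str | Path,
    seed: int = 0,
    n_per_group: int = 20,
    n_sites: int = 5,
    preset: str = "group-effect",
    config: PipelineConfig | None = None,
) -> Path:
    """Write a complete synthetic study directory.

    Presets: 'null' (no planted effects), 'group-effect' (group AI
    difference in the language network), 'interaction' (group-specific age
    slopes), 'trait' (group effect plus ADOS coupled to intra features).
    """
    config = config or PipelineConfig()
    out = Path(out_dir)
    (out / "fc").mkdir(parents=True, exist_ok=True)
    scheme = syn.make_parcellation(180, 12, seed=seed)
    cohort = syn.simulate_cohort(n_per_group=n_per_group, n_sites=n_sites, seed=seed + 1)
    kwargs = dict(calibrate=True, n_sites=n_sites)
    if preset == "null":
        kwargs.update(asym_effect_size=0.0, age_slope_nai=0.0, age_slope_autism=0.0)
    elif preset == "interaction":
        kwargs.update(asym_effect_size=0.0)
    elif preset not in ("group-effect", "trait"):
        raise ValueError(f"unknown preset {preset!r}")
    truth = syn.default_truth(scheme, seed=seed + 2, **kwargs)
    sc = syn.simulate_connectomes(cohort, scheme, truth, seed=seed + 3)
    if preset == "trait":
        ai_true = syn.simulate_ai_features(
            cohort, scheme, truth, seed=seed + 4, apply_site_effects=False
        )
        causal = [(int(p), 0) for p in truth.asym_effect_pairs]
        w = syn.make_trait_weights(scheme.n_pairs, truth.k, causal)
        cohort = syn.attach_trait_scores(cohort, ai_true, w, seed=seed + 5)
        truth.trait_weights = w

    cohort.table.to_csv(out / "phenotype.csv", index=False, float_format=FLOAT_FMT)
    scheme.table.to_csv(out / "parcellation.tsv", sep="\t", index=False)
    tmpl = syn.reference_template(truth, config.n_gradients_computed)
    write_matrix(tmpl.components, out / "template.txt")
    for sid, blocks in sc.blocks.items():
        write_matrix(full_matrix(blocks, scheme), out / "fc" / f"{sid}.txt")
    meta = {
        "seed": seed,
        "preset": preset,
        "asym_effect_pairs": truth.asym_effect_pairs.tolist(),
        "asym_effect_gradient": truth.asym_effect_gradient,
        "asym_effect_size": truth.asym_effect_size,
        "age_effect_pairs": truth.age_effect_pairs.tolist(),
        "age_slope_by_group": truth.age_slope_by_group,
        "site_shift": truth.site_shift,
        "site_scale": truth.site_scale,
    }
    (out / "truth.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    config.save(out / "config.json")
    return out


def compute_asymmetry_stage(
    study_dir: str | Path, config: PipelineConfig | None = None
) -> dict[str, np.ndarray]:
    """FC -> blocks -> aligned gradients -> AI stacks for both patterns."""
    study = Path(study_dir)
    config = config or (
        PipelineConfig.load(study / "config.json")
        if (study / "config.json").exists()
        else PipelineConfig()
    )
    scheme = load_parcellation(study / "parcellation.tsv")
    cohort = load_phenotype(study / "phenotype.csv", config)
    template = GradientTemplate(read_matrix(study / "template.txt"))
    intra, inter = [], []
    for sid in cohort.table["subject_id"]:
        fc = read_matrix(study / "fc" / f"{sid}.txt", (scheme.n_parcels, scheme.n_parcels))
        blocks = split_blocks(fc, scheme)
        aligned = align_subject(blocks, template, config)
        ai = subject_asymmetry(aligned, config.n_gradients_analyzed)
        intra.append(ai["intra"])
        inter.append(ai["inter"])
    stacks = {"intra": np.stack(intra), "inter": np.stack(inter)}
    for pattern, stack in stacks.items():
        np.save(study / f"ai_{pattern}.npy", stack)
        long = ai_long_table(stack, cohort)
        _write_csv(long, study / f"ai_{pattern}.csv")
    return stacks


def ai_long_table(stack: np.ndarray, cohort: CohortTable) -> pd.DataFrame:
    """Tidy long format: subject, pair, gradient, value."""
    n, n_pairs, k = stack.shape
    sids = np.asarray(cohort.table["subject_id"])
    return pd.DataFrame(
        {
            "subject_id": np.repeat(sids, n_pairs * k),
            "pair": np.tile(np.repeat(np.arange(n_pairs), k), n),
            "gradient": np.tile([f"G{g+1}" for g in range(k)], n * n_pairs),
            "value": stack.reshape(-1),
        }
    )


def harmonize_stage(
    stacks: dict[str, np.ndarray], cohort: CohortTable
) -> dict[str, np.ndarray]:
    """Site harmonization of AI features with age as a retained covariate."""
    t = cohort.table
    out = {}
    for pattern, stack in stacks.items():
        n, n_pairs, k = stack.shape
        X = stack.reshape(n, -1)
        adj, _ = combat_fit_transform(
            X,
            batch=np.asarray(t["site"]),
            covariates=np.asarray(t["age"], dtype=float),
            group=np.asarray(t["group"]),
        )
        out[pattern] = adj.reshape(n, n_pairs, k)
    return out


def stats_stage(
    study_dir: str | Path,
    stacks: dict[str, np.ndarray] | None = None,
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """Harmonize and run all group/age/interaction contrasts; write tables."""
    study = Path(study_dir)
    config = config or (
        PipelineConfig.load(study / "config.json")
        if (study / "config.json").exists()
        else PipelineConfig()
    )
    scheme = load_parcellation(study / "parcellation.tsv")
    cohort = load_phenotype(study / "phenotype.csv", config)
    if stacks is None:
        stacks = {
            p: np.load(study / f"ai_{p}.npy") for p in ("intra", "inter")
        }
    harmonized = harmonize_stage(stacks, cohort)
    tables = group_pipeline(harmonized, cohort, scheme, config)
    (study / "stats").mkdir(exist_ok=True)
    for name, df in tables.items():
        _write_csv(df, study / "stats" / f"{name}.csv")
    sim = intersubject_similarity(harmonized["intra"], cohort)
    _write_csv(sim, study / "similarity_intra.csv")
    return tables


def decoding_stage(
    study_dir: str | Path,
    tables: dict[str, pd.DataFrame],
    n_terms: int = 24,
    seed: int = 0,
) -> pd.DataFrame:
    """Decode the intra-pattern G1 group t-map against synthetic term maps."""
    study = Path(study_dir)
    gt = tables["group_intra_pair"]
    t_map = gt["t_G1"].to_numpy()
    terms = syn.simulate_term_maps(n_terms, n_parcels=t_map.size, seed=seed,
                                   planted_map=t_map)
    scores = decode(t_map, terms)
    _write_csv(scores, study / "decoding_scores.csv")
    return scores


def run_full_study(
    out_dir: str | Path,
    seed: int = 0,
    n_per_group: int = 20,
    preset: str = "group-effect",
    config: PipelineConfig | None = None,
) -> dict[str, pd.DataFrame]:
    """simulate -> gradients -> asymmetry -> harmonize -> stats -> decoding."""
    config = config or PipelineConfig()
    study = simulate_study(out_dir, seed=seed, n_per_group=n_per_group,
                           preset=preset, config=config)
    stacks = compute_asymmetry_stage(study, config)
    tables = stats_stage(study, stacks, config)
    decoding_stage(study, tables, seed=seed + 10)
    return tables
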