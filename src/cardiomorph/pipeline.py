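"""One-call synthetic study: simulate → measure → compare → report.

``run_study`` generates a small multi-group rat study (cardiomyocyte
fields, collagen fields, serum lipid panels, qPCR Ct tables), pushes every
piece through the corresponding analysis module and writes tidy CSV/JSON
outputs. Everything is driven by a single integer seed and is byte-
reproducible: two runs with the same seed produce identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import collagen as coll
from . import group_stats as gs
from . import morphometry as morph
from . import serum as ser
from . import synthetic as syn

__all__ = ["StudyConfig", "run_study"]


@dataclass(frozen=True)
class StudyConfig:
    """Scale and group structure of the simulated study.

    Defaults keep a laptop-scale run: three groups of five animals, 60
    measured cells per animal (two fields), four collagen fields per animal.
    ``mixtures`` gives each group's morphometric class mixture; ``collagen``
    the per-group true stained fraction; ``lipids`` per-group mean lipid
    panel; ``mir122_folds`` per-group miR-122 fold change vs control.
    """

    groups: tuple[str, ...] = ("control", "NAFLD", "NAFLD+LOLA")
    n_animals: int = 5
    cells_per_animal: int = 60
    fields_per_animal: int = 2
    collagen_fields: int = 4
    collagen_shape: tuple[int, int] = (192, 192)
    n_control_cells: int = 400  # pooled control reference for thresholds
    pixel_size: float = 0.35
    mixtures: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "control": {"N": 0.88, "I": 0.03, "HR": 0.04, "HI": 0.01, "AR": 0.03, "AI": 0.01},
        "NAFLD": {"N": 0.62, "I": 0.08, "HR": 0.18, "HI": 0.06, "AR": 0.04, "AI": 0.02},
        "NAFLD+LOLA": {"N": 0.76, "I": 0.05, "HR": 0.10, "HI": 0.03, "AR": 0.04, "AI": 0.02},
    })
    collagen: dict[str, float] = field(default_factory=lambda: {
        "control": 0.05, "NAFLD": 0.22, "NAFLD+LOLA": 0.12,
    })
    lipids: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "control": {"TC": 70.0, "LDLc": 20.0, "HDLc": 32.0, "TG": 60.0},
        "NAFLD": {"TC": 95.0, "LDLc": 38.0, "HDLc": 24.0, "TG": 110.0},
        "NAFLD+LOLA": {"TC": 82.0, "LDLc": 28.0, "HDLc": 28.0, "TG": 85.0},
    })
    lipid_cv: float = 0.12
    mir122_folds: dict[str, float] = field(default_factory=lambda: {
        "control": 1.0, "NAFLD": 4.0, "NAFLD+LOLA": 2.0,
    })
    ct_noise_sd: float = 0.2


def _animal_cells(mixture, n_cells, fields, pixel_size, seed):
    cells = []
    per_field = int(np.ceil(n_cells / fields))
    for f in range(fields):
        n = per_field if f < fields - 1 else n_cells - per_field * (fields - 1)
        if n <= 0:
            continue
        spec = syn.PopulationSpec(
            class_mixture=mixture, n_cells=n, seed=seed + f, pixel_size=pixel_size
        )
        truths = syn.sample_cell_truth(spec)
        _, labels = syn.render_field(truths, syn.RenderConfig(pixel_size=pixel_size, seed=seed + f))
        cells.extend(morph.measure_cells(labels, pixel_size=pixel_size))
    return cells


def run_study(seed: int, out_dir: str | Path, config: StudyConfig | None = None) -> dict:
    """Simulate and analyse one full study; write outputs under ``out_dir``.

    Returns a dict with the in-memory results (per-cell table, profiles,
    thresholds, collagen scores, ratio table, fold changes, comparison
    results) for programmatic use.
    """
    cfg = config or StudyConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # --- morphometry ---------------------------------------------------
    ctrl_spec_seed = int(rng.integers(2**31 - 1))
    control_cells = _animal_cells(
        cfg.mixtures[cfg.groups[0]], cfg.n_control_cells,
        max(1, cfg.n_control_cells // 100), cfg.pixel_size, ctrl_spec_seed,
    )
    thresholds = morph.derive_thresholds(control_cells)
    (out / "thresholds.json").write_text(thresholds.to_json())

    cell_rows, profile_rows = [], []
    for g in cfg.groups:
        for a in range(cfg.n_animals):
            animal = f"{g}_{a + 1:02d}"
            cells = _animal_cells(
                cfg.mixtures[g], cfg.cells_per_animal, cfg.fields_per_animal,
                cfg.pixel_size, int(rng.integers(2**31 - 1)),
            )
            df = morph.cells_to_frame(cells, thresholds)
            df.insert(0, "animal_id", animal)
            df.insert(0, "group", g)
            cell_rows.append(df)
            p = morph.population_profile(cells, thresholds, animal_id=animal)
            profile_rows.append({
                "group": g, "animal_id": animal, "n_cells": p.n_cells,
                **{f"pct_{c.value}": p.percents[c] for c in morph.MorphClass},
                "mean_cii": p.mean_cii, "area_variability": p.area_variability,
            })
    cells_df = pd.concat(cell_rows, ignore_index=True)
    profiles_df = pd.DataFrame(profile_rows)
    cells_df.to_csv(out / "cells.csv", index=False)
    profiles_df.to_csv(out / "profiles.csv", index=False)

    # --- collagen -------------------------------------------------------
    coll_rows = []
    for g in cfg.groups:
        for a in range(cfg.n_animals):
            animal = f"{g}_{a + 1:02d}"
            fields = []
            for f in range(cfg.collagen_fields):
                img, _ = syn.simulate_collagen_field(
                    cfg.collagen[g], seed=int(rng.integers(2**31 - 1)),
                    shape=cfg.collagen_shape,
                )
                fields.append(coll.quantify_field(img, field_id=f"{animal}_f{f + 1}"))
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                score = coll.animal_collagen_score(fields, animal_id=animal)
            coll_rows.append({
                "group": g, "animal_id": animal, "n_fields": score.n_fields,
                "collagen_score": score.score, "dispersion": score.dispersion,
            })
    collagen_df = pd.DataFrame(coll_rows)
    collagen_df.to_csv(out / "collagen.csv", index=False)

    # --- serum lipids and atherogenic ratios ---------------------------
    serum_specs = [
        syn.SerumGroupSpec(
            name=g,
            analytes={
                k: syn.AnalyteSpec(loc=v, scale=cfg.lipid_cv * v, family="symmetric")
                for k, v in cfg.lipids[g].items()
            },
            n_animals=cfg.n_animals,
            seed=int(rng.integers(2**31 - 1)),
        )
        for g in cfg.groups
    ]
    serum_long = syn.simulate_serum_panel(serum_specs)
    panels = serum_long.pivot_table(
        index=["group", "animal_id"], columns="analyte", values="value", sort=False
    ).reset_index()
    panels.columns.name = None
    ratios_df = ser.atherogenic_ratios_table(panels)
    serum_long.to_csv(out / "serum.csv", index=False)
    ratios_df.to_csv(out / "ratios.csv", index=False)

    # --- circulating miR-122 -------------------------------------------
    ct_df = syn.simulate_ct_table(
        cfg.mir122_folds, seed=int(rng.integers(2**31 - 1)),
        reference_group=cfg.groups[0], n_per_group=cfg.n_animals,
        noise_sd=cfg.ct_noise_sd,
    )
    folds = ser.fold_change_ddct(ct_df, reference_group=cfg.groups[0])
    folds_df = ser.fold_changes_to_frame(folds)
    ct_df.to_csv(out / "ct.csv", index=False)
    folds_df.to_csv(out / "mirna_folds.csv", index=False)

    # --- group statistics ----------------------------------------------
    stat_inputs = pd.concat(
        [
            profiles_df.melt(
                id_vars=["group", "animal_id"],
                value_vars=["pct_N", "pct_HR", "mean_cii", "area_variability"],
                var_name="variable",
            ),
            collagen_df.rename(columns={"collagen_score": "value"})
            .assign(variable="collagen_score")[["group", "animal_id", "variable", "value"]],
            ratios_df.melt(
                id_vars=["group", "animal_id"], value_vars=["CRI_I", "CRI_II", "AC"],
                var_name="variable",
            ),
            folds_df.rename(columns={"sample_id": "animal_id", "fold": "value"})
            .assign(variable="miR-122_fold")[["group", "animal_id", "variable", "value"]],
        ],
        ignore_index=True,
    )
    results = gs.compare_variables(stat_inputs, variable_col="variable")
    summary = gs.summary_frame(results)
    summary.to_csv(out / "summary.csv", index=False)
    pairwise_rows = [
        {"variable": r.variable, "group_a": a, "group_b": b, "p_adjusted": p,
         "route": r.route, "adjustment": r.adjustment}
        for r in results.values()
        for (a, b), p in r.pairwise.items()
    ]
    pd.DataFrame(pairwise_rows).to_csv(out / "pairwise.csv", index=False)
    (out / "omnibus.json").write_text(json.dumps(
        {v: {"route": r.route, "omnibus_p": r.omnibus_p, "letters": r.letters}
         for v, r in results.items()}, indent=2))

    return {
        "cells": cells_df, "profiles": profiles_df, "thresholds": thresholds,
        "collagen": collagen_df, "serum": serum_long, "ratios": ratios_df,
        "folds": folds_df, "results": results, "summary": summary,
    }
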