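"""Ground-truth recovery experiments for pipeline validation.

Each experiment simulates data with known truth through ``synthetic``, runs
the corresponding analysis module, and reports how well the truth is
recovered. They are the package's built-in calibration checks; the test
suite asserts their tolerances and the acceptance script reports their
numbers.
"""

from __future__ import annotations

import itertools
from typing import Mapping

import numpy as np
import pandas as pd

from . import collagen as coll
from . import group_stats as gs
from . import morphometry as morph
from . import serum as ser
from . import synthetic as syn

__all__ = [
    "measure_synthetic_animal",
    "mixture_recovery_experiment",
    "collagen_recovery_experiment",
    "fold_change_recovery_experiment",
    "type_i_error_experiment",
]


def measure_synthetic_animal(
    mixture: Mapping[str, float],
    n_cells: int,
    seed: int,
    pixel_size: float = 0.35,
    cells_per_field: int = 100,
) -> list[morph.CellMorphometry]:
    """Simulate one animal's fields and measure every rendered cell.

    Cells are split across fields of ``cells_per_field`` (mirroring multi-
    field acquisition), rendered, extracted from the label masks and
    measured. Returns the pooled per-cell morphometry.
    """
    cells: list[morph.CellMorphometry] = []
    done, f = 0, 0
    while done < n_cells:
        k = min(cells_per_field, n_cells - done)
        spec = syn.PopulationSpec(
            class_mixture=mixture, n_cells=k, seed=seed + f, pixel_size=pixel_size
        )
        truths = syn.sample_cell_truth(spec)
        _, labels = syn.render_field(truths, syn.RenderConfig(pixel_size=pixel_size, seed=seed + f))
        cells.extend(morph.measure_cells(labels, pixel_size=pixel_size))
        done += k
        f += 1
    return cells


def mixture_recovery_experiment(
    seed: int,
    n_replicates: int = 10,
    mixture: Mapping[str, float] | None = None,
    n_cells: int = 500,
    n_control: int = 1000,
    pixel_size: float = 0.35,
) -> pd.DataFrame:
    """Recover known class mixtures through the full image pipeline.

    Per replicate: render and measure a pure-normal control population,
    derive default thresholds from it, then render, measure and classify an
    animal with the given class mixture. Returns one row per replicate ×
    class with truth and recovered percentages.
    """
    mixture = dict(mixture or {"N": 0.70, "HR": 0.20, "AR": 0.10})
    rows = []
    for rep in range(n_replicates):
        base = seed + 10_000 * rep
        control = measure_synthetic_animal({"N": 1.0}, n_control, base, pixel_size)
        thresholds = morph.derive_thresholds(control)
        cells = measure_synthetic_animal(mixture, n_cells, base + 5_000, pixel_size)
        profile = morph.population_profile(cells, thresholds, animal_id=f"rep{rep}")
        for label, truth_p in mixture.items():
            rows.append({
                "replicate": rep,
                "morph_class": label,
                "truth_pct": 100.0 * truth_p,
                "recovered_pct": profile.percents[morph.MorphClass(label)],
            })
    return pd.DataFrame(rows)


def collagen_recovery_experiment(
    seed: int,
    fractions: tuple[float, ...] = (0.05, 0.15, 0.30, 0.50),
    n_fields: int = 10,
    shape: tuple[int, int] = (256, 256),
) -> pd.DataFrame:
    """Animal-level collagen scores for known stained fractions."""
    rows = []
    for i, f in enumerate(fractions):
        fields = [
            coll.quantify_field(
                syn.simulate_collagen_field(f, seed=seed + 100 * i + j, shape=shape)[0],
                field_id=f"f{j}",
            )
            for j in range(n_fields)
        ]
        score = coll.animal_collagen_score(fields, animal_id=f"truth_{f}")
        rows.append({
            "true_fraction": f,
            "score": score.score,
            "abs_error": abs(score.score - f),
            "n_fields": n_fields,
        })
    return pd.DataFrame(rows)


def fold_change_recovery_experiment(
    seed: int,
    folds: tuple[float, ...] = (0.5, 1.0, 4.0),
    noise_sd: float = 0.2,
    n_per_group: int = 30,
) -> pd.DataFrame:
    """Recover known fold changes through Ct simulation + 2^−ΔΔCt."""
    fold_map = {"control": 1.0}
    fold_map.update({f"g{i}": f for i, f in enumerate(folds)})
    ct = syn.simulate_ct_table(
        fold_map, seed=seed, reference_group="control",
        n_per_group=n_per_group, noise_sd=noise_sd,
    )
    est = (
        ser.fold_changes_to_frame(ser.fold_change_ddct(ct, "control"))
        .groupby("group")["fold"].mean()
    )
    rows = [
        {"group": g, "true_fold": f, "estimated_fold": float(est[g]),
         "rel_error": float(est[g] / f - 1.0)}
        for g, f in fold_map.items()
    ]
    return pd.DataFrame(rows)


def type_i_error_experiment(
    seed: int,
    n_replicates: int = 2000,
    n_groups: int = 5,
    n_per_group: int = 10,
    alpha: float = 0.05,
    tukey_method: str = "approx",
) -> dict:
    """Empirical size of the gate→omnibus path under a Gaussian null.

    All groups are drawn from the same N(0, 1); the reported rate is the
    fraction of replicates with omnibus p < α. On every replicate the
    compact letter display is checked pair-by-pair against the adjusted
    pairwise p-values (share a letter ⟺ p ≥ α); any violation is counted.
    """
    rng = np.random.default_rng(seed)
    group_names = [f"g{i}" for i in range(n_groups)]
    n_sig = 0
    letter_violations = 0
    routes = {"parametric": 0, "nonparametric": 0}
    for _ in range(n_replicates):
        df = pd.DataFrame({
            "group": np.repeat(group_names, n_per_group),
            "value": rng.normal(0.0, 1.0, n_groups * n_per_group),
        })
        r = gs.compare_groups(df, alpha=alpha, tukey_method=tukey_method)
        routes[r.route] += 1
        if r.omnibus_p < alpha:
            n_sig += 1
        for a, b in itertools.combinations(r.groups, 2):
            share = bool(set(r.letters[a]) & set(r.letters[b]))
            p = r.pairwise.get((a, b), r.pairwise.get((b, a)))
            if share != (p >= alpha):
                letter_violations += 1
    return {
        "type_i_rate": n_sig / n_replicates,
        "n_replicates": n_replicates,
        "letter_violations": letter_violations,
        "routes": routes,
        "alpha": alpha,
    }
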