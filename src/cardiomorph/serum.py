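"""Serum analytics: atherogenic lipid ratios and 2^−ΔΔCt fold changes.

Atherogenic ratios (unit-free cardiovascular-risk markers):

    CRI-I = TC / HDLc        Castelli's risk index I
    CRI-II = LDLc / HDLc     Castelli's risk index II
    AC = (TC − HDLc) / HDLc  atherogenic coefficient (≡ CRI-I − 1)

Circulating-miRNA relative expression against the cel-miR-39 spike-in:

    ΔCt = Ct(target) − Ct(normalizer)
    ΔΔCt = ΔCt − mean reference-group ΔCt (per target)
    fold = 2^−ΔΔCt
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

from .exceptions import NormalizationError, ValidationError

__all__ = [
    "LipidPanel",
    "AtherogenicRatios",
    "CtRecord",
    "FoldChange",
    "atherogenic_ratios",
    "atherogenic_ratios_table",
    "fold_change_ddct",
    "fold_changes_to_frame",
]

KNOWN_TARGETS = ("miR-122", "miR-33a", "miR-126", "miR-499", "miR-186", "miR-146a")


@dataclass(frozen=True)
class LipidPanel:
    """One animal's serum lipid panel, concentrations in mg/dL.

    Any consistent concentration unit works: the ratios are scale invariant.
    """

    animal_id: str
    TC: float
    LDLc: float
    HDLc: float
    TG: float
    ALT: float | None = None  # U/L
    AST: float | None = None  # U/L

    def __post_init__(self) -> None:
        for name in ("TC", "LDLc", "HDLc", "TG"):
            if getattr(self, name) < 0:
                raise ValidationError(f"animal {self.animal_id}: {name} must be >= 0")


@dataclass(frozen=True)
class AtherogenicRatios:
    """Castelli risk indices and atherogenic coefficient (dimensionless)."""

    animal_id: str
    CRI_I: float
    CRI_II: float
    AC: float

    def __post_init__(self) -> None:
        vals = (self.CRI_I, self.CRI_II, self.AC)
        if not all(math.isfinite(v) for v in vals):
            raise ValidationError(f"animal {self.animal_id}: non-finite ratio in {vals}")
        if abs(self.AC - (self.CRI_I - 1.0)) > 1e-12:
            raise ValidationError(f"animal {self.animal_id}: AC must equal CRI_I - 1")


def atherogenic_ratios(panel: LipidPanel) -> AtherogenicRatios:
    """Compute CRI-I, CRI-II and AC from one lipid panel."""
    if panel.HDLc <= 0:
        raise ValidationError(f"animal {panel.animal_id}: HDLc must be > 0 to form ratios")
    cri_i = panel.TC / panel.HDLc
    return AtherogenicRatios(
        animal_id=panel.animal_id,
        CRI_I=cri_i,
        CRI_II=panel.LDLc / panel.HDLc,
        AC=cri_i - 1.0,  # (TC - HDLc)/HDLc, algebraically
    )


def atherogenic_ratios_table(panels: pd.DataFrame) -> pd.DataFrame:
    """Vectorised ratios for a panel table with columns animal_id, TC, LDLc, HDLc.

    Extra columns (e.g. group) are carried through unchanged.
    """
    required = {"animal_id", "TC", "LDLc", "HDLc"}
    missing = required - set(panels.columns)
    if missing:
        raise ValidationError(f"panel table missing columns: {sorted(missing)}")
    bad = panels.loc[panels["HDLc"] <= 0, "animal_id"].tolist()
    if bad:
        raise ValidationError(f"HDLc must be > 0 to form ratios; offending animals: {bad}")
    out = panels.copy()
    out["CRI_I"] = out["TC"] / out["HDLc"]
    out["CRI_II"] = out["LDLc"] / out["HDLc"]
    out["AC"] = (out["TC"] - out["HDLc"]) / out["HDLc"]
    return out


@dataclass(frozen=True)
class CtRecord:
    """One sample × target qPCR measurement with its spike-in normaliser Ct."""

    sample_id: str
    group: str
    target: str
    ct_target: float
    ct_normalizer: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_target) and math.isfinite(self.ct_normalizer)):
            raise ValidationError(f"sample {self.sample_id}: non-finite Ct value")
        for name, ct in (("target", self.ct_target), ("normalizer", self.ct_normalizer)):
            if not (10.0 <= ct <= 40.0):
                warnings.warn(
                    f"sample {self.sample_id}: {name} Ct {ct:.2f} outside the typical "
                    "10-40 cycle range",
                    stacklevel=3,
                )


@dataclass(frozen=True)
class FoldChange:
    """Per-sample relative expression 2^−ΔΔCt."""

    sample_id: str
    group: str
    target: str
    ddct: float
    fold: float

    def __post_init__(self) -> None:
        if abs(self.fold - 2.0 ** (-self.ddct)) > 1e-12 * max(1.0, self.fold):
            raise ValidationError(f"sample {self.sample_id}: fold must equal 2^-ddct")


def _records_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        required = {"sample_id", "group", "target", "ct_target", "ct_normalizer"}
        missing = required - set(records.columns)
        if missing:
            raise ValidationError(f"Ct table missing columns: {sorted(missing)}")
        return records.copy()
    return pd.DataFrame(
        [(r.sample_id, r.group, r.target, r.ct_target, r.ct_normalizer) for r in records],
        columns=["sample_id", "group", "target", "ct_target", "ct_normalizer"],
    )


def fold_change_ddct(
    records: Sequence[CtRecord] | pd.DataFrame, reference_group: str
) -> list[FoldChange]:
    """Relative expression per sample by the 2^−ΔΔCt method.

    Technical replicates (repeated sample_id × target rows) are averaged at
    the Ct level first. The reference ΔCt is the arithmetic mean over the
    reference group per target (equivalently the geometric mean in fold
    space), so reference-group folds have geometric mean exactly 1.

    Raises
    ------
    NormalizationError
        If a target has no records in the reference group.
    """
    df = _records_frame(records)
    if df.empty:
        return []
    df = (
        df.groupby(["sample_id", "group", "target"], sort=False, as_index=False)[
            ["ct_target", "ct_normalizer"]
        ].mean()
    )
    df["dct"] = df["ct_target"] - df["ct_normalizer"]
    out: list[FoldChange] = []
    for target, sub in df.groupby("target", sort=False):
        ref = sub.loc[sub["group"] == reference_group, "dct"]
        if ref.empty:
            raise NormalizationError(
                f"target {target!r} has no records in reference group {reference_group!r}"
            )
        ref_mean = float(ref.mean())
        for row in sub.itertuples(index=False):
            ddct = float(row.dct - ref_mean)
            out.append(
                FoldChange(
                    sample_id=row.sample_id,
                    group=row.group,
                    target=target,
                    ddct=ddct,
                    fold=2.0 ** (-ddct),
                )
            )
    return out


def fold_changes_to_frame(folds: Sequence[FoldChange]) -> pd.DataFrame:
    """Tidy fold-change table (sample_id, group, target, ddct, fold)."""
    return pd.DataFrame(
        [(f.sample_id, f.group, f.target, f.ddct, f.fold) for f in folds],
        columns=["sample_id", "group", "target", "ddct", "fold"],
    )
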