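"""Functional-ROI selection, condition-response extraction, lateralization,
and the dummy-coded model table for condition-effect estimation.

A functional ROI (fROI) is the top fraction (default 10%) of voxels within
an anatomical mask ranked by a localizer contrast statistic; condition
responses (percent BOLD signal change) are averaged over the selected
voxels.  Lateralization is (LH - RH)/(LH + RH) over significant-voxel
counts, with values at or below -0.25 classified right-lateralized.
Mixed-model fitting itself is delegated (statsmodels MixedLM via
:func:`fit_mixed_model`); this module owns the long-format table, the dummy
coding with a reference condition, and an ordinary-least-squares
fixed-effects estimator used for parameter-recovery checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RIGHT_LATERALIZED_CUTOFF = -0.25
DEFAULT_FROI_FRACTION = 0.10


class EmptyMaskError(ValueError):
    pass


class UndefinedIndexError(ValueError):
    pass


class CodingError(ValueError):
    pass


@dataclass
class VoxelMap:
    """Localizer statistics and per-condition responses for the voxels of
    one mask, index-aligned across arrays."""

    voxel_ids: np.ndarray  # (n,)
    localizer_stat: np.ndarray  # (n,)
    condition_responses: dict[str, np.ndarray]  # condition -> (n,)
    mask_label: str = ""

    def __post_init__(self):
        self.voxel_ids = np.asarray(self.voxel_ids)
        self.localizer_stat = np.asarray(self.localizer_stat, dtype=float)
        n = len(self.voxel_ids)
        if n == 0:
            raise EmptyMaskError(f"mask {self.mask_label!r} is empty")
        if len(self.localizer_stat) != n or any(
            len(v) != len(self.voxel_ids) for v in self.condition_responses.values()
        ):
            raise ValueError("voxel arrays are not index-aligned")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_ids)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"voxel_id": self.voxel_ids, "stat": self.localizer_stat})
        for cond, vals in self.condition_responses.items():
            df[cond] = vals
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, mask_label: str = "") -> "VoxelMap":
        df = pd.read_csv(path, sep="\t")
        conds = [c for c in df.columns if c not in ("voxel_id", "stat")]
        return cls(
            voxel_ids=df["voxel_id"].to_numpy(),
            localizer_stat=df["stat"].to_numpy(float),
            condition_responses={c: df[c].to_numpy(float) for c in conds},
            mask_label=mask_label,
        )

    @classmethod
    def from_nifti(
        cls,
        stat_path: str | Path,
        mask_path: str | Path,
        response_paths: Mapping[str, str | Path],
        mask_label: str = "",
    ) -> "VoxelMap":
        """Build a map from NIfTI volumes: a statistic image, a binary mask,
        and one response image per condition (all same grid)."""
        import nibabel as nib

        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
        stat = np.asarray(nib.load(str(stat_path)).dataobj, dtype=float)
        idx = np.flatnonzero(mask.ravel())
        responses = {
            cond: np.asarray(nib.load(str(p)).dataobj, dtype=float).ravel()[idx]
            for cond, p in response_paths.items()
        }
        return cls(
            voxel_ids=idx,
            localizer_stat=stat.ravel()[idx],
            condition_responses=responses,
            mask_label=mask_label,
        )


def froi_size(n_voxels: int, fraction: float = DEFAULT_FROI_FRACTION) -> int:
    """Rounding rule: ceil(fraction * mask size)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    return math.ceil(fraction * n_voxels)


def select_froi(m: VoxelMap, fraction: float = DEFAULT_FROI_FRACTION) -> np.ndarray:
    """Indices (into the map's arrays) of the top-``fraction`` voxels by
    localizer statistic; ties broken deterministically by voxel id
    (lower id wins)."""
    k = froi_size(m.n_voxels, fraction)
    order = np.lexsort((m.voxel_ids, -m.localizer_stat))
    return np.sort(order[:k])


@dataclass
class FroiResponse:
    participant: str
    roi_label: str
    condition_means: dict[str, float]
    n_voxels_selected: int


def extract_condition_responses(
    m: VoxelMap, selected: np.ndarray, participant: str = ""
) -> FroiResponse:
    """Per-condition mean response over the selected voxels."""
    selected = np.asarray(selected)
    if selected.size == 0:
        raise ValueError("empty voxel selection")
    return FroiResponse(
        participant=participant,
        roi_label=m.mask_label,
        condition_means={
            cond: float(np.mean(vals[selected])) for cond, vals in m.condition_responses.items()
        },
        n_voxels_selected=int(selected.size),
    )


def lateralization_index(lh_count: int, rh_count: int) -> tuple[float, bool]:
    """(LH - RH)/(LH + RH) over significant voxel counts, plus the
    right-lateralized classification (index <= -0.25)."""
    if lh_count < 0 or rh_count < 0:
        raise ValueError("voxel counts must be non-negative")
    if lh_count + rh_count == 0:
        raise UndefinedIndexError("no significant voxels in either hemisphere")
    index = (lh_count - rh_count) / (lh_count + rh_count)
    return index, index <= RIGHT_LATERALIZED_CUTOFF


def count_significant_voxels(stats: np.ndarray, threshold: float) -> int:
    """Voxels whose statistic exceeds a fixed (uncorrected) threshold."""
    return int(np.sum(np.asarray(stats) > threshold))


# ---------------------------------------------------------------------------
# model table and estimation


@dataclass
class ModelSpec:
    """Condition-effect model: response ~ condition, dummy-coded against a
    reference level, with by-participant and by-ROI random intercepts and a
    by-both random slope for condition (fitting delegated)."""

    reference: str = "Sentence"
    conditions: list[str] = field(default_factory=list)

    @property
    def formula(self) -> str:
        return f"response ~ C(condition, Treatment(reference={self.reference!r}))"


def build_model_table(
    responses: Iterable[FroiResponse], spec: ModelSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format analysis table plus its dummy-coding matrix.

    One row per (participant, roi, condition); dummy columns
    ``cond_<level>`` for every non-reference condition (the reference
    condition codes all-zero).
    """
    rows = []
    for r in responses:
        for cond, val in r.condition_means.items():
            rows.append(
                {
                    "participant": r.participant,
                    "roi": r.roi_label,
                    "condition": cond,
                    "response": val,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ValueError("no responses provided")
    conditions = spec.conditions or sorted(table["condition"].unique())
    if spec.reference not in conditions:
        raise CodingError(f"reference level {spec.reference!r} absent from conditions")
    if len(conditions) < 2:
        raise CodingError("need at least 2 conditions")
    non_ref = [c for c in conditions if c != spec.reference]
    coding = pd.DataFrame(
        {f"cond_{c}": [int(cond == c) for cond in table["condition"]] for c in non_ref}
    )
    return pd.concat([table, coding], axis=1), coding


def fit_fixed_effects(table: pd.DataFrame, spec: ModelSpec) -> dict[str, float]:
    """OLS estimates of the intercept (reference-condition mean) and the
    per-condition contrasts vs. the reference; used for parameter-recovery
    checks (the mixed-model fit is delegated to an external solver)."""
    import statsmodels.api as sm

    dummy_cols = [c for c in table.columns if c.startswith("cond_")]
    X = sm.add_constant(table[dummy_cols].to_numpy(float))
    fit = sm.OLS(table["response"].to_numpy(float), X).fit()
    out = {"intercept": float(fit.params[0])}
    for i, c in enumerate(dummy_cols, start=1):
        out[c.removeprefix("cond_")] = float(fit.params[i])
    return out


def fit_mixed_model(table: pd.DataFrame, spec: ModelSpec):
    """Delegated mixed-model fit (random intercepts for participants) via
    statsmodels MixedLM; returns the fitted results object."""
    import statsmodels.formula.api as smf

    model = smf.mixedlm(spec.formula, data=table, groups=table["participant"])
    return model.fit(reml=True)
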