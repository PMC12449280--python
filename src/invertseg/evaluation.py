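"""Class-wise Dice evaluation, aggregation, and tumor analyses.

Per-case, per-class Dice similarity coefficients are collected as
:class:`EvalRecord` rows in an :class:`EvalTable` (a thin pandas-backed
container).  Aggregation mirrors the usual reporting layout of
cross-modality segmentation studies: mean DSC per (sequence x
preprocessing-variant) group with 95% confidence intervals from a
seeded case-level percentile bootstrap, plus a per-case tumor
localization classification and a median-volume stratification of tumor
DSC.

A DSC is *undefined* when both the prediction and the reference mask
are empty; such records carry ``dsc = NaN`` and are excluded from means
(with their count reported) rather than scored as 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .volume_io import GeometryError, LabelMap

__all__ = [
    "ClassMapping",
    "EvalRecord",
    "EvalTable",
    "dice",
    "evaluate_case",
    "summarize",
    "classify_localization",
    "stratify_by_volume",
]

LOCALIZATION_OUTCOMES = ("correct", "incorrect", "not_detected")


def dice(pred_mask: np.ndarray, ref_mask: np.ndarray) -> float:
    """Dice similarity coefficient 2|A.B| / (|A|+|B|) of two binary masks.

    Returns NaN (the undefined marker) when both masks are empty.
    """
    pred_mask = np.asarray(pred_mask).astype(bool)
    ref_mask = np.asarray(ref_mask).astype(bool)
    if pred_mask.shape != ref_mask.shape:
        raise GeometryError(
            f"mask shapes differ: {pred_mask.shape} vs {ref_mask.shape}"
        )
    a = int(pred_mask.sum())
    b = int(ref_mask.sum())
    if a + b == 0:
        return float("nan")
    inter = int(np.count_nonzero(pred_mask & ref_mask))
    return 2.0 * inter / (a + b)


@dataclass(frozen=True)
class ClassMapping:
    """Many-to-one map from prediction class names to reference class names.

    Prediction classes absent from the map are ignored.  The identity
    mapping over a vocabulary is built with :meth:`identity`.
    """

    pairs: tuple[tuple[str, str], ...]

    @classmethod
    def from_dict(cls, mapping: Mapping[str, str]) -> "ClassMapping":
        return cls(tuple(sorted(mapping.items())))

    @classmethod
    def identity(cls, class_names: Iterable[str]) -> "ClassMapping":
        return cls(tuple((n, n) for n in sorted(set(class_names))))

    @property
    def reference_classes(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for _, ref in self.pairs:
            seen.setdefault(ref, None)
        return tuple(seen)

    def prediction_classes_for(self, ref_class: str) -> tuple[str, ...]:
        return tuple(p for p, r in self.pairs if r == ref_class)


@dataclass
class EvalRecord:
    """One (case, sequence, variant, class) cell of the evaluation."""

    case_id: str
    sequence: str
    variant: str
    class_name: str
    dsc: float
    ref_volume_cm3: float
    pred_volume_cm3: float


RECORD_COLUMNS = list(EvalRecord.__dataclass_fields__)


@dataclass
class EvalTable:
    """Collection of EvalRecords with provenance metadata."""

    records: list[EvalRecord] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def extend(self, records: Iterable[EvalRecord]) -> None:
        self.records.extend(records)
        self._check_unique()

    def _check_unique(self) -> None:
        keys = [(r.case_id, r.sequence, r.variant, r.class_name) for r in self.records]
        if len(keys) != len(set(keys)):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate (case, sequence, variant, class) keys: {dupes[:5]}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records], columns=RECORD_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: dict | None = None) -> "EvalTable":
        records = [EvalRecord(**{c: row[c] for c in RECORD_COLUMNS})
                   for _, row in frame.iterrows()]
        table = cls(records=records, provenance=provenance or {})
        table._check_unique()
        return table


def _masks_by_name(lm: LabelMap) -> dict[str, np.ndarray]:
    return {name: lm.data == cid for cid, name in lm.vocabulary.items()}


def evaluate_case(
    pred: LabelMap,
    ref: LabelMap,
    mapping: ClassMapping,
    *,
    case_id: str = "case",
    sequence: str = "other",
    variant: str = "unprocessed",
) -> list[EvalRecord]:
    """Per-reference-class DSC of one prediction against one reference.

    For each reference class in ``mapping`` the prediction mask is the
    union of all prediction classes mapped to it.  Volumes are voxel
    count x voxel volume.  Both label maps must live on the same grid.
    """
    if pred.shape != ref.shape:
        raise GeometryError(f"grid mismatch: pred {pred.shape} vs ref {ref.shape}")
    pred_masks = _masks_by_name(pred)
    vox_cm3 = ref.voxel_volume_mm3 / 1000.0
    records = []
    for ref_class in mapping.reference_classes:
        try:
            ref_mask = ref.mask(ref.id_of(ref_class))
        except KeyError:
            ref_mask = np.zeros(ref.shape, dtype=bool)
        pred_mask = np.zeros(pred.shape, dtype=bool)
        for pred_class in mapping.prediction_classes_for(ref_class):
            if pred_class in pred_masks:
                pred_mask |= pred_masks[pred_class]
        records.append(
            EvalRecord(
                case_id=case_id,
                sequence=sequence,
                variant=variant,
                class_name=ref_class,
                dsc=dice(pred_mask, ref_mask),
                ref_volume_cm3=float(ref_mask.sum()) * vox_cm3,
                pred_volume_cm3=float(pred_mask.sum()) * vox_cm3,
            )
        )
    return records


def summarize(
    table: EvalTable | pd.DataFrame,
    group_by: Sequence[str] = ("sequence", "variant"),
    *,
    n_boot: int = 2000,
    seed: int = 0,
    level: str = "pooled",
) -> pd.DataFrame:
    """Mean DSC with 95% bootstrap CI per group.

    The CI is a seeded case-level percentile bootstrap: cases are
    resampled with replacement ``n_boot`` times and the group mean
    recomputed over the records of the drawn cases.  ``level='pooled'``
    averages over all (case, class) records in the group;
    ``level='per_class'`` first averages within each class, then across
    classes.  Undefined DSCs (NaN) are excluded and counted.
    """
    if level not in ("pooled", "per_class"):
        raise ValueError(f"level must be 'pooled' or 'per_class', got {level!r}")
    frame = table.to_frame() if isinstance(table, EvalTable) else table.copy()
    if frame.empty:
        raise ValueError("cannot summarize an empty table")
    rng = np.random.default_rng(seed)
    rows = []
    for group_key, sub in frame.groupby(list(group_by), sort=True):
        if not isinstance(group_key, tuple):
            group_key = (group_key,)
        defined = sub.dropna(subset=["dsc"])
        n_undefined = len(sub) - len(defined)
        if defined.empty:
            rows.append(dict(zip(group_by, group_key))
                        | {"mean_dsc": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                           "n_records": 0, "n_cases": 0, "n_undefined": n_undefined,
                           "empty_group": True})
            continue

        def group_mean(sub_frame: pd.DataFrame) -> float:
            if level == "per_class":
                return float(sub_frame.groupby("class_name")["dsc"].mean().mean())
            return float(sub_frame["dsc"].mean())

        cases = sorted(defined["case_id"].unique())
        by_case = {c: g for c, g in defined.groupby("case_id")}
        boots = np.empty(n_boot)
        for b in range(n_boot):
            drawn = rng.choice(cases, size=len(cases), replace=True)
            boots[b] = group_mean(pd.concat([by_case[c] for c in drawn]))
        rows.append(dict(zip(group_by, group_key))
                    | {"mean_dsc": group_mean(defined),
                       "ci_lo": float(np.percentile(boots, 2.5)),
                       "ci_hi": float(np.percentile(boots, 97.5)),
                       "n_records": len(defined), "n_cases": len(cases),
                       "n_undefined": n_undefined, "empty_group": False})
    return pd.DataFrame(rows)


def classify_localization(
    pred_tumor: np.ndarray,
    ref_tumor: np.ndarray,
    *,
    min_overlap_fraction: float = 0.0,
) -> str:
    """Categorize one tumor prediction as correct / incorrect / not_detected.

    ``not_detected`` if the prediction is empty; ``correct`` if the
    overlapping fraction of the reference exceeds
    ``min_overlap_fraction`` (default: any overlap counts);
    ``incorrect`` otherwise.  The reference must be non-empty.
    """
    pred_tumor = np.asarray(pred_tumor).astype(bool)
    ref_tumor = np.asarray(ref_tumor).astype(bool)
    if pred_tumor.shape != ref_tumor.shape:
        raise GeometryError("localization masks must share a grid")
    n_ref = int(ref_tumor.sum())
    if n_ref == 0:
        raise ValueError("reference tumor mask is empty; localization undefined")
    if not pred_tumor.any():
        return "not_detected"
    overlap = int(np.count_nonzero(pred_tumor & ref_tumor)) / n_ref
    return "correct" if overlap > min_overlap_fraction or (
        min_overlap_fraction == 0.0 and overlap > 0.0
    ) else "incorrect"


def stratify_by_volume(records: Sequence[EvalRecord] | pd.DataFrame) -> dict:
    """Median split of tumor DSC by reference volume.

    Records are split at the median ``ref_volume_cm3`` (strictly below
    vs at-or-above; the exact-median record joins the upper stratum) and
    the mean DSC of each stratum is returned.  An empty stratum — e.g.
    all volumes equal — is flagged with a NaN mean.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame([asdict(r) for r in records])
    frame = frame.dropna(subset=["ref_volume_cm3"])
    if len(frame) < 2:
        raise ValueError("need at least 2 records with defined volumes")
    median = float(frame["ref_volume_cm3"].median())
    below = frame[frame["ref_volume_cm3"] < median]
    above = frame[frame["ref_volume_cm3"] >= median]
    return {
        "median_volume_cm3": median,
        "n_below": len(below),
        "n_above": len(above),
        "mean_dsc_below": float(below["dsc"].mean()) if len(below) else float("nan"),
        "mean_dsc_above": float(above["dsc"].mean()) if len(above) else float("nan"),
        "empty_stratum": len(below) == 0 or len(above) == 0,
    }
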