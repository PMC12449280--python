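"""Canonical desk-scale study definitions.

Two studies summarize what the package demonstrates on synthetic data:

``direction_study``
    The sequence x preprocessing-variant grid (T1w/T2wfs x unprocessed/
    inverted/inverted-black) on a seeded phantom cohort, scored with the
    window backend — the synthetic analog of the tabulated mean-DSC
    comparison between preprocessing arms, including the paired
    Wilcoxon/BH statistics.

``tumor_volume_study``
    Lesion-focused run on T1w inverted-black only: per-case tumor DSC
    against lesion volume (log-uniform 1-200 cm3), Spearman correlation,
    median-volume stratification and localization counts.

Study problem sizes (cohort n, 72-voxel cubic grid at 2.5 mm, 1.5 mm
working resolution) are package defaults chosen for desk-scale runs;
both studies are fully deterministic given their master seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .backends import default_windows, make_window_backend
from .evaluation import (ClassMapping, classify_localization, dice,
                         stratify_by_volume)
from .inversion import preprocess
from .phantom import PhantomSpec, generate_cohort
from .pipeline import config_from_dict, run_experiment
from .stats import spearman
from .volume_io import resample_isotropic

__all__ = ["direction_study", "tumor_volume_study",
           "DEFAULT_GRID", "DEFAULT_SPACING_MM", "DEFAULT_RESAMPLE_MM"]

DEFAULT_GRID = (72, 72, 72)
DEFAULT_SPACING_MM = (2.5, 2.5, 2.5)
DEFAULT_RESAMPLE_MM = 1.5


def direction_study(master_seed: int, out_dir, n: int = 20,
                    n_boot: int = 2000) -> dict:
    """Run the full variant-grid experiment; returns the key tables.

    Returns a dict with ``summary`` (per sequence x variant mean DSC +
    CI), ``stats`` (pairwise Wilcoxon comparisons, BH-adjusted) and
    ``report_dir``.
    """
    out_dir = Path(out_dir)
    config = config_from_dict({
        "output_dir": str(out_dir),
        "data": {"phantom": {"n": n, "master_seed": int(master_seed),
                             "grid_shape": list(DEFAULT_GRID),
                             "spacing_mm": list(DEFAULT_SPACING_MM)}},
        "sequences": ["T1w", "T2wfs"],
        "variants": ["unprocessed", "inverted", "inverted_black"],
        "resample_mm": DEFAULT_RESAMPLE_MM,
        "bootstrap": {"n_boot": n_boot, "seed": int(master_seed)},
    }, base_dir=out_dir.parent)
    report_dir = run_experiment(config)
    return {
        "summary": pd.read_csv(report_dir / "summary.csv"),
        "stats": pd.read_csv(report_dir / "stats.csv"),
        "report_dir": report_dir,
    }


def tumor_volume_study(master_seed: int, n: int = 30,
                       volume_range_cm3: tuple[float, float] = (1.0, 200.0)) -> dict:
    """Tumor DSC vs lesion volume on T1w inverted-black.

    Returns per-case records plus the Spearman correlation, the
    median-volume stratification, and localization counts.
    """
    base = PhantomSpec(grid_shape=DEFAULT_GRID, spacing_mm=DEFAULT_SPACING_MM)
    cases = generate_cohort(n, master_seed=int(master_seed),
                            tumor_volume_range_cm3=volume_range_cm3,
                            base_spec=base)
    backend = make_window_backend(default_windows())
    rows = []
    outcomes = []
    for case in cases:
        truth = resample_isotropic(case.truth, DEFAULT_RESAMPLE_MM)
        t1 = resample_isotropic(case.t1, DEFAULT_RESAMPLE_MM)
        pred = backend(preprocess(t1, "inverted_black"))
        ref_mask = truth.mask(truth.id_of("tumor"))
        pred_mask = pred.mask(pred.id_of("tumor"))
        vox_cm3 = truth.voxel_volume_mm3 / 1000.0
        rows.append({
            "case_id": case.case_id,
            "ref_volume_cm3": float(ref_mask.sum()) * vox_cm3,
            "dsc": dice(pred_mask, ref_mask),
        })
        outcomes.append(classify_localization(pred_mask, ref_mask))
    records = pd.DataFrame(rows)
    corr = spearman(records["ref_volume_cm3"], records["dsc"])
    strata = stratify_by_volume(records.assign(
        case_id=records["case_id"], sequence="T1w", variant="inverted_black",
        class_name="tumor", pred_volume_cm3=np.nan))
    counts = {o: outcomes.count(o) for o in ("correct", "incorrect", "not_detected")}
    return {"records": records, "spearman": corr, "stratification": strata,
            "localization_counts": counts}
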