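"""Segmentation backends: intensity-window rules and external commands.

Two backends satisfy the same contract (a callable mapping a
:class:`~invertseg.volume_io.Volume` to a :class:`~invertseg.volume_io.LabelMap`
on the same grid):

``window_segment``
    A deterministic rule-based segmenter driven by a table of
    :class:`ClassWindow` rows.  Each window claims voxels whose
    intensity lies in ``[lo, hi]`` (optionally restricted to one side of
    the grid's midline sagittal plane), discards 26-connected components
    smaller than a physical size threshold, and assigns its class id to
    surviving voxels not already claimed by a higher-priority window.
    Because the windows encode CT intensity priors (air very dark, bone
    very bright, soft tissue in between), this backend behaves like a
    frozen CT-trained model: it works on CT-like intensity distributions
    and fails on un-inverted T1w-like ones.

``external_segment``
    A subprocess adapter for real segmentation tools (e.g. CNN models
    with pretrained weights).  The input volume is written to NIfTI, a
    command template with ``{input}``/``{output}`` placeholders is
    executed, and the resulting label map (single file, or a directory
    of per-class masks merged through an explicit name -> id JSON map)
    is read back.  Nothing is resampled or renamed silently.

The default abdominal window table shipped in ``data/ct_windows.json``
is matched to the phantom's CT intensity model; its numbers are package
defaults, not literature values.
"""

from __future__ import annotations

import json
import shlex
import subprocess
import tempfile
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .volume_io import LabelMap, Volume, read_labelmap, write_volume

__all__ = [
    "ClassWindow",
    "BackendError",
    "default_windows",
    "load_windows",
    "window_segment",
    "make_window_backend",
    "external_segment",
]

SIDE_CONSTRAINTS = ("none", "left_of_midline", "right_of_midline")

# Under the canonical (closest-to-RAS) affine the first array axis
# increases toward the patient's right, so patient-left is low index.
_CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=int)


class BackendError(RuntimeError):
    """An external segmentation command failed or produced no output."""


@dataclass(frozen=True)
class ClassWindow:
    """One rule of the window segmenter.

    ``priority`` resolves overlaps: higher-priority windows claim voxels
    first.  ``min_component_mm3`` drops 26-connected components below a
    physical volume.  ``side_constraint`` restricts the rule to one side
    of the grid's middle sagittal plane.
    """

    class_name: str
    lo: float
    hi: float
    min_component_mm3: float = 0.0
    side_constraint: str = "none"
    priority: int = 0

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError(f"{self.class_name}: lo must be < hi, got ({self.lo}, {self.hi})")
        if self.min_component_mm3 < 0:
            raise ValueError(f"{self.class_name}: min_component_mm3 must be >= 0")
        if self.side_constraint not in SIDE_CONSTRAINTS:
            raise ValueError(
                f"{self.class_name}: side_constraint must be one of {SIDE_CONSTRAINTS}"
            )


def load_windows(path) -> list[ClassWindow]:
    """Load a window table from a JSON file (list of ClassWindow fields)."""
    rows = json.loads(Path(path).read_text())
    return [ClassWindow(**row) for row in rows]


def default_windows() -> list[ClassWindow]:
    """The package's default abdominal CT window table."""
    text = resources.files("invertseg").joinpath("data/ct_windows.json").read_text()
    return [ClassWindow(**row) for row in json.loads(text)]


def _side_mask(shape: tuple[int, ...], side: str) -> np.ndarray | None:
    if side == "none":
        return None
    mid = shape[0] / 2.0
    idx = np.arange(shape[0])
    keep = idx < mid if side == "left_of_midline" else idx >= mid
    return keep[:, None, None]


def window_segment(v: Volume, windows: Sequence[ClassWindow]) -> LabelMap:
    """Segment a volume with a table of intensity windows.

    Windows are processed in descending priority (ties broken by table
    order).  For each one, candidate voxels are those inside
    ``[lo, hi]`` satisfying the side constraint; 26-connected components
    smaller than ``min_component_mm3`` are discarded; surviving voxels
    not yet assigned receive the window's class id (1-based, in table
    order).  Deterministic: identical input gives identical output.
    """
    if not windows:
        raise ValueError("window table must be non-empty")
    data = np.asarray(v.data)
    voxel_mm3 = v.voxel_volume_mm3
    out = np.zeros(data.shape, dtype=np.int16)
    ids = {w: i + 1 for i, w in enumerate(windows)}
    order = sorted(range(len(windows)), key=lambda i: (-windows[i].priority, i))
    for i in order:
        w = windows[i]
        candidate = (data >= w.lo) & (data <= w.hi)
        side = _side_mask(data.shape, w.side_constraint)
        if side is not None:
            candidate &= side
        if w.min_component_mm3 > 0 and candidate.any():
            labels, n = ndimage.label(candidate, structure=_CONNECTIVITY_26)
            if n:
                counts = np.bincount(labels.ravel())
                min_vox = w.min_component_mm3 / voxel_mm3
                small = np.flatnonzero(counts < min_vox)
                small = small[small > 0]
                if small.size:
                    candidate &= ~np.isin(labels, small)
        out[candidate & (out == 0)] = ids[w]
    vocabulary = {ids[w]: w.class_name for w in windows}
    return LabelMap(data=out, spacing=v.spacing.copy(), affine=v.affine.copy(),
                    vocabulary=vocabulary)


def make_window_backend(windows: Sequence[ClassWindow] | None = None) -> Callable[[Volume], LabelMap]:
    """A SegmenterContract callable closing over a window table."""
    table = list(windows) if windows is not None else default_windows()

    def backend(v: Volume) -> LabelMap:
        return window_segment(v, table)

    backend.vocabulary = tuple(w.class_name for w in table)  # type: ignore[attr-defined]
    return backend


def external_segment(
    command_template: str,
    v: Volume,
    workdir,
    *,
    class_map: Mapping[str, int] | None = None,
    timeout: float | None = None,
) -> LabelMap:
    """Run an external segmentation command on a volume.

    ``command_template`` must contain ``{input}`` and ``{output}``
    placeholders.  The volume is written to ``workdir/input.nii.gz``,
    the command is executed with the placeholders substituted, and the
    label map is read from the output path.  If the command writes a
    directory of per-class masks instead of a single file, ``class_map``
    (name -> id, e.g. loaded from a JSON file) selects and merges
    ``<name>.nii.gz`` files; ids follow the map explicitly.

    A non-zero exit status or a missing output raises
    :class:`BackendError` carrying the captured output; partial output
    files are removed.
    """
    if "{input}" not in command_template or "{output}" not in command_template:
        raise ValueError("command template must contain {input} and {output} placeholders")
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    in_path = workdir / "input.nii.gz"
    out_path = workdir / "output.nii.gz"
    write_volume(v, in_path)
    command = command_template.format(input=shlex.quote(str(in_path)),
                                      output=shlex.quote(str(out_path)))
    proc = subprocess.run(command, shell=True, capture_output=True, text=True,
                          timeout=timeout)
    if proc.returncode != 0:
        if out_path.exists():
            out_path.unlink()
        raise BackendError(
            f"backend command exited with status {proc.returncode}:\n"
            f"stdout: {proc.stdout}\nstderr: {proc.stderr}"
        )
    if out_path.is_dir() or (class_map and not out_path.exists()):
        return _merge_multifile(out_path if out_path.is_dir() else workdir, v, class_map)
    if not out_path.exists():
        raise BackendError(f"backend produced no output at {out_path}")
    lm = read_labelmap(out_path, vocabulary=None if class_map is None
                       else {int(i): n for n, i in class_map.items()})
    if lm.shape != v.shape:
        raise BackendError(f"backend output grid {lm.shape} does not match input {v.shape}")
    return lm


def _merge_multifile(directory: Path, v: Volume, class_map: Mapping[str, int] | None) -> LabelMap:
    if not class_map:
        raise BackendError("multi-file backend output requires an explicit name -> id map")
    merged = np.zeros(v.shape, dtype=np.int16)
    vocabulary: dict[int, str] = {}
    found = False
    for name, cid in sorted(class_map.items(), key=lambda kv: kv[1]):
        path = directory / f"{name}.nii.gz"
        if not path.exists():
            path = directory / f"{name}.nii"
        if not path.exists():
            continue
        found = True
        part = read_labelmap(path)
        if part.shape != v.shape:
            raise BackendError(f"{path}: grid {part.shape} does not match input {v.shape}")
        merged[part.data > 0] = int(cid)
        vocabulary[int(cid)] = name
    if not found:
        raise BackendError(f"no mapped class files found in {directory}")
    return LabelMap(data=merged, spacing=v.spacing.copy(), affine=v.affine.copy(),
                    vocabulary=vocabulary)
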