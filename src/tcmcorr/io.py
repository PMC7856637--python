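"""File I/O: NIfTI volumes and masks, timing/motion/label text formats."""

from __future__ import annotations

import re
from pathlib import Path

import nibabel as nib
import numpy as np

from .simulate import BoldRun, MotionParams

__all__ = [
    "ParseError",
    "save_volume",
    "load_volume",
    "save_mask",
    "load_mask",
    "save_run",
    "load_run",
    "write_onsets",
    "read_onsets",
    "write_motion",
    "read_motion",
    "format_noise_labels",
    "parse_noise_labels",
    "write_noise_labels",
    "read_noise_labels",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file (and line)."""


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])


def save_volume(data: np.ndarray, path, voxel_size_mm: float = 3.0, tr_s: float | None = None) -> None:
    img = nib.Nifti1Image(np.asarray(data, np.float64), _affine(voxel_size_mm))
    if tr_s is not None and data.ndim == 4:
        img.header.set_zooms((*img.header.get_zooms()[:3], tr_s))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, float, float | None]:
    """Returns (data, voxel_size_mm, tr_s or None)."""
    try:
        img = nib.load(str(path))
    except Exception as err:  # noqa: BLE001 - re-raise with file name
        raise ParseError(f"cannot read NIfTI file {path}: {err}") from err
    zooms = img.header.get_zooms()
    data = np.asarray(img.get_fdata())
    tr = float(zooms[3]) if data.ndim == 4 and len(zooms) > 3 else None
    return data, float(zooms[0]), tr


def save_mask(mask: np.ndarray, path, voxel_size_mm: float = 3.0) -> None:
    save_volume(np.asarray(mask, np.uint8), path, voxel_size_mm)


def load_mask(path) -> np.ndarray:
    data, _, _ = load_volume(path)
    return data > 0.5


def save_run(run: BoldRun, path) -> None:
    save_volume(run.data, path, run.voxel_size_mm, run.tr_s)


def load_run(path, tr_s: float | None = None) -> BoldRun:
    data, vox, tr = load_volume(path)
    if data.ndim != 4:
        raise ParseError(f"{path}: expected a 4D volume, got {data.ndim}D")
    if tr_s is None:
        tr_s = tr if tr and tr > 0 else 1.7
    return BoldRun(data=data, tr_s=tr_s, voxel_size_mm=vox)


def write_onsets(onsets_s, path) -> None:
    Path(path).write_text("".join(f"{t:.6g}\n" for t in onsets_s))


def read_onsets(path) -> tuple[float, ...]:
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            out.append(float(line))
        except ValueError as err:
            raise ParseError(f"{path}:{i}: not a number: {line!r}") from err
    return tuple(out)


def write_motion(motion: MotionParams, path) -> None:
    np.savetxt(path, motion.params, fmt="%.17g")


def read_motion(path) -> MotionParams:
    try:
        params = np.loadtxt(path, ndmin=2)
    except ValueError as err:
        raise ParseError(f"{path}: malformed motion table: {err}") from err
    if params.shape[1] != 6:
        raise ParseError(f"{path}: expected 6 columns, got {params.shape[1]}")
    return MotionParams(params=params)


def format_noise_labels(indices_zero_based) -> str:
    """FIX-style noise line: 1-based, comma-separated, bracketed."""
    ones = sorted(int(i) + 1 for i in indices_zero_based)
    return "[" + ", ".join(str(i) for i in ones) + "]"


def parse_noise_labels(text: str, source: str = "<string>") -> set[int]:
    """Parse a FIX-style noise line back to 0-based indices."""
    m = re.fullmatch(r"\s*\[\s*(.*?)\s*\]\s*", text, flags=re.S)
    if m is None:
        raise ParseError(f"{source}: expected a bracketed list, got {text!r}")
    body = m.group(1)
    if not body:
        return set()
    try:
        return {int(tok) - 1 for tok in body.split(",")}
    except ValueError as err:
        raise ParseError(f"{source}: non-integer component index in {text!r}") from err


def write_noise_labels(indices_zero_based, path) -> None:
    Path(path).write_text(format_noise_labels(indices_zero_based) + "\n")


def read_noise_labels(path) -> set[int]:
    return parse_noise_labels(Path(path).read_text(), source=str(path))
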