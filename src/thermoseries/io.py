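"""Plain-text readers and writers for thermogram sequences.

On-disk layout of one subject (the same layout the phantom writer emits and
the reader consumes; the adapter point for real floating-temperature
matrices):

    subject_dir/
        frame_000.txt ... frame_019.txt   whitespace-delimited degC grids
        mask.png | mask.pgm | mask.txt    binary RoI mask
        meta.json                         label, timing, pitch, seed

All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path

import numpy as np
from PIL import Image

from .phantom import ThermalFrame, ThermogramSequence

__all__ = [
    "ParseError",
    "read_temperature_matrix",
    "write_temperature_matrix",
    "read_mask",
    "write_mask",
    "write_sequence",
    "read_sequence",
    "write_json_atomic",
]


class ParseError(ValueError):
    """Malformed temperature-matrix file; carries the offending line."""

    def __init__(self, message: str, path, line_no: int):
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _atomic_write(path, write_fn) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            write_fn(fh)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json_atomic(path, obj) -> None:
    _atomic_write(path, lambda fh: json.dump(obj, fh, indent=2))


def read_temperature_matrix(path, pitch: float = 1e-3) -> ThermalFrame:
    """Read a whitespace-delimited numeric grid (degC).

    Raises :class:`ParseError` naming the line on ragged rows or
    non-numeric tokens.
    """
    rows = []
    width = None
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            try:
                row = [float(tok) for tok in tokens]
            except ValueError as exc:
                raise ParseError(f"non-numeric token: {exc}", path, line_no) from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise ParseError(
                    f"ragged row: expected {width} values, got {len(row)}",
                    path,
                    line_no,
                )
            rows.append(row)
    if not rows:
        raise ParseError("empty temperature matrix", path, 1)
    return ThermalFrame(np.asarray(rows, dtype=float), pitch)


def write_temperature_matrix(path, frame: ThermalFrame) -> None:
    def _write(fh):
        for row in frame.values:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")

    _atomic_write(path, _write)


def read_mask(path, expected_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Binary RoI mask from a PNG/PGM image or a 0/1 text grid.

    Nonzero pixels are inside the RoI.
    """
    path = Path(path)
    if path.suffix.lower() in {".png", ".pgm"}:
        arr = np.asarray(Image.open(path).convert("L"))
        mask = arr > 0
    else:
        mask = read_temperature_matrix(path).values > 0.5
    if expected_shape is not None and mask.shape != tuple(expected_shape):
        raise ValueError(
            f"mask shape {mask.shape} does not match frames {tuple(expected_shape)}"
        )
    return mask


def write_mask(path, mask: np.ndarray) -> None:
    path = Path(path)
    if path.suffix.lower() in {".png", ".pgm"}:
        img = Image.fromarray((mask.astype(np.uint8)) * 255, mode="L")
        fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=path.suffix)
        os.close(fd)
        img.save(tmp, format="PNG" if path.suffix.lower() == ".png" else "PPM")
        os.replace(tmp, path)
    else:
        frame = ThermalFrame(mask.astype(float), 1.0)
        write_temperature_matrix(path, frame)


def write_sequence(seq: ThermogramSequence, directory) -> Path:
    """Write one subject's sequence in the plain-text layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frame_files = []
    for i in range(seq.n_frames):
        name = f"frame_{i:03d}.txt"
        write_temperature_matrix(directory / name, seq.frame(i))
        frame_files.append(name)
    write_mask(directory / "mask.txt", seq.mask)
    meta = {
        "subject_id": seq.subject_id,
        "label": seq.label,
        "pitch_m": seq.pitch,
        "times_s": [float(t) for t in seq.times],
        "frames": frame_files,
        "mask": "mask.txt",
    }
    write_json_atomic(directory / "meta.json", meta)
    return directory


def read_sequence(directory) -> ThermogramSequence:
    """Read one subject's sequence from the plain-text layout."""
    directory = Path(directory)
    meta_path = directory / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"missing metadata file {meta_path}")
    with open(meta_path) as fh:
        meta = json.load(fh)
    pitch = float(meta["pitch_m"])
    frames = [
        read_temperature_matrix(directory / name, pitch).values
        for name in meta["frames"]
    ]
    mask_path = directory / meta["mask"]
    if not mask_path.exists():
        raise FileNotFoundError(f"missing mask file {mask_path}")
    frames = np.stack(frames)
    mask = read_mask(mask_path, expected_shape=frames.shape[1:])
    return ThermogramSequence(
        frames=frames,
        mask=mask,
        times=np.asarray(meta["times_s"], dtype=float),
        label=meta["label"],
        subject_id=meta["subject_id"],
        pitch=pitch,
    )
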