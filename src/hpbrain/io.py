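"""File input/output for images, time series and metadata sidecars.

Images travel as NIfTI (via nibabel); complex-valued stacks are stored as a
pair of real/imaginary volumes so any NIfTI viewer can open them.  Each image
carries a flat JSON sidecar (key -> scalar/string/list) holding acquisition
metadata and provenance.  Time series and tabular reports are CSV written
with fixed column order and formatting so repeated runs are byte identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Mapping, Optional, Union

import nibabel as nib
import numpy as np
import pandas as pd

PathLike = Union[str, Path]

#: Fixed float format used for all CSV output (byte-identical reruns).
CSV_FLOAT_FORMAT = "%.10g"


def _nifti(data: np.ndarray) -> nib.Nifti1Image:
    return nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine=np.eye(4))


def save_image(path: PathLike, data: np.ndarray,
               sidecar: Optional[Mapping] = None) -> None:
    """Save a real array as NIfTI, or a complex one as ``_real``/``_imag`` pair.

    ``path`` should end in ``.nii.gz``; a JSON sidecar with the same stem is
    written when metadata is given.
    """
    path = Path(path)
    data = np.asarray(data)
    if np.iscomplexobj(data):
        nib.save(_nifti(data.real), _component_path(path, "real"))
        nib.save(_nifti(data.imag), _component_path(path, "imag"))
    else:
        nib.save(_nifti(data), str(path))
    if sidecar is not None:
        save_sidecar(sidecar_path(path), sidecar)


def load_image(path: PathLike) -> np.ndarray:
    """Load a NIfTI image saved by :func:`save_image` (re-joining complex pairs)."""
    path = Path(path)
    real_p, imag_p = _component_path(path, "real"), _component_path(path, "imag")
    if Path(real_p).exists() and Path(imag_p).exists():
        real = np.asanyarray(nib.load(real_p).dataobj)
        imag = np.asanyarray(nib.load(imag_p).dataobj)
        return real + 1j * imag
    return np.asanyarray(nib.load(str(path)).dataobj)


def _component_path(path: Path, tag: str) -> str:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return str(path.with_name(name[: -len(suffix)] + f"_{tag}" + suffix))
    raise ValueError(f"image path must end in .nii or .nii.gz: {path}")


def sidecar_path(path: PathLike) -> Path:
    """JSON sidecar path corresponding to an image path."""
    path = Path(path)
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def save_sidecar(path: PathLike, metadata: Mapping) -> None:
    """Write a flat metadata dict as sorted, indented JSON (deterministic)."""
    clean = {}
    for key, value in metadata.items():
        if isinstance(value, (np.floating, np.integer)):
            value = value.item()
        elif isinstance(value, np.ndarray):
            value = value.tolist()
        elif isinstance(value, tuple):
            value = list(value)
        clean[str(key)] = value
    Path(path).write_text(json.dumps(clean, indent=2, sort_keys=True) + "\n")


def load_sidecar(path: PathLike) -> Dict:
    return json.loads(Path(path).read_text())


def save_series_csv(path: PathLike, frame_times: np.ndarray,
                    series: Mapping[str, np.ndarray]) -> None:
    """Write metabolite time courses as CSV with a ``time_s`` column.

    Complex series are stored by magnitude.  Column order follows the mapping
    order; output bytes are deterministic.
    """
    data = {"time_s": np.asarray(frame_times, dtype=float)}
    for name, values in series.items():
        values = np.asarray(values)
        if len(values) != len(data["time_s"]):
            raise ValueError(f"series {name!r} length does not match frame_times")
        data[name] = np.abs(values) if np.iscomplexobj(values) else values.astype(float)
    pd.DataFrame(data).to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT,
                              lineterminator="\n")


def load_series_csv(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def save_table_csv(path: PathLike, table: pd.DataFrame,
                   index: bool = True) -> None:
    """Write a report table as deterministic CSV."""
    table.to_csv(path, index=index, float_format=CSV_FLOAT_FORMAT,
                 lineterminator="\n")
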