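"""NIfTI and sidecar I/O.

T1 maps are written as NIfTI-1 with invalid voxels NaN-coded, so the
validity mask round-trips without a second file; label maps carry their
name->integer dictionary in a YAML sidecar next to the image.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .phantom import ROILabelMap
from .relaxometry import AcquisitionParams, QT1Volume

__all__ = [
    "save_qt1", "load_qt1", "save_labels", "load_labels",
    "save_acquisition", "load_acquisition",
]


def save_qt1(vol: QT1Volume, path: str | Path) -> None:
    data = np.where(vol.mask, vol.t1_map, np.nan).astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_xyzt_units("mm")
    img.header["descrip"] = f"qT1 [ms] session={vol.session}".encode()[:80]
    nib.save(img, str(path))


def load_qt1(path: str | Path, session: str | None = None) -> QT1Volume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if session is None:
        descrip = img.header["descrip"].tobytes().decode(errors="ignore")
        session = "noncontrast"
        for cand in QT1Volume.SESSIONS:
            if f"session={cand}" in descrip:
                session = cand
    return QT1Volume(data, img.affine, session, np.isfinite(data))


def _sidecar(path: Path) -> Path:
    name = path.name
    for suf in (".nii.gz", ".nii"):
        if name.endswith(suf):
            return path.with_name(name[: -len(suf)] + ".labels.yaml")
    return path.with_suffix(".labels.yaml")


def save_labels(labels: ROILabelMap, path: str | Path) -> None:
    path = Path(path)
    img = nib.Nifti1Image(labels.data.astype(np.int16), labels.affine)
    nib.save(img, str(path))
    _sidecar(path).write_text(yaml.safe_dump({"labels": labels.labels}))


def load_labels(path: str | Path) -> ROILabelMap:
    path = Path(path)
    img = nib.load(str(path))
    meta = yaml.safe_load(_sidecar(path).read_text())
    return ROILabelMap(np.asarray(img.dataobj).astype(np.int16), meta["labels"], img.affine)


def save_acquisition(acq: AcquisitionParams, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(
            {
                "repetition_time_ms": acq.repetition_time,
                "echo_time_ms": acq.echo_time,
                "flip_angles_deg": list(acq.flip_angles),
            }
        )
    )


def load_acquisition(path: str | Path) -> AcquisitionParams:
    d = yaml.safe_load(Path(path).read_text())
    return AcquisitionParams(
        repetition_time=float(d["repetition_time_ms"]),
        echo_time=float(d.get("echo_time_ms", 6.7)),
        flip_angles=tuple(float(a) for a in d["flip_angles_deg"]),
    )
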