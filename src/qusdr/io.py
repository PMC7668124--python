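"""On-disk containers: HDF5 RF frames, cohort manifests, feature tables.

One HDF5 file per frame holds the RF matrix (dataset ``rf``, axial sample x
scan line) with acquisition metadata as attributes, an optional ``roi``
raster, and an optional ``truth`` group of planted simulation parameters.
A cohort is a directory of frame files plus a CSV manifest with columns
patient_id, label, timepoint, path, followup_months, event.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .synthetic import AcquisitionGeometry, RFFrame, CohortDataset

__all__ = ["save_frame", "load_frame", "save_cohort", "load_manifest"]

_GEOM_ATTRS = {
    "sampling_rate_hz": "sampling_rate",
    "n_lines": "n_lines",
    "lateral_width_cm": "lateral_width",
    "depth_cm": "depth",
    "center_frequency_hz": "center_frequency",
    "pulse_bandwidth": "pulse_bandwidth",
    "speed_mps": "speed_of_sound",
}


def save_frame(frame: RFFrame, path, roi: np.ndarray | None = None) -> None:
    """Write one RF frame (and optional ROI raster) to an HDF5 file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as h5:
        ds = h5.create_dataset("rf", data=frame.samples.astype(np.float32))
        for attr, field in _GEOM_ATTRS.items():
            ds.attrs[attr] = getattr(frame.geometry, field)
        if roi is not None:
            h5.create_dataset("roi", data=roi.astype(np.uint8))
        if frame.truth:
            grp = h5.create_group("truth")
            for key, val in frame.truth.items():
                if isinstance(val, (int, float, str)):
                    grp.attrs[key] = val


def load_frame(path):
    """Read a frame written by :func:`save_frame`.

    Returns (frame, roi) where roi is None if the file stores no mask.
    """
    with h5py.File(path, "r") as h5:
        ds = h5["rf"]
        geom = AcquisitionGeometry(**{
            field: (int(ds.attrs[attr]) if field == "n_lines"
                    else float(ds.attrs[attr]))
            for attr, field in _GEOM_ATTRS.items()
        })
        samples = ds[()].astype(np.float64)
        roi = h5["roi"][()].astype(bool) if "roi" in h5 else None
        truth = dict(h5["truth"].attrs) if "truth" in h5 else None
    return RFFrame(samples=samples, geometry=geom, truth=truth), roi


def save_cohort(cohort: CohortDataset, out_dir) -> pd.DataFrame:
    """Write all cohort frames + the reference frame and return the manifest.

    The manifest CSV (``manifest.csv`` in ``out_dir``) has one row per
    patient scan; the reference frame is stored as ``reference.h5``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    save_frame(cohort.reference_frame, out_dir / "reference.h5")
    rows = []
    for patient in cohort.patients:
        for tp, frame in patient.frames.items():
            rel = f"{patient.id}_{tp}.h5"
            save_frame(frame, out_dir / rel, roi=patient.roi_mask)
            rows.append({
                "patient_id": patient.id, "label": patient.label,
                "timepoint": tp, "path": rel,
                "followup_months": patient.followup_months,
                "event": patient.event,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_manifest(cohort_dir) -> pd.DataFrame:
    """Read a cohort manifest, leaving frame loading to the caller."""
    cohort_dir = Path(cohort_dir)
    return pd.read_csv(cohort_dir / "manifest.csv")
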