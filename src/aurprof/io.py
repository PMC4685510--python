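"""Readers and writers for the package's plain-text interchange formats.

* Plate CSV (long format): ``plate_id, well, compound_id, assay_id,
  conc_nM, replicate, signal`` -- one row per well.
* ATP-titration CSV: ``enzyme_id, atp_uM, velocity``.
* Track CSV: one row per (track, frame) with the live-imaging annotations.
* Multi-channel TIFF + channel order metadata for image fields.
* Output tables: Ki table (compound x enzyme, mean +/- SD, n, bound flags)
  and selectivity-ratio matrix, as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cellular import CHANNEL_ROLES, ImageField
from .enzymology import (
    DoseResponseDataset,
    KiEstimate,
    SelectivityRatio,
    VelocityDataset,
    format_ratio,
)
from .live_events import CellTrack

__all__ = [
    "read_plate_csv",
    "read_atp_csv",
    "read_tracks_csv",
    "write_tracks_csv",
    "save_image_field",
    "load_image_field",
    "write_ki_table",
    "write_selectivity_table",
]

PLATE_COLUMNS = ["plate_id", "well", "compound_id", "assay_id",
                 "conc_nM", "replicate", "signal"]


def read_plate_csv(path) -> dict:
    """Load a long-format plate CSV into per-(compound, assay) datasets."""
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")
    out = {}
    for (compound, assay), grp in df.groupby(["compound_id", "assay_id"]):
        out[(compound, assay)] = DoseResponseDataset(
            inhibitor_conc=grp["conc_nM"].to_numpy(float),
            response=grp["signal"].to_numpy(float),
            compound_id=str(compound), assay_id=str(assay))
    return out


def read_atp_csv(path) -> dict:
    """Load an ATP-titration CSV into per-enzyme velocity datasets."""
    df = pd.read_csv(path)
    missing = {"enzyme_id", "atp_uM", "velocity"} - set(df.columns)
    if missing:
        raise ValueError(f"ATP CSV missing columns: {sorted(missing)}")
    return {
        str(enzyme): VelocityDataset(
            substrate_conc=grp["atp_uM"].to_numpy(float),
            velocity=grp["velocity"].to_numpy(float), enzyme_id=str(enzyme))
        for enzyme, grp in df.groupby("enzyme_id")
    }


TRACK_COLUMNS = ["track_id", "frame", "frame_interval_min", "pcna_foci_visible",
                 "nebd_frame", "mitosis_frame", "midbody_present",
                 "daughter_nuclei", "dose_nM", "compound_id"]


def write_tracks_csv(tracks: Sequence[CellTrack], path) -> None:
    """One row per (track, frame); track-level fields repeated on each row.

    Tracks without per-frame annotations (cytokinesis assay) get a single
    row with frame = -1.
    """
    rows = []
    for t in tracks:
        daughters = ";".join(str(d) for d in t.daughter_nuclei) \
            if t.daughter_nuclei is not None else ""
        common = dict(
            track_id=t.track_id, frame_interval_min=t.frame_interval,
            nebd_frame="" if t.nebd_frame is None else t.nebd_frame,
            mitosis_frame="" if t.mitosis_frame is None else t.mitosis_frame,
            midbody_present="" if t.midbody_present is None
            else int(t.midbody_present),
            daughter_nuclei=daughters, dose_nM=t.dose, compound_id=t.compound_id)
        if t.pcna_foci_visible:
            for f, vis in enumerate(t.pcna_foci_visible):
                rows.append({**common, "frame": f,
                             "pcna_foci_visible": int(vis)})
        else:
            rows.append({**common, "frame": -1, "pcna_foci_visible": ""})
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False)


def _opt_int(val):
    if pd.isna(val) or val == "":
        return None
    return int(val)


def read_tracks_csv(path) -> list[CellTrack]:
    """Load and validate a track CSV written by :func:`write_tracks_csv`."""
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"track CSV missing columns: {sorted(missing)}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        frames = grp["frame"].to_numpy(int)
        if len(frames) > 1 and np.any(np.diff(frames) <= 0):
            raise ValueError(f"track {tid!r}: frames not strictly increasing")
        first = grp.iloc[0]
        if frames[0] >= 0:
            visible = tuple(bool(int(v)) for v in grp["pcna_foci_visible"])
        else:
            visible = ()
        daughters = first["daughter_nuclei"]
        if pd.isna(daughters) or daughters == "":
            daughters = None
        else:
            daughters = tuple(int(x) for x in str(daughters).split(";"))
        midbody = first["midbody_present"]
        midbody = None if (pd.isna(midbody) or midbody == "") else bool(int(midbody))
        tracks.append(CellTrack(
            track_id=str(tid), frame_interval=float(first["frame_interval_min"]),
            pcna_foci_visible=visible, nebd_frame=_opt_int(first["nebd_frame"]),
            mitosis_frame=_opt_int(first["mitosis_frame"]),
            midbody_present=midbody, daughter_nuclei=daughters,
            dose=float(first["dose_nM"]), compound_id=str(first["compound_id"])))
    return tracks


def save_image_field(fld: ImageField, path) -> None:
    """Write a field as a 4-page TIFF (channel order in the image description)."""
    import tifffile

    stack = np.stack([fld.channels[k] for k in CHANNEL_ROLES]).astype(np.float32)
    meta = {"channels": list(CHANNEL_ROLES), "pixel_size_um": fld.pixel_size_um,
            "dose": fld.dose, "compound_id": fld.compound_id,
            "well": fld.well, "field_id": fld.field_id}
    tifffile.imwrite(path, stack, description=json.dumps(meta))


def load_image_field(path) -> ImageField:
    import tifffile

    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    channels = {k: stack[i].astype(float)
                for i, k in enumerate(meta["channels"])}
    return ImageField(channels=channels, pixel_size_um=meta["pixel_size_um"],
                      dose=meta["dose"], compound_id=meta["compound_id"],
                      well=meta["well"], field_id=meta["field_id"])


def write_ki_table(ki_table: Mapping[str, Mapping[str, KiEstimate]], path) -> None:
    """Ki summary CSV: one row per (compound, enzyme) with display rounding.

    ``ki_display`` rounds to 3 significant figures and renders upper bounds
    as "<x"; the unrounded mean/SD columns are retained for auditability.
    """
    rows = []
    for compound, per_enzyme in ki_table.items():
        for enzyme, est in per_enzyme.items():
            if est.is_upper_bound:
                display = f"<{est.bound_value:.3g}"
            else:
                display = f"{est.mean:.3g} ± {est.sd:.2g}"
            rows.append(dict(compound_id=compound, enzyme=enzyme,
                             ki_mean_nM=est.mean, ki_sd_nM=est.sd, n=est.n,
                             is_upper_bound=est.is_upper_bound,
                             bound_nM=est.bound_value, ki_display=display))
    pd.DataFrame(rows).to_csv(path, index=False)


def write_selectivity_table(ratios: Sequence[SelectivityRatio], path) -> None:
    rows = [dict(compound_id=r.compound_id, preferred=r.preferred_enzyme,
                 comparator=r.comparator_enzyme, ratio=r.ratio,
                 is_lower_bound=r.is_lower_bound, display=format_ratio(r))
            for r in ratios]
    pd.DataFrame(rows).to_csv(path, index=False)
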