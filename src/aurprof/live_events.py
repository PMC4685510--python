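"""Cell-cycle event calling from frame-indexed live-imaging annotations.

Two assays are supported, both built on manually annotated single-cell
tracks rather than raw pixels:

* **G2 duration** -- cells expressing GFP-PCNA and H2B-RFP are followed
  from the appearance of PCNA replication foci to the next mitosis.  The
  first frame in which the foci are no longer visible marks the start of
  G2, and nuclear envelope breakdown (NEBD) marks mitotic entry, so
  ``duration = (nebd_frame - start_frame) * frame_interval``.  G2
  lengthening is a specific readout of Aurora A inhibition.

* **Cytokinesis outcome** -- cells are followed through mitosis; the
  appearance of a microtubule midbody and two mononucleated daughters
  scores success, a binucleated daughter (or a single daughter with no
  midbody) scores failure.  Cytokinesis failure is the canonical cellular
  phenotype of Aurora B inhibition.

Per-dose summaries of either statistic are fitted with the same
variable-slope 4PL used for the biochemical curves.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .enzymology import LogisticFit, fit_fourpl

__all__ = [
    "CellTrack",
    "G2Duration",
    "CytokinesisCall",
    "InvalidTrackError",
    "call_g2_duration",
    "call_cytokinesis",
    "summarize_g2",
    "summarize_cytokinesis",
    "fit_event_dose_response",
]

log = logging.getLogger(__name__)


class InvalidTrackError(ValueError):
    """The track does not support the requested call (e.g. foci never seen)."""


@dataclass(frozen=True)
class CellTrack:
    """Frame-indexed annotations for one tracked cell.

    ``pcna_foci_visible[f]`` is the foci flag at frame f (frames are
    implicit 0..len-1); ``frame_interval`` is in minutes (12 for the G2
    assay, 5 for the cytokinesis assay).  ``daughter_nuclei`` holds the
    nucleus count of each daughter cell after mitosis (e.g. (1, 1) for two
    mononucleated daughters, (2,) for one binucleated daughter).
    """

    track_id: str
    frame_interval: float
    pcna_foci_visible: Sequence[bool] = field(default_factory=tuple)
    nebd_frame: int | None = None
    mitosis_frame: int | None = None
    midbody_present: bool | None = None
    daughter_nuclei: Sequence[int] | None = None
    dose: float = 0.0
    compound_id: str = ""

    def __post_init__(self):
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")
        object.__setattr__(self, "pcna_foci_visible",
                           tuple(bool(v) for v in self.pcna_foci_visible))
        if self.daughter_nuclei is not None:
            object.__setattr__(self, "daughter_nuclei",
                               tuple(int(d) for d in self.daughter_nuclei))


@dataclass(frozen=True)
class G2Duration:
    """G2 call for one track; duration is a multiple of frame_interval."""

    track_id: str
    duration_min: float
    start_frame: int
    nebd_frame: int


@dataclass(frozen=True)
class CytokinesisCall:
    outcome: Literal["success", "failure", "indeterminate"]
    track_id: str


def _defliker(visible: tuple) -> list:
    """Ignore 1-frame flickers: a single absent frame flanked by visible ones."""
    v = list(visible)
    for i in range(1, len(v) - 1):
        if not v[i] and visible[i - 1] and visible[i + 1]:
            v[i] = True
    return v


def call_g2_duration(track: CellTrack) -> G2Duration | None:
    """Call G2 duration: last foci frame + 1 -> NEBD, in minutes.

    Returns ``None`` for censored tracks (no NEBD within the imaging
    window), which are excluded from per-dose means.  Raises
    :class:`InvalidTrackError` when foci were never visible.
    """
    visible = _defliker(track.pcna_foci_visible)
    if not any(visible):
        raise InvalidTrackError(f"track {track.track_id}: PCNA foci never visible")
    last_visible = max(i for i, v in enumerate(visible) if v)
    start = last_visible + 1
    if track.nebd_frame is None:
        log.info("track %s censored: no NEBD within window", track.track_id)
        return None
    if track.nebd_frame < start:
        raise InvalidTrackError(
            f"track {track.track_id}: NEBD at frame {track.nebd_frame} "
            f"precedes foci dissolution at frame {start}")
    duration = (track.nebd_frame - start) * track.frame_interval
    return G2Duration(track_id=track.track_id, duration_min=float(duration),
                      start_frame=start, nebd_frame=track.nebd_frame)


def call_cytokinesis(track: CellTrack) -> CytokinesisCall:
    """Score cytokinesis from midbody and daughter-nucleation annotations.

    Failure: any binucleated daughter, or a single daughter with no
    midbody.  Success: midbody observed and two mononucleated daughters.
    Anything else (truncated window, missing annotations) is indeterminate.
    """
    if track.mitosis_frame is None or track.daughter_nuclei is None:
        return CytokinesisCall(outcome="indeterminate", track_id=track.track_id)
    d = track.daughter_nuclei
    if any(n >= 2 for n in d):
        return CytokinesisCall(outcome="failure", track_id=track.track_id)
    if track.midbody_present is False and len(d) == 1:
        return CytokinesisCall(outcome="failure", track_id=track.track_id)
    if track.midbody_present and len(d) == 2 and all(n == 1 for n in d):
        return CytokinesisCall(outcome="success", track_id=track.track_id)
    return CytokinesisCall(outcome="indeterminate", track_id=track.track_id)


def summarize_g2(tracks: Sequence[CellTrack]) -> dict:
    """Per-dose mean G2 duration (minutes) over uncensored, valid tracks."""
    by_dose: dict = {}
    for t in tracks:
        try:
            call = call_g2_duration(t)
        except InvalidTrackError:
            continue
        if call is None:
            continue
        by_dose.setdefault(t.dose, []).append(call.duration_min)
    return {dose: float(np.mean(vals)) for dose, vals in sorted(by_dose.items())}


def summarize_cytokinesis(tracks: Sequence[CellTrack]) -> dict:
    """Per-dose % cytokinesis failure over determinate tracks."""
    by_dose: dict = {}
    for t in tracks:
        call = call_cytokinesis(t)
        if call.outcome == "indeterminate":
            continue
        by_dose.setdefault(t.dose, []).append(call.outcome == "failure")
    return {dose: 100.0 * float(np.mean(flags))
            for dose, flags in sorted(by_dose.items())}


def fit_event_dose_response(per_dose: dict) -> LogisticFit:
    """Fit a 4PL to a per-dose event statistic (rising curves supported).

    ``per_dose`` maps dose (nM) to the statistic (mean G2 duration or %
    failure); a vehicle (dose 0) entry is required and at least 6 nonzero
    doses.  The fit midpoint is the assay IC50.
    """
    doses = np.asarray(sorted(per_dose), dtype=float)
    values = np.asarray([per_dose[d] for d in doses], dtype=float)
    if (doses > 0).sum() < 6:
        raise ValueError("need >= 6 nonzero doses")
    return fit_fourpl(doses, values, normalize=False)
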