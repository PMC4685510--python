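"""Image-based cellular potency quantification for Aurora kinase activity.

The readouts are two phospho-epitopes measured by immunofluorescence in
mitotic cells: pLATS2(Ser 83) at spindle poles (Aurora A activity) and
pH3(Ser 28) on mitotic chromatin (Aurora B activity).  Fields are imaged in
four channels (DNA, pLATS2, pH3, MPM2); mitotic cells are gated by bright
MPM2 labeling, phospho-objects are identified by intensity threshold plus
morphological erosion/dilation and an area filter, and the per-cell mean
object intensity feeds a per-well summary, control normalization, and an
IC50 / no-effect / partial classification of each dose-response curve.

Thresholds are meant to be fixed on vehicle (DMSO) wells and applied
unchanged to all inhibitor-treated wells of the same plate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats as _stats
from skimage import measure, morphology

from .enzymology import FitError, LogisticFit, fit_fourpl

__all__ = [
    "ImageField",
    "SegmentationParams",
    "MitoticCellMeasurement",
    "WellSummary",
    "NormalizedCurve",
    "CellularPotencyResult",
    "max_project",
    "auto_threshold",
    "segment_mitotic",
    "extract_phospho_objects",
    "measure_cells",
    "summarize_well",
    "normalize_to_control",
    "calibrate_thresholds",
    "analyze_field",
    "analyze_dose_series",
    "classify_potency",
    "box_quantify_pole",
    "mask_quantify_chromatin",
    "unpaired_t_test",
    "viability_normalize",
    "apoptotic_fraction",
]

CHANNEL_ROLES = ("dna", "plats2", "ph3", "mpm2")


@dataclass(frozen=True)
class ImageField:
    """One four-channel field: equal-shape 2-D rasters keyed by role."""

    channels: dict
    pixel_size_um: float = 1.0
    dose: float = 0.0
    compound_id: str = ""
    well: str = ""
    field_id: str = ""

    def __post_init__(self):
        missing = set(CHANNEL_ROLES) - set(self.channels)
        if missing:
            raise ValueError(f"missing channels: {sorted(missing)}")
        shapes = {np.asarray(v).shape for v in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")
        for k, v in self.channels.items():
            arr = np.asarray(v, dtype=float)
            if np.any(arr < 0):
                raise ValueError(f"channel {k!r} has negative intensities")
            self.channels[k] = arr

    @property
    def shape(self):
        return self.channels["dna"].shape


@dataclass(frozen=True)
class SegmentationParams:
    """Thresholds and morphology settings for mitotic-cell quantification.

    Intensity thresholds are in raw camera counts and should be frozen on
    vehicle wells.  Areas are px^2; the foci bounds apply to pLATS2 pole
    objects, the chromatin bounds to pH3 objects, and the cell bounds to
    MPM2 connected components.
    """

    mpm2_threshold: float
    plats2_threshold: float
    ph3_threshold: float
    erosion_radius: int = 1
    dilation_radius: int = 1
    foci_area: tuple = (4, 400)
    chromatin_area: tuple = (50, 5000)
    cell_area: tuple = (50, 5000)
    min_cells_per_well: int = 20

    def __post_init__(self):
        if self.erosion_radius < 0 or self.dilation_radius < 0:
            raise ValueError("morphology radii must be >= 0")
        for lo, hi in (self.foci_area, self.chromatin_area, self.cell_area):
            if not (0 < lo < hi):
                raise ValueError("area bounds must satisfy 0 < min < max")

    def marker_threshold(self, marker: str) -> float:
        return {"plats2": self.plats2_threshold, "ph3": self.ph3_threshold}[marker]

    def marker_area(self, marker: str) -> tuple:
        return {"plats2": self.foci_area, "ph3": self.chromatin_area}[marker]


@dataclass(frozen=True)
class MitoticCellMeasurement:
    """Per-cell mean object intensities within one MPM2-gated cell."""

    cell_id: int
    mean_plats2: float
    mean_ph3: float
    area_px: int


@dataclass(frozen=True)
class WellSummary:
    """Per-well mean of per-cell means, with the mitotic cell count."""

    well: str
    dose: float
    mean_plats2: float
    mean_ph3: float
    n_cells: int
    low_count: bool = False

    def marker_mean(self, marker: str) -> float:
        return {"plats2": self.mean_plats2, "ph3": self.mean_ph3}[marker]


@dataclass(frozen=True)
class NormalizedCurve:
    """Control-normalized dose-response of one marker (vehicle -> 1.0)."""

    marker: str
    doses: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.doses, dtype=float)
        v = np.asarray(self.values, dtype=float)
        order = np.argsort(d)
        object.__setattr__(self, "doses", d[order])
        object.__setattr__(self, "values", v[order])


@dataclass(frozen=True)
class CellularPotencyResult:
    """IC50 / no-effect / partial-inhibition call for one marker curve.

    Mirrors the vocabulary of published cellular-potency tables: an IC50 in
    nM when a full curve was obtained, ``NE@<top dose>`` when the top dose
    inhibits less than the no-effect threshold, and ``<x>% Inh@<top dose>``
    when there is a response but the curve does not reach a low plateau.
    """

    marker: str
    classification: Literal["IC50", "NE", "partial"]
    ic50: float | None
    top_dose: float
    percent_inhibition_at_top: float
    fit: LogisticFit | None = None

    def label(self) -> str:
        if self.classification == "IC50":
            return f"IC50 {self.ic50:.3g} nM"
        if self.classification == "NE":
            return f"NE@{self.top_dose:g} nM"
        return f"{self.percent_inhibition_at_top:.0f}% Inh@{self.top_dose:g} nM"


# ---------------------------------------------------------------------------
# Projection and segmentation
# ---------------------------------------------------------------------------


def max_project(planes: Sequence[ImageField]) -> ImageField:
    """Per-pixel maximum-intensity projection of a z-stack, per channel."""
    if len(planes) == 0:
        raise ValueError("need at least one plane")
    shape = planes[0].shape
    if any(p.shape != shape for p in planes):
        raise ValueError("all planes must share one shape")
    channels = {
        k: np.max(np.stack([p.channels[k] for p in planes]), axis=0)
        for k in CHANNEL_ROLES
    }
    return replace(planes[0], channels=channels)


def auto_threshold(background_pixels: np.ndarray, k: float = 5.0) -> float:
    """Vehicle-well auto-threshold: background level + k * background sigma.

    Background statistics are estimated robustly (median and MAD-derived
    sigma) so that the bright objects present in vehicle wells do not
    inflate the threshold.
    """
    bg = np.asarray(background_pixels, dtype=float).ravel()
    med = float(np.median(bg))
    sigma = 1.4826 * float(np.median(np.abs(bg - med)))
    return med + k * sigma


def segment_mitotic(fld: ImageField, params: SegmentationParams) -> np.ndarray:
    """Label mitotic cells: MPM2 >= threshold connected components, size-filtered.

    Returns an int label image (0 = background); an empty mask is valid.
    """
    mask = fld.channels["mpm2"] >= params.mpm2_threshold
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return labels
    lo, hi = params.cell_area
    counts = np.bincount(labels.ravel())
    bad = np.nonzero((counts < lo) | (counts > hi))[0]
    keep = np.ones(counts.size, dtype=bool)
    keep[bad] = False
    keep[0] = False
    labels[~keep[labels]] = 0
    return measure.label(labels > 0, connectivity=2)


def extract_phospho_objects(
    fld: ImageField, marker: Literal["plats2", "ph3"], params: SegmentationParams
) -> np.ndarray:
    """Binary phospho-object mask: threshold -> erode -> dilate -> area filter.

    With both radii 0 this reduces to a pure threshold plus area filter.
    """
    mask = fld.channels[marker] >= params.marker_threshold(marker)
    if params.erosion_radius > 0:
        mask = morphology.erosion(mask, morphology.disk(params.erosion_radius))
    if params.dilation_radius > 0:
        mask = morphology.dilation(mask, morphology.disk(params.dilation_radius))
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return mask
    lo, hi = params.marker_area(marker)
    counts = np.bincount(labels.ravel())
    keep = (counts >= lo) & (counts <= hi)
    keep[0] = False
    return keep[labels]


def measure_cells(
    cell_labels: np.ndarray,
    object_masks: dict,
    fld: ImageField,
) -> list[MitoticCellMeasurement]:
    """Per-cell mean marker intensity over (object mask ∩ cell footprint).

    Only MPM2-gated cells (nonzero labels) are measured; a cell with no
    surviving object pixels scores 0 for that marker.
    """
    out = []
    for lab in range(1, int(cell_labels.max()) + 1):
        cell = cell_labels == lab
        if not np.any(cell):
            continue
        means = {}
        for marker in ("plats2", "ph3"):
            px = cell & object_masks[marker]
            means[marker] = float(fld.channels[marker][px].mean()) if np.any(px) else 0.0
        out.append(MitoticCellMeasurement(
            cell_id=lab, mean_plats2=means["plats2"], mean_ph3=means["ph3"],
            area_px=int(cell.sum())))
    return out


def summarize_well(
    measurements: Sequence[MitoticCellMeasurement],
    *,
    well: str,
    dose: float,
    min_cells: int = 20,
) -> WellSummary:
    """Average per-cell means into a well summary (cells weighted equally)."""
    n = len(measurements)
    low = n < min_cells
    if low:
        warnings.warn(f"well {well!r}: only {n} mitotic cells (<{min_cells})",
                      stacklevel=2)
    if n == 0:
        return WellSummary(well=well, dose=dose, mean_plats2=float("nan"),
                           mean_ph3=float("nan"), n_cells=0, low_count=True)
    return WellSummary(
        well=well, dose=dose,
        mean_plats2=float(np.mean([m.mean_plats2 for m in measurements])),
        mean_ph3=float(np.mean([m.mean_ph3 for m in measurements])),
        n_cells=n, low_count=low)


# ---------------------------------------------------------------------------
# Curves and classification
# ---------------------------------------------------------------------------


def normalize_to_control(
    summaries: Sequence[WellSummary], marker: str
) -> NormalizedCurve:
    """Divide each dose's marker summary by the vehicle-well mean.

    Vehicle wells are those with dose == 0; their normalized value is 1.0
    by construction.  Low-count wells are excluded.
    """
    usable = [s for s in summaries if not s.low_count]
    controls = [s.marker_mean(marker) for s in usable if s.dose == 0]
    if not controls:
        raise ValueError("no usable vehicle (dose 0) well summaries")
    ctrl = float(np.mean(controls))
    if ctrl == 0:
        raise ValueError("vehicle-well mean is zero")
    doses, values = [], []
    for dose in sorted({s.dose for s in usable}):
        vals = [s.marker_mean(marker) for s in usable if s.dose == dose]
        doses.append(dose)
        values.append(float(np.mean(vals)) / ctrl)
    return NormalizedCurve(marker=marker, doses=np.asarray(doses),
                           values=np.asarray(values))


def classify_potency(
    curve: NormalizedCurve,
    *,
    ne_threshold: float = 0.20,
    partial_threshold: float = 0.50,
) -> CellularPotencyResult:
    """Classify a normalized curve as IC50, no-effect, or partial inhibition.

    NE: inhibition at the top dose is strictly below ``ne_threshold``.
    Partial: responsive, but the fitted bottom plateau stays above
    ``partial_threshold`` (fraction of control) or the fit does not
    converge.  Otherwise the 4PL IC50 is reported.
    """
    nonzero = curve.doses[curve.doses > 0]
    if len(nonzero) < 6:
        raise ValueError("potency classification needs >= 6 doses")
    top_dose = float(nonzero.max())
    top_value = float(curve.values[curve.doses == top_dose][0])
    pct_inh = 100.0 * (1.0 - top_value)
    if (1.0 - top_value) < ne_threshold:
        return CellularPotencyResult(marker=curve.marker, classification="NE",
                                     ic50=None, top_dose=top_dose,
                                     percent_inhibition_at_top=pct_inh)
    if 0.0 not in curve.doses:
        raise ValueError("curve must include the vehicle (dose 0) point")
    try:
        fit = fit_fourpl(curve.doses, curve.values, normalize=False,
                         ne_threshold=ne_threshold)
    except FitError:
        return CellularPotencyResult(marker=curve.marker, classification="partial",
                                     ic50=None, top_dose=top_dose,
                                     percent_inhibition_at_top=pct_inh)
    if fit.no_effect:
        return CellularPotencyResult(marker=curve.marker, classification="NE",
                                     ic50=None, top_dose=top_dose,
                                     percent_inhibition_at_top=pct_inh, fit=fit)
    if not np.isfinite(fit.bottom) or fit.bottom / fit.top > partial_threshold:
        return CellularPotencyResult(marker=curve.marker, classification="partial",
                                     ic50=None, top_dose=top_dose,
                                     percent_inhibition_at_top=pct_inh, fit=fit)
    return CellularPotencyResult(marker=curve.marker, classification="IC50",
                                 ic50=fit.ic50, top_dose=top_dose,
                                 percent_inhibition_at_top=pct_inh, fit=fit)


# ---------------------------------------------------------------------------
# End-to-end dose-series pipeline
# ---------------------------------------------------------------------------


def calibrate_thresholds(
    vehicle_fields: Sequence[ImageField], *, k: float = 5.0, **overrides
) -> SegmentationParams:
    """Freeze segmentation thresholds on vehicle (DMSO) fields.

    MPM2 gating uses an Otsu threshold on the pooled vehicle MPM2 channel
    (bright mitotic labeling is strongly bimodal); the pLATS2/pH3 object
    thresholds use mean + k*SD of the pooled vehicle marker channel.  The
    returned params are then applied unchanged to every inhibitor-treated
    field of the series.
    """
    from skimage.filters import threshold_otsu

    if len(vehicle_fields) == 0:
        raise ValueError("need at least one vehicle field")
    pooled = {m: np.concatenate([f.channels[m].ravel() for f in vehicle_fields])
              for m in ("mpm2", "plats2", "ph3")}
    return SegmentationParams(
        mpm2_threshold=float(threshold_otsu(pooled["mpm2"])),
        plats2_threshold=auto_threshold(pooled["plats2"], k),
        ph3_threshold=auto_threshold(pooled["ph3"], k),
        **overrides)


def analyze_field(fld: ImageField, params: SegmentationParams):
    """Gate, extract objects and measure one field; returns the cell list."""
    cells = segment_mitotic(fld, params)
    objects = {m: extract_phospho_objects(fld, m, params)
               for m in ("plats2", "ph3")}
    return measure_cells(cells, objects, fld)


def analyze_dose_series(
    fields_by_dose: Mapping[float, Sequence[ImageField]],
    params: SegmentationParams | None = None,
    *,
    k: float = 5.0,
):
    """Run the full quantification on a dose series of image fields.

    ``fields_by_dose`` maps dose (nM) to that well's fields; dose 0 must be
    present (it calibrates thresholds when ``params`` is None and anchors
    normalization).  Returns ``(curves, summaries, params)`` where
    ``curves`` maps marker to its control-normalized dose-response.
    """
    if 0.0 not in fields_by_dose:
        raise ValueError("dose series must include vehicle (dose 0) fields")
    if params is None:
        params = calibrate_thresholds(fields_by_dose[0.0], k=k)
    summaries = []
    for dose, fields in sorted(fields_by_dose.items()):
        measurements = []
        for fld in fields:
            measurements.extend(analyze_field(fld, params))
        summaries.append(summarize_well(
            measurements, well=f"dose-{dose:g}", dose=dose,
            min_cells=params.min_cells_per_well))
    curves = {m: normalize_to_control(summaries, m) for m in ("plats2", "ph3")}
    return curves, summaries, params


# ---------------------------------------------------------------------------
# Box/mask quantification variants (RNAi validation style)
# ---------------------------------------------------------------------------


def box_quantify_pole(
    fld: ImageField,
    pole_rc: tuple,
    background_rc: tuple,
    *,
    box: int = 10,
) -> float:
    """Integrated pLATS2 signal in a box at a spindle pole, background-subtracted.

    ``pole_rc`` and ``background_rc`` are (row, col) box centers; the same
    ``box`` x ``box`` integration window is used for both, and the
    background (cytoplasm) integral is subtracted from the pole integral.
    """
    img = fld.channels["plats2"]

    def integrate(rc):
        r0 = int(round(rc[0])) - box // 2
        c0 = int(round(rc[1])) - box // 2
        if r0 < 0 or c0 < 0 or r0 + box > img.shape[0] or c0 + box > img.shape[1]:
            raise ValueError(f"{box}x{box} box at {rc} out of field bounds")
        return float(img[r0:r0 + box, c0:c0 + box].sum())

    return integrate(pole_rc) - integrate(background_rc)


def mask_quantify_chromatin(
    fld: ImageField,
    *,
    dna_threshold: float | None = None,
    expand_px: int = 20,
) -> float:
    """Mean pH3 inside the DNA mask minus the mean in a surrounding annulus.

    The DNA channel is thresholded (Otsu when no explicit threshold is
    given) to define chromatin; the background region is the ``expand_px``
    dilation of that mask minus the mask itself.
    """
    from skimage.filters import threshold_otsu

    dna = fld.channels["dna"]
    thr = threshold_otsu(dna) if dna_threshold is None else dna_threshold
    mask = dna >= thr
    if not np.any(mask):
        raise ValueError("empty DNA mask; no chromatin measurement")
    expanded = morphology.isotropic_dilation(mask, expand_px)
    annulus = expanded & ~mask
    ph3 = fld.channels["ph3"]
    bg = float(ph3[annulus].mean()) if np.any(annulus) else 0.0
    return float(ph3[mask].mean()) - bg


def unpaired_t_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided unpaired (independent two-sample) t-test: returns (t, p).

    Degenerate zero-variance groups with equal means return (0, 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        return 0.0, 1.0
    t, p = _stats.ttest_ind(a, b)
    return float(t), float(p)


# ---------------------------------------------------------------------------
# Viability and apoptosis
# ---------------------------------------------------------------------------


def viability_normalize(
    doses, luminescence, *, marker: str = "viability"
) -> NormalizedCurve:
    """Relative-proliferation curve: per-dose luminescence over the vehicle mean.

    ``doses`` and ``luminescence`` are matched per-well arrays; wells with
    dose 0 are the vehicle controls.  The result feeds
    :func:`classify_potency` for cytotoxicity flagging.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(luminescence, dtype=float)
    if d.shape != y.shape:
        raise ValueError("doses and luminescence must have equal length")
    ctrl = y[d == 0]
    if ctrl.size == 0 or ctrl.mean() == 0:
        raise ValueError("missing or zero vehicle wells")
    uniq = np.sort(np.unique(d))
    values = np.array([y[d == u].mean() for u in uniq]) / ctrl.mean()
    return NormalizedCurve(marker=marker, doses=uniq, values=values)


def apoptotic_fraction(caspase_positive: int, nuclei: int) -> float:
    """Fraction of apoptotic cells: caspase-reporter-positive over nuclei."""
    if nuclei <= 0:
        raise ValueError("nuclei count must be > 0")
    if caspase_positive < 0 or caspase_positive > nuclei:
        raise ValueError("caspase-positive count must be in [0, nuclei]")
    return caspase_positive / nuclei
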