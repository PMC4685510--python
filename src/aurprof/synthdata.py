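"""Synthetic inputs with the statistical structure the analysis assumes.

Every generator is fully deterministic under a fixed seed and returns a
ground-truth record alongside the data, so each pipeline stage can be tested
for parameter recovery without any external downloads:

* ``simulate_biochem_plate`` -- tight-binding (Morrison) inhibitor curves
  with multiplicative plate-reader noise,
* ``simulate_mm_titration`` -- Michaelis-Menten ATP titrations,
* ``render_image_field`` -- four-channel immunofluorescence fields with
  MPM2-bright mitotic cells carrying pole foci (pLATS2) and a chromatin
  blob (pH3) whose intensities follow a per-marker 4PL of dose,
* ``simulate_tracks`` -- live-imaging cell tracks with dose-dependent G2
  duration and cytokinesis-failure probability.

Default parameter values encode the study conditions of the assays being
emulated: [E]t = 0.4 nM active kinase in the reaction, [ATP] = Km, 24-point
triplicate dose curves at 2% CV, 12-min (G2) and 5-min (cytokinesis) frame
intervals over a 24-h imaging window, and 40-100 tracks per dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .cellular import ImageField
from .enzymology import (
    DoseResponseDataset,
    VelocityDataset,
    morrison_fractional_activity,
)
from .live_events import CellTrack

__all__ = [
    "BiochemSpec",
    "MMTitrationSpec",
    "ImagingSpec",
    "LiveSpec",
    "SimulationSpec",
    "simulate_biochem_plate",
    "simulate_mm_titration",
    "render_image_field",
    "simulate_tracks",
    "logistic_fraction",
]


def logistic_fraction(dose, ic50: float, hill: float):
    """Falling 4PL fraction in [0, 1]: 1 at dose 0, 1/2 at dose = ic50."""
    dose = np.asarray(dose, dtype=float)
    frac = np.where(dose > 0, 1.0 / (1.0 + (dose / ic50) ** hill), 1.0)
    return frac if frac.ndim else float(frac)


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiochemSpec:
    """Conditions of one simulated inhibitor dose-response experiment.

    ``Ki`` in nM, ``Et`` (total active enzyme) in nM; ``s_over_km`` is
    [S]/Km (1.0: assay run at [ATP] = Km, giving Ki_app = 2*Ki).  The dose
    grid is log-spaced over ``dose_decades`` decades centred on the expected
    IC50 = Ki_app + Et/2, mimicking a plate titration designed around the
    compound's expected potency.
    """

    Ki: float = 1.0
    Et: float = 0.4
    s_over_km: float = 1.0
    n_doses: int = 24
    n_replicates: int = 3
    dose_decades: float = 2.5
    cv: float = 0.02
    v0: float = 1.0e6

    def __post_init__(self):
        if self.Ki < 0 or self.Et <= 0 or self.s_over_km <= 0:
            raise ValueError("Ki >= 0, Et > 0 and s_over_km > 0 required")
        if self.cv < 0 or self.v0 <= 0:
            raise ValueError("cv >= 0 and v0 > 0 required")

    @property
    def ki_app(self) -> float:
        return self.Ki * (1.0 + self.s_over_km)

    @property
    def expected_ic50(self) -> float:
        return self.ki_app + self.Et / 2.0

    def dose_grid(self) -> np.ndarray:
        half = self.dose_decades / 2.0
        return np.logspace(np.log10(self.expected_ic50) - half,
                           np.log10(self.expected_ic50) + half, self.n_doses)


@dataclass(frozen=True)
class MMTitrationSpec:
    """ATP-titration conditions: Km in uM, Vmax in signal units/time."""

    Km: float = 35.0
    Vmax: float = 1.0
    n_points: int = 8
    conc_decades: float = 3.0
    cv: float = 0.03

    def conc_grid(self) -> np.ndarray:
        half = self.conc_decades / 2.0
        return np.logspace(np.log10(self.Km) - half,
                           np.log10(self.Km) + half, self.n_points)


@dataclass(frozen=True)
class ImagingSpec:
    """Geometry, intensities and ground-truth pharmacology of image fields.

    Marker object intensities sit well above the background so that the
    un-subtracted object-mean readout is, to within ~2%, proportional to
    the planted activity fraction.  Foci and chromatin are uniform-intensity
    disks for the same reason: the mean over a thresholded object mask then
    scales linearly with the planted 4PL fraction, so the planted IC50 is
    the true midpoint of the measured curve.
    """

    shape: tuple = (256, 256)
    cells_per_field: int = 16
    mitotic_fraction: float = 0.5
    cell_radius: float = 11.0
    focus_radius: float = 2.2
    chromatin_radius: float = 4.5
    mpm2_amplitude: float = 600.0
    plats2_amplitude: float = 500.0
    ph3_amplitude: float = 450.0
    dna_amplitude: float = 300.0
    background: float = 10.0
    noise_sd: float = 5.0
    cell_cv: float = 0.10
    plats2_ic50: float = 600.0   # nM; None-like: set responsive=False instead
    ph3_ic50: float = 50.0
    hill: float = 1.5
    plats2_responsive: bool = True
    ph3_responsive: bool = True
    fields_per_dose: int = 4

    def marker_fraction(self, marker: str, dose: float) -> float:
        """Planted activity fraction for a marker at a dose."""
        if marker == "plats2":
            if not self.plats2_responsive:
                return 1.0
            return logistic_fraction(dose, self.plats2_ic50, self.hill)
        if marker == "ph3":
            if not self.ph3_responsive:
                return 1.0
            return logistic_fraction(dose, self.ph3_ic50, self.hill)
        raise ValueError(f"unknown marker {marker!r}")


@dataclass(frozen=True)
class LiveSpec:
    """Ground truth for live-imaging cohorts.

    G2 durations are Normal(baseline + shift*r(dose), sd) minutes rounded to
    the frame grid, where r is a rising 4PL; cytokinesis failures are
    Bernoulli with probability baseline + (max-baseline)*r(dose).  The two
    effects are controlled by independent midpoints so that a compound can
    lengthen G2 (Aurora A inhibition) without causing cytokinesis failure
    (Aurora B inhibition), and vice versa.
    """

    g2_baseline: float = 240.0     # min
    g2_sd: float = 45.0            # min
    g2_max_shift: float = 360.0    # min, at saturating Aurora A inhibition
    g2_ic50: float = 800.0         # nM
    g2_hill: float = 1.5
    g2_frame_interval: float = 12.0  # min
    cyto_baseline: float = 0.05
    cyto_max: float = 0.90
    cyto_ic50: float = 600.0       # nM
    cyto_hill: float = 1.5
    cyto_frame_interval: float = 5.0  # min
    window_hours: float = 24.0
    tracks_per_dose: int = 60

    def g2_mean(self, dose: float) -> float:
        rise = 1.0 - logistic_fraction(dose, self.g2_ic50, self.g2_hill)
        return self.g2_baseline + self.g2_max_shift * rise

    def failure_prob(self, dose: float) -> float:
        rise = 1.0 - logistic_fraction(dose, self.cyto_ic50, self.cyto_hill)
        return self.cyto_baseline + (self.cyto_max - self.cyto_baseline) * rise


@dataclass(frozen=True)
class SimulationSpec:
    """Bundle of all generator regimes plus the mandatory seed."""

    seed: int
    biochem: BiochemSpec = field(default_factory=BiochemSpec)
    mm: MMTitrationSpec = field(default_factory=MMTitrationSpec)
    imaging: ImagingSpec = field(default_factory=ImagingSpec)
    live: LiveSpec = field(default_factory=LiveSpec)


# ---------------------------------------------------------------------------
# Biochemical generators
# ---------------------------------------------------------------------------


def simulate_biochem_plate(
    spec: BiochemSpec, seed: int, *, compound_id: str = "sim", assay_id: str = "sim"
):
    """Simulate one tight-binding inhibitor plate.

    Responses are v0 * morrison(v/v0)(I; Et, Ki_app) * (1 + eps) with
    eps ~ Normal(0, cv), i.e. multiplicative luminescence noise.  Returns
    ``(DoseResponseDataset, truth)`` where ``truth`` records Ki, Ki_app,
    Et and the expected IC50 = Ki_app + Et/2.
    """
    rng = np.random.default_rng(seed)
    doses = spec.dose_grid()
    conc = np.concatenate([np.zeros(spec.n_replicates),
                           np.repeat(doses, spec.n_replicates)])
    frac = morrison_fractional_activity(conc, spec.Et, spec.ki_app)
    noise = 1.0 + spec.cv * rng.standard_normal(conc.shape)
    response = spec.v0 * np.asarray(frac) * noise
    ds = DoseResponseDataset(inhibitor_conc=conc, response=response,
                             compound_id=compound_id, assay_id=assay_id)
    truth = {"Ki": spec.Ki, "Ki_app": spec.ki_app, "Et": spec.Et,
             "ic50": spec.expected_ic50, "v0": spec.v0}
    return ds, truth


def simulate_mm_titration(spec: MMTitrationSpec, seed: int, *, enzyme_id: str = "sim"):
    """Simulate an ATP titration: v = Vmax*S/(Km+S) with multiplicative noise."""
    rng = np.random.default_rng(seed)
    S = spec.conc_grid()
    v = spec.Vmax * S / (spec.Km + S)
    v = v * (1.0 + spec.cv * rng.standard_normal(S.shape))
    ds = VelocityDataset(substrate_conc=S, velocity=np.clip(v, 0.0, None),
                         enzyme_id=enzyme_id)
    return ds, {"Km": spec.Km, "Vmax": spec.Vmax}


# ---------------------------------------------------------------------------
# Image-field renderer
# ---------------------------------------------------------------------------


def _disk_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _place_centers(rng, shape, n, radius, max_tries=2000):
    """Rejection-sample non-overlapping cell centers; may return fewer."""
    centers = []
    margin = radius + 2
    for _ in range(max_tries):
        if len(centers) >= n:
            break
        c = (rng.uniform(margin, shape[0] - margin),
             rng.uniform(margin, shape[1] - margin))
        if all((c[0] - o[0]) ** 2 + (c[1] - o[1]) ** 2 > (2.2 * radius) ** 2
               for o in centers):
            centers.append(c)
    return centers


def render_image_field(spec: ImagingSpec, dose: float, seed: int, *,
                       compound_id: str = "sim", well: str = "", field_id: str = ""):
    """Render one four-channel field at a dose; returns (ImageField, truth).

    Mitotic cells get a bright MPM2 disk, two pole foci in the pLATS2
    channel and a chromatin disk in the pH3 channel; marker amplitudes are
    scaled by the marker's 4PL fraction of dose and a per-cell lognormal
    factor (CV ``cell_cv``).  Interphase cells show only DNA.  Gaussian
    camera noise (sd ``noise_sd``) is added to all channels, which are then
    clipped at zero.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(spec.shape)
    chans = {k: np.full(shape, spec.background, dtype=float)
             for k in ("dna", "plats2", "ph3", "mpm2")}

    centers = _place_centers(rng, shape, spec.cells_per_field, spec.cell_radius)
    if len(centers) < spec.cells_per_field:
        import warnings
        warnings.warn(
            f"placed {len(centers)}/{spec.cells_per_field} cells "
            "(packing infeasible)", stacklevel=2)
    n_mitotic = int(round(len(centers) * spec.mitotic_fraction))
    cells = []
    f_plats2 = spec.marker_fraction("plats2", dose)
    f_ph3 = spec.marker_fraction("ph3", dose)
    for i, c in enumerate(centers):
        mitotic = i < n_mitotic
        chans["dna"][_disk_mask(shape, c, spec.cell_radius * 0.7)] += spec.dna_amplitude
        rec = {"center": c, "mitotic": mitotic}
        if mitotic:
            chans["mpm2"][_disk_mask(shape, c, spec.cell_radius)] += spec.mpm2_amplitude
            scale = rng.lognormal(mean=0.0, sigma=spec.cell_cv)
            # two pole foci, symmetric about the cell center
            angle = rng.uniform(0, np.pi)
            off = spec.cell_radius * 0.55
            d = np.array([np.cos(angle), np.sin(angle)]) * off
            amp_p = spec.plats2_amplitude * scale * f_plats2
            for sgn in (+1, -1):
                pole = (c[0] + sgn * d[0], c[1] + sgn * d[1])
                chans["plats2"][_disk_mask(shape, pole, spec.focus_radius)] += amp_p
            amp_h = spec.ph3_amplitude * scale * f_ph3
            chans["ph3"][_disk_mask(shape, c, spec.chromatin_radius)] += amp_h
            rec.update({"plats2_amplitude": amp_p, "ph3_amplitude": amp_h,
                        "scale": scale})
        cells.append(rec)

    for k in chans:
        chans[k] = np.clip(
            chans[k] + spec.noise_sd * rng.standard_normal(shape), 0.0, None)

    fld = ImageField(channels=chans, pixel_size_um=0.325, dose=dose,
                     compound_id=compound_id, well=well, field_id=field_id)
    truth = {"cells": cells, "f_plats2": f_plats2, "f_ph3": f_ph3,
             "n_mitotic": n_mitotic}
    return fld, truth


# ---------------------------------------------------------------------------
# Live-imaging track generator
# ---------------------------------------------------------------------------


def simulate_tracks(
    spec: LiveSpec, dose: float, seed: int,
    assay: Literal["g2", "cytokinesis"], *, compound_id: str = "sim",
):
    """Simulate a cohort of annotated cell tracks at one dose.

    ``assay='g2'``: tracks carry a PCNA-foci-visible epoch followed by a
    foci-absent (G2) epoch ending at NEBD; the planted G2 duration is
    Normal(mean(dose), sd) truncated at one frame and rounded to the frame
    grid.  ``assay='cytokinesis'``: tracks carry a mitosis and post-mitotic
    midbody/daughter-nuclei annotations with failure ~ Bernoulli(p(dose)).
    Returns ``(tracks, truth)``.
    """
    rng = np.random.default_rng(seed)
    tracks: list[CellTrack] = []
    if assay == "g2":
        interval = spec.g2_frame_interval
        n_frames = int(spec.window_hours * 60 / interval)
        mean = spec.g2_mean(dose)
        durations = []
        for i in range(spec.tracks_per_dose):
            dur_frames = max(1, int(round(
                rng.normal(mean, spec.g2_sd) / interval)))
            foci_end = int(rng.integers(3, 10))  # last foci-visible frame
            nebd = foci_end + 1 + dur_frames  # G2 starts the frame after foci_end
            n = min(nebd + 2, n_frames)
            if nebd >= n:  # censored: window ends before NEBD
                nebd_frame = None
                n = n_frames
            else:
                nebd_frame = nebd
            visible = [f <= foci_end for f in range(n)]
            tracks.append(CellTrack(
                track_id=f"g2-{dose:g}-{i}", frame_interval=interval,
                pcna_foci_visible=visible, nebd_frame=nebd_frame,
                dose=dose, compound_id=compound_id))
            durations.append(dur_frames * interval)
        truth = {"mean": mean, "durations": durations}
    elif assay == "cytokinesis":
        interval = spec.cyto_frame_interval
        p = spec.failure_prob(dose)
        fails = rng.random(spec.tracks_per_dose) < p
        for i, failed in enumerate(fails):
            if failed:
                # binucleated single daughter, no midbody
                daughters, midbody = (2,), False
            else:
                daughters, midbody = (1, 1), True
            tracks.append(CellTrack(
                track_id=f"ck-{dose:g}-{i}", frame_interval=interval,
                pcna_foci_visible=[], mitosis_frame=10,
                midbody_present=midbody, daughter_nuclei=daughters,
                dose=dose, compound_id=compound_id))
        truth = {"p_failure": p, "n_failures": int(fails.sum())}
    else:
        raise ValueError("assay must be 'g2' or 'cytokinesis'")
    return tracks, truth
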