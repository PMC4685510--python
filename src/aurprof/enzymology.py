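"""Biochemical potency analysis for ATP-competitive kinase inhibitors.

Implements the workflow used to turn plate-reader dose-response data into
equilibrium inhibition constants (Ki) under tight-binding conditions:

1. estimate Km(ATP) from a substrate titration (Michaelis-Menten fit),
2. estimate the total *active* enzyme concentration [E]t from an inhibitor
   titration run with [E]t, [I] >> Ki, where IC50 ~ [E]t/2,
3. fit a variable-slope four-parameter logistic (4PL) to each inhibitor
   dose-response curve to obtain an IC50,
4. convert IC50 to Ki with the tight-binding correction

       Ki = (IC50 - [E]t/2) / (1 + [S]/Km)

   which reduces to the Cheng-Prusoff relation Ki = IC50/(1 + [S]/Km)
   when [E]t is negligible, and to Ki = (IC50 - [E]t/2)/2 when the assay
   is run at [S] = Km,
5. aggregate replicate experiments (mean +/- sample SD) and compute fold
   selectivity ratios between enzyme species.

Concentration units are nM for inhibitors and enzyme, uM for ATP.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "VelocityDataset",
    "KineticConstants",
    "DoseResponseDataset",
    "LogisticFit",
    "TightBindingContext",
    "KiConversion",
    "KiEstimate",
    "SelectivityRatio",
    "FitError",
    "fit_michaelis_menten",
    "fit_fourpl",
    "fit_four_parameter_logistic",
    "estimate_active_enzyme",
    "ic50_to_ki",
    "morrison_fractional_activity",
    "aggregate_ki",
    "compute_selectivity_ratios",
    "format_ratio",
]


class FitError(RuntimeError):
    """A nonlinear fit failed to converge or the input is degenerate."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VelocityDataset:
    """ATP-titration data: reaction velocity versus substrate concentration.

    ``substrate_conc`` is in uM; ``velocity`` may be raw end-point signal or
    signal per unit time (the Km estimate is invariant to that scale).
    """

    substrate_conc: np.ndarray
    velocity: np.ndarray
    enzyme_id: str = ""

    def __post_init__(self):
        s = np.asarray(self.substrate_conc, dtype=float)
        v = np.asarray(self.velocity, dtype=float)
        if s.shape != v.shape:
            raise ValueError("substrate_conc and velocity must have equal length")
        if np.any(s < 0) or np.any(v < 0):
            raise ValueError("concentrations and velocities must be non-negative")
        if len(np.unique(s)) < 5:
            raise ValueError("need at least 5 distinct substrate concentrations")
        object.__setattr__(self, "substrate_conc", s)
        object.__setattr__(self, "velocity", v)


@dataclass(frozen=True)
class KineticConstants:
    """Michaelis-Menten parameters: Km (uM) and Vmax (signal/time)."""

    Km: float
    Vmax: float
    Km_se: float
    Vmax_se: float
    km_outside_sampled_range: bool = False

    def predict(self, S):
        S = np.asarray(S, dtype=float)
        return self.Vmax * S / (self.Km + S)


@dataclass(frozen=True)
class DoseResponseDataset:
    """One enzyme-or-cell/compound dose-response table.

    ``inhibitor_conc`` (nM) and ``response`` are flat, matched arrays; wells
    at the same concentration are replicates.  Zero-dose (vehicle) wells are
    required: they anchor the top plateau of the 4PL fit.
    """

    inhibitor_conc: np.ndarray
    response: np.ndarray
    compound_id: str = ""
    assay_id: str = ""

    def __post_init__(self):
        c = np.asarray(self.inhibitor_conc, dtype=float)
        r = np.asarray(self.response, dtype=float)
        if c.shape != r.shape:
            raise ValueError("inhibitor_conc and response must have equal length")
        if np.any(c < 0):
            raise ValueError("inhibitor concentrations must be non-negative")
        if not np.all(np.isfinite(r)):
            raise ValueError("responses must be finite")
        nonzero = np.unique(c[c > 0])
        if len(nonzero) < 8:
            raise ValueError("need at least 8 distinct nonzero concentrations")
        if not np.any(c == 0):
            raise ValueError("need at least one zero-dose (vehicle) well")
        object.__setattr__(self, "inhibitor_conc", c)
        object.__setattr__(self, "response", r)

    @property
    def n_replicates(self) -> int:
        conc, counts = np.unique(self.inhibitor_conc, return_counts=True)
        return int(counts[conc > 0].min())

    def control_mean(self) -> float:
        return float(self.response[self.inhibitor_conc == 0].mean())


@dataclass(frozen=True)
class LogisticFit:
    """Variable-slope 4PL fit: response = bottom + (top-bottom)/(1+(x/ic50)^h).

    ``top`` is the zero-dose plateau and ``bottom`` the saturating-dose
    plateau for an inhibition curve (hill_slope > 0); a negative hill_slope
    describes a rising curve with the same midpoint semantics.  The predicted
    response at x = ic50 is (top+bottom)/2 by construction.
    """

    top: float
    bottom: float
    ic50: float
    hill_slope: float
    top_se: float = float("nan")
    bottom_se: float = float("nan")
    ic50_se: float = float("nan")
    hill_slope_se: float = float("nan")
    rss: float = float("nan")
    converged: bool = True
    no_effect: bool = False

    def predict(self, conc):
        conc = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(conc > 0, conc / self.ic50, 0.0)
            term = np.where(conc > 0, ratio**self.hill_slope,
                            0.0 if self.hill_slope > 0 else np.inf)
        return self.bottom + (self.top - self.bottom) / (1.0 + term)


@dataclass(frozen=True)
class TightBindingContext:
    """([E]t, [S], Km) triple used by the tight-binding IC50 -> Ki conversion.

    Et in nM, S and Km in uM (same enzyme species for S and Km).
    """

    Et: float
    S: float
    Km: float

    def __post_init__(self):
        if self.Et < 0:
            raise ValueError("Et must be >= 0")
        if self.S <= 0 or self.Km <= 0:
            raise ValueError("S and Km must be > 0")

    @property
    def competition_factor(self) -> float:
        """1 + [S]/Km; exactly 2 when the assay is run at [S] = Km."""
        return 1.0 + self.S / self.Km


@dataclass(frozen=True)
class KiConversion:
    """A single-experiment Ki (nM), possibly only an upper bound."""

    ki: float
    is_upper_bound: bool = False
    bound_value: float = float("nan")

    @property
    def reportable(self) -> float:
        """The number to carry forward: Ki, or the bound when flagged."""
        return self.bound_value if self.is_upper_bound else self.ki


@dataclass(frozen=True)
class KiEstimate:
    """Replicate-aggregated Ki: mean +/- sample SD over n experiments."""

    ki_values: tuple
    mean: float
    sd: float
    n: int
    is_upper_bound: bool = False
    bound_value: float = float("nan")
    note: str = ""

    @property
    def reportable(self) -> float:
        return self.bound_value if self.is_upper_bound else self.mean


@dataclass(frozen=True)
class SelectivityRatio:
    """Fold preference of a compound for one enzyme species over another.

    ratio = Ki(comparator)/Ki(preferred): a ratio > 1 means the compound is
    more potent against ``preferred_enzyme``.  When the preferred enzyme's
    Ki is only an upper bound the ratio is a lower bound (">x" in tables).
    """

    compound_id: str
    preferred_enzyme: str
    comparator_enzyme: str
    ratio: float
    is_lower_bound: bool = False


# ---------------------------------------------------------------------------
# Michaelis-Menten
# ---------------------------------------------------------------------------


def fit_michaelis_menten(data: VelocityDataset) -> KineticConstants:
    """Estimate Km and Vmax by nonlinear least squares on v = Vmax*S/(Km+S)."""
    S, v = data.substrate_conc, data.velocity

    vmax0 = float(v.max())
    # initialize Km at the substrate conc whose velocity is nearest Vmax/2
    km0 = float(S[np.argmin(np.abs(v - vmax0 / 2.0))])
    km0 = max(km0, 1e-9)

    def model(s, vmax, km):
        return vmax * s / (km + s)

    try:
        popt, pcov = optimize.curve_fit(
            model, S, v, p0=[vmax0, km0],
            bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=20000,
        )
    except (RuntimeError, optimize.OptimizeWarning) as exc:  # pragma: no cover
        raise FitError(f"Michaelis-Menten fit did not converge: {exc}") from exc

    vmax, km = float(popt[0]), float(popt[1])
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan, np.nan]
    pos = S[S > 0]
    outside = not (pos.min() <= km <= pos.max())
    if outside:
        warnings.warn(
            f"Km estimate {km:.3g} uM lies outside the sampled substrate "
            f"range [{pos.min():.3g}, {pos.max():.3g}] uM", stacklevel=2)
    return KineticConstants(Km=km, Vmax=vmax, Km_se=float(se[1]),
                            Vmax_se=float(se[0]), km_outside_sampled_range=outside)


# ---------------------------------------------------------------------------
# Four-parameter logistic
# ---------------------------------------------------------------------------

# vehicle wells enter the fit at a pseudo-concentration this many decades
# below the lowest tested dose (the log axis cannot host zero)
_ZERO_DOSE_DECADES = 3.0


def _fourpl_log(logx, top, bottom, logic50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - logic50)))


def _hill_init(logx, y, top0, bottom0):
    """Slope guess from the log-dose distance between the quartile crossings."""
    span = top0 - bottom0
    if span == 0:
        return 1.0
    frac = (y - bottom0) / span
    order = np.argsort(logx)
    lx, fr = logx[order], frac[order]
    try:
        hi = lx[np.nonzero(fr <= 0.75)[0][0]]
        lo = lx[np.nonzero(fr <= 0.25)[0][0]]
    except IndexError:
        return 1.0
    d = abs(lo - hi)
    if d < 1e-9:
        return 10.0
    return float(np.clip(2.0 * math.log10(3.0) / d, 0.3, 10.0))


def fit_fourpl(
    conc,
    response,
    *,
    normalize: bool = True,
    weights: np.ndarray | None = None,
    ne_threshold: float = 0.20,
) -> LogisticFit:
    """Fit a variable-slope 4PL on linear response vs log10 concentration.

    Array-level core shared by plate, cellular and live-event curves.
    Zero-dose wells, when present, anchor the top plateau at a
    pseudo-concentration three decades below the lowest tested dose.  With
    ``normalize=True`` (default) responses are first divided by the
    vehicle-well mean, so ``top`` is ~1.  If the span between the control
    level and the top-dose mean is below ``ne_threshold`` (as a fraction of
    the control level) the curve is flagged ``no_effect`` and no IC50 is
    reported.
    """
    conc = np.asarray(conc, dtype=float).copy()
    y = np.asarray(response, dtype=float).copy()
    if conc.shape != y.shape:
        raise ValueError("conc and response must have equal length")
    order = np.lexsort((y, conc))  # fit is invariant to well order
    conc, y = conc[order], y[order]
    has_zero = bool(np.any(conc == 0))
    ctrl = float(y[conc == 0].mean()) if has_zero \
        else float(y[conc == conc.min()].mean())
    if normalize:
        if ctrl == 0:
            raise FitError("vehicle-well mean is zero; cannot normalize")
        y = y / ctrl
        ctrl = 1.0

    top_dose = conc.max()
    top_dose_mean = float(y[conc == top_dose].mean())
    # orientation-aware span check: fraction of control separating plateaus
    ref = abs(ctrl) if ctrl != 0 else max(np.abs(y).max(), 1e-12)
    span_frac = abs(ctrl - top_dose_mean) / ref
    if span_frac < ne_threshold:
        return LogisticFit(top=ctrl, bottom=ctrl, ic50=float("nan"),
                           hill_slope=float("nan"), converged=False,
                           no_effect=True)

    lowest = conc[conc > 0].min()
    pseudo = lowest * 10.0 ** (-_ZERO_DOSE_DECADES)
    x = np.where(conc == 0, pseudo, conc) if has_zero else conc
    logx = np.log10(x)

    falling = top_dose_mean < ctrl
    top0 = float(ctrl)
    bottom0 = float(top_dose_mean)
    hill0 = _hill_init(logx, y, top0, bottom0)
    if not falling:
        hill0 = -hill0
    # midpoint guess: dose whose response is nearest half-span
    half = 0.5 * (top0 + bottom0)
    pos = conc > 0
    logic500 = float(logx[pos][np.argmin(np.abs(y[pos] - half))])

    sigma = None
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match the data")
        sigma = 1.0 / np.sqrt(w[order])

    try:
        popt, pcov = optimize.curve_fit(
            _fourpl_log, logx, y, p0=[top0, bottom0, logic500, hill0],
            sigma=sigma, maxfev=20000, xtol=1e-12, ftol=1e-12, gtol=1e-12,
        )
    except RuntimeError as exc:
        raise FitError(f"4PL fit did not converge: {exc}") from exc

    top, bottom, logic50, hill = (float(p) for p in popt)
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 4
    ic50 = 10.0**logic50
    # delta-method SE for ic50 from the SE of log10(ic50)
    ic50_se = float(ic50 * math.log(10.0) * perr[2])
    resid = y - _fourpl_log(logx, *popt)
    # orientation normalization: report top >= bottom
    if top < bottom:
        top, bottom = bottom, top
        top_se, bottom_se = float(perr[1]), float(perr[0])
        hill = -hill
    else:
        top_se, bottom_se = float(perr[0]), float(perr[1])
    if ic50 <= 0 or not np.isfinite(ic50):
        raise FitError("4PL fit produced a non-positive IC50")
    return LogisticFit(
        top=top, bottom=bottom, ic50=float(ic50), hill_slope=hill,
        top_se=top_se, bottom_se=bottom_se, ic50_se=ic50_se,
        hill_slope_se=float(perr[3]), rss=float(np.sum(resid**2)),
        converged=True, no_effect=False,
    )


def fit_four_parameter_logistic(
    data: DoseResponseDataset,
    *,
    normalize: bool = True,
    weights: np.ndarray | None = None,
    ne_threshold: float = 0.20,
) -> LogisticFit:
    """Fit a variable-slope 4PL to a validated plate dose-response dataset.

    See :func:`fit_fourpl` for the model, initialization, zero-dose
    anchoring and the no-effect rule.
    """
    return fit_fourpl(data.inhibitor_conc, data.response, normalize=normalize,
                      weights=weights, ne_threshold=ne_threshold)


# ---------------------------------------------------------------------------
# Active-enzyme (stoichiometric) titration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ActiveEnzymeEstimate:
    Et: float
    ic50: float
    in_stoichiometric_regime: bool


def estimate_active_enzyme(
    titration: DoseResponseDataset,
    reference_ki: float,
    *,
    min_ratio: float = 100.0,
) -> ActiveEnzymeEstimate:
    """Estimate [E]t (nM) from a titration with [E]t, [I] >> Ki.

    In that regime the half-activity point sits at IC50 ~ [E]t/2, so
    Et = 2*IC50.  The result is flagged "not in stoichiometric regime"
    unless IC50/reference_ki >= ``min_ratio``.
    """
    fit = fit_four_parameter_logistic(titration)
    if fit.no_effect:
        raise FitError("titration shows no dose response; cannot estimate [E]t")
    ok = reference_ki > 0 and (fit.ic50 / reference_ki) >= min_ratio
    if not ok:
        warnings.warn(
            "active-enzyme titration not in stoichiometric regime "
            f"(IC50/Ki = {fit.ic50 / reference_ki:.3g} < {min_ratio:g})",
            stacklevel=2)
    return ActiveEnzymeEstimate(Et=2.0 * fit.ic50, ic50=fit.ic50,
                                in_stoichiometric_regime=bool(ok))


# ---------------------------------------------------------------------------
# IC50 -> Ki conversion (tight binding)
# ---------------------------------------------------------------------------

#: Smallest Ki the assay resolves (nM); 0.01 nM = 10 pM.
DEFAULT_RESOLUTION_FLOOR_NM = 0.01


def ic50_to_ki(
    ic50: float,
    ctx: TightBindingContext,
    *,
    ic50_se: float | None = None,
    resolution_floor: float = DEFAULT_RESOLUTION_FLOOR_NM,
) -> KiConversion:
    """Convert a measured IC50 (nM) to Ki via Ki = (IC50 - Et/2)/(1 + S/Km).

    With Et = 0 this is the Cheng-Prusoff relation; at S = Km the
    denominator is exactly 2.  When the numerator approaches the titration
    limit -- (IC50 - Et/2) < 0.1*Et, or the ~95% IC50 interval includes
    Et/2 -- the conversion is unreliable and an upper bound is reported
    instead of a point estimate (never a negative Ki).
    """
    if ic50 <= 0:
        raise ValueError("ic50 must be > 0")
    denom = ctx.competition_factor
    excess = ic50 - ctx.Et / 2.0

    near_floor = ctx.Et > 0 and excess < 0.1 * ctx.Et
    se_straddles = (
        ic50_se is not None
        and np.isfinite(ic50_se)
        and (ic50 - 1.96 * ic50_se) <= ctx.Et / 2.0
    )
    if near_floor or se_straddles:
        upper = ic50 + 1.96 * ic50_se if (ic50_se and np.isfinite(ic50_se)) else ic50
        bound = max(resolution_floor, (upper - ctx.Et / 2.0) / denom)
        return KiConversion(ki=float("nan"), is_upper_bound=True,
                            bound_value=float(bound))
    return KiConversion(ki=excess / denom)


def morrison_fractional_activity(I, Et: float, Ki_app: float):
    """Fractional activity v/v0 for a tight-binding inhibitor (Morrison).

    v/v0 = 1 - [(Et + I + Ki_app) - sqrt((Et + I + Ki_app)^2 - 4*Et*I)]/(2*Et)

    ``Ki_app`` is the apparent Ki under the assay's substrate competition,
    Ki_app = Ki*(1 + S/Km).  Valid for any [I] >= 0, including the
    stoichiometric regime Ki_app << Et.  Vectorized over ``I``.
    """
    if Et <= 0:
        raise ValueError("Et must be > 0")
    if Ki_app < 0:
        raise ValueError("Ki_app must be >= 0")
    I = np.asarray(I, dtype=float)
    if np.any(I < 0):
        raise ValueError("inhibitor concentrations must be >= 0")
    b = Et + I + Ki_app
    disc = b * b - 4.0 * Et * I
    if np.any(disc < 0):
        warnings.warn("negative Morrison discriminant clamped to 0", stacklevel=2)
        disc = np.clip(disc, 0.0, None)
    frac = 1.0 - (b - np.sqrt(disc)) / (2.0 * Et)
    frac = np.clip(frac, 0.0, 1.0)
    return frac if frac.ndim else float(frac)


# ---------------------------------------------------------------------------
# Replicate aggregation and selectivity
# ---------------------------------------------------------------------------


def aggregate_ki(per_experiment: Sequence[float | KiConversion]) -> KiEstimate:
    """Aggregate independent-experiment Ki values: mean +/- sample SD, n.

    Accepts plain positive floats or :class:`KiConversion` results; any
    upper-bound experiment makes the aggregate an upper bound (mixed
    flagged/unflagged inputs are noted).
    """
    if len(per_experiment) == 0:
        raise ValueError("need at least one Ki value")
    values, flags, bounds = [], [], []
    for item in per_experiment:
        if isinstance(item, KiConversion):
            flags.append(item.is_upper_bound)
            if item.is_upper_bound:
                bounds.append(item.bound_value)
                values.append(item.bound_value)
            else:
                values.append(item.ki)
        else:
            v = float(item)
            flags.append(False)
            values.append(v)
    arr = np.asarray(values, dtype=float)
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ValueError("Ki values must be positive and finite")
    n = len(arr)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if n > 1 else 0.0
    any_bound = any(flags)
    note = ""
    if any_bound and not all(flags):
        note = "mixed point estimates and upper bounds; aggregate is a bound"
    if any_bound:
        return KiEstimate(ki_values=tuple(arr), mean=float("nan"), sd=sd, n=n,
                          is_upper_bound=True, bound_value=float(max(bounds)),
                          note=note)
    return KiEstimate(ki_values=tuple(arr), mean=mean, sd=sd, n=n)


def compute_selectivity_ratios(
    ki_table: Mapping[str, Mapping[str, KiEstimate]],
    pairs: Sequence[tuple[str, str]],
) -> list[SelectivityRatio]:
    """Fold selectivity ratios from a {compound: {enzyme: KiEstimate}} table.

    For each requested (preferred, comparator) pair the ratio is
    Ki(comparator)/Ki(preferred).  Upper-bound Ki values in the preferred
    (denominator) position yield lower-bound (">x") ratios; compounds
    missing either enzyme are skipped with a warning.
    """
    out: list[SelectivityRatio] = []
    for compound, per_enzyme in ki_table.items():
        for preferred, comparator in pairs:
            if preferred not in per_enzyme or comparator not in per_enzyme:
                warnings.warn(
                    f"{compound}: missing Ki for "
                    f"{preferred if preferred not in per_enzyme else comparator};"
                    " ratio skipped", stacklevel=2)
                continue
            num = per_enzyme[comparator]
            den = per_enzyme[preferred]
            ratio = num.reportable / den.reportable
            # a bound in the numerator makes the ratio itself a bound in the
            # opposite direction; only denominator bounds yield ">x" entries
            out.append(SelectivityRatio(
                compound_id=compound, preferred_enzyme=preferred,
                comparator_enzyme=comparator, ratio=float(ratio),
                is_lower_bound=den.is_upper_bound,
            ))
    return out


def format_ratio(r: SelectivityRatio) -> str:
    """Display-round a selectivity ratio: >=100 as an integer, else 1 decimal.

    Lower-bound ratios are prefixed with ">" and shown as integers.
    """
    if r.is_lower_bound:
        return f">{r.ratio:.0f}"
    if r.ratio >= 100:
        return f"{r.ratio:.0f}"
    return f"{r.ratio:.1f}"
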