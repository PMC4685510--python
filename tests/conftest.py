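"""Shared fixtures and independent reference fitters used as test oracles."""

from __future__ import annotations

import numpy as np
import pytest

from aurprof.synthdata import ImagingSpec, LiveSpec


@pytest.fixture
def imaging_spec() -> ImagingSpec:
    return ImagingSpec()


@pytest.fixture
def live_spec() -> LiveSpec:
    return LiveSpec()


# ---------------------------------------------------------------------------
# Independent grid-search fitters (oracles)
# ---------------------------------------------------------------------------


def grid_fit_michaelis(S, v, km_lo=1e-2, km_hi=1e4, n=60, levels=4):
    """Coarse-to-fine 1-D grid search over Km with Vmax solved analytically.

    For fixed Km the model is linear in Vmax, so the least-squares Vmax is
    sum(v*m)/sum(m^2) with m = S/(Km+S).  Independent of curve_fit.
    """
    S = np.asarray(S, float)
    v = np.asarray(v, float)
    lo, hi = np.log10(km_lo), np.log10(km_hi)
    best = None
    for _ in range(levels):
        kms = np.logspace(lo, hi, n)
        losses = []
        for km in kms:
            m = S / (km + S)
            vmax = float(np.dot(v, m) / np.dot(m, m))
            losses.append(float(np.sum((v - vmax * m) ** 2)))
        i = int(np.argmin(losses))
        best = (kms[i], losses[i])
        step = (hi - lo) / (n - 1)
        lo, hi = np.log10(kms[i]) - 2 * step, np.log10(kms[i]) + 2 * step
    km = best[0]
    m = S / (km + S)
    vmax = float(np.dot(v, m) / np.dot(m, m))
    return km, vmax, best[1]


def grid_fit_fourpl(conc, y, levels=4, n_mid=60, n_hill=40):
    """Coarse-to-fine grid over (log10 ic50, hill) with plateaus solved linearly.

    For fixed midpoint and slope the 4PL is linear in (bottom, top-bottom):
    y = a + b*s with s = 1/(1 + 10^(h*(logx - m))).  Zero doses use the same
    3-decade pseudo-concentration convention as the package fitter, but the
    optimizer itself is an independent exhaustive search.
    """
    conc = np.asarray(conc, float)
    y = np.asarray(y, float)
    lowest = conc[conc > 0].min()
    x = np.where(conc == 0, lowest * 1e-3, conc)
    logx = np.log10(x)
    mlo, mhi = logx.min(), logx.max()
    hlo, hhi = -6.0, 6.0
    best = None
    for _ in range(levels):
        mids = np.linspace(mlo, mhi, n_mid)
        hills = np.linspace(hlo, hhi, n_hill)
        for m in mids:
            for h in hills:
                if abs(h) < 1e-3:
                    continue
                s = 1.0 / (1.0 + 10.0 ** (h * (logx - m)))
                A = np.column_stack([np.ones_like(s), s])
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                loss = float(np.sum((y - A @ coef) ** 2))
                if best is None or loss < best[0]:
                    best = (loss, m, h, coef)
        _, m0, h0, _ = best
        mstep = (mhi - mlo) / (n_mid - 1)
        hstep = (hhi - hlo) / (n_hill - 1)
        mlo, mhi = m0 - 2 * mstep, m0 + 2 * mstep
        hlo, hhi = h0 - 2 * hstep, h0 + 2 * hstep
    loss, m, h, coef = best
    bottom, span = coef
    return {"ic50": 10.0**m, "hill": h, "bottom": bottom,
            "top": bottom + span, "loss": loss}
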