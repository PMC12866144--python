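"""ZIP (zero-interaction-potency) synergy scoring for two-drug dose grids.

Monotherapy responses are fitted with a four-parameter log-logistic (4PL)
curve; the Bliss-independence expectation y1 + y2 - y1*y2 of the fitted
monotherapy effects defines the zero-interaction surface. Observed
combination responses are smoothed by conditional 4PL refits along each dose
axis (the potency-shift idea: the curve along drug 1 at a fixed drug-2 dose
is anchored at drug 2's fitted effect), and delta = (fitted observed -
expected) x 100 percentage points. The mean delta over combination wells is
the ZIP score: > 10 synergistic, < -10 antagonistic, otherwise additive
(boundaries inclusive of additive).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .datatypes import DoseResponseMatrix

log = logging.getLogger("mutlike")

SYNERGY_THRESHOLD = 10.0


class SynergyError(ValueError):
    pass


@dataclass
class MonotherapyFit:
    """Four-parameter log-logistic fit y(d) = ymin + (ymax-ymin) d^s/(d^s+m^s)."""

    ymin: float
    ymax: float
    midpoint: float
    slope: float
    residual: float
    flat: bool = False

    def predict(self, doses) -> np.ndarray:
        d = np.asarray(doses, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(d > 0, d**self.slope / (d**self.slope + self.midpoint**self.slope), 0.0)
        return self.ymin + (self.ymax - self.ymin) * frac


def _fit_4pl(doses, responses, ymin_fixed: float | None = None):
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    pos = d[d > 0]
    m0 = float(np.median(pos)) if len(pos) else 1.0

    if ymin_fixed is None:
        def resid(theta):
            ymin, ymax, logm, s = theta
            return MonotherapyFit(ymin, ymax, np.exp(logm), s, 0.0).predict(d) - y
        x0 = [float(np.min(y)), float(np.max(y)), np.log(m0), 1.0]
        lb = [0.0, 0.0, np.log(m0) - 12.0, 0.05]
        ub = [1.0, 1.0, np.log(m0) + 12.0, 20.0]
    else:
        def resid(theta):
            ymax, logm, s = theta
            return MonotherapyFit(ymin_fixed, ymax, np.exp(logm), s, 0.0).predict(d) - y
        x0 = [float(np.max(y)), np.log(m0), 1.0]
        lb = [0.0, np.log(m0) - 12.0, 0.05]
        ub = [1.0, np.log(m0) + 12.0, 20.0]
    x0 = np.clip(x0, lb, ub)
    sol = least_squares(resid, x0, bounds=(lb, ub))
    if ymin_fixed is None:
        ymin, ymax, logm, s = sol.x
    else:
        ymin = ymin_fixed
        ymax, logm, s = sol.x
    rss = float(np.sqrt(np.mean(sol.fun**2)))
    return MonotherapyFit(float(ymin), float(ymax), float(np.exp(logm)), float(s), rss), sol


def fit_monotherapy(doses, responses) -> MonotherapyFit:
    """Least-squares 4PL fit of a single-drug dose-response margin.

    Needs >= 4 dose points including dose 0; responses are inhibition
    fractions in [0, 1]. Flat data yield a flat-line fit with a warning.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(d) < 4:
        raise SynergyError("monotherapy fit needs >= 4 dose points")
    if d[0] != 0 or np.any(np.diff(d) <= 0):
        raise SynergyError("doses must be strictly increasing and include 0")
    if np.any((y < 0) | (y > 1)):
        raise SynergyError("responses must be inhibition fractions in [0, 1]")
    if np.ptp(y) < 1e-12:
        log.warning("fit_monotherapy: flat response data; returning flat-line fit")
        return MonotherapyFit(float(y[0]), float(y[0]), float(np.median(d[d > 0])), 1.0, 0.0, flat=True)
    fit, _ = _fit_4pl(d, y)
    return fit


@dataclass
class ZipResult:
    """ZIP delta surface (percentage points), mean score and classification."""

    delta: pd.DataFrame
    mean_zip: float
    classification: str
    fit_drug1: MonotherapyFit = None
    fit_drug2: MonotherapyFit = None
    flags: list = field(default_factory=list)


def classify_zip(mean_zip: float) -> str:
    if mean_zip > SYNERGY_THRESHOLD:
        return "synergistic"
    if mean_zip < -SYNERGY_THRESHOLD:
        return "antagonistic"
    return "additive"


def zip_delta(matrix: DoseResponseMatrix) -> ZipResult:
    """ZIP synergy score of a full dose grid with monotherapy margins.

    delta(d1, d2) = 100 x (fitted observed - (y1 + y2 - y1*y2)) over
    combination wells (both doses > 0); the mean delta is the ZIP score.
    Conditional-fit failures fall back to the observed response with a
    logged flag.
    """
    d1, d2, resp = matrix.doses_drug1, matrix.doses_drug2, matrix.response
    flags: list = []
    fit1 = fit_monotherapy(d1, resp[:, 0])
    fit2 = fit_monotherapy(d2, resp[0, :])
    y1 = fit1.predict(d1)  # along rows
    y2 = fit2.predict(d2)  # along cols
    expected = y1[:, None] + y2[None, :] - y1[:, None] * y2[None, :]

    n1, n2 = len(d1), len(d2)
    fitted_rowwise = np.full((n1, n2), np.nan)  # refit along d1 at fixed d2
    fitted_colwise = np.full((n1, n2), np.nan)
    for j in range(1, n2):  # fixed drug-2 dose, curve in d1
        anchor = float(np.clip(y2[j], 0.0, 1.0))
        try:
            fit, _ = _fit_4pl(d1, resp[:, j], ymin_fixed=anchor)
            fitted_rowwise[:, j] = fit.predict(d1)
        except Exception as e:  # pragma: no cover - scipy failures are rare
            flags.append(f"conditional fit failed at d2={d2[j]}: {e}")
            fitted_rowwise[:, j] = resp[:, j]
    for i in range(1, n1):
        anchor = float(np.clip(y1[i], 0.0, 1.0))
        try:
            fit, _ = _fit_4pl(d2, resp[i, :], ymin_fixed=anchor)
            fitted_colwise[i, :] = fit.predict(d2)
        except Exception as e:  # pragma: no cover
            flags.append(f"conditional fit failed at d1={d1[i]}: {e}")
            fitted_colwise[i, :] = resp[i, :]
    if flags:
        log.warning("zip_delta: %d conditional fit fallback(s)", len(flags))

    fitted_rowwise[0, 0] = resp[0, 0]  # untreated well: no conditional fit exists
    fitted = np.nanmean(np.stack([fitted_rowwise, fitted_colwise]), axis=0)
    delta = (fitted - expected) * 100.0
    comb = delta[1:, 1:]  # both doses > 0
    mean_zip = float(np.mean(comb))
    delta_df = pd.DataFrame(delta, index=d1, columns=d2)
    delta_df.iloc[0, :] = np.nan  # margins carry no interaction information
    delta_df.iloc[:, 0] = np.nan
    return ZipResult(
        delta=delta_df,
        mean_zip=mean_zip,
        classification=classify_zip(mean_zip),
        fit_drug1=fit1,
        fit_drug2=fit2,
        flags=flags,
    )
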