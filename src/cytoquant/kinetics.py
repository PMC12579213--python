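"""One-phase-association kinetics for FRAP and condensate-formation curves.

A recovery (or formation) time course normalized to its pre-event baseline is
fitted with the one-phase association model

    F(t) = F0 + (plateau - F0) * (1 - exp(-k t)),   t from the event,

yielding the rate ``k``, half-time ``t_half = ln 2 / k``, and — against a
pre-bleach level of 1 — mobile fraction (plateau - F0) / (1 - F0) and
immobile fraction 1 - mobile.

The module follows a Model/Results layout: build
:class:`OnePhaseAssociation` from an :class:`IntensityCurve`, call ``fit()``
and read estimates, standard errors and ``summary()`` off the results object.
Functional wrappers (:func:`normalize_frap`, :func:`fit_one_phase`,
:func:`half_time`) cover script use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


class UndefinedValueError(ValueError):
    pass


class FitError(RuntimeError):
    pass


@dataclass
class IntensityCurve:
    """Mean-ROI intensity time course around a perturbation.

    ``t`` is in seconds (strictly increasing); ``pre_frames`` frames precede
    the bleach/stimulus event.
    """

    t: np.ndarray
    values: np.ndarray
    pre_frames: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.t) != len(self.values):
            raise ValueError("t and values must have equal length")
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("t must be strictly increasing")
        if not 0 <= self.pre_frames < len(self.t):
            raise ValueError("pre_frames out of range")

    @property
    def post_t(self) -> np.ndarray:
        """Time from the event (first post-event frame at 0)."""
        return self.t[self.pre_frames:] - self.t[self.pre_frames]

    @property
    def post_values(self) -> np.ndarray:
        return self.values[self.pre_frames:]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_s": self.t, "value": self.values})


def one_phase(t, f0, plateau, k):
    """One-phase association model."""
    return f0 + (plateau - f0) * (1.0 - np.exp(-k * t))


def normalize_frap(raw: IntensityCurve, single_frame: bool = False) -> IntensityCurve:
    """Divide every value by the pre-bleach baseline.

    The baseline is the mean of all pre-bleach frames (or the last single
    pre-bleach frame with ``single_frame=True``); after normalization the
    pre-bleach level is 1. Idempotent on already-normalized curves.
    """
    if raw.pre_frames < 1:
        raise ValueError("normalization needs at least one pre-bleach frame")
    pre = raw.values[: raw.pre_frames]
    base = float(pre[-1]) if single_frame else float(pre.mean())
    if base <= 0:
        raise UndefinedValueError("non-positive pre-bleach baseline")
    return IntensityCurve(t=raw.t.copy(), values=raw.values / base,
                          pre_frames=raw.pre_frames)


@dataclass
class OnePhaseResults:
    """Fit results: estimates, uncertainties, derived kinetic quantities."""

    f0: float
    plateau: float
    k: float
    bse: np.ndarray  # standard errors of (f0, plateau, k)
    cov: np.ndarray
    residual_rms: float
    pre_level: float = 1.0
    n_obs: int = 0
    k_at_bound: bool = False

    @property
    def params(self) -> np.ndarray:
        return np.array([self.f0, self.plateau, self.k])

    @property
    def t_half(self) -> float:
        return float(np.log(2.0) / self.k)

    @property
    def mobile_fraction(self) -> float:
        denom = self.pre_level - self.f0
        if denom <= 0:
            return float("nan")
        return float((self.plateau - self.f0) / denom)

    @property
    def immobile_fraction(self) -> float:
        return 1.0 - self.mobile_fraction

    def predict(self, t) -> np.ndarray:
        return one_phase(np.asarray(t, dtype=float), self.f0, self.plateau, self.k)

    def summary(self) -> pd.DataFrame:
        rows = [
            ("F0", self.f0, self.bse[0]),
            ("plateau", self.plateau, self.bse[1]),
            ("k (1/s)", self.k, self.bse[2]),
            ("t_half (s)", self.t_half, np.nan),
            ("mobile fraction", self.mobile_fraction, np.nan),
            ("immobile fraction", self.immobile_fraction, np.nan),
            ("residual RMS", self.residual_rms, np.nan),
        ]
        return pd.DataFrame(rows, columns=["quantity", "estimate", "std err"])


class OnePhaseAssociation:
    """One-phase association model for a post-event recovery curve.

    Parameters
    ----------
    curve : IntensityCurve
        Normalized curve; the fit uses the post-event segment with time
        origin at the first post-event frame.
    pre_level : float
        Reference level for the mobile fraction (1 for a curve normalized to
        its pre-bleach baseline).
    """

    def __init__(self, curve: IntensityCurve, pre_level: float = 1.0):
        if len(curve.post_t) < 5:
            raise ValueError("need at least 5 post-event points")
        if not np.all(np.isfinite(curve.post_values)):
            raise ValueError("non-finite values in curve")
        self.curve = curve
        self.pre_level = pre_level

    def fit(self) -> OnePhaseResults:
        t = self.curve.post_t
        y = self.curve.post_values
        f0_init = float(y[0])
        plat_init = float(np.mean(y[max(len(y) - 5, 0):]))
        # initial rate from the first crossing of the half level
        half = (f0_init + plat_init) / 2.0
        above = np.nonzero(y >= half)[0] if plat_init >= f0_init else np.nonzero(y <= half)[0]
        t_half_guess = t[above[0]] if above.size and t[above[0]] > 0 else (t[-1] / 5 or 1.0)
        k_init = np.log(2.0) / max(t_half_guess, t[1] - t[0] if len(t) > 1 else 1.0)
        k_lo, k_hi = 1e-12, 1e6
        try:
            popt, pcov = curve_fit(
                one_phase, t, y,
                p0=[f0_init, plat_init, k_init],
                bounds=([-np.inf, -np.inf, k_lo], [np.inf, np.inf, k_hi]),
                maxfev=20000,
            )
        except RuntimeError as exc:
            raise FitError(f"one-phase fit did not converge: {exc}") from exc
        resid = y - one_phase(t, *popt)
        bse = np.sqrt(np.diag(pcov))
        return OnePhaseResults(
            f0=float(popt[0]), plateau=float(popt[1]), k=float(popt[2]),
            bse=bse, cov=pcov,
            residual_rms=float(np.sqrt(np.mean(resid**2))),
            pre_level=self.pre_level, n_obs=len(t),
            k_at_bound=bool(popt[2] <= k_lo * 10 or popt[2] >= k_hi / 10),
        )


def fit_one_phase(curve: IntensityCurve, pre_level: float = 1.0) -> OnePhaseResults:
    """Fit the one-phase association model to the post-event segment."""
    return OnePhaseAssociation(curve, pre_level=pre_level).fit()


def half_time(obj, mode: str = "fit") -> float:
    """Half-maximal time of a recovery curve.

    ``mode="fit"`` returns ln2/k from a model fit (``obj`` may be an
    :class:`IntensityCurve` or an existing :class:`OnePhaseResults`).
    ``mode="interp"`` linearly interpolates the first crossing of
    (F0 + plateau)/2 on the raw post-event curve, taking F0 as the first and
    plateau as the last post-event value.
    """
    if mode == "fit":
        res = obj if isinstance(obj, OnePhaseResults) else fit_one_phase(obj)
        return res.t_half
    if mode != "interp":
        raise ValueError(f"unknown mode {mode!r}")
    if not isinstance(obj, IntensityCurve):
        raise TypeError("interp mode needs an IntensityCurve")
    t = obj.post_t
    y = obj.post_values
    half = (y[0] + y[-1]) / 2.0
    rising = y[-1] >= y[0]
    for i in range(1, len(y)):
        crossed = y[i] >= half if rising else y[i] <= half
        if crossed:
            if y[i] == y[i - 1]:
                return float(t[i])
            frac = (half - y[i - 1]) / (y[i] - y[i - 1])
            return float(t[i - 1] + frac * (t[i] - t[i - 1]))
    raise UndefinedValueError("curve never crosses its half level")
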