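"""Temporal models of lung elasticity across the breathing cycle.

Per-phase elasticity samples (t, E) and (t, v) are fitted by four
low-complexity parametric families:

* ``Exp2``:     f(t) = c1 e^(c2 t) + c3 e^(c4 t)
* ``Fourier1``: f(t) = c1 cos(c2 t) + c3 sin(c4 t) + c5
* ``Gauss2``:   f(t) = c1 e^(-((t-c2)/c3)^2) + c4 e^(-((t-c5)/c6)^2)
* ``Poly2``:    f(t) = c1 t^2 + c2 t + c3

Fourier1 is written with independent cosine/sine frequencies c2, c4 (the
conventional single-frequency series is available via
``shared_frequency=True``).  Nonlinear families are fitted by seeded
multi-start least squares; Poly2 is closed-form.  Models are ranked by R^2
computed on the fitted samples only, ties broken by MSE then by fewer
coefficients.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

MODEL_NAMES = ("Exp2", "Fourier1", "Gauss2", "Poly2")
N_COEFFS = {"Exp2": 4, "Fourier1": 5, "Gauss2": 6, "Poly2": 3}


def model_predict(model: str, coeffs: np.ndarray, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    c = np.asarray(coeffs, dtype=float)
    if model == "Exp2":
        return c[0] * np.exp(c[1] * t) + c[2] * np.exp(c[3] * t)
    if model == "Fourier1":
        return c[0] * np.cos(c[1] * t) + c[2] * np.sin(c[3] * t) + c[4]
    if model == "Gauss2":
        return c[0] * np.exp(-(((t - c[1]) / c[2]) ** 2)) + c[3] * np.exp(
            -(((t - c[4]) / c[5]) ** 2)
        )
    if model == "Poly2":
        return c[0] * t**2 + c[1] * t + c[2]
    raise ValueError(f"unknown temporal model {model!r}")


@dataclass
class TemporalModelFit:
    """One fitted temporal family with goodness-of-fit on the samples."""

    model: str
    coefficients: np.ndarray
    r2: float
    mse: float
    success: bool
    message: str = ""

    def predict(self, t) -> np.ndarray:
        return model_predict(self.model, self.coefficients, t)


def _goodness(values: np.ndarray, pred: np.ndarray) -> tuple[float, float]:
    resid = values - pred
    mse = float(np.mean(resid**2))
    ss_tot = float(np.sum((values - values.mean()) ** 2))
    if ss_tot == 0.0:
        # constant samples: define R^2 = 1 when residuals also vanish
        logger.info("zero-variance samples; R^2 set to 1 by convention")
        return (1.0 if np.allclose(resid, 0, atol=1e-12) else -np.inf), mse
    return 1.0 - float(np.sum(resid**2)) / ss_tot, mse


def _starts(model: str, t, values, period: float, rng: np.random.Generator,
            n_starts: int, shared_frequency: bool):
    w0 = 2 * np.pi / period
    mean, span = float(values.mean()), float(values.max() - values.min()) or 1.0
    t0, t1 = float(t.min()), float(t.max())
    starts = []
    for k in range(n_starts):
        if model == "Fourier1":
            w = w0 * (1 + k % 3) * (1 + 0.2 * rng.standard_normal()) if k else w0
            starts.append([span / 2, w, span / 2, w, mean])
        elif model == "Exp2":
            r = 0.5 * rng.standard_normal(2) / period
            starts.append([mean / 2, r[0], mean / 2, r[1]])
        elif model == "Gauss2":
            c2, c5 = rng.uniform(t0, t1, 2) if k else (t0 + 0.25 * (t1 - t0),
                                                       t0 + 0.75 * (t1 - t0))
            width = (t1 - t0) / 3 * (1 + 0.3 * abs(rng.standard_normal()))
            starts.append([span, c2, width, span, c5, width])
    return starts


def fit_model(times, values, model: str, seed: int = 0, period: float | None = None,
              n_starts: int = 16, shared_frequency: bool = False) -> TemporalModelFit:
    """Fit one temporal family to (t, value) samples.

    ``period`` seeds the frequency/width starts of the nonlinear families;
    when omitted it is estimated as the sample span extended by one step
    (breathing-cycle data covers one period with the last phase open).
    Failure across all starts yields a fit record with ``success=False``
    rather than an exception.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if model not in MODEL_NAMES:
        raise ValueError(f"unknown temporal model {model!r}")
    if t.ndim != 1 or y.shape != t.shape:
        raise ValueError("times and values must be equal-length 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if len(t) < N_COEFFS[model] + 1:
        raise ValueError(
            f"{model} needs at least {N_COEFFS[model] + 1} samples, got {len(t)}"
        )
    if period is None:
        period = float(t[-1] - t[0]) * len(t) / max(len(t) - 1, 1)

    if model == "Poly2":
        c = np.polyfit(t, y, 2)
        r2, mse = _goodness(y, np.polyval(c, t))
        return TemporalModelFit(model, c, r2, mse, True)

    rng = np.random.default_rng(seed)

    def resid(c):
        if shared_frequency and model == "Fourier1":
            c = np.array([c[0], c[1], c[2], c[1], c[3]])
        return model_predict(model, c, t) - y

    lb, ub = -np.inf, np.inf
    if model == "Gauss2":
        lb = np.array([-np.inf, -np.inf, 1e-3, -np.inf, -np.inf, 1e-3])
        ub = np.inf

    best = None
    for start in _starts(model, t, y, period, rng, n_starts, shared_frequency):
        x0 = np.asarray(start, dtype=float)
        if shared_frequency and model == "Fourier1":
            x0 = np.array([x0[0], x0[1], x0[2], x0[4]])
        try:
            res = least_squares(resid, x0, bounds=(lb, ub) if model == "Gauss2"
                                else (-np.inf, np.inf), max_nfev=2000)
        except Exception as exc:  # noqa: BLE001
            logger.debug("start failed: %s", exc)
            continue
        cost = float(np.sum(res.fun**2))
        if best is None or cost < best[0]:
            best = (cost, res.x)
    if best is None:
        return TemporalModelFit(model, np.full(N_COEFFS[model], np.nan),
                                -np.inf, np.inf, False, "all starts failed")
    c = best[1]
    if shared_frequency and model == "Fourier1":
        c = np.array([c[0], c[1], c[2], c[1], c[3]])
    r2, mse = _goodness(y, model_predict(model, c, t))
    return TemporalModelFit(model, c, r2, mse, True)


def rank_models(fits) -> list[TemporalModelFit]:
    """Order successful fits by R^2 desc, then MSE asc, then fewer coefficients."""
    ok = [f for f in fits if f.success]
    if not ok:
        raise ValueError("no successful fits to rank")
    return sorted(ok, key=lambda f: (-f.r2, f.mse, N_COEFFS[f.model]))


@dataclass
class ElasticityTrajectory:
    """Per-phase elasticity samples with fitted temporal models."""

    times: np.ndarray
    E_samples: np.ndarray                 # kPa
    v_samples: np.ndarray
    E_fits: dict = field(default_factory=dict)
    v_fits: dict = field(default_factory=dict)
    best_model_E: str = ""
    best_model_v: str = ""


def fit_trajectory(times, E_samples, v_samples, seed: int = 0,
                   period: float | None = None,
                   models=MODEL_NAMES) -> ElasticityTrajectory:
    """Fit all temporal families to E(t) and v(t) samples and rank them."""
    traj = ElasticityTrajectory(
        times=np.asarray(times, dtype=float),
        E_samples=np.asarray(E_samples, dtype=float),
        v_samples=np.asarray(v_samples, dtype=float),
    )
    for model in models:
        traj.E_fits[model] = fit_model(times, E_samples, model, seed=seed,
                                       period=period)
        traj.v_fits[model] = fit_model(times, v_samples, model, seed=seed + 1,
                                       period=period)
    traj.best_model_E = rank_models(traj.E_fits.values())[0].model
    traj.best_model_v = rank_models(traj.v_fits.values())[0].model
    return traj


class TemporalModelRegressor(BaseEstimator, RegressorMixin):
    """Scikit-learn estimator wrapper around one temporal family.

    Parameters
    ----------
    model : one of ``"Exp2" | "Fourier1" | "Gauss2" | "Poly2"``.
    period : breathing-cycle period hint (seconds); estimated when None.
    shared_frequency : constrain Fourier1 to a single frequency c2 = c4.
    seed : multi-start RNG seed.
    """

    def __init__(self, model: str = "Fourier1", period: float | None = None,
                 shared_frequency: bool = False, seed: int = 0,
                 n_starts: int = 16):
        self.model = model
        self.period = period
        self.shared_frequency = shared_frequency
        self.seed = seed
        self.n_starts = n_starts

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        fit = fit_model(t, y, self.model, seed=self.seed, period=self.period,
                        n_starts=self.n_starts,
                        shared_frequency=self.shared_frequency)
        self.fit_ = fit
        self.coefficients_ = fit.coefficients
        self.r2_ = fit.r2
        self.mse_ = fit.mse
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "fit_")
        t = np.asarray(X, dtype=float).reshape(-1)
        return self.fit_.predict(t)
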