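"""Patient-level features and the two-step LASSO on average elasticity.

Eleven features per case relate imaging and clinical covariates to the
cycle-averaged lung elasticity: relative lung volume change X1, relative
mean-HU change X2, bounding-box extent changes X3-X5, surface-to-volume
ratio change X6 (all between end-inspiration P00 and end-expiration P50),
age X7, lung motion amplitude X8, BMI X9, and two shape descriptors of
the volume-averaged deformation — the anisotropic deformation index

    ADI = sqrt(((l1-l2)/l2)^2 + ((l2-l3)/l3)^2)

and the slab-rod index

    SRI = (2/pi) * arctan sqrt( l3 (l1-l2) / (l2 (l2-l3)) ),

where l1 >= l2 >= l3 are the principal stretches (eigenvalues of the
right stretch tensor of the volume-averaged deformation gradient).

Feature selection and regression use LASSO with leave-one-out
cross-validation twice: once to select features at the LOOCV-MSE-minimal
penalty, then refit on the selected subset.  Features are standardized
internally; coefficients are reported on the standardized scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import LeaveOneOut
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "dV", "dHU", "dx", "dy", "dz", "dSV", "Age", "LMA", "BMI", "ADI", "SRI",
)


def principal_strains(mean_F: np.ndarray) -> tuple[float, float, float]:
    """Principal stretches l1 >= l2 >= l3 of the right stretch tensor.

    Eigenvalues of U = sqrt(F^T F) from the polar decomposition F = R U;
    rotation-invariant by construction.
    """
    F = np.asarray(mean_F, dtype=float)
    if np.linalg.det(F) <= 0:
        raise ValueError("deformation gradient must have positive determinant")
    C = F.T @ F
    lam = np.sqrt(np.maximum(np.linalg.eigvalsh(C), 0.0))
    l3, l2, l1 = lam
    return float(l1), float(l2), float(l3)


def adi(l1: float, l2: float, l3: float) -> float:
    """Anisotropic deformation index; zero iff the stretch is isotropic."""
    if l2 <= 0 or l3 <= 0:
        raise ValueError("principal stretches must be positive")
    return float(np.sqrt(((l1 - l2) / l2) ** 2 + ((l2 - l3) / l3) ** 2))


def sri(l1: float, l2: float, l3: float) -> float:
    """Slab-rod index in [0, 1]; 0 for oblate (l1 = l2), 1 for prolate
    (l2 = l3) limits, by the arctan limit convention."""
    if not (l1 >= l2 >= l3 > 0):
        raise ValueError("need l1 >= l2 >= l3 > 0")
    num = l3 * (l1 - l2)
    den = l2 * (l2 - l3)
    if num == 0.0:
        return 0.0
    if den == 0.0:
        logger.info("SRI prolate limit (l2 == l3): returning 1 by convention")
        return 1.0
    return float((2.0 / np.pi) * np.arctan(np.sqrt(num / den)))


def volume_averaged_F(solution, region: str = "lung") -> np.ndarray:
    """Volume-weighted mean deformation gradient over one region."""
    from .mesh import tet_signed_volumes

    mesh = solution.mesh
    mask = mesh.region_mask(region)
    vols = tet_signed_volumes(mesh.nodes, mesh.tets)[mask]
    return np.einsum("m,mij->ij", vols, solution.F[mask]) / vols.sum()


@dataclass
class PatientFeatures:
    """The eleven per-case regression inputs (dimensionless unless noted)."""

    dV: float          # (V00 - V50)/V50, lung volume
    dHU: float         # (HU00 - HU50)/HU50, mean CT number
    dx: float          # bounding-box extent changes, P00 vs P50
    dy: float
    dz: float
    dSV: float         # surface-to-volume ratio change
    Age: float         # years
    LMA: float         # lung motion amplitude, mm
    BMI: float         # kg/m^2
    ADI: float
    SRI: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)


def extract_features(bundle, clinical: dict, solution_p00) -> PatientFeatures:
    """Compute all eleven features for one case.

    ``clinical`` supplies ``age`` (years) and ``bmi`` (kg/m^2);
    ``solution_p00`` is the converged P50 -> P00 solve whose
    volume-averaged lung deformation gradient feeds ADI and SRI.
    """
    tags = bundle.phase_tags
    for needed in ("P00", "P50"):
        if needed not in tags:
            raise ValueError(f"phase {needed} missing from bundle")
    m00, m50 = bundle.mesh_for("P00"), bundle.mesh_for("P50")
    v00, v50 = m00.volume("lung"), m50.volume("lung")
    s00, s50 = m00.surface_area(), m50.surface_area()
    lo00, hi00 = m00.bounding_box("lung")
    lo50, hi50 = m50.bounding_box("lung")
    ext00, ext50 = hi00 - lo00, hi50 - lo50

    hu = bundle.mean_hu
    i00, i50 = tags.index("P00"), tags.index("P50")
    dhu = (hu[i00] - hu[i50]) / hu[i50]

    # lung motion amplitude: max centroid excursion from the reference phase
    ref_c = m50.centroid("lung")
    lma = max(
        float(np.linalg.norm(bundle.mesh_for(tag).centroid("lung") - ref_c))
        for tag in tags
    )

    l1, l2, l3 = principal_strains(volume_averaged_F(solution_p00, "lung"))
    return PatientFeatures(
        dV=(v00 - v50) / v50,
        dHU=float(dhu),
        dx=float((ext00[0] - ext50[0]) / ext50[0]),
        dy=float((ext00[1] - ext50[1]) / ext50[1]),
        dz=float((ext00[2] - ext50[2]) / ext50[2]),
        dSV=float((s00 / v00 - s50 / v50) / (s50 / v50)),
        Age=float(clinical["age"]),
        LMA=lma,
        BMI=float(clinical["bmi"]),
        ADI=adi(l1, l2, l3),
        SRI=sri(l1, l2, l3),
    )


def features_frame(features_list) -> pd.DataFrame:
    """One row per case, columns in the standard feature order."""
    return pd.DataFrame(
        [f.as_array() for f in features_list], columns=list(FEATURE_NAMES)
    )


# -- two-step LASSO with LOOCV ----------------------------------------------


def _penalty_grid(X: np.ndarray, y: np.ndarray, n_alphas: int = 50) -> np.ndarray:
    alpha_max = np.abs(X.T @ (y - y.mean())).max() / len(y)
    return alpha_max * np.logspace(-4, 1, n_alphas)


@dataclass
class LassoResult:
    """Two-step LASSO fit for one elasticity target."""

    selected: list
    coef: np.ndarray             # standardized scale, zeros where unselected
    intercept: float
    alpha_select: float
    alpha_refit: float
    loocv_mse: float

    def as_series(self) -> pd.Series:
        return pd.Series(self.coef, index=list(FEATURE_NAMES))


class LassoLoocvRegressor(BaseEstimator, RegressorMixin):
    """Two-step LASSO with leave-one-out CV, scikit-learn style.

    Step 1 is selection-oriented: features with nonzero coefficients at
    the penalty chosen from the LOOCV MSE path survive.  With
    ``selection_rule="1se"`` (default) the penalty is the largest one
    whose LOOCV MSE lies within one standard error of the minimum — the
    standard sparsity-favoring rule, since the MSE-minimizing penalty is
    known not to be selection-consistent and retains spurious features at
    any noise level.  ``selection_rule="min"`` uses the MSE minimizer.
    Step 2 is prediction-oriented: a LASSO refit on the selected subset at
    its own LOOCV-MSE-minimizing penalty.  Inputs are standardized
    internally; ``coef_`` is on the standardized scale with exact zeros
    for unselected features.
    """

    def __init__(self, n_alphas: int = 50, max_iter: int = 50000,
                 selection_rule: str = "1se"):
        self.n_alphas = n_alphas
        self.max_iter = max_iter
        self.selection_rule = selection_rule

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        if n < 5:
            raise ValueError(f"need at least 5 cases for LOOCV, got {n}")
        if np.var(y) == 0:
            raise ValueError("constant target: regression undefined")
        if self.selection_rule not in ("1se", "min"):
            raise ValueError(f"unknown selection_rule {self.selection_rule!r}")
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        grid = _penalty_grid(Xs, y, self.n_alphas)
        cv = LeaveOneOut()
        step1 = LassoCV(alphas=grid, cv=cv, max_iter=self.max_iter).fit(Xs, y)
        alpha_sel = float(step1.alpha_)
        if self.selection_rule == "1se":
            mean_mse = step1.mse_path_.mean(axis=1)
            se = step1.mse_path_.std(axis=1) / np.sqrt(n)
            i_min = int(np.argmin(mean_mse))
            within = mean_mse <= mean_mse[i_min] + se[i_min]
            alpha_sel = float(step1.alphas_[within].max())
        sel_model = Lasso(alpha=alpha_sel, max_iter=self.max_iter).fit(Xs, y)
        sel = np.flatnonzero(sel_model.coef_ != 0)
        self.alpha_select_ = alpha_sel
        coef = np.zeros(p)
        if len(sel) == 0:
            # nothing survives selection: intercept-only model
            self.alpha_refit_ = float(step1.alpha_)
            self.intercept_ = float(y.mean())
            self.loocv_mse_ = float(
                np.mean((y - (y.sum() - y) / (n - 1)) ** 2)
            )
        else:
            grid2 = _penalty_grid(Xs[:, sel], y, self.n_alphas)
            step2 = LassoCV(alphas=grid2, cv=cv, max_iter=self.max_iter).fit(
                Xs[:, sel], y
            )
            coef[sel] = step2.coef_
            self.alpha_refit_ = float(step2.alpha_)
            self.intercept_ = float(step2.intercept_)
            self.loocv_mse_ = float(
                step2.mse_path_[np.argmin(step2.mse_path_.mean(axis=1))].mean()
            )
        self.coef_ = coef
        self.selected_ = np.flatnonzero(coef != 0)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        Xs = self.scaler_.transform(np.asarray(X, dtype=float))
        return Xs @ self.coef_ + self.intercept_


def lasso_loocv(features, targets: dict, n_alphas: int = 50) -> dict:
    """Fit the two-step LASSO for each elasticity target.

    ``features`` is an (n, 11) matrix or DataFrame; ``targets`` maps a
    name (e.g. ``"avg_E"``, ``"avg_v"``) to its per-case values.  Returns
    a :class:`LassoResult` per target.
    """
    X = np.asarray(features, dtype=float)
    results = {}
    for name, y in targets.items():
        est = LassoLoocvRegressor(n_alphas=n_alphas).fit(X, np.asarray(y, dtype=float))
        results[name] = LassoResult(
            selected=[FEATURE_NAMES[i] for i in est.selected_],
            coef=est.coef_,
            intercept=est.intercept_,
            alpha_select=est.alpha_select_,
            alpha_refit=est.alpha_refit_,
            loocv_mse=est.loocv_mse_,
        )
    return results
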