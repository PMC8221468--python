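"""Calibration and application of ecosystem-service models.

Each ecosystem service (erosion prevention, forage provision, presence of
iconic species) is proxied by a field indicator — stratified vegetation
cover (%), green biomass (kg m^-2), spekboom cover (%) — regressed on one
spectral index (linear or degree-2 polynomial), optionally with additive
terrain terms. Candidate models are screened for multicollinearity
(VIF < 5), ranked by AIC, and evaluated with repeated 5-fold
cross-validation (mean R^2 and range-standardized RMSE).

``published_models()`` returns the calibrated models of the source study:

    StrVC = 56.36 BSI^2 - 36.66 BSI + 6.06
    GB    = 47.62 NBR^2 + 55.55 NBR + 8.71
    SbC   = 12.24 MSAVI + 0.01 Elevation - 10.49
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .indices import IndexRaster
from .rasterdata import SERVICE_INDICATORS, TerrainStack

logger = logging.getLogger(__name__)

VIF_LIMIT = 5.0

#: physically meaningful indicator ranges, used only for out-of-range logging
PHYSICAL_RANGE = {
    "erosion_prevention": (0.0, 100.0),
    "forage_provision": (0.0, np.inf),
    "iconic_species": (0.0, 100.0),
}

TERRAIN_NAMES = ("Elevation", "Slope")


@dataclass
class ESModel:
    """A calibrated map from spectral index (+ optional terrain) to an
    ecosystem-service indicator.

    ``predictors`` names the design columns in order (e.g. ``["BSI^2",
    "BSI", "intercept"]``); ``coefficients`` matches it one-to-one.
    """

    service: str
    form: str  # "linear" | "quadratic" in the index
    index: str
    terrain: tuple[str, ...]
    predictors: tuple[str, ...]
    coefficients: np.ndarray
    diagnostics: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.predictors):
            raise ValueError("coefficient count does not match predictor names")

    def evaluate(self, index_values, terrain_values: dict | None = None):
        """Evaluate the model; inputs broadcast like numpy arrays."""
        x = np.asarray(index_values, dtype=float)
        cols = []
        if self.form == "quadratic":
            cols.append(x**2)
        cols.append(x)
        for t in self.terrain:
            if terrain_values is None or t not in terrain_values:
                raise ValueError(f"model requires terrain layer {t!r}")
            cols.append(np.asarray(terrain_values[t], dtype=float))
        cols.append(np.ones_like(x))
        return sum(c * col for c, col in zip(self.coefficients, cols))

    def to_json(self, path=None) -> str:
        payload = {
            "service": self.service,
            "form": self.form,
            "index": self.index,
            "terrain": list(self.terrain),
            "predictors": list(self.predictors),
            "coefficients": self.coefficients.tolist(),
            "diagnostics": self.diagnostics,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ESModel":
        from .scenesel import _is_file

        if isinstance(source, (str, Path)) and _is_file(source):
            source = Path(source).read_text()
        d = json.loads(source)
        return cls(
            service=d["service"],
            form=d["form"],
            index=d["index"],
            terrain=tuple(d["terrain"]),
            predictors=tuple(d["predictors"]),
            coefficients=np.asarray(d["coefficients"]),
            diagnostics=d.get("diagnostics", {}),
        )


def published_models() -> dict[str, ESModel]:
    """The three calibrated ecosystem-service models of the source study."""
    return {
        "erosion_prevention": ESModel(
            service="erosion_prevention",
            form="quadratic",
            index="BSI",
            terrain=(),
            predictors=("BSI^2", "BSI", "intercept"),
            coefficients=np.array([56.36, -36.66, 6.06]),
            diagnostics={"cv_r2": 0.85, "std_rmse": 0.19, "n": 32},
        ),
        "forage_provision": ESModel(
            service="forage_provision",
            form="quadratic",
            index="NBR",
            terrain=(),
            predictors=("NBR^2", "NBR", "intercept"),
            coefficients=np.array([47.62, 55.55, 8.71]),
            diagnostics={"cv_r2": 0.71, "std_rmse": 1.19, "n": 32},
        ),
        "iconic_species": ESModel(
            service="iconic_species",
            form="linear",
            index="MSAVI",
            terrain=("Elevation",),
            predictors=("MSAVI", "Elevation", "intercept"),
            coefficients=np.array([12.24, 0.01, -10.49]),
            diagnostics={"cv_r2": 0.53, "std_rmse": 0.62, "n": 20},
        ),
    }


def compute_vif(design: np.ndarray) -> np.ndarray:
    """Variance inflation factor per column: VIF_j = 1/(1 - R^2_j), with
    R^2_j from regressing column j on the other columns plus an intercept.

    Perfectly collinear columns are reported as ``inf`` flags, not raised.
    """
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two predictor columns")
    if n <= p:
        raise ValueError("VIF needs more rows than columns")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant predictor column")
    vifs = np.empty(p)
    for j in range(p):
        y = X[:, j]
        others = np.column_stack([np.delete(X, j, axis=1), np.ones(n)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_tot = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / ss_tot
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def _design_matrix(df: pd.DataFrame, index: str, form: str, terrain: tuple[str, ...]):
    names = []
    cols = []
    x = df[index].to_numpy(dtype=float)
    if form == "quadratic":
        names.append(f"{index}^2")
        cols.append(x**2)
    names.append(index)
    cols.append(x)
    for t in terrain:
        names.append(t)
        cols.append(df[t].to_numpy(dtype=float))
    names.append("intercept")
    cols.append(np.ones(len(df)))
    return np.column_stack(cols), tuple(names)


def _ols(X: np.ndarray, y: np.ndarray):
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ coef) ** 2))
    return coef, rss


def aic(rss: float, n: int, k: int, corrected: bool = False) -> float:
    """AIC = n ln(RSS/n) + 2k (constant terms cancel in within-run ranking);
    ``corrected`` adds the small-sample AICc penalty."""
    rss = max(rss, 1e-300)
    value = n * np.log(rss / n) + 2 * k
    if corrected:
        if n - k - 1 <= 0:
            return np.inf
        value += 2 * k * (k + 1) / (n - k - 1)
    return float(value)


def candidate_forms(index_names, terrain_names=TERRAIN_NAMES):
    """Candidate family: per index a linear and a quadratic single-index
    model, plus multi-predictor linear forms (index + one terrain term)."""
    cands = []
    for ix in index_names:
        cands.append((ix, "linear", ()))
        cands.append((ix, "quadratic", ()))
        for t in terrain_names:
            cands.append((ix, "linear", (t,)))
    return cands


def fit_candidates(
    plots: pd.DataFrame,
    service: str,
    predictors: pd.DataFrame,
    index_names=None,
    terrain_names=None,
    corrected_aic: bool = False,
) -> list[ESModel]:
    """Fit every candidate model for one service and rank by AIC ascending.

    ``plots`` carries the indicator columns; ``predictors`` (same row order)
    carries index values and terrain at the plot pixels. Rows with a missing
    indicator are dropped per service. Multi-predictor candidates with any
    VIF >= 5 are screened out before fitting.
    """
    indicator = SERVICE_INDICATORS[service]
    y_all = plots[indicator]
    keep = y_all.notna().to_numpy()
    y = y_all.to_numpy(dtype=float)[keep]
    df = predictors.loc[keep].reset_index(drop=True)
    n = len(y)
    if n < 8:
        raise ValueError(f"need >= 8 plots with non-missing {indicator}, have {n}")
    if index_names is None:
        index_names = [c for c in predictors.columns if c not in TERRAIN_NAMES]
    if terrain_names is None:
        terrain_names = [c for c in predictors.columns if c in TERRAIN_NAMES]
    models = []
    for ix, form, terrain in candidate_forms(index_names, terrain_names):
        X, names = _design_matrix(df, ix, form, terrain)
        if terrain:  # multi-predictor linear form -> multicollinearity screen
            vifs = compute_vif(X[:, :-1])
            if np.any(vifs >= VIF_LIMIT):
                logger.info("candidate %s+%s screened out, VIF=%s", ix, terrain, vifs)
                continue
        coef, rss = _ols(X, y)
        k = X.shape[1]
        models.append(
            ESModel(
                service=service,
                form=form,
                index=ix,
                terrain=terrain,
                predictors=names,
                coefficients=coef,
                diagnostics={
                    "aic": aic(rss, n, k, corrected_aic),
                    "rss": rss,
                    "n": n,
                    "k": k,
                },
            )
        )
    if not models:
        logger.warning("all candidates for %s failed the VIF screen", service)
    models.sort(key=lambda m: (m.diagnostics["aic"], m.diagnostics["k"]))
    return models


def cross_validate(
    model: ESModel,
    plots: pd.DataFrame,
    predictors: pd.DataFrame,
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
) -> tuple[float, float]:
    """Repeated k-fold cross-validation of one model form.

    Folds are re-randomized each repeat. Returns (mean held-out R^2,
    Std.RMSE), where the per-fold R^2 is the squared Pearson correlation
    between held-out observations and predictions (the caret scoring
    convention, nearly unbiased at small fold sizes) and Std.RMSE =
    RMSE / (Ymax - Ymin) with the range taken over all measured values of
    the indicator. Folds with a constant response or constant predictions
    contribute no R^2 term; they are counted and logged.
    """
    indicator = SERVICE_INDICATORS[model.service]
    keep = plots[indicator].notna().to_numpy()
    y = plots[indicator].to_numpy(dtype=float)[keep]
    df = predictors.loc[keep].reset_index(drop=True)
    n = len(y)
    if n < k:
        raise ValueError(f"n={n} < k={k}")
    X, _ = _design_matrix(df, model.index, model.form, model.terrain)
    y_range = float(np.ptp(y))
    rng = np.random.default_rng(seed)
    r2s, rmses, skipped = [], [], 0
    for _ in range(repeats):
        order = rng.permutation(n)
        folds = np.array_split(order, k)
        sq_err = np.empty(n)
        for fold in folds:
            train = np.setdiff1d(order, fold, assume_unique=True)
            coef, _ = _ols(X[train], y[train])
            pred = X[fold] @ coef
            sq_err[fold] = (y[fold] - pred) ** 2
            if np.ptp(y[fold]) == 0 or np.ptp(pred) == 0:
                skipped += 1
                continue
            r2s.append(float(np.corrcoef(y[fold], pred)[0, 1] ** 2))
        rmses.append(np.sqrt(sq_err.mean()))
    if skipped:
        logger.info("%d constant-response folds skipped in CV", skipped)
    std_rmse = float(np.mean(rmses) / y_range) if y_range > 0 else 0.0
    return float(np.mean(r2s)), std_rmse


def predict_es(
    model: ESModel,
    index: IndexRaster,
    terrain: TerrainStack | None = None,
) -> np.ndarray:
    """Apply a calibrated model per pixel; NaN where the index is invalid.

    Predictions are not clipped to physical ranges; the out-of-range
    fraction is logged for QA.
    """
    if index.name != model.index:
        raise ValueError(f"model expects index {model.index}, got {index.name}")
    terrain_values = None
    if model.terrain:
        if terrain is None:
            raise ValueError(f"model requires terrain layers {model.terrain}")
        terrain_values = {}
        for t in model.terrain:
            layer = {"Elevation": "elevation", "Slope": "slope"}.get(t)
            if layer is None:
                raise ValueError(f"unknown terrain predictor {t!r}")
            terrain_values[t] = getattr(terrain, layer)
    out = model.evaluate(index.values, terrain_values)
    out = np.where(index.valid_mask, out, np.nan)
    lo, hi = PHYSICAL_RANGE.get(model.service, (-np.inf, np.inf))
    valid = out[index.valid_mask]
    if valid.size:
        frac = float(np.mean((valid < lo) | (valid > hi)))
        logger.info("%s: %.1f%% of predictions outside [%s, %s]",
                    model.service, 100 * frac, lo, hi)
    return out
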