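"""Allometric leaf-area models: LA = a · x, fitted through the origin.

The candidate predictors x are simple functions of the leaf length L and
width W (both cm): ``L``, ``W``, ``L+W``, ``L*W`` and ``L/W``.  Each model
is a straight line through the origin — a leaf of vanishing size has no
area — so the only parameter is the slope ``a``:

    a = Σ x_i · LA_i / Σ x_i²          (least squares through the origin)

Predictors are first screened by a Pearson-correlation t-test (default
alpha 0.01); a predictor uncorrelated with area (in cassava, L/W) is
excluded before fitting.  Model comparison uses R² (descending) then RMSE
(ascending).

A registry of published slopes for cassava ships with the package
(``BUILTIN_MODELS``), so leaf area can be predicted without refitting:
the product model ``L*W`` with a = 0.42 is the recommended default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PREDICTOR_KINDS",
    "AllometricModel",
    "ScreenResult",
    "build_predictor",
    "screen_predictor",
    "fit_through_origin",
    "fit_candidate_models",
    "select_best_model",
    "predict_la",
    "BUILTIN_MODELS",
    "get_builtin_model",
]

#: Candidate predictors in increasing order of complexity; this order also
#: breaks exact ties during model selection.
PREDICTOR_KINDS = ("L", "W", "L+W", "L*W", "L/W")


@dataclass(frozen=True)
class AllometricModel:
    """A through-origin leaf-area model LA = a · x.

    Attributes
    ----------
    kind
        Which predictor x is, one of :data:`PREDICTOR_KINDS`.
    a
        Slope, in cm² per predictor unit.
    n
        Number of leaves the slope was fitted on.
    r2
        Squared Pearson correlation between fitted and observed LA by
        default (bounded [0, 1]); the uncentered 1 - SSE/Σ LA² variant is
        available at fit time.  For registry models this is the published
        value and is carried as metadata.
    rmse
        Root mean squared residual of the fit, cm² (denominator n).
    provenance
        "fitted" for models produced by :func:`fit_through_origin`,
        otherwise a registry tag.
    """

    kind: str
    a: float
    n: int | None = None
    r2: float | None = None
    rmse: float | None = None
    provenance: str = "fitted"

    def predict(self, L, W):
        return self.a * build_predictor(L, W, self.kind)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "AllometricModel":
        return cls(**json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the correlation screen for one predictor."""

    kind: str
    passed: bool
    p_value: float
    r: float


def build_predictor(L, W, kind: str):
    """Evaluate the predictor ``kind`` for length(s) L and width(s) W (cm)."""
    L = np.asarray(L, dtype=float)
    W = np.asarray(W, dtype=float)
    if np.any(L <= 0) or np.any(W <= 0):
        raise ValueError("L and W must be > 0")
    if kind == "L":
        out = L
    elif kind == "W":
        out = W
    elif kind == "L+W":
        out = L + W
    elif kind == "L*W":
        out = L * W
    elif kind == "L/W":
        out = L / W
    else:
        raise ValueError(f"unknown predictor kind {kind!r}")
    return out if out.ndim else float(out)


def screen_predictor(x, la, alpha: float = 0.01, kind: str = "") -> ScreenResult:
    """Pearson-correlation t-test between a predictor and measured area.

    The predictor fails the screen (and is excluded from fitting) when the
    two-sided p-value exceeds ``alpha``.
    """
    x = np.asarray(x, dtype=float)
    la = np.asarray(la, dtype=float)
    if x.size != la.size or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(la) == 0:
        raise ValueError("zero-variance input")
    res = stats.pearsonr(x, la)
    return ScreenResult(kind=kind, passed=bool(res.pvalue <= alpha),
                        p_value=float(res.pvalue), r=float(res.statistic))


def fit_through_origin(x, la, kind: str = "L*W", r2_method: str = "pearson") -> AllometricModel:
    """Least-squares fit of LA = a · x constrained through the origin.

    Parameters
    ----------
    x, la
        Predictor values and measured leaf areas (cm²), equal length n ≥ 2.
    r2_method
        ``"pearson"`` (default): squared correlation between fitted and
        observed values.  ``"uncentered"``: 1 - SSE / Σ la², the no-intercept
        analogue of R².
    """
    x = np.asarray(x, dtype=float)
    la = np.asarray(la, dtype=float)
    if x.size != la.size:
        raise ValueError("length mismatch")
    if x.size < 2:
        raise ValueError("need n >= 2")
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("predictor is identically zero")
    a = float(np.dot(x, la) / sxx)
    resid = la - a * x
    rmse = float(np.sqrt(np.mean(resid**2)))
    if r2_method == "pearson":
        if np.std(x) == 0 or np.std(la) == 0:
            r2 = 1.0 if np.allclose(resid, 0) else 0.0
        else:
            r2 = float(np.corrcoef(a * x, la)[0, 1] ** 2)
    elif r2_method == "uncentered":
        r2 = float(1.0 - np.dot(resid, resid) / np.dot(la, la))
    else:
        raise ValueError(f"unknown r2_method {r2_method!r}")
    return AllometricModel(kind=kind, a=a, n=int(x.size), r2=r2, rmse=rmse)


def fit_candidate_models(
    L,
    W,
    la,
    kinds: Sequence[str] = PREDICTOR_KINDS,
    alpha: float = 0.01,
    screen: bool = True,
    r2_method: str = "pearson",
) -> tuple[list[AllometricModel], list[ScreenResult]]:
    """Screen and fit every candidate predictor.

    Returns the fitted models (screened-out predictors omitted when
    ``screen`` is true) together with all screening results.
    """
    models: list[AllometricModel] = []
    screens: list[ScreenResult] = []
    for kind in kinds:
        x = build_predictor(L, W, kind)
        res = screen_predictor(x, la, alpha=alpha, kind=kind)
        screens.append(res)
        if screen and not res.passed:
            continue
        models.append(fit_through_origin(x, la, kind=kind, r2_method=r2_method))
    return models, screens


def select_best_model(models: Iterable[AllometricModel]) -> AllometricModel:
    """Pick the best model: highest R², ties by lowest RMSE, then by
    predictor simplicity (the order of :data:`PREDICTOR_KINDS`)."""
    models = list(models)
    if not models:
        raise ValueError("no models to select from")

    def sort_key(m: AllometricModel):
        simplicity = PREDICTOR_KINDS.index(m.kind) if m.kind in PREDICTOR_KINDS else 99
        r2 = -np.inf if m.r2 is None else m.r2
        rmse_ = np.inf if m.rmse is None else m.rmse
        return (-r2, rmse_, simplicity)

    return min(models, key=sort_key)


def predict_la(model: AllometricModel, L, W):
    """Predicted leaf area a · x(L, W), in cm²."""
    return model.predict(L, W)


#: Published cassava slopes (fitted on 111 representative leaves), carried
#: with their reported fit diagnostics as metadata.  The L/W predictor
#: failed the correlation screen and has no published model.
BUILTIN_MODELS: dict[str, AllometricModel] = {
    "model1": AllometricModel(kind="L", a=11.58, n=111, r2=0.7221, rmse=44.30,
                              provenance="builtin:cassava"),
    "model2": AllometricModel(kind="W", a=8.54, n=111, r2=0.6921, rmse=60.58,
                              provenance="builtin:cassava"),
    "model3": AllometricModel(kind="L+W", a=4.92, n=111, r2=0.7113, rmse=155.47,
                              provenance="builtin:cassava"),
    "model4": AllometricModel(kind="L*W", a=0.42, n=111, r2=0.9566, rmse=17.54,
                              provenance="builtin:cassava"),
}


def get_builtin_model(name: str = "model4") -> AllometricModel:
    """Look up a published model; accepts ``model4`` or ``builtin:model4``."""
    key = name.split(":", 1)[-1]
    try:
        return BUILTIN_MODELS[key]
    except KeyError:
        raise KeyError(
            f"unknown builtin model {name!r}; choose from {sorted(BUILTIN_MODELS)}"
        ) from None
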