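"""Additive smooth model of qPCR efficiency over sequence covariates.

The model is a Gaussian generalized additive model on the efficiency scale

    efficiency ~ intercept + s(lengthSequence, gcSequence)
                           + s(primersLength, gcPrimers)
                           + s(gcImbalance, primerDimers)

with each ``s`` a bivariate penalized regression spline: a tensor product
of marginal cubic B-spline bases (6 x 5 = 30 coefficients per term by
default) with second-order difference penalties on both margins and one
smoothing parameter per term, selected by minimizing the generalized
cross-validation score GCV = n * RSS / (n - edf)^2.  Each smooth's design
columns are centred so the fitted smooths average to zero over the
training rows and the intercept carries the mean response.

The three covariate pairs capture, respectively, the interaction of
amplicon length with amplicon G+C content, of primer length with primer
G+C content, and of the primers' G+C imbalance with their triplet-based
cross-hybridization (primer-dimer) score.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .errors import (
    ConfigurationError,
    DegenerateDesignError,
    IncomparableModelsError,
    ModelIOError,
    SchemaError,
    UnsupportedVersionError,
)

__all__ = [
    "DEFAULT_SMOOTH_PAIRS",
    "EfficiencyModel",
    "FitSummary",
    "TensorSmooth",
    "compare_models_aic",
    "fit_gam",
    "gcv_score",
    "load_model",
    "predict_efficiency",
    "save_model",
]

DEFAULT_SMOOTH_PAIRS = (
    ("lengthSequence", "gcSequence"),
    ("primersLength", "gcPrimers"),
    ("gcImbalance", "primerDimers"),
)

MODEL_FORMAT_VERSION = 1
_DEGREE = 3
_MIN_RECORDS = 100
_LOGLAM_STARTS = ((0.0, 0.0, 0.0), (4.0, 4.0, 4.0), (-4.0, -4.0, -4.0))


def _marginal_knots(lo: float, hi: float, k: int) -> np.ndarray:
    """Open uniform cubic knot vector giving exactly *k* basis functions."""
    if k < _DEGREE + 1:
        raise ConfigurationError(f"marginal basis dimension must be >= {_DEGREE + 1}")
    inner = np.linspace(lo, hi, k - _DEGREE + 1)
    return np.r_[[lo] * _DEGREE, inner, [hi] * _DEGREE]


def _basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    lo, hi = knots[0], knots[-1]
    return BSpline.design_matrix(np.clip(x, lo, hi), knots, _DEGREE).toarray()


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    d = np.diff(np.eye(k), order, axis=0)
    return d.T @ d


@dataclass
class TensorSmooth:
    """One fitted bivariate smooth term."""

    names: tuple[str, str]
    knots1: np.ndarray
    knots2: np.ndarray
    k1: int
    k2: int
    col_means: np.ndarray  # training column means of the tensor design
    coef: np.ndarray
    lam: float
    edf: float

    def design(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        b1 = _basis(x1, self.knots1)
        b2 = _basis(x2, self.knots2)
        x = (b1[:, :, None] * b2[:, None, :]).reshape(len(x1), self.k1 * self.k2)
        return x - self.col_means

    def __call__(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        return self.design(x1, x2) @ self.coef

    def penalty(self) -> np.ndarray:
        return np.kron(_difference_penalty(self.k1), np.eye(self.k2)) + np.kron(
            np.eye(self.k1), _difference_penalty(self.k2)
        )


@dataclass
class EfficiencyModel:
    """Fitted additive model: intercept plus bivariate smooth terms."""

    intercept: float
    terms: list[TensorSmooth]
    scale: float                       # residual variance estimate RSS/(n-edf)
    n_train: int
    edf_total: float
    rss: float
    covariate_ranges: dict[str, tuple[float, float]]
    response_range: tuple[float, float] = (1.0, 2.0)
    data_fingerprint: str = ""

    @property
    def covariates(self) -> list[str]:
        seen: list[str] = []
        for t in self.terms:
            for nm in t.names:
                if nm not in seen:
                    seen.append(nm)
        return seen

    def aic(self) -> float:
        """-2 * Gaussian log-likelihood (MLE variance) + 2 * total edf."""
        n = self.n_train
        m2ll = n * math.log(2.0 * math.pi * self.rss / n) + n
        return m2ll + 2.0 * self.edf_total


@dataclass
class FitSummary:
    """Fit diagnostics in the layout of a standard GAM summary."""

    intercept: float
    r_squared_adj: float
    deviance_explained: float
    gcv_score: float
    scale_estimate: float
    n: int
    aic: float
    smooth_terms: list[dict] = field(default_factory=list)

    def __str__(self) -> str:
        lines = [
            "Gaussian additive model",
            f"(Intercept) {self.intercept:.5f}",
            "",
            "Approximate significance of smooth terms",
            f"{'term':34s} {'edf':>7s} {'F':>9s} {'p-value':>10s}",
        ]
        for t in self.smooth_terms:
            lines.append(
                f"s({t['names'][0]},{t['names'][1]})".ljust(34)
                + f" {t['edf']:7.2f} {t['f_stat']:9.3f} {t['p_value']:10.3g}"
            )
        lines += [
            "",
            f"R-sq.(adj) = {self.r_squared_adj:.3f}   "
            f"Deviance explained = {100 * self.deviance_explained:.1f}%",
            f"GCV score = {self.gcv_score:.7g}   Scale est. = {self.scale_estimate:.7g}"
            f"   n = {self.n}",
        ]
        return "\n".join(lines)


def _fingerprint(y: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(np.sort(y), dtype=float).tobytes()).hexdigest()


def fit_gam(
    table: pd.DataFrame,
    response: str = "efficiency",
    smooth_pairs=DEFAULT_SMOOTH_PAIRS,
    k: tuple[int, int] = (6, 5),
) -> tuple[EfficiencyModel, FitSummary]:
    """Fit the penalized additive model to a feature table.

    Requires at least 100 rows with a finite response.  Smoothing parameters
    are chosen by GCV minimization (Nelder-Mead from three fixed starts), so
    the fit is deterministic.
    """
    smooth_pairs = [tuple(p) for p in smooth_pairs]
    needed = [response] + [nm for p in smooth_pairs for nm in p]
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table is missing columns {missing}")
    df = table.loc[np.isfinite(pd.to_numeric(table[response], errors="coerce"))]
    n = len(df)
    if n < _MIN_RECORDS:
        raise ConfigurationError(
            f"need at least {_MIN_RECORDS} records with a measured response, got {n}"
        )
    y = df[response].to_numpy(dtype=float)
    cov: dict[str, np.ndarray] = {}
    for nm in {nm for p in smooth_pairs for nm in p}:
        x = df[nm].to_numpy(dtype=float)
        if not np.all(np.isfinite(x)):
            raise SchemaError(f"covariate {nm!r} contains non-finite values")
        if np.ptp(x) == 0.0:
            raise DegenerateDesignError(f"covariate {nm!r} is constant")
        cov[nm] = x

    terms: list[TensorSmooth] = []
    blocks: list[np.ndarray] = []
    penalties: list[np.ndarray] = []
    for nm1, nm2 in smooth_pairs:
        x1, x2 = cov[nm1], cov[nm2]
        t1 = _marginal_knots(x1.min(), x1.max(), k[0])
        t2 = _marginal_knots(x2.min(), x2.max(), k[1])
        term = TensorSmooth(
            names=(nm1, nm2), knots1=t1, knots2=t2, k1=k[0], k2=k[1],
            col_means=np.zeros(k[0] * k[1]), coef=np.zeros(k[0] * k[1]),
            lam=math.nan, edf=math.nan,
        )
        raw = term.design(x1, x2)  # col_means still zero here
        term.col_means = raw.mean(axis=0)
        x_c = raw - term.col_means
        pen = term.penalty()
        # normalize so one lambda unit means the same thing for every term
        pen = pen * (np.trace(x_c.T @ x_c) / max(np.trace(pen), 1e-12))
        terms.append(term)
        blocks.append(x_c)
        penalties.append(pen)

    x_full = np.hstack([np.ones((n, 1))] + blocks)
    p = x_full.shape[1]
    xtx = x_full.T @ x_full
    xty = x_full.T @ y
    yty = float(y @ y)
    jitter = 1e-7 * np.trace(xtx) / p
    kk = k[0] * k[1]
    slices = [slice(1 + i * kk, 1 + (i + 1) * kk) for i in range(len(terms))]

    def penalized(loglam):
        lam = np.exp(np.clip(loglam, -15.0, 15.0))
        a = xtx + jitter * np.eye(p)
        for lam_i, s, pen in zip(lam, slices, penalties):
            a[s, s] += lam_i * pen
        cho = cho_factor(a)
        beta = cho_solve(cho, xty)
        hat_core = cho_solve(cho, xtx)
        edf = float(np.trace(hat_core))
        rss = max(yty - 2.0 * beta @ xty + beta @ (xtx @ beta), 0.0)
        return beta, edf, rss, cho, hat_core, lam

    def gcv(loglam):
        try:
            _, edf, rss, *_ = penalized(loglam)
        except np.linalg.LinAlgError:
            return 1e12
        if edf >= n - 1:
            return 1e12
        return n * rss / (n - edf) ** 2

    best = None
    for start in _LOGLAM_STARTS:
        res = minimize(
            gcv, np.array(start[: len(terms)] or [0.0] * len(terms)),
            method="Nelder-Mead",
            options=dict(xatol=1e-2, fatol=1e-10, maxiter=200 * len(terms) + 200),
        )
        if best is None or res.fun < best.fun:
            best = res
    beta, edf_total, _, cho, hat_core, lam = penalized(best.x)
    # recompute the final RSS from actual residuals: the quadratic form used
    # inside the GCV loop cancels catastrophically for near-perfect fits
    fitted = x_full @ beta
    rss = float(((y - fitted) ** 2).sum())

    scale = rss / (n - edf_total)
    tss = float(((y - y.mean()) ** 2).sum())
    # a response that is constant to machine precision has no variance to explain
    tss_floor = n * (1e-10 * max(1.0, float(np.abs(y).max()))) ** 2
    if tss <= tss_floor:
        tss = 0.0
    intercept = float(beta[0])
    smooth_info = []
    for i, (term, s, lam_i) in enumerate(zip(terms, slices, lam)):
        term.coef = beta[s]
        term.lam = float(lam_i)
        term.edf = float(np.trace(hat_core[s, s]))
        # Wald-type approximate test of the whole smooth
        fitted_j = blocks[i] @ term.coef
        f_stat = float((fitted_j @ fitted_j) / max(term.edf, 1e-9) / max(scale, 1e-300))
        p_val = float(stats.f.sf(f_stat, max(term.edf, 1e-9), max(n - edf_total, 1.0)))
        smooth_info.append(
            dict(names=term.names, edf=term.edf, lam=term.lam,
                 f_stat=f_stat, p_value=p_val)
        )

    model = EfficiencyModel(
        intercept=intercept,
        terms=terms,
        scale=float(scale),
        n_train=n,
        edf_total=float(edf_total),
        rss=float(rss),
        covariate_ranges={nm: (float(v.min()), float(v.max())) for nm, v in cov.items()},
        data_fingerprint=_fingerprint(y),
    )
    summary = FitSummary(
        intercept=intercept,
        r_squared_adj=(
            float(1.0 - (rss / (n - edf_total)) / (tss / (n - 1))) if tss > 0 else 0.0
        ),
        deviance_explained=float(1.0 - rss / tss) if tss > 0 else 0.0,
        gcv_score=float(n * rss / (n - edf_total) ** 2),
        scale_estimate=float(scale),
        n=n,
        aic=model.aic(),
        smooth_terms=smooth_info,
    )
    return model, summary


def predict_efficiency(
    model: EfficiencyModel, records: pd.DataFrame, clamp: bool = True
) -> pd.DataFrame:
    """Predict efficiency for each record.

    Returns a DataFrame (same index) with columns ``predicted`` (clamped to
    the physical [1, 2] range when *clamp* is true), ``raw`` (unclamped),
    ``clamped`` and ``extrapolated`` flags.  Covariates are clipped to the
    training range for basis evaluation; records outside it are flagged.
    """
    missing = [nm for nm in model.covariates if nm not in records.columns]
    if missing:
        raise SchemaError(f"prediction records are missing columns {missing}")
    cov = {nm: records[nm].to_numpy(dtype=float) for nm in model.covariates}
    for nm, x in cov.items():
        if not np.all(np.isfinite(x)):
            raise SchemaError(f"covariate {nm!r} contains non-finite values")
    raw = np.full(len(records), model.intercept)
    for term in model.terms:
        raw = raw + term(cov[term.names[0]], cov[term.names[1]])
    extrapolated = np.zeros(len(records), dtype=bool)
    for nm, (lo, hi) in model.covariate_ranges.items():
        extrapolated |= (cov[nm] < lo) | (cov[nm] > hi)
    lo, hi = model.response_range
    clipped = np.clip(raw, lo, hi)
    out = pd.DataFrame(
        {
            "predicted": clipped if clamp else raw,
            "raw": raw,
            "clamped": clamp & (raw != clipped),
            "extrapolated": extrapolated,
        },
        index=records.index,
    )
    return out


def gcv_score(model: EfficiencyModel, data: pd.DataFrame, response: str = "efficiency") -> float:
    """GCV = n * RSS / (n - edf)^2 of *model* evaluated on *data*."""
    if response not in data.columns:
        raise SchemaError(f"data is missing the response column {response!r}")
    y = data[response].to_numpy(dtype=float)
    n = len(y)
    if model.edf_total >= n:
        raise ConfigurationError(
            f"total edf {model.edf_total:.1f} must be below n = {n}"
        )
    pred = predict_efficiency(model, data, clamp=False)["raw"].to_numpy()
    rss = float(((y - pred) ** 2).sum())
    return n * rss / (n - model.edf_total) ** 2


def compare_models_aic(
    model_a: EfficiencyModel, model_b: EfficiencyModel
) -> tuple[EfficiencyModel, float]:
    """Prefer the model with lower AIC; ties go to fewer effective df.

    Returns ``(preferred, delta_aic)`` with ``delta_aic`` = AIC(other) -
    AIC(preferred) >= 0.  Models fitted on different responses are not
    comparable.
    """
    if (
        model_a.n_train != model_b.n_train
        or model_a.data_fingerprint != model_b.data_fingerprint
    ):
        raise IncomparableModelsError("models were fitted on different training data")
    aic_a, aic_b = model_a.aic(), model_b.aic()
    if math.isclose(aic_a, aic_b, abs_tol=1e-9):
        preferred = model_a if model_a.edf_total <= model_b.edf_total else model_b
        return preferred, 0.0
    if aic_a < aic_b:
        return model_a, aic_b - aic_a
    return model_b, aic_a - aic_b


# ---------------------------------------------------------------------------
# serialization

def save_model(model: EfficiencyModel, path) -> None:
    """Write the model to a self-describing, versioned JSON file."""
    doc = {
        "format": "ampeff-gam",
        "format_version": MODEL_FORMAT_VERSION,
        "intercept": model.intercept,
        "scale": model.scale,
        "n_train": model.n_train,
        "edf_total": model.edf_total,
        "rss": model.rss,
        "covariate_ranges": {k: list(v) for k, v in model.covariate_ranges.items()},
        "response_range": list(model.response_range),
        "data_fingerprint": model.data_fingerprint,
        "terms": [
            {
                "names": list(t.names),
                "knots1": t.knots1.tolist(),
                "knots2": t.knots2.tolist(),
                "k1": t.k1,
                "k2": t.k2,
                "col_means": t.col_means.tolist(),
                "coef": t.coef.tolist(),
                "lambda": t.lam,
                "edf": t.edf,
            }
            for t in model.terms
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_model(path) -> EfficiencyModel:
    """Load a model written by :func:`save_model`; predictions round-trip exactly."""
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelIOError(f"cannot parse model file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("format") != "ampeff-gam":
        raise ModelIOError(f"{path} is not an ampeff model file")
    version = doc.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"model format version {version!r} is not supported "
            f"(this build reads version {MODEL_FORMAT_VERSION})"
        )
    try:
        terms = [
            TensorSmooth(
                names=tuple(t["names"]),
                knots1=np.asarray(t["knots1"], dtype=float),
                knots2=np.asarray(t["knots2"], dtype=float),
                k1=int(t["k1"]),
                k2=int(t["k2"]),
                col_means=np.asarray(t["col_means"], dtype=float),
                coef=np.asarray(t["coef"], dtype=float),
                lam=float(t["lambda"]),
                edf=float(t["edf"]),
            )
            for t in doc["terms"]
        ]
        return EfficiencyModel(
            intercept=float(doc["intercept"]),
            terms=terms,
            scale=float(doc["scale"]),
            n_train=int(doc["n_train"]),
            edf_total=float(doc["edf_total"]),
            rss=float(doc["rss"]),
            covariate_ranges={
                k: (float(v[0]), float(v[1]))
                for k, v in doc["covariate_ranges"].items()
            },
            response_range=tuple(doc.get("response_range", (1.0, 2.0))),
            data_fingerprint=doc.get("data_fingerprint", ""),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ModelIOError(f"model file {path} is incomplete or corrupt: {exc}") from exc
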