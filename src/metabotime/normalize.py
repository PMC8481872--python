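"""Dataset-level normalization of skewed intensity data.

Two transforms are provided, matching the two analysed compartments: the
Box-Cox power transform (parametric; lambda chosen by profile maximum
likelihood) and the Ordered Quantile (ORQ) rank-based inverse-normal
transform. A selector searches over candidate transforms and picks the one
whose transformed values look most Gaussian, scored by a Pearson chi-square
normality statistic estimated *out of sample* via repeated K-fold
cross-validation with folds shared across candidates. In-sample scoring would
be meaningless here: ORQ maps any tie-free sample onto deterministic normal
scores and would always win.

Normalization is fitted on the pooled vector of all matrix cells per dataset
and applied elementwise, leaving the (feature, sample) addressing unchanged;
per-feature fitting is available behind a flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar

from .errors import DataError
from .io import IntensityMatrix

LAMBDA_BOUNDS = (-2.0, 2.0)
LAMBDA_TOL = 1e-5

#: Fixed candidate order; earlier wins ties.
DEFAULT_CANDIDATES = ("identity", "log", "boxcox", "orq")


# ---------------------------------------------------------------------------
# Box-Cox

@dataclass(frozen=True)
class BoxCoxParams:
    """Fitted Box-Cox transform: y = ((x + shift)^lam - 1)/lam, log at lam=0."""

    lam: float
    shift: float = 0.0


def _shift_for(x: np.ndarray) -> float:
    lo = float(np.min(x))
    if lo > 0:
        return 0.0
    rng = float(np.max(x) - lo)
    return -lo + 1e-6 * (rng if rng > 0 else 1.0)


def boxcox_fit(x: np.ndarray) -> BoxCoxParams:
    """Profile-likelihood fit of lambda on [-2, 2] to 1e-5 tolerance.

    A shift is applied first when the data are not strictly positive
    (raw intensities should be, so that path is defensive).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise DataError(f"boxcox_fit needs at least 3 values, got {x.size}")
    if np.ptp(x) == 0:
        raise DataError("boxcox_fit: constant input")
    shift = _shift_for(x)
    xs = x + shift
    if (xs <= 0).any():
        raise DataError("boxcox_fit: non-positive values remain after shift")
    res = minimize_scalar(
        lambda lam: -stats.boxcox_llf(lam, xs),
        bounds=LAMBDA_BOUNDS,
        method="bounded",
        options={"xatol": LAMBDA_TOL},
    )
    return BoxCoxParams(lam=float(res.x), shift=shift)


def boxcox_apply(x: np.ndarray, params: BoxCoxParams) -> np.ndarray:
    """Elementwise Box-Cox transform; strictly increasing on its domain."""
    xs = np.asarray(x, dtype=float) + params.shift
    if (xs <= 0).any():
        raise DataError("boxcox_apply: non-positive values after shift")
    if abs(params.lam) < 1e-12:
        return np.log(xs)
    return (np.power(xs, params.lam) - 1.0) / params.lam


# ---------------------------------------------------------------------------
# Ordered Quantile (rank-based inverse normal)

@dataclass(frozen=True)
class OrqParams:
    """Sorted (value, normal-score) reference for out-of-sample interpolation."""

    ref_values: np.ndarray
    ref_scores: np.ndarray

    @property
    def n_ref(self) -> int:
        return self.ref_values.size


def orq_fit(x: np.ndarray) -> OrqParams:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3:
        raise DataError(f"orq_fit needs at least 3 values, got {x.size}")
    if np.ptp(x) == 0:
        raise DataError("orq_fit: constant input (all values tied)")
    ranks = stats.rankdata(x, method="average")
    scores = stats.norm.ppf(ranks / (x.size + 1.0))
    order = np.argsort(x, kind="stable")
    return OrqParams(ref_values=x[order], ref_scores=scores[order])


def orq_apply(x: np.ndarray, params: OrqParams) -> np.ndarray:
    """Transform new values by linear interpolation on the fitted reference.

    Values outside the reference range are extrapolated linearly using the
    slope of the outermost reference segment.
    """
    x = np.asarray(x, dtype=float)
    rv, rs = params.ref_values, params.ref_scores
    y = np.interp(x, rv, rs)
    # np.interp clamps; replace the clamped tails with linear extrapolation
    lo, hi = x < rv[0], x > rv[-1]
    if lo.any():
        i = np.searchsorted(rv, rv[0], side="right")  # first strictly larger value
        slope = (rs[i] - rs[0]) / (rv[i] - rv[0])
        y = np.where(lo, rs[0] + slope * (x - rv[0]), y)
    if hi.any():
        i = np.searchsorted(rv, rv[-1], side="left") - 1
        slope = (rs[-1] - rs[i]) / (rv[-1] - rv[i])
        y = np.where(hi, rs[-1] + slope * (x - rv[-1]), y)
    return y


def orq_fit_apply(x: np.ndarray) -> tuple[np.ndarray, OrqParams]:
    """Fit ORQ on ``x`` and return its (distribution-free) transformed values."""
    x = np.asarray(x, dtype=float)
    params = orq_fit(x.ravel())
    ranks = stats.rankdata(x.ravel(), method="average").reshape(x.shape)
    return stats.norm.ppf(ranks / (x.size + 1.0)), params


# ---------------------------------------------------------------------------
# Normality scoring and the transform selector

def pearson_normality(z: np.ndarray) -> float:
    """Pearson chi-square / df against the normal, equiprobable sqrt(n) bins."""
    z = np.asarray(z, dtype=float).ravel()
    sd = z.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        raise DataError("pearson_normality: zero-variance input")
    z = (z - z.mean()) / sd
    nbins = max(int(math.ceil(math.sqrt(z.size))), 4)
    edges = stats.norm.ppf(np.linspace(0.0, 1.0, nbins + 1))
    observed, _ = np.histogram(z, bins=edges)
    expected = z.size / nbins
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2 / max(nbins - 3, 1)  # 2 estimated moments + closure


@dataclass
class NormalizationReport:
    """Per-candidate CV normality statistics and the chosen transform."""

    statistics: dict[str, float]
    chosen: str
    skipped: dict[str, str] = field(default_factory=dict)
    params: object | None = None

    def to_dict(self) -> dict:
        out = {
            "chosen": self.chosen,
            "statistics": {k: float(v) for k, v in self.statistics.items()},
            "skipped": dict(self.skipped),
        }
        if isinstance(self.params, BoxCoxParams):
            out["params"] = {"lambda": self.params.lam, "shift": self.params.shift}
        elif isinstance(self.params, OrqParams):
            out["params"] = {"n_ref": int(self.params.n_ref)}
        else:
            out["params"] = None
        return out


def _fit_apply(name: str, train: np.ndarray, test: np.ndarray) -> np.ndarray:
    if name == "identity":
        return test
    if name == "log":
        if (train <= 0).any() or (test <= 0).any():
            raise DataError("log requires strictly positive values")
        return np.log(test)
    if name == "boxcox":
        return boxcox_apply(test, boxcox_fit(train))
    if name == "orq":
        return orq_apply(test, orq_fit(train))
    raise DataError(f"unknown normalization candidate {name!r}")


def fit_named(name: str, x: np.ndarray):
    """Fit the named transform on ``x`` and return (transformed, params)."""
    x = np.asarray(x, dtype=float)
    if name == "identity":
        return x.copy(), None
    if name == "log":
        if (x <= 0).any():
            raise DataError("log requires strictly positive values")
        return np.log(x), None
    if name == "boxcox":
        params = boxcox_fit(x.ravel())
        return boxcox_apply(x, params), params
    if name == "orq":
        return orq_fit_apply(x)
    raise DataError(f"unknown normalization method {name!r}")


def select_normalization(
    x: np.ndarray,
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES,
    n_folds: int = 10,
    n_repeats: int = 5,
    seed: int = 0,
) -> NormalizationReport:
    """Pick the candidate with the smallest cross-validated normality statistic.

    All candidates are scored on identical fold splits so comparisons are
    paired; candidates whose domain is violated (or that degenerate) are
    skipped with a note. Ties break by candidate order.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 3 * n_folds:
        n_folds = max(2, x.size // 3)
    rng = np.random.default_rng(seed)
    folds: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(n_repeats):
        perm = rng.permutation(x.size)
        for f in range(n_folds):
            test_idx = perm[f::n_folds]
            train_idx = np.delete(perm, np.arange(f, perm.size, n_folds))
            folds.append((train_idx, test_idx))

    statistics: dict[str, float] = {}
    skipped: dict[str, str] = {}
    for name in candidates:
        scores = []
        try:
            for train_idx, test_idx in folds:
                z = _fit_apply(name, x[train_idx], x[test_idx])
                scores.append(pearson_normality(z))
            statistics[name] = float(np.mean(scores))
        except DataError as exc:
            skipped[name] = str(exc)
    if not statistics:
        notes = "; ".join(f"{k}: {v}" for k, v in skipped.items())
        raise DataError(f"all normalization candidates were skipped ({notes})")
    chosen = min(statistics, key=lambda k: (statistics[k], candidates.index(k)))
    return NormalizationReport(statistics=statistics, chosen=chosen, skipped=skipped)


def normalize_matrix(
    matrix: IntensityMatrix,
    method: str = "auto",
    per_feature: bool = False,
    seed: int = 0,
) -> tuple[IntensityMatrix, dict]:
    """Normalize a matrix and return it with a reproducibility report.

    ``method`` is one of ``auto`` (cross-validated search), ``identity``,
    ``log``, ``boxcox`` or ``orq``. The default fits one transform on the
    pooled vector of all cells; ``per_feature=True`` fits row by row (the
    selector, when ``auto``, still runs once on the pooled vector).
    """
    pooled = matrix.values.ravel()
    if method == "auto":
        report = select_normalization(pooled, seed=seed)
        chosen = report.chosen
    else:
        chosen = method
        report = NormalizationReport(statistics={}, chosen=chosen)

    if per_feature:
        rows = []
        for i in range(matrix.values.shape[0]):
            y, _ = fit_named(chosen, matrix.values[i])
            rows.append(y)
        values = np.vstack(rows)
        report.params = None
    else:
        values, params = fit_named(chosen, matrix.values)
        report.params = params

    out = matrix.with_values(values, positive=False)
    info = report.to_dict()
    info.update({"method": method, "per_feature": per_feature})
    return out, info
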