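"""Weighted multiple regression on distance matrices with AICc permutation
significance and Akaike-weight model averaging (MRMPA).

The response is a pairwise genetic-differentiation matrix (F_ST); predictors
are pairwise landscape matrices (cost-weighted dispersal distance, climate
dissimilarities, or Euclidean distance alone).  Matrices are unrolled in a
fixed lower-triangle order, each pair weighted by the total number of
individuals behind it (``n_i + n_j`` by default), and fitted by weighted
least squares with an intercept.

Significance of a model is assessed against matrix permutations: one
designated predictor matrix has its rows *and* columns permuted by the same
population-label permutation (so permuted configurations remain valid
distance matrices), the model is refitted, and the p-value is the proportion
of permuted fits achieving a smaller AICc than the observed fit.  All
``2^p - 1`` non-empty predictor subsets plus the intercept-only model form
the candidate set; Akaike weights ``w_m = exp(-Delta_m/2) / sum exp(-Delta/2)``
summarize model support, averaged coefficients are conditional (over models
containing the predictor), and adjusted standard errors follow the
Burnham–Anderson unconditional-variance formula.  Residuals of the best
model are checked for normality with the Shapiro–Wilk test.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genotype_core import GenotypeDataset
from .matrices import PairwiseMatrix

__all__ = [
    "MatrixRegressionProblem",
    "MRMPAResult",
    "WLSFit",
    "pair_weight_matrix",
    "vectorize",
    "wls_fit",
    "aicc",
    "permutation_test",
    "model_average",
    "residual_normality",
]


def pair_weight_matrix(
    ds_or_sizes: "GenotypeDataset | Mapping[str, int]",
    labels: Sequence[str] | None = None,
    rule: str = "sum",
) -> PairwiseMatrix:
    """Pair weights from per-site sample sizes.

    ``rule='sum'`` gives ``n_i + n_j`` (the total number of samples behind a
    pairwise comparison); ``rule='min'`` is the conservative alternative.
    """
    if isinstance(ds_or_sizes, GenotypeDataset):
        sizes = ds_or_sizes.sample_sizes()
    else:
        sizes = dict(ds_or_sizes)
    labs = tuple(labels) if labels is not None else tuple(sizes)
    n = np.array([sizes[l] for l in labs], dtype=float)
    if rule == "sum":
        w = n[:, None] + n[None, :]
    elif rule == "min":
        w = np.minimum(n[:, None], n[None, :])
    else:
        raise ValueError(f"unknown weighting rule {rule!r}")
    np.fill_diagonal(w, 0.0)
    return PairwiseMatrix(labs, w)


@dataclass(frozen=True)
class MatrixRegressionProblem:
    """Response, named predictor and weight matrices over a shared label set."""

    response: PairwiseMatrix
    predictors: Mapping[str, PairwiseMatrix]
    weights: PairwiseMatrix

    def __post_init__(self) -> None:
        labs = self.response.labels
        for name, m in self.predictors.items():
            if m.labels != labs:
                raise ValueError(
                    f"predictor {name!r} labels differ from the response's; "
                    "reorder with PairwiseMatrix.reorder"
                )
        if self.weights.labels != labs:
            raise ValueError("weight matrix labels differ from the response's")
        if np.any(self.weights.condensed() <= 0):
            raise ValueError("pair weights must be positive")

    @property
    def labels(self) -> tuple[str, ...]:
        return self.response.labels

    @property
    def predictor_names(self) -> tuple[str, ...]:
        return tuple(self.predictors)


def vectorize(
    problem: MatrixRegressionProblem,
    model: Sequence[str] | None = None,
    permuted: dict[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Unroll matrices to (y, X, w) over the canonical pair order.

    ``X`` includes the intercept column first.  Pairs with any NA in the
    response or the selected predictors are dropped listwise; the count of
    dropped pairs is returned.  ``permuted`` optionally substitutes full
    square value arrays for named predictors (used by the permutation test).
    """
    names = list(model) if model is not None else list(problem.predictors)
    k = problem.response.n
    iu = np.triu_indices(k, 1)
    y = problem.response.values[iu]
    cols = []
    for name in names:
        vals = (
            permuted[name]
            if permuted is not None and name in permuted
            else problem.predictors[name].values
        )
        cols.append(vals[iu])
    w = problem.weights.values[iu]
    X = np.column_stack([np.ones_like(y)] + cols) if cols else np.ones((len(y), 1))
    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    dropped = int((~keep).sum())
    y, X, w = y[keep], X[keep], w[keep]
    if len(y) < X.shape[1] + 1:
        raise ValueError(
            f"only {len(y)} usable pairs after dropping {dropped} NA pairs; "
            f"model with {X.shape[1]} parameters is unidentifiable"
        )
    return y, X, w, dropped


# ---------------------------------------------------------------------------
# Weighted least squares and AICc
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WLSFit:
    params: np.ndarray  # intercept first
    bse: np.ndarray
    rss: float  # weighted RSS with weights normalized to mean 1
    n: int
    n_params: int  # intercept + slopes + error variance
    residuals: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    weights: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]


def _normalize_weights(w: np.ndarray) -> np.ndarray:
    # mean-1 normalization makes AICc invariant to rescaling the weights
    return w / w.mean()


def _wls_core(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, float]:
    """Fast WLS: coefficients and weighted RSS (weights pre-normalized)."""
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    resid = y - X @ beta
    return beta, float(np.sum(w * resid**2))


def wls_fit(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> WLSFit:
    """Weighted least squares via statsmodels, minimizing sum w (y - Xb)^2.

    ``X`` must carry the intercept column and be full column rank; a rank
    deficiency is reported naming duplicated columns where detectable.
    """
    w = _normalize_weights(np.asarray(w, dtype=float))
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        dupes = []
        for i, j in itertools.combinations(range(X.shape[1]), 2):
            xi, xj = X[:, i], X[:, j]
            if np.allclose(xi - xi.mean(), xj - xj.mean(), atol=1e-10):
                dupes.append((i, j))
        detail = f"; collinear column pairs (0 = intercept): {dupes}" if dupes else ""
        raise ValueError(f"design matrix is rank deficient ({rank}/{X.shape[1]}){detail}")
    res = sm.WLS(y, X, weights=w).fit()
    resid = y - X @ res.params
    return WLSFit(
        params=np.asarray(res.params),
        bse=np.asarray(res.bse),
        rss=float(np.sum(w * resid**2)),
        n=len(y),
        n_params=X.shape[1] + 1,
        residuals=resid,
        weights=w,
    )


def aicc(rss: float, n: int, k: int) -> float:
    """Small-sample Akaike information criterion.

    ``n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)`` with ``k`` counting the intercept,
    slopes and error variance.  ``RSS = 0`` marks a saturated model and comes
    back as ``-inf`` (callers exclude it from averaging with a warning).
    """
    if n <= k + 1:
        raise ValueError(
            f"AICc undefined: n={n} must exceed k+1={k + 1} (correction-term pole)"
        )
    if rss <= 0:
        return -math.inf
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _model_aicc(
    problem: MatrixRegressionProblem,
    model: Sequence[str],
    permuted: dict[str, np.ndarray] | None = None,
) -> float:
    y, X, w, _ = vectorize(problem, model, permuted)
    w = _normalize_weights(w)
    _, rss = _wls_core(y, X, w)
    return aicc(rss, len(y), X.shape[1] + 1)


# ---------------------------------------------------------------------------
# Permutation significance
# ---------------------------------------------------------------------------

def permutation_test(
    problem: MatrixRegressionProblem,
    model: Sequence[str],
    B: int = 10_000,
    seed: int = 0,
    exhaustive: bool = False,
    permute: str | None = None,
    plus_one: bool = True,
) -> float:
    """AICc permutation p-value for one candidate model.

    The designated predictor matrix (``permute``, defaulting to the model's
    single predictor) has rows and columns permuted by the same random
    population permutation while the response, weights and other predictors
    stay fixed; the model is refitted and its AICc compared to the observed
    one.  ``p = (#{AICc_perm < AICc_obs} + 1) / (B + 1)`` (the +1 correction
    is dropped with ``plus_one=False``, giving the raw proportion).
    Exhaustive mode enumerates all ``k!`` label permutations and counts ties
    with the observed AICc as non-exceedances, so ``p >= 1/k!``.
    """
    model = list(model)
    if not model:
        raise ValueError("permutation test needs at least one predictor")
    if permute is None:
        if len(model) != 1:
            raise ValueError(
                "a multi-predictor model needs an explicit `permute` target"
            )
        permute = model[0]
    if permute not in model:
        raise ValueError(f"permuted predictor {permute!r} not in model {model}")
    target = problem.predictors[permute]
    off = target.condensed()
    if np.nanmax(off) - np.nanmin(off) < 1e-15:
        warnings.warn(
            f"predictor {permute!r} is constant across pairs; permutation "
            "p-value undefined"
        )
        return math.nan
    obs = _model_aicc(problem, model)
    kpop = problem.response.n
    if exhaustive:
        if kpop > 8:
            raise ValueError("exhaustive enumeration limited to <= 8 populations")
        n_perm = 0
        n_le = 0
        for perm in itertools.permutations(range(kpop)):
            a = _model_aicc(problem, model, {permute: target.permute(perm)})
            n_perm += 1
            if a < obs - 1e-9 or abs(a - obs) <= 1e-9:
                n_le += 1
        return n_le / n_perm
    if B < 99:
        raise ValueError("need B >= 99 Monte Carlo permutations")
    rng = np.random.default_rng(seed)
    smaller = 0
    for _ in range(B):
        perm = rng.permutation(kpop)
        a = _model_aicc(problem, model, {permute: target.permute(perm)})
        if a < obs - 1e-9:
            smaller += 1
    if plus_one:
        return (smaller + 1) / (B + 1)
    return smaller / B


# ---------------------------------------------------------------------------
# Model set, Akaike weights, averaging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MRMPAResult:
    """Per-model and model-averaged per-predictor summary tables."""

    models: pd.DataFrame  # model, k, aicc, delta, akaike_weight, perm_p
    predictors: pd.DataFrame  # total weight, averaged beta, adjusted SE, z, p
    best_model: tuple[str, ...]
    shapiro_w: float
    shapiro_p: float
    n_pairs: int
    n_dropped: int


def residual_normality(residuals: np.ndarray) -> tuple[float, float]:
    """Shapiro–Wilk W and p on (weighted) residuals; NA for constant input."""
    r = np.asarray(residuals, dtype=float)
    if len(r) < 3 or len(r) > 5000:
        raise ValueError("Shapiro–Wilk requires 3 <= n <= 5000")
    if np.ptp(r) < 1e-14:
        return math.nan, math.nan
    w, p = stats.shapiro(r)
    return float(w), float(p)


def model_average(
    problem: MatrixRegressionProblem,
    B: int = 10_000,
    seed: int = 0,
    conditional: bool = True,
    plus_one: bool = True,
    exhaustive: bool = False,
) -> MRMPAResult:
    """All-subsets AICc comparison with permutation p-values and averaging.

    The candidate set is every non-empty predictor subset plus the
    intercept-only model.  Per-predictor permutation p-values permute that
    predictor under the full model; a multi-predictor model's own p is the
    largest of its members' single-matrix permutation p-values (each member
    permuted in turn while the rest stay fixed).  Averaged betas are
    conditional on the models containing the predictor
    (``conditional=False`` zero-fills absent models instead); adjusted SEs
    use the Burnham–Anderson formula.
    """
    names = list(problem.predictors)
    if not names:
        raise ValueError("empty model set")
    subsets: list[tuple[str, ...]] = [()]
    for r in range(1, len(names) + 1):
        subsets.extend(itertools.combinations(names, r))

    fits: dict[tuple[str, ...], WLSFit] = {}
    aiccs: dict[tuple[str, ...], float] = {}
    n_pairs = n_dropped = 0
    for m in subsets:
        y, X, w, n_dropped = vectorize(problem, m)
        n_pairs = len(y)
        fit = wls_fit(y, X, w)
        if fit.n <= fit.n_params + 1:
            warnings.warn(
                f"model {' + '.join(m) or '(intercept)'} dropped: {fit.n} pairs "
                f"cannot support {fit.n_params} parameters (AICc pole)"
            )
            continue
        a = aicc(fit.rss, fit.n, fit.n_params)
        if not math.isfinite(a):
            warnings.warn(f"model {m or '(intercept)'} saturated (RSS=0); excluded")
            continue
        fits[m] = fit
        aiccs[m] = a
    if not aiccs:
        raise ValueError("every candidate model was saturated")

    amin = min(aiccs.values())
    weights = {m: math.exp(-(a - amin) / 2) for m, a in aiccs.items()}
    total_w = sum(weights.values())
    weights = {m: wgt / total_w for m, wgt in weights.items()}

    ss = np.random.SeedSequence(seed)
    perm_seeds = {
        (m, x): int(c.generate_state(1)[0] % (2**31))
        for (m, x), c in zip(
            [(m, x) for m in aiccs for x in m],
            ss.spawn(sum(len(m) for m in aiccs)),
        )
    }

    def perm_p(m: tuple[str, ...], x: str) -> float:
        return permutation_test(
            problem, m, B=B, seed=perm_seeds[(m, x)], permute=x,
            plus_one=plus_one, exhaustive=exhaustive,
        )

    model_rows = []
    member_p: dict[tuple[tuple[str, ...], str], float] = {}
    for m in sorted(aiccs, key=aiccs.get):
        ps = {}
        for x in m:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ps[x] = perm_p(m, x)
        member_p.update({(m, x): p for x, p in ps.items()})
        valid = [p for p in ps.values() if not math.isnan(p)]
        model_rows.append(
            {
                "model": " + ".join(m) if m else "(intercept)",
                "k": len(m) + 2,
                "AICc": aiccs[m],
                "delta": aiccs[m] - amin,
                "akaike_weight": weights[m],
                "perm_p": max(valid) if valid else math.nan,
            }
        )
    models_df = pd.DataFrame(model_rows)

    full = tuple(names)
    pred_rows = []
    for x in names:
        containing = [m for m in aiccs if x in m]
        if not containing:
            pred_rows.append(
                {"predictor": x, "total_aicc_weight": 0.0,
                 "beta_avg": math.nan, "adjusted_se": math.nan,
                 "z": math.nan, "p_z": math.nan,
                 "perm_p_full_model": math.nan}
            )
            continue
        tw = sum(weights[m] for m in containing)
        betas, ses, ws = [], [], []
        for m in containing:
            i = 1 + m.index(x)  # intercept first
            betas.append(fits[m].params[i])
            ses.append(fits[m].bse[i])
            ws.append(weights[m])
        betas, ses, ws = map(np.asarray, (betas, ses, ws))
        if conditional:
            wn = ws / ws.sum()
        else:
            # zero-filled averaging over the whole model set
            wn = ws  # absent models contribute beta 0 with weight w_m
        beta_bar = float((wn * betas).sum()) if conditional else float((ws * betas).sum())
        adj_se = float(
            (wn * np.sqrt(ses**2 + (betas - beta_bar) ** 2)).sum()
            if conditional
            else (ws * np.sqrt(ses**2 + (betas - beta_bar) ** 2)).sum()
            + (1 - ws.sum()) * abs(beta_bar)
        )
        z = abs(beta_bar) / adj_se if adj_se > 0 else math.nan
        p_z = 2 * (1 - stats.norm.cdf(z)) if not math.isnan(z) else math.nan
        p_perm = member_p.get((full, x), math.nan)
        pred_rows.append(
            {
                "predictor": x,
                "total_aicc_weight": tw,
                "beta_avg": beta_bar,
                "adjusted_se": adj_se,
                "z": z,
                "p_z": p_z,
                "perm_p_full_model": p_perm,
            }
        )
    predictors_df = pd.DataFrame(pred_rows)

    best = min(aiccs, key=aiccs.get)
    bf = fits[best]
    if len(bf.residuals) >= 3:
        sw, sp = residual_normality(bf.residuals * np.sqrt(bf.weights))
    else:
        sw = sp = math.nan
    return MRMPAResult(
        models=models_df,
        predictors=predictors_df,
        best_model=best,
        shapiro_w=sw,
        shapiro_p=sp,
        n_pairs=n_pairs,
        n_dropped=n_dropped,
    )
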