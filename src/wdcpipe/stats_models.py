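"""Random-intercept mixed models, permutation inference, and two-stage FDR.

Model
-----
Per network the full model is

    mean_wdc ~ b0 + b1*group + b2*drug + b3*group:drug + b4*mfd + (1 | participant)

and the within-group model (one group's rows only) is

    mean_wdc ~ b0 + b1*drug + b2*mfd + (1 | participant)

with a Gaussian random intercept per participant absorbing the crossover
design's repeated measures.  Reference levels are nonautistic and placebo.

Fitting
-------
For a single random intercept the covariance is block diagonal,
Var(y) = sigma_e^2 (I + lam * Z Z') with lam = sigma_b^2 / sigma_e^2, so the
profiled (restricted) log-likelihood is a smooth function of the single
scalar lam: for fixed lam the GLS estimates and the residual variance have
closed forms via per-participant sums.  The fitter maximises the profiled
criterion by golden-section search on log(lam) and is vectorised over many
outcome columns at once, which is what makes 5000-permutation tests and
Monte-Carlo calibration studies affordable.  REML is the default for
estimation and reporting; information criteria are always computed from ML
refits because REML likelihoods are not comparable across different
fixed-effect structures.

Wald t statistics use bse from the profiled GLS covariance and a residual
degrees-of-freedom convention df = n_obs - n_fixed (recorded in the result).
The convention cancels out of permutation p-values because observed and
permuted statistics use the identical fitter.

Permutation test
----------------
The outcome column is permuted without restriction across all rows of the
per-network table, the model refitted per permutation, and two-sided
p-values computed with the add-one estimator p = (1 + #{|t*| >= |t|}) / (m + 1).
Unrestricted outcome permutation is the default; permuting within
participants is available via ``scheme="within_participant"``.  Note that
unrestricted permutation ignores the within-participant correlation
structure; it remains approximately calibrated here because every refit
restandardises the statistic under its own variance estimate.

FDR
---
Multiple comparisons within each fitted model's family of tested fixed
effects are handled by a two-stage procedure built on the Benjamini-
Yekutieli (BY) step-up, which is valid under arbitrary dependence: stage 1
runs BY at level alpha/(1+alpha) to estimate the number of true nulls m0,
stage 2 reruns the BY step-up at the sharpened level alpha/(1+alpha) * m/m0.
Reported adjusted p-values are calibrated so that p_fdr <= alpha reproduces
the two-stage decision at level alpha.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    ComparisonError,
    DegenerateInputError,
    DesignError,
    PermutationError,
    ValidationError,
)

log = logging.getLogger(__name__)

N_PERMUTATIONS = 5000
ALPHA = 0.05
#: variance-ratio below which the random intercept is flagged as singular
SINGULAR_TOL = 1e-6
#: golden-section search bounds on log(lam) and iteration count
_LOG_LAM_BOUNDS = (-25.0, 20.0)
_GOLDEN_ITERS = 64

DF_CONVENTION = "residual (n_obs - n_fixed_effects)"

FULL_TERMS = ("intercept", "group", "drug", "group:drug", "mfd")
REDUCED_TERMS = ("intercept", "group", "drug", "mfd")
WITHIN_TERMS = ("intercept", "drug", "mfd")


# ---------------------------------------------------------------------------
# Design matrices
# ---------------------------------------------------------------------------

def _check_long_table(table: pd.DataFrame) -> pd.DataFrame:
    required = {"participant_id", "group", "drug", "mfd", "mean_wdc"}
    missing = required - set(table.columns)
    if missing:
        raise DegenerateInputError(f"long table missing columns: {sorted(missing)}")
    if "network" in table.columns and table["network"].nunique() > 1:
        raise DegenerateInputError(
            "long table contains several networks; filter to one before fitting"
        )
    if not np.all(np.isfinite(table["mfd"])) or np.any(table["mfd"] < 0):
        raise ValidationError("mfd must be finite and >= 0")
    return table


def _design_full(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    group = (table["group"] == "autistic").to_numpy(float)
    drug = (table["drug"] == "drug").to_numpy(float)
    mfd = table["mfd"].to_numpy(float)
    x = np.column_stack([np.ones(len(table)), group, drug, group * drug, mfd])
    return x, list(FULL_TERMS)


def _design_reduced(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    group = (table["group"] == "autistic").to_numpy(float)
    drug = (table["drug"] == "drug").to_numpy(float)
    mfd = table["mfd"].to_numpy(float)
    x = np.column_stack([np.ones(len(table)), group, drug, mfd])
    return x, list(REDUCED_TERMS)


def _design_within(table: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    drug = (table["drug"] == "drug").to_numpy(float)
    mfd = table["mfd"].to_numpy(float)
    x = np.column_stack([np.ones(len(table)), drug, mfd])
    return x, list(WITHIN_TERMS)


# ---------------------------------------------------------------------------
# Profiled random-intercept fitter (vectorised over outcome columns)
# ---------------------------------------------------------------------------

class _Precomp:
    """Quantities depending on the design and grouping only."""

    def __init__(self, x: np.ndarray, codes: np.ndarray):
        self.x = x
        self.codes = codes
        self.n, self.p = x.shape
        self.n_groups = int(codes.max()) + 1
        self.group_sizes = np.bincount(codes, minlength=self.n_groups).astype(float)
        self.xtx = x.T @ x
        sx = np.zeros((self.n_groups, self.p))
        np.add.at(sx, codes, x)
        self.sx = sx


def _eval_profile(
    pre: _Precomp,
    xty: np.ndarray,
    sy: np.ndarray,
    yty: np.ndarray,
    lam: np.ndarray,
    reml: bool,
    want_fit: bool = False,
):
    """Profiled -2 log-(restricted-)likelihood at variance ratio ``lam``.

    ``lam`` has one entry per outcome column.  With ``want_fit`` the GLS
    estimates, covariance and variance components are returned as well.
    """
    n, p = pre.n, pre.p
    w = lam[None, :] * pre.group_sizes[:, None] / (1.0 + lam[None, :] * pre.group_sizes[:, None])
    w = w / pre.group_sizes[:, None]  # = lam / (1 + lam * n_g), stable for huge lam
    a = pre.xtx[None, :, :] - np.einsum("gb,gp,gq->bpq", w, pre.sx, pre.sx)
    c = xty.T - np.einsum("gb,gb,gp->bp", w, sy, pre.sx)
    beta = np.linalg.solve(a, c[..., None])[..., 0]
    yvy = yty - np.einsum("gb,gb->b", w, sy**2)
    rvr = np.maximum(yvy - np.einsum("bp,bp->b", c, beta), 1e-300)
    logdet_v = np.log1p(lam[None, :] * pre.group_sizes[:, None]).sum(axis=0)
    if reml:
        sign, logdet_a = np.linalg.slogdet(a)
        nu = n - p
        crit = logdet_v + logdet_a + nu * (1.0 + np.log(2.0 * np.pi * rvr / nu))
    else:
        crit = logdet_v + n * (1.0 + np.log(2.0 * np.pi * rvr / n))
    if not want_fit:
        return crit
    nu = n - p if reml else n
    sigma2 = rvr / nu
    cov = np.linalg.inv(a) * sigma2[:, None, None]
    bse = np.sqrt(np.einsum("bpp->bp", cov))
    return crit, beta, bse, sigma2


def _fit_batch(
    pre: _Precomp, y: np.ndarray, reml: bool = True
) -> dict[str, np.ndarray]:
    """Fit the random-intercept model for every column of ``y`` (n x B)."""
    if y.ndim == 1:
        y = y[:, None]
    xty = pre.x.T @ y
    sy = np.zeros((pre.n_groups, y.shape[1]))
    np.add.at(sy, pre.codes, y)
    yty = np.einsum("nb,nb->b", y, y)

    def f(s: np.ndarray) -> np.ndarray:
        return _eval_profile(pre, xty, sy, yty, np.exp(s), reml)

    lo, hi = _LOG_LAM_BOUNDS
    b_cols = y.shape[1]
    a = np.full(b_cols, lo)
    b = np.full(b_cols, hi)
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    x1 = b - invphi * (b - a)
    x2 = a + invphi * (b - a)
    f1, f2 = f(x1), f(x2)
    for _ in range(_GOLDEN_ITERS):
        upd = f1 < f2
        a = np.where(upd, a, x1)
        b = np.where(upd, x2, b)
        x1n = b - invphi * (b - a)
        x2n = a + invphi * (b - a)
        xnew = np.where(upd, x1n, x2n)
        fnew = f(xnew)
        f1, f2 = np.where(upd, fnew, f2), np.where(upd, f1, fnew)
        x1, x2 = np.where(upd, x1n, x2), np.where(upd, x1, x2n)
    s_opt = np.where(f1 < f2, x1, x2)
    lam = np.exp(s_opt)
    crit, beta, bse, sigma2 = _eval_profile(pre, xty, sy, yty, lam, reml, want_fit=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = beta / bse
    return {
        "lam": lam,
        "beta": beta,
        "bse": bse,
        "tval": tval,
        "sigma2_resid": sigma2,
        "sigma2_participant": lam * sigma2,
        "llf": -0.5 * crit,
        "crit": crit,
    }


@dataclass
class LmmFit:
    """One fitted random-intercept mixed model."""

    term_names: list[str]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    df_resid: int
    llf: float
    reml: bool
    sigma2_participant: float
    sigma2_resid: float
    var_ratio: float
    singular: bool
    n_obs: int
    n_participants: int
    aic: float
    bic: float
    df_convention: str = DF_CONVENTION
    # data retained for permutation tests and model comparison
    _x: np.ndarray = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)
    _codes: np.ndarray = field(repr=False, default=None)


def _n_model_params(p: int) -> int:
    # fixed effects + random-intercept variance + residual variance
    return p + 2


def _fit_table(
    table: pd.DataFrame, design, reml: bool = True
) -> LmmFit:
    table = _check_long_table(table)
    x, names = design(table)
    y = table["mean_wdc"].to_numpy(float)
    codes, uniques = pd.factorize(table["participant_id"], sort=True)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignError(
            "rank-deficient design matrix (a term is constant or collinear)"
        )
    if np.max(np.bincount(codes)) < 2:
        raise DegenerateInputError(
            "need at least one participant with >= 2 observations"
        )
    if x.shape[0] <= x.shape[1]:
        raise DegenerateInputError(
            f"{x.shape[0]} observations cannot identify {x.shape[1]} fixed effects"
        )
    pre = _Precomp(x, codes)
    res = _fit_batch(pre, y, reml=reml)
    lam = float(res["lam"][0])
    # zero (or numerically vanishing) random-intercept variance
    singular = lam < SINGULAR_TOL or float(res["sigma2_participant"][0]) < 1e-12
    if singular:
        log.warning("random-intercept variance estimated at zero (singular fit)")
    # information criteria from an ML fit (comparable across fixed effects)
    if reml:
        ml = _fit_batch(pre, y, reml=False)
        llf_ml = float(ml["llf"][0])
    else:
        llf_ml = float(res["llf"][0])
    k = _n_model_params(x.shape[1])
    n = x.shape[0]
    return LmmFit(
        term_names=names,
        params=res["beta"][0].copy(),
        bse=res["bse"][0].copy(),
        tvalues=res["tval"][0].copy(),
        df_resid=n - x.shape[1],
        llf=float(res["llf"][0]),
        reml=reml,
        sigma2_participant=float(res["sigma2_participant"][0]),
        sigma2_resid=float(res["sigma2_resid"][0]),
        var_ratio=lam,
        singular=singular,
        n_obs=n,
        n_participants=len(uniques),
        aic=-2.0 * llf_ml + 2.0 * k,
        bic=-2.0 * llf_ml + k * np.log(n),
        _x=x,
        _y=y,
        _codes=codes,
    )


def fit_lmm_full(table: pd.DataFrame, reml: bool = True) -> LmmFit:
    """Fit mean_wdc ~ group * drug + mfd + (1 | participant) on one network."""
    table = _check_long_table(table)
    counts = table.groupby("group")["participant_id"].nunique()
    for grp in ("nonautistic", "autistic"):
        if counts.get(grp, 0) < 2:
            raise DegenerateInputError(f"need >= 2 participants in group {grp!r}")
    return _fit_table(table, _design_full, reml=reml)


def fit_lmm_reduced(table: pd.DataFrame, reml: bool = True) -> LmmFit:
    """Fit the full model without the group:drug interaction term."""
    return _fit_table(table, _design_reduced, reml=reml)


def fit_lmm_within(table: pd.DataFrame, reml: bool = True) -> LmmFit:
    """Fit mean_wdc ~ drug + mfd + (1 | participant) within one group."""
    table = _check_long_table(table)
    if table["group"].nunique() != 1:
        raise DegenerateInputError("within-group model expects a single-group table")
    return _fit_table(table, _design_within, reml=reml)


_DESIGNS = {"full": _design_full, "reduced": _design_reduced, "within": _design_within}


# ---------------------------------------------------------------------------
# Permutation test
# ---------------------------------------------------------------------------

def permutation_test(
    table: pd.DataFrame,
    model_spec: str = "full",
    n_permutations: int = N_PERMUTATIONS,
    seed: int = 0,
    reml: bool = True,
    scheme: str = "unrestricted",
    max_failure_fraction: float = 0.05,
) -> dict:
    """Permutation p-values for each fixed effect of one mixed model.

    The outcome is permuted across all rows (``scheme="unrestricted"``, the
    default) or within each participant's rows (``scheme="within_participant"``),
    the model is refitted per permutation, and two-sided add-one p-values are
    returned per term.  The intercept is not a tested effect and gets NaN.
    Permutations whose refit produces non-finite statistics are redrawn; more
    than ``max_failure_fraction`` failures is an error.
    """
    if n_permutations < 1:
        raise ValidationError("n_permutations must be >= 1")
    if model_spec not in _DESIGNS:
        raise ValidationError(f"unknown model_spec {model_spec!r}")
    observed = _fit_table(table, _DESIGNS[model_spec], reml=reml)
    x, y, codes = observed._x, observed._y, observed._codes
    pre = _Precomp(x, codes)
    tested = [i for i, name in enumerate(observed.term_names) if name != "intercept"]
    t_obs = np.abs(observed.tvalues[tested])

    rng = np.random.default_rng(seed)
    n = len(y)
    exceed = np.zeros(len(tested))
    n_valid = 0
    n_failed = 0
    max_failures = max(1, int(np.ceil(max_failure_fraction * n_permutations)))
    while n_valid < n_permutations:
        b = min(1000, n_permutations - n_valid + n_failed + 8)
        if scheme == "unrestricted":
            idx = rng.permuted(np.tile(np.arange(n), (b, 1)), axis=1)
        elif scheme == "within_participant":
            idx = np.tile(np.arange(n), (b, 1))
            for g in range(pre.n_groups):
                rows = np.flatnonzero(codes == g)
                idx[:, rows] = rows[rng.permuted(np.tile(np.arange(len(rows)), (b, 1)), axis=1)]
        else:
            raise ValidationError(f"unknown permutation scheme {scheme!r}")
        yperm = y[idx.T]  # n x b
        res = _fit_batch(pre, yperm, reml=reml)
        tperm = np.abs(res["tval"][:, tested])  # b x n_tested
        valid = np.all(np.isfinite(tperm), axis=1)
        n_failed += int((~valid).sum())
        if n_failed > max_failures:
            raise PermutationError(
                f"{n_failed} permutation refits failed (> {max_failure_fraction:.0%})"
            )
        tperm = tperm[valid]
        take = min(len(tperm), n_permutations - n_valid)
        exceed += (tperm[:take] >= t_obs[None, :]).sum(axis=0)
        n_valid += take
    if n_failed:
        log.info("redrew %d failed permutations", n_failed)
    p = (1.0 + exceed) / (n_permutations + 1.0)
    p_perm = np.full(len(observed.term_names), np.nan)
    p_perm[tested] = p
    return {
        "term_names": observed.term_names,
        "p_perm": p_perm,
        "tested": tested,
        "observed": observed,
        "n_failed": n_failed,
    }


# ---------------------------------------------------------------------------
# Two-stage Benjamini-Yekutieli FDR
# ---------------------------------------------------------------------------

def _by_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjusted p-values."""
    m = len(p)
    c_m = np.sum(1.0 / np.arange(1, m + 1))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    adj = ranked * c_m * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def fdr_adjust_by_two_stage(
    p_values: Sequence[float], alpha: float = ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage BY FDR control at level ``alpha``.

    Stage 1 runs the BY step-up at alpha' = alpha/(1+alpha); the number of
    rejections r1 estimates the number of true nulls as m0 = m - r1.  Stage 2
    reruns the BY step-up at the sharpened level alpha' * m/m0 (rejecting
    everything if r1 = m, nothing more if r1 = 0).

    Returns ``(p_fdr, reject)`` with adjusted p-values calibrated so that
    ``reject == (p_fdr <= alpha)``.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    alpha1 = alpha / (1.0 + alpha)
    adj = _by_adjust(p)
    r1 = int((adj <= alpha1).sum())
    m0 = m - r1
    # p_fdr <= alpha  <=>  adj * (m0/m) <= alpha1, the stage-2 BY step-up
    p_fdr = np.minimum(adj * (m0 / m) * (1.0 + alpha), 1.0)
    reject = p_fdr <= alpha
    return p_fdr, reject


# ---------------------------------------------------------------------------
# Model comparison by information criteria
# ---------------------------------------------------------------------------

@dataclass
class ICComparison:
    aic: tuple[float, float]
    bic: tuple[float, float]
    preferred_aic: str
    preferred_bic: str


def compare_models_ic(full: LmmFit, reduced: LmmFit, tol: float = 1e-9) -> ICComparison:
    """Compare two models fitted on identical rows by ML AIC/BIC.

    Both models are refitted by maximum likelihood (REML likelihoods are not
    comparable across fixed-effect structures); AIC = -2l + 2k and
    BIC = -2l + k log(n_obs) with k counting fixed effects plus the two
    variance components.
    """
    if full._y is None or reduced._y is None:
        raise ComparisonError("fits must carry their data to be compared")
    if full.n_obs != reduced.n_obs or not np.array_equal(full._y, reduced._y) or not np.array_equal(full._codes, reduced._codes):
        raise ComparisonError("models were fitted on different rows")

    def _ml_ic(fit: LmmFit) -> tuple[float, float]:
        pre = _Precomp(fit._x, fit._codes)
        ml = _fit_batch(pre, fit._y, reml=False)
        k = _n_model_params(fit._x.shape[1])
        llf = float(ml["llf"][0])
        return -2.0 * llf + 2.0 * k, -2.0 * llf + k * np.log(fit.n_obs)

    aic_f, bic_f = _ml_ic(full)
    aic_r, bic_r = _ml_ic(reduced)

    def _prefer(a: float, b: float) -> str:
        if abs(a - b) <= tol:
            return "tie"
        return "full" if a < b else "reduced"

    return ICComparison(
        aic=(aic_f, aic_r),
        bic=(bic_f, bic_r),
        preferred_aic=_prefer(aic_f, aic_r),
        preferred_bic=_prefer(bic_f, bic_r),
    )


# ---------------------------------------------------------------------------
# One-call inference summary
# ---------------------------------------------------------------------------

@dataclass
class LmmPermResult:
    """Fixed effects, permutation p-values and FDR decisions for one model."""

    term_names: list[str]
    estimates: np.ndarray
    t_observed: np.ndarray
    df: int
    p_perm: np.ndarray
    p_fdr: np.ndarray
    reject: np.ndarray
    n_permutations: int
    seed: int
    aic: float
    bic: float
    reml: bool
    df_convention: str
    singular: bool
    n_failed_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.term_names,
                "estimate": self.estimates,
                "t": self.t_observed,
                "df": self.df,
                "p_perm": self.p_perm,
                "p_fdr": self.p_fdr,
                "reject": self.reject,
            }
        )


def lmm_permutation_inference(
    table: pd.DataFrame,
    model_spec: str = "full",
    n_permutations: int = N_PERMUTATIONS,
    seed: int = 0,
    alpha: float = ALPHA,
    reml: bool = True,
    scheme: str = "unrestricted",
) -> LmmPermResult:
    """Fit one model, run the permutation test, and FDR-correct its family.

    The FDR family is the model's set of tested (non-intercept) fixed-effect
    permutation p-values, corrected by the two-stage BY procedure at
    ``alpha``.
    """
    perm = permutation_test(
        table,
        model_spec=model_spec,
        n_permutations=n_permutations,
        seed=seed,
        reml=reml,
        scheme=scheme,
    )
    fit: LmmFit = perm["observed"]
    tested = perm["tested"]
    p_fam, rej_fam = fdr_adjust_by_two_stage(perm["p_perm"][tested], alpha=alpha)
    p_fdr = np.full(len(fit.term_names), np.nan)
    reject = np.zeros(len(fit.term_names), dtype=bool)
    p_fdr[tested] = p_fam
    reject[tested] = rej_fam
    return LmmPermResult(
        term_names=fit.term_names,
        estimates=fit.params,
        t_observed=fit.tvalues,
        df=fit.df_resid,
        p_perm=perm["p_perm"],
        p_fdr=p_fdr,
        reject=reject,
        n_permutations=n_permutations,
        seed=seed,
        aic=fit.aic,
        bic=fit.bic,
        reml=reml,
        df_convention=fit.df_convention,
        singular=fit.singular,
        n_failed_permutations=perm["n_failed"],
    )
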