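"""Bayesian whole-genome regression and genomic prediction.

Implements the "Bayesian alphabet" of marker-effect priors — Bayesian ridge
regression (BRR), BayesA, BayesB, BayesC and the Bayesian lasso (BL) — via a
single Gibbs sampler whose marker-update loop is JIT-compiled with numba.
The model is

    y = 1 mu + X b + Z beta + e,    e ~ N(0, se2 I)

with flat priors on the intercept and fixed effects (e.g. family indicator
columns), and prior-specific shrinkage on the marker effects beta. Default
hyperparameters follow the usual variance-partition heuristic: the prior
expects the markers to explain a fraction R2 (default 0.5) of Var(y).

Genomic estimated breeding values (GEBVs) are Z beta-hat; prediction
accuracy is the Pearson correlation between observed phenotypes and
out-of-fold GEBVs under leave-one-out cross-validation, and accuracies are
compared with Fisher's r-to-z test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .errors import TetrapanelError, UndefinedStatisticError

PRIOR_NAMES = ("BRR", "BayesA", "BayesB", "BayesC", "BL")
_PRIOR_CODE = {name: i for i, name in enumerate(PRIOR_NAMES)}


@dataclass(frozen=True)
class ChainSettings:
    """Gibbs chain settings: 10,000 iterations, burn-in 5,000, thinning 10."""

    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass(frozen=True)
class PriorSpec:
    """Marker-effect prior and hyperparameters.

    Scales are solved at fit time so the prior-expected marker contribution
    equals ``r2`` x Var(y). ``pi0`` is the prior mean probability that a
    marker is *in* the model for the spike-and-slab priors (BayesB/BayesC),
    with Beta concentration ``pi_conc``.
    """

    name: str = "BRR"
    df_beta: float = 5.0
    df_e: float = 5.0
    r2: float = 0.5
    pi0: float = 0.05
    pi_conc: float = 10.0
    bl_shape: float = 1.1

    def __post_init__(self):
        if self.name not in PRIOR_NAMES:
            raise ValueError(
                f"unknown prior {self.name!r}; choose from {PRIOR_NAMES}"
            )
        if self.df_beta <= 0 or self.df_e <= 0:
            raise ValueError("degrees of freedom must be positive")
        if not (0.0 < self.pi0 < 1.0):
            raise ValueError("pi0 must be in (0, 1)")
        if not (0.0 < self.r2 < 1.0):
            raise ValueError("r2 must be in (0, 1)")


@dataclass
class FitResult:
    """Posterior means from one Gibbs run."""

    prior: str
    mu: float
    fixed_effects: np.ndarray
    beta: np.ndarray
    col_means: np.ndarray
    se2: float
    genomic_variance: float
    genomic_share: float
    inclusion_prob: np.ndarray | None
    n_saved: int


@dataclass
class CvResult:
    """Leave-one-out predictions and the resulting accuracy."""

    gebv: np.ndarray
    observed: np.ndarray
    accuracy: float
    prior: str
    family_fixed: bool
    flag: str = ""


@njit(cache=False)
def _rinvgauss(mu, lam):
    v = np.random.normal()
    ysq = v * v
    x = (mu + mu * mu * ysq / (2.0 * lam)
         - (mu / (2.0 * lam)) * np.sqrt(4.0 * mu * lam * ysq
                                        + mu * mu * ysq * ysq))
    if x <= 0.0:
        x = 1e-12
    if np.random.random() <= mu / (mu + x):
        return x
    return mu * mu / x


@njit(cache=False)
def _gibbs(y, Z, X, prior_kind, n_iter, burn_in, thin, seed,
           df_b, S_b, df_e, S_e, pi_a, pi_b, bl_shape, bl_rate):
    """Single-site Gibbs sampler for all five marker-effect priors.

    prior_kind: 0=BRR, 1=BayesA, 2=BayesB, 3=BayesC, 4=BL. Returns posterior
    means of (mu, b, beta, se2, var_g, genomic share, inclusion prob).
    """
    np.random.seed(seed)
    n = y.shape[0]
    m = Z.shape[1]
    nf = X.shape[1]

    zsq = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Z[i, j] * Z[i, j]
        zsq[j] = s
    xsq = np.empty(nf)
    for f in range(nf):
        s = 0.0
        for i in range(n):
            s += X[i, f] * X[i, f]
        xsq[f] = s

    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    b = np.zeros(nf)
    beta = np.zeros(m)
    delta = np.ones(m)                     # spike-slab inclusion indicators
    sb2 = np.full(m, S_b)                  # per-marker slab variances
    sb2_common = S_b
    tau2 = np.full(m, 1.0)
    lam2 = bl_shape / bl_rate if bl_rate > 0 else 1.0
    vy = 0.0
    for i in range(n):
        vy += (y[i] - mu) ** 2
    vy /= max(n - 1, 1)
    se2 = vy * 0.5
    pi_in = pi_a / (pi_a + pi_b)

    e = np.empty(n)
    for i in range(n):
        e[i] = y[i] - mu

    mu_s = 0.0
    b_s = np.zeros(nf)
    beta_s = np.zeros(m)
    se2_s = 0.0
    varg_s = 0.0
    share_s = 0.0
    incl_s = np.zeros(m)
    n_saved = 0

    for it in range(n_iter):
        # intercept (flat prior)
        s = 0.0
        for i in range(n):
            s += e[i] + mu
        mu_new = s / n + np.random.normal() * np.sqrt(se2 / n)
        for i in range(n):
            e[i] += mu - mu_new
        mu = mu_new

        # fixed effects (flat prior)
        for f in range(nf):
            if xsq[f] <= 0.0:
                continue
            rhs = 0.0
            for i in range(n):
                rhs += X[i, f] * e[i]
            rhs += xsq[f] * b[f]
            bn = rhs / xsq[f] + np.random.normal() * np.sqrt(se2 / xsq[f])
            d = bn - b[f]
            for i in range(n):
                e[i] -= X[i, f] * d
            b[f] = bn

        # marker effects
        for j in range(m):
            if zsq[j] <= 0.0:
                beta[j] = 0.0
                continue
            rhs = 0.0
            for i in range(n):
                rhs += Z[i, j] * e[i]
            rhs += zsq[j] * beta[j]
            old = beta[j]

            if prior_kind == 0 or prior_kind == 3:
                vj = sb2_common
            elif prior_kind == 4:
                vj = se2 * tau2[j]
            else:
                vj = sb2[j]

            if prior_kind == 2 or prior_kind == 3:
                # spike-and-slab: sample inclusion indicator
                C = zsq[j] + se2 / vj
                loglik = (0.5 * rhs * rhs / (se2 * C)
                          - 0.5 * np.log(vj * C / se2))
                logodds = np.log(pi_in / (1.0 - pi_in)) + loglik
                if logodds > 35.0:
                    p_in = 1.0
                elif logodds < -35.0:
                    p_in = 0.0
                else:
                    p_in = 1.0 / (1.0 + np.exp(-logodds))
                if np.random.random() < p_in:
                    delta[j] = 1.0
                    bn = (rhs / C
                          + np.random.normal() * np.sqrt(se2 / C))
                else:
                    delta[j] = 0.0
                    bn = 0.0
            else:
                C = zsq[j] + se2 / vj
                bn = rhs / C + np.random.normal() * np.sqrt(se2 / C)

            if bn != old:
                d = bn - old
                for i in range(n):
                    e[i] -= Z[i, j] * d
            beta[j] = bn

        # prior-specific variance updates
        if prior_kind == 0:                       # BRR common variance
            ssb = 0.0
            for j in range(m):
                ssb += beta[j] * beta[j]
            sb2_common = ((ssb + df_b * S_b)
                          / np.random.chisquare(df_b + m))
        elif prior_kind == 1:                     # BayesA per-marker
            for j in range(m):
                sb2[j] = ((beta[j] * beta[j] + df_b * S_b)
                          / np.random.chisquare(df_b + 1.0))
        elif prior_kind == 2:                     # BayesB
            n_in = 0.0
            for j in range(m):
                if delta[j] > 0.5:
                    n_in += 1.0
                    sb2[j] = ((beta[j] * beta[j] + df_b * S_b)
                              / np.random.chisquare(df_b + 1.0))
                else:
                    sb2[j] = df_b * S_b / np.random.chisquare(df_b)
            pi_in = np.random.beta(pi_a + n_in, pi_b + (m - n_in))
            if pi_in < 1e-4:
                pi_in = 1e-4
            if pi_in > 1.0 - 1e-4:
                pi_in = 1.0 - 1e-4
        elif prior_kind == 3:                     # BayesC
            ssb = 0.0
            n_in = 0.0
            for j in range(m):
                if delta[j] > 0.5:
                    n_in += 1.0
                    ssb += beta[j] * beta[j]
            sb2_common = ((ssb + df_b * S_b)
                          / np.random.chisquare(df_b + n_in))
            pi_in = np.random.beta(pi_a + n_in, pi_b + (m - n_in))
            if pi_in < 1e-4:
                pi_in = 1e-4
            if pi_in > 1.0 - 1e-4:
                pi_in = 1.0 - 1e-4
        elif prior_kind == 4:                     # Bayesian lasso
            sum_tau2 = 0.0
            for j in range(m):
                bj2 = beta[j] * beta[j]
                if bj2 < 1e-12:
                    bj2 = 1e-12
                mu_ig = np.sqrt(lam2 * se2 / bj2)
                if mu_ig > 1e8:
                    mu_ig = 1e8
                inv_tau2 = _rinvgauss(mu_ig, lam2)
                tau2[j] = 1.0 / inv_tau2
                sum_tau2 += tau2[j]
            lam2 = np.random.gamma(bl_shape + m,
                                   1.0 / (bl_rate + 0.5 * sum_tau2))

        # residual variance
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        if prior_kind == 4:
            ssb_scaled = 0.0
            for j in range(m):
                ssb_scaled += beta[j] * beta[j] / tau2[j]
            se2 = ((sse + ssb_scaled + df_e * S_e)
                   / np.random.chisquare(n + m + df_e))
        else:
            se2 = (sse + df_e * S_e) / np.random.chisquare(n + df_e)

        # accumulate post-burn-in thinned draws
        if it >= burn_in and (it - burn_in) % thin == 0:
            n_saved += 1
            mu_s += mu
            for f in range(nf):
                b_s[f] += b[f]
            gsum = 0.0
            gsq = 0.0
            for i in range(n):
                gi = 0.0
                for j in range(m):
                    gi += Z[i, j] * beta[j]
                gsum += gi
                gsq += gi * gi
            varg = gsq / n - (gsum / n) ** 2
            varg_s += varg
            share_s += varg / (varg + se2)
            for j in range(m):
                beta_s[j] += beta[j]
                if prior_kind == 2 or prior_kind == 3:
                    incl_s[j] += delta[j]
                else:
                    incl_s[j] += 1.0
            se2_s += se2

    inv = 1.0 / max(n_saved, 1)
    return (mu_s * inv, b_s * inv, beta_s * inv, se2_s * inv,
            varg_s * inv, share_s * inv, incl_s * inv, n_saved)


def _hyperparameters(y, Z, prior: PriorSpec):
    vy = float(np.var(y, ddof=1))
    msx = float(np.sum(np.var(Z, axis=0)))
    if msx <= 0:
        msx = 1.0
    S_e = vy * (1.0 - prior.r2) * (prior.df_e + 2.0) / prior.df_e
    if prior.name in ("BayesB", "BayesC"):
        S_b = (vy * prior.r2 / (msx * prior.pi0)
               * (prior.df_beta + 2.0) / prior.df_beta)
    else:
        S_b = vy * prior.r2 / msx * (prior.df_beta + 2.0) / prior.df_beta
    lam0_sq = 2.0 * (1.0 - prior.r2) / prior.r2 * msx
    bl_rate = (prior.bl_shape - 1.0) / lam0_sq if prior.bl_shape > 1 else 1.0
    pi_a = prior.pi0 * prior.pi_conc
    pi_b = (1.0 - prior.pi0) * prior.pi_conc
    return S_b, S_e, pi_a, pi_b, bl_rate


def fit(y, Z, X=None, prior: PriorSpec | str = "BRR",
        chain: ChainSettings = ChainSettings()) -> FitResult:
    """Fit one Bayesian whole-genome regression by Gibbs sampling.

    Z is the raw (uncentered) marker matrix; it is column-centered
    internally and the training means are stored for prediction. X, if
    given, holds fixed-effect columns (e.g. family indicators) with flat
    priors.
    """
    if isinstance(prior, str):
        prior = PriorSpec(name=prior)
    y = np.ascontiguousarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise TetrapanelError("phenotype vector contains non-finite values")
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] != y.shape[0]:
        raise TetrapanelError("Z not conformable with y")
    col_means = Z.mean(axis=0)
    Zc = np.asfortranarray(Z - col_means)
    if X is None:
        Xc = np.zeros((y.shape[0], 0))
    else:
        Xc = np.asarray(X, dtype=float)
        if Xc.ndim == 1:
            Xc = Xc[:, None]
        if Xc.shape[0] != y.shape[0]:
            raise TetrapanelError("X not conformable with y")
    Xc = np.asfortranarray(Xc)

    S_b, S_e, pi_a, pi_b, bl_rate = _hyperparameters(y, Zc, prior)
    (mu, b, beta, se2, varg, share, incl, n_saved) = _gibbs(
        y, Zc, Xc, _PRIOR_CODE[prior.name],
        chain.n_iter, chain.burn_in, chain.thin, int(chain.seed) % (2**31),
        prior.df_beta, S_b, prior.df_e, S_e, pi_a, pi_b,
        prior.bl_shape, bl_rate,
    )
    return FitResult(
        prior=prior.name, mu=float(mu), fixed_effects=b, beta=beta,
        col_means=col_means, se2=float(se2), genomic_variance=float(varg),
        genomic_share=float(share),
        inclusion_prob=incl if prior.name in ("BayesB", "BayesC") else None,
        n_saved=int(n_saved),
    )


def predict_gebv(fit_result: FitResult, Z_new, X_new=None,
                 include_fixed: bool = True) -> np.ndarray:
    """Predicted values for new samples: intercept + X b-hat + Z beta-hat.

    Z_new is centered with the *training* column means.
    """
    Z_new = np.asarray(Z_new, dtype=float)
    if Z_new.shape[1] != fit_result.beta.shape[0]:
        raise TetrapanelError(
            f"Z_new has {Z_new.shape[1]} markers, fit has "
            f"{fit_result.beta.shape[0]}"
        )
    pred = fit_result.mu + (Z_new - fit_result.col_means) @ fit_result.beta
    if include_fixed and fit_result.fixed_effects.size:
        if X_new is None:
            raise TetrapanelError("fit has fixed effects but X_new is None")
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new[:, None]
        pred = pred + X_new @ fit_result.fixed_effects
    return pred


def loo_cv(y, Z, X=None, prior: PriorSpec | str = "BRR",
           chain: ChainSettings = ChainSettings()) -> CvResult:
    """Leave-one-out cross-validation accuracy of GEBVs.

    Each sample is predicted from a chain fit on the other n-1; fold i runs
    with seed ``chain.seed + i`` so the whole CV is reproducible. Accuracy
    is the Pearson correlation of observed phenotypes with out-of-fold
    predictions.
    """
    if isinstance(prior, str):
        prior = PriorSpec(name=prior)
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 5:
        raise TetrapanelError(f"leave-one-out CV needs n >= 5, got {n}")
    Z = np.asarray(Z, dtype=float)
    X_arr = None
    if X is not None:
        X_arr = np.asarray(X, dtype=float)
        if X_arr.ndim == 1:
            X_arr = X_arr[:, None]
    preds = np.empty(n)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        fold_chain = ChainSettings(chain.n_iter, chain.burn_in, chain.thin,
                                   (chain.seed + i) % (2**31))
        fr = fit(y[mask], Z[mask], None if X_arr is None else X_arr[mask],
                 prior, fold_chain)
        preds[i] = predict_gebv(
            fr, Z[i][None, :], None if X_arr is None else X_arr[i][None, :]
        )[0]
    flag = ""
    if np.std(preds) < 1e-12 or np.std(y) < 1e-12:
        warnings.warn("constant predictions: accuracy undefined, reported 0")
        acc = 0.0
        flag = "undefined-accuracy"
    else:
        acc = float(np.corrcoef(y, preds)[0, 1])
    return CvResult(gebv=preds, observed=y.copy(), accuracy=acc,
                    prior=prior.name, family_fixed=X is not None, flag=flag)


def compare_accuracies(r1: float, n1: int, r2: float, n2: int
                       ) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)); two-sided normal
    p-value.
    """
    if n1 <= 3 or n2 <= 3:
        raise UndefinedStatisticError("Fisher z needs n > 3 in both groups")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise UndefinedStatisticError("|r| must be < 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def grid_evaluate(traits: dict, Z_full, marker_ids, subsets, X=None,
                  priors=PRIOR_NAMES, family_flags=(False, True),
                  chain: ChainSettings = ChainSettings()) -> "pd.DataFrame":
    """LOO-CV accuracy grid over trait x panel subset x prior x family flag.

    ``traits`` maps trait name -> phenotype vector (ancestors already
    excluded); ``subsets`` is a list of PanelSubset. Returns a tidy table
    with one row per cell, plus Fisher comparisons of every cell against the
    best one.
    """
    import pandas as pd

    marker_pos = {m: j for j, m in enumerate(marker_ids)}
    Z_full = np.asarray(Z_full, dtype=float)
    rows = []
    for trait, y in traits.items():
        y = np.asarray(y, dtype=float)
        n = y.shape[0]
        for subset in subsets:
            cols = [marker_pos[m] for m in subset.retained_marker_ids
                    if m in marker_pos]
            Z = Z_full[:, cols]
            for prior in priors:
                for flag in family_flags:
                    cv = loo_cv(y, Z, X if flag else None, prior, chain)
                    rows.append({
                        "trait": trait, "subset_size": subset.size,
                        "r2_threshold": subset.params.r2_threshold,
                        "prior": prior, "family_fixed": flag,
                        "accuracy": cv.accuracy, "n": n, "flag": cv.flag,
                    })
    table = pd.DataFrame(rows)
    if len(table):
        best = table.loc[table["accuracy"].idxmax()]
        zs, ps = [], []
        for _, row in table.iterrows():
            z, p = compare_accuracies(
                min(row["accuracy"], 0.999999), row["n"],
                min(best["accuracy"], 0.999999), best["n"],
            )
            zs.append(z)
            ps.append(p)
        table["z_vs_best"] = zs
        table["p_vs_best"] = ps
    return table
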