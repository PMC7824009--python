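"""Trait computations and phenotype-guided sampling of individuals.

Covers the field-trial side of the pipeline: the area under the disease
progress curve (AUDPC) for late-blight scoring, intra-class correlation as a
proxy for broad-sense heritability in family-structured data, trait
correlations, and the PCA-based choice of which clones from each biparental
family to send for high-throughput genotyping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError

#: default traits entering the sampling PCA; flowering time is excluded
#: because it is typically scored incompletely in the field
DEFAULT_PCA_TRAITS = ("tuber_number", "tuber_weight_total",
                      "tuber_weight_avg", "audpc")


def audpc(days, severities) -> float:
    """Area under the disease progress curve, by the trapezoidal rule.

    ``days`` must be strictly increasing; severities are percentages in
    [0, 100]. Lower AUDPC means a more resistant clone.
    """
    t = np.asarray(days, dtype=float)
    y = np.asarray(severities, dtype=float)
    if t.size != y.size or t.size < 2:
        raise UndefinedStatisticError(
            f"AUDPC needs >= 2 time points, got {t.size}"
        )
    if np.any(np.diff(t) <= 0):
        raise ValueError("scoring days must be strictly increasing")
    return float(np.trapezoid(y, t))


def icc(values, families) -> float:
    """Intra-class correlation from a one-way random-effects ANOVA.

    sigma2_b is estimated as (MSB - MSW) / n0 with n0 the weighted mean
    family size; ICC = sigma2_b / (sigma2_b + sigma2_w), truncated to [0, 1].
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "fam": list(families)}).dropna()
    groups = [g["y"].to_numpy() for _, g in df.groupby("fam")]
    k = len(groups)
    sizes = np.array([len(g) for g in groups])
    N = sizes.sum()
    if k < 2 or sizes.max() < 2:
        raise UndefinedStatisticError(
            "ICC needs >= 2 families and one family with >= 2 members"
        )
    grand = df["y"].mean()
    ssb = float(sum(n * (g.mean() - grand) ** 2 for n, g in zip(sizes, groups)))
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msb = ssb / (k - 1)
    msw = ssw / (N - k) if N > k else 0.0
    n0 = (N - (sizes ** 2).sum() / N) / (k - 1)
    sigma_b = (msb - msw) / n0
    if sigma_b <= 0:
        return 0.0
    return float(min(sigma_b / (sigma_b + msw), 1.0))


def trait_correlation(x, y) -> tuple[float, float]:
    """Pearson correlation of two traits on complete pairs, with two-sided
    t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 4:
        raise UndefinedStatisticError("need >= 4 complete pairs")
    xs, ys = x[ok], y[ok]
    if xs.std() == 0 or ys.std() == 0:
        raise UndefinedStatisticError("correlation undefined for constant trait")
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def select_representatives(phenotypes: pd.DataFrame,
                           traits=DEFAULT_PCA_TRAITS,
                           k_per_family: int = 11,
                           guide_trait: str = "audpc") -> list[str]:
    """Pick k clones per family spanning the disease-resistance axis.

    Procedure: standardize the trait columns over all scored samples, run a
    pooled PCA (SVD), take the component whose loading magnitude on
    ``guide_trait`` is largest (sign fixed so that loading is positive),
    then within each family select k samples at evenly spaced empirical
    quantiles (0, 1/(k-1), ..., 1) of that component's scores, nearest-rank
    rule. Ties in score are broken by sample id, so the output is
    deterministic and invariant to row shuffling.
    """
    traits = list(traits)
    ph = phenotypes.dropna(subset=traits).copy()
    counts = ph.groupby("family")["sample_id"].count()
    small = counts[counts < k_per_family]
    if len(small):
        raise ValueError(
            "families smaller than k after dropping incomplete samples: "
            + ", ".join(f"{f} (n={n})" for f, n in small.items())
        )
    X = ph[traits].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0       # constant trait carries no information
    X = (X - X.mean(axis=0)) / sd
    _, sv, vt = np.linalg.svd(X, full_matrices=False)
    gi = traits.index(guide_trait)
    # consider only non-degenerate components (rank of the trait matrix)
    real = sv > sv[0] * 1e-9
    loadings = np.where(real, np.abs(vt[:, gi]), -1.0)
    comp = int(np.argmax(loadings))
    load = vt[comp]
    if load[gi] < 0:
        load = -load
    ph["score"] = X @ load
    chosen: list[str] = []
    for fam, grp in ph.groupby("family", sort=True):
        grp = grp.sort_values(["score", "sample_id"]).reset_index(drop=True)
        n = len(grp)
        if k_per_family == 1:
            desired = np.array([0])
        else:
            q = np.linspace(0.0, 1.0, k_per_family)
            desired = np.round(q * (n - 1)).astype(int)
        # nearest-rank collisions (when n is barely above k): assign each
        # desired rank to the nearest still-free rank, deterministically
        free = list(range(n))
        picked = []
        for r in desired:
            j = int(np.argmin([abs(f - r) for f in free]))
            picked.append(free.pop(j))
        ranks = np.array(sorted(picked))
        chosen.extend(grp.loc[ranks, "sample_id"].tolist())
    return chosen
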