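"""Marker-based kinship, population structure, and mixed-model association.

The association scan follows the Q+K tradition for structured breeding
populations: a realized-relationship kinship matrix (K) as random effect and
principal coordinates of the genotypic data (Q) as fixed covariates. Variance
components are estimated once under the null model by REML ("P3D"); each
marker is then tested by generalized least squares under one or more
polyploid gene-action encodings, with a Bonferroni threshold across all
marker x model tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import TetrapanelError
from .io import DosageMatrix

GENE_ACTION_MODELS = ("additive", "general", "simplex-dom-ref",
                      "simplex-dom-alt")


@dataclass
class StructureCoordinates:
    """Principal-coordinate scores (columns centered, by decreasing
    eigenvalue) and explained-variance shares."""

    scores: np.ndarray
    explained: np.ndarray
    sample_ids: list[str] | None = None


@dataclass
class GwasResult:
    """Per-(marker, model) score statistics with the Bonferroni threshold."""

    table: pd.DataFrame            # marker, model, stat, df1, pvalue, flag
    alpha: float
    threshold: float
    n_tests: int

    @property
    def significant(self) -> list[str]:
        sig = self.table.loc[self.table["pvalue"] < self.threshold, "marker"]
        return sorted(set(sig))


def _imputed_centered(g: DosageMatrix) -> np.ndarray:
    """Column mean-imputed and centered dosage matrix (never written back)."""
    d = g.dosages.copy()
    mu = np.nanmean(d, axis=0)
    nan = np.isnan(d)
    d[nan] = np.take(mu, np.nonzero(nan)[1])
    return d - mu


def kinship(g: DosageMatrix) -> np.ndarray:
    """Realized-relationship matrix K = M M' / s.

    M is the column-centered (about ploidy * p-hat per marker), mean-imputed
    dosage matrix; s normalizes so the mean diagonal equals 1. Symmetric and
    PSD by construction.
    """
    if g.n_markers == 0:
        raise TetrapanelError("kinship undefined with zero markers")
    M = _imputed_centered(g)
    G = M @ M.T
    tr = np.trace(G)
    if tr <= 0:
        raise TetrapanelError("kinship undefined: no marker variation")
    return G * (g.n_samples / tr)


def pcoa(mat: np.ndarray, n_components: int = 2,
         kind: str = "kinship") -> StructureCoordinates:
    """Classical metric scaling (PCoA) of a kinship or distance matrix.

    A kinship input is first converted to squared Euclidean-type distances
    d2_ij = K_ii + K_jj - 2 K_ij. The decomposition itself is delegated to
    scikit-bio's ordination routine.
    """
    from skbio import DistanceMatrix
    from skbio.stats.ordination import pcoa as _skbio_pcoa

    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise TetrapanelError("PCoA input must be square")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise TetrapanelError("PCoA input must be symmetric")
    if kind == "kinship":
        diag = np.diag(mat)
        d2 = np.maximum(diag[:, None] + diag[None, :] - 2.0 * mat, 0.0)
        dist = np.sqrt(d2)
    elif kind == "distance":
        dist = mat.copy()
    else:
        raise ValueError(f"unknown PCoA input kind {kind!r}")
    np.fill_diagonal(dist, 0.0)
    n_components = min(n_components, dist.shape[0] - 1)
    res = _skbio_pcoa(DistanceMatrix(dist),
                      number_of_dimensions=max(n_components, 1))
    scores = res.samples.to_numpy()[:, :n_components]
    explained = res.proportion_explained.to_numpy()[:n_components]
    return StructureCoordinates(scores - scores.mean(axis=0), explained)


def encode_gene_action(dosage: np.ndarray, model: str) -> np.ndarray:
    """Design column(s) for one marker under a polyploid gene-action model.

    additive: the dosage itself. simplex-dom-ref: presence of at least one
    alternate allele. simplex-dom-alt: presence of at least one reference
    allele. general: one indicator per non-reference dosage class (1..4).
    """
    d = np.asarray(dosage, dtype=float)
    if model == "additive":
        return d[:, None]
    if model == "simplex-dom-ref":
        return (d >= 1).astype(float)[:, None]
    if model == "simplex-dom-alt":
        return (d <= 3).astype(float)[:, None]
    if model == "general":
        return np.column_stack([(d == c).astype(float) for c in (1, 2, 3, 4)])
    raise ValueError(f"unknown gene-action model {model!r}")


# ---------------------------------------------------------------------------
# REML for the null mixed model (EMMA-style profile on the variance ratio)
# ---------------------------------------------------------------------------

def _reml_null(y: np.ndarray, X: np.ndarray, K: np.ndarray):
    """REML fit of y = X b + u + e with u ~ (0, sg2 K), e ~ (0, se2 I).

    Profiles the restricted likelihood over delta = se2/sg2 on the spectrum
    of K. Returns (sg2, se2, U, S) with K = U diag(S) U'.
    """
    n, p = X.shape
    S, U = np.linalg.eigh(K)
    S = np.maximum(S, 0.0)
    yt = U.T @ y
    Xt = U.T @ X

    def neg_restricted_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = S + delta
        Xw = Xt / w[:, None]
        XtWX = Xt.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
        r = yt - Xt @ beta
        rss = float(r @ (r / w))
        sg2 = rss / (n - p)
        _, ld1 = np.linalg.slogdet(XtWX)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi * sg2) + np.sum(np.log(w))
                     + ld1 + (n - p))
        return -ll

    grid = np.linspace(np.log(1e-5), np.log(1e5), 25)
    vals = [neg_restricted_ll(g) for g in grid]
    i = int(np.argmin(vals))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(lo, hi),
                                   method="bounded")
    delta = float(np.exp(res.x))
    w = S + delta
    Xw = Xt / w[:, None]
    beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
    r = yt - Xt @ beta
    sg2 = float(r @ (r / w)) / (n - p)
    se2 = sg2 * delta
    return sg2, se2, U, S, delta


def gwas_scan(y: np.ndarray, g: DosageMatrix, K: np.ndarray | None = None,
              n_pcs: int = 2, models=("additive",), alpha: float = 0.05,
              covariates: np.ndarray | None = None) -> GwasResult:
    """Mixed-model association scan over all markers and gene-action models.

    Two-stage: REML variance components from the null model (once), then a
    GLS F-test of each marker term given the fixed V-hat. The significance
    threshold is alpha / (markers x models tested).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise TetrapanelError("phenotype must be complete for tested samples")
    if K is None:
        K = kinship(g)
    if K.shape != (g.n_samples, g.n_samples):
        raise TetrapanelError("kinship not conformable with genotypes")
    parts = [np.ones((g.n_samples, 1))]
    if covariates is not None:
        parts.append(np.asarray(covariates, dtype=float))
    elif n_pcs > 0:
        parts.append(pcoa(K, n_components=n_pcs).scores)
    X0 = np.column_stack(parts)

    sg2, se2, U, S, delta = _reml_null(y, X0, K)
    w = S + delta                           # V = sg2 * U diag(w) U'
    sw = 1.0 / np.sqrt(w)
    yw = (U.T @ y) * sw
    X0w = (U.T @ X0) * sw[:, None]

    # null residual maker on the whitened scale
    Q0, _ = np.linalg.qr(X0w)
    resid0 = yw - Q0 @ (Q0.T @ yw)
    rss0 = float(resid0 @ resid0)
    p0 = X0w.shape[1]
    n = g.n_samples

    D = g.dosages.copy()
    mu = np.nanmean(D, axis=0)
    nanmask = np.isnan(D)
    D[nanmask] = np.take(mu, np.nonzero(nanmask)[1])

    rows = []
    for model in models:
        for j, marker in enumerate(g.marker_ids):
            Z = encode_gene_action(D[:, j], model)
            Zw = (U.T @ Z) * sw[:, None]
            Zr = Zw - Q0 @ (Q0.T @ Zw)       # project out null design
            # rank of the added term after projection
            qz, rz = np.linalg.qr(Zr)
            keep = np.abs(np.diag(rz)) > 1e-8 * max(1.0, np.abs(rz).max())
            df1 = int(keep.sum())
            if df1 == 0:
                rows.append((marker, model, 0.0, 0, 1.0, "constant"))
                continue
            qz = qz[:, keep]
            proj = qz.T @ resid0
            rss1 = rss0 - float(proj @ proj)
            df2 = n - p0 - df1
            if df2 <= 0 or rss1 <= 0:
                rows.append((marker, model, 0.0, df1, 1.0, "degenerate"))
                continue
            F = ((rss0 - rss1) / df1) / (rss1 / df2)
            p = float(stats.f.sf(F, df1, df2))
            rows.append((marker, model, float(F), df1, max(p, 1e-300), ""))

    table = pd.DataFrame(
        rows, columns=["marker", "model", "stat", "df1", "pvalue", "flag"]
    )
    n_tests = g.n_markers * len(models)
    threshold = alpha / n_tests
    res = GwasResult(table=table, alpha=alpha, threshold=threshold,
                     n_tests=n_tests)
    res.variance_components = {"sg2": sg2, "se2": se2, "delta": delta}
    return res


def bonferroni_threshold(alpha: float, n_markers: int, n_models: int = 1) -> float:
    """Family-wise threshold alpha / (markers x models)."""
    return alpha / (n_markers * n_models)


def count_qtl(result: GwasResult) -> int:
    """Number of distinct significant markers (union over models)."""
    return len(result.significant)


def qtl_per_snp(n_qtl: int, panel_size: int) -> float:
    """QTL yield per marker of a panel."""
    return n_qtl / panel_size
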