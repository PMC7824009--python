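"""Windowed linkage-disequilibrium pruning of SNP panels.

LD between two markers is measured as the squared Pearson correlation (r^2)
of their genotype codes over pairwise-complete samples. Pruning slides a
window of ``window_snps`` currently-retained markers along each chromosome
(pseudomolecule) in map order, removing one member of every retained pair
whose r^2 exceeds the threshold, then advances by ``step_snps``. Chromosomes
— including unanchored groups — are pruned independently; pruning never
crosses a chromosome boundary.

Removal rule: of an offending pair, drop the member with the lower minor
allele frequency (the less informative marker); on a tie, drop the one later
in map order. Offending pairs are resolved highest-r^2 first. Passes repeat
until a full sweep removes nothing, so on exit no window over the retained
set contains a pair above the threshold.

``subset_for_target_size`` searches the threshold by bisection, exploiting
that the retained count is non-decreasing in the threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, UnreachableTargetError
from .io import DosageMatrix, maf as _maf

_VAR_EPS = 1e-12


@dataclass(frozen=True)
class PruneParams:
    """Sliding-window pruning parameters.

    window_snps x step_snps default to 50 x 10, the standard
    "indep-pairwise"-style frame for array data of this density.
    """

    window_snps: int = 50
    step_snps: int = 10
    r2_threshold: float = 1.0

    def __post_init__(self):
        if not (1 <= self.step_snps <= self.window_snps):
            raise ValueError("need 1 <= step_snps <= window_snps")
        if not (0.0 <= self.r2_threshold <= 1.0):
            raise ValueError("r2_threshold must be in [0, 1]")


@dataclass
class PanelSubset:
    """An ordered retained-marker set and the parameters that produced it."""

    retained_marker_ids: list[str]
    params: PruneParams
    per_chrom_counts: dict[str, int] = field(default_factory=dict)
    note: str = ""

    @property
    def size(self) -> int:
        return len(self.retained_marker_ids)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# r2_threshold={self.params.r2_threshold} "
                     f"window={self.params.window_snps} "
                     f"step={self.params.step_snps} size={self.size}\n")
            for m in self.retained_marker_ids:
                fh.write(m + "\n")

    @staticmethod
    def read(path) -> "PanelSubset":
        ids, params = [], PruneParams()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    kv = dict(tok.split("=") for tok in line[1:].split()
                              if "=" in tok)
                    params = PruneParams(int(kv.get("window", 50)),
                                         int(kv.get("step", 10)),
                                         float(kv.get("r2_threshold", 1.0)))
                elif line:
                    ids.append(line)
        return PanelSubset(ids, params)


def pairwise_r2(x, y) -> float:
    """Squared Pearson correlation of two genotype-code vectors.

    Computed over pairwise-complete samples. A constant vector carries no
    evidence of LD and yields 0. Fewer than two complete pairs is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        raise UndefinedStatisticError(
            f"r2 undefined: only {int(ok.sum())} pairwise-complete samples"
        )
    xs, ys = x[ok], y[ok]
    vx = xs.var()
    vy = ys.var()
    if vx < _VAR_EPS or vy < _VAR_EPS:
        return 0.0
    c = ((xs - xs.mean()) * (ys - ys.mean())).mean()
    return min(float(c * c / (vx * vy)), 1.0)


def r2_matrix(X: np.ndarray) -> np.ndarray:
    """Pairwise-complete r^2 matrix for the columns of X (n x k), NaN-aware.

    Pairs with < 2 complete observations or a constant member get 0.
    """
    M = np.isfinite(X).astype(float)
    W = np.where(np.isfinite(X), X, 0.0)
    N = M.T @ M                      # joint observation counts
    Sx = W.T @ M                     # sum of x over joint support
    Sxy = W.T @ W
    Sxx = (W * W).T @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = Sxy - Sx * Sx.T / N
        varx = Sxx - Sx * Sx / N
        r2 = cov * cov / (varx * varx.T)
    bad = (N < 2) | (varx < _VAR_EPS) | (varx.T < _VAR_EPS) | ~np.isfinite(r2)
    r2[bad] = 0.0
    return np.minimum(r2, 1.0)


def _prune_window(r2, order_maf, order_pos, alive_local, threshold):
    """Greedy removal inside one window given its r^2 matrix.

    Mutates ``alive_local`` (bool per window column). Highest-r^2 offending
    pair first; remove the lower-MAF member, tie -> later in map order.
    """
    k = r2.shape[0]
    work = r2.copy()
    np.fill_diagonal(work, 0.0)
    work[~alive_local, :] = 0.0
    work[:, ~alive_local] = 0.0
    removed = []
    while True:
        idx = int(np.argmax(work))
        a, b = divmod(idx, k)
        if work[a, b] <= threshold:
            break
        if (order_maf[a], -order_pos[a]) < (order_maf[b], -order_pos[b]):
            drop = a
        else:
            drop = b
        alive_local[drop] = False
        work[drop, :] = 0.0
        work[:, drop] = 0.0
        removed.append(drop)
    return removed


def prune_chromosome(X: np.ndarray, marker_ids: list[str],
                     params: PruneParams,
                     maf_for_ties: np.ndarray | None = None) -> list[str]:
    """Prune one chromosome's markers (columns of X, in map order).

    Returns the retained marker ids in map order. The comparison is strict:
    only pairs with r^2 > threshold are pruned, so threshold 1.0 retains
    everything except exact duplicates-beyond-1 (impossible), i.e. all.
    """
    m = X.shape[1]
    if m == 0:
        return []
    if maf_for_ties is None:
        with np.errstate(invalid="ignore"):
            p = np.nanmean(X, axis=0) / max(np.nanmax(X), 1.0)
        maf_for_ties = np.minimum(p, 1 - p)
    alive = np.ones(m, dtype=bool)
    W, S = params.window_snps, params.step_snps
    thr = params.r2_threshold
    changed = True
    while changed:
        changed = False
        start = 0
        while True:
            alive_idx = np.flatnonzero(alive)
            if start >= len(alive_idx):
                break
            win = alive_idx[start:start + W]
            if len(win) >= 2:
                r2 = r2_matrix(X[:, win])
                local_alive = np.ones(len(win), dtype=bool)
                removed = _prune_window(r2, maf_for_ties[win], win,
                                        local_alive, thr)
                if removed:
                    changed = True
                    alive[win[~local_alive]] = False
            if start + W >= len(np.flatnonzero(alive)):
                break
            start += S
    return [marker_ids[j] for j in np.flatnonzero(alive)]


def _chrom_blocks(marker_map: pd.DataFrame):
    """Yield (chrom, marker ids sorted by position) per chromosome label."""
    for chrom, grp in marker_map.groupby("chrom", sort=True):
        yield chrom, list(grp.sort_values(["pos_bp", "marker"])["marker"])


def prune_genome(d: DosageMatrix, marker_map: pd.DataFrame,
                 params: PruneParams,
                 maf_for_ties: np.ndarray | None = None) -> PanelSubset:
    """Prune every chromosome independently and concatenate the results."""
    if maf_for_ties is not None:
        maf_by_marker = dict(zip(d.marker_ids, maf_for_ties))
    else:
        maf_by_marker = dict(zip(d.marker_ids, _maf(d)))
    mm = marker_map[marker_map["marker"].isin(set(d.marker_ids))]
    retained_by_chrom: dict[str, list[str]] = {}
    for chrom, ids in _chrom_blocks(mm):
        sub = d.subset_markers(ids)
        kept = prune_chromosome(
            sub.dosages, ids, params,
            np.array([maf_by_marker[m] for m in ids]),
        )
        retained_by_chrom[chrom] = kept
    retained: list[str] = []
    for chrom in sorted(retained_by_chrom):
        retained.extend(retained_by_chrom[chrom])
    counts = {c: len(v) for c, v in retained_by_chrom.items()}
    return PanelSubset(retained, params, counts)


def subset_for_target_size(d: DosageMatrix, marker_map: pd.DataFrame,
                           target_n: int, window_snps: int = 50,
                           step_snps: int = 10, max_iter: int = 40,
                           maf_for_ties: np.ndarray | None = None,
                           ) -> tuple[float, PanelSubset]:
    """Bisect the r^2 threshold to reach a requested panel size.

    The retained count is non-decreasing in the threshold, so bisection
    converges; returns the smallest tested threshold whose subset size is
    >= target_n. Stops when the achieved size is within max(1, 1% of target)
    of the target, or after ``max_iter`` bisection steps.
    """
    total = len(set(d.marker_ids) & set(marker_map["marker"]))
    if not (1 <= target_n <= total):
        raise ValueError(
            f"target_n={target_n} outside [1, {total}] mappable markers"
        )

    def run(thr: float) -> PanelSubset:
        return prune_genome(
            d, marker_map,
            PruneParams(window_snps, step_snps, thr), maf_for_ties,
        )

    floor = run(0.0)
    if target_n < floor.size:
        raise UnreachableTargetError(
            f"target {target_n} below the floor of {floor.size} markers "
            f"retained at threshold 0", floor.size,
        )
    tol = max(1, round(0.01 * target_n))
    if abs(floor.size - target_n) <= tol:
        return 0.0, floor
    lo, hi = 0.0, 1.0
    best_thr, best = 1.0, run(1.0)
    if best.size < target_n:  # cannot happen with strict '>' pruning
        raise UnreachableTargetError(
            f"target {target_n} above {best.size} at threshold 1", best.size
        )
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        sub = run(mid)
        if sub.size >= target_n:
            hi = mid
            if sub.size < best.size or mid < best_thr:
                best_thr, best = mid, sub
            if abs(sub.size - target_n) <= tol:
                return mid, sub
        else:
            lo = mid
    best.note = f"bisection stopped at size {best.size} for target {target_n}"
    return best_thr, best


def spacing_report(subset: PanelSubset, marker_map: pd.DataFrame) -> pd.Series:
    """Mean inter-SNP distance (bp) per chromosome among retained markers.

    Chromosomes with fewer than two retained markers get NaN (undefined).
    """
    mm = marker_map.set_index("marker")
    rows = mm.loc[[m for m in subset.retained_marker_ids if m in mm.index]]
    out = {}
    for chrom, grp in rows.groupby("chrom"):
        pos = np.sort(grp["pos_bp"].to_numpy())
        out[str(chrom)] = float(np.diff(pos).mean()) if len(pos) >= 2 else np.nan
    return pd.Series(out, name="mean_spacing_bp").sort_index()
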