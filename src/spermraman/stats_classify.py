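"""PCA grouping, nonparametric comparison, and ROC cutoff derivation.

The inferential chain mirrors a standard chemometric workflow for
two-group single-cell spectra:

1. PCA of the preprocessed spectra over the 650-1800 cm^-1 fingerprint
   window (absolute intensities, mean-centered per channel but not
   normalized -- absolute intensity carries the DNA-content signal);
2. Hotelling-T2 screening of PCA scores to drop aberrant cells, with one
   refit on the remainder;
3. unsupervised 2-means grouping of the retained scores (deterministic
   farthest-pair initialization) as the label-free counterpart of the
   X/Y split;
4. Shapiro-Wilk normality screening, then a two-sided Mann-Whitney U test
   of each DNA-content score between FISH-labeled X and Y cells (exact by
   enumeration for small samples without ties, tie- and
   continuity-corrected normal approximation otherwise);
5. ROC analysis of each score with X as the positive class, AUC by the
   trapezoid rule, and the operating cutoff chosen by the Youden index
   (ties resolved toward the lower threshold, i.e. higher sensitivity).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .spectra_io import CellRecord

__all__ = [
    "PcaResult",
    "GroupComparison",
    "RocSummary",
    "Histogram",
    "run_pca",
    "hotelling_t2",
    "exclude_outliers",
    "split_groups",
    "normality_check",
    "mann_whitney",
    "roc_analysis",
    "frequency_histogram",
    "classify",
]


# ---------------------------------------------------------------------------
# PCA


@dataclass(frozen=True)
class PcaResult:
    """Mean-centered PCA of a cell-by-channel intensity matrix.

    ``retained`` is the smallest component count explaining >= 90% of the
    variance (minimum 2); ``excluded_ids`` lists cells removed by the
    Hotelling-T2 screen; ``group_assignment`` maps cell_id to the
    unsupervised group (``A`` or ``B``) once :func:`split_groups` has run.
    """

    cell_ids: tuple[str, ...]
    scores: np.ndarray                 # cells x components
    loadings: np.ndarray               # components x channels
    explained_variance: np.ndarray     # fractions, nonincreasing
    retained: int
    wavenumbers: np.ndarray
    matrix: np.ndarray                 # the analyzed cells x channels data
    excluded_ids: tuple[str, ...] = ()
    group_assignment: Mapping[str, str] = field(default_factory=dict)

    @property
    def retained_scores(self) -> np.ndarray:
        return self.scores[:, : self.retained]


def _cell_matrix(cells: Sequence[CellRecord],
                 window: tuple[float, float]) -> tuple[list[str], np.ndarray, np.ndarray]:
    lo, hi = window
    ids, rows = [], []
    grid: np.ndarray | None = None
    for c in cells:
        wn = c.spectrum.wavenumbers
        mask = (wn >= lo) & (wn <= hi)
        sub = wn[mask]
        if grid is None:
            grid = sub
        elif not np.array_equal(grid, sub):
            raise ValueError(
                f"cell {c.cell_id!r}: wavenumber grid differs within the PCA window"
            )
        ids.append(c.cell_id)
        rows.append(c.spectrum.intensities[mask])
    assert grid is not None
    return ids, grid, np.vstack(rows)


def run_pca(cells: Sequence[CellRecord],
            window: tuple[float, float] = (650.0, 1800.0)) -> PcaResult:
    """Standard PCA of the spectra inside `window`.

    Channels are mean-centered; spectra are deliberately *not* vector-
    normalized (see module docstring).  Components carry a deterministic
    sign: the channel with the largest |loading| is made positive.
    """
    if len(cells) < 3:
        raise ValueError("PCA needs at least 3 cells")
    ids, grid, X = _cell_matrix(cells, window)
    if np.allclose(X, X[0], rtol=1e-12, atol=0):
        raise ValueError("all spectra identical: PCA undefined")
    n_comp = min(len(ids) - 1, X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    loadings = pca.components_
    # deterministic sign convention
    flip = np.sign(loadings[np.arange(n_comp), np.abs(loadings).argmax(axis=1)])
    flip[flip == 0] = 1.0
    loadings = loadings * flip[:, None]
    scores = scores * flip[None, :]
    evr = pca.explained_variance_ratio_
    retained = max(2, int(np.searchsorted(np.cumsum(evr), 0.90) + 1))
    retained = min(retained, n_comp)
    return PcaResult(
        cell_ids=tuple(ids), scores=scores, loadings=loadings,
        explained_variance=evr, retained=retained,
        wavenumbers=grid, matrix=X,
    )


def hotelling_t2(p: PcaResult) -> np.ndarray:
    """Per-cell Hotelling T2 over the retained components."""
    t = p.retained_scores
    lam = t.var(axis=0, ddof=1)
    if np.any(lam <= 0):
        raise ValueError("degenerate component variance in Hotelling T2")
    return (t**2 / lam).sum(axis=1)


def exclude_outliers(p: PcaResult, alpha: float = 0.025,
                     window: tuple[float, float] | None = None) -> PcaResult:
    """Drop cells whose Hotelling T2 exceeds the F-based critical value.

    The reference is the classical chemometric limit
    ``k (n-1)(n+1) / (n (n-k)) * F_{1-alpha}(k, n-k)`` with ``k`` retained
    components and ``n`` cells; the PCA is refit once on the remainder.
    Note the limit is a per-cell quantile, so in clean data the *expected*
    number of flagged cells is about ``alpha * n``, not zero.
    """
    n, k = p.scores.shape[0], p.retained
    if k < 2:
        raise ValueError("outlier screen needs >= 2 retained components")
    t2 = hotelling_t2(p)
    crit = k * (n - 1) * (n + 1) / (n * (n - k)) * stats.f.ppf(1 - alpha, k, n - k)
    keep = t2 <= crit
    if keep.all():
        return p
    if keep.sum() < 3:
        raise ValueError("outlier exclusion would leave fewer than 3 cells")
    excluded = tuple(np.asarray(p.cell_ids)[~keep])
    kept_cells = [
        CellRecord(cell_id=cid,
                   spectrum=_spectrum_from_row(p.wavenumbers, row))
        for cid, row in zip(np.asarray(p.cell_ids)[keep], p.matrix[keep])
    ]
    lo, hi = (float(p.wavenumbers[0]), float(p.wavenumbers[-1])) if window is None else window
    refit = run_pca(kept_cells, (lo, hi))
    return replace(refit, excluded_ids=p.excluded_ids + excluded)


def _spectrum_from_row(wn, row):
    from .spectra_io import RamanSpectrum

    return RamanSpectrum(wn, row)


def split_groups(p: PcaResult, i785: Mapping[str, float] | None = None,
                 k: int = 2) -> PcaResult:
    """Deterministic 2-means clustering of the retained PCA scores.

    Initial centers are the two cells at maximal distance in retained
    score space; Lloyd iteration then runs to convergence.  Group ``A`` is
    the cluster with the higher mean I785 (higher DNA-content score) when
    `i785` is given, otherwise the cluster with the higher mean first
    principal-component score.
    """
    if k != 2:
        raise ValueError("only k=2 grouping is supported")
    t = p.retained_scores
    if np.allclose(t, t[0], rtol=0, atol=0 if t.std() == 0 else 1e-12 * t.std()):
        raise ValueError("all scores identical: grouping undefined")
    d2 = ((t[:, None, :] - t[None, :, :]) ** 2).sum(axis=2)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    centers = t[[i, j]].copy()
    assign = np.zeros(len(t), dtype=int)
    for it in range(100):
        dist = ((t[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = dist.argmin(axis=1)
        if it > 0 and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(2):
            if (assign == c).any():
                centers[c] = t[assign == c].mean(axis=0)
    if i785 is not None:
        means = [np.mean([i785[cid] for cid, a in zip(p.cell_ids, assign) if a == c])
                 for c in range(2)]
    else:
        means = [t[assign == c, 0].mean() for c in range(2)]
    a_cluster = int(np.argmax(means))
    mapping = {cid: ("A" if a == a_cluster else "B")
               for cid, a in zip(p.cell_ids, assign)}
    return replace(p, group_assignment=mapping)


# ---------------------------------------------------------------------------
# group comparison


def normality_check(groups: Mapping[str, Sequence[float]],
                    alpha: float = 0.05) -> dict:
    """Shapiro-Wilk per group; verdict ``nonparametric`` if any p < alpha.

    Constant groups have no defined test; they are flagged and force the
    nonparametric path.
    """
    per_group = {}
    verdict = "parametric"
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        if v.size < 3:
            raise ValueError(f"group {name!r}: normality check needs n >= 3")
        if np.ptp(v) == 0:
            per_group[name] = {"p_value": float("nan"), "constant": True}
            verdict = "nonparametric"
            continue
        p = float(stats.shapiro(v).pvalue)
        per_group[name] = {"p_value": p, "constant": False}
        if p < alpha:
            verdict = "nonparametric"
    return {"groups": per_group, "verdict": verdict}


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Mann-Whitney comparison of one feature between X and Y."""

    feature: str
    n_x: int
    n_y: int
    mean_x: float
    mean_y: float
    median_x: float
    median_y: float
    u: float
    p_value: float
    method: str  # "exact" or "normal_approx"


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    # U for x: concordant pairs (x > y) counting ties as 1/2
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = ranks[: x.size].sum()
    return float(r_x - x.size * (x.size + 1) / 2.0)


def _exact_p(x: np.ndarray, y: np.ndarray, u: float) -> float:
    """Two-sided exact p by enumerating all label assignments."""
    pooled = np.sort(np.concatenate([x, y]))
    n, nx = pooled.size, x.size
    ranks = np.arange(1, n + 1)
    offset = nx * (nx + 1) / 2.0
    us = np.array([
        sum(combo) - offset for combo in itertools.combinations(ranks, nx)
    ])
    lo = (us <= u).mean()
    hi = (us >= u).mean()
    return float(min(1.0, 2.0 * min(lo, hi)))


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 feature: str = "") -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Exact p by full enumeration of the ``C(n_x + n_y, n_x)`` label
    assignments when ``n_x + n_y <= 14`` and there are no ties; otherwise
    the normal approximation with tie correction and a 0.5 continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    u = _u_statistic(x, y)
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if nx + ny <= 14 and not has_ties:
        p = _exact_p(x, y, u)
        method = "exact"
    else:
        mu = nx * ny / 2.0
        n = nx + ny
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = (counts**3 - counts).sum() / (n * (n - 1.0))
        var = nx * ny / 12.0 * ((n + 1.0) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            cc = 0.5 * np.sign(u - mu)
            z = (u - mu - cc) / math.sqrt(var)
            p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
        method = "normal_approx"
    return GroupComparison(
        feature=feature, n_x=nx, n_y=ny,
        mean_x=float(x.mean()), mean_y=float(y.mean()),
        median_x=float(np.median(x)), median_y=float(np.median(y)),
        u=u, p_value=p, method=method,
    )


# ---------------------------------------------------------------------------
# ROC


@dataclass(frozen=True)
class RocSummary:
    """ROC curve of one feature with X as the positive class.

    ``cutoff`` is the Youden-optimal threshold: a cell is called X when
    its score is >= cutoff.
    """

    feature: str
    thresholds: np.ndarray  # descending, +inf ... -inf
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float


def roc_analysis(table: pd.DataFrame, feature: str,
                 positive_label: str = "X") -> RocSummary:
    """ROC analysis of a feature column of the feature table.

    Thresholds are the midpoints between consecutive sorted unique scores
    plus +/- infinity sentinels; prediction is positive when
    ``score >= threshold``.  AUC is the trapezoid integral of TPR over
    FPR; the cutoff maximizes Youden's J = TPR - FPR, ties broken toward
    the lower threshold (higher sensitivity).
    """
    labeled = table[table["label"].isin(["X", "Y"])]
    scores = labeled[feature].to_numpy(dtype=float)
    pos = (labeled["label"] == positive_label).to_numpy()
    if pos.all() or not pos.any():
        raise ValueError("ROC needs both classes present")
    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    thresholds = np.concatenate(([np.inf], mids[::-1], [-np.inf]))
    pred = scores[None, :] >= thresholds[:, None]
    tpr = (pred & pos).sum(axis=1) / pos.sum()
    fpr = (pred & ~pos).sum(axis=1) / (~pos).sum()
    auc = float(np.trapezoid(tpr, fpr))
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())[-1]  # thresholds descend: last = lowest
    return RocSummary(
        feature=feature, thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc,
        cutoff=float(thresholds[best]),
        sensitivity=float(tpr[best]), specificity=float(1.0 - fpr[best]),
    )


# ---------------------------------------------------------------------------
# frequency histogram and classification


@dataclass(frozen=True)
class Histogram:
    """Per-label frequency histogram with a CDF-gap breakpoint.

    ``breakpoint`` is the bin edge where the empirical CDFs of the X and Y
    scores differ most (the visual 'frequency difference trend').
    """

    feature: str
    edges: np.ndarray
    counts: Mapping[str, np.ndarray]
    breakpoint: float
    cdf_gap: float


DEFAULT_BIN_WIDTHS = {"I785": 2500.0, "area_714_1162": 250000.0}


def frequency_histogram(table: pd.DataFrame, feature: str,
                        bin_width: float | None = None) -> Histogram:
    """Histogram of one feature per label, bins anchored at 0."""
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTHS.get(feature)
        if bin_width is None:
            raise ValueError(f"no default bin width for feature {feature!r}")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    labeled = table[table["label"].isin(["X", "Y"])]
    vals = labeled[feature].to_numpy(dtype=float)
    lo = math.floor(vals.min() / bin_width)
    hi = math.ceil(vals.max() / bin_width)
    if hi * bin_width <= vals.max():
        hi += 1
    edges = bin_width * np.arange(lo, hi + 1)
    counts = {}
    for lab in ("X", "Y"):
        v = labeled.loc[labeled["label"] == lab, feature].to_numpy(dtype=float)
        counts[lab], _ = np.histogram(v, bins=edges)
    x = labeled.loc[labeled["label"] == "X", feature].to_numpy(dtype=float)
    y = labeled.loc[labeled["label"] == "Y", feature].to_numpy(dtype=float)
    if x.size and y.size:
        fx = (x[None, :] <= edges[:, None]).mean(axis=1)
        fy = (y[None, :] <= edges[:, None]).mean(axis=1)
        gap = np.abs(fx - fy)
        best = int(gap.argmax())
        breakpoint_, cdf_gap = float(edges[best]), float(gap[best])
    else:
        breakpoint_, cdf_gap = float("nan"), float("nan")
    return Histogram(feature=feature, edges=edges, counts=counts,
                     breakpoint=breakpoint_, cdf_gap=cdf_gap)


def classify(table: pd.DataFrame, cutoff: float, feature: str) -> tuple[pd.Series, dict]:
    """Threshold classification: score >= cutoff -> X, else Y.

    Returns per-cell predictions (all cells) and a confusion summary
    against the known labels (cells labeled ``unknown`` are excluded from
    the confusion counts).
    """
    if not np.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    pred = pd.Series(
        np.where(table[feature].to_numpy(dtype=float) >= cutoff, "X", "Y"),
        index=table["cell_id"].to_numpy(), name="predicted",
    )
    labeled = table[table["label"].isin(["X", "Y"])]
    p = pred.loc[labeled["cell_id"].to_numpy()].to_numpy()
    t = labeled["label"].to_numpy()
    conf = {
        "tp": int(((p == "X") & (t == "X")).sum()),
        "fp": int(((p == "X") & (t == "Y")).sum()),
        "fn": int(((p == "Y") & (t == "X")).sum()),
        "tn": int(((p == "Y") & (t == "Y")).sum()),
    }
    n = len(t)
    conf["accuracy"] = (conf["tp"] + conf["tn"]) / n if n else float("nan")
    return pred, conf
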