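"""Between-class analysis, permutation validation, and the stressor span screen.

Between-class analysis (BCA) is the special case of PCA in which a
categorical factor is the explanatory variable: the prepared matrix's
class means, weighted by class frequency, are eigen-decomposed.  The
*between-class inertia ratio* — between-class inertia over total
inertia — measures how much multivariate variance the factor explains,
and is the descriptive statistic used both to validate the stream
groups (with a Monte-Carlo label-permutation test) and to compare them
against an alternative categorical scheme (the ecoregions) on the same
matrix.

Inertia here is the total variance of the prepared matrix with the
``1/n`` convention, so the decomposition *between + within = total* is
exact.  Columns are centred inside :func:`fit_bca`; scaling is the
matrix-preparation step's responsibility (z-scored by default).

The stressor *span screen* checks that every stream group covers the
observed range of anthropogenic-stressor gradients: groups confined to
one end of a stressor axis would indicate a group defined by
degradation rather than natural setting.  Axes are unsupervised PCA
components of the stressor matrix; a group is flagged when its
[q10, q90] score interval overlaps less than a threshold fraction of
the pooled interval on any screened axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from streamarch.datamodel import AnalysisMatrix


@dataclass
class BCAResult:
    total_inertia: float
    between_inertia: float
    within_inertia: float
    inertia_ratio: float
    eigenvalues: np.ndarray
    axis_percents: np.ndarray
    class_scores: pd.DataFrame  # class x axis
    row_scores: np.ndarray
    loadings: pd.DataFrame  # feature x axis
    n_classes: int

    @property
    def inertia_percent(self) -> float:
        """Display form, whole-percent convention (e.g. 27.0)."""
        return float(round(self.inertia_ratio * 100.0))


@dataclass
class PermutationReport:
    observed_ratio: float
    n_replicates: int
    permuted_ratios: np.ndarray
    p_value: float
    seed: int


@dataclass
class SpanReport:
    """Per-(group, axis) coverage of the pooled stressor-score interval."""

    table: pd.DataFrame  # group, axis, lo, hi, pooled_lo, pooled_hi, overlap, status, flagged
    overlap_threshold: float
    axes: int

    @property
    def flagged_groups(self) -> list[str]:
        return sorted(self.table.loc[self.table["flagged"], "group"].unique())


def _as_array(matrix) -> np.ndarray:
    X = matrix.values if isinstance(matrix, AnalysisMatrix) else np.asarray(matrix, float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _feature_names(matrix, p):
    if isinstance(matrix, AnalysisMatrix):
        return list(matrix.column_names)
    return [f"x{j}" for j in range(p)]


def _between_ratio(Xc: np.ndarray, codes: np.ndarray, k: int, total: float) -> float:
    """Between-class inertia ratio from centred data and integer class codes."""
    n, p = Xc.shape
    sums = np.zeros((k, p))
    np.add.at(sums, codes, Xc)
    counts = np.bincount(codes, minlength=k).astype(float)
    ok = counts > 0
    means = sums[ok] / counts[ok, None]
    between = float((counts[ok] / n * (means**2).sum(axis=1)).sum())
    return between / total if total > 0 else 0.0


def fit_bca(matrix: AnalysisMatrix | np.ndarray, labels) -> BCAResult:
    """Between-class PCA of a prepared matrix under a categorical factor.

    Class means of the (column-centred) matrix, weighted by class
    frequency, are eigen-decomposed; rows and class means are projected
    onto the resulting axes.  A single class yields ratio 0 with no
    axes.  Classes with identical rows are allowed.
    """
    X = _as_array(matrix)
    labels = np.asarray(labels, dtype=object)
    n, p = X.shape
    if len(labels) != n:
        raise ValueError("labels length does not match matrix rows")
    names = _feature_names(matrix, p)
    Xc = X - X.mean(axis=0)
    total = float((Xc**2).sum() / n)
    classes = sorted(set(labels))
    k = len(classes)
    if k < 2 or total == 0:
        zero = np.zeros(0)
        return BCAResult(
            total_inertia=total,
            between_inertia=0.0,
            within_inertia=total,
            inertia_ratio=0.0,
            eigenvalues=zero,
            axis_percents=zero,
            class_scores=pd.DataFrame(index=classes),
            row_scores=np.zeros((n, 0)),
            loadings=pd.DataFrame(index=names),
            n_classes=k,
        )
    code_of = {c: i for i, c in enumerate(classes)}
    codes = np.array([code_of[c] for c in labels])
    counts = np.bincount(codes, minlength=k).astype(float)
    sums = np.zeros((k, p))
    np.add.at(sums, codes, Xc)
    means = sums / counts[:, None]
    freqs = counts / n
    between = float((freqs * (means**2).sum(axis=1)).sum())
    within = total - between
    # frequency-weighted between-class covariance
    B = (means * freqs[:, None]).T @ means
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    n_axes = min(k - 1, p)
    axes = eigvec[:, :n_axes]
    # sign convention: largest-|loading| feature positive, for stable output
    for j in range(n_axes):
        lead = np.argmax(np.abs(axes[:, j]))
        if axes[lead, j] < 0:
            axes[:, j] = -axes[:, j]
    eig_kept = eigval[:n_axes]
    percents = 100.0 * eig_kept / eigval.sum() if eigval.sum() > 0 else np.zeros(n_axes)
    axis_names = [f"axis{j + 1}" for j in range(n_axes)]
    return BCAResult(
        total_inertia=total,
        between_inertia=between,
        within_inertia=within,
        inertia_ratio=between / total,
        eigenvalues=eigval,
        axis_percents=percents,
        class_scores=pd.DataFrame(means @ axes, index=classes, columns=axis_names),
        row_scores=Xc @ axes,
        loadings=pd.DataFrame(axes, index=names, columns=axis_names),
        n_classes=k,
    )


def permutation_test(
    matrix: AnalysisMatrix | np.ndarray,
    labels,
    n_replicates: int = 999,
    seed: int = 0,
) -> PermutationReport:
    """Monte-Carlo test of the between-class inertia ratio.

    Labels are shuffled uniformly per replicate and the ratio
    recomputed; ``p = (1 + #{permuted >= observed}) / (n_replicates + 1)``
    (exceedance with add-one smoothing, so p is never 0).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    X = _as_array(matrix)
    labels = np.asarray(labels, dtype=object)
    Xc = X - X.mean(axis=0)
    total = float((Xc**2).sum() / X.shape[0])
    classes = sorted(set(labels))
    code_of = {c: i for i, c in enumerate(classes)}
    codes = np.array([code_of[c] for c in labels])
    k = len(classes)
    observed = _between_ratio(Xc, codes, k, total)
    rng = np.random.default_rng(seed)
    permuted = np.empty(n_replicates)
    for r in range(n_replicates):
        permuted[r] = _between_ratio(Xc, rng.permutation(codes), k, total)
    p = (1.0 + float((permuted >= observed).sum())) / (n_replicates + 1.0)
    return PermutationReport(
        observed_ratio=observed,
        n_replicates=n_replicates,
        permuted_ratios=permuted,
        p_value=p,
        seed=seed,
    )


def compare_partitions(
    matrix: AnalysisMatrix | np.ndarray,
    labels_a,
    labels_b,
    n_replicates: int = 999,
    seed: int = 0,
) -> dict:
    """Descriptive explanatory-power comparison of two partitions.

    Fits independent BCAs (and permutation tests) for each labelling on
    the identical prepared matrix and reports both inertia percentages;
    no cross-partition test is performed.
    """
    X = _as_array(matrix)
    a = np.asarray(labels_a, dtype=object)
    b = np.asarray(labels_b, dtype=object)
    if len(a) != X.shape[0] or len(b) != X.shape[0]:
        raise ValueError("both labelings must cover the same matrix rows")
    out = {}
    for name, labs, s in (("a", a, seed), ("b", b, seed + 1)):
        out[name] = {
            "bca": fit_bca(matrix, labs),
            "permutation": permutation_test(matrix, labs, n_replicates=n_replicates, seed=s),
        }
    return out


def stressor_span_screen(
    stressor_matrix: AnalysisMatrix | np.ndarray,
    labels,
    overlap_threshold: float = 0.5,
    axes: int = 2,
    min_group_size: int = 5,
) -> SpanReport:
    """Check that every group spans the pooled stressor gradients.

    Unsupervised PCA axes of the stressor matrix are computed; per group
    and axis, the [q10, q90] interval of scores is compared with the
    pooled [q10, q90] interval, ``overlap = |intersection| / |pooled|``.
    A group is flagged when overlap falls below ``overlap_threshold`` on
    any screened axis; groups with fewer than ``min_group_size`` sites
    are marked "insufficient n" and never flagged.
    """
    from sklearn.decomposition import PCA

    X = _as_array(stressor_matrix)
    labels = np.asarray(labels, dtype=object)
    if len(labels) != X.shape[0]:
        raise ValueError("labels length does not match matrix rows")
    n_axes = min(axes, X.shape[1], X.shape[0])
    scores = PCA(n_components=n_axes, svd_solver="full").fit_transform(X)
    rows = []
    for axis in range(n_axes):
        s = scores[:, axis]
        plo, phi = np.quantile(s, [0.10, 0.90])
        for group in sorted(set(labels)):
            g = s[labels == group]
            status = "ok" if len(g) >= min_group_size else "insufficient n"
            glo, ghi = (np.quantile(g, [0.10, 0.90]) if len(g) else (np.nan, np.nan))
            inter = max(0.0, min(ghi, phi) - max(glo, plo))
            width = phi - plo
            overlap = inter / width if width > 0 else 1.0
            flagged = status == "ok" and overlap < overlap_threshold
            rows.append(
                (group, axis + 1, glo, ghi, plo, phi, overlap, status, flagged)
            )
    table = pd.DataFrame(
        rows,
        columns=["group", "axis", "lo", "hi", "pooled_lo", "pooled_hi", "overlap", "status", "flagged"],
    )
    return SpanReport(table=table, overlap_threshold=overlap_threshold, axes=n_axes)
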