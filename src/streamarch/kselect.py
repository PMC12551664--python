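"""K-means fitting, internal validity indices, and vote-based choice of k.

The number of clusters is chosen by *validity-index voting*: K-means is
fitted for every k in a range (default 2..15), a suite of internal
validity indices is evaluated on each fit, each index nominates the k
that optimises it under its own documented decision rule, and the k
with the most nominations ("votes") wins.  A parsimony margin lets a
smaller k win when it is within ``margin`` votes of the maximum,
reflecting the bioassessment goal of the fewest groups necessary.

K-means itself is standard Lloyd iteration with k-means++ starts and
multiple restarts (delegated to :class:`sklearn.cluster.KMeans`);
the index suite and the voting rule are implemented here.  Twelve
indices are registered (decision rule in brackets):

========================  =======================================================
Calinski-Harabasz         (B/(k-1)) / (W/(n-k))                       [max]
silhouette                mean silhouette width, 0 for singletons     [max]
Davies-Bouldin            mean worst pairwise cluster similarity      [min]
Dunn                      min between-pair dist / max diameter        [max]
C-index                   (Sw - Smin) / (Smax - Smin)                 [min]
McClain-Rao               mean within-dist / mean between-dist        [min]
point-biserial            corr(pair distance, different-cluster)      [max]
Ball-Hall                 W/k                                         [max drop]
Hartigan                  (W_k/W_{k+1} - 1)(n - k - 1)                [max drop]
Krzanowski-Lai            |DIFF_k| / |DIFF_{k+1}|                     [max]
Ratkowsky-Lance           mean_j sqrt(B_j/T_j) / sqrt(k)              [max]
gap statistic             E*[log W] - log W, B uniform references     [Tibshirani]
========================  =======================================================

"max drop" nominates the k at which the index falls the most relative
to k-1 (an elbow rule); the gap rule is the smallest k with
``gap(k) >= gap(k+1) - s(k+1)``.  Indices whose rule needs neighbours
abstain at range edges; an index with no defined value abstains
entirely.  The default voting set is the eleven closed-form indices;
the gap statistic (50 reference sets) is registered and available but
opt-in because of its simulation cost.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans

from streamarch.datamodel import AnalysisMatrix


class RegistryError(KeyError):
    """Requested validity index is not registered."""


class SelectionError(RuntimeError):
    """No index produced a winner; k cannot be chosen."""


@dataclass
class KMeansResult:
    """Best-of-restarts K-means fit.  Labels are 1-based (1..k)."""

    k: int
    labels: np.ndarray
    centroids: np.ndarray
    within_ss: float
    n_iter: int
    restarts_used: int
    seed: int


@dataclass
class VoteTable:
    """Index-by-k criterion grid, per-index winners, and the chosen k."""

    grid: dict  # index_name -> {k: value}
    winners: dict  # index_name -> winning k (indices that abstained are absent)
    votes: dict  # k -> vote count
    chosen_k: int
    parsimony_applied: bool

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.grid).T.sort_index(axis=1)


def kmeans_fit(
    matrix: AnalysisMatrix | np.ndarray,
    k: int,
    restarts: int = 25,
    seed: int = 0,
) -> KMeansResult:
    """Fit K-means with k-means++ starts, keeping the best of ``restarts`` runs.

    Deterministic given ``seed``.  Raises on ``k`` larger than the row
    count or non-finite input.
    """
    X = matrix.values if isinstance(matrix, AnalysisMatrix) else np.asarray(matrix, float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n < k:
        raise ValueError(f"need at least k={k} rows, got {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite values")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=restarts,
        max_iter=100,
        algorithm="lloyd",
        random_state=seed % (2**31),
    ).fit(X)
    return KMeansResult(
        k=k,
        labels=km.labels_.astype(int) + 1,
        centroids=km.cluster_centers_.copy(),
        within_ss=float(km.inertia_),
        n_iter=int(km.n_iter_),
        restarts_used=restarts,
        seed=seed,
    )


def total_ss(X: np.ndarray) -> float:
    """Total sum of squares about the grand centroid."""
    return float(((X - X.mean(axis=0)) ** 2).sum())


def within_between(X: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """(within-SS, between-SS) for a labelling; they sum to total SS."""
    w = 0.0
    b = 0.0
    grand = X.mean(axis=0)
    for lab in np.unique(labels):
        sub = X[labels == lab]
        c = sub.mean(axis=0)
        w += float(((sub - c) ** 2).sum())
        b += len(sub) * float(((c - grand) ** 2).sum())
    return w, b


# ---------------------------------------------------------------------------
# index computations.  ctx carries shared precomputed quantities.


@dataclass
class _Ctx:
    X: np.ndarray
    dist: np.ndarray | None = None  # condensed pairwise distances
    dmat: np.ndarray | None = None
    results: dict = field(default_factory=dict)  # k -> KMeansResult

    def pairwise(self):
        if self.dist is None:
            self.dist = pdist(self.X)
            self.dmat = squareform(self.dist)
        return self.dist, self.dmat


def _stats(ctx: _Ctx, k: int):
    res = ctx.results[k]
    X = ctx.X
    n = X.shape[0]
    W = res.within_ss
    T = total_ss(X)
    B = T - W
    return X, res.labels, n, W, B, T


def _calinski_harabasz(ctx, k):
    X, labels, n, W, B, T = _stats(ctx, k)
    if k < 2 or n <= k or W <= 0:
        return np.nan
    return (B / (k - 1)) / (W / (n - k))


def _silhouette(ctx, k):
    X, labels, n, W, B, T = _stats(ctx, k)
    if k < 2 or k >= n:
        return np.nan
    _, dmat = ctx.pairwise()
    vals = np.empty(n)
    sizes = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
    for i in range(n):
        own = labels[i]
        if sizes[own] == 1:
            vals[i] = 0.0  # singleton convention
            continue
        a = dmat[i][labels == own].sum() / (sizes[own] - 1)
        b = min(
            dmat[i][labels == lab].mean() for lab in sizes if lab != own
        )
        vals[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(vals.mean())


def _davies_bouldin(ctx, k):
    X, labels, n, W, B, T = _stats(ctx, k)
    if k < 2:
        return np.nan
    labs = np.unique(labels)
    cents = np.array([X[labels == lab].mean(axis=0) for lab in labs])
    scatter = np.array(
        [np.linalg.norm(X[labels == lab] - cents[i], axis=1).mean() for i, lab in enumerate(labs)]
    )
    worst = 0.0
    for i in range(len(labs)):
        best = 0.0
        for j in range(len(labs)):
            if i == j:
                continue
            m = np.linalg.norm(cents[i] - cents[j])
            if m > 0:
                best = max(best, (scatter[i] + scatter[j]) / m)
        worst += best
    return worst / len(labs)


def _dunn(ctx, k):
    X, labels, n, W, B, T = _stats(ctx, k)
    if k < 2:
        return np.nan
    _, dmat = ctx.pairwise()
    labs = np.unique(labels)
    diam = max(
        (dmat[np.ix_(labels == lab, labels == lab)].max() for lab in labs), default=0.0
    )
    if diam == 0:
        return np.nan
    sep = np.inf
    for a, b in itertools.combinations(labs, 2):
        sep = min(sep, dmat[np.ix_(labels == a, labels == b)].min())
    return float(sep / diam)


def _within_mask(labels):
    same = labels[:, None] == labels[None, :]
    iu = np.triu_indices(len(labels), 1)
    return same[iu]


def _c_index(ctx, k):
    X, labels, n, W, B, T = _stats(ctx, k)
    dist, _ = ctx.pairwise()
    within = _within_mask(labels)
    nw = int(within.sum())
    if nw == 0 or nw == len(dist):
        return np.nan
    sw = float(dist[within].sum())
    srt = np.sort(dist)
    smin = float(srt[:nw].sum())
    smax = float(srt[-nw:].sum())
    if smax == smin:
        return np.nan
    return (sw - smin) / (smax - smin)


def _mcclain_rao(ctx, k):
    X, labels, n, W, B, T = _stats(ctx, k)
    dist, _ = ctx.pairwise()
    within = _within_mask(labels)
    nw = int(within.sum())
    nb = len(dist) - nw
    if nw == 0 or nb == 0:
        return np.nan
    mean_w = float(dist[within].mean())
    mean_b = float(dist[~within].mean())
    if mean_b == 0:
        return np.nan
    return mean_w / mean_b


def _point_biserial(ctx, k):
    X, labels, n, W, B, T = _stats(ctx, k)
    dist, _ = ctx.pairwise()
    within = _within_mask(labels)
    ind = (~within).astype(float)  # 1 = different cluster
    if ind.std() == 0 or dist.std() == 0:
        return np.nan
    return float(np.corrcoef(dist, ind)[0, 1])


def _ball_hall(ctx, k):
    X, labels, n, W, B, T = _stats(ctx, k)
    return W / k


def _hartigan(ctx, k):
    if k + 1 not in ctx.results:
        return np.nan
    X, labels, n, W, B, T = _stats(ctx, k)
    W1 = ctx.results[k + 1].within_ss
    if W1 <= 0:
        return np.nan
    return (W / W1 - 1.0) * (n - k - 1)


def _kl_diff(ctx, k):
    # DIFF_k = (k-1)^(2/p) W_{k-1} - k^(2/p) W_k
    if k - 1 not in ctx.results or k not in ctx.results:
        return np.nan
    p = ctx.X.shape[1]
    Wk = ctx.results[k].within_ss
    Wk1 = ctx.results[k - 1].within_ss
    return (k - 1) ** (2.0 / p) * Wk1 - k ** (2.0 / p) * Wk


def _krzanowski_lai(ctx, k):
    d1 = _kl_diff(ctx, k)
    d2 = _kl_diff(ctx, k + 1)
    if np.isnan(d1) or np.isnan(d2) or d2 == 0:
        return np.nan
    return abs(d1) / abs(d2)


def _ratkowsky_lance(ctx, k):
    X, labels, n, W, B, T = _stats(ctx, k)
    grand = X.mean(axis=0)
    bj = np.zeros(X.shape[1])
    tj = ((X - grand) ** 2).sum(axis=0)
    for lab in np.unique(labels):
        sub = X[labels == lab]
        bj += len(sub) * (sub.mean(axis=0) - grand) ** 2
    ok = tj > 0
    if not ok.any():
        return np.nan
    cbar = float(np.sqrt(bj[ok] / tj[ok]).mean())
    return cbar / np.sqrt(k)


def _winner_max(values):
    return _arg_opt(values, max)


def _winner_min(values):
    return _arg_opt(values, min)


def _arg_opt(values, agg):
    defined = {k: v for k, v in values.items() if np.isfinite(v)}
    if not defined:
        return None
    best = agg(defined.values())
    return min(k for k, v in defined.items() if v == best)  # smallest-k tie-break


def _winner_max_drop(values):
    """Elbow rule: k where the index drops the most from k-1."""
    drops = {}
    ks = sorted(k for k, v in values.items() if np.isfinite(v))
    for k in ks:
        if k - 1 in values and np.isfinite(values[k - 1]):
            drops[k] = values[k - 1] - values[k]
    return _arg_opt(drops, max)


@dataclass(frozen=True)
class IndexDef:
    name: str
    value_fn: object
    rule: str  # "max" | "min" | "max_drop" | "gap"


INDEX_REGISTRY: dict[str, IndexDef] = {
    d.name: d
    for d in [
        IndexDef("calinski_harabasz", _calinski_harabasz, "max"),
        IndexDef("silhouette", _silhouette, "max"),
        IndexDef("davies_bouldin", _davies_bouldin, "min"),
        IndexDef("dunn", _dunn, "max"),
        IndexDef("c_index", _c_index, "min"),
        IndexDef("mcclain_rao", _mcclain_rao, "min"),
        IndexDef("point_biserial", _point_biserial, "max"),
        IndexDef("ball_hall", _ball_hall, "max_drop"),
        IndexDef("hartigan", _hartigan, "max_drop"),
        IndexDef("krzanowski_lai", _krzanowski_lai, "max"),
        IndexDef("ratkowsky_lance", _ratkowsky_lance, "max"),
        IndexDef("gap", None, "gap"),  # handled specially (needs reference sets)
    ]
}

#: Default voting set: the closed-form indices (gap is opt-in).
DEFAULT_INDEX_SET = [n for n in INDEX_REGISTRY if n != "gap"]

GAP_B = 50  # uniform reference sets for the gap statistic


def _gap_values(ctx: _Ctx, ks: list[int], restarts: int, seed: int):
    """Gap statistic values and their Monte-Carlo standard errors."""
    X = ctx.X
    rng = np.random.default_rng([seed & 0x7FFFFFFF, 97])
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w_ref = {k: np.empty(GAP_B) for k in ks}
    for b in range(GAP_B):
        ref = rng.uniform(lo, hi, size=X.shape)
        for k in ks:
            km = KMeans(n_clusters=k, n_init=3, max_iter=100, algorithm="lloyd",
                        random_state=int(rng.integers(2**31))).fit(ref)
            log_w_ref[k][b] = np.log(max(km.inertia_, 1e-300))
    gaps, sks = {}, {}
    for k in ks:
        logw = np.log(max(ctx.results[k].within_ss, 1e-300))
        gaps[k] = float(log_w_ref[k].mean() - logw)
        sks[k] = float(log_w_ref[k].std() * np.sqrt(1.0 + 1.0 / GAP_B))
    return gaps, sks


def _gap_winner(gaps, sks):
    ks = sorted(gaps)
    for k in ks[:-1]:
        if gaps[k] >= gaps[k + 1] - sks[k + 1]:
            return k
    return _arg_opt(gaps, max)


def validity_index(
    matrix: AnalysisMatrix | np.ndarray,
    results_by_k: dict[int, KMeansResult],
    index_name: str,
    restarts: int = 25,
    seed: int = 0,
) -> tuple[dict[int, float], int | None]:
    """Evaluate one validity index over a grid of fits.

    Returns ``(values, winner)``; ``winner`` is ``None`` when the index
    abstains (no defined value).  Difference-based rules need fits at
    neighbouring k; undefined cells are NaN.
    """
    if index_name not in INDEX_REGISTRY:
        raise RegistryError(f"unregistered validity index {index_name!r}")
    X = matrix.values if isinstance(matrix, AnalysisMatrix) else np.asarray(matrix, float)
    ctx = _Ctx(X=X, results=dict(results_by_k))
    ks = sorted(results_by_k)
    idx = INDEX_REGISTRY[index_name]
    if idx.rule == "gap":
        gaps, sks = _gap_values(ctx, ks, restarts, seed)
        return gaps, _gap_winner(gaps, sks)
    values = {k: float(idx.value_fn(ctx, k)) for k in ks}
    winner = {"max": _winner_max, "min": _winner_min, "max_drop": _winner_max_drop}[idx.rule](
        values
    )
    return values, winner


def tally_votes(
    winners: dict[str, int | None], parsimony_margin: int = 0
) -> tuple[dict[int, int], int, bool]:
    """Aggregate per-index winners into a chosen k.

    The k with the most votes wins; ties go to the smallest k.  With a
    positive ``parsimony_margin``, any smaller k whose vote count is
    within ``margin`` of the maximum is preferred (fewest-groups goal).
    """
    votes: dict[int, int] = {}
    for w in winners.values():
        if w is not None:
            votes[w] = votes.get(w, 0) + 1
    if not votes:
        raise SelectionError("every validity index abstained")
    max_votes = max(votes.values())
    chosen = min(k for k, v in votes.items() if v == max_votes)
    parsimony_applied = False
    if parsimony_margin > 0:
        eligible = [k for k, v in votes.items() if v >= max_votes - parsimony_margin]
        best = min(eligible)
        if best < chosen:
            chosen = best
            parsimony_applied = True
    return votes, chosen, parsimony_applied


def vote_for_k(
    matrix: AnalysisMatrix | np.ndarray,
    k_range: tuple[int, int] = (2, 15),
    index_set: list[str] | None = None,
    restarts: int = 25,
    seed: int = 0,
    parsimony_margin: int = 1,
) -> tuple[VoteTable, dict[int, KMeansResult]]:
    """Choose the number of clusters by validity-index voting.

    Fits one :func:`kmeans_fit` per k (shared across indices), evaluates
    every index in ``index_set`` (default: all closed-form indices),
    tallies winners, and applies the parsimony rule.  Deterministic
    given ``seed``.
    """
    X = matrix.values if isinstance(matrix, AnalysisMatrix) else np.asarray(matrix, float)
    if X.ndim == 1:
        X = X[:, None]
    index_set = list(index_set) if index_set is not None else list(DEFAULT_INDEX_SET)
    if not index_set:
        raise SelectionError("empty index set")
    lo, hi = k_range
    hi = min(hi, X.shape[0] - 1)
    if hi < lo:
        raise ValueError(f"k range ({lo}, {hi}) empty for {X.shape[0]} rows")
    results = {
        k: kmeans_fit(X, k, restarts=restarts, seed=(seed * 1009 + k) % (2**31))
        for k in range(lo, hi + 1)
    }
    grid: dict[str, dict[int, float]] = {}
    winners: dict[str, int | None] = {}
    for name in index_set:
        values, winner = validity_index(X, results, name, restarts=restarts, seed=seed)
        grid[name] = values
        if winner is not None:
            winners[name] = winner
    votes, chosen, parsimony_applied = tally_votes(winners, parsimony_margin)
    table = VoteTable(
        grid=grid,
        winners=winners,
        votes=votes,
        chosen_k=chosen,
        parsimony_applied=parsimony_applied,
    )
    return table, results
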