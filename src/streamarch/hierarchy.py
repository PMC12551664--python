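"""Two-tier clustering orchestration, modal site assignment, and CART resolution.

The pipeline mirrors hierarchy theory: Tier I clusters *samples* on
catchment-scale climate/geology (yielding regions, named East/West by
descending mean annual rainfall), then Tier II clusters the samples of
each region on reach-scale habitat + chemistry (yielding subgroups,
named by archetype habitat profile).  Because sites are surveyed in
several monitoring cycles, a site's samples can disagree: each site
gets the *mode* of its sample labels, and sites with tied modes
("non-modal" sites) are assigned by a classification tree trained on
the modally-labelled samples.  The tree doubles as the human-readable
description of the groups via extracted threshold rules.

The CART here is binary recursive partitioning on the Gini criterion
with rpart-style stopping (``min_split``, ``min_bucket``, and a
``complexity`` threshold on the normalised impurity decrease).  Split
thresholds sit at the midpoint between adjacent observed values;
routing sends ``value < threshold`` left and equality right.  Trees are
fitted on transformed (logged) but *unscaled* features so thresholds
read in natural units (mm of rainfall, percent substrate).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from streamarch.datamodel import (
    AnalysisMatrix,
    FeatureSet,
    SampleTable,
    build_feature_matrix,
    feature_set,
)
from streamarch.kselect import KMeansResult, VoteTable, kmeans_fit, vote_for_k

log = logging.getLogger("streamarch")

NON_MODAL = "NON_MODAL"
EXCLUDED_INCOMPLETE = "excluded: incomplete chemistry"

#: subgroup label -> archetype lookup for the published six-group scheme.
ARCHETYPE_LOOKUP = {
    "East Plains": "Plains",
    "West Plains": "Plains",
    "East Valleys": "Valley",
    "West Valleys": "Valley",
    "Hills": "Rocky",
    "Highlands": "Rocky",
}


# ---------------------------------------------------------------------------
# classification tree


@dataclass
class TreeNode:
    klass: str
    n: int
    proportions: dict
    split_feature: str | None = None
    split_threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_feature is None


@dataclass
class TreeModel:
    root: TreeNode
    feature_names: list[str]
    classes: list[str]
    hyperparams: dict


@dataclass
class TreeRule:
    """Conjunction of (feature, direction, threshold) terms leading to a leaf."""

    terms: list[tuple[str, str, float]]  # direction "<" (left) or ">=" (right)
    predicted: str
    support: int

    def __str__(self) -> str:
        if not self.terms:
            return f"(always) -> {self.predicted} [n={self.support}]"
        cond = " and ".join(f"{f} {d} {t:.1f}" for f, d, t in self.terms)
        return f"{cond} -> {self.predicted} [n={self.support}]"


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - (p**2).sum())


def _majority(y: np.ndarray, classes: list[str]) -> tuple[str, dict]:
    counts = Counter(y)
    # deterministic tie-break: count desc, then class-name order
    best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
    props = {c: counts.get(c, 0) / len(y) for c in classes}
    return best, props


def fit_tree(
    matrix: AnalysisMatrix | np.ndarray,
    labels,
    feature_names: list[str] | None = None,
    min_split: int = 20,
    min_bucket: int = 7,
    complexity: float = 0.01,
) -> TreeModel:
    """Grow a Gini CART on ``matrix`` rows labelled with ``labels``.

    A node is split only when it has at least ``min_split`` rows, both
    children would keep at least ``min_bucket`` rows, and the best
    split's impurity decrease (weighted by node fraction, relative to
    the root Gini) is at least ``complexity``.  Candidate thresholds are
    midpoints between consecutive distinct sorted values; ties between
    equally good splits go to the earlier feature, then the smaller
    threshold.  Single-class input yields a stump.
    """
    if isinstance(matrix, AnalysisMatrix):
        X = matrix.values
        feature_names = feature_names or list(matrix.column_names)
    else:
        X = np.asarray(matrix, float)
        if X.ndim == 1:
            X = X[:, None]
        feature_names = feature_names or [f"x{j}" for j in range(X.shape[1])]
    y = np.asarray(labels, dtype=object)
    if len(y) != X.shape[0]:
        raise ValueError("labels length does not match matrix rows")
    classes = sorted(set(y))
    n_total = len(y)
    root_counts = np.array([(y == c).sum() for c in classes], float)
    root_gini = _gini(root_counts)

    def build(idx: np.ndarray) -> TreeNode:
        ysub = y[idx]
        klass, props = _majority(ysub, classes)
        node = TreeNode(klass=klass, n=len(idx), proportions=props)
        if len(idx) < min_split or len(set(ysub)) < 2 or root_gini == 0:
            return node
        parent_gini = _gini(np.array([(ysub == c).sum() for c in classes], float))
        best = None  # (gain, j, threshold, left_mask)
        for j in range(X.shape[1]):
            col = X[idx, j]
            order = np.argsort(col, kind="mergesort")
            sc, sy = col[order], ysub[order]
            counts_left = np.zeros(len(classes))
            counts_right = np.array([(sy == c).sum() for c in classes], float)
            for i in range(len(sc) - 1):
                ci = classes.index(sy[i])
                counts_left[ci] += 1
                counts_right[ci] -= 1
                if sc[i] == sc[i + 1]:
                    continue
                nl, nr = i + 1, len(sc) - i - 1
                if nl < min_bucket or nr < min_bucket:
                    continue
                gain = parent_gini - (nl * _gini(counts_left) + nr * _gini(counts_right)) / len(sc)
                thr = (sc[i] + sc[i + 1]) / 2.0
                cand = (gain, -j, -thr)
                if best is None or cand > (best[0], -best[1], -best[2]):
                    best = (gain, j, thr)
        if best is None:
            return node
        gain, j, thr = best
        # normalised decrease relative to the root impurity, rpart-style cp
        if (gain * len(idx) / n_total) < complexity * root_gini:
            return node
        left_mask = X[idx, j] < thr
        node.split_feature = feature_names[j]
        node.split_threshold = float(thr)
        node.left = build(idx[left_mask])
        node.right = build(idx[~left_mask])
        return node

    root = build(np.arange(n_total))
    return TreeModel(
        root=root,
        feature_names=list(feature_names),
        classes=classes,
        hyperparams={"min_split": min_split, "min_bucket": min_bucket, "complexity": complexity},
    )


def predict_tree(model: TreeModel, samples: AnalysisMatrix | np.ndarray) -> np.ndarray:
    """Route each row to a leaf; ``value < threshold`` goes left, equality right."""
    if isinstance(samples, AnalysisMatrix):
        names = samples.column_names
        X = samples.values
    else:
        X = np.asarray(samples, float)
        if X.ndim == 1:
            X = X[:, None]
        names = model.feature_names
    col_of = {}
    for f in _tree_features(model.root):
        if f not in names:
            raise KeyError(f"matrix lacks split feature {f!r}")
        col_of[f] = names.index(f)
    out = np.empty(X.shape[0], dtype=object)
    for i in range(X.shape[0]):
        node = model.root
        while not node.is_leaf:
            if X[i, col_of[node.split_feature]] < node.split_threshold:
                node = node.left
            else:
                node = node.right
        out[i] = node.klass
    return out


def _tree_features(node: TreeNode) -> set:
    if node.is_leaf:
        return set()
    return {node.split_feature} | _tree_features(node.left) | _tree_features(node.right)


def extract_rules(model: TreeModel) -> list[TreeRule]:
    """One threshold rule per leaf, in left-to-right leaf order."""
    rules: list[TreeRule] = []

    def walk(node: TreeNode, terms):
        if node.is_leaf:
            rules.append(TreeRule(terms=list(terms), predicted=node.klass, support=node.n))
            return
        walk(node.left, terms + [(node.split_feature, "<", node.split_threshold)])
        walk(node.right, terms + [(node.split_feature, ">=", node.split_threshold)])

    walk(model.root, [])
    return rules


def tree_to_dict(node: TreeNode) -> dict:
    d = {"class": node.klass, "n": node.n, "proportions": node.proportions}
    if not node.is_leaf:
        d.update(
            split_feature=node.split_feature,
            split_threshold=node.split_threshold,
            left=tree_to_dict(node.left),
            right=tree_to_dict(node.right),
        )
    return d


# ---------------------------------------------------------------------------
# modal assignment


def modal_site_assignment(sample_labels: pd.DataFrame) -> pd.Series:
    """Per-site strict mode of sample labels; ties yield ``NON_MODAL``.

    ``sample_labels`` needs columns ``site_id`` and ``label``.
    """

    def mode_or_tie(vals) -> str:
        counts = Counter(vals)
        top = counts.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            return NON_MODAL
        return top[0][0]

    return sample_labels.groupby("site_id", sort=True)["label"].agg(mode_or_tie)


def resolve_non_modal(model: TreeModel, site_rows: AnalysisMatrix | np.ndarray) -> str:
    """Tree-resolve one non-modal site from its sample rows.

    Each sample is predicted and the strict mode taken; a residual tie
    falls back to a single prediction on the site's feature-wise mean.
    """
    X = site_rows.values if isinstance(site_rows, AnalysisMatrix) else np.asarray(site_rows, float)
    if X.ndim == 1:
        X = X[None, :]
    names = site_rows.column_names if isinstance(site_rows, AnalysisMatrix) else None
    preds = predict_tree(model, AnalysisMatrix(X, [], names) if names else X)
    counts = Counter(preds)
    top = counts.most_common()
    if len(top) == 1 or top[0][1] > top[1][1]:
        return top[0][0]
    mean_row = X.mean(axis=0, keepdims=True)
    return str(
        predict_tree(model, AnalysisMatrix(mean_row, [], names) if names else mean_row)[0]
    )


# ---------------------------------------------------------------------------
# tier clustering


def _tier_matrix(samples: SampleTable, fset: FeatureSet, scale=True) -> AnalysisMatrix:
    return build_feature_matrix(samples, fset, scale=scale)


def _fit_or_vote(matrix, fixed_k, k_range, index_set, restarts, seed, parsimony_margin):
    if fixed_k is not None:
        return kmeans_fit(matrix, fixed_k, restarts=restarts, seed=seed), None
    table, results = vote_for_k(
        matrix,
        k_range=k_range,
        index_set=index_set,
        restarts=restarts,
        seed=seed,
        parsimony_margin=parsimony_margin,
    )
    return results[table.chosen_k], table


def tier1_cluster(
    samples: SampleTable,
    fixed_k: int | None = 2,
    k_range: tuple[int, int] = (2, 15),
    index_set=None,
    restarts: int = 25,
    seed: int = 0,
    parsimony_margin: int = 1,
) -> tuple[pd.DataFrame, VoteTable | None, KMeansResult, AnalysisMatrix]:
    """Cluster all samples on Tier-I climate/geology features into regions.

    Cluster labels are renamed by descending mean annual rainfall
    (``AnRainC``): with k=2 the wetter cluster is ``East`` and the drier
    ``West``; with other k, ``R1`` (wettest) .. ``Rk`` (driest).
    Returns (per-sample labels frame, vote table or None, fit, matrix).
    """
    fset = feature_set("TIER1")
    matrix = _tier_matrix(samples, fset)
    res, table = _fit_or_vote(matrix, fixed_k, k_range, index_set, restarts, seed, parsimony_margin)
    rain = samples.data.set_index(list(("site_id", "cycle_id"))).loc[
        pd.MultiIndex.from_tuples(matrix.row_index), "AnRainC"
    ].to_numpy(float)
    means = {
        lab: float(rain[res.labels == lab].mean()) for lab in np.unique(res.labels)
    }
    ordered = sorted(means, key=means.get, reverse=True)  # wettest first
    if len(ordered) == 2:
        name_of = {ordered[0]: "East", ordered[1]: "West"}
    else:
        name_of = {lab: f"R{i + 1}" for i, lab in enumerate(ordered)}
    labels = pd.DataFrame(matrix.row_index, columns=["site_id", "cycle_id"])
    labels["label"] = [name_of[lab] for lab in res.labels]
    return labels, table, res, matrix


_ROCKY_SCORE = ["Gravel", "Cobble", "Boulder", "Bedrock"]
_VALLEY_SCORE = ["Silt", "Pools"]
_PLAINS_SCORE = ["Sand", "Runs"]


def _name_subgroups(samples_df: pd.DataFrame, row_index, labels: np.ndarray, region: str):
    """Name clusters by archetype habitat profile.

    Per cluster, three scores are compared on raw percentages: rocky
    substrate (gravel+cobble+boulder+bedrock), valley (silt + pool
    units) and plains (sand + run units); the best score names the
    archetype.  Clusters sharing an archetype get " 2", " 3" suffixes in
    descending size order.
    """
    df = samples_df.set_index(["site_id", "cycle_id"]).loc[
        pd.MultiIndex.from_tuples(list(row_index))
    ]
    name_of, arch_of = {}, {}
    assigned: Counter = Counter()
    sizes = {lab: int((labels == lab).sum()) for lab in np.unique(labels)}
    for lab in sorted(sizes, key=sizes.get, reverse=True):
        sub = df[labels == lab]
        scores = {
            "Rocky": float(sub[_ROCKY_SCORE].sum(axis=1).mean()),
            "Valley": float(sub[_VALLEY_SCORE].sum(axis=1).mean()),
            "Plains": float(sub[_PLAINS_SCORE].sum(axis=1).mean()),
        }
        arch = max(sorted(scores), key=scores.get)
        assigned[arch] += 1
        name = f"{region} {arch}" if assigned[arch] == 1 else f"{region} {arch} {assigned[arch]}"
        name_of[lab] = name
        arch_of[name] = arch
    return name_of, arch_of


def tier2_cluster(
    samples: SampleTable,
    region: str,
    fixed_k: int | None = None,
    k_range: tuple[int, int] = (2, 15),
    index_set=None,
    restarts: int = 25,
    seed: int = 0,
    parsimony_margin: int = 1,
    name_overrides: dict | None = None,
) -> tuple[pd.DataFrame, VoteTable | None, KMeansResult, AnalysisMatrix, dict]:
    """Cluster one region's chemistry-complete samples on Tier-II features.

    Returns (per-sample labels frame, vote table, fit, matrix,
    subgroup -> archetype map).  Degenerate clustering (zero between-SS)
    is logged as a warning, not an error.
    """
    fset = feature_set("TIER2")
    matrix = _tier_matrix(samples, fset)
    if fixed_k is not None and matrix.n_rows < fixed_k:
        raise ValueError(
            f"region {region}: {matrix.n_rows} complete rows < k={fixed_k}"
        )
    res, table = _fit_or_vote(matrix, fixed_k, k_range, index_set, restarts, seed, parsimony_margin)
    tss = float(((matrix.values - matrix.values.mean(axis=0)) ** 2).sum())
    if tss - res.within_ss <= 1e-12 * max(tss, 1.0):
        log.warning("tier2 region=%s degenerate clustering (zero between-SS)", region)
    name_of, arch_of = _name_subgroups(samples.data, matrix.row_index, res.labels, region)
    if name_overrides:
        for old, new in name_overrides.items():
            if old in arch_of:
                arch_of[new] = arch_of.pop(old)
        name_of = {lab: name_overrides.get(n, n) for lab, n in name_of.items()}
    labels = pd.DataFrame(matrix.row_index, columns=["site_id", "cycle_id"])
    labels["label"] = [name_of[lab] for lab in res.labels]
    return labels, table, res, matrix, arch_of


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class GroupAssignment:
    """Final per-site labels with tier path, provenance and exclusions."""

    frame: pd.DataFrame  # site_id, region, subgroup, archetype, provenance, n_samples, status
    subgroup_archetype: dict = field(default_factory=dict)

    def assigned(self) -> pd.DataFrame:
        return self.frame[self.frame["status"] == "assigned"]


@dataclass
class PipelineResult:
    assignment: GroupAssignment
    vote_tables: dict
    trees: dict
    sample_labels: dict  # "tier1" -> frame, "tier2:<region>" -> frame
    matrices: dict


def _assign_sites(
    sample_labels: pd.DataFrame,
    tree_matrix: AnalysisMatrix,
    tree_labels: pd.DataFrame,
    hyperparams: dict,
) -> tuple[pd.Series, pd.Series, TreeModel]:
    """Modal assignment plus tree resolution of non-modal sites.

    The tree is trained on all modally-assigned *samples* using the
    unscaled (natural-units) matrix, then used to resolve each
    non-modal site from its own sample rows.
    """
    modal = modal_site_assignment(sample_labels)
    provenance = pd.Series("modal", index=modal.index)
    site_of_row = np.array([s for s, _ in tree_matrix.row_index])
    label_by_key = tree_labels.set_index(["site_id", "cycle_id"])["label"]
    row_labels = label_by_key.loc[pd.MultiIndex.from_tuples(tree_matrix.row_index)].to_numpy(
        object
    )
    modal_sites = set(modal[modal != NON_MODAL].index)
    train_mask = np.array(
        [s in modal_sites and modal[s] == lab for s, lab in zip(site_of_row, row_labels)]
    )
    model = fit_tree(
        AnalysisMatrix(
            tree_matrix.values[train_mask],
            [ri for ri, m in zip(tree_matrix.row_index, train_mask) if m],
            tree_matrix.column_names,
        ),
        row_labels[train_mask],
        **hyperparams,
    )
    for site in modal[modal == NON_MODAL].index:
        rows = tree_matrix.values[site_of_row == site]
        resolved = resolve_non_modal(
            model, AnalysisMatrix(rows, [], tree_matrix.column_names)
        )
        modal.loc[site] = resolved
        provenance.loc[site] = "tree"
    return modal, provenance, model


def assemble_samples(
    sites: SampleTable, surveys: SampleTable, chemistry: pd.DataFrame
) -> SampleTable:
    """Join survey rows with site-level Tier-I features and chemistry medians.

    Chemistry medians (per site and cycle) replace the survey
    alkalinity/conductivity columns; surveys without chemistry get
    missing values there and fall out of chemistry-requiring matrices.
    """
    from streamarch.datamodel import aggregate_medians

    t1_names = feature_set("TIER1").names
    samples_df = surveys.data.merge(
        sites.data[["site_id"] + t1_names], on="site_id", how="left", validate="m:1"
    )
    analytes = feature_set("CHEM_BCA").names + ["Alkalinity", "Conductivity"]
    medians = aggregate_medians(chemistry, analytes)
    samples_df = samples_df.drop(columns=["Alkalinity", "Conductivity"]).merge(
        medians, on=["site_id", "cycle_id"], how="left", validate="1:1"
    )
    return SampleTable(samples_df)


def run_pipeline(tables: dict, config=None) -> PipelineResult:
    """Run Tier I -> Tier II classification end to end.

    ``tables`` carries ``sites`` (Tier-I per-site features), ``surveys``
    (Tier-II per-(site, cycle) habitat) and ``chemistry`` (long-format
    measurements).  Chemistry medians replace the survey alkalinity/
    conductivity columns, so surveys without chemistry drop out of
    Tier II (but keep their Tier-I region).  Every input site ends with
    exactly one final label or the explicit status
    ``"excluded: incomplete chemistry"``.
    """
    from streamarch.config import RunConfig

    cfg = config or RunConfig()
    sites: SampleTable = tables["sites"]
    surveys: SampleTable = tables["surveys"]
    chemistry: pd.DataFrame = tables["chemistry"]

    samples = assemble_samples(sites, surveys, chemistry)
    log.info("stage=assemble n_samples=%d n_sites=%d", len(samples), len(sites.data))

    # Tier I: regions
    t1_labels, t1_votes, t1_fit, t1_matrix = tier1_cluster(
        samples,
        fixed_k=cfg.fixed_k.get("tier1", 2),
        k_range=cfg.k_range,
        index_set=cfg.indices,
        restarts=cfg.restarts,
        seed=cfg.seed,
        parsimony_margin=cfg.parsimony_margin,
    )
    t1_unscaled = build_feature_matrix(samples, feature_set("TIER1"), scale=False)
    region_site, region_prov, t1_tree = _assign_sites(
        t1_labels, t1_unscaled, t1_labels, cfg.tree
    )
    log.info("stage=tier1 k=%d regions=%s", t1_fit.k, sorted(region_site.unique()))

    # Tier II: subgroups within each region
    vote_tables = {"tier1": t1_votes}
    trees = {"tier1": t1_tree}
    sample_labels = {"tier1": t1_labels}
    matrices = {"tier1": t1_matrix}
    subgroup_site = pd.Series(dtype=object)
    subgroup_prov = pd.Series(dtype=object)
    arch_map: dict = {}
    for region in sorted(region_site.unique()):
        region_sites = set(region_site[region_site == region].index)
        sub_df = samples.data[samples.data["site_id"].isin(region_sites)]
        sub_samples = SampleTable(sub_df.reset_index(drop=True))
        fixed = cfg.fixed_k.get(region)
        t2_labels, t2_votes, t2_fit, t2_matrix, arch_of = tier2_cluster(
            sub_samples,
            region,
            fixed_k=fixed,
            k_range=cfg.k_range,
            index_set=cfg.indices,
            restarts=cfg.restarts,
            seed=cfg.seed + 1,
            parsimony_margin=cfg.parsimony_margin,
            name_overrides=cfg.subgroup_names.get(region),
        )
        arch_map.update(arch_of)
        t2_unscaled = build_feature_matrix(sub_samples, feature_set("TIER2"), scale=False)
        sg, prov, t2_tree = _assign_sites(t2_labels, t2_unscaled, t2_labels, cfg.tree)
        subgroup_site = pd.concat([subgroup_site, sg])
        subgroup_prov = pd.concat([subgroup_prov, prov])
        vote_tables[f"tier2:{region}"] = t2_votes
        trees[f"tier2:{region}"] = t2_tree
        sample_labels[f"tier2:{region}"] = t2_labels
        matrices[f"tier2:{region}"] = t2_matrix
        log.info(
            "stage=tier2 region=%s k=%d n_complete=%d groups=%s",
            region, t2_fit.k, t2_matrix.n_rows, sorted(sg.unique()),
        )

    # final per-site frame; no silent drops
    n_samples = samples.data.groupby("site_id").size()
    rows = []
    for site in sites.data["site_id"]:
        region = region_site.get(site)
        if region is None:
            rows.append((site, None, None, None, None, 0, "excluded: no surveys"))
            continue
        if site in subgroup_site.index:
            sg = subgroup_site[site]
            prov = subgroup_prov[site]
            rows.append(
                (site, region, sg, arch_map.get(sg), prov, int(n_samples.get(site, 0)), "assigned")
            )
        else:
            rows.append(
                (site, region, None, None, None, int(n_samples.get(site, 0)), EXCLUDED_INCOMPLETE)
            )
    frame = pd.DataFrame(
        rows,
        columns=["site_id", "region", "subgroup", "archetype", "provenance", "n_samples", "status"],
    )
    # optional manual overrides, applied last
    for site, sg in cfg.label_overrides.items():
        sel = frame["site_id"] == site
        frame.loc[sel, "subgroup"] = sg
        frame.loc[sel, "archetype"] = arch_map.get(sg, frame.loc[sel, "archetype"])
        frame.loc[sel, "provenance"] = "override"
    assignment = GroupAssignment(frame=frame, subgroup_archetype=arch_map)
    return PipelineResult(
        assignment=assignment,
        vote_tables=vote_tables,
        trees=trees,
        sample_labels=sample_labels,
        matrices=matrices,
    )
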