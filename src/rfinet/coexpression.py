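"""Weighted co-expression network construction and module detection.

The procedure follows the weighted gene co-expression network analysis
(WGCNA) recipe: Pearson correlation between feature expression profiles, a
soft-threshold power chosen for approximate scale-free topology, topological
overlap similarity, average-linkage hierarchical clustering of the
topological overlap dissimilarity, a static tree cut into modules with a
minimum size, eigengene computation (first principal component of the
standardized member expression), and merging of modules whose eigengenes are
nearly collinear.  Modules are named with the conventional color sequence
(largest module = "turquoise"), with "grey" reserved for unassigned features.

Usage is statsmodels-like::

    net = CoexpressionNetwork(log_expr, NetworkParams(beta=6, min_module_size=30))
    result = net.fit()
    result.assignment      # feature -> module color
    result.eigengenes      # module x sample eigengene profiles
    print(result.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

GREY = "grey"

# conventional module color order; largest module gets the first color
MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta", "sienna",
    "yellowgreen", "plum", "orangered", "mediumpurple", "lightsteelblue",
    "ivory", "floralwhite", "honeydew", "bisque", "darkslateblue", "thistle",
    "salmon4", "maroon", "lavenderblush", "navajowhite",
]


def module_color(rank: int) -> str:
    """Color name for the module of a given size rank (0 = largest)."""
    if rank < len(MODULE_COLORS):
        return MODULE_COLORS[rank]
    return f"module{rank + 1}"


@dataclass
class NetworkParams:
    """Construction parameters for one weighted co-expression network.

    ``beta`` is the soft-threshold power (the study used beta=6 with
    scale-free fit R^2 > 0.90 for both data types); ``min_module_size`` is 5
    for miRNA and 30 for mRNA networks; ``merge_height`` is the eigengene
    dissimilarity below which modules are merged (default 0.25).
    ``cut_height_quantile`` places the static tree cut at that quantile of
    the dendrogram merge heights.
    """

    beta: int = 6
    signed: bool = False
    min_module_size: int = 30
    merge_height: float = 0.25
    cut_height_quantile: float = 0.99
    scale_free_target_r2: float = 0.90
    detection: str = "hybrid"  # "hybrid" (cores + kME classification) or "static"
    core_quantiles: tuple = (0.1, 0.2, 0.3, 0.4, 0.5)
    kme_threshold: float = 0.8
    kme_iterations: int = 3

    def __post_init__(self):
        if self.beta < 1:
            raise ValueError("beta must be >= 1")
        if not 0.0 < self.merge_height < 1.0:
            raise ValueError("merge_height must be in (0, 1)")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if self.detection not in ("hybrid", "static"):
            raise ValueError("detection must be 'hybrid' or 'static'")


def correlation_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between feature profiles (features x samples in)."""
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")
    arr = expr.to_numpy(float)
    if (arr.std(axis=1) < 1e-12).any():
        raise ValueError("zero-variance features must be excluded upstream")
    r = np.corrcoef(arr)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=expr.index, columns=expr.index)


def adjacency(r: pd.DataFrame | np.ndarray, beta: int, signed: bool = False):
    """Soft-threshold adjacency: |r|^beta (unsigned) or ((1+r)/2)^beta (signed)."""
    arr = np.asarray(r, dtype=float)
    a = ((1.0 + arr) / 2.0) ** beta if signed else np.abs(arr) ** beta
    np.fill_diagonal(a, 1.0)
    if isinstance(r, pd.DataFrame):
        return pd.DataFrame(a, index=r.index, columns=r.columns)
    return a


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10):
    """Scale-free topology fit of a connectivity distribution.

    Bins the connectivities into ``n_bins`` equal-width bins, regresses
    log10 p(k) on log10 mean(k) over nonempty bins, and returns
    ``(-sign(slope) * R^2, slope)``.  Degenerate inputs return (nan, nan).
    """
    k = np.asarray(connectivity, float)
    if k.size < 2 or np.ptp(k) == 0 or (k <= 0).any():
        return float("nan"), float("nan")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        xs.append(np.log10(k[mask].mean()))
        ys.append(np.log10(mask.mean()))
    if len(xs) < 3 or np.ptp(xs) == 0:
        return float("nan"), float("nan")
    xs, ys = np.asarray(xs), np.asarray(ys)
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = ys - (slope * xs + intercept)
    ss_tot = ((ys - ys.mean()) ** 2).sum()
    r2 = 1.0 - (resid**2).sum() / ss_tot if ss_tot > 0 else float("nan")
    return float(-np.sign(slope) * r2), float(slope)


def pick_soft_threshold(
    expr: pd.DataFrame,
    candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16),
    target_r2: float = 0.90,
    signed: bool = False,
):
    """Smallest power whose scale-free fit reaches ``target_r2``.

    Returns ``(beta, fit_table)``; if no candidate reaches the target the
    power with the maximum fit is returned with a warning.
    """
    powers = list(candidate_powers)
    if not powers or sorted(powers) != powers:
        raise ValueError("candidate_powers must be nonempty and ascending")
    r = correlation_matrix(expr).to_numpy()
    rows = []
    for beta in powers:
        a = adjacency(r, beta, signed)
        k = a.sum(axis=1) - 1.0
        if np.ptp(k) == 0:
            warnings.warn(f"pick_soft_threshold: degenerate connectivity at beta={beta}")
            rows.append((beta, float("nan"), float("nan"), float(k.mean())))
            continue
        fit, slope = scale_free_fit(k)
        rows.append((beta, fit, slope, float(k.mean())))
    table = pd.DataFrame(rows, columns=["power", "fit", "slope", "mean_k"])
    ok = table[table["fit"] >= target_r2]
    if len(ok):
        beta = int(ok["power"].iloc[0])
    else:
        if table["fit"].isna().all():
            raise ValueError("scale-free fit undefined for all candidate powers")
        beta = int(table.loc[table["fit"].idxmax(), "power"])
        warnings.warn(
            f"no candidate power reaches scale-free fit {target_r2}; "
            f"using argmax fit (beta={beta})"
        )
    return beta, table


def tom_similarity(a: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap similarity of a weighted adjacency matrix.

    TOM_ij = (sum_{u != i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij)
    with k_i the connectivity of node i; TOM_ii = 1.
    """
    arr = np.asarray(a, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if arr.min() < -1e-12 or arr.max() > 1 + 1e-12:
        raise ValueError("adjacency entries must lie in [0, 1]")
    if not np.allclose(np.diag(arr), 1.0):
        raise ValueError("adjacency diagonal must be 1")
    k = arr.sum(axis=1) - 1.0
    shared = arr @ arr
    # remove the u=i and u=j terms (each contributes a_ij via the unit diagonal)
    numer = shared - 2.0 * arr + arr
    denom = np.minimum.outer(k, k) + 1.0 - arr
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = np.where(denom > 0, numer / denom, 0.0)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    if isinstance(a, pd.DataFrame):
        return pd.DataFrame(tom, index=a.index, columns=a.columns)
    return tom


def average_linkage_dendrogram(dissimilarity) -> np.ndarray:
    """UPGMA (average linkage) merge table of a symmetric dissimilarity matrix."""
    arr = np.asarray(dissimilarity, dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-10):
        raise ValueError("dissimilarity must be square symmetric")
    if arr.shape[0] == 1:
        return np.empty((0, 4))
    d = arr.copy()
    np.fill_diagonal(d, 0.0)
    return hierarchy.average(squareform(d, checks=False))


def cut_tree_to_modules(
    dendrogram: np.ndarray,
    feature_ids,
    min_module_size: int,
    cut_height_quantile: float = 0.99,
) -> pd.Series:
    """Static cut of the dendrogram into color-labelled modules.

    The tree is cut at the given quantile of merge heights; resulting
    clusters smaller than ``min_module_size`` become "grey".  Surviving
    modules are named by decreasing size with the fixed color sequence
    (ties broken by the order of first appearance in ``feature_ids``).
    """
    feature_ids = list(feature_ids)
    n = len(feature_ids)
    if n == 0:
        raise ValueError("no features")
    if dendrogram.shape[0] != n - 1:
        raise ValueError("dendrogram does not match feature count")
    if n == 1 or dendrogram.shape[0] == 0:
        return pd.Series([GREY] * n, index=feature_ids, name="module")
    heights = dendrogram[:, 2]
    cut = float(np.quantile(heights, cut_height_quantile))
    flat = hierarchy.fcluster(dendrogram, t=cut, criterion="distance")
    labels = _size_rank_colors(flat, feature_ids, min_module_size)
    if (labels == GREY).all():
        warnings.warn("cut_tree_to_modules: all features are grey")
    return labels


def find_module_cores(
    dendrogram: np.ndarray,
    n_features: int,
    core_min: int,
    quantiles=(0.1, 0.2, 0.3, 0.4, 0.5),
) -> list[np.ndarray]:
    """Tight cluster cores from static cuts at several merge-height quantiles.

    Different modules finish agglomerating at different heights, so a single
    static cut either misses slowly-coalescing modules or absorbs background.
    Scanning a ladder of conservative cut heights and claiming each cluster of
    at least ``core_min`` mostly-unclaimed features yields one pure core per
    module; features are assigned around these cores afterwards.
    """
    heights = dendrogram[:, 2]
    claimed = np.zeros(n_features, dtype=bool)
    cores: list[np.ndarray] = []
    for q in quantiles:
        cut = float(np.quantile(heights, q))
        flat = hierarchy.fcluster(dendrogram, t=cut, criterion="distance")
        for c in np.unique(flat):
            idx = np.where(flat == c)[0]
            if len(idx) < core_min:
                continue
            if claimed[idx].mean() > 0.2:
                continue  # grown version of an already-claimed core
            cores.append(idx[~claimed[idx]])
            claimed[idx] = True
    return cores


def _classify_by_kme(expr, assignment, kme_threshold, n_iter, min_module_size):
    """Iteratively (re)assign features to the best module by signed kME.

    After eigengene orientation true members correlate positively with their
    module eigengene, so assignment requires kME >= threshold (not absolute
    value), which halves the rate of chance background recruits.
    """
    for _ in range(n_iter):
        if (assignment != GREY).sum() == 0:
            return assignment
        eig = module_eigengenes(expr, assignment)
        mm = module_membership(expr, eig)
        best = mm.idxmax(axis=1)
        best_val = mm.max(axis=1)
        assignment = pd.Series(
            np.where(best_val >= kme_threshold, best, GREY),
            index=expr.index, name="module",
        )
        sizes = assignment[assignment != GREY].value_counts()
        for m in sizes[sizes < 2].index:
            assignment[assignment == m] = GREY
    return assignment


def _size_rank_colors(flat, feature_ids, min_module_size) -> pd.Series:
    flat = np.asarray(flat)
    counts = pd.Series(flat).value_counts()
    big = counts[counts >= min_module_size]
    first_pos = {c: int(np.argmax(flat == c)) for c in big.index}
    ordered = sorted(big.index, key=lambda c: (-big[c], first_pos[c]))
    color_of = {c: module_color(i) for i, c in enumerate(ordered)}
    labels = pd.Series(
        [color_of.get(c, GREY) for c in flat], index=feature_ids, name="module"
    )
    return labels


@dataclass
class Eigengenes:
    """Module eigengene profiles (module x sample) and variance explained."""

    profiles: pd.DataFrame
    var_explained: pd.Series

    def modules(self) -> list[str]:
        return list(self.profiles.index)


def module_eigengenes(expr: pd.DataFrame, assignment: pd.Series) -> Eigengenes:
    """First principal component of each module's standardized expression.

    Member rows are z-scored over samples; the eigengene is the first right
    singular vector (unit norm), oriented so that the mean correlation with
    member profiles is nonnegative.  Constant member rows are excluded with a
    warning.  Grey features are ignored.
    """
    assignment = assignment.loc[expr.index]
    profiles, var_exp = {}, {}
    for mod in sorted(set(assignment) - {GREY}):
        members = expr.loc[assignment == mod].to_numpy(float)
        sd = members.std(axis=1)
        if (sd < 1e-12).any():
            warnings.warn(
                f"module_eigengenes: {int((sd == 0).sum())} constant rows "
                f"excluded from module {mod}"
            )
            members = members[sd >= 1e-12]
        if members.shape[0] < 2:
            raise ValueError(f"module {mod} has fewer than 2 usable members")
        z = (members - members.mean(axis=1, keepdims=True)) / members.std(
            axis=1, keepdims=True
        )
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        me = vt[0]
        corrs = _row_correlations(z, me)
        if corrs.mean() < 0:
            me = -me
        profiles[mod] = me
        var_exp[mod] = float(s[0] ** 2 / (s**2).sum())
    me_df = pd.DataFrame(profiles, index=expr.columns).T
    me_df.index.name = "module"
    return Eigengenes(me_df, pd.Series(var_exp, name="var_explained"))


def _row_correlations(rows: np.ndarray, profile: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    pc = profile - profile.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (pc**2).sum())
    with np.errstate(invalid="ignore"):
        return np.where(denom > 0, rc @ pc / denom, 0.0)


def merge_close_modules(
    expr: pd.DataFrame,
    assignment: pd.Series,
    eigengenes: Eigengenes | None = None,
    merge_height: float = 0.25,
):
    """Merge modules whose eigengenes are closer than ``merge_height``.

    Iteratively merges the closest pair with eigengene dissimilarity
    1 - cor(ME_a, ME_b) below the threshold, recomputing eigengenes after
    each merge until a fixed point.  The merged module keeps the label of the
    larger member (ties: earlier color in the naming sequence).
    """
    assignment = assignment.copy()
    if eigengenes is None:
        eigengenes = module_eigengenes(expr, assignment)
    while True:
        mods = eigengenes.modules()
        if len(mods) < 2:
            break
        me = eigengenes.profiles.to_numpy(float)
        corr = np.corrcoef(me)
        diss = 1.0 - corr
        np.fill_diagonal(diss, np.inf)
        i, j = np.unravel_index(np.argmin(diss), diss.shape)
        if diss[i, j] >= merge_height:
            break
        a, b = mods[i], mods[j]
        keep, drop = _merge_order(assignment, a, b)
        assignment[assignment == drop] = keep
        eigengenes = module_eigengenes(expr, assignment)
    return assignment, eigengenes


def _merge_order(assignment: pd.Series, a: str, b: str):
    size_a = int((assignment == a).sum())
    size_b = int((assignment == b).sum())
    if size_a != size_b:
        return (a, b) if size_a > size_b else (b, a)
    rank = {c: i for i, c in enumerate(MODULE_COLORS)}
    ra = rank.get(a, len(rank))
    rb = rank.get(b, len(rank))
    return (a, b) if ra <= rb else (b, a)


def module_membership(expr: pd.DataFrame, eigengenes: Eigengenes) -> pd.DataFrame:
    """Module membership kME: cor(feature profile, module eigengene)."""
    arr = expr.to_numpy(float)
    out = {}
    for mod in eigengenes.modules():
        me = eigengenes.profiles.loc[mod].to_numpy(float)
        out[mod] = _row_correlations(arr, me)
    return pd.DataFrame(out, index=expr.index)


class CoexpressionNetwork:
    """Weighted co-expression network model for one expression matrix.

    Parameters
    ----------
    expr : DataFrame
        Network input expression (features x samples), typically
        log2-transformed normalized counts with zero-variance features
        removed.
    params : NetworkParams, optional
        Construction parameters; defaults follow the study (beta=6,
        unsigned, merge height 0.25).
    """

    def __init__(self, expr: pd.DataFrame, params: NetworkParams | None = None):
        if expr.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if expr.shape[1] < 3:
            raise ValueError("need at least 3 samples")
        if expr.shape[1] < 15:
            warnings.warn(
                f"only {expr.shape[1]} samples: correlation estimates will be "
                "noisy; interpret modules with caution"
            )
        self.expr = expr
        self.params = params or NetworkParams()

    def fit(self, pick_beta: bool = False, candidate_powers=(1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16)) -> "CoexpressionResult":
        """Run the full construction: correlation -> adjacency -> TOM ->
        clustering -> static cut -> eigengenes -> merge -> module membership."""
        p = self.params
        fit_table = None
        beta = p.beta
        if pick_beta:
            beta, fit_table = pick_soft_threshold(
                self.expr, candidate_powers, p.scale_free_target_r2, p.signed
            )
        r = correlation_matrix(self.expr)
        a = adjacency(r, beta, p.signed)
        tom = tom_similarity(a)
        diss = 1.0 - tom.to_numpy()
        dendrogram = average_linkage_dendrogram(diss)
        if p.detection == "static":
            assignment = cut_tree_to_modules(
                dendrogram, self.expr.index, p.min_module_size,
                p.cut_height_quantile,
            )
        else:
            core_min = max(5, p.min_module_size // 4)
            cores = find_module_cores(
                dendrogram, len(self.expr), core_min, p.core_quantiles
            )
            assignment = pd.Series(GREY, index=self.expr.index, name="module")
            for i, idx in enumerate(cores):
                assignment.iloc[idx] = f"core{i}"
            assignment = _classify_by_kme(
                self.expr, assignment, p.kme_threshold, p.kme_iterations,
                p.min_module_size,
            )
        if (assignment != GREY).sum():
            eigengenes = module_eigengenes(self.expr, assignment)
            assignment, eigengenes = merge_close_modules(
                self.expr, assignment, eigengenes, p.merge_height
            )
            sizes = assignment[assignment != GREY].value_counts()
            for m in sizes[sizes < p.min_module_size].index:
                assignment[assignment == m] = GREY
        if (assignment == GREY).all():
            warnings.warn("no modules detected; all features grey")
            eigengenes = Eigengenes(
                pd.DataFrame(columns=self.expr.columns), pd.Series(dtype=float)
            )
            mm = pd.DataFrame(index=self.expr.index)
        else:
            assignment = _rename_by_size(assignment)
            eigengenes = module_eigengenes(self.expr, assignment)
            mm = module_membership(self.expr, eigengenes)
        return CoexpressionResult(
            model=self,
            beta=beta,
            assignment=assignment,
            eigengenes=eigengenes,
            module_membership=mm,
            dendrogram=dendrogram,
            soft_threshold_table=fit_table,
        )


def _rename_by_size(assignment: pd.Series) -> pd.Series:
    """Re-apply the color sequence after merging so names track module size."""
    counts = assignment[assignment != GREY].value_counts()
    first_pos = {
        m: int(np.argmax((assignment == m).to_numpy())) for m in counts.index
    }
    ordered = sorted(counts.index, key=lambda m: (-counts[m], first_pos[m]))
    mapping = {m: module_color(i) for i, m in enumerate(ordered)}
    mapping[GREY] = GREY
    return assignment.map(mapping)


@dataclass
class CoexpressionResult:
    """Fitted co-expression network: module assignment and derived profiles."""

    model: CoexpressionNetwork
    beta: int
    assignment: pd.Series
    eigengenes: Eigengenes
    module_membership: pd.DataFrame
    dendrogram: np.ndarray
    soft_threshold_table: pd.DataFrame | None = None

    @property
    def modules(self) -> list[str]:
        return self.eigengenes.modules()

    def module_sizes(self) -> pd.Series:
        return self.assignment[self.assignment != GREY].value_counts()

    def summary(self) -> str:
        n_feat = len(self.assignment)
        sizes = self.module_sizes()
        grey = int((self.assignment == GREY).sum())
        lines = [
            "Weighted co-expression network",
            f"features: {n_feat}, samples: {self.model.expr.shape[1]}",
            f"soft threshold beta: {self.beta} "
            f"({'signed' if self.model.params.signed else 'unsigned'})",
            f"modules: {len(sizes)} (grey/unassigned: {grey})",
        ]
        for mod, size in sizes.items():
            ve = self.eigengenes.var_explained.get(mod, float("nan"))
            lines.append(f"  {mod:<14} size {size:>5}  var explained {ve:.2f}")
        return "\n".join(lines)

    def to_tsv(self, assignment_path=None, eigengene_path=None) -> None:
        if assignment_path is not None:
            self.assignment.rename("module").to_csv(
                assignment_path, sep="\t", index_label="feature_id"
            )
        if eigengene_path is not None:
            self.eigengenes.profiles.to_csv(eigengene_path, sep="\t")
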