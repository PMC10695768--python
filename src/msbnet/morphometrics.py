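"""Synapse morphometry statistics and dendrite self-proximity analysis.

The central question: are the synaptic contacts of one multi-synaptic bouton
(MSB) more alike than comparable groups of neighboring single-synaptic
boutons (SSBs) on a dendrite?  The comparison computes one sample variance per
MSB (over its contacts' spine volume, PSD area or active-zone area) and one
per group of consecutive same-dendrite SSBs, then contrasts the two variance
populations with Cliff's delta, a label-permutation test and a BCa bootstrap
confidence interval, with Ryan-Holm step-down adjustment across comparisons.

The proximity analysis asks how often a traced dendritic arbor comes close to
itself: after resampling the tree at constant 0.5 um node spacing, each node
counts the distinct *other* unbranched segments having at least one node
within a 5 um Euclidean radius, and counts are averaged within 10 equal-count
bins of path distance to the soma.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial import cKDTree

__all__ = [
    "SYNAPSE_COLUMNS",
    "validate_synapse_table",
    "read_synapse_table",
    "write_synapse_table",
    "within_bouton_variances",
    "ssb_neighbor_variances",
    "cliffs_delta",
    "permutation_test",
    "BootstrapResult",
    "bca_bootstrap_diff",
    "ryan_holm_adjust",
    "holm_adjust_pvalues",
    "VarianceComparisonResult",
    "compare_msb_ssb_variances",
    "NeuriteTree",
    "read_swc",
    "write_swc",
    "resample_tree",
    "dendrite_self_proximity",
]

SYNAPSE_COLUMNS = (
    "contact_id", "bouton_id", "dendrite_id", "position_um",
    "spine_volume_um3", "psd_area_um2", "az_area_um2",
    "bouton_volume_um3", "contact_count",
)

MEASURES = ("spine_volume_um3", "psd_area_um2", "az_area_um2")


def validate_synapse_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the per-contact schema and the per-bouton consistency invariants."""
    missing = [c for c in SYNAPSE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"synapse table missing columns: {missing}")
    if (table["contact_count"] < 1).any():
        raise ValueError("contact_count must be >= 1")
    for m in MEASURES + ("bouton_volume_um3",):
        if (table[m] <= 0).any():
            raise ValueError(f"{m} must be positive")
    g = table.groupby("bouton_id")
    if (g["contact_count"].nunique() > 1).any():
        raise ValueError("contacts of one bouton must share contact_count")
    if (g["bouton_volume_um3"].nunique() > 1).any():
        raise ValueError("contacts of one bouton must share bouton_volume")
    sizes = g.size()
    bad = sizes != g["contact_count"].first()
    if bad.any():
        raise ValueError(
            f"boutons whose row count differs from contact_count: "
            f"{list(sizes.index[bad])[:5]}"
        )
    return table


def read_synapse_table(path: str | Path) -> pd.DataFrame:
    return validate_synapse_table(pd.read_csv(path, sep="\t"))


def write_synapse_table(table: pd.DataFrame, path: str | Path) -> None:
    validate_synapse_table(table).to_csv(path, sep="\t", index=False)


def within_bouton_variances(
    table: pd.DataFrame,
    measure: str,
    alpha_range: tuple[int, int] = (2, 5),
) -> np.ndarray:
    """Unbiased sample variance of ``measure`` within each qualifying MSB.

    One value per bouton whose contact count lies in ``alpha_range``
    (inclusive), computed over that bouton's contacts.
    """
    if measure not in table.columns:
        raise ValueError(f"unknown measure {measure!r}")
    lo, hi = alpha_range
    sub = table[(table["contact_count"] >= lo) & (table["contact_count"] <= hi)]
    if sub.empty:
        warnings.warn("no boutons in the requested contact-count range")
        return np.empty(0)
    return sub.groupby("bouton_id")[measure].var(ddof=1).to_numpy()


def ssb_neighbor_variances(
    table: pd.DataFrame,
    measure: str,
    rng: np.random.Generator,
    group_sizes: tuple[int, int] = (2, 5),
    matching: str = "msb_histogram",
    fixed_size: int = 2,
    return_sizes: bool = False,
):
    """Variances over groups of neighboring SSB contacts on a dendrite.

    SSB contacts (contact_count == 1) are ordered by position along each
    dendrite and chopped into consecutive non-overlapping runs.  Under the
    default ``msb_histogram`` matching, run lengths are drawn from the
    empirical contact-count histogram of the table's MSBs (restricted to
    ``group_sizes``) so the SSB groups are size-matched to the MSBs they are
    compared with; ``matching="fixed"`` uses ``fixed_size`` throughout.
    Dendrites with fewer remaining contacts than the drawn size contribute
    nothing further.
    """
    lo, hi = group_sizes
    ssb = table[table["contact_count"] == 1]
    if matching == "msb_histogram":
        msb_alpha = (
            table[(table["contact_count"] >= lo) & (table["contact_count"] <= hi)]
            .groupby("bouton_id")["contact_count"].first().to_numpy()
        )
        if len(msb_alpha) == 0:
            raise ValueError("no MSBs to match group sizes against")
        sizes_pool, probs = np.unique(msb_alpha, return_counts=True)
        probs = probs / probs.sum()
        draw = lambda: int(rng.choice(sizes_pool, p=probs))
    elif matching == "fixed":
        draw = lambda: fixed_size
    else:
        raise ValueError(f"unknown matching strategy {matching!r}")

    variances = []
    sizes = []
    for _, dend in ssb.groupby("dendrite_id"):
        vals = dend.sort_values("position_um")[measure].to_numpy()
        i = 0
        while True:
            s = draw()
            if i + s > len(vals):
                break  # leftover contacts unused
            variances.append(np.var(vals[i:i + s], ddof=1))
            sizes.append(s)
            i += s
    if not variances:
        warnings.warn("no SSB neighbor groups could be formed")
    variances = np.asarray(variances)
    if return_sizes:
        return variances, np.asarray(sizes, dtype=int)
    return variances


# ---------------------------------------------------------------------------
# estimation statistics

def cliffs_delta(a, b) -> float:
    """Cliff's dominance effect size in [-1, 1], computed exactly.

    delta = (#{a_i > b_j} - #{a_i < b_j}) / (|a| * |b|).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("cliffs_delta requires two non-empty samples")
    if len(a) * len(b) <= 4_000_000:
        diff = np.sign(a[:, None] - b[None, :])
        return float(diff.mean())
    # large inputs: count via sorted ranks instead of the n*m matrix
    bs = np.sort(b)
    gt = np.searchsorted(bs, a, side="left").sum()
    le = len(a) * len(b) - np.searchsorted(bs, a, side="right").sum()
    return float((gt - le) / (len(a) * len(b)))


def _mean_diff(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(a) - np.mean(b))


def _t_stat(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    sp = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
    denom = np.sqrt(sp * (1 / na + 1 / nb))
    if denom == 0:
        return 0.0
    return float((np.mean(a) - np.mean(b)) / denom)


def permutation_test(
    a,
    b,
    rng: np.random.Generator,
    n_perm: int = 5000,
    statistic: str = "mean_difference",
    two_sided: bool = True,
) -> float:
    """Label-reshuffling permutation test between two samples.

    The observed statistic (mean difference by default, pooled-variance t as
    an option) is compared against ``n_perm`` random relabelings; the p-value
    uses the add-one correction p = (1 + #extreme) / (n_perm + 1), so it is
    never exactly zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    stat = {"mean_difference": _mean_diff, "t": _t_stat}[statistic]
    obs = stat(a, b)
    pooled = np.concatenate([a, b])
    na = len(a)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        s = stat(perm[:na], perm[na:])
        if two_sided:
            if abs(s) >= abs(obs) - 1e-12:
                count += 1
        else:
            if s >= obs - 1e-12:
                count += 1
    return (1 + count) / (n_perm + 1)


@dataclass
class BootstrapResult:
    estimate: float
    low: float
    high: float
    level: float
    method: str          # "bca" or "percentile" (degenerate fallback)
    n_boot: int


def _stat_fn(name: str):
    if name == "median_difference":
        return lambda a, b: float(np.median(a) - np.median(b))
    if name == "mean_difference":
        return _mean_diff
    raise ValueError(f"unknown statistic {name!r}")


def bca_bootstrap_diff(
    a,
    b,
    rng: np.random.Generator,
    stat: str = "median_difference",
    n_boot: int = 5000,
    level: float = 0.95,
) -> BootstrapResult:
    """Bias-corrected and accelerated bootstrap CI for a two-sample difference.

    Both samples are resampled independently.  The bias correction z0 comes
    from the fraction of bootstrap statistics below the observed value; the
    acceleration comes from the jackknife skewness of the statistic
    (delete-one over both samples).  If the bootstrap distribution or the
    jackknife is degenerate the percentile interval is returned instead, with
    a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per sample")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    fn = _stat_fn(stat)
    obs = fn(a, b)

    idx_a = rng.integers(0, len(a), size=(n_boot, len(a)))
    idx_b = rng.integers(0, len(b), size=(n_boot, len(b)))
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = fn(a[idx_a[i]], b[idx_b[i]])

    alpha = 1.0 - level
    lo_q, hi_q = alpha / 2, 1 - alpha / 2

    def percentile(reason: str) -> BootstrapResult:
        warnings.warn(f"BCa degenerate ({reason}); falling back to percentile interval")
        lo, hi = np.quantile(boots, [lo_q, hi_q])
        return BootstrapResult(obs, float(lo), float(hi), level, "percentile", n_boot)

    prop = np.mean(boots < obs)
    if prop <= 0.0 or prop >= 1.0 or np.ptp(boots) == 0:
        return percentile("bootstrap distribution entirely on one side")
    z0 = sps.norm.ppf(prop)

    # delete-one jackknife across both samples
    jack = np.empty(len(a) + len(b))
    for i in range(len(a)):
        jack[i] = fn(np.delete(a, i), b)
    for j in range(len(b)):
        jack[len(a) + j] = fn(a, np.delete(b, j))
    d = jack.mean() - jack
    denom = 6.0 * (d @ d) ** 1.5
    if denom == 0:
        return percentile("zero jackknife spread")
    accel = (d ** 3).sum() / denom

    z_lo, z_hi = sps.norm.ppf([lo_q, hi_q])
    q_lo = sps.norm.cdf(z0 + (z0 + z_lo) / (1 - accel * (z0 + z_lo)))
    q_hi = sps.norm.cdf(z0 + (z0 + z_hi) / (1 - accel * (z0 + z_hi)))
    lo, hi = np.quantile(boots, [q_lo, q_hi])
    return BootstrapResult(obs, float(lo), float(hi), level, "bca", n_boot)


def ryan_holm_adjust(n_comparisons: int, base_level: float = 0.95) -> np.ndarray:
    """Step-down Bonferroni confidence levels for ``m`` ranked comparisons.

    The most extreme comparison (rank 1) is held to level 1 - alpha/m, rank k
    to 1 - alpha/(m - k + 1); the least extreme keeps the base level.
    """
    m = n_comparisons
    if m < 1:
        raise ValueError("need at least one comparison")
    alpha = 1.0 - base_level
    k = np.arange(1, m + 1)
    return 1.0 - alpha / (m - k + 1)


def holm_adjust_pvalues(pvalues) -> np.ndarray:
    """Holm step-down adjusted p-values (the dual of ryan_holm_adjust)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p)
    mult = (m - np.arange(m)) * p[order]
    adj_sorted = np.minimum(np.maximum.accumulate(mult), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass
class VarianceComparisonResult:
    """Within-MSB vs neighboring-SSB variance comparison for one measure."""

    measure: str
    msb_variances: np.ndarray
    ssb_variances: np.ndarray
    mean_difference: float       # mean(MSB variances) - mean(SSB variances)
    cliffs_delta: float
    permutation_p: float
    bootstrap: BootstrapResult
    n_permutations: int
    n_bootstrap: int


def compare_msb_ssb_variances(
    table: pd.DataFrame,
    measure: str,
    rng: np.random.Generator,
    alpha_range: tuple[int, int] = (2, 5),
    n_perm: int = 5000,
    n_boot: int = 5000,
    level: float = 0.95,
    matching: str = "msb_histogram",
) -> VarianceComparisonResult:
    """Full pipeline for one measure: group, compare, and quantify the effect.

    A negative Cliff's delta means within-MSB variances tend to be smaller
    than the size-matched neighboring-SSB group variances, i.e. contacts of
    one bouton are more alike than contacts spread across boutons.
    """
    msb_v = within_bouton_variances(table, measure, alpha_range)
    ssb_v = ssb_neighbor_variances(table, measure, rng,
                                   group_sizes=alpha_range, matching=matching)
    if len(msb_v) == 0 or len(ssb_v) == 0:
        raise ValueError("variance comparison needs both MSB and SSB groups")
    delta = cliffs_delta(msb_v, ssb_v)
    p = permutation_test(msb_v, ssb_v, rng, n_perm=n_perm)
    boot = bca_bootstrap_diff(msb_v, ssb_v, rng, stat="mean_difference",
                              n_boot=n_boot, level=level)
    return VarianceComparisonResult(
        measure, msb_v, ssb_v, _mean_diff(msb_v, ssb_v), delta, p, boot,
        n_perm, n_boot)


# ---------------------------------------------------------------------------
# traced neurite trees (SWC) and self-proximity

@dataclass
class NeuriteTree:
    """Rooted 3D neurite morphology; node 0 is the soma.

    ``parent[i]`` is the index of node i's parent (-1 for the root); parents
    always precede children.  Coordinates are in micrometres.
    """

    xyz: np.ndarray                 # (n, 3) um
    parent: np.ndarray              # (n,) int, -1 at root
    node_type: np.ndarray | None = None
    radius: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.parent)
        if self.xyz.shape != (n, 3):
            raise ValueError("xyz must be (n, 3)")
        roots = np.where(self.parent < 0)[0]
        if len(roots) != 1 or roots[0] != 0:
            raise ValueError("tree must have a single root at index 0")
        if (self.parent[1:] >= np.arange(1, n)).any():
            raise ValueError("each parent must precede its children")
        if self.node_type is None:
            self.node_type = np.full(n, 3, dtype=int)
            self.node_type[0] = 1
        if self.radius is None:
            self.radius = np.full(n, 0.5)

    @property
    def n(self) -> int:
        return len(self.parent)

    def edge_lengths(self) -> np.ndarray:
        """Length of the edge to each node's parent (0 at the root)."""
        out = np.zeros(self.n)
        out[1:] = np.linalg.norm(
            self.xyz[1:] - self.xyz[self.parent[1:]], axis=1)
        return out

    def path_distances(self) -> np.ndarray:
        """Path distance along the tree from the soma to every node."""
        d = np.zeros(self.n)
        el = self.edge_lengths()
        for i in range(1, self.n):
            d[i] = d[self.parent[i]] + el[i]
        return d

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n)]
        for i in range(1, self.n):
            ch[self.parent[i]].append(i)
        return ch


def read_swc(path: str | Path) -> NeuriteTree:
    """Read a standard 7-column SWC file (ids may be arbitrary but sorted)."""
    ids, types, xs, ys, zs, rs, parents = [], [], [], [], [], [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        f = line.split()
        ids.append(int(f[0]))
        types.append(int(f[1]))
        xs.append(float(f[2]))
        ys.append(float(f[3]))
        zs.append(float(f[4]))
        rs.append(float(f[5]))
        parents.append(int(f[6]))
    index = {nid: i for i, nid in enumerate(ids)}
    parent = np.array([-1 if p == -1 else index[p] for p in parents])
    return NeuriteTree(
        xyz=np.column_stack([xs, ys, zs]).astype(float),
        parent=parent,
        node_type=np.asarray(types, dtype=int),
        radius=np.asarray(rs, dtype=float),
    )


def write_swc(tree: NeuriteTree, path: str | Path) -> None:
    lines = []
    for i in range(tree.n):
        p = -1 if tree.parent[i] < 0 else tree.parent[i] + 1
        x, y, z = tree.xyz[i]
        lines.append(
            f"{i + 1} {tree.node_type[i]} {float(x)!r} {float(y)!r} "
            f"{float(z)!r} {float(tree.radius[i])!r} {p}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _segments(tree: NeuriteTree) -> list[list[int]]:
    """Maximal unbranched segments as node-index paths.

    Each segment starts at the root or at a branch point and runs to the next
    branch point or tip; the starting node is included so consecutive segments
    share their junction node.
    """
    ch = tree.children()
    segs: list[list[int]] = []
    # segment seeds: children of the root and of every branch point
    stack = [(0, c) for c in ch[0]]
    while stack:
        start_parent, node = stack.pop()
        seg = [start_parent, node]
        while len(ch[node]) == 1:
            node = ch[node][0]
            seg.append(node)
        segs.append(seg)
        for c in ch[node]:
            stack.append((node, c))
    return segs


@dataclass
class _ResampledArbor:
    xyz: np.ndarray            # (n, 3)
    soma_dist: np.ndarray      # (n,) path distance to soma, um
    branch: np.ndarray         # (n,) segment index
    seg_parent: np.ndarray     # per segment: parent segment (-1 if at soma)
    seg_start_dist: np.ndarray  # per segment: soma path distance of its origin


def resample_tree(tree: NeuriteTree, spacing: float = 0.5) -> _ResampledArbor:
    """Resample every unbranched segment at constant arc-length spacing."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    path_d = tree.path_distances()
    segs = _segments(tree)
    # map each segment to its parent segment: the segment whose last node is
    # this segment's first node
    seg_of_end: dict[int, int] = {}
    for si, seg in enumerate(segs):
        seg_of_end[seg[-1]] = si
    seg_parent = np.array([seg_of_end.get(seg[0], -1) for seg in segs])
    seg_start_dist = np.array([path_d[seg[0]] for seg in segs])

    pts, dists, branch = [], [], []
    for si, seg in enumerate(segs):
        coords = tree.xyz[seg]
        arc = np.concatenate([[0.0], np.cumsum(
            np.linalg.norm(np.diff(coords, axis=0), axis=1))])
        total = arc[-1]
        n_new = max(int(np.floor(total / spacing + 1e-9)), 1)
        s_new = np.arange(1, n_new + 1) * spacing
        s_new = s_new[s_new <= total + 1e-9]
        if len(s_new) == 0:
            s_new = np.array([total])
        for s in s_new:
            j = np.searchsorted(arc, s, side="right") - 1
            j = min(j, len(seg) - 2)
            f = 0.0 if arc[j + 1] == arc[j] else (s - arc[j]) / (arc[j + 1] - arc[j])
            pts.append(coords[j] + f * (coords[j + 1] - coords[j]))
            dists.append(seg_start_dist[si] + s)
            branch.append(si)
    return _ResampledArbor(
        xyz=np.asarray(pts), soma_dist=np.asarray(dists),
        branch=np.asarray(branch, dtype=int),
        seg_parent=seg_parent, seg_start_dist=seg_start_dist)


def _seg_ancestors(seg_parent: np.ndarray, si: int) -> list[int]:
    chain = [si]
    while seg_parent[chain[-1]] >= 0:
        chain.append(seg_parent[chain[-1]])
    return chain


def _tree_path_distance(arbor: _ResampledArbor, seg_end_dist: np.ndarray,
                        i: int, j: int) -> float:
    """Path distance through the tree between two resampled nodes."""
    si, sj = arbor.branch[i], arbor.branch[j]
    di, dj = arbor.soma_dist[i], arbor.soma_dist[j]
    if si == sj:
        return abs(di - dj)
    ai = _seg_ancestors(arbor.seg_parent, si)
    aj = _seg_ancestors(arbor.seg_parent, sj)
    common = set(ai) & set(aj)
    if not common:
        meet = 0.0  # meet at the soma
    else:
        # deepest common ancestor segment; children attach at its distal end,
        # unless one node lies on the common segment itself
        c = next(s for s in ai if s in common)
        if c == si:
            meet = min(di, seg_end_dist[c])
        elif c == sj:
            meet = min(dj, seg_end_dist[c])
        else:
            meet = seg_end_dist[c]
    return abs(di - meet) + abs(dj - meet)


def dendrite_self_proximity(
    tree: NeuriteTree,
    node_spacing: float = 0.5,
    threshold: float = 5.0,
    n_bins: int = 10,
    path_exclusion: float | None = None,
) -> np.ndarray:
    """Mean count of nearby separate branches per soma-distance bin.

    The tree is resampled at ``node_spacing``; for each node, the number of
    distinct other unbranched segments with at least one node within
    ``threshold`` (Euclidean) is counted.  Nodes closer than
    ``path_exclusion`` (default: ``threshold``) along the tree are ignored, so
    a segment's own continuation across a branch point does not register as a
    separate nearby branch.  Nodes are ordered by path distance to the soma
    and split into ``n_bins`` equal-count bins; the per-bin mean counts are
    returned (possibly fewer bins, with a warning, for tiny trees).
    """
    path_exclusion = threshold if path_exclusion is None else path_exclusion
    arbor = resample_tree(tree, node_spacing)
    n = len(arbor.xyz)
    # distal end of each segment = max soma distance among its nodes
    n_segs = len(arbor.seg_parent)
    seg_end_dist = np.zeros(n_segs)
    np.maximum.at(seg_end_dist, arbor.branch, arbor.soma_dist)

    kdt = cKDTree(arbor.xyz)
    neighbor_lists = kdt.query_ball_point(arbor.xyz, r=threshold)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        seen: set[int] = set()
        for j in neighbor_lists[i]:
            bj = arbor.branch[j]
            if j == i or bj == arbor.branch[i] or bj in seen:
                continue
            if _tree_path_distance(arbor, seg_end_dist, i, j) > path_exclusion:
                seen.add(bj)
        counts[i] = len(seen)

    order = np.argsort(arbor.soma_dist, kind="stable")
    if n < n_bins:
        warnings.warn(f"only {n} nodes for {n_bins} bins; returning {n} bins")
        n_bins = n
    return np.array([chunk.mean() for chunk in
                     np.array_split(counts[order].astype(float), n_bins)])
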