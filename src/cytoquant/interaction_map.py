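"""GTPase x effector interaction matrix: assembly, scaling, family
reduction, hierarchical clustering and positive calling.

Raw protein-interaction-index (PI) scores per bait-prey pair are assembled
into a matrix (missing pairs kept distinct from zero), rescaled so the
maximum within a normalization scope (per effector column, or globally)
equals 1, optionally reduced to gene families by taking the maximum over
member effectors, clustered on both axes with complete linkage on Euclidean
distances, and thresholded into positive/negative interaction calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .condensates import PairScore


@dataclass
class PIMatrix:
    """Interaction-index matrix over GTPases (rows) x effectors (columns).

    ``raw`` holds raw PI values (NaN = pair not measured); ``scaled`` the
    rescaled values; ``efficiency`` the per-pair formation efficiency (%).
    """

    raw: pd.DataFrame
    scaled: pd.DataFrame | None = None
    efficiency: pd.DataFrame | None = None
    scope: str | None = None

    @property
    def gtpases(self) -> list[str]:
        return list(self.raw.index)

    @property
    def effectors(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def n_pairs(self) -> int:
        """Number of measured bait-prey pairs."""
        return int(self.raw.notna().sum().sum())


@dataclass
class ClusterResult:
    row_linkage: np.ndarray | None
    col_linkage: np.ndarray | None
    row_labels: np.ndarray
    col_labels: np.ndarray
    row_stability: dict
    col_stability: dict
    row_items: list[str] = field(default_factory=list)
    col_items: list[str] = field(default_factory=list)


def assemble(scores: list[PairScore], gtpases, effectors) -> PIMatrix:
    """Place pair scores into a labelled matrix; unmeasured pairs stay NaN.

    Raises on duplicate (bait, prey) pairs or labels outside the rosters.
    """
    gtpases = list(gtpases)
    effectors = list(effectors)
    raw = pd.DataFrame(np.nan, index=gtpases, columns=effectors, dtype=float)
    eff = raw.copy()
    seen = set()
    for s in scores:
        key = (s.bait, s.prey)
        if key in seen:
            raise ValueError(f"duplicate pair {key}")
        if s.bait not in raw.index or s.prey not in raw.columns:
            raise ValueError(f"pair {key} outside the supplied rosters")
        seen.add(key)
        raw.loc[s.bait, s.prey] = s.pi_raw
        eff.loc[s.bait, s.prey] = s.efficiency_pct
    return PIMatrix(raw=raw, efficiency=eff)


def scale(m: PIMatrix, scope: str = "per_effector_column") -> PIMatrix:
    """Rescale raw PI so the maximum of each scope equals 1.

    ``scope`` is ``"per_effector_column"`` (each effector column divided by
    its own max) or ``"global"`` (whole matrix divided by its max). All-zero
    scopes map to zeros; NaN entries stay NaN. Idempotent.
    """
    raw = m.raw
    if scope == "per_effector_column":
        col_max = raw.max(axis=0, skipna=True)
        # an all-zero (or all-missing) column is left unchanged: zeros stay
        # zeros, NaNs stay NaN
        denom = col_max.where(col_max > 0, 1.0)
        scaled = raw.div(denom, axis=1)
    elif scope == "global":
        mx = np.nanmax(raw.to_numpy()) if m.n_pairs else np.nan
        scaled = raw / mx if (np.isfinite(mx) and mx > 0) else raw.copy()
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return PIMatrix(raw=raw.copy(), scaled=scaled,
                    efficiency=None if m.efficiency is None else m.efficiency.copy(),
                    scope=scope)


def family_reduce(m: PIMatrix, families: dict[str, str],
                  use_scaled: bool = False) -> PIMatrix:
    """Reduce effector columns to gene families by the per-family maximum.

    Every effector must map to exactly one family; NaN entries are ignored in
    the max, and an all-missing family stays missing.
    """
    src = m.scaled if (use_scaled and m.scaled is not None) else m.raw
    missing = [e for e in src.columns if e not in families]
    if missing:
        raise KeyError(f"effectors without a family: {missing}")
    fam_order = list(dict.fromkeys(families[e] for e in src.columns))
    reduced = pd.DataFrame(np.nan, index=src.index, columns=fam_order, dtype=float)
    for fam in fam_order:
        members = [e for e in src.columns if families[e] == fam]
        reduced[fam] = src[members].max(axis=1, skipna=True)
    out = PIMatrix(raw=reduced)
    if m.efficiency is not None:
        effr = pd.DataFrame(np.nan, index=src.index, columns=fam_order, dtype=float)
        for fam in fam_order:
            members = [e for e in src.columns if families[e] == fam]
            effr[fam] = m.efficiency[members].max(axis=1, skipna=True)
        out.efficiency = effr
    return out


def _cluster_axis(data: np.ndarray, items, n_boot: int, rng: np.random.Generator):
    """Complete-linkage clustering of rows of ``data`` with bootstrap
    cluster stability over resampled columns.

    Stability of a cluster = fraction of bootstrap resamples (columns drawn
    with replacement) in which some cluster of the re-clustered partition has
    Jaccard overlap >= 0.5 with it. The flat partition is the k in
    2..n-1 maximizing mean cluster stability (k=1 if n < 3).
    """
    n = data.shape[0]
    if n < 2:
        return None, np.ones(n, dtype=int), {}
    link = hierarchy.linkage(data, method="complete", metric="euclidean")
    if n == 2:
        return link, np.array([1, 2]), {}

    def parts_for_k(lk, k):
        labels = hierarchy.fcluster(lk, t=k, criterion="maxclust")
        return [frozenset(np.flatnonzero(labels == c)) for c in np.unique(labels)], labels

    candidates = range(2, n)
    boot_parts = []
    for _ in range(n_boot):
        cols = rng.integers(0, data.shape[1], size=data.shape[1])
        blink = hierarchy.linkage(data[:, cols], method="complete",
                                  metric="euclidean")
        boot_parts.append(blink)

    best = None
    for k in candidates:  # ascending: ties resolved toward fewer clusters
        clusters, labels = parts_for_k(link, k)
        stab = []
        for cl in clusters:
            if len(cl) < 2:
                stab.append(np.nan)  # stability undefined for singletons
                continue
            hits = 0
            for blink in boot_parts:
                bcl, _ = parts_for_k(blink, k)
                best_j = max(len(cl & b) / len(cl | b) for b in bcl)
                if best_j >= 0.5:
                    hits += 1
            stab.append(hits / max(n_boot, 1))
        finite = [s for s in stab if np.isfinite(s)]
        score = float(np.mean(finite)) if finite else 0.0
        if best is None or score > best[0]:
            best = (score, labels,
                    {int(c): float(s) for c, s in zip(np.unique(labels), stab)})
    _, labels, stability = best
    return link, labels, stability


def cluster(m: PIMatrix, n_boot: int = 100, seed: int = 0,
            use_scaled: bool = True, impute: float = 0.0) -> ClusterResult:
    """Cluster GTPases (rows) and effectors (columns) with Euclidean
    distance and complete linkage; choose flat clusters by bootstrap
    stability (resampling the opposite axis).

    Missing entries are imputed with ``impute`` (default 0: screen-negative
    and unmeasured look identical in the heatmap).
    """
    src = m.scaled if (use_scaled and m.scaled is not None) else m.raw
    data = src.fillna(impute).to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    row_link, row_labels, row_stab = _cluster_axis(data, src.index, n_boot, rng)
    col_link, col_labels, col_stab = _cluster_axis(data.T, src.columns, n_boot, rng)
    return ClusterResult(
        row_linkage=row_link, col_linkage=col_link,
        row_labels=np.asarray(row_labels), col_labels=np.asarray(col_labels),
        row_stability=row_stab, col_stability=col_stab,
        row_items=list(src.index), col_items=list(src.columns),
    )


def call_positives(m: PIMatrix, pi_floor: float = 0.0,
                   eff_floor: float = 10.0) -> pd.DataFrame:
    """Boolean interaction calls: positive iff pi_raw > pi_floor and
    efficiency >= eff_floor (missing entries are negative)."""
    pos = m.raw > pi_floor
    if m.efficiency is not None:
        pos &= m.efficiency >= eff_floor
    return pos.fillna(False).astype(bool)


def linkage_to_newick(link: np.ndarray, labels) -> str:
    """Serialize a scipy linkage matrix as a Newick string."""
    tree = hierarchy.to_tree(link)

    def rec(node) -> str:
        if node.is_leaf():
            return str(labels[node.id])
        return (f"({rec(node.left)}:{node.dist - node.left.dist:.6g},"
                f"{rec(node.right)}:{node.dist - node.right.dist:.6g})")

    return rec(tree) + ";"


def plot_heatmap(m: PIMatrix, result: ClusterResult | None = None, ax=None,
                 use_scaled: bool = True):
    """Render the (optionally cluster-ordered) PI matrix as a heatmap."""
    import matplotlib.pyplot as plt

    src = m.scaled if (use_scaled and m.scaled is not None) else m.raw
    data = src.to_numpy(dtype=float)
    rows = list(src.index)
    cols = list(src.columns)
    if result is not None and result.row_linkage is not None:
        ro = hierarchy.leaves_list(result.row_linkage)
        data = data[ro]
        rows = [rows[i] for i in ro]
    if result is not None and result.col_linkage is not None:
        co = hierarchy.leaves_list(result.col_linkage)
        data = data[:, co]
        cols = [cols[i] for i in co]
    if ax is None:
        _, ax = plt.subplots(figsize=(0.4 * len(cols) + 2, 0.4 * len(rows) + 2))
    im = ax.imshow(data, cmap="viridis", aspect="auto", vmin=0)
    ax.set_xticks(range(len(cols)), cols, rotation=90)
    ax.set_yticks(range(len(rows)), rows)
    ax.figure.colorbar(im, ax=ax, label="scaled PI")
    return ax
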