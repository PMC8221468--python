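"""Nonparametric comparison of BACI contrasts across groups.

Pixel samples (distance-thinned to break neighbor correlation) are compared
across interventions, vegetation clusters, aspect classes, or soil parent
materials with the Kruskal-Wallis test followed by Games-Howell pairwise
post-hoc comparisons (robust to unequal variances and sample sizes).
Per-group location is summarized by the Hodges-Lehmann pseudo-median and
dispersion by the interquartile range; Shapiro-Wilk per group records the
normality pre-check that motivates the nonparametric route.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GroupComparison:
    """Summary of one grouped comparison."""

    by: str
    groups: pd.DataFrame  # group, n, hl_estimator, iqr, shapiro_p, letters
    kruskal_h: float
    kruskal_p: float
    pairwise_p: pd.DataFrame  # symmetric p-value matrix
    alpha: float = 0.05
    notes: list[str] = field(default_factory=list)


def thin_sample(
    mask: np.ndarray,
    pixel_size_m: float = 30.0,
    min_distance_m: float = 60.0,
    seed: int = 0,
    max_points: int | None = None,
) -> np.ndarray:
    """Greedy random thinning: (k, 2) row/col whose pixel centers are
    pairwise >= min_distance_m apart (center-to-center, so pixels two
    columns apart qualify at 30 m resolution).

    A random permutation is scanned and each candidate kept iff it clears
    every already-kept point — a maximal-effort (not maximum) independent
    subset, reproducible by seed.
    """
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return np.empty((0, 2), dtype=int)
    rng = np.random.default_rng(seed)
    order = rng.permutation(rows.size)
    pts = np.column_stack([rows, cols]).astype(float) * pixel_size_m
    min_d2 = min_distance_m**2
    kept_idx: list[int] = []
    kept_pts = np.empty((0, 2))
    for i in order:
        p = pts[i]
        if kept_pts.size:
            d2 = ((kept_pts - p) ** 2).sum(axis=1)
            if d2.min() < min_d2:
                continue
        kept_idx.append(i)
        kept_pts = np.vstack([kept_pts, p])
        if max_points is not None and len(kept_idx) >= max_points:
            break
    return np.column_stack([rows[kept_idx], cols[kept_idx]])


def hodges_lehmann(x) -> float:
    """One-sample Hodges-Lehmann pseudo-median: the median of all Walsh
    averages (x_i + x_j)/2 over i <= j."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    s = np.add.outer(x, x) / 2.0
    iu = np.triu_indices(x.size)
    return float(np.median(s[iu]))


def games_howell(samples: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Games-Howell pairwise comparisons.

    Welch-type statistic on group means with Welch-Satterthwaite degrees of
    freedom, referred to the studentized-range distribution with k groups.
    Returns a symmetric p-value matrix (diagonal 1). Pairs involving a
    zero-variance group are flagged with NaN df and a p from the degenerate
    limit (0 if means differ, 1 otherwise).
    """
    names = list(samples)
    k = len(names)
    stats_ = {
        g: (np.mean(v), np.var(v, ddof=1) / len(v), len(v))
        for g, v in ((g, np.asarray(v, float)) for g, v in samples.items())
    }
    p = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for a, b in itertools.combinations(names, 2):
        ma, sa, na = stats_[a]
        mb, sb, nb = stats_[b]
        se2 = sa + sb
        if se2 == 0:
            pv = 1.0 if ma == mb else 0.0
        else:
            t = abs(ma - mb) / np.sqrt(se2)
            df = se2**2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
            pv = float(stats.studentized_range.sf(t * np.sqrt(2), k, df))
        p.loc[a, b] = p.loc[b, a] = pv
    return p


def compact_letters(pairwise_p: pd.DataFrame, order, alpha: float = 0.05) -> dict:
    """Compact letter display: one letter per maximal clique of the
    not-significantly-different graph, lettered in ``order`` (groups sorted
    by their location estimate). Two groups share a letter iff no pairwise
    test separates them at ``alpha``."""
    import networkx as nx

    pos = {g: i for i, g in enumerate(order)}
    graph = nx.Graph()
    graph.add_nodes_from(order)
    for a, b in itertools.combinations(order, 2):
        if pairwise_p.loc[a, b] >= alpha:
            graph.add_edge(a, b)
    cliques = sorted(
        (sorted(c, key=pos.get) for c in nx.find_cliques(graph)),
        key=lambda c: [pos[g] for g in c],
    )
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in order}
    for letter, clique in zip(alphabet, cliques):
        for g in order:
            if g in clique:
                out[g] += letter
    return out


def kruskal_games_howell(groups: dict, by: str = "group", alpha: float = 0.05) -> GroupComparison:
    """Kruskal-Wallis across >= 2 groups with Games-Howell post-hoc.

    Per group: Hodges-Lehmann estimator, IQR (75th - 25th percentile), n,
    Shapiro-Wilk p (normality pre-check). Letters come from the pairwise
    matrix at ``alpha``; groups sharing no letter differ significantly.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    notes = []
    for g, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {g!r} has n={v.size} < 3")
        if np.ptp(v) == 0:
            notes.append(f"group {g!r} is constant; its pairwise tests are degenerate")
    h, p_kw = stats.kruskal(*groups.values())
    pairwise = games_howell(groups, alpha=alpha)
    hl = {g: hodges_lehmann(v) for g, v in groups.items()}
    order = sorted(groups, key=lambda g: hl[g])
    letters = compact_letters(pairwise, order, alpha=alpha)
    rows = []
    for g, v in groups.items():
        q25, q75 = np.percentile(v, [25, 75])
        sh_p = stats.shapiro(v).pvalue if np.ptp(v) > 0 else np.nan
        rows.append({
            "group": g, "n": v.size, "hl_estimator": hl[g],
            "iqr": q75 - q25, "shapiro_p": sh_p, "letters": letters[g],
        })
    return GroupComparison(
        by=by,
        groups=pd.DataFrame(rows),
        kruskal_h=float(h),
        kruskal_p=float(p_kw),
        pairwise_p=pairwise,
        alpha=alpha,
        notes=notes,
    )


def terrain_regression(
    baci_table: pd.DataFrame,
    terrain,
    covariate: str = "slope",
    sample_frac: float = 0.10,
    seed: int = 0,
) -> pd.DataFrame:
    """R^2 of contrast on a terrain covariate over a random 10% pixel sample,
    per intervention. Samples smaller than 10 pixels are skipped with a note."""
    if baci_table.empty:
        raise ValueError("empty BACI table")
    layer = terrain.layer(covariate)
    rng = np.random.default_rng(seed)
    rows = []
    for interv, sub in baci_table.groupby("intervention"):
        sub = sub.dropna(subset=["contrast"])
        n_take = int(round(sample_frac * len(sub)))
        if n_take < 10:
            rows.append({"intervention": interv, "covariate": covariate,
                         "n": n_take, "r2": np.nan, "note": "sample < 10 pixels"})
            continue
        idx = rng.choice(len(sub), size=n_take, replace=False)
        s = sub.iloc[idx]
        x = layer[s.row.to_numpy(), s.col.to_numpy()]
        y = s.contrast.to_numpy()
        res = stats.linregress(x, y)
        rows.append({"intervention": interv, "covariate": covariate,
                     "n": n_take, "r2": float(res.rvalue**2), "note": ""})
    return pd.DataFrame(rows)


def top_soil_classes(
    soil_parent: np.ndarray,
    intervention_labels: np.ndarray,
    class_names: list[str],
    k: int = 5,
) -> list[str]:
    """The k soil-parent-material classes with the largest intervened-pixel
    coverage; ties broken alphabetically. Returns all classes (with an
    implicit note via length) when fewer than k are present."""
    vals = soil_parent[intervention_labels > 0]
    counts = pd.Series(vals).value_counts()
    named = sorted(
        ((class_names[int(c)], int(n)) for c, n in counts.items()),
        key=lambda t: (-t[1], t[0]),
    )
    return [name for name, _ in named[:k]]


def aspect_classes(aspect_deg: np.ndarray, slope_deg: np.ndarray,
                   flat_below: float = 2.0) -> np.ndarray:
    """Discretize aspect into 8 compass octants (1=N ... 8=NW), 0 = flat
    (slope below ``flat_below`` degrees)."""
    octant = (np.floor(((aspect_deg + 22.5) % 360) / 45.0).astype(int) % 8) + 1
    return np.where(slope_deg < flat_below, 0, octant).astype(np.int8)
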