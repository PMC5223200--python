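"""Clustering, heat-map rendering, and table exports.

The agglomerative clustering is implemented directly (not delegated) so its
tie-breaking is deterministic: among equally close cluster pairs the one
whose smallest original leaf index is lowest wins.  Default distance is
1 - Pearson correlation over groups with average linkage; both are artifact
choices exposed as parameters.  Heat maps always write a plain-text sidecar
of the plotted standardized values, which is the testable surface; the
image itself is cosmetic.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from glycolect.differential import DifferentialCall

__all__ = [
    "ClusteringResult",
    "HeatmapMatrix",
    "cluster_lectins",
    "standardize_columns",
    "render_heatmap",
    "export_tables",
    "cophenetic_matrix",
]


@dataclass(frozen=True)
class ClusteringResult:
    """Leaf order plus a linkage matrix in the usual (id, id, height, size)
    row layout, with leaf ids 0..n-1 and merged-cluster ids n, n+1, ..."""

    leaves: tuple[str, ...]
    linkage: np.ndarray
    metric: str
    method: str


@dataclass(frozen=True)
class HeatmapMatrix:
    """Column-standardized values: rows are samples/groups, columns lectins."""

    values: pd.DataFrame


def standardize_columns(df: pd.DataFrame, ddof: int = 0) -> HeatmapMatrix:
    """Z-score each column; constant columns become all zeros."""
    means = df.mean(axis=0)
    sds = df.std(axis=0, ddof=ddof)
    z = (df - means).div(sds.where(sds > 0, 1.0), axis=1)
    return HeatmapMatrix(z)


# ---------------------------------------------------------------------------
# Agglomerative clustering
# ---------------------------------------------------------------------------

def _distance_matrix(X: np.ndarray, metric: str, names: Sequence[str]) -> np.ndarray:
    """Pairwise distances between columns of X (observations in rows)."""
    n = X.shape[1]
    D = np.zeros((n, n))
    if metric == "correlation":
        constant = [j for j in range(n) if np.ptp(X[:, j]) == 0]
        if constant:
            warnings.warn(
                f"constant columns under correlation metric "
                f"({[names[j] for j in constant]}); using Euclidean distance "
                "for pairs involving them",
                stacklevel=3,
            )
        for i, j in itertools.combinations(range(n), 2):
            if i in constant or j in constant:
                d = float(np.linalg.norm(X[:, i] - X[:, j]))
            else:
                d = 1.0 - float(np.corrcoef(X[:, i], X[:, j])[0, 1])
            D[i, j] = D[j, i] = d
    elif metric == "euclidean":
        for i, j in itertools.combinations(range(n), 2):
            D[i, j] = D[j, i] = float(np.linalg.norm(X[:, i] - X[:, j]))
    else:
        raise ValueError(f"unsupported metric {metric!r}")
    return D


def _cluster_distance(members_a: list[int], members_b: list[int],
                      D: np.ndarray, method: str) -> float:
    block = D[np.ix_(members_a, members_b)]
    if method == "average":
        return float(block.mean())
    if method == "complete":
        return float(block.max())
    if method == "single":
        return float(block.min())
    raise ValueError(f"unsupported method {method!r}")


def cluster_lectins(matrix: pd.DataFrame, metric: str = "correlation",
                    method: str = "average") -> ClusteringResult:
    """Cluster lectins (columns) of a groups x lectins profile matrix.

    Missing cells are imputed as the column mean with a warning; a fully
    missing column is imputed as 0.  Requires >= 2 lectins.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 lectins to cluster")
    df = matrix.astype(float)
    if df.isna().any().any():
        warnings.warn("missing cells imputed as column means", stacklevel=2)
        df = df.fillna(df.mean(axis=0)).fillna(0.0)
    names = list(df.columns)
    X = df.to_numpy()
    n = len(names)
    D = _distance_matrix(X, metric, names)

    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    active = list(range(n))
    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best: Optional[tuple[float, int, int, int]] = None
        for a, b in itertools.combinations(sorted(active), 2):
            d = _cluster_distance(members[a], members[b], D, method)
            key = min(min(members[a]), min(members[b]))
            cand = (d, key, a, b)
            if best is None or cand[:2] < best[:2]:
                best = cand
        d, _, a, b = best
        Z[step] = (a, b, d, len(members[a]) + len(members[b]))
        members[next_id] = members[a] + members[b]
        active.remove(a)
        active.remove(b)
        active.append(next_id)
        next_id += 1

    leaves_idx = _leaf_order(Z, n)
    return ClusteringResult(tuple(names[i] for i in leaves_idx), Z, metric, method)


def _leaf_order(Z: np.ndarray, n: int) -> list[int]:
    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b = int(Z[node - n, 0]), int(Z[node - n, 1])
        return walk(a) + walk(b)

    return walk(n + len(Z) - 1)


def cophenetic_matrix(result: ClusteringResult) -> np.ndarray:
    """Pairwise merge heights between leaves (order-independent summary)."""
    n = len(result.leaves)
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    C = np.zeros((n, n))
    for step, (a, b, d, _) in enumerate(result.linkage):
        ma, mb = members[int(a)], members[int(b)]
        for i in ma:
            for j in mb:
                C[i, j] = C[j, i] = d
        members[n + step] = ma + mb
    return C


# ---------------------------------------------------------------------------
# Heat map
# ---------------------------------------------------------------------------

def render_heatmap(matrix: HeatmapMatrix, clustering: Optional[ClusteringResult],
                   path: Union[str, Path]) -> Path:
    """Write a green-black-red heat map image plus a TSV sidecar.

    Columns are ordered by the clustering leaves when given.  Returns the
    sidecar path (``<image path>.tsv``) holding exactly the plotted values.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    df = matrix.values
    if clustering is not None:
        df = df.loc[:, list(clustering.leaves)]
    path = Path(path)
    sidecar = Path(str(path) + ".tsv")

    vmax = float(np.abs(df.to_numpy()).max()) or 1.0
    cmap = LinearSegmentedColormap.from_list("gbr", ["#00ff00", "#000000", "#ff0000"])
    fig, ax = plt.subplots(figsize=(max(4.0, 0.3 * df.shape[1]), max(2.0, 0.5 * df.shape[0])))
    im = ax.imshow(df.to_numpy(), cmap=cmap, vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(df.shape[1]))
    ax.set_xticklabels(df.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(df.shape[0]))
    ax.set_yticklabels(df.index, fontsize=7)
    fig.colorbar(im, ax=ax, shrink=0.7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)

    df.to_csv(sidecar, sep="\t", float_format="%.10g")
    return sidecar


# ---------------------------------------------------------------------------
# Table exports
# ---------------------------------------------------------------------------

def read_calls(path: Union[str, Path]) -> list[DifferentialCall]:
    """Read back a ``calls.tsv`` written by :func:`export_tables`."""
    import csv

    calls = []
    with open(path, encoding="utf-8") as fh:
        for r in csv.DictReader(fh, delimiter="\t"):
            model, control = r["Contrast"].split("/", 1)
            ratio = float("nan") if r["Ratio"] == "NA" else float(r["Ratio"])
            p = None if r["PValue"] == "NA" else float(r["PValue"])
            calls.append(
                DifferentialCall(r["Lectin"], (model, control), ratio, p,
                                 r["Direction"], r["Specificity"])
            )
    return calls


def _fmt_ratio(r: float) -> str:
    return "NA" if not np.isfinite(r) else f"{r:.2f}"


def export_tables(calls: Sequence[DifferentialCall], cross, out_dir: Union[str, Path],
                  ) -> dict[str, Path]:
    """Write per-contrast significant-lectin tables, the full call table,
    and (when a cross-model result is given) the opposite-pattern table
    with one ratio column per contrast."""
    if not calls:
        raise ValueError("no calls to export")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    full = out_dir / "calls.tsv"
    with full.open("w", encoding="utf-8") as fh:
        fh.write("Lectin\tSpecificity\tContrast\tRatio\tPValue\tDirection\n")
        for c in calls:
            p = "NA" if c.p_value is None else f"{c.p_value:.4g}"
            fh.write(
                f"{c.lectin}\t{c.specificity}\t{c.contrast[0]}/{c.contrast[1]}\t"
                f"{_fmt_ratio(c.ratio)}\t{p}\t{c.direction}\n"
            )
    written["calls"] = full

    contrasts = list(dict.fromkeys(c.contrast for c in calls))
    for contrast in contrasts:
        name = f"significant_{contrast[0]}_vs_{contrast[1]}.tsv"
        fp = out_dir / name
        with fp.open("w", encoding="utf-8") as fh:
            fh.write("Lectin\tSpecificity\tRatio\n")
            for c in calls:
                if c.contrast == contrast and c.significant:
                    fh.write(f"{c.lectin}\t{c.specificity}\t{_fmt_ratio(c.ratio)}\n")
        written[name] = fp

    if cross is not None:
        by_key = {(c.lectin, c.contrast): c for c in calls}
        fp = out_dir / "cross_model.tsv"
        with fp.open("w", encoding="utf-8") as fh:
            header = "Lectin\t" + "\t".join(f"{m}/{c}" for m, c in contrasts)
            fh.write(header + "\n")
            for lec in cross.opposite_lectins:
                cells = [
                    _fmt_ratio(by_key[(lec, ct)].ratio) if (lec, ct) in by_key else "NA"
                    for ct in contrasts
                ]
                fh.write(lec + "\t" + "\t".join(cells) + "\n")
        written["cross_model"] = fp
    return written
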