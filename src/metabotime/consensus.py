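"""Venn-style combination of the two selections and clustered heat maps."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .errors import DataError
from .io import IntensityMatrix

HEATMAP_DEFAULTS = {"metric": "euclidean", "linkage": "complete", "z_score": True}


@dataclass
class SelectionResult:
    """Both approaches' selections, their Venn combination and membership table.

    ``consensus`` is the intersection (features both approaches agree on);
    ``combined`` is the set reported per ``mode`` (default union) and is what
    feeds the final heat map. All sets are ordered by the feature universe.
    """

    set_t2: tuple[str, ...]
    set_rayleigh: tuple[str, ...]
    intersection: tuple[str, ...]
    union: tuple[str, ...]
    mode: str
    membership: pd.DataFrame

    @property
    def combined(self) -> tuple[str, ...]:
        return self.union if self.mode == "union" else self.intersection


def combine_selections(
    set_t2,
    set_rayleigh,
    universe: list[str],
    mode: str = "union",
) -> SelectionResult:
    """Intersect/unite the two feature sets over a common universe.

    Raises on feature ids foreign to the universe; output ordering follows the
    universe (i.e. input feature order), making results deterministic.
    """
    if mode not in ("union", "intersection"):
        raise DataError(f"mode must be 'union' or 'intersection', got {mode!r}")
    a, b, uni = set(set_t2), set(set_rayleigh), list(universe)
    foreign = sorted((a | b) - set(uni))
    if foreign:
        raise DataError(f"feature id(s) not in the universe: {', '.join(foreign)}")
    inter = a & b
    union = a | b
    membership = pd.DataFrame(
        {
            "feature_id": uni,
            "selected_t2": [f in a for f in uni],
            "selected_rayleigh": [f in b for f in uni],
            "consensus": [f in inter for f in uni],
            "combined": [f in (union if mode == "union" else inter) for f in uni],
        }
    )
    ordered = lambda s: tuple(f for f in uni if f in s)
    return SelectionResult(
        set_t2=ordered(a),
        set_rayleigh=ordered(b),
        intersection=ordered(inter),
        union=ordered(union),
        mode=mode,
        membership=membership,
    )


def cluster_heatmap(
    matrix: IntensityMatrix,
    feature_ids,
    metric: str = "euclidean",
    linkage_method: str = "complete",
    z_score: bool = True,
    render_path=None,
) -> list[str]:
    """Hierarchically cluster the selected features and return the leaf order.

    Rows are the selected features taken in input-matrix order (the
    documented tie-break), optionally z-scaled per row; columns keep the
    matrix order (condition-major, time-ordered). Rendering is optional so
    the pipeline stays testable headless; when ``render_path`` is given a
    heat-map image is written there.
    """
    universe = {f: i for i, f in enumerate(matrix.feature_ids)}
    missing = sorted(set(feature_ids) - set(universe))
    if missing:
        raise DataError(f"feature id(s) not in the matrix: {', '.join(missing)}")
    selected = sorted(set(feature_ids), key=universe.__getitem__)
    if len(selected) == 0:
        raise DataError("no features selected for the heat map")

    rows = matrix.values[[universe[f] for f in selected]]
    if z_score:
        mu = rows.mean(axis=1, keepdims=True)
        sd = rows.std(axis=1, ddof=0, keepdims=True)
        sd[sd == 0] = 1.0  # constant rows map to zero, not NaN
        rows = (rows - mu) / sd

    if len(selected) < 2:
        warnings.warn("fewer than 2 selected features; emitting a single-row heat map")
        leaf_order = list(selected)
    else:
        Z = hierarchy.linkage(rows, method=linkage_method, metric=metric)
        leaf_order = [selected[i] for i in hierarchy.leaves_list(Z)]

    if render_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        idx = [selected.index(f) for f in leaf_order]
        fig, ax = plt.subplots(
            figsize=(max(6, 0.28 * rows.shape[1]), max(3, 0.22 * len(leaf_order)))
        )
        im = ax.imshow(rows[idx], aspect="auto", cmap="RdBu_r", interpolation="nearest")
        ax.set_yticks(range(len(leaf_order)), labels=leaf_order, fontsize=6)
        ax.set_xticks(range(len(matrix.sample_ids)), labels=matrix.sample_ids,
                      rotation=90, fontsize=5)
        fig.colorbar(im, ax=ax, shrink=0.6, label="row z-score" if z_score else "value")
        fig.tight_layout()
        fig.savefig(render_path, dpi=150)
        plt.close(fig)

    return leaf_order
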