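"""End-to-end pipeline: normalize → both tests → consensus → heat map → files.

Every run writes a manifest recording package and library versions, the seed,
and every tunable decision flag, so that a result can be reproduced exactly;
two runs from the same configuration produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import DataError
from .io import (
    IntensityMatrix,
    StudyDesign,
    read_design,
    read_intensity_table,
    write_design,
    write_intensity_table,
    write_results,
)
from .normalize import normalize_matrix
from .hotelling import score_features, select_top_fraction
from .rayleigh import test_features
from .consensus import combine_selections, cluster_heatmap
from .synthetic import GeneratorConfig, generate_dataset


@dataclass
class PipelineConfig:
    """All tunable decisions of one pipeline run.

    Exactly one input source must be set: ``generator`` (simulate) or the
    ``matrix_path``/``design_path`` pair (load from files).
    """

    generator: GeneratorConfig | None = None
    matrix_path: str | None = None
    design_path: str | None = None
    impute_missing: bool = False
    normalization: str = "auto"     # auto | identity | log | boxcox | orq | none
    per_feature: bool = False
    selector_seed: int = 0
    fraction: float = 0.10          # top fraction retained by the T² ranking
    q: int = 2                      # retained principal components
    alpha: float = 1e-4             # strict significance threshold
    null: str = "rayleigh"          # rayleigh | chi
    consensus_mode: str = "union"   # set fed to the heat map
    heatmap_metric: str = "euclidean"
    heatmap_linkage: str = "complete"
    heatmap_z_score: bool = True
    render: bool = False


def _load_inputs(
    config: PipelineConfig, outdir: Path
) -> tuple[IntensityMatrix, StudyDesign, pd.DataFrame | None]:
    if (config.generator is None) == (config.matrix_path is None):
        raise DataError(
            "set exactly one input source: generator, or matrix_path + design_path"
        )
    if config.generator is not None:
        matrix, design, truth = generate_dataset(config.generator)
        write_intensity_table(matrix, outdir / "intensity_raw.tsv")
        write_design(design, outdir / "design.tsv")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        return matrix, design, truth
    if config.design_path is None:
        raise DataError("matrix_path given without design_path")
    matrix = read_intensity_table(config.matrix_path, impute_missing=config.impute_missing)
    design = read_design(config.design_path)
    design.check_pairing(matrix)
    return matrix, design, None


def _manifest(config: PipelineConfig, extra: dict) -> dict:
    import scipy

    cfg = asdict(config)
    if config.generator is not None:
        cfg["generator"] = {
            **{k: v for k, v in asdict(config.generator).items() if k != "effect_assignments"},
            "effect_assignments": [
                {"feature_index": i, **asdict(p)}
                for i, p in config.generator.effect_assignments
            ],
        }
    return {
        "versions": {
            "metabotime": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "config": cfg,
        **extra,
    }


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, Exception):
                raise DataError(f"stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute the full analysis and write all result files into ``outdir``.

    Returns a summary dict (selection sizes, fitted scale, file paths).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    with _stage("load"):
        matrix, design, truth = _load_inputs(config, outdir)

    with _stage("normalize"):
        if config.normalization == "none":
            normalized, norm_info = matrix, {"chosen": "none", "method": "none"}
        else:
            normalized, norm_info = normalize_matrix(
                matrix,
                method=config.normalization,
                per_feature=config.per_feature,
                seed=config.selector_seed,
            )
        write_intensity_table(normalized, outdir / "intensity_normalized.tsv")
        (outdir / "normalization.json").write_text(
            json.dumps(norm_info, indent=2, sort_keys=True) + "\n"
        )

    with _stage("test-t2"):
        scores, prior = score_features(normalized, design)
        set_t2 = select_top_fraction(scores, fraction=config.fraction)
        scores["selected_t2"] = scores["feature_id"].isin(set_t2)

    with _stage("test-rayleigh"):
        distances, diagnostics = test_features(
            normalized, design, q=config.q, alpha=config.alpha, null=config.null
        )
        set_rayleigh = distances.loc[distances["significant"], "feature_id"].tolist()

    with _stage("consensus"):
        selection = combine_selections(
            set_t2, set_rayleigh, universe=matrix.feature_ids, mode=config.consensus_mode
        )

    with _stage("heatmap"):
        if len(selection.combined) >= 1:
            leaf_order = cluster_heatmap(
                normalized,
                selection.combined,
                metric=config.heatmap_metric,
                linkage_method=config.heatmap_linkage,
                z_score=config.heatmap_z_score,
                render_path=(outdir / "heatmap.png") if config.render else None,
            )
        else:
            leaf_order = []
        (outdir / "leaf_order.txt").write_text("".join(f"{f}\n" for f in leaf_order))

    with _stage("write"):
        paths = write_results(selection, scores, distances, outdir)
        manifest = _manifest(
            config,
            {
                "moderation": {
                    "nu": float(prior.nu),
                    "lambda_diag": [float(v) for v in np.diag(prior.Lambda)],
                },
                "rayleigh_diagnostics": diagnostics,
                "selection_counts": {
                    "t2": len(selection.set_t2),
                    "rayleigh": len(selection.set_rayleigh),
                    "intersection": len(selection.intersection),
                    "union": len(selection.union),
                },
            },
        )
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )

    return {
        "selection": selection,
        "scores": scores,
        "distances": distances,
        "diagnostics": diagnostics,
        "nu": float(prior.nu),
        "leaf_order": leaf_order,
        "truth": truth,
        "paths": {**{k: str(v) for k, v in paths.items()},
                  "manifest": str(outdir / "manifest.json")},
    }
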