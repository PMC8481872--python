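"""Synthetic two-condition time-course LC-MS intensity data with known truth.

The generator emulates an untargeted-metabolomics study layout: two conditions
(untreated / treated), biological replicates, a short shared time axis, and
strictly positive, right-skewed intensities. Intensities are log-normal —
per-feature baseline log-means are drawn once so features span a realistic
abundance range — with sparse multiplicative outlier contamination producing
the narrow-peaked, long-tailed marginal shape typical of such data. Treatment
effects are planted on the log scale in treated samples only, following one of
four archetypes:

``early``
    shift at the first timepoint only (an immediate response that relaxes);
``late``
    shift at the last timepoint only (a response appearing at stationary phase);
``constant_shift``
    shift at every timepoint;
``absent_in_treated``
    intensity collapsed to a near-zero floor at every timepoint, emulating a
    compound completely consumed under treatment (e.g. a thiol scavenged by
    the stressor) while remaining detectable in untreated cultures.

Everything is a pure function of the configuration, including its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import CONDITIONS, IntensityMatrix, StudyDesign

ARCHETYPES = ("early", "late", "absent_in_treated", "constant_shift", "null")

#: Archetypes cycled by :func:`study_mimic_config`: the three temporal
#: response patterns reported for the emulated study (immediate response,
#: stationary-phase response, compound consumed under treatment).
MIMIC_ARCHETYPES = ("early", "late", "absent_in_treated")


@dataclass(frozen=True)
class EffectProfile:
    """A planted treatment effect for one feature.

    ``effect_size`` is expressed in units of the replicate noise
    ``baseline_log_sd``; ``affected_timepoints`` defaults to the archetype's
    canonical rule (first / last / all timepoints) when ``None``.
    """

    archetype: str
    effect_size: float = 3.0
    affected_timepoints: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ConfigError(
                f"effect_assignments: unknown archetype {self.archetype!r}; "
                f"choose one of {ARCHETYPES}"
            )
        if self.archetype == "null" and self.effect_size != 0:
            raise ConfigError("effect_assignments: archetype 'null' requires effect_size = 0")

    def resolve_timepoints(self, timepoints: tuple[float, ...]) -> tuple[float, ...]:
        if self.affected_timepoints is not None:
            extra = set(self.affected_timepoints) - set(timepoints)
            if extra:
                raise ConfigError(
                    f"effect_assignments: affected_timepoints {sorted(extra)} "
                    "not on the design time axis"
                )
            return tuple(sorted(self.affected_timepoints))
        if self.archetype == "early":
            return (timepoints[0],)
        if self.archetype == "late":
            return (timepoints[-1],)
        if self.archetype in ("constant_shift", "absent_in_treated"):
            return tuple(timepoints)
        return ()


@dataclass(frozen=True)
class GeneratorConfig:
    """Full description of one synthetic dataset (seed included)."""

    n_features: int = 125
    n_replicates: int = 3
    timepoints_h: tuple[float, ...] = (3.0, 12.0, 18.0, 24.0, 48.0)
    baseline_log_mean: float = 8.0
    baseline_log_sd: float = 0.35
    feature_log_spread: float = 1.5
    outlier_fraction: float = 0.02
    outlier_scale: float = 10.0
    absent_floor: float = 1e-6
    effect_assignments: tuple[tuple[int, EffectProfile], ...] = ()
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ConfigError(f"n_features must be >= 1, got {self.n_features}")
        if self.n_replicates < 2:
            raise ConfigError(f"n_replicates must be >= 2, got {self.n_replicates}")
        tps = tuple(float(t) for t in self.timepoints_h)
        if len(tps) < 2 or any(b <= a for a, b in zip(tps, tps[1:])):
            raise ConfigError(
                f"timepoints_h must be strictly increasing with length >= 2, got {tps}"
            )
        object.__setattr__(self, "timepoints_h", tps)
        if self.baseline_log_sd <= 0:
            raise ConfigError(f"baseline_log_sd must be > 0, got {self.baseline_log_sd}")
        if not 0 <= self.outlier_fraction < 1:
            raise ConfigError(
                f"outlier_fraction must lie in [0, 1), got {self.outlier_fraction}"
            )
        if self.outlier_scale <= 1:
            raise ConfigError(f"outlier_scale must be > 1, got {self.outlier_scale}")
        if not 0 < self.absent_floor < 1:
            raise ConfigError(f"absent_floor must lie in (0, 1), got {self.absent_floor}")
        seen: set[int] = set()
        assignments = []
        for idx, prof in self.effect_assignments:
            idx = int(idx)
            if not 0 <= idx < self.n_features:
                raise ConfigError(
                    f"effect_assignments: feature index {idx} out of range "
                    f"[0, {self.n_features})"
                )
            if idx in seen:
                raise ConfigError(f"effect_assignments: feature index {idx} assigned twice")
            seen.add(idx)
            prof.resolve_timepoints(self.timepoints_h)  # validates subset
            assignments.append((idx, prof))
        object.__setattr__(self, "effect_assignments", tuple(assignments))

    @property
    def n_samples(self) -> int:
        return 2 * self.n_replicates * len(self.timepoints_h)


def _feature_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"M{i + 1:0{width}d}" for i in range(n)]


def _design_frame(config: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for cond in CONDITIONS:  # condition-major, then timepoint, then replicate
        for t in config.timepoints_h:
            for r in range(1, config.n_replicates + 1):
                rows.append((f"{cond}_t{t:g}_r{r}", cond, t, r))
    return pd.DataFrame(rows, columns=["sample_id", "condition", "time_h", "replicate"])


def generate_dataset(
    config: GeneratorConfig,
) -> tuple[IntensityMatrix, StudyDesign, pd.DataFrame]:
    """Generate one dataset and the ground-truth table describing it.

    Returns the intensity matrix (features x samples, strictly positive), the
    matching study design, and a truth table with columns ``feature_id``,
    ``is_differential``, ``archetype`` and ``effect_size``. Identical configs
    (seed included) yield bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    F, n, tps = config.n_features, config.n_replicates, config.timepoints_h
    k = len(tps)

    feat_mean = config.baseline_log_mean + config.feature_log_spread * rng.standard_normal(F)
    # log-intensity cube: (feature, condition, timepoint, replicate)
    log_x = feat_mean[:, None, None, None] + config.baseline_log_sd * rng.standard_normal(
        (F, 2, k, n)
    )

    treated = CONDITIONS.index("treated")
    tp_index = {t: i for i, t in enumerate(tps)}
    for idx, prof in config.effect_assignments:
        sel = [tp_index[t] for t in prof.resolve_timepoints(tps)]
        if prof.archetype == "null":
            continue
        if prof.archetype == "absent_in_treated":
            floor = feat_mean[idx] + math.log(config.absent_floor)
            log_x[idx, treated, sel, :] = floor + 0.05 * rng.standard_normal((len(sel), n))
        else:
            log_x[idx, treated, sel, :] += prof.effect_size * config.baseline_log_sd

    if config.outlier_fraction > 0:
        mask = rng.random(log_x.shape) < config.outlier_fraction
        log_x = log_x + mask * math.log(config.outlier_scale)

    # column order matches _design_frame: condition-major, timepoint, replicate
    values = np.exp(log_x).reshape(F, 2 * k * n)

    design = StudyDesign(_design_frame(config))
    feature_ids = _feature_ids(F)
    matrix = IntensityMatrix(
        feature_ids=feature_ids, sample_ids=design.sample_ids, values=values
    )

    truth = pd.DataFrame(
        {
            "feature_id": feature_ids,
            "is_differential": False,
            "archetype": "null",
            "effect_size": 0.0,
        }
    )
    for idx, prof in config.effect_assignments:
        truth.loc[idx, "archetype"] = prof.archetype
        truth.loc[idx, "effect_size"] = prof.effect_size
        truth.loc[idx, "is_differential"] = prof.archetype != "null"
    return matrix, design, truth


def study_mimic_config(
    n_features: int = 125,
    n_differential: int = 16,
    effect_size: float = 3.0,
    seed: int = 42,
    **overrides,
) -> GeneratorConfig:
    """The packaged default emulating the study design.

    125 features (intracellular mimic; pass ``n_features=124`` for the
    extracellular one), biological triplicates, timepoints {3, 12, 18, 24, 48} h,
    and ``n_differential`` planted features (default 16, the intracellular
    significant-list size) cycled evenly through the early/late/absent
    archetypes at ``effect_size`` noise-units, on evenly spaced feature
    indices.
    """
    if not 0 <= n_differential <= n_features:
        raise ConfigError(
            f"n_differential must lie in [0, {n_features}], got {n_differential}"
        )
    assignments = []
    for j in range(n_differential):
        idx = round(j * n_features / max(n_differential, 1))
        archetype = MIMIC_ARCHETYPES[j % len(MIMIC_ARCHETYPES)]
        assignments.append((idx, EffectProfile(archetype=archetype, effect_size=effect_size)))
    return GeneratorConfig(
        n_features=n_features,
        effect_assignments=tuple(assignments),
        seed=seed,
        **overrides,
    )
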