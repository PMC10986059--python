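"""Synthetic longitudinal cohorts of choroidal metrics.

Emulates a two-cohort (myopic adults, myopic children) crossover design in
which each subject attends one visit per near-work duration (20, 40, 60 min)
and every choroidal metric is measured immediately before and after the
task.  Baseline values are drawn from the study population's baseline
distributions; the post-task value is the baseline plus a normally
distributed change whose mean and SD are the per-(group, metric, duration)
effect sizes.  Durations without a detectable effect use mean change zero
with the metric's typical change SD.

Units: SFCT µm; LA/SA/TCA 10³ µm²; CVI and CcFD percentage points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortSimParams",
    "generate_cohort",
    "DEFAULT_GROUP_EFFECTS",
    "DEFAULT_BASELINES",
    "METRICS",
    "DURATIONS_MIN",
]

METRICS = ("SFCT", "LA", "SA", "TCA", "CVI", "CcFD")
DURATIONS_MIN = (20, 40, 60)

#: (mean, SD) of each baseline metric per group, on reporting scales.
DEFAULT_BASELINES: dict[str, dict[str, tuple[float, float]]] = {
    "adult": {
        "SFCT": (267.2, 68.6),
        "LA": (990.0, 229.3),
        "SA": (589.4, 113.7),
        "TCA": (1579.4, 331.8),
        "CVI": (62.45, 3.08),
        "CcFD": (8.41, 2.20),
    },
    "child": {
        "SFCT": (255.9, 52.8),
        "LA": (919.6, 167.6),
        "SA": (587.8, 115.4),
        "TCA": (1507.4, 269.6),
        "CVI": (61.06, 2.90),
        "CcFD": (7.05, 1.33),
    },
}

#: (mean change, SD of change) per (group, metric, duration). Cells without
#: a detectable effect carry mean 0 with the metric's typical change SD.
DEFAULT_GROUP_EFFECTS: dict[tuple[str, str, int], tuple[float, float]] = {
    # adults
    ("adult", "SFCT", 20): (-5.1, 6.5),
    ("adult", "SFCT", 40): (0.0, 6.5),
    ("adult", "SFCT", 60): (0.0, 6.5),
    ("adult", "LA", 20): (-19.2, 18.6),
    ("adult", "LA", 40): (-9.4, 18.3),
    ("adult", "LA", 60): (0.0, 18.5),
    ("adult", "SA", 20): (-8.2, 12.6),
    ("adult", "SA", 40): (0.0, 12.6),
    ("adult", "SA", 60): (0.0, 12.6),
    ("adult", "TCA", 20): (-27.4, 24.9),
    ("adult", "TCA", 40): (0.0, 24.9),
    ("adult", "TCA", 60): (0.0, 24.9),
    ("adult", "CVI", 20): (0.0, 0.70),
    ("adult", "CVI", 40): (-0.39, 0.70),
    ("adult", "CVI", 60): (-0.28, 0.59),
    ("adult", "CcFD", 20): (0.0, 0.78),
    ("adult", "CcFD", 40): (0.30, 0.78),
    ("adult", "CcFD", 60): (0.37, 0.75),
    # children
    ("child", "SFCT", 20): (0.0, 6.5),
    ("child", "SFCT", 40): (0.0, 6.5),
    ("child", "SFCT", 60): (0.0, 6.5),
    ("child", "LA", 20): (0.0, 18.5),
    ("child", "LA", 40): (0.0, 18.5),
    ("child", "LA", 60): (0.0, 18.5),
    ("child", "SA", 20): (0.0, 13.0),
    ("child", "SA", 40): (0.0, 13.0),
    ("child", "SA", 60): (7.2, 13.0),
    ("child", "TCA", 20): (0.0, 25.3),
    ("child", "TCA", 40): (0.0, 25.3),
    ("child", "TCA", 60): (9.7, 25.3),
    ("child", "CVI", 20): (0.0, 0.72),
    ("child", "CVI", 40): (0.0, 0.72),
    ("child", "CVI", 60): (-0.28, 0.72),
    ("child", "CcFD", 20): (0.55, 0.64),
    ("child", "CcFD", 40): (0.0, 0.70),
    ("child", "CcFD", 60): (0.0, 0.70),
}

#: Axial-length distribution (mean mm, SD mm) per group.
DEFAULT_AL: dict[str, tuple[float, float]] = {
    "adult": (25.00, 1.05),
    "child": (24.56, 0.67),
}


@dataclass(frozen=True)
class CohortSimParams:
    """Simulation parameters for :func:`generate_cohort`."""

    n_per_group: int = 30
    group_effects: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_EFFECTS))
    baseline_means_sds: dict = field(default_factory=lambda: {
        g: dict(m) for g, m in DEFAULT_BASELINES.items()
    })
    al_distribution: dict = field(default_factory=lambda: dict(DEFAULT_AL))
    visit_jitter_frac: float = 0.2  # visit-to-visit baseline wobble, fraction of baseline SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for key, (_, sd) in self.group_effects.items():
            if sd < 0:
                raise ValueError(f"negative change SD for {key}")
        for g, metrics in self.baseline_means_sds.items():
            for m, (_, sd) in metrics.items():
                if sd < 0:
                    raise ValueError(f"negative baseline SD for {(g, m)}")


def generate_cohort(params: CohortSimParams) -> pd.DataFrame:
    """Simulate a long-format cohort table.

    One row per (subject, visit duration, phase, metric).  A subject-level
    baseline is drawn once per metric; each visit's pre value adds a small
    within-subject wobble so repeat visits agree but are not identical, as
    seen with repeated OCT sessions.

    Columns: ``subject, group, visit_min, phase, metric, value, al_mm``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    rows: list[tuple] = []
    for group in sorted(p.baseline_means_sds):
        al_mean, al_sd = p.al_distribution[group]
        for i in range(p.n_per_group):
            subject = f"{group[0].upper()}{i + 1:03d}"
            al = float(rng.normal(al_mean, al_sd))
            base = {
                m: rng.normal(mu, sd)
                for m, (mu, sd) in p.baseline_means_sds[group].items()
            }
            for dur in DURATIONS_MIN:
                for metric, (mu, sd) in p.baseline_means_sds[group].items():
                    pre = base[metric] + rng.normal(0.0, p.visit_jitter_frac * sd)
                    dmu, dsd = p.group_effects.get((group, metric, dur), (0.0, 0.0))
                    delta = dmu + (rng.normal(0.0, dsd) if dsd > 0 else 0.0)
                    rows.append((subject, group, dur, "pre", metric, float(pre), al))
                    rows.append((subject, group, dur, "post", metric, float(pre + delta), al))
    return pd.DataFrame(
        rows, columns=["subject", "group", "visit_min", "phase", "metric", "value", "al_mm"]
    )
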