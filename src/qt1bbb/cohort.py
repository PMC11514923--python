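"""Summary-level cohort simulation.

Generates a tidy table of per-subject, per-ROI normalized delta-qT1
summaries together with the clinical covariates the statistical layer
consumes: TLE/ETLE group, seizure-onset side, duration of epilepsy,
injection-to-scan latencies and standardized memory scores.

The value model is deliberately simple: for each subject, ROI,
hemisphere and map kind,

    value = baseline + group/ROI effect (lateralized) + slope * duration
            + subject intercept + noise,

where the group/ROI effect loads fully on the hemisphere ipsilateral to
the presumed seizure onset zone and partially on the contralateral one.
Memory scores are shifted downward for subjects whose onset side matches
the material-specific hemisphere (left for verbal, right for figural),
which induces the memory/biomarker association without a separate dial.

A full volumetric route (phantom volumes through the image pipeline)
lives in :mod:`qt1bbb.pipeline`; this module is the fast generator used
for statistical calibration at cohort scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "simulate_cohort"]

ROIS = ("cortex", "hippocampus", "amygdala", "piriform")


def _default_effects_ni() -> dict:
    # lateralized leakage excess (normalized delta-qT1 units) by group/ROI
    return {
        ("TLE", "piriform"): 0.025,
        ("TLE", "hippocampus"): 0.028,
        ("ETLE", "hippocampus"): 0.024,
    }


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and effect structure.

    Defaults mirror the covariate structure of a 37-subject epilepsy
    cohort: 14 TLE / 23 ETLE, duration of epilepsy with median ~15 y in
    [2, 44], injection-to-scan latencies with median ~35 min in
    [18, 266] (interictal and postictal latencies matched), memory
    scores standardized to a normative mean 100 / SD 10 with the cohort
    centred around 90.  Effects are additive shifts of the normalized
    interictal biomarker in the named group/ROI.
    """

    n_tle: int = 14
    n_etle: int = 23
    duration_median: float = 14.0
    duration_log_sd: float = 0.55
    duration_range: tuple[float, float] = (2.0, 44.0)
    latency_median: float = 34.6
    latency_log_sd: float = 0.5
    latency_range: tuple[float, float] = (18.0, 266.0)
    verbal_memory_mean: float = 90.0
    verbal_memory_sd: float = 12.0
    figural_memory_mean: float = 88.0
    figural_memory_sd: float = 13.0
    #: probability of left / right / unknown presumed onset side
    side_probs: tuple[float, float, float] = (14 / 37, 14 / 37, 9 / 37)
    baseline_ni: float = 0.02
    baseline_ip: float = 0.0
    effects_ni: dict = field(default_factory=_default_effects_ni)
    effects_ip: dict = field(default_factory=dict)
    duration_slope_ni: float = 0.001
    duration_slope_ip: float = 0.0
    #: fraction of the effect expressed contralaterally
    contralateral_fraction: float = 0.5
    #: SD of the per-subject shared intercept and the per-cell noise
    subject_sd: float = 0.008
    noise_sd_ni: float = 0.02
    noise_sd_ip: float = 0.05
    #: memory-score shift for side-concordant subjects (left->verbal,
    #: right->figural)
    memory_shift: float = -8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tle < 1 or self.n_etle < 1:
            raise ValueError("each group must contain at least one subject")
        if self.duration_range[0] < 0:
            raise ValueError("durations must be non-negative")
        if not np.isclose(sum(self.side_probs), 1.0):
            raise ValueError(f"side probabilities must sum to 1, got {self.side_probs}")


def _clipped_lognormal(rng, median, log_sd, lo, hi, size):
    return np.clip(rng.lognormal(np.log(median), log_sd, size), lo, hi)


def simulate_cohort(cs: CohortSpec) -> pd.DataFrame:
    """Draw one cohort; deterministic given ``cs.seed``.

    Returns a tidy frame with one row per subject x ROI x hemisphere x
    map kind: columns ``subject, group, side, duration, latency_ii,
    latency_pi, verbal_memory, figural_memory, roi, hemisphere, kind,
    value``.
    """
    rng = np.random.default_rng(cs.seed)
    n = cs.n_tle + cs.n_etle
    groups = ["TLE"] * cs.n_tle + ["ETLE"] * cs.n_etle

    duration = _clipped_lognormal(
        rng, cs.duration_median, cs.duration_log_sd, *cs.duration_range, size=n
    )
    latency_ii = _clipped_lognormal(
        rng, cs.latency_median, cs.latency_log_sd, *cs.latency_range, size=n
    )
    # postictal latencies were deliberately matched to interictal ones
    latency_pi = np.clip(
        latency_ii * rng.lognormal(0.0, 0.05, n), *cs.latency_range
    )
    side = rng.choice(["left", "right", "unknown"], size=n, p=cs.side_probs)
    verbal = rng.normal(cs.verbal_memory_mean, cs.verbal_memory_sd, n)
    figural = rng.normal(cs.figural_memory_mean, cs.figural_memory_sd, n)
    verbal = verbal + np.where(side == "left", cs.memory_shift, 0.0)
    figural = figural + np.where(side == "right", cs.memory_shift, 0.0)

    rows = []
    for i in range(n):
        sid = f"sub-{i + 1:03d}"
        intercept = {
            "ni": rng.normal(0.0, cs.subject_sd),
            "ip": rng.normal(0.0, cs.subject_sd),
        }
        for roi in ROIS:
            eff_ni = cs.effects_ni.get((groups[i], roi), 0.0)
            eff_ip = cs.effects_ip.get((groups[i], roi), 0.0)
            for hemi in ("left", "right"):
                if side[i] == "unknown":
                    lat_frac = (1.0 + cs.contralateral_fraction) / 2.0
                else:
                    lat_frac = 1.0 if hemi == side[i] else cs.contralateral_fraction
                for kind, eff, base, slope, sd in (
                    ("ni", eff_ni, cs.baseline_ni, cs.duration_slope_ni, cs.noise_sd_ni),
                    ("ip", eff_ip, cs.baseline_ip, cs.duration_slope_ip, cs.noise_sd_ip),
                ):
                    value = (
                        base
                        + eff * lat_frac
                        + slope * duration[i]
                        + intercept[kind]
                        + rng.normal(0.0, sd)
                    )
                    rows.append(
                        {
                            "subject": sid,
                            "group": groups[i],
                            "side": side[i],
                            "duration": duration[i],
                            "latency_ii": latency_ii[i],
                            "latency_pi": latency_pi[i],
                            "verbal_memory": verbal[i],
                            "figural_memory": figural[i],
                            "roi": roi,
                            "hemisphere": hemi,
                            "kind": kind,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)
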