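"""Cohort simulator: clinical tables and acoustic feature tables with
planted clinical structure.

The generator emulates the study cohort's published marginals (n = 122, 39%
female, 11% bulbar onset, median [IQR] summaries for the six clinical
measures, and the per-measure missing-value counts). Continuous measures are
drawn from logistic distributions quantile-matched to the median and IQR
(s = IQR / (2 ln 3)), then clamped to their valid ranges; ordinal rating-scale
scores are rounded to integers.

The acoustic feature table carries two latent "nuisance" factors shared across
features — emulating the strong within-family correlation of real acoustic
measures — plus a planted severity effect: a designated subset of feature
columns is shifted by ``effect_size`` standard deviations between the
less-severe and more-severe subgroups of one clinical measure. This planted
structure is what the downstream validation machinery is tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features.names import FEATURE_NAMES

# Table-matched defaults: measure -> (median, IQR, low clamp, high clamp, integer?)
DEFAULT_MARGINALS = {
    "age": (59.0, 14.0, 18.0, 95.0, True),
    "frs_total": (35.0, 12.0, 0.0, 48.0, True),
    "frs_bulb": (11.0, 3.0, 0.0, 12.0, True),
    "frs_resp": (10.0, 6.0, 0.0, 12.0, True),
    "sit_rate": (148.0, 51.0, 20.0, 280.0, False),
    "sit_intell": (99.0, 5.0, 0.0, 100.0, False),
    "fvc_pct": (75.0, 30.0, 5.0, 150.0, False),
}

DEFAULT_MISSING = {
    "onset_site": 2,
    "age": 28,
    "frs_total": 28,
    "frs_bulb": 28,
    "frs_resp": 32,
    "sit_rate": 4,
    "sit_intell": 4,
    "fvc_pct": 53,
}

# Features carrying the planted severity effect by default: perturbation and
# timing families, which the study found most clinically informative.
DEFAULT_DESIGNATED = (
    "jitter local",
    "jitter local abs",
    "jitter rap",
    "jitter PPQ5",
    "jitter DDP",
    "shimmer local",
    "shimmer APQ3",
    "speech rate",
    "articulation rate",
    "avg word dur",
)

CLINICAL_COLUMNS = (
    "sex_code",
    "onset_site",
    "age",
    "frs_total",
    "frs_bulb",
    "frs_resp",
    "sit_rate",
    "sit_intell",
    "fvc_pct",
)


@dataclass
class CohortSpec:
    """Configuration of one simulated cohort draw."""

    n: int = 122
    frac_female: float = 0.39
    frac_bulbar_onset: float = 0.11
    clinical_marginals: dict = field(default_factory=lambda: dict(DEFAULT_MARGINALS))
    missing_counts: dict = field(default_factory=lambda: dict(DEFAULT_MISSING))
    effect_size: float = 1.0
    designated_features: tuple = DEFAULT_DESIGNATED
    severity_measure: str = "sit_rate"
    severity_threshold: float = 160.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("cohort size must be at least 2")
        for frac in (self.frac_female, self.frac_bulbar_onset):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        for name, spec in self.clinical_marginals.items():
            if spec[1] <= 0:
                raise ValueError(f"infeasible marginal for {name}: IQR must be > 0")
        for name, cnt in self.missing_counts.items():
            if not 0 <= cnt <= self.n:
                raise ValueError(f"missing count for {name} outside [0, n]")
        unknown = set(self.designated_features) - set(FEATURE_NAMES)
        if unknown:
            raise ValueError(f"unknown designated features: {sorted(unknown)}")


def _logistic_draw(rng, median, iqr, lo, hi, integer, size):
    s = iqr / (2.0 * np.log(3.0))
    x = rng.logistic(median, s, size)
    x = np.clip(x, lo, hi)
    return np.round(x) if integer else x


def simulate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw one cohort; returns ``(feature_table, clinical_table)``.

    Both tables are indexed by participant id. The feature table has the 53
    canonical acoustic columns; the clinical table has demographic and
    clinical measures with the configured missingness inserted.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    ids = [f"P{i:03d}" for i in range(n)]

    sex = np.where(rng.random(n) < spec.frac_female, 2, 1)  # male = 1, female = 2
    onset = np.where(rng.random(n) < spec.frac_bulbar_onset, "bulbar", "spinal")

    clin = pd.DataFrame(index=pd.Index(ids, name="participant_id"))
    clin["sex_code"] = sex
    clin["onset_site"] = onset
    for name, (median, iqr, lo, hi, integer) in spec.clinical_marginals.items():
        clin[name] = _logistic_draw(rng, median, iqr, lo, hi, integer, n)

    # Severity indicator from the underlying (pre-missingness) values.
    sev_values = clin[spec.severity_measure].to_numpy(dtype=float)
    more_severe = sev_values < spec.severity_threshold

    # One latent nuisance factor shared across the non-designated features
    # (emulating the strong within-family correlation of acoustic measures);
    # designated features carry the severity shift instead. Keeping a single
    # nuisance factor leaves room in a 2-D representation for both the
    # shared acoustic factor and the severity contrast.
    u = rng.normal(0.0, 1.0, n)
    designated = set(spec.designated_features)
    cols = {}
    for name in FEATURE_NAMES:
        if name in designated:
            x = rng.normal(0.0, 1.0, n) + spec.effect_size * more_severe.astype(float)
        else:
            load = 0.6
            x = load * u + np.sqrt(1.0 - load**2) * rng.normal(0.0, 1.0, n)
        cols[name] = x
    feats = pd.DataFrame(cols, index=clin.index)

    # Insert missingness (uniform at random within each measure).
    for name, cnt in spec.missing_counts.items():
        if cnt == 0 or name not in clin.columns:
            continue
        idx = rng.choice(n, size=cnt, replace=False)
        if clin[name].dtype == object:
            clin.loc[clin.index[idx], name] = None
        else:
            col = clin[name].to_numpy(dtype=float)
            col[idx] = np.nan
            clin[name] = col

    return feats, clin
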