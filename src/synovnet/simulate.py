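"""Synthetic synovial-fluid cohort generator.

The clinical study this package models published only group-level summary
statistics for its 108-patient cohort: per clinical group and per marker, a
mean, the 95% confidence interval of that mean, and the observed
[min, max] range. This module turns those four numbers into a sampling
distribution — a truncated normal on [min, max] whose location parameter is
adjusted by bisection so that the *truncated* mean equals the printed mean
— and generates patient tables with the published group structure:

========  ===  =====================================================
group       n  description
========  ===  =====================================================
PJI        16  culture-positive prosthetic joint infection
LG-PJI      8  low-grade (culture-negative) prosthetic joint infection
OL/AL      20  osteolysis / aseptic loosening (non-infected implants)
OA-INF     28  osteoarthritis with native-joint infection
OA         36  osteoarthritis controls
========  ===  =====================================================

PJI and LG-PJI together form the "PJI-all" contrast group (n=24).

A second, *archetype* mode plants known cluster structure: each archetype
is a centroid on the rescaled [0,1] marker scale (levels high/mid/low ->
0.8/0.5/0.2) plus isotropic Gaussian noise, and each generated record
carries its ground-truth archetype label for cluster-recovery testing.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from synovnet.cohort import CohortTable

# conventional 95% two-sided normal quantile used to invert the CI
# half-width of the mean (the value the published summaries were built with)
_Z95 = 1.96

#: alpha-defensin positivity thresholds, both expressed in pg/ml.
ELISA_LOD_PG_ML = 156.0
LATERAL_FLOW_LOD_PG_ML = 1_560.0 * 1_000.0  # 1,560 ng/ml

#: Levels an archetype can assign to a marker, on the rescaled [0,1] scale.
ARCHETYPE_LEVELS = {"high": 0.8, "mid": 0.5, "low": 0.2}

#: Composition markers constrained to sum to at most 100% of CD45+ cells.
COMPOSITION_MARKERS = ("lym_pct", "mon_mphi_pct", "neu_pct")


@dataclass(frozen=True)
class MarkerCalibration:
    """Published summary statistics for one marker in one clinical group.

    ``ci_half`` is the half-width of the 95% confidence interval of the
    group mean (the "mean ± x" form the study reports); ``min_val`` and
    ``max_val`` are the observed range.
    """

    marker_name: str
    mean: float
    ci_half: float
    min_val: float
    max_val: float

    def __post_init__(self) -> None:
        if self.ci_half < 0:
            raise ValueError(f"{self.marker_name}: ci_half must be >= 0")
        if self.min_val > self.max_val:
            raise ValueError(f"{self.marker_name}: min_val > max_val")
        if not (self.min_val <= self.mean <= self.max_val):
            raise ValueError(
                f"{self.marker_name}: mean {self.mean} outside "
                f"[{self.min_val}, {self.max_val}]"
            )


@dataclass(frozen=True)
class GroupCalibration:
    """All marker calibrations for one clinical group of size ``n``."""

    group_label: str
    n: int
    markers: tuple[MarkerCalibration, ...]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size n must be >= 1")
        names = [m.marker_name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate marker names in group {self.group_label}")

    def marker(self, name: str) -> MarkerCalibration:
        for m in self.markers:
            if m.marker_name == name:
                return m
        raise KeyError(name)


@dataclass(frozen=True)
class ArchetypeProfile:
    """A planted cluster: a level per marker, a size, and a noise scale.

    ``level_per_marker`` maps each marker of the panel to one of
    ``{"high", "mid", "low"}``; the centroid is the level-mapped vector on
    the rescaled [0,1] scale and records are drawn as centroid + N(0,
    noise_sd) clipped to [0,1].
    """

    archetype_id: str
    level_per_marker: dict[str, str]
    size: int
    noise_sd: float = 0.08
    group_label: str = ""

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("archetype size must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        bad = {v for v in self.level_per_marker.values()} - set(ARCHETYPE_LEVELS)
        if bad:
            raise ValueError(f"unknown level(s) {bad}; use high/mid/low")

    def centroid(self, markers: list[str]) -> np.ndarray:
        missing = [m for m in markers if m not in self.level_per_marker]
        if missing:
            raise ValueError(
                f"archetype {self.archetype_id} has no level for {missing}"
            )
        return np.array([ARCHETYPE_LEVELS[self.level_per_marker[m]] for m in markers])


@dataclass
class GeneratorConfig:
    """Configuration for :func:`generate_cohort`."""

    groups: list[GroupCalibration]
    seed: int = 0
    mode: str = "calibrated"  # or "archetype"
    archetypes: list[ArchetypeProfile] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [g.group_label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate group labels in generator config")
        if self.mode not in ("calibrated", "archetype"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "archetype" and not self.archetypes:
            raise ValueError("archetype mode requires a non-empty archetype list")


# ---------------------------------------------------------------------------
# Published calibrations (main-text cohort table).
# Each entry: marker -> (mean, ci_half, min, max). Units: cd45_abs in
# 1e9 cells/l, the rest in % of CD45+ cells.
# ---------------------------------------------------------------------------

_T1 = {
    "PJI-all": dict(
        n=24,
        cd45_abs=(25.6, 17.5, 0.1, 149.1),
        lym_pct=(14.1, 8.3, 0.5, 67.4),
        mon_mphi_pct=(11.9, 4.2, 0.5, 28.8),
        neu_pct=(73.2, 11.3, 4.2, 98.1),
    ),
    "LG-PJI": dict(
        n=8,
        cd45_abs=(2.4, 2.0, 0.5, 6.3),
        lym_pct=(8.3, 3.9, 3.1, 15.3),
        mon_mphi_pct=(12.5, 8.7, 1.0, 28.8),
        neu_pct=(78.2, 10.5, 59.4, 92.2),
    ),
    "PJI": dict(
        n=16,
        cd45_abs=(37.3, 24.9, 0.1, 149.1),
        lym_pct=(17.0, 12.6, 0.5, 67.4),
        mon_mphi_pct=(11.5, 5.3, 0.5, 27.2),
        neu_pct=(70.7, 16.8, 4.2, 98.1),
    ),
    "OL/AL": dict(
        n=20,
        cd45_abs=(1.2, 1.0, 0.1, 9.7),
        lym_pct=(46.5, 11.1, 6.4, 89.1),
        mon_mphi_pct=(32.9, 10.6, 6.0, 77.9),
        neu_pct=(19.5, 6.6, 2.5, 47.0),
    ),
    "OA-INF": dict(
        n=28,
        cd45_abs=(17.3, 6.4, 0.2, 59.3),
        lym_pct=(7.6, 3.2, 0.2, 29.5),
        mon_mphi_pct=(13.7, 5.0, 0.9, 66.8),
        neu_pct=(70.9, 7.1, 1.7, 97.8),
    ),
    "OA": dict(
        n=36,
        cd45_abs=(0.5, 0.2, 0.1, 2.9),
        lym_pct=(34.8, 6.5, 4.5, 84.1),
        mon_mphi_pct=(50.5, 6.8, 12.3, 92.2),
        neu_pct=(13.6, 3.6, 1.4, 44.8),
    ),
}

MARKER_UNITS = {
    "cd45_abs": "1e9 cells/l",
    "lym_pct": "% of CD45+",
    "mon_mphi_pct": "% of CD45+",
    "neu_pct": "% of CD45+",
}


def group_calibration(label: str) -> GroupCalibration:
    """The published calibration for one clinical group (incl. ``PJI-all``)."""
    entry = dict(_T1[label])
    n = entry.pop("n")
    markers = tuple(
        MarkerCalibration(name, *vals) for name, vals in entry.items()
    )
    return GroupCalibration(label, n, markers)


def default_generator_config(seed: int = 0) -> GeneratorConfig:
    """Generator config reproducing the study's five disjoint groups (n=108).

    PJI-all is not generated directly: its members are the union of the PJI
    (n=16) and LG-PJI (n=8) subgroups, each drawn from its own calibration.
    """
    groups = [group_calibration(g) for g in ("PJI", "LG-PJI", "OL/AL", "OA-INF", "OA")]
    return GeneratorConfig(groups=groups, seed=seed)


#: The six parameters of the published best-clustering similarity network.
NETWORK_PANEL = (
    "cdc2_pct",
    "lym_pct",
    "nk_pct",
    "hladr_nk_pct",
    "cd88_cdc1_pct",
    "hladr_mon_mphi",
)


def default_archetypes(noise_sd: float = 0.08) -> list[ArchetypeProfile]:
    """Four planted archetypes over the six-parameter network panel.

    They mirror the reported infection-vs-aseptic contrast (infection: low
    cDC2, high CD88+ cDC1, low LYM with high NK, low HLA-DR+ NK, low
    HLA-DR on MON-Mphi) across a 44-patient implant cohort (24 infected +
    20 aseptic). Every pairwise centroid distance is >= 6 x noise_sd at
    the default noise level, which is what makes recovery well-posed.
    """
    aseptic_adaptive = {
        "cdc2_pct": "high", "lym_pct": "high", "nk_pct": "low",
        "hladr_nk_pct": "high", "cd88_cdc1_pct": "low", "hladr_mon_mphi": "high",
    }
    aseptic_moderate = {
        "cdc2_pct": "high", "lym_pct": "mid", "nk_pct": "low",
        "hladr_nk_pct": "mid", "cd88_cdc1_pct": "low", "hladr_mon_mphi": "mid",
    }
    infected_innate = {
        "cdc2_pct": "low", "lym_pct": "low", "nk_pct": "high",
        "hladr_nk_pct": "low", "cd88_cdc1_pct": "high", "hladr_mon_mphi": "low",
    }
    infected_lowgrade = {
        "cdc2_pct": "low", "lym_pct": "mid", "nk_pct": "mid",
        "hladr_nk_pct": "low", "cd88_cdc1_pct": "mid", "hladr_mon_mphi": "low",
    }
    return [
        ArchetypeProfile("C1", aseptic_adaptive, size=10, noise_sd=noise_sd,
                         group_label="OL/AL"),
        ArchetypeProfile("C2", infected_innate, size=14, noise_sd=noise_sd,
                         group_label="PJI"),
        ArchetypeProfile("C3", aseptic_moderate, size=10, noise_sd=noise_sd,
                         group_label="OL/AL"),
        ArchetypeProfile("C4", infected_lowgrade, size=10, noise_sd=noise_sd,
                         group_label="LG-PJI"),
    ]


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------


def calibrate_sd(ci_half: float, n: int) -> float:
    """Convert a 95% CI half-width of the mean into a sampling sd.

    The CI half-width of a mean over ``n`` observations is
    ``1.96 * sd / sqrt(n)``, so ``sd = ci_half * sqrt(n) / 1.96``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if ci_half < 0:
        raise ValueError("ci_half must be >= 0")
    return ci_half * np.sqrt(n) / _Z95


def _truncnorm_mean(mu: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mu) / sd, (hi - mu) / sd
    return float(stats.truncnorm.mean(a, b, loc=mu, scale=sd))


def _solve_location(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter mu such that the [lo, hi]-truncated N(mu, sd)
    has mean ``target_mean``; found by bisection (the truncated mean is
    strictly increasing in mu)."""
    span = max(hi - lo, sd)
    mu_lo, mu_hi = lo - 10 * span, hi + 10 * span
    # widen the bracket if the target is still outside (cannot happen for
    # interior targets with this span, but cheap to guard)
    for _ in range(60):
        if _truncnorm_mean(mu_lo, sd, lo, hi) <= target_mean:
            break
        mu_lo -= span
    for _ in range(60):
        if _truncnorm_mean(mu_hi, sd, lo, hi) >= target_mean:
            break
        mu_hi += span
    return float(
        optimize.brentq(
            lambda mu: _truncnorm_mean(mu, sd, lo, hi) - target_mean,
            mu_lo,
            mu_hi,
            xtol=1e-12,
        )
    )


def sample_marker(
    cal: MarkerCalibration,
    size: int,
    rng: np.random.Generator,
    n_obs: int,
) -> np.ndarray:
    """Draw ``size`` marker values from the truncation-corrected sampler.

    The sampler is a normal distribution truncated to the published
    [min, max] range, with scale ``calibrate_sd(cal.ci_half, n_obs)`` and
    location adjusted so the truncated-distribution mean equals the
    published mean exactly. ``n_obs`` is the number of patients behind the
    published summary (the group size), which sets the CI-to-sd conversion.
    """
    if size < 0:
        raise ValueError("size must be >= 0")
    if size == 0:
        return np.empty(0)
    if cal.min_val == cal.max_val:
        return np.full(size, cal.min_val)
    sd = calibrate_sd(cal.ci_half, n_obs)
    if sd == 0.0:
        return np.full(size, cal.mean)
    mu = _solve_location(cal.mean, sd, cal.min_val, cal.max_val)
    a = (cal.min_val - mu) / sd
    b = (cal.max_val - mu) / sd
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size, random_state=rng)


def _substream(seed: int, *tokens: str) -> np.random.Generator:
    """Deterministic per-(group, marker) random substream.

    Derived from the master seed and stable CRC32 hashes of the tokens, so
    adding or removing one marker never perturbs another marker's draws.
    """
    keys = [zlib.crc32(t.encode("utf8")) for t in tokens]
    return np.random.default_rng(np.random.SeedSequence([seed, *keys]))


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Generate a calibrated patient cohort table.

    Each group x marker is drawn from its own substream of the master seed
    via :func:`sample_marker`. Rows whose composition markers (LYM,
    MON-Mphi, NEU percentages) sum above 100 are rescaled proportionally to
    sum to 100 and flagged in the ``composition_rescaled`` column.
    """
    if config.mode == "archetype":
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xA2C]))
        return generate_archetype_cohort(config.archetypes, rng)

    frames = []
    offset = 0
    for group in config.groups:
        cols: dict[str, np.ndarray] = {}
        for cal in group.markers:
            rng = _substream(config.seed, group.group_label, cal.marker_name)
            cols[cal.marker_name] = sample_marker(cal, group.n, rng, group.n)
        df = pd.DataFrame(cols)
        df.insert(0, "group", group.group_label)
        df.insert(
            0,
            "patient_id",
            [f"P{offset + i + 1:03d}" for i in range(group.n)],
        )
        offset += group.n
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)

    comp = [m for m in COMPOSITION_MARKERS if m in table.columns]
    if comp:
        total = table[comp].sum(axis=1)
        over = total > 100.0
        table.loc[over, comp] = table.loc[over, comp].mul(
            100.0 / total[over], axis=0
        )
        table["composition_rescaled"] = over
    units = {m: MARKER_UNITS.get(m, "") for m in table.columns
             if m not in ("patient_id", "group", "composition_rescaled")}
    return CohortTable(table, units=units)


def generate_archetype_cohort(
    profiles: list[ArchetypeProfile], rng: np.random.Generator
) -> CohortTable:
    """Generate a planted-cluster cohort on the rescaled [0,1] scale.

    Every record carries its generating ``archetype`` label as ground
    truth; marker values are the level-mapped centroid plus isotropic
    Gaussian noise, clipped to [0,1].
    """
    if not profiles:
        raise ValueError("need at least one archetype profile")
    markers = sorted({m for p in profiles for m in p.level_per_marker})
    frames = []
    offset = 0
    for prof in profiles:
        centroid = prof.centroid(markers)
        noise = rng.normal(0.0, prof.noise_sd, size=(prof.size, len(markers)))
        values = np.clip(centroid + noise, 0.0, 1.0)
        df = pd.DataFrame(values, columns=markers)
        df.insert(0, "archetype", prof.archetype_id)
        df.insert(0, "group", prof.group_label or prof.archetype_id)
        df.insert(
            0,
            "patient_id",
            [f"A{offset + i + 1:03d}" for i in range(prof.size)],
        )
        offset += prof.size
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    units = {m: "rescaled [0,1]" for m in markers}
    return CohortTable(table, units=units)


def load_generator_config(path, seed: int = 0) -> GeneratorConfig:
    """Load a generator config from YAML (schema of the packaged default).

    Each group entry carries ``group_label``, ``n`` and a ``markers`` map
    of ``name: [mean, ci_half, min, max]``. Archetype-mode files list
    ``archetypes`` with ``archetype_id``, ``level_per_marker``, ``size``
    and optional ``noise_sd``/``group_label``.
    """
    import yaml
    from pathlib import Path

    raw = yaml.safe_load(Path(path).read_text())
    groups = [
        GroupCalibration(
            g["group_label"],
            g["n"],
            tuple(
                MarkerCalibration(name, *vals)
                for name, vals in g.get("markers", {}).items()
            ),
        )
        for g in raw.get("groups", [])
    ]
    archetypes = [
        ArchetypeProfile(
            a["archetype_id"],
            a["level_per_marker"],
            a["size"],
            a.get("noise_sd", 0.08),
            a.get("group_label", ""),
        )
        for a in raw.get("archetypes", [])
    ]
    return GeneratorConfig(
        groups=groups,
        seed=raw.get("seed", seed),
        mode=raw.get("mode", "calibrated"),
        archetypes=archetypes,
    )


def packaged_default_config_path():
    """Path of the packaged default calibration YAML."""
    from importlib.resources import files

    return files("synovnet").joinpath("data/default_calibration.yaml")


def defensin_classify(values: np.ndarray, threshold: float = ELISA_LOD_PG_ML) -> int:
    """Count samples positive for alpha-defensins at a concentration threshold.

    ``values`` and ``threshold`` must share a unit (the shipped presets
    :data:`ELISA_LOD_PG_ML` and :data:`LATERAL_FLOW_LOD_PG_ML` are both in
    pg/ml). A sample is positive when its concentration is >= threshold.
    """
    values = np.asarray(values, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if (values < 0).any():
        raise ValueError("concentrations must be non-negative")
    return int(np.count_nonzero(values >= threshold))
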