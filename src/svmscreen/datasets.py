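"""Synthetic LC-MS feature tables emulating a spiked-maize screening study.

The generator reproduces the statistical structure the downstream analysis
assumes: three spiked concentration groups (20/50/100 ng/mL, nine
replicates each), twelve pooled quality-control injections, two
isotope-labelled internal standards with per-sample extraction recoveries,
concentration-independent matrix background features, "erratic" features
that vary between groups without a library identity, and measurement
jitter on accurate mass (ppm) and retention time (minutes).

Marker intensities follow

    I_ij = base_j * C(group i) * recovery_i * (1 + eps),   eps ~ N(0, cv)

so that with no noise and unit recoveries the group-mean fold changes equal
the theoretical concentration ratios exactly (2.5 for 50/20, 5.0 for
100/20).  Noise is multiplicative on the relative scale and truncated at
-0.9 to keep intensities positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (
    QC_GROUP,
    ROLE_FEATURE,
    ROLE_INTERNAL_STANDARD,
    CompoundLibrary,
    FeatureTable,
    GroundTruth,
    variable_id,
)

__all__ = [
    "SyntheticConfig",
    "CurveData",
    "INTERNAL_STANDARDS",
    "generate_compound_library",
    "generate_spiked_dataset",
    "generate_is_curve",
    "make_two_class_data",
    "spike_concentration",
]

#: the two deuterated recovery internal standards: (name, [M+H]+ mass, RT min)
INTERNAL_STANDARDS = (
    ("enrofloxacin-d5", 365.21092, 7.01),
    ("atrazine-d5", 221.14017, 5.77),
)

#: in-vial internal-standard concentration: 0.5 mL of a 100 ng/mL mix
#: carried into a 1 mL final extract
IS_NOMINAL_NG_ML = 50.0

#: calibration-curve levels for the internal standards, ng/mL
IS_CURVE_LEVELS = (5.0, 10.0, 25.0, 50.0, 100.0)

_PESTICIDE_CATEGORIES = ("insecticide", "bactericide", "herbicide", "growth regulator")
_VETDRUG_CATEGORIES = (
    "sulfamido",
    "nitroimidazoles",
    "quinolones",
    "tetracyclines",
    "macrolides",
    "vermifuge",
)


def spike_concentration(
    spike_volume_ul: float, stock_ug_per_ml: float, final_volume_ml: float
) -> float:
    """Final concentration (ng/mL) after reconstituting a spike.

    E.g. 20 uL of a 1 ug/mL mix taken to a 1 mL final extract gives
    20 ng/mL.
    """
    if final_volume_ml <= 0:
        raise ValueError("final volume must be positive")
    return spike_volume_ul * stock_ug_per_ml / final_volume_ml


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the synthetic generator."""

    seed: int = 0
    n_markers: int = 124
    n_background: int = 150
    n_erratic: int = 34
    group_levels: tuple[float, ...] = (20.0, 50.0, 100.0)
    replicates_per_group: int = 9
    n_qc: int = 12
    recovery_range_is1: tuple[float, float] = (72.9, 96.4)
    recovery_range_is2: tuple[float, float] = (73.6, 96.4)
    intensity_cv: float = 0.10
    ppm_jitter: float = 5.0
    rt_jitter: float = 0.25
    is_response_slopes: tuple[float, float] = (120.0, 80.0)

    def __post_init__(self) -> None:
        for name in ("n_markers", "n_background", "n_erratic", "replicates_per_group", "n_qc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        levels = self.group_levels
        if any(c <= 0 for c in levels) or any(
            b <= a for a, b in zip(levels, levels[1:])
        ):
            raise ValueError("group levels must be strictly increasing and positive")
        for rng in (self.recovery_range_is1, self.recovery_range_is2):
            if not (0 < rng[0] <= rng[1] <= 100):
                raise ValueError("recovery bounds must lie in (0, 100] and be ordered")
        if self.intensity_cv < 0:
            raise ValueError("intensity_cv must be non-negative")

    def blank(self) -> "SyntheticConfig":
        """Configuration of a matrix blank: background features only."""
        return replace(self, n_markers=0, n_erratic=0)


@dataclass
class CurveData:
    """Calibration-curve raw data: (concentration level, peak area) pairs."""

    levels: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.levels.shape != self.areas.shape:
            raise ValueError("levels and areas must have equal length")


def generate_compound_library(
    n_pesticides: int, n_vetdrugs: int, seed: int = 0
) -> CompoundLibrary:
    """Draw a synthetic reference library of pesticides and veterinary drugs.

    Exact [M+H]+ masses are uniform on [100, 1000] Da (respaced so no two
    compounds sit within 20 ppm of each other, which keeps accurate-mass
    annotation unambiguous); retention times are uniform on [2, 12] min.
    Deterministic for a fixed seed.
    """
    if n_pesticides < 0 or n_vetdrugs < 0:
        raise ValueError("compound counts must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_pesticides + n_vetdrugs
    masses: list[float] = []
    while len(masses) < n:
        m = float(rng.uniform(100.0, 1000.0))
        if all(abs(m - m0) / m0 > 20e-6 for m0 in masses):
            masses.append(m)
    rows = []
    for i in range(n):
        if i < n_pesticides:
            name = f"pesticide-{i + 1:03d}"
            cat = _PESTICIDE_CATEGORIES[rng.integers(len(_PESTICIDE_CATEGORIES))]
        else:
            name = f"vetdrug-{i - n_pesticides + 1:03d}"
            cat = _VETDRUG_CATEGORIES[rng.integers(len(_VETDRUG_CATEGORIES))]
        rows.append(
            {
                "no": i + 1,
                "name": name,
                "category": cat,
                "exact_mass": masses[i],
                "rt_min": float(rng.uniform(2.0, 12.0)),
            }
        )
    cols = ["no", "name", "category", "exact_mass", "rt_min"]
    return CompoundLibrary(pd.DataFrame(rows, columns=cols))


def generate_is_curve(
    nominal_levels=IS_CURVE_LEVELS,
    slope: float = 100.0,
    intercept: float = 0.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> CurveData:
    """Simulate a matrix-matched internal-standard calibration curve."""
    levels = np.asarray(nominal_levels, dtype=float)
    if np.any(levels <= 0):
        raise ValueError("curve levels must be positive")
    if slope <= 0:
        raise ValueError("curve slope must be positive")
    rng = np.random.default_rng(seed)
    areas = slope * levels + intercept
    if noise_cv > 0:
        areas = areas * (1.0 + rng.normal(0.0, noise_cv, size=levels.shape))
    return CurveData(levels, areas)


def _truncated_relative_noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise factors 1 + eps, eps ~ N(0, cv) truncated at -0.9."""
    if cv == 0:
        return np.ones(size)
    eps = np.clip(rng.normal(0.0, cv, size=size), -0.9, None)
    return 1.0 + eps


def generate_spiked_dataset(
    cfg: SyntheticConfig, library: CompoundLibrary
) -> tuple[FeatureTable, GroundTruth]:
    """Generate a spiked feature table and its ground truth.

    Markers are the first ``cfg.n_markers`` library compounds; their
    intensities scale with the group concentration and the per-sample
    internal-standard recovery.  Background features have group-independent
    means.  Erratic features alternate between a high-variance
    concentration-proportional profile and a non-monotone profile, and
    their masses match no library compound.  QC columns are the pooled
    mean of all spiked samples plus small noise.  Two internal-standard
    rows with known per-sample recoveries are appended.
    """
    if cfg.n_markers > len(library):
        raise ValueError(
            f"n_markers={cfg.n_markers} exceeds library size {len(library)}"
        )
    rng = np.random.default_rng(cfg.seed)

    groups = [f"{lvl:g}" for lvl in cfg.group_levels]
    sample_ids = [
        f"{g} ng/mL-{r + 1}" for g in groups for r in range(cfg.replicates_per_group)
    ]
    qc_ids = [f"QC-{i + 1}" for i in range(cfg.n_qc)]
    n_spiked = len(sample_ids)
    conc = np.repeat(cfg.group_levels, cfg.replicates_per_group).astype(float)

    # per-sample true recoveries for the two internal standards (percent)
    r1 = rng.uniform(*cfg.recovery_range_is1, size=n_spiked)
    r2 = rng.uniform(*cfg.recovery_range_is2, size=n_spiked)
    r_comb = 2.0 / (1.0 / r1 + 1.0 / r2) / 100.0  # harmonic mean, as a fraction

    lib = library.records
    marker_rows = lib.iloc[: cfg.n_markers]

    true_mass: list[float] = []
    true_rt: list[float] = []
    kinds: list[str] = []
    compounds: list[str] = []
    spiked = np.empty((0, n_spiked))

    blocks = []
    # markers
    base_m = 10.0 ** rng.uniform(1.5, 3.0, size=cfg.n_markers)
    noise = _truncated_relative_noise(rng, cfg.intensity_cv, (cfg.n_markers, n_spiked))
    blocks.append(base_m[:, None] * conc[None, :] * r_comb[None, :] * noise)
    true_mass += list(marker_rows["exact_mass"])
    true_rt += list(marker_rows["rt_min"])
    kinds += ["marker"] * cfg.n_markers
    compounds += list(marker_rows["name"])

    def _unmatched_mass() -> float:
        while True:
            m = float(rng.uniform(100.0, 1000.0))
            if all(abs(m - m0) / m0 > 20e-6 for m0 in lib["exact_mass"]):
                return m

    # background: group-independent mean, scaled by recovery like any
    # co-extracted matrix component
    base_b = 10.0 ** rng.uniform(3.0, 5.0, size=cfg.n_background)
    noise = _truncated_relative_noise(rng, cfg.intensity_cv, (cfg.n_background, n_spiked))
    blocks.append(base_b[:, None] * r_comb[None, :] * noise)
    for _ in range(cfg.n_background):
        true_mass.append(_unmatched_mass())
        true_rt.append(float(rng.uniform(2.0, 12.0)))
    kinds += ["background"] * cfg.n_background
    compounds += [""] * cfg.n_background

    # erratic: group-dependent but without a library identity
    err_block = np.empty((cfg.n_erratic, n_spiked))
    erratic_cv = max(cfg.intensity_cv, 0.15)
    for j in range(cfg.n_erratic):
        base = 10.0 ** rng.uniform(2.0, 3.5)
        if j % 2 == 0:
            # concentration-proportional but noisy (eligible yet unmatched)
            profile = conc
        else:
            # non-monotone: peaks in the middle group
            mid = np.array([1.0, 2.5, 1.2])
            profile = np.repeat(mid[: len(cfg.group_levels)], cfg.replicates_per_group)
            profile = np.resize(profile, n_spiked)
        noise_j = _truncated_relative_noise(rng, erratic_cv, n_spiked)
        err_block[j] = base * profile * r_comb * noise_j
        true_mass.append(_unmatched_mass())
        true_rt.append(float(rng.uniform(2.0, 12.0)))
    blocks.append(err_block)
    kinds += ["erratic"] * cfg.n_erratic
    compounds += [""] * cfg.n_erratic

    # internal standards: peak areas follow their calibration response at
    # the nominal in-vial level, attenuated by each sample's true recovery
    is_block = np.empty((2, n_spiked))
    for k, (slope, rk) in enumerate(zip(cfg.is_response_slopes, (r1, r2))):
        is_block[k] = slope * IS_NOMINAL_NG_ML * rk / 100.0
    blocks.append(is_block)
    for name, mass, rt in INTERNAL_STANDARDS:
        true_mass.append(mass)
        true_rt.append(rt)
        kinds.append("internal_standard")
        compounds.append(name)

    spiked = np.vstack(blocks)
    n_vars = spiked.shape[0]

    # measurement jitter on the consensus feature coordinates
    obs_mass = np.asarray(true_mass) * (
        1.0 + rng.uniform(-cfg.ppm_jitter, cfg.ppm_jitter, size=n_vars) * 1e-6
    )
    obs_rt = np.asarray(true_rt) + rng.uniform(-cfg.rt_jitter, cfg.rt_jitter, size=n_vars)

    ids: list[str] = []
    seen: set[str] = set()
    for m, t in zip(obs_mass, obs_rt):
        vid = variable_id(m, t)
        while vid in seen:  # rare collision: nudge the retention time label
            t += 1.0 / 60.0
            vid = variable_id(m, t)
        seen.add(vid)
        ids.append(vid)

    # QC columns: pooled mean of all spiked samples, tight noise
    qc_cv = min(cfg.intensity_cv, 0.05)
    pooled = spiked.mean(axis=1)
    qc = pooled[:, None] * _truncated_relative_noise(rng, qc_cv, (n_vars, cfg.n_qc))

    intensities = pd.DataFrame(
        np.hstack([spiked, qc]), index=pd.Index(ids, name="variable_id"),
        columns=sample_ids + qc_ids,
    )
    variables = pd.DataFrame(
        {
            "mz": obs_mass,
            "rt_min": obs_rt,
            "role": [
                ROLE_INTERNAL_STANDARD if k == "internal_standard" else ROLE_FEATURE
                for k in kinds
            ],
        },
        index=intensities.index,
    )
    samples = pd.DataFrame(
        {
            "group": [g for g in groups for _ in range(cfg.replicates_per_group)]
            + [QC_GROUP] * cfg.n_qc,
            "sample_type": ["spiked"] * n_spiked + ["qc"] * cfg.n_qc,
        },
        index=pd.Index(sample_ids + qc_ids, name="sample_id"),
    )
    table = FeatureTable(intensities, variables, samples)

    truth = GroundTruth(
        marker_compounds={
            ids[i]: compounds[i] for i in range(n_vars) if kinds[i] == "marker"
        },
        background_ids={ids[i] for i in range(n_vars) if kinds[i] == "background"},
        erratic_ids={ids[i] for i in range(n_vars) if kinds[i] == "erratic"},
        recoveries=pd.DataFrame(
            {"r_is1": r1, "r_is2": r2}, index=pd.Index(sample_ids, name="sample_id")
        ),
    )
    return table, truth


def make_two_class_data(
    n_per_class: int = 18,
    n_variables: int = 200,
    n_informative: int = 20,
    effect_sd: float = 3.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-class Gaussian data with a subset of discriminating variables.

    The informative variables separate the classes by ``effect_sd``
    standard deviations; the rest are pure noise.  Used for model
    diagnostics (permutation tests, cross-validation behaviour).
    """
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(2 * n_per_class, n_variables))
    y = np.array([-1] * n_per_class + [1] * n_per_class)
    x[:, :n_informative] += 0.5 * effect_sd * y[:, None]
    return x, y
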