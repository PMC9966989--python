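"""Synthetic survey-cohort generator.

The real survey data are embargoed, so every downstream stage is exercised on
cohorts drawn from a generative model with the structure the analysis assumes:
five correlated latent psychosomatic traits drive ordinal 4-point item
responses through a graded-response mechanism, and nutrient intakes are
log-normal with configurable mean shifts between the better- and worse-status
latent strata.  The graded thresholds are chosen so that collapsing response
categories {3,4} (or {1,2} for the reversed vigor items) yields exactly a
two-parameter logistic item with difficulty equal to the middle threshold,
which is what the downstream IRT stage fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .bjsq import ITEM_CODES, REVERSED_ITEMS, SUBSCALES
from .nutrient_screen import NUTRIENT_COLUMNS

N_ITEMS = 29
N_FACTORS = 5

#: Latent trait order; index 0 mirrors the merged anxiety+depression factor.
FACTOR_NAMES: list[str] = ["anx_dep", "vigor", "irritability", "fatigue", "somatic"]

#: Indices of the four MHC-relevant traits (vigor, irritability, fatigue,
#: somatic), all oriented so that a higher value means worse status.
MHC_FACTOR_INDICES: list[int] = [1, 2, 3, 4]


class ConfigurationError(ValueError):
    """Raised for an invalid generator or pipeline configuration."""


def _default_item_assignment() -> list[tuple[str, int, float, float]]:
    """(item, factor index, discrimination a, middle threshold b) per item.

    Calibrated qualitatively: the vigor factor has the lowest (earliest)
    difficulties, then fatigue, then irritability, then anxiety+depression;
    the somatic factor has low discrimination and dispersed difficulties so
    its averaged response curve is flat.  Q27 and Q29 load on the merged
    anxiety+depression factor, leaving nine somatic items.
    """
    spec: list[tuple[str, int, float, float]] = []
    for q, b in zip(SUBSCALES["lack_of_vigor"], (-1.1, -0.9, -0.7)):
        spec.append((q, 1, 2.2, b))
    for q, b in zip(SUBSCALES["irritability"], (0.0, 0.1, 0.2)):
        spec.append((q, 2, 2.0, b))
    for q, b in zip(SUBSCALES["fatigue"], (-0.35, -0.25, -0.15)):
        spec.append((q, 3, 2.0, b))
    anx_dep = SUBSCALES["anxiety"] + SUBSCALES["depressed_mood"]
    for q, b in zip(anx_dep, np.linspace(0.8, 1.3, len(anx_dep))):
        spec.append((q, 0, 1.8, float(b)))
    somatic9 = [q for q in SUBSCALES["somatic"] if q not in ("Q27", "Q29")]
    for q, b in zip(somatic9, np.linspace(-1.3, 1.3, len(somatic9))):
        spec.append((q, 4, 1.3, float(b)))
    spec.append(("Q27", 0, 1.2, 0.9))
    spec.append(("Q29", 0, 1.2, 1.0))
    spec.sort(key=lambda t: ITEM_CODES.index(t[0]))
    return spec


def default_item_loadings() -> np.ndarray:
    """29x5 matrix whose nonzero entry per row is the item's discrimination."""
    loadings = np.zeros((N_ITEMS, N_FACTORS))
    for q, f, a, _ in _default_item_assignment():
        loadings[ITEM_CODES.index(q), f] = a
    return loadings


def default_graded_thresholds(spread: float = 0.9) -> np.ndarray:
    """29x3 ordered cut points; the middle one is the item's 2PL difficulty."""
    thr = np.zeros((N_ITEMS, 3))
    for q, _, _, b in _default_item_assignment():
        i = ITEM_CODES.index(q)
        thr[i] = (b - spread, b, b + spread)
    return thr


def default_factor_correlations() -> np.ndarray:
    phi = np.full((N_FACTORS, N_FACTORS), 0.4)
    np.fill_diagonal(phi, 1.0)
    return phi


#: Per-nutrient (location, scale) of the positive intake distribution, in the
#: units of the column name.  Locations are set near plausible daily intakes.
DEFAULT_NUTRIENT_BASE: dict[str, tuple[float, float]] = {
    "Na_mg": (3600.0, 900.0), "K_mg": (2450.0, 620.0), "Ca_mg": (480.0, 160.0),
    "Mg_mg": (270.0, 70.0), "P_mg": (1085.0, 260.0), "Fe_mg": (8.2, 2.1),
    "Zn_mg": (8.45, 2.1), "Cu_mg": (1.16, 0.30), "VA_ugRE": (570.0, 230.0),
    "Retinol_ug": (300.0, 140.0), "bCx_ug": (225.0, 140.0), "bCt_ug": (3100.0, 1400.0),
    "VD_ug": (7.0, 3.2), "VE_mg": (6.6, 2.0), "VK_ug": (230.0, 100.0),
    "VB1_mg": (0.97, 0.26), "VB2_mg": (1.22, 0.32), "Niacin_mgNE": (32.4, 8.5),
    "VB6_mg": (1.23, 0.32), "VB12_ug": (5.3, 2.4), "FA_ug": (302.0, 92.0),
    "PA_mg": (6.05, 1.5), "VC_mg": (95.0, 38.0), "SFA_g": (18.2, 5.8),
    "MUFA_g": (21.8, 6.8), "PUFA_g": (12.1, 3.8), "Chol_mg": (330.0, 120.0),
    "TDF_g": (18.4, 5.1), "SDF_g": (4.5, 1.4), "IDF_g": (11.9, 3.4),
    "n3FA_g": (2.2, 0.8), "n6FA_g": (9.6, 3.0), "TG_g": (55.0, 15.0),
    "Mn_mg": (3.2, 1.0), "I_ug": (260.0, 120.0), "Se_ug": (72.0, 26.0),
    "Cr_ug": (8.0, 3.2), "Mo_ug": (220.0, 80.0), "Biotin_ug": (41.3, 12.0),
}

#: Nutrients carrying a planted better-vs-worse mean shift by default (17),
#: matching the abbreviation set of the reference subgroup-means table; the
#: remaining 22 nutrients are null.
DEFAULT_PLANTED_NUTRIENTS: list[str] = [
    "K_mg", "Mg_mg", "P_mg", "Fe_mg", "Zn_mg", "Cu_mg", "VA_ugRE", "bCx_ug",
    "bCt_ug", "VB1_mg", "Niacin_mgNE", "VB6_mg", "FA_ug", "PA_mg", "TDF_g",
    "IDF_g", "Biotin_ug",
]

DEFAULT_PLANTED_SHIFT = 0.6


def default_nutrient_effects(shift: float = DEFAULT_PLANTED_SHIFT) -> dict[str, float]:
    return {
        name: (shift if name in DEFAULT_PLANTED_NUTRIENTS else 0.0)
        for name in NUTRIENT_COLUMNS
    }


@dataclass
class GeneratorConfig:
    """Full parameterization of the synthetic cohort generator."""

    n_subjects: int = 887
    seed: int = 0
    factor_correlations: np.ndarray = field(default_factory=default_factor_correlations)
    item_loadings: np.ndarray = field(default_factory=default_item_loadings)
    graded_thresholds: np.ndarray = field(default_factory=default_graded_thresholds)
    nutrient_effects: dict[str, float] = field(default_factory=default_nutrient_effects)
    nutrient_base: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_NUTRIENT_BASE)
    )
    nutrient_common: float = 0.6
    n_non_worker: int = 75
    n_high_stress: int = 18

    def __post_init__(self) -> None:
        self.factor_correlations = np.asarray(self.factor_correlations, dtype=float)
        self.item_loadings = np.asarray(self.item_loadings, dtype=float)
        self.graded_thresholds = np.asarray(self.graded_thresholds, dtype=float)
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be >= 0")
        if self.n_non_worker < 0 or self.n_high_stress < 0:
            raise ConfigurationError("exclusion counts must be >= 0")
        if self.n_non_worker + self.n_high_stress > self.n_subjects:
            raise ConfigurationError("exclusion counts exceed n_subjects")
        phi = self.factor_correlations
        if phi.shape != (N_FACTORS, N_FACTORS) or not np.allclose(phi, phi.T):
            raise ConfigurationError("factor_correlations must be a symmetric 5x5 matrix")
        if not np.allclose(np.diag(phi), 1.0):
            raise ConfigurationError("factor_correlations must have unit diagonal")
        if np.linalg.eigvalsh(phi).min() < -1e-10:
            raise ConfigurationError("factor_correlations is not positive semi-definite")
        if self.item_loadings.shape != (N_ITEMS, N_FACTORS):
            raise ConfigurationError("item_loadings must be 29x5")
        if self.graded_thresholds.shape != (N_ITEMS, 3):
            raise ConfigurationError("graded_thresholds must be 29x3")
        if not (np.diff(self.graded_thresholds, axis=1) > 0).all():
            raise ConfigurationError("graded_thresholds must be strictly increasing per item")
        if set(self.nutrient_effects) != set(NUTRIENT_COLUMNS):
            raise ConfigurationError(
                "nutrient_effects must cover exactly the 39 canonical nutrients"
            )
        for name, (loc, scale) in self.nutrient_base.items():
            if loc <= 0 or scale <= 0:
                raise ConfigurationError(
                    f"nutrient_base for '{name}' must have positive location and scale"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown generator config keys: {sorted(unknown)}")
        if "planted_shift" in raw:  # convenience key resolved by from_yaml only
            raw["nutrient_effects"] = default_nutrient_effects(raw.pop("planted_shift"))
        return cls(**raw)


@dataclass
class CohortTable:
    """Subject, response, and intake tables joined by subject_id."""

    subjects: pd.DataFrame
    responses: pd.DataFrame
    intakes: pd.DataFrame

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (("subjects", self.subjects), ("bjsq", self.responses),
                         ("nutrients", self.intakes)):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        return paths


def generate_theta(
    n: int, factor_correlations: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """n x 5 latent traits ~ N(0, Phi); higher always means worse status."""
    phi = np.asarray(factor_correlations, dtype=float)
    eigval, eigvec = np.linalg.eigh(phi)
    if eigval.min() < -1e-10:
        raise ConfigurationError("factor correlation matrix is not positive semi-definite")
    root = eigvec @ np.diag(np.sqrt(np.clip(eigval, 0, None))) @ eigvec.T
    return rng.standard_normal((n, N_FACTORS)) @ root


def generate_responses(
    theta: np.ndarray,
    loadings: np.ndarray,
    thresholds: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Ordinal 1-4 responses from a graded-response mechanism.

    For item j with discrimination a_j on its dominant factor and cut points
    (b1 < b2 < b3), the internal worse-direction category Y satisfies
    P(Y > c) = logistic(a_j (theta - b_c)); reversed items report 5 - Y, so a
    higher raw response on Q01-Q03 means better status.  Dichotomizing at the
    middle cut point therefore yields a 2PL item with difficulty b2.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    loadings = np.asarray(loadings, dtype=float)
    thresholds = np.asarray(thresholds, dtype=float)
    n = theta.shape[0]
    if theta.shape[1] != loadings.shape[1]:
        raise ConfigurationError("theta and loadings disagree on factor count")
    if loadings.shape[0] != thresholds.shape[0]:
        raise ConfigurationError("loadings and thresholds disagree on item count")
    if not (np.diff(thresholds, axis=1) > 0).all():
        raise ConfigurationError("thresholds must be strictly increasing per item")
    n_items = loadings.shape[0]
    out = np.empty((n, n_items), dtype=int)
    u = rng.uniform(size=(n, n_items))
    for j in range(n_items):
        f = int(np.argmax(np.abs(loadings[j])))
        a = loadings[j, f]
        z = a * (theta[:, f][:, None] - thresholds[j][None, :])  # n x 3
        p_gt = 1.0 / (1.0 + np.exp(-z))
        cat = 1 + (u[:, j][:, None] < p_gt).sum(axis=1)
        code = ITEM_CODES[j] if n_items == N_ITEMS else None
        if code in REVERSED_ITEMS:
            cat = 5 - cat
        out[:, j] = cat
    cols = ITEM_CODES if n_items == N_ITEMS else [f"Q{j+1:02d}" for j in range(n_items)]
    return pd.DataFrame(out, columns=cols)


def generate_nutrients(
    mhc_latent: np.ndarray,
    effects: dict[str, float],
    base: dict[str, tuple[float, float]],
    rng: np.random.Generator,
    common: float = 0.6,
) -> pd.DataFrame:
    """Strictly positive intakes, log-normal with stratum-conditional shift.

    The cohort is split at the median of the composite worse-direction latent
    score; a nutrient with effect d receives +d/2 (better stratum) and -d/2
    (worse stratum) shifts of its log-intake in units of the log-scale sd, so
    the better-status mean exceeds the worse-status mean by about d * scale.
    A shared diet-quality factor with loading ``common`` correlates intakes
    across nutrients (total unit variance on the log scale), so per-subject
    above-cut-off counts spread over the whole 0..17 range as real diets do.
    """
    if not 0 <= common < 1:
        raise ConfigurationError("common loading must be in [0, 1)")
    mhc_latent = np.atleast_2d(np.asarray(mhc_latent, dtype=float))
    n = mhc_latent.shape[0]
    composite = mhc_latent.mean(axis=1)
    better = composite <= np.median(composite) if n else np.zeros(0, bool)
    sign = np.where(better, 0.5, -0.5)  # better status -> higher intake for d > 0
    g = rng.standard_normal(n)
    resid = np.sqrt(1.0 - common * common)
    data = {}
    for name in effects:
        loc, scale = base[name]
        if loc <= 0 or scale <= 0:
            raise ConfigurationError(f"non-positive base for '{name}'")
        cv = scale / loc
        s_log = np.sqrt(np.log1p(cv * cv))
        mu = np.log(loc) - 0.5 * s_log * s_log
        eps = common * g + resid * rng.standard_normal(n)
        d = effects[name]
        data[name] = np.exp(mu + s_log * (eps + d * sign))
    return pd.DataFrame(data)


def _generate_subjects(n: int, rng: np.random.Generator) -> pd.DataFrame:
    sex = rng.choice(["M", "F"], size=n, p=[0.3, 0.7])
    age_groups = ["20 to 29", "30 to 39", "40 to 49", "50 to 59", "60 to 69",
                  "70 and more"]
    age_p = np.array([0.053, 0.149, 0.292, 0.330, 0.146, 0.030])
    age = rng.choice(age_groups, size=n, p=age_p / age_p.sum())
    year = rng.choice([2019, 2020], size=n, p=[0.655, 0.345])
    season = rng.choice(["summer", "winter"], size=n)
    return pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(1, n + 1)],
        "sex": sex,
        "age_group": age,
        "fiscal_year": year,
        "season": season,
        "occupation_flag": np.ones(n, dtype=int),
        "high_stress_flag": np.zeros(n, dtype=int),
    })


def generate_cohort(config: GeneratorConfig) -> CohortTable:
    """Draw a full synthetic cohort; the same config yields identical tables."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    subjects = _generate_subjects(n, rng)
    theta = generate_theta(n, config.factor_correlations, rng)
    responses = generate_responses(
        theta, config.item_loadings, config.graded_thresholds, rng
    )
    responses.insert(0, "subject_id", subjects["subject_id"].to_numpy())
    intakes = generate_nutrients(
        theta[:, MHC_FACTOR_INDICES], config.nutrient_effects,
        config.nutrient_base, rng, common=config.nutrient_common,
    )
    intakes.insert(0, "subject_id", subjects["subject_id"].to_numpy())
    # exclusion flags planted on disjoint random subsets
    perm = rng.permutation(n)
    subjects.loc[perm[: config.n_non_worker], "occupation_flag"] = 0
    hs = perm[config.n_non_worker: config.n_non_worker + config.n_high_stress]
    subjects.loc[hs, "high_stress_flag"] = 1
    return CohortTable(subjects=subjects, responses=responses, intakes=intakes)
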