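"""Nutrient-intake screening against minor-health-complaint (MHC) median splits.

Implements the end-to-end screen: Mann-Whitney comparison of each nutrient
between the low/high subgroup of each of the four MHC items, selection of
nutrients significant in at least three of the four items, derivation of a
separating cut-off from the subgroup means, per-subject counting of selected
nutrients consumed at or above their cut-offs, and comparison of MHC levels
across the resulting N-count groups.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .bjsq import ValidationError

#: Canonical intake-table schema: 39 nutrient columns, named abbreviation_unit.
NUTRIENT_COLUMNS: list[str] = [
    "Na_mg", "K_mg", "Ca_mg", "Mg_mg", "P_mg", "Fe_mg", "Zn_mg", "Cu_mg",
    "VA_ugRE", "Retinol_ug", "bCx_ug", "bCt_ug", "VD_ug", "VE_mg", "VK_ug",
    "VB1_mg", "VB2_mg", "Niacin_mgNE", "VB6_mg", "VB12_ug", "FA_ug", "PA_mg",
    "VC_mg", "SFA_g", "MUFA_g", "PUFA_g", "Chol_mg", "TDF_g", "SDF_g",
    "IDF_g", "n3FA_g", "n6FA_g", "TG_g", "Mn_mg", "I_ug", "Se_ug", "Cr_ug",
    "Mo_ug", "Biotin_ug",
]

#: Caloric intake, if present, is tested and reported but never selectable.
ENERGY_COLUMN = "Energy_kcal"

MHC_ITEMS: list[str] = ["lack_of_vigor", "irritability", "fatigue", "somatic"]

#: Which split label identifies the *better-status* subgroup per MHC item.
#: Vigor is scored so that a high score is good; for the other three a low
#: score is good.  Orientation is fixed by this map, never inferred from data.
BETTER_LABEL: dict[str, str] = {
    "lack_of_vigor": "high",
    "irritability": "low",
    "fatigue": "low",
    "somatic": "low",
}


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses exact enumeration when both samples have n <= 8 and there are no
    ties across the pooled sample; otherwise the normal approximation with
    tie and continuity corrections.  Returns (U for the first sample, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("mann_whitney requires two nonempty samples")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if a.size <= 8 and b.size <= 8 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


@dataclass
class ScreenResult:
    """Long-format screen table plus the selected nutrient set."""

    cells: pd.DataFrame  # nutrient, mhc_item, low_mean, high_mean, U, p, significant
    selected: list[str]
    alpha: float
    n_tests: int

    def pivot_p(self) -> pd.DataFrame:
        return self.cells.pivot(index="nutrient", columns="mhc_item", values="p")


def screen(
    intakes: pd.DataFrame,
    splits: pd.DataFrame,
    alpha: float = 0.05,
    min_items: int = 3,
    nutrient_columns: list[str] | None = None,
    fdr: bool = False,
) -> ScreenResult:
    """Mann-Whitney screen of every nutrient across the four MHC splits.

    A nutrient is selected when its two-sided p-value is below ``alpha`` for
    at least ``min_items`` of the four MHC items.  No multiple-testing
    correction is applied by default (the raw-alpha rule is intentional; the
    number of tests is reported as a caveat).  ``fdr=True`` switches to
    Benjamini-Hochberg adjusted p-values.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    cols = list(nutrient_columns) if nutrient_columns is not None else list(NUTRIENT_COLUMNS)
    missing = [c for c in cols if c not in intakes.columns]
    if missing:
        raise ValidationError(f"intake table lacks nutrient columns: {missing}")
    extra_energy = ENERGY_COLUMN in intakes.columns and ENERGY_COLUMN not in cols
    test_cols = cols + ([ENERGY_COLUMN] if extra_energy else [])

    merged = intakes.merge(splits, on="subject_id", how="inner")
    rows = []
    for item in MHC_ITEMS:
        label = merged[f"{item}_split"]
        low = merged[label == "low"]
        high = merged[label == "high"]
        for nut in test_cols:
            u, p = mann_whitney(low[nut], high[nut])
            rows.append({
                "nutrient": nut,
                "mhc_item": item,
                "low_mean": float(low[nut].mean()),
                "high_mean": float(high[nut].mean()),
                "U": u,
                "p": p,
            })
    cells = pd.DataFrame(rows)
    n_tests = len(cells)
    if fdr:
        from statsmodels.stats.multitest import multipletests
        cells["p_adj"] = multipletests(cells["p"], method="fdr_bh")[1]
        cells["significant"] = cells["p_adj"] < alpha
    else:
        cells["significant"] = cells["p"] < alpha
    hits = (
        cells[cells["nutrient"].isin(cols)]
        .groupby("nutrient")["significant"].sum()
    )
    selected = sorted(hits[hits >= min_items].index, key=cols.index)
    return ScreenResult(cells=cells, selected=selected, alpha=alpha, n_tests=n_tests)


@dataclass
class CutoffEntry:
    nutrient: str
    worse_means: dict[str, float]
    better_means: dict[str, float]
    lo: float  # max over items of the worse-status subgroup mean
    hi: float  # min over items of the better-status subgroup mean
    cutoff: float | None
    source: str = "derived"  # derived | override | undefined
    violations: list[tuple[str, str]] = field(default_factory=list)

    @property
    def feasible(self) -> bool:
        return self.lo < self.hi


def feasible_interval(
    cells: pd.DataFrame,
    nutrient: str,
    better_label: dict[str, str] | None = None,
) -> tuple[float, float, dict[str, float], dict[str, float]]:
    """Interval of cut-offs separating worse-status from better-status means.

    ``lo`` is the maximum worse-status subgroup mean over the four MHC items
    and ``hi`` the minimum better-status subgroup mean; a separating cut-off
    exists iff lo < hi.  An empty interval (lo >= hi) is a reportable state,
    not an error.
    """
    labels = better_label if better_label is not None else BETTER_LABEL
    sub = cells[cells["nutrient"] == nutrient]
    if set(sub["mhc_item"]) != set(MHC_ITEMS):
        raise ValidationError(
            f"nutrient '{nutrient}' does not have cells for all four MHC items"
        )
    worse, better = {}, {}
    for _, row in sub.iterrows():
        item = row["mhc_item"]
        if labels[item] == "high":
            better[item], worse[item] = row["high_mean"], row["low_mean"]
        else:
            better[item], worse[item] = row["low_mean"], row["high_mean"]
    lo = max(worse.values())
    hi = min(better.values())
    return lo, hi, worse, better


def round_2sf(x: float) -> float:
    """Round to two significant figures (round-half-even)."""
    if x == 0:
        return 0.0
    return float(round(x, -int(math.floor(math.log10(abs(x)))) + 1))


def midpoint_2sf(lo: float, hi: float) -> float:
    """Default cut-off rule: interval midpoint, two significant figures."""
    return round_2sf((lo + hi) / 2.0)


def derive_cutoff(lo: float, hi: float, rule=midpoint_2sf) -> float:
    """Apply a cut-off rule to a nonempty feasible interval."""
    if not lo < hi:
        raise ValueError(
            f"empty feasible interval ({lo}, {hi}); supply a manual override"
        )
    return float(rule(lo, hi))


def validate_cutoff(
    cutoff: float,
    worse_means: dict[str, float],
    better_means: dict[str, float],
) -> list[tuple[str, str]]:
    """Every (item, bound) where the cut-off fails to separate the means.

    A valid cut-off lies strictly above every worse-status mean and strictly
    below every better-status mean.
    """
    violations = []
    for item, m in worse_means.items():
        if m >= cutoff:
            violations.append((item, "worse_mean_at_or_above_cutoff"))
    for item, m in better_means.items():
        if m <= cutoff:
            violations.append((item, "better_mean_at_or_below_cutoff"))
    return violations


def derive_cutoffs(
    screen_result: ScreenResult,
    overrides: dict[str, float] | None = None,
    rule=midpoint_2sf,
    better_label: dict[str, str] | None = None,
) -> list[CutoffEntry]:
    """Cut-off entries for every selected nutrient (overrides win)."""
    overrides = overrides or {}
    entries = []
    for nut in screen_result.selected:
        lo, hi, worse, better = feasible_interval(
            screen_result.cells, nut, better_label
        )
        if nut in overrides:
            cutoff, source = float(overrides[nut]), "override"
        elif lo < hi:
            cutoff, source = derive_cutoff(lo, hi, rule), "derived"
        else:
            cutoff, source = None, "undefined"
        entry = CutoffEntry(nut, worse, better, lo, hi, cutoff, source)
        if cutoff is not None:
            entry.violations = validate_cutoff(cutoff, worse, better)
        entries.append(entry)
    return entries


#: N-count group bins: label -> (min count, max count), as printed.
COUNT_GROUPS: list[tuple[str, int, int]] = [
    ("0N", 0, 0),
    ("1-4N", 1, 4),
    ("5-8N", 5, 8),
    ("9-12N", 9, 12),
    ("13-17N", 13, 17),
]


def count_group_label(count: int) -> str:
    for label, lo, hi in COUNT_GROUPS:
        if lo <= count <= hi:
            return label
    raise ValueError(f"count {count} outside the defined groups")


def stratify_and_compare(
    intakes: pd.DataFrame,
    cutoffs: list[CutoffEntry],
    mhc_scores: pd.DataFrame,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Count selected nutrients consumed at/above cut-off and compare MHC levels.

    Counting uses >= (the prose rule "at or above the cut-off"), not the
    strict ">" glyph printed in the reference table header.  Returns the
    per-subject group table, the per-group summary with Mann-Whitney p-values
    against the 0N control group, and any warnings.
    """
    usable = [e for e in cutoffs if e.cutoff is not None]
    skipped = [e.nutrient for e in cutoffs if e.cutoff is None]
    warnings = []
    if skipped:
        warnings.append(f"nutrients without cut-off excluded from counting: {skipped}")
    counts = np.zeros(len(intakes), dtype=int)
    for e in usable:
        counts += (intakes[e.nutrient].to_numpy() >= e.cutoff).astype(int)
    groups = pd.DataFrame({
        "subject_id": intakes["subject_id"].to_numpy(),
        "count": counts,
        "group": [count_group_label(c) for c in counts],
    })
    merged = groups.merge(mhc_scores, on="subject_id", how="inner")
    control = merged[merged["group"] == "0N"]
    if control.empty:
        warnings.append("0N control group empty; group comparisons skipped")
    rows = []
    for label, _, _ in COUNT_GROUPS:
        sub = merged[merged["group"] == label]
        for item in MHC_ITEMS:
            row = {
                "group": label,
                "mhc_item": item,
                "n": int(len(sub)),
                "mean": float(sub[item].mean()) if len(sub) else float("nan"),
                "se": float(sub[item].std(ddof=1) / np.sqrt(len(sub)))
                if len(sub) > 1 else float("nan"),
                "p_vs_0N": float("nan"),
            }
            if label != "0N" and len(sub) and not control.empty:
                _, p = mann_whitney(sub[item], control[item])
                row["p_vs_0N"] = p
                row["significant"] = p < alpha
            rows.append(row)
    summary = pd.DataFrame(rows)
    return groups, summary, warnings


def load_reference_subgroup_means() -> pd.DataFrame:
    """Published per-subgroup nutrient means (17 nutrients), as shipped fixture."""
    ref = importlib.resources.files("mhckit.data") / "nutrient_subgroup_reference.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def reference_cells(reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Reshape the shipped reference means into screen-cell long format."""
    ref = reference if reference is not None else load_reference_subgroup_means()
    rows = []
    for _, row in ref.iterrows():
        for item in MHC_ITEMS:
            rows.append({
                "nutrient": row["nutrient"],
                "mhc_item": item,
                "low_mean": row[f"{item}_low"],
                "high_mean": row[f"{item}_high"],
                "U": float("nan"),
                "p": row[f"{item}_p"],
            })
    return pd.DataFrame(rows)
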