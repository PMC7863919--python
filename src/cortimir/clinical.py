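"""Clinical feature derivations and mutated-vs-wild-type group contrasts.

Covers the derived tumor descriptors (ellipsoid volume h*l*w*pi/6,
Knosp-grade invasiveness, macro/microadenoma size class) and the group
comparison machinery: quantitative variables routed to a two-sided
unpaired t-test or Mann-Whitney U-test by a Shapiro-Wilk normality gate,
proportions to a two-sided exact Fisher test. Patients carrying a USP48
mutation are excluded whenever the grouping variable is USP8 status, as
the two driver mutations act on the same pathway.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ClinicalRecord",
    "ContingencyTable",
    "tumor_volume",
    "classify_invasive",
    "classify_size",
    "fisher_exact_two_sided",
    "mann_whitney_two_sided",
    "compare_groups",
    "ClinicalComparison",
    "ClinicalComparisonResults",
    "read_clinical_tsv",
]

QUANTITATIVE_VARS = (
    "age_years",
    "cortisol_morning",
    "acth_morning",
    "ufc_24h",
    "tumor_volume_mm3",
    "ki67_percent",
)
CATEGORICAL_VARS = ("sex", "remission", "granulation", "invasive", "size_class")


@dataclass(frozen=True)
class ClinicalRecord:
    """One patient; hormone units: cortisol ug/dL, ACTH pg/dL, UFC ug/24 h."""

    patient_id: str
    diagnosis: str  # CD (Cushing's disease) or SCA (silent corticotroph adenoma)
    sex: str  # F / M
    age_years: float | None = None
    cortisol_morning: float | None = None
    acth_morning: float | None = None
    ufc_24h: float | None = None
    tumor_height_mm: float | None = None
    tumor_length_mm: float | None = None
    tumor_width_mm: float | None = None
    knosp_grade: int | None = None
    ki67_percent: float | None = None
    remission: str | None = None  # yes / no / None (not defined for SCA)
    granulation: str | None = None  # sparse / dense
    usp8_status: str = "wt"
    usp48_status: str = "wt"

    def __post_init__(self) -> None:
        if self.diagnosis not in {"CD", "SCA"}:
            raise ValueError(f"diagnosis must be CD or SCA, got {self.diagnosis!r}")
        if self.sex not in {"F", "M"}:
            raise ValueError(f"sex must be F or M, got {self.sex!r}")
        for name in ("age_years", "cortisol_morning", "acth_morning", "ufc_24h",
                     "tumor_height_mm", "tumor_length_mm", "tumor_width_mm",
                     "ki67_percent"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.knosp_grade is not None and self.knosp_grade not in range(5):
            raise ValueError(f"knosp_grade must be integral in 0..4, got {self.knosp_grade}")
        for name in ("usp8_status", "usp48_status"):
            if getattr(self, name) not in {"mut", "wt"}:
                raise ValueError(f"{name} must be mut or wt")


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cell counts; rows are groups, columns outcome categories."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in cells):
            raise ValueError("cells must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def tumor_volume(height_mm: float, length_mm: float, width_mm: float) -> float:
    """Ellipsoid tumor volume, height x length x width x pi/6 (mm^3)."""
    if min(height_mm, length_mm, width_mm) <= 0:
        raise ValueError("tumor dimensions must be positive")
    return height_mm * length_mm * width_mm * math.pi / 6.0


def classify_invasive(knosp_grade: int) -> str:
    """Knosp grades 0-2 are non-invasive, 3-4 invasive."""
    if knosp_grade not in range(5):
        raise ValueError(f"Knosp grade must be in 0..4, got {knosp_grade}")
    return "invasive" if knosp_grade >= 3 else "non_invasive"


def classify_size(height_mm: float, length_mm: float, width_mm: float) -> str:
    """Macroadenoma iff at least one diameter strictly exceeds 10 mm."""
    if min(height_mm, length_mm, width_mm) <= 0:
        raise ValueError("tumor dimensions must be positive")
    return "macroadenoma" if max(height_mm, length_mm, width_mm) > 10 else "microadenoma"


def fisher_exact_two_sided(table: ContingencyTable) -> float:
    """Two-sided exact Fisher p: the sum of hypergeometric probabilities of
    all tables with the observed margins whose point probability does not
    exceed the observed one (ties judged with relative tolerance 1e-7)."""
    return float(stats.fisher_exact(table.as_array(), alternative="two-sided")[1])


def mann_whitney_two_sided(x, y) -> float:
    """Two-sided Mann-Whitney U p-value.

    Exact enumeration when both samples have n <= 8 and there are no ties;
    otherwise the normal approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (no_ties and x.size <= 8 and y.size <= 8) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return float(res.pvalue)


@dataclass(frozen=True)
class GroupTestResult:
    """Outcome of one variable's contrast between groups."""

    variable: str
    test: str  # t, mwu, or fisher
    p: float
    group_summaries: dict

    def __repr__(self) -> str:  # compact, table-friendly
        return f"GroupTestResult({self.variable}: {self.test}, p={self.p:.4g})"


def _summary(values: np.ndarray) -> dict:
    return {
        "n": int(values.size),
        "median": float(np.median(values)) if values.size else math.nan,
        "min": float(values.min()) if values.size else math.nan,
        "max": float(values.max()) if values.size else math.nan,
    }


def compare_groups(
    records: pd.DataFrame, variable: str, grouping: str = "usp8_status"
) -> GroupTestResult:
    """Contrast one clinical variable between the two levels of ``grouping``.

    Quantitative variables pass a Shapiro-Wilk gate at alpha = 0.05 in both
    groups to earn a two-sided unpaired t-test; otherwise Mann-Whitney.
    Categorical variables go to the exact Fisher test on the 2x2 table of
    counts. USP48-mutated patients are excluded when grouping by USP8
    status. Variables that are all-missing in either group are an error.
    """
    df = records_frame(records)
    if grouping == "usp8_status" and "usp48_status" in df.columns:
        df = df[df["usp48_status"] != "mut"]
    if variable not in df.columns:
        raise KeyError(f"unknown variable {variable!r}")
    levels = sorted(df[grouping].dropna().unique(), reverse=True)  # mut before wt
    if len(levels) != 2:
        raise ValueError(f"grouping {grouping!r} must have exactly 2 levels, got {levels}")

    sub = df[[grouping, variable]].dropna()
    parts = [sub.loc[sub[grouping] == g, variable] for g in levels]
    if any(p.empty for p in parts):
        raise ValueError(f"variable {variable!r} is all-missing in one group")

    if variable in QUANTITATIVE_VARS or pd.api.types.is_numeric_dtype(sub[variable]):
        xs = [p.to_numpy(dtype=float) for p in parts]
        if any(x.size < 2 for x in xs):
            raise ValueError("need >= 2 records per group for a quantitative contrast")
        if all(np.ptp(x) == 0 for x in xs) and xs[0][0] == xs[1][0]:
            # identical constant samples: no evidence either way
            return GroupTestResult(variable, "mwu", 1.0,
                                   dict(zip(levels, map(_summary, xs))))
        normal = all(
            x.size >= 3 and np.ptp(x) > 0 and stats.shapiro(x).pvalue >= 0.05
            for x in xs
        )
        if normal:
            p = float(stats.ttest_ind(xs[0], xs[1], equal_var=True).pvalue)
            test = "t"
        else:
            p = mann_whitney_two_sided(xs[0], xs[1])
            test = "mwu"
        return GroupTestResult(variable, test, p, dict(zip(levels, map(_summary, xs))))

    cats = sorted(sub[variable].unique())
    if len(cats) != 2:
        raise ValueError(
            f"categorical variable {variable!r} must have exactly 2 levels, got {cats}"
        )
    counts = [
        [int((parts[i] == c).sum()) for c in cats] for i in range(2)
    ]
    table = ContingencyTable(counts[0][0], counts[0][1], counts[1][0], counts[1][1])
    p = fisher_exact_two_sided(table)
    summaries = {
        levels[i]: {cats[j]: counts[i][j] for j in range(2)} for i in range(2)
    }
    return GroupTestResult(variable, "fisher", p, summaries)


def records_frame(records) -> pd.DataFrame:
    """Accept a DataFrame or an iterable of ClinicalRecord; derive the
    volume/invasiveness/size-class columns where dimensions are present."""
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    dims = ("tumor_height_mm", "tumor_length_mm", "tumor_width_mm")
    if all(c in df.columns for c in dims) and "tumor_volume_mm3" not in df.columns:
        def vol(row):
            if any(pd.isna(row[c]) for c in dims):
                return np.nan
            return tumor_volume(*(row[c] for c in dims))
        df["tumor_volume_mm3"] = df.apply(vol, axis=1)
        def size(row):
            if any(pd.isna(row[c]) for c in dims):
                return None
            return classify_size(*(row[c] for c in dims))
        df["size_class"] = df.apply(size, axis=1)
    if "knosp_grade" in df.columns and "invasive" not in df.columns:
        df["invasive"] = [
            classify_invasive(int(g)) if pd.notna(g) else None
            for g in df["knosp_grade"]
        ]
    return df


class ClinicalComparison:
    """Model of mutated-vs-wild-type clinical contrasts over a patient table.

    ``fit()`` runs :func:`compare_groups` for every requested variable,
    separately per diagnosis stratum (CD and SCA) when ``by_diagnosis``,
    and returns a results object with a summary table in the style of a
    per-cohort clinical comparison table.
    """

    def __init__(
        self,
        records,
        grouping: str = "usp8_status",
        variables: tuple[str, ...] | None = None,
        by_diagnosis: bool = True,
    ) -> None:
        self.records = records_frame(records)
        self.grouping = grouping
        self.variables = variables
        self.by_diagnosis = by_diagnosis

    def fit(self) -> "ClinicalComparisonResults":
        df = self.records
        variables = self.variables
        if variables is None:
            variables = [
                v for v in QUANTITATIVE_VARS + CATEGORICAL_VARS if v in df.columns
            ]
        strata = (
            {d: df[df["diagnosis"] == d] for d in ("CD", "SCA") if (df["diagnosis"] == d).any()}
            if self.by_diagnosis and "diagnosis" in df.columns
            else {"all": df}
        )
        rows = []
        results: dict[tuple[str, str], GroupTestResult] = {}
        for stratum, sdf in strata.items():
            for var in variables:
                try:
                    res = compare_groups(sdf, var, self.grouping)
                except (ValueError, KeyError) as exc:
                    warnings.warn(f"{stratum}/{var}: skipped ({exc})", stacklevel=2)
                    continue
                results[(stratum, var)] = res
                rows.append(
                    {"stratum": stratum, "variable": var, "test": res.test, "p": res.p}
                )
        table = pd.DataFrame(rows, columns=["stratum", "variable", "test", "p"])
        return ClinicalComparisonResults(table=table, tests=results, model=self)


@dataclass
class ClinicalComparisonResults:
    table: pd.DataFrame
    tests: dict
    model: ClinicalComparison

    def summary(self) -> str:
        lines = [f"Clinical contrasts by {self.model.grouping}"]
        for _, row in self.table.iterrows():
            lines.append(
                f"  {row['stratum']:>4} {row['variable']:<18} {row['test']:<6} p={row['p']:.4f}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g",
                          lineterminator="\n")


def read_clinical_tsv(path: str | Path) -> pd.DataFrame:
    """One row per patient, columns as :class:`ClinicalRecord` fields."""
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    required = {"patient_id", "diagnosis", "sex", "usp8_status"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    return records_frame(df)
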