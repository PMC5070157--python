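"""Cohort-level validation study: model and results objects.

:class:`GFRValidation` is built from a cohort table (one row per patient,
canonical columns) and :meth:`~GFRValidation.fit` runs the whole study
replica: evaluate all six equations, compute each one's validation panel
overall and within subgroups (GFR, age, sex, obstruction laterality,
disease-duration class), compare every equation pair (paired t on bias,
McNemar on P30 accuracy), and collect Bland–Altman and ROC plot data.
The returned :class:`GFRValidationResults` carries the tables, renders a
``summary()`` and writes a report directory with ``save()``.

Patients missing an analyte are excluded per equation (complete-case per
column) with the n used reported; records missing laterality or duration
are excluded from those stratifications only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import metrics as m
from .equations import EquationId, estimate_table, read_patients

__all__ = ["SubgroupSpec", "GFRValidation", "GFRValidationResults",
           "partition_subgroups", "GFR_BINS", "AGE_BINS", "DEFAULT_SUBGROUPS"]


@dataclass(frozen=True)
class Bin:
    """Half-line or interval with explicit boundary inclusion."""

    label: str
    lower: float
    upper: float
    lower_closed: bool
    upper_closed: bool

    def contains(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lo = x >= self.lower if self.lower_closed else x > self.lower
        hi = x <= self.upper if self.upper_closed else x < self.upper
        return lo & hi


@dataclass(frozen=True)
class SubgroupSpec:
    """A stratification rule: numeric bins or categorical levels.

    Numeric bins must partition the variable's domain (no overlap, no gap);
    the bracket convention follows the study's printed labels — "<60",
    "60 to 90" and ">90" are read as [0, 60), [60, 90], (90, ∞) so the
    three labels tile the line, and ages likewise as [18, 45), [45, 60],
    (60, ∞).
    """

    variable: str
    column: str
    bins: tuple[Bin, ...] = ()
    levels: tuple[tuple[str, object], ...] = ()  # (label, value) pairs

    def partition(self, data: pd.DataFrame) -> dict[str, pd.DataFrame]:
        if self.column not in data.columns:
            raise ValueError(f"stratification column missing: {self.column}")
        col = data[self.column]
        usable = data[col.notna()]
        out: dict[str, pd.DataFrame] = {}
        if self.bins:
            vals = usable[self.column].to_numpy(dtype=float)
            assigned = np.zeros(len(usable), dtype=bool)
            for b in self.bins:
                mask = b.contains(vals)
                if np.any(mask & assigned):
                    raise ValueError(f"overlapping bins in {self.variable}")
                assigned |= mask
                out[b.label] = usable[mask]
            if not assigned.all():
                raise ValueError(f"bins do not cover all {self.variable} values")
        else:
            for label, value in self.levels:
                out[label] = usable[usable[self.column] == value]
        return out


GFR_BINS = SubgroupSpec(
    variable="gfr",
    column="mgfr_std",
    bins=(
        Bin("<60", 0.0, 60.0, True, False),
        Bin("60-90", 60.0, 90.0, True, True),
        Bin(">90", 90.0, np.inf, False, False),
    ),
)

AGE_BINS = SubgroupSpec(
    variable="age",
    column="age",
    bins=(
        Bin("<45", 18.0, 45.0, True, False),
        Bin("45-60", 45.0, 60.0, True, True),
        Bin(">60", 60.0, np.inf, False, False),
    ),
)

SEX_LEVELS = SubgroupSpec(
    variable="sex", column="sex",
    levels=(("male", "male"), ("female", "female")),
)

LATERALITY_LEVELS = SubgroupSpec(
    variable="laterality", column="laterality",
    levels=(("unilateral", "unilateral"), ("bilateral", "bilateral")),
)

DURATION_LEVELS = SubgroupSpec(
    variable="duration", column="duration_ge_3mo",
    levels=((">=3 months", True), ("<3 months", False)),
)

DEFAULT_SUBGROUPS = (GFR_BINS, AGE_BINS, SEX_LEVELS, LATERALITY_LEVELS, DURATION_LEVELS)


def partition_subgroups(data: pd.DataFrame, spec: SubgroupSpec) -> dict[str, pd.DataFrame]:
    """Split a cohort by a stratification rule; see :class:`SubgroupSpec`."""
    return spec.partition(data)


class GFRValidation:
    """Validation study of the six eGFR equations on one cohort.

    Parameters
    ----------
    data : DataFrame with the canonical patient columns. ``mgfr_std``
        (measured GFR indexed to 1.73 m²) must be present, or derivable
        from ``mgfr_raw_mlmin`` with weight and height.
    gfr_threshold : dichotomisation for ROC/sensitivity, ml/min/1.73 m²
        (default 60, the chronic-kidney-disease staging boundary).
    tolerances : relative-accuracy tolerances (default P15/P30/P50).
    subgroups : stratification rules (default: GFR, age, sex, laterality,
        duration).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        gfr_threshold: float = 60.0,
        tolerances: Sequence[float] = (0.15, 0.30, 0.50),
        subgroups: Sequence[SubgroupSpec] = DEFAULT_SUBGROUPS,
    ):
        data = data.copy().reset_index(drop=True)
        if "mgfr_std" not in data.columns or data["mgfr_std"].isna().all():
            if {"mgfr_raw_mlmin", "weight_kg", "height_cm"}.issubset(data.columns):
                from .equations import bsa_dubois, standardize_gfr
                bsa = bsa_dubois(
                    data["weight_kg"].to_numpy(float), data["height_cm"].to_numpy(float)
                )
                data["mgfr_std"] = standardize_gfr(
                    data["mgfr_raw_mlmin"].to_numpy(float), bsa
                )
            else:
                raise ValueError("measured GFR (mgfr_std or mgfr_raw_mlmin) required")
        if len(data) == 0:
            raise ValueError("empty cohort")
        self.data = data
        self.gfr_threshold = float(gfr_threshold)
        self.tolerances = tuple(float(t) for t in tolerances)
        self.subgroups = tuple(subgroups)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "GFRValidation":
        """Build from a delimited-text cohort file."""
        return cls(read_patients(path), **kwargs)

    @classmethod
    def from_records(cls, records, **kwargs) -> "GFRValidation":
        """Build from an iterable of :class:`~gfrbench.equations.PatientRecord`."""
        return cls(pd.DataFrame([r.to_row() for r in records]), **kwargs)

    # -- fitting ---------------------------------------------------------

    def fit(self) -> "GFRValidationResults":
        data = self.data
        estimates = estimate_table(data)
        mgfr = data["mgfr_std"].to_numpy(dtype=float)
        p30_tol = 0.30 if 0.30 in self.tolerances else self.tolerances[len(self.tolerances) // 2]

        overall: dict[str, m.ValidationMetrics] = {}
        complete_masks: dict[str, np.ndarray] = {}
        for eq in EquationId:
            est = estimates[eq.value].to_numpy(dtype=float)
            mask = ~np.isnan(est) & ~np.isnan(mgfr)
            complete_masks[eq.value] = mask
            if mask.sum() < 3:
                continue
            overall[eq.value] = m.validate_equation(
                est[mask], mgfr[mask], equation=eq.value,
                gfr_threshold=self.gfr_threshold, tolerances=self.tolerances,
            )

        # subgroup panel: bias, precision, P30 per (variable, bin, equation)
        sub_rows = []
        subgroup_exclusions = {}
        for spec in self.subgroups:
            if spec.column not in data.columns:
                subgroup_exclusions[spec.variable] = len(data)
                continue
            subgroup_exclusions[spec.variable] = int(data[spec.column].isna().sum())
            for label, sub in spec.partition(data).items():
                idx = sub.index.to_numpy()
                for eq in overall:
                    est = estimates.loc[idx, eq].to_numpy(dtype=float)
                    mg = data.loc[idx, "mgfr_std"].to_numpy(dtype=float)
                    ok = ~np.isnan(est) & ~np.isnan(mg)
                    row = {"variable": spec.variable, "bin": label,
                           "equation": eq, "n": int(ok.sum())}
                    if ok.sum() >= 2:
                        bias, prec = m.bias_precision(est[ok] - mg[ok])
                        row.update(
                            bias=bias, precision=prec,
                            p30=m.accuracy_within(est[ok], mg[ok], p30_tol),
                        )
                    else:
                        row.update(bias=np.nan, precision=np.nan, p30=np.nan)
                    sub_rows.append(row)
        subgroup_metrics = pd.DataFrame(
            sub_rows, columns=["variable", "bin", "equation", "n", "bias", "precision", "p30"]
        )

        # all unordered pairs on their common complete cases
        pair_rows = []
        fitted = list(overall)
        for a, b in combinations(fitted, 2):
            both = complete_masks[a] & complete_masks[b]
            est_a = estimates[a].to_numpy(float)[both]
            est_b = estimates[b].to_numpy(float)[both]
            mg = mgfr[both]
            err_a, err_b = est_a - mg, est_b - mg
            t, p_t = m.paired_bias_test(err_a, err_b)
            mc = m.mcnemar_accuracy_test(
                m.within_tolerance(est_a, mg, p30_tol),
                m.within_tolerance(est_b, mg, p30_tol),
            )
            pair_rows.append(
                m.PairedComparison(
                    equation_a=a, equation_b=b, n=int(both.sum()),
                    bias_t_statistic=t, bias_p_value=p_t,
                    mcnemar_statistic=mc.statistic, mcnemar_p_value=mc.p_value,
                    mcnemar_degenerate=mc.degenerate,
                )
            )
        pairwise = pd.DataFrame(
            [vars(p) for p in pair_rows],
            columns=["equation_a", "equation_b", "n", "bias_t_statistic",
                     "bias_p_value", "mcnemar_statistic", "mcnemar_p_value",
                     "mcnemar_degenerate"],
        )
        # Holm-adjusted columns (an extension: the source analysis reports raw p)
        if len(pairwise):
            pairwise["bias_p_holm"] = multipletests(
                pairwise["bias_p_value"], method="holm")[1]
            pairwise["mcnemar_p_holm"] = multipletests(
                pairwise["mcnemar_p_value"], method="holm")[1]

        # plot data
        bland_altman = {}
        roc_data = {}
        positive_all = mgfr < self.gfr_threshold
        for eq in fitted:
            mask = complete_masks[eq]
            est = estimates[eq].to_numpy(float)[mask]
            mg = mgfr[mask]
            bland_altman[eq] = pd.DataFrame(
                {
                    "patient_id": data.loc[mask, "patient_id"].to_numpy(),
                    "mean_egfr_mgfr": (est + mg) / 2.0,
                    "mgfr": mg,
                    "difference": est - mg,
                }
            )
            pos = positive_all[mask]
            if pos.any() and not pos.all():
                fpr, tpr, thr = m.roc_points(est, pos)
                roc_data[eq] = pd.DataFrame({"fpr": fpr, "tpr": tpr, "egfr_cutoff": thr})

        metadata = {
            "n_total": int(len(data)),
            "gfr_threshold": self.gfr_threshold,
            "tolerances": list(self.tolerances),
            "roc_positive_class": f"mgfr_std < {self.gfr_threshold}",
            "roc_orientation": "lower eGFR scores as more diseased",
            "sensitivity_operating_point": f"eGFR < {self.gfr_threshold}",
            "subgroup_missing_counts": subgroup_exclusions,
            "equation_n": {eq: int(complete_masks[eq].sum()) for eq in fitted},
        }
        return GFRValidationResults(
            model=self, estimates=estimates, overall=overall,
            subgroup_metrics=subgroup_metrics, pairwise=pairwise,
            bland_altman=bland_altman, roc_data=roc_data, metadata=metadata,
        )


@dataclass
class GFRValidationResults:
    """Fitted validation study: metric tables, pairwise tests, plot data."""

    model: GFRValidation
    estimates: pd.DataFrame
    overall: dict[str, m.ValidationMetrics]
    subgroup_metrics: pd.DataFrame
    pairwise: pd.DataFrame
    bland_altman: dict[str, pd.DataFrame]
    roc_data: dict[str, pd.DataFrame]
    metadata: dict = field(default_factory=dict)

    # -- tabular views ---------------------------------------------------

    def diagnostic_table(self) -> pd.DataFrame:
        """Correlation, ROC area and sensitivity per equation."""
        return pd.DataFrame(
            [
                {"equation": eq, "n": v.n, "R": v.pearson_r,
                 "ROC_AUC": v.roc_auc, "Sensitivity": v.sensitivity}
                for eq, v in self.overall.items()
            ]
        ).set_index("equation")

    def performance_table(self) -> pd.DataFrame:
        """Bias, precision, P15/P30/P50 and limits of agreement per equation."""
        return pd.DataFrame(
            [
                {"equation": eq, "n": v.n, "Bias": v.bias, "Precision": v.precision,
                 "P15": v.p15, "P30": v.p30, "P50": v.p50,
                 "LoA_lower": v.loa_lower, "LoA_upper": v.loa_upper}
                for eq, v in self.overall.items()
            ]
        ).set_index("equation")

    def summary(self) -> str:
        """Human-readable study summary."""
        meta = self.metadata
        lines = [
            "GFR estimating-equation validation",
            "=" * 70,
            f"Patients: {meta.get('n_total')}   "
            f"ROC positive class: {meta.get('roc_positive_class')}",
            "",
            "Diagnostic values (R, ROC AUC, sensitivity at "
            f"eGFR < {self.model.gfr_threshold:g}):",
            self.diagnostic_table().round(3).to_string(),
            "",
            "Performance (bias, precision, accuracy %, 95% limits of agreement):",
            self.performance_table().round(2).to_string(),
            "",
            "Pairwise comparisons (paired t on bias, McNemar on P30):",
            self.pairwise.round(4).to_string(index=False)
            if len(self.pairwise) else "  (fewer than two equations fitted)",
        ]
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------

    def save(self, out_dir) -> list[Path]:
        """Write the report directory.

        Emits ``table3.csv`` (diagnostic values), ``table4.csv``
        (performance + limits of agreement), ``table5.csv`` (subgroup
        panel, long format), ``pairwise.csv``, per-equation Bland–Altman
        and ROC CSVs, and ``run_metadata.json``. Numeric cells are rounded
        to 2 decimals, matching the study's display precision.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        def dump(df: pd.DataFrame, path: Path, index: bool) -> None:
            df.to_csv(path, index=index, float_format="%.2f")
            written.append(path)

        dump(self.diagnostic_table(), out / "table3.csv", True)
        dump(self.performance_table(), out / "table4.csv", True)
        dump(self.subgroup_metrics, out / "table5.csv", False)
        # p-values keep 4 decimals; 2 would erase significance structure
        self.pairwise.to_csv(out / "pairwise.csv", index=False, float_format="%.4f")
        written.append(out / "pairwise.csv")
        ba_dir = out / "bland_altman"
        ba_dir.mkdir(exist_ok=True)
        for eq, df in sorted(self.bland_altman.items()):
            dump(df, ba_dir / f"{eq}.csv", False)
        roc_dir = out / "roc"
        roc_dir.mkdir(exist_ok=True)
        for eq, df in sorted(self.roc_data.items()):
            dump(df, roc_dir / f"{eq}.csv", False)
        meta_path = out / "run_metadata.json"
        meta_path.write_text(json.dumps(self.metadata, indent=2, sort_keys=True) + "\n")
        written.append(meta_path)
        return written
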