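"""Waveform agreement statistics and range-of-motion comparisons.

Implements the validation statistics used to compare an IMU-derived knee-angle
channel against an optical motion capture reference: per-trial RMSD and
Pearson R on mean-centered 101-point cycle curves, correlation-strength
banding, sagittal range of motion (ROM), a one-way repeated-measures ANOVA
across measurement methods, and Bonferroni-corrected post-hoc paired t-tests
with 95% confidence intervals on the mean differences.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .pipeline import NormalizedCurve

__all__ = [
    "AgreementResult",
    "AnovaResult",
    "PosthocComparison",
    "PosthocResult",
    "rmsd",
    "pearson_r",
    "stratify_r",
    "range_of_motion",
    "rm_anova",
    "posthoc_bonferroni",
    "summarize_cohort",
    "analyze_angle_table",
]

#: Correlation-strength bands: label and half-open interval [lo, hi);
#: the last band is closed at 1.  A value exactly on a boundary is assigned
#: to the higher band.
R_BANDS = (
    ("poor", 0.00, 0.60),
    ("moderate", 0.60, 0.75),
    ("good", 0.75, 0.85),
    ("very good", 0.85, 0.95),
    ("excellent", 0.95, 1.00),
)

ALPHA = 0.05
N_COMPARISONS = 3
#: Per-comparison Bonferroni threshold, reported at the field's customary
#: rounding (0.05 / 3 -> 0.017).
BONFERRONI_THRESHOLD = round(ALPHA / N_COMPARISONS, 3)

METHOD_PAIRS = (("OMC", "m_IMU"), ("OMC", "r_IMU"), ("m_IMU", "r_IMU"))


def _values(curve) -> np.ndarray:
    return curve.values if isinstance(curve, NormalizedCurve) else np.asarray(curve, dtype=float)


def rmsd(a, b) -> float:
    """Root-mean-square difference between two equal-length curves (degrees)."""
    a, b = _values(a), _values(b)
    if a.shape != b.shape:
        raise ValueError(f"curve length mismatch: {a.shape} vs {b.shape}")
    if isinstance(a, np.ndarray) and len(a) == 0:
        raise ValueError("empty curves")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def pearson_r(a, b) -> float:
    """Sample Pearson correlation over the cycle grid."""
    a, b = _values(a), _values(b)
    if a.shape != b.shape:
        raise ValueError(f"curve length mismatch: {a.shape} vs {b.shape}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("Pearson correlation undefined for a constant curve")
    return float(sps.pearsonr(a, b).statistic)


def stratify_r(r: float) -> str:
    """Correlation-strength band: poor [0, 0.60), moderate [0.60, 0.75),
    good [0.75, 0.85), very good [0.85, 0.95), excellent [0.95, 1].

    Negative correlations are banded "poor" with a warning flag; the boundary
    value 0.95 is assigned upward ("excellent").
    """
    if abs(r) > 1.0 + 1e-12:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    if r < 0:
        warnings.warn(f"negative correlation ({r:.3f}) banded as 'poor'", stacklevel=2)
        return "poor"
    for label, lo, hi in R_BANDS[:-1]:
        if lo <= r < hi:
            return label
    return R_BANDS[-1][0]


def range_of_motion(values) -> float:
    """Maximum minus minimum angle over a movement cycle (degrees).

    Invariant under mean-centering and any constant offset.
    """
    values = _values(values)
    if values.size == 0:
        raise ValueError("empty curve has no range of motion")
    return float(np.max(values) - np.min(values))


@dataclass(frozen=True)
class AgreementResult:
    """Per-trial agreement of one IMU method against the reference channel."""

    participant: str
    task: str
    method: str
    plane: str
    r: float
    rmsd_deg: float

    @property
    def band(self) -> str:
        return stratify_r(self.r)


@dataclass(frozen=True)
class AnovaResult:
    """One-way repeated-measures ANOVA over measurement methods."""

    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    alpha: float = ALPHA

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


@dataclass(frozen=True)
class PosthocComparison:
    pair: tuple[str, str]
    mean_diff: float
    ci_low: float
    ci_high: float
    t_statistic: float
    p_value: float

    @property
    def label(self) -> str:
        return f"{self.pair[0]}-{self.pair[1]}"


@dataclass(frozen=True)
class PosthocResult:
    comparisons: tuple[PosthocComparison, ...]
    corrected_threshold: float = BONFERRONI_THRESHOLD


def _as_method_table(rom: pd.DataFrame | np.ndarray, methods=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(rom, pd.DataFrame):
        if rom.isna().any().any():
            missing = rom[rom.isna().any(axis=1)].index.tolist()
            raise ValueError(f"missing ROM cells for participant(s): {missing}")
        return rom.to_numpy(dtype=float), list(rom.columns)
    arr = np.asarray(rom, dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError("missing ROM cells (NaN) — complete cases only")
    names = list(methods) if methods is not None else [f"method_{i}" for i in range(arr.shape[1])]
    return arr, names


def rm_anova(rom, methods=None) -> AnovaResult:
    """One-way repeated-measures ANOVA: does mean ROM differ across methods?

    ``rom`` is an ``(n_subjects, k_methods)`` table (DataFrame columns name
    the methods).  F = MS_method / MS_(method x subject) with
    df = (k-1, (k-1)(n-1)); no sphericity correction is applied by default,
    matching the plain F and p customarily reported for k = 3 methods.
    """
    arr, _ = _as_method_table(rom, methods)
    n, k = arr.shape
    if n < 2:
        raise ValueError(f"repeated-measures ANOVA needs >= 2 participants, got {n}")
    grand = arr.mean()
    ss_method = n * np.sum((arr.mean(axis=0) - grand) ** 2)
    ss_subject = k * np.sum((arr.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((arr - grand) ** 2)
    ss_error = ss_total - ss_method - ss_subject
    df_num = k - 1
    df_den = (k - 1) * (n - 1)
    ms_method = ss_method / df_num
    ms_error = ss_error / df_den
    if ms_error <= 0:
        # all residual variation vanished: identical methods per participant
        f = 0.0 if ss_method <= 1e-12 else np.inf
    else:
        f = ms_method / ms_error
    p = 1.0 if f == 0.0 else float(sps.f.sf(f, df_num, df_den))
    return AnovaResult(f_statistic=float(f), df_num=df_num, df_den=df_den, p_value=p)


def posthoc_bonferroni(rom, methods=None) -> PosthocResult:
    """Pairwise paired t-tests between methods with Bonferroni correction.

    Reports, per pair, the mean difference with a two-sided t-based 95% CI
    (n-1 df) and the uncorrected paired-t p value; the corrected
    per-comparison significance threshold is 0.05 / 3 = 0.017.
    """
    arr, names = _as_method_table(rom, methods)
    n, k = arr.shape
    if n < 2:
        raise ValueError("paired t-tests need >= 2 participants")
    cols = {name: arr[:, i] for i, name in enumerate(names)}
    pairs = METHOD_PAIRS if set(names) == {"OMC", "m_IMU", "r_IMU"} else [
        (names[i], names[j]) for i in range(k) for j in range(i + 1, k)
    ]
    comparisons = []
    tcrit = sps.t.ppf(1 - ALPHA / 2, n - 1)
    for a, b in pairs:
        d = cols[a] - cols[b]
        md = float(d.mean())
        sd = float(d.std(ddof=1))
        se = sd / np.sqrt(n)
        if sd == 0.0:
            t_stat, p = (0.0, 1.0)
            lo = hi = md
        else:
            res = sps.ttest_rel(cols[a], cols[b])
            t_stat, p = float(res.statistic), float(res.pvalue)
            lo, hi = md - tcrit * se, md + tcrit * se
        comparisons.append(
            PosthocComparison(pair=(a, b), mean_diff=md, ci_low=lo, ci_high=hi, t_statistic=t_stat, p_value=p)
        )
    return PosthocResult(comparisons=tuple(comparisons))


def summarize_cohort(results: list[AgreementResult]) -> pd.DataFrame:
    """Cohort summary per task/method/plane: R mean (SD), RMSD mean (min-max).

    One row per cell, mirroring the customary group-summary layout of IMU
    validation studies; the ``band`` column bands the cell's mean R.
    """
    if not results:
        warnings.warn("no agreement results to summarize", stacklevel=2)
        return pd.DataFrame(
            columns=["task", "method", "plane", "n", "r_mean", "r_sd",
                     "rmsd_mean", "rmsd_sd", "rmsd_min", "rmsd_max", "band"]
        )
    df = pd.DataFrame(
        [
            {"task": x.task, "method": x.method, "plane": x.plane, "r": x.r, "rmsd": x.rmsd_deg}
            for x in results
        ]
    )
    rows = []
    for (task, method, plane), g in df.groupby(["task", "method", "plane"], sort=False):
        r = g["r"].to_numpy()
        e = g["rmsd"].to_numpy()
        rows.append(
            {
                "task": task,
                "method": method,
                "plane": plane,
                "n": len(g),
                "r_mean": r.mean(),
                "r_sd": r.std(ddof=1) if len(r) > 1 else 0.0,
                "rmsd_mean": e.mean(),
                "rmsd_sd": e.std(ddof=1) if len(e) > 1 else 0.0,
                "rmsd_min": e.min(),
                "rmsd_max": e.max(),
                "band": stratify_r(float(np.clip(r.mean(), -1.0, 1.0))),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full-table analysis (S1-style angle table in, agreement + ROM tables out)

PCT_COLS = [f"pct_{i}" for i in range(101)]


def analyze_angle_table(
    table: pd.DataFrame, center: bool = True, reference: str = "OMC"
) -> dict:
    """Recompute all agreement statistics from a normalized angle table.

    ``table`` has one row per participant x task x method x plane with columns
    ``participant, task, method, plane, pct_0 ... pct_100`` (the layout of the
    deposited per-cycle angle datasets).  For every non-reference method the
    per-participant R and RMSD against the reference are computed on
    (optionally) mean-centered curves; sagittal ROM per participant x method
    feeds the repeated-measures ANOVA and Bonferroni post-hoc tests per task.

    Returns a dict with keys ``agreement`` (list of AgreementResult),
    ``summary`` (cohort summary DataFrame), ``rom`` (per-task ROM DataFrames),
    ``anova`` and ``posthoc`` (per-task results).
    """
    missing = [c for c in ("participant", "task", "method", "plane") if c not in table.columns]
    if missing:
        raise ValueError(f"angle table missing column(s): {missing}")
    if any(c not in table.columns for c in PCT_COLS):
        raise ValueError("angle table must contain the 101 columns pct_0 ... pct_100")

    agreement: list[AgreementResult] = []
    key = ["participant", "task", "plane"]
    for (participant, task, plane), g in table.groupby(key, sort=False):
        by_method = {m: sub[PCT_COLS].to_numpy(dtype=float)[0] for m, sub in g.groupby("method")}
        if reference not in by_method:
            continue
        ref = by_method[reference]
        for method, vals in by_method.items():
            if method == reference:
                continue
            a, b = (ref - ref.mean(), vals - vals.mean()) if center else (ref, vals)
            agreement.append(
                AgreementResult(
                    participant=str(participant), task=task, method=method, plane=plane,
                    r=pearson_r(a, b), rmsd_deg=rmsd(a, b),
                )
            )

    sag = table[table["plane"] == "sagittal"]
    rom_tables: dict[str, pd.DataFrame] = {}
    anova: dict[str, AnovaResult] = {}
    posthoc: dict[str, PosthocResult] = {}
    for task, g in sag.groupby("task", sort=False):
        roms = g.apply(
            lambda row: range_of_motion(row[PCT_COLS].to_numpy(dtype=float)), axis=1
        )
        wide = (
            g.assign(rom=roms)
            .pivot_table(index="participant", columns="method", values="rom")
            .dropna()
        )
        rom_tables[task] = wide
        if wide.shape[0] >= 2 and wide.shape[1] >= 2:
            anova[task] = rm_anova(wide)
            posthoc[task] = posthoc_bonferroni(wide)
    return {
        "agreement": agreement,
        "summary": summarize_cohort(agreement),
        "rom": rom_tables,
        "anova": anova,
        "posthoc": posthoc,
    }


def rom_summary_table(analysis: dict) -> pd.DataFrame:
    """Flatten the ROM / ANOVA / post-hoc results into one tidy table."""
    rows = []
    for task, wide in analysis["rom"].items():
        an = analysis["anova"].get(task)
        ph = analysis["posthoc"].get(task)
        for method in wide.columns:
            rows.append(
                {
                    "task": task,
                    "method": method,
                    "n": wide.shape[0],
                    "rom_mean": float(wide[method].mean()),
                    "rom_sd": float(wide[method].std(ddof=1)),
                    "F": an.f_statistic if an else np.nan,
                    "p_anova": an.p_value if an else np.nan,
                }
            )
        if ph:
            for comp in ph.comparisons:
                rows.append(
                    {
                        "task": task,
                        "method": comp.label,
                        "n": wide.shape[0],
                        "mean_diff": comp.mean_diff,
                        "ci_low": comp.ci_low,
                        "ci_high": comp.ci_high,
                        "p": comp.p_value,
                        "F": an.f_statistic if an else np.nan,
                        "p_anova": an.p_value if an else np.nan,
                    }
                )
    return pd.DataFrame(rows)
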