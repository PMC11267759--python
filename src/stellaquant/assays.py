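"""Tabular assay arithmetic and statistics.

Covers protein normalization (to the 100 mg/mL reference), radiotracer
uptake/fractional oxidation, Seahorse %-of-baseline normalization and
basal/maximal respiration, per-24 h rates, fold changes and group ratios,
Welch's unequal-variance t-test, ROUT outlier removal (Q = 1% default),
per-gene z-score matrices, and five-number boxplot summaries.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .types import OxidationRecord, SeahorseTrace, StatResult

CONDITIONS = ("Control", "Starvation", "TGF-β", "Starvation+TGF-β")
PROTEIN_REFERENCE = 100.0  # mg/mL


def normalize_protein(table: pd.DataFrame) -> pd.DataFrame:
    """Normalize assay values to the 100 mg/mL protein reference.

    ``value' = value × 100 / protein_conc``; the returned copy carries a
    ``value_units`` attribute noting the reference. Rows with missing or
    non-positive protein concentration raise, listing the offenders.
    """
    if "protein_conc" not in table.columns:
        raise ValueError("table has no protein_conc column")
    bad = table.index[~(table["protein_conc"] > 0)].tolist()
    if bad:
        raise ValueError(f"non-positive or missing protein_conc in rows {bad}")
    out = table.copy()
    out["value"] = out["value"] * PROTEIN_REFERENCE / out["protein_conc"]
    out.attrs["value_units"] = "per 100 mg/mL protein"
    return out


def oxidation(co2: float, ca: float) -> OxidationRecord:
    """Radiotracer oxidation arithmetic: uptake = CO₂ + CA;
    fractional oxidation = CO₂ / uptake (null with a warning at zero
    uptake)."""
    if co2 < 0 or ca < 0:
        raise ValueError("radioactivity counts must be non-negative")
    uptake = co2 + ca
    if uptake == 0:
        warnings.warn("zero uptake; fractional oxidation undefined")
        frac = None
    else:
        frac = co2 / uptake
    return OxidationRecord(co2=co2, ca=ca, uptake=uptake, fractional_oxidation=frac)


def _baseline_cycles(trace: SeahorseTrace, n_baseline: int = 5) -> slice:
    """Pre-injection measurement cycles (5 baseline cycles by default,
    capped at the first injection)."""
    first = min(trace.injection_marks.values()) if trace.injection_marks else trace.ocr.size
    return slice(0, min(n_baseline, first))


def seahorse_percent_baseline(
    trace: SeahorseTrace,
    control_trace: SeahorseTrace,
    n_baseline: int = 5,
) -> SeahorseTrace:
    """Express a trace as % of the Control condition's baseline.

    Every OCR (ECAR) value is divided by the mean of the control trace's
    pre-injection baseline OCR (ECAR) cycles and scaled to percent. The
    control trace normalized against itself therefore averages to 100% over
    its baseline cycles.
    """
    sl = _baseline_cycles(control_trace, n_baseline)
    base_ocr = float(control_trace.ocr[sl].mean()) if control_trace.ocr[sl].size else np.nan
    base_ecar = float(control_trace.ecar[sl].mean()) if control_trace.ecar[sl].size else np.nan
    if not (base_ocr > 0 and base_ecar > 0):
        raise ValueError("control baseline mean must be positive")
    return SeahorseTrace(
        timepoints=trace.timepoints.copy(),
        ocr=100.0 * trace.ocr / base_ocr,
        ecar=100.0 * trace.ecar / base_ecar,
        injection_marks=dict(trace.injection_marks),
    )


def respiration_metrics(
    trace: SeahorseTrace,
    subtract_non_mito: bool = True,
    n_baseline: int = 5,
) -> tuple[float, float]:
    """Basal and maximal mitochondrial respiration from an OCR trace.

    Standard derivation: non-mitochondrial OCR is the mean of the
    post-rotenone/antimycin-A cycles; basal = mean(pre-injection cycles) −
    non-mito; maximal = max(post-FCCP cycles) − non-mito. Both are
    invariant to adding a constant to the whole trace. With
    ``subtract_non_mito=False`` the raw baseline mean and FCCP maximum are
    returned instead.
    """
    marks = trace.injection_marks
    if "rot_aa" not in marks:
        raise ValueError("trace lacks a rotenone/antimycin A injection mark")
    if "fccp" not in marks:
        raise ValueError("trace lacks an FCCP injection mark")
    sl = _baseline_cycles(trace, n_baseline)
    baseline = float(trace.ocr[sl].mean())
    post_fccp = trace.ocr[marks["fccp"]:marks["rot_aa"]]
    post_rot = trace.ocr[marks["rot_aa"]:]
    if post_fccp.size == 0 or post_rot.size == 0:
        raise ValueError("missing measurement cycles after an injection")
    non_mito = float(post_rot.mean()) if subtract_non_mito else 0.0
    basal = baseline - non_mito
    maximal = float(post_fccp.max()) - non_mito
    return basal, maximal


def per_day_rate(value: float, duration_h: float) -> float:
    """Convert an accumulated amount over ``duration_h`` hours to a per-24 h
    rate."""
    if duration_h <= 0:
        raise ValueError("duration must be positive")
    return value * 24.0 / duration_h


def fold_and_ratio(group_means: dict, reference: str = "Control") -> dict:
    """Fold differences of group means versus a reference group.

    Returns ``{group: mean_group / mean_reference}``. Raises when the
    reference mean is zero.
    """
    if reference not in group_means:
        raise ValueError(f"reference group {reference!r} absent")
    ref = group_means[reference]
    if ref == 0:
        raise ValueError("reference mean is zero")
    return {g: m / ref for g, m in group_means.items()}


def percentage_ratio(mean_a: float, mean_b: float) -> float:
    """``100 × mean_a / mean_b`` — e.g. the pHSC/scHSC vitamin-A content
    ratio in percent."""
    if mean_b == 0:
        raise ValueError("denominator mean is zero")
    return 100.0 * mean_a / mean_b


def five_number(x, method: str = "linear") -> tuple[float, float, float, float, float]:
    """Five-number summary (min, Q1, median, Q3, max).

    Quartiles use linear interpolation between order statistics by default;
    ``method='tukey'`` switches to Tukey hinges (medians of the lower/upper
    halves).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    if method == "linear":
        q1, q2, q3 = np.percentile(x, [25, 50, 75])
    elif method == "tukey":
        s = np.sort(x)
        n = s.size
        q2 = float(np.median(s))
        half = (n + 1) // 2
        q1 = float(np.median(s[:half]))
        q3 = float(np.median(s[n - half:]))
    else:
        raise ValueError(f"unknown quartile method {method!r}")
    return (float(x.min()), float(q1), float(q2), float(q3), float(x.max()))


def welch_ttest(x, y, names: tuple[str, str] = ("x", "y")) -> StatResult:
    """Unpaired two-sample t-test with Welch's correction (two-sided).

    ``t = (x̄ − ȳ) / √(s²x/nx + s²y/ny)`` with Welch–Satterthwaite degrees
    of freedom; the p-value comes from the t distribution. When both
    samples have zero variance and equal means, ``t = 0, p = 1`` by
    convention.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            t_stat, df, p = 0.0, float(nx + ny - 2), 1.0
        else:
            raise ValueError("both groups have zero variance with unequal means")
    else:
        se2 = vx / nx + vy / ny
        t_stat = float((x.mean() - y.mean()) / np.sqrt(se2))
        df = float(se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)))
        p = float(2.0 * stats.t.sf(abs(t_stat), df))
    summaries = {
        names[0]: {"mean": float(x.mean()), "sd": float(x.std(ddof=1)), "n": nx,
                   "five_number": five_number(x)},
        names[1]: {"mean": float(y.mean()), "sd": float(y.std(ddof=1)), "n": ny,
                   "five_number": five_number(y)},
    }
    return StatResult(t=t_stat, df=df, p=p, group_summaries=summaries,
                      five_number=five_number(np.concatenate([x, y])))


def rout_outliers(x, q_percent: float = 1.0) -> tuple[np.ndarray, list[int]]:
    """ROUT outlier identification for a single sample (Q in percent).

    The robust fit of a lone sample reduces to its median; the robust
    standard deviation of the residuals (RSDR) is the 68.27th percentile of
    the absolute residuals with the small-sample correction ``n / (n − 1)``.
    Candidates are tested from the most extreme inward: the i-th most
    extreme point is an outlier when its two-tailed t-tail probability
    (df = n − 1) falls below the Benjamini–Hochberg threshold
    ``(Q/100) · i / n``; testing stops at the first retained point
    (step-down false-discovery-rate control).

    Returns ``(kept values, removed indices)``; samples with n < 4 are
    returned untouched with a warning.
    """
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    if not 0 < q_percent < 100:
        raise ValueError("Q must be in (0, 100) percent")
    if n < 4:
        warnings.warn("ROUT requires n >= 4; no outliers removed")
        return x.copy(), []
    resid = x - np.median(x)
    absr = np.abs(resid)
    p68 = np.percentile(absr, 68.27)
    rsdr = p68 * n / (n - 1)
    if rsdr == 0:
        removed = np.flatnonzero(absr > 0).tolist()
        kept = np.delete(x, removed)
        return kept, removed
    df = n - 1
    order = np.argsort(absr)[::-1]
    removed: list[int] = []
    for i, idx in enumerate(order, start=1):
        alpha_i = (q_percent / 100.0) * i / n
        p_i = 2.0 * stats.t.sf(absr[idx] / rsdr, df)
        if p_i < alpha_i:
            removed.append(int(idx))
        else:
            break
    removed.sort()
    kept = np.delete(x, removed)
    return kept, removed


def zscore_matrix(matrix, sample_sd: bool = False):
    """Per-row (gene) z-scores of an expression matrix.

    Each row is centered by its mean and scaled by its standard deviation
    (population convention by default; ``sample_sd=True`` uses ddof=1).
    Zero-variance rows are returned as NaN and their indices listed in the
    second return value.

    Accepts a DataFrame (genes × samples) or a 2D array; returns the same
    container type plus the list of flagged rows.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    arr = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("need a 2D matrix with >= 2 samples per gene")
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, ddof=1 if sample_sd else 0, keepdims=True)
    flagged = np.flatnonzero(sd.ravel() == 0).tolist()
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (arr - mean) / sd
    z[sd.ravel() == 0, :] = np.nan
    if is_df:
        z = pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
        flagged = [matrix.index[i] for i in flagged]
    return z, flagged
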