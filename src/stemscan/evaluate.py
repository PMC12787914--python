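"""Error statistics and device comparison.

Per-object estimation error is ``estimate - reference`` (positive means
overestimation).  Accuracy is summarised by RMSE = sqrt(mean(err^2)),
bias = mean(err), their percentages of the reference mean (rRMSE, rBias),
the squared Pearson correlation of reference vs estimate, and the target
detection rate (TDR, % of reference objects recovered).  Undetected
objects are excluded from RMSE/bias but counted against TDR.

Devices are compared by a paired t-test of estimates against the
reference, a one-way ANOVA on per-device error groups and, when the
ANOVA is significant, Tukey's HSD post hoc test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ReferenceTable

__all__ = [
    "ErrorStats",
    "DeviceComparison",
    "PairedT",
    "error_table",
    "rmse",
    "bias",
    "rrmse",
    "rbias",
    "r2",
    "detection_rate",
    "summary_stats",
    "error_stats",
    "paired_t",
    "anova_tukey",
    "report",
]


def error_table(ref: ReferenceTable, device: str) -> pd.DataFrame:
    """One row per object: reference, estimate, error, detected flag."""
    det = ref.detected(device)
    est = ref.estimates(device)
    err = np.where(det, est - ref.reference, np.nan)
    return pd.DataFrame(
        {
            "id": ref.ids,
            "reference": ref.reference,
            "estimate": est,
            "error": err,
            "detected": det,
        }
    )


def _finite(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v)]


def rmse(errors) -> float:
    """Root-mean-square error, divisor n."""
    e = _finite(errors)
    if len(e) == 0:
        raise ValueError("no detected records")
    return float(np.sqrt(np.mean(e**2)))


def bias(errors) -> float:
    """Mean error; positive = overestimation."""
    e = _finite(errors)
    if len(e) == 0:
        raise ValueError("no detected records")
    return float(np.mean(e))


def rrmse(errors, refs) -> float:
    """RMSE as a percentage of the mean reference value."""
    return 100.0 * rmse(errors) / float(np.mean(_finite(refs)))


def rbias(errors, refs) -> float:
    """Bias as a percentage of the mean reference value."""
    return 100.0 * bias(errors) / float(np.mean(_finite(refs)))


def r2(refs, ests) -> float:
    """Squared Pearson correlation of reference vs estimate."""
    refs = np.asarray(refs, dtype=float)
    ests = np.asarray(ests, dtype=float)
    ok = np.isfinite(refs) & np.isfinite(ests)
    if ok.sum() < 2:
        raise ValueError("need at least 2 paired values for r2")
    r, _ = stats.pearsonr(refs[ok], ests[ok])
    return float(r**2)


def detection_rate(ref: ReferenceTable, device: str) -> float:
    """Percentage of reference objects the device detected."""
    det = ref.detected(device)
    return 100.0 * det.sum() / len(det)


def summary_stats(values, population: bool = True) -> tuple[float, float, float, float]:
    """(mean, SD, min, max); SD uses divisor n by default (population form)."""
    v = _finite(values)
    if len(v) == 0:
        raise ValueError("no values")
    sd = float(np.std(v, ddof=0 if population else 1)) if len(v) > 1 else 0.0
    return float(np.mean(v)), sd, float(v.min()), float(v.max())


@dataclass(frozen=True)
class ErrorStats:
    """Accuracy summary for one device on one variable."""

    n: int
    rmse: float
    bias: float
    rrmse: float
    rbias: float
    r_squared: float | None
    tdr: float
    est_min: float
    est_max: float
    err_min: float
    err_max: float


def error_stats(ref: ReferenceTable, device: str) -> ErrorStats:
    """Full accuracy summary of a device against a reference table."""
    tab = error_table(ref, device)
    det = tab[tab["detected"]]
    e = det["error"].to_numpy()
    refs = det["reference"].to_numpy()
    ests = det["estimate"].to_numpy()
    return ErrorStats(
        n=len(det),
        rmse=rmse(e),
        bias=bias(e),
        rrmse=rrmse(e, refs),
        rbias=rbias(e, refs),
        r_squared=r2(refs, ests) if len(det) >= 2 else None,
        tdr=detection_rate(ref, device),
        est_min=float(ests.min()),
        est_max=float(ests.max()),
        err_min=float(e.min()),
        err_max=float(e.max()),
    )


@dataclass(frozen=True)
class PairedT:
    mean_diff: float
    ci95: tuple[float, float]
    t: float
    p: float
    df: int


def paired_t(est, ref) -> PairedT:
    """Classical paired t-test of estimates against references.

    Two-sided p with n-1 degrees of freedom and a 95% CI for the mean
    difference.  Zero-variance differences leave t undefined and raise.
    """
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape or est.ndim != 1:
        raise ValueError("est and ref must be equal-length 1D arrays")
    n = len(est)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = est - ref
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero-variance differences: t statistic undefined")
    mean = d.mean()
    se = sd / np.sqrt(n)
    t = mean / se
    p = 2 * stats.t.sf(abs(t), df=n - 1)
    half = stats.t.ppf(0.975, df=n - 1) * se
    return PairedT(
        mean_diff=float(mean),
        ci95=(float(mean - half), float(mean + half)),
        t=float(t),
        p=float(p),
        df=n - 1,
    )


@dataclass
class DeviceComparison:
    """One-way ANOVA over device error groups, with Tukey HSD when significant."""

    anova_f: float
    anova_p: float
    alpha: float
    tukey: pd.DataFrame | None  # pairwise (group1, group2, meandiff, lo, hi, p_adj, reject)

    @property
    def significant(self) -> bool:
        return self.anova_p < self.alpha


def anova_tukey(groups: dict[str, np.ndarray], alpha: float = 0.05) -> DeviceComparison:
    """F-test across error groups; Tukey HSD pairwise when ANOVA rejects.

    ``groups`` maps device label to its error sample (each n >= 2).
    The Tukey table is only computed when the ANOVA p-value is below
    ``alpha``, mirroring the gated post hoc protocol.  Critical values
    come from the exact studentized-range distribution, with the
    Tukey-Kramer correction when group sizes differ.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs at least 2 observations")
    f, p = stats.f_oneway(*arrays.values())
    tukey = None
    if p < alpha:
        tukey = _tukey_hsd(arrays, alpha)
    return DeviceComparison(anova_f=float(f), anova_p=float(p), alpha=alpha, tukey=tukey)


def _tukey_hsd(arrays: dict[str, np.ndarray], alpha: float) -> pd.DataFrame:
    k = len(arrays)
    ns = {g: len(v) for g, v in arrays.items()}
    means = {g: v.mean() for g, v in arrays.items()}
    df_w = sum(ns.values()) - k
    ms_w = sum(((v - means[g]) ** 2).sum() for g, v in arrays.items()) / df_w
    q_crit = stats.studentized_range.ppf(1 - alpha, k, df_w)
    rows = []
    names = list(arrays)
    for i, g1 in enumerate(names):
        for g2 in names[i + 1 :]:
            diff = means[g2] - means[g1]
            se = np.sqrt(ms_w / 2 * (1 / ns[g1] + 1 / ns[g2]))
            half = q_crit * se
            p_adj = float(
                np.clip(stats.studentized_range.sf(abs(diff) / se, k, df_w), 0, 1)
            )
            rows.append(
                {
                    "group1": g1,
                    "group2": g2,
                    "meandiff": diff,
                    "p-adj": p_adj,
                    "lower": diff - half,
                    "upper": diff + half,
                    "reject": bool(abs(diff) > half),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting

def _fmt(x, nd=2):
    return "" if x is None or (isinstance(x, float) and not np.isfinite(x)) else f"{x:.{nd}f}"


def report(
    ref: ReferenceTable,
    devices: list[str] | None = None,
    comparison: DeviceComparison | None = None,
    unit: str = "cm",
) -> str:
    """Markdown report: per-object table plus per-device accuracy summary."""
    devices = devices or ref.devices
    lines = []
    head = ["id", f"reference ({unit})"]
    for d in devices:
        head += [f"{d} est.", f"{d} diff."]
    lines.append("| " + " | ".join(head) + " |")
    lines.append("|" + "---|" * len(head))
    tabs = {d: error_table(ref, d) for d in devices}
    for i, oid in enumerate(ref.ids):
        row = [oid, _fmt(ref.reference[i])]
        for d in devices:
            t = tabs[d].iloc[i]
            if t["detected"]:
                row += [_fmt(t["estimate"]), _fmt(t["error"])]
            else:
                row += ["-", "-"]
        lines.append("| " + " | ".join(row) + " |")
    lines.append("")
    lines.append("| statistic | " + " | ".join(devices) + " |")
    lines.append("|" + "---|" * (len(devices) + 1))
    stats_rows = [
        (f"RMSE ({unit})", lambda s: _fmt(s.rmse)),
        (f"Bias ({unit})", lambda s: _fmt(s.bias)),
        ("rRMSE (%)", lambda s: _fmt(s.rrmse, 1)),
        ("rBias (%)", lambda s: _fmt(s.rbias, 1)),
        ("R2", lambda s: _fmt(s.r_squared, 3)),
        ("N", lambda s: str(s.n)),
        ("TDR (%)", lambda s: _fmt(s.tdr, 1)),
    ]
    summaries = {d: error_stats(ref, d) for d in devices}
    for label, getter in stats_rows:
        lines.append(
            f"| {label} | " + " | ".join(getter(summaries[d]) for d in devices) + " |"
        )
    if comparison is not None:
        lines.append("")
        lines.append(
            f"ANOVA: F = {comparison.anova_f:.3f}, p = {comparison.anova_p:.4g}"
            + (" (significant)" if comparison.significant else " (not significant)")
        )
        if comparison.tukey is not None:
            lines.append("")
            lines.append(comparison.tukey.to_string(index=False))
    return "\n".join(lines) + "\n"
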