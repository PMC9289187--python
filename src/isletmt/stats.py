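"""Functional-endpoint derivations and dose-response statistics.

Implements the statistical workflow of a dose-response screen on islet
microtissues: glucose-stimulated-insulin-secretion fold-stimulation,
robust outlier removal (ROUT) at a chosen false-discovery rate,
one-way ANOVA with Dunnett's many-to-one post hoc against the vehicle
control, Student's t-test, and tidy per-endpoint group summaries
(mean ± SEM) with peak annotation.

ROUT was published for nonlinear regression; applied to a single group
of measurements it reduces to the constant (one-sample) model: robust
center = median, robust scale = the 68.27th percentile of absolute
residuals with an n/(n-1) small-sample correction, per-point two-tailed
p-values from the t distribution on the studentized residuals, and an
FDR stepping schedule from the most extreme residual inward.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: Endpoints for which no outlier test is performed (proliferating-cell
#: fractions are reported as measured).
PROLIFERATION_ENDPOINTS = frozenset({
    "pct_prolif_total", "pct_prolif_beta", "pct_prolif_nonbeta",
})

#: Derived endpoint computed from basal/stimulated columns on demand.
FOLD_STIMULATION = "fold_stimulation"

FUNCTIONAL_ENDPOINTS = (
    "basal_secretion", "stimulated_secretion", "chronic_secretion",
    "insulin_content", "atp_content", "caspase_lum",
)

_DUNNETT_SEED = 171717  # fixed: Dunnett p-values are Monte-Carlo integrated


@dataclass
class GroupSummary:
    """Mean ± SEM of one endpoint in one dose group."""

    dose: float
    endpoint: str
    n: int
    mean: float
    sem: float
    flagged_outliers: int
    dunnett_p_vs_control: float  # nan when not applicable (control itself, or single group)

    def __post_init__(self) -> None:
        assert self.n >= 1
        assert self.sem >= 0 or np.isnan(self.sem)
        assert np.isnan(self.dunnett_p_vs_control) or \
            0.0 <= self.dunnett_p_vs_control <= 1.0


def fold_stimulation(basal: float, stimulated: float) -> float:
    """Stimulated-to-basal secretion ratio (16.7 mM / 2.8 mM glucose).

    A marker of β-cell functional quality; scale-invariant in the common
    units of the two measurements. ``basal`` must be strictly positive.
    """
    if basal <= 0:
        raise ValueError(f"basal secretion must be > 0, got {basal}")
    return stimulated / basal


def rout_outliers(values, q: float = 0.05) -> tuple[list[float], list[float]]:
    """One-sample ROUT outlier detection at false-discovery rate ``q``.

    Residuals are taken from the median; the robust scale (RSDR) is the
    68.27th percentile of the absolute residuals times n/(n-1). Each
    point gets a two-tailed p-value from the t distribution (n-1 df) on
    its studentized residual; stepping inward from the most extreme
    residual, point i (1 = most extreme) is flagged while
    ``p_i < q * (n - i + 1) / n``, stopping at the first failure.

    Returns ``(kept, flagged)``; their union is the input. With fewer
    than 4 points the test is skipped (all kept) with a warning.
    """
    values = [float(v) for v in values]
    if not 0.0 < q < 0.5:
        raise ValueError(f"q must be in (0, 0.5), got {q}")
    n = len(values)
    if n < 4:
        warnings.warn(f"ROUT skipped: need >= 4 points, got {n}", stacklevel=2)
        return list(values), []

    arr = np.asarray(values)
    resid = arr - np.median(arr)
    abs_resid = np.abs(resid)
    rsdr = float(np.percentile(abs_resid, 68.27)) * n / (n - 1)
    if rsdr == 0:
        return list(values), []

    t_stat = abs_resid / rsdr
    pvals = 2.0 * sps.t.sf(t_stat, df=n - 1)
    order = np.argsort(abs_resid)[::-1]  # most extreme first
    flagged_idx: set[int] = set()
    for i, idx in enumerate(order, start=1):
        if pvals[idx] < q * (n - i + 1) / n:
            flagged_idx.add(int(idx))
        else:
            break
    kept = [values[i] for i in range(n) if i not in flagged_idx]
    flagged = [values[i] for i in range(n) if i in flagged_idx]
    return kept, flagged


def students_t(a, b, welch: bool = False) -> float:
    """Two-sided two-sample t-test p-value (pooled variance by default)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    if not welch and np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance: t-test undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.pvalue)


def anova_dunnett(groups: list[tuple[float, list[float]]],
                  control_dose: float = 0.0) -> dict:
    """One-way ANOVA with Dunnett's many-to-one comparisons vs. control.

    ``groups`` is a list of ``(dose, values)``; the group at
    ``control_dose`` is the shared control. Adjusted p-values come from
    the equicorrelated multivariate-t distribution of the Dunnett
    statistics (Monte-Carlo integrated with a fixed seed; repeatability
    ~1e-3). Returns ``{"f_stat", "p_anova", "p_adjusted": {dose: p}}``.

    Raises
    ------
    ValueError
        If fewer than 2 groups, any group has n < 2, the control dose is
        absent, or every group has zero within-group variance.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    doses = [d for d, _ in groups]
    if control_dose not in doses:
        raise ValueError(f"control dose {control_dose} not among doses {sorted(doses)}")
    samples = {d: np.asarray(v, dtype=float) for d, v in groups}
    if any(len(v) < 2 for v in samples.values()):
        raise ValueError("every group needs n >= 2")
    if all(np.var(v, ddof=1) == 0 for v in samples.values()):
        raise ValueError("zero within-group variance in all groups")

    control = samples[control_dose]
    treatment_doses = [d for d in samples if d != control_dose]
    f_stat, p_anova = sps.f_oneway(*samples.values())

    res = sps.dunnett(*[samples[d] for d in treatment_doses], control=control,
                      rng=np.random.default_rng(_DUNNETT_SEED))
    p_adj = {d: float(p) for d, p in zip(treatment_doses, res.pvalue)}
    return {"f_stat": float(f_stat), "p_anova": float(p_anova),
            "p_adjusted": p_adj}


def dose_response_table(records, endpoint: str, control_dose: float = 0.0,
                        q: float = 0.05) -> pd.DataFrame:
    """Tidy per-dose summary of one endpoint with outlier removal, Dunnett
    p-values, and peak annotation.

    ``records`` is a DataFrame (or anything :func:`pandas.DataFrame`
    accepts) with a dose column (``dose_uM`` or ``dose``) and the
    endpoint column; ``fold_stimulation`` is derived on the fly from the
    basal/stimulated columns. ROUT cleaning at FDR ``q`` is applied per
    dose group except for proliferating-cell fractions, which are
    summarized as measured. The dose with the maximal cleaned group mean
    is annotated ``is_peak``. Dunnett p-values are reported when >= 2
    groups including the control are present, else left missing.

    Columns: endpoint, dose, n, mean, sem, n_outliers_removed, p_adj, is_peak.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    dose_col = "dose_uM" if "dose_uM" in df.columns else "dose"
    if dose_col not in df.columns:
        raise ValueError("records need a 'dose_uM' or 'dose' column")

    if endpoint == FOLD_STIMULATION and endpoint not in df.columns:
        df = df.assign(**{FOLD_STIMULATION: [
            fold_stimulation(b, s)
            for b, s in zip(df["basal_secretion"], df["stimulated_secretion"])]})
    if endpoint not in df.columns:
        available = sorted(c for c in df.columns
                           if c not in (dose_col, "mt_id", "well", "donor",
                                        "duration_days", "treatment"))
        raise ValueError(
            f"unknown endpoint {endpoint!r}; available: "
            f"{available + [FOLD_STIMULATION]}")

    skip_rout = endpoint in PROLIFERATION_ENDPOINTS
    cleaned: dict[float, np.ndarray] = {}
    n_flagged: dict[float, int] = {}
    for dose, grp in df.groupby(dose_col):
        vals = grp[endpoint].dropna().to_numpy(dtype=float)
        if skip_rout or len(vals) < 4:
            kept, flagged = list(vals), []
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                kept, flagged = rout_outliers(vals, q=q)
        cleaned[float(dose)] = np.asarray(kept)
        n_flagged[float(dose)] = len(flagged)

    p_adj: dict[float, float] = {}
    eligible = {d: v for d, v in cleaned.items() if len(v) >= 2}
    if len(eligible) >= 2 and control_dose in eligible:
        try:
            p_adj = anova_dunnett(list(eligible.items()), control_dose)["p_adjusted"]
        except ValueError as exc:  # e.g. all-constant groups
            logger.warning("Dunnett skipped for %s: %s", endpoint, exc)

    rows = []
    for dose in sorted(cleaned):
        vals = cleaned[dose]
        rows.append({
            "endpoint": endpoint, "dose": dose, "n": len(vals),
            "mean": float(np.mean(vals)) if len(vals) else float("nan"),
            "sem": float(sps.sem(vals)) if len(vals) > 1 else float("nan"),
            "n_outliers_removed": n_flagged[dose],
            "p_adj": p_adj.get(dose, float("nan")),
            "is_peak": False,
        })
    table = pd.DataFrame(rows)
    if table["mean"].notna().any():
        table.loc[table["mean"].idxmax(), "is_peak"] = True
    return table


def summarize_endpoints(records, endpoints, control_dose: float = 0.0,
                        q: float = 0.05) -> pd.DataFrame:
    """Concatenated :func:`dose_response_table` over several endpoints."""
    tables = [dose_response_table(records, ep, control_dose=control_dose, q=q)
              for ep in endpoints]
    return pd.concat(tables, ignore_index=True)
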