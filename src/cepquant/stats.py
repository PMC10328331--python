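"""Cohort-level comparison of degeneration metrics across treatment groups.

Each dendrite is one observation (N = 1 per dendrite). Two comparative
outputs are produced: per-metric z-scores of every treatment against the
control group, and per-metric one-way ANOVA with either Bonferroni
(all pairwise) or Dunnett (treatments vs control) corrected follow-ups.

The z-score denominator is the control group's standard deviation, not a
pooled one: z = (mean_treatment - mean_control) / sd_control, so the sign
encodes the direction of the treatment effect relative to control.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import METRIC_COLUMNS

__all__ = ["zscore_vs_control", "anova_with_correction"]


def _group_values(table: pd.DataFrame, metric: str) -> dict[str, np.ndarray]:
    out = {}
    for g, sub in table.groupby("group", sort=False):
        vals = sub[metric].to_numpy(dtype=float)
        out[str(g)] = vals[np.isfinite(vals)]
    return out


def zscore_vs_control(table: pd.DataFrame, control: str,
                      metrics: list[str] | None = None) -> pd.DataFrame:
    """Per (group, metric) z-score of the treatment mean versus control.

    ``table`` holds one row per dendrite with a ``group`` column. Metrics
    whose control variance is zero get a null z and a warning.
    """
    metrics = metrics or [m for m in METRIC_COLUMNS if m in table.columns]
    if control not in set(table["group"].astype(str)):
        raise ValueError(f"control group {control!r} not present")
    rows = []
    for metric in metrics:
        groups = _group_values(table, metric)
        ctrl = groups[control]
        if len(ctrl) < 2:
            # e.g. feature aggregates are null-coded on feature-free dendrites
            warnings.warn(f"fewer than 2 finite control observations for "
                          f"{metric!r}; z-scores null-coded")
            for g in groups:
                if g != control:
                    rows.append({"group": g, "metric": metric, "z": np.nan,
                                 "n": len(groups[g]), "n_control": len(ctrl)})
            continue
        sd = ctrl.std(ddof=1)
        for g, vals in groups.items():
            if g == control:
                continue
            if sd == 0 or len(vals) == 0:
                if sd == 0:
                    warnings.warn(f"zero control variance for {metric!r}; "
                                  "z-score null-coded")
                z = np.nan
            else:
                z = (vals.mean() - ctrl.mean()) / sd
            rows.append({"group": g, "metric": metric, "z": z,
                         "n": len(vals), "n_control": len(ctrl)})
    return pd.DataFrame(rows)


def anova_with_correction(table: pd.DataFrame, control: str | None = None,
                          method: str = "bonferroni",
                          metrics: list[str] | None = None,
                          alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA per metric with corrected follow-up comparisons.

    ``method="bonferroni"`` runs all pairwise two-sample t-tests and
    multiplies each p by the number of comparisons (clipped at 1);
    ``method="dunnett"`` compares every treatment against ``control``
    using the multivariate-t Dunnett distribution. Groups with fewer than
    two observations are excluded with a warning.
    """
    if method not in ("bonferroni", "dunnett"):
        raise ValueError("method must be 'bonferroni' or 'dunnett'")
    if method == "dunnett" and control is None:
        raise ValueError("Dunnett comparisons need a control group")
    metrics = metrics or [m for m in METRIC_COLUMNS if m in table.columns]

    rows = []
    for metric in metrics:
        groups = _group_values(table, metric)
        small = [g for g, v in groups.items() if len(v) < 2]
        if small:
            warnings.warn(f"excluding groups with <2 observations for "
                          f"{metric!r}: {small}")
            groups = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(groups) < 2:
            continue
        names = list(groups)
        samples = [groups[g] for g in names]
        if any(v.std(ddof=1) == 0 for v in samples) and \
                all(np.allclose(v, samples[0][0]) for v in samples):
            anova_p = np.nan
        else:
            anova_p = float(sps.f_oneway(*samples).pvalue)

        if method == "bonferroni":
            pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
            m = len(pairs)
            for a, b in pairs:
                raw = float(sps.ttest_ind(groups[a], groups[b]).pvalue)
                corr = min(1.0, raw * m)
                rows.append({"metric": metric, "comparison": f"{a} vs {b}",
                             "group": b if a == control else a,
                             "anova_p": anova_p, "raw_p": raw,
                             "corrected_p": corr,
                             "significant": corr < alpha})
        else:
            if control not in groups:
                warnings.warn(f"control excluded for {metric!r}; skipping")
                continue
            treats = [g for g in names if g != control]
            res = sps.dunnett(*[groups[g] for g in treats],
                              control=groups[control])
            for g, corr in zip(treats, np.atleast_1d(res.pvalue)):
                raw = float(sps.ttest_ind(groups[g], groups[control]).pvalue)
                rows.append({"metric": metric, "comparison": f"{g} vs {control}",
                             "group": g, "anova_p": anova_p, "raw_p": raw,
                             "corrected_p": float(corr),
                             "significant": float(corr) < alpha})
    return pd.DataFrame(rows)
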