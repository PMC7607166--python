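"""Median-split survival stratification: Kaplan-Meier curves and log-rank.

For each gene, samples are split at the median of its normalized expression
(values equal to the median go to the low group, so "high" is strictly above
the median) and the two groups' survival distributions are compared with the
standard two-group log-rank test (chi-square, 1 df).  Estimation is
delegated to lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from raceqtl.errors import ConfigError


@dataclass
class SurvivalCurve:
    """Product-limit estimate at distinct event times.

    S is evaluated just after each event time; S before the first event is 1.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def s_at(self, t: float) -> float:
        """S(t), right-continuous step function."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float
    p: float


def median_split(values: pd.Series) -> tuple[list, list]:
    """Split sample ids at the median: low = values <= median, high = rest."""
    if len(values) < 4:
        raise ConfigError("median split needs at least 4 samples")
    v = values.astype(float)
    med = float(v.median())
    if v.nunique() == 1:
        raise ConfigError("constant expression: median split undefined")
    low = list(v.index[v <= med])
    high = list(v.index[v > med])
    return low, high


def km_curve(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i/n_i)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t < 0).any():
        raise ConfigError("negative survival times")
    if not np.isin(e, [0, 1]).all():
        raise ConfigError("events must be binary")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    ev = table[table["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    return SurvivalCurve(
        event_times=event_times,
        survival=surv,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        events=ev["observed"].to_numpy(dtype=int),
    )


def logrank_test(group_a: tuple, group_b: tuple) -> LogRankResult:
    """Two-group log-rank test; degenerate risk sets give p = 1 with a warning."""
    ta, ea = np.asarray(group_a[0], float), np.asarray(group_a[1], int)
    tb, eb = np.asarray(group_b[0], float), np.asarray(group_b[1], int)
    if len(ta) == 0 or len(tb) == 0:
        raise ConfigError("both groups must be nonempty")
    if ea.sum() + eb.sum() == 0:
        raise ConfigError("at least one event is required")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    stat, p = float(res.test_statistic), float(res.p_value)
    if not np.isfinite(stat) or not np.isfinite(p):
        warnings.warn("log-rank variance is zero; no comparable risk sets", stacklevel=2)
        return LogRankResult(statistic=0.0, p=1.0)
    return LogRankResult(statistic=stat, p=p)


def survival_screen(
    norm_matrix: pd.DataFrame, clinical: pd.DataFrame, genes=None
) -> pd.DataFrame:
    """Median-split log-rank screen over genes.

    Returns gene_id-indexed statistic, p, BH padj across screened genes, and
    direction_of_effect: the sign of S_high - S_low at the last common event
    time (negative means high expression tracks worse survival).
    """
    clin = clinical.set_index("sample_id")
    samples = [s for s in norm_matrix.columns if s in clin.index]
    if genes is None:
        genes = list(norm_matrix.index)
    rows = []
    for gene in genes:
        expr = norm_matrix.loc[gene, samples]
        try:
            low, high = median_split(expr)
        except ConfigError:
            rows.append((gene, np.nan, 1.0, 0.0))
            continue
        tl, el = clin.loc[low, "time"].to_numpy(), clin.loc[low, "event"].to_numpy()
        th, eh = clin.loc[high, "time"].to_numpy(), clin.loc[high, "event"].to_numpy()
        res = logrank_test((tl, el), (th, eh))
        curve_l, curve_h = km_curve(tl, el), km_curve(th, eh)
        if len(curve_l.event_times) and len(curve_h.event_times):
            t_last = min(curve_l.event_times[-1], curve_h.event_times[-1])
            diff = curve_h.s_at(t_last) - curve_l.s_at(t_last)
        else:
            diff = 0.0
        rows.append((gene, res.statistic, res.p, float(np.sign(diff))))
    out = pd.DataFrame(
        rows, columns=["gene_id", "logrank_statistic", "p", "direction_of_effect"]
    ).set_index("gene_id")
    out["padj"] = bh_on_valid(out["p"])
    return out[["logrank_statistic", "p", "padj", "direction_of_effect"]]


def bh_on_valid(p: pd.Series) -> pd.Series:
    """BH adjust, passing through NaN rows untouched."""
    from raceqtl.de import bh_adjust

    out = pd.Series(np.nan, index=p.index)
    mask = p.notna()
    if mask.any():
        out[mask] = bh_adjust(p[mask].to_numpy())
    return out
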