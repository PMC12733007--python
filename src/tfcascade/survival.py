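"""Kaplan-Meier estimation and log-rank comparison of altered vs unaltered.

Product-limit curves and the unweighted log-rank test are delegated to
lifelines; medians are the smallest time at which the survival function
drops to <= 0.5 (no interpolation). Across the four endpoints the p-values
are Benjamini-Hochberg adjusted into q-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

ENDPOINTS = ("disease_specific", "overall", "progression_free", "disease_free")
GROUPS = ("altered", "unaltered")

ENDPOINT_LABELS = {
    "disease_specific": "Disease Specific",
    "overall": "Overall",
    "progression_free": "Progression Free",
    "disease_free": "Disease Free",
}


@dataclass
class KMResult:
    """Stepwise survival curve with its median (NaN if S never reaches 0.5)."""

    times: np.ndarray
    survival: np.ndarray
    median: float
    n: int
    n_events: int


def load_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"patient_id", "endpoint", "months", "event", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing column(s): {sorted(missing)}")
    bad_ep = set(df["endpoint"]) - set(ENDPOINTS)
    if bad_ep:
        raise ValueError(f"unknown endpoint(s): {sorted(bad_ep)}")
    bad_gr = set(df["group"]) - set(GROUPS)
    if bad_gr:
        raise ValueError(f"unknown group(s): {sorted(bad_gr)}")
    if (df["months"] < 0).any():
        raise ValueError("negative follow-up months")
    return df


def km_estimate(records: pd.DataFrame) -> KMResult:
    """Product-limit estimate for one endpoint+group stratum."""
    if len(records) == 0:
        raise ValueError("no records")
    kmf = KaplanMeierFitter()
    kmf.fit(records["months"], event_observed=records["event"])
    sf = kmf.survival_function_
    median = float(kmf.median_survival_time_)  # inf when S stays > 0.5
    return KMResult(
        times=sf.index.to_numpy(dtype=float),
        survival=sf.iloc[:, 0].to_numpy(dtype=float),
        median=median if np.isfinite(median) else float("nan"),
        n=int(len(records)),
        n_events=int(records["event"].sum()),
    )


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Unweighted two-sample log-rank statistic (1 df) and its p-value."""
    if group_a["event"].sum() < 1 or group_b["event"].sum() < 1:
        raise ValueError("each group needs at least one observed event")
    res = _ll_logrank(group_a["months"], group_b["months"],
                      event_observed_A=group_a["event"],
                      event_observed_B=group_b["event"])
    return float(res.test_statistic), float(res.p_value)


def endpoint_qvalues(p_by_endpoint: Mapping[str, float]) -> dict[str, float]:
    """BH step-up across exactly the four endpoints."""
    if set(p_by_endpoint) != set(ENDPOINTS):
        raise ValueError(f"need exactly the endpoints {ENDPOINTS}, "
                         f"got {sorted(p_by_endpoint)}")
    keys = list(ENDPOINTS)
    q = bh_adjust([p_by_endpoint[k] for k in keys])
    return dict(zip(keys, (float(v) for v in q)))


def analyze_endpoints(records: pd.DataFrame) -> pd.DataFrame:
    """Per-endpoint log-rank comparison of altered vs unaltered, with q-values.

    Output columns: Survival Type, Number of Patients, p-Value, q-Value.
    """
    p_by_endpoint: dict[str, float] = {}
    n_by_endpoint: dict[str, int] = {}
    chi2_by_endpoint: dict[str, float] = {}
    for ep in ENDPOINTS:
        sub = records[records["endpoint"] == ep]
        a = sub[sub["group"] == "altered"]
        u = sub[sub["group"] == "unaltered"]
        chi2, p = logrank_test(a, u)
        p_by_endpoint[ep] = p
        chi2_by_endpoint[ep] = chi2
        n_by_endpoint[ep] = len(sub)
    q = endpoint_qvalues(p_by_endpoint)
    return pd.DataFrame({
        "Survival Type": [ENDPOINT_LABELS[ep] for ep in ENDPOINTS],
        "Number of Patients": [n_by_endpoint[ep] for ep in ENDPOINTS],
        "chi2": [chi2_by_endpoint[ep] for ep in ENDPOINTS],
        "p-Value": [p_by_endpoint[ep] for ep in ENDPOINTS],
        "q-Value": [q[ep] for ep in ENDPOINTS],
    })


def group_summary(records: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    """Per-group case/event counts and KM median for one endpoint."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"unknown endpoint {endpoint!r}")
    sub = records[records["endpoint"] == endpoint]
    rows = []
    for group in GROUPS:
        g = sub[sub["group"] == group]
        if len(g) == 0:
            logger.warning("group %r empty for endpoint %r; omitted",
                           group, endpoint)
            continue
        km = km_estimate(g)
        rows.append((f"{group.capitalize()} group", km.n, km.n_events,
                     km.median))
    return pd.DataFrame(rows, columns=["Group", "Number of Cases, Total",
                                       "Number of Events",
                                       "Median Months"])


def plot_km(records: pd.DataFrame, endpoint: str, path) -> None:
    """Optional step-function plot of both group curves (PNG/PDF by suffix)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    sub = records[records["endpoint"] == endpoint]
    for group in GROUPS:
        g = sub[sub["group"] == group]
        if len(g) == 0:
            continue
        kmf = KaplanMeierFitter(label=group)
        kmf.fit(g["months"], event_observed=g["event"])
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("months")
    ax.set_ylabel("S(t)")
    ax.set_title(ENDPOINT_LABELS[endpoint])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
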