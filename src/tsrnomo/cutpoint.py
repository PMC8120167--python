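"""Best-P-value dichotomization of a continuous marker against survival.

Emulates the X-tile procedure: evaluate the two-group log-rank statistic at
every admissible split of the observed marker values and return the cutoff
that maximizes it.  Because the cutoff is selected to maximize the
statistic, the naive P value is anti-conservative; the Miller-Siegmund
corrected P for maximally selected statistics is reported alongside it.
A two-cutpoint extension searches ordered pairs of splits for three risk
groups by the overall three-group log-rank statistic.

Candidate cutoffs are midpoints between consecutive distinct observed
values; a marker equal to the cutoff goes to the low group (the <=/>
convention used for the 55.5% TSR cutoff).  Ties in the statistic break
toward the smallest cutoff, so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "CutpointResult",
    "TwoCutpointResult",
    "optimal_cutpoint",
    "optimal_two_cutpoints",
    "categorize",
    "miller_siegmund_p",
]


@dataclass(frozen=True)
class CutpointResult:
    cutoff: float
    chi2: float
    p_raw: float
    p_adjusted: float
    group_sizes: tuple[int, int]  # (low, high)


@dataclass(frozen=True)
class TwoCutpointResult:
    cutoffs: tuple[float, float]
    chi2: float
    p_raw: float
    group_sizes: tuple[int, int, int]  # (I, II, III)


def categorize(marker: float | np.ndarray, cutoff: float) -> np.ndarray | str:
    """'low' iff marker <= cutoff, else 'high' (boundary goes to low)."""
    arr = np.asarray(marker)
    out = np.where(arr <= cutoff, "low", "high")
    return out.item() if out.ndim == 0 else out


def miller_siegmund_p(chi2: float, eps_low: float, eps_high: float) -> float:
    """Miller-Siegmund corrected P for a maximally selected chi-square.

    ``eps_low``/``eps_high`` bound the fraction of observations allowed in
    the low group over the search window.  The approximation is accurate
    for large statistics; it is clamped into (0, 1].
    """
    if chi2 <= 0:
        return 1.0
    b = float(np.sqrt(chi2))
    phi = sps.norm.pdf(b)
    log_term = np.log((eps_high * (1.0 - eps_low)) / (eps_low * (1.0 - eps_high)))
    p = phi * (b - 1.0 / b) * log_term + 4.0 * phi / b
    return float(min(max(p, 0.0), 1.0))


def _validate(marker, time, event):
    marker = np.asarray(marker, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if not (len(marker) == len(time) == len(event)):
        raise ValueError("marker, time, event must have equal length")
    if np.any(time < 0):
        raise ValueError("time must be non-negative")
    if event.sum() == 0:
        raise ValueError("cutpoint search requires at least one event")
    if len(np.unique(marker)) < 2:
        raise ValueError("cutpoint search requires >= 2 distinct marker values")
    return marker, time, event


def _prefix_logrank_tables(marker, time, event):
    """Per-event-time totals and prefix (low-group) tables, marker-sorted.

    Returns (order, cutcand_m, d, N, n1, d1, cum_d1) where for each event
    time j and prefix size m: ``n1[j, m-1]`` patients of the first m (by
    marker) are at risk and ``d1[j, m-1]`` of them die at t_j.
    """
    order = np.argsort(marker, kind="stable")
    t_s, e_s = time[order], event[order]
    uniq_t = np.unique(time[event == 1])
    at_risk = t_s[None, :] >= uniq_t[:, None]  # k x n
    dies = (t_s[None, :] == uniq_t[:, None]) & (e_s[None, :] == 1)
    N = at_risk.sum(axis=1).astype(float)
    d = dies.sum(axis=1).astype(float)
    n1 = np.cumsum(at_risk, axis=1).astype(float)  # prefix at-risk
    d1 = np.cumsum(dies, axis=1).astype(float)  # prefix deaths
    return order, uniq_t, d, N, n1, d1


def _two_group_chi2(d, N, n1_m, d1_m):
    """Log-rank chi-square for the prefix group, vectorized over prefixes."""
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = n1_m / N[:, None]
        E1 = (d[:, None] * frac).sum(axis=0)
        safe = N > 1
        cj = np.where(safe, d * (N - d) / np.maximum(N - 1, 1.0), 0.0)
        V = (cj[:, None] * frac * (1.0 - frac)).sum(axis=0)
        O1 = d1_m.sum(axis=0)
        chi2 = np.where(V > 0, (O1 - E1) ** 2 / np.where(V > 0, V, 1.0), 0.0)
    return chi2


def optimal_cutpoint(
    marker, time, event, min_group_frac: float = 0.10
) -> CutpointResult:
    """Best-P-value cutoff of a continuous marker for survival.

    Scans every split between consecutive distinct marker values whose two
    groups each hold at least ``min_group_frac`` of the cohort, computes
    the two-group log-rank statistic for each, and returns the argmax with
    the raw and Miller-Siegmund corrected P values.
    """
    marker, time, event = _validate(marker, time, event)
    n = len(marker)
    if n < 20:
        raise ValueError("cutpoint search requires at least 20 patients")
    order, _, d, N, n1, d1 = _prefix_logrank_tables(marker, time, event)
    m_sorted = marker[order]
    # candidate split after position m-1 requires a strict value change
    change = np.flatnonzero(np.diff(m_sorted)) + 1  # prefix sizes m
    min_n = int(np.ceil(min_group_frac * n))
    m_cand = change[(change >= min_n) & (n - change >= min_n)]
    if m_cand.size == 0:
        raise ValueError("no admissible split satisfies the group-size floor")
    chi2 = _two_group_chi2(d, N, n1[:, m_cand - 1], d1[:, m_cand - 1])
    best = int(np.argmax(chi2))  # first max -> smallest cutoff on ties
    m = int(m_cand[best])
    cutoff = float((m_sorted[m - 1] + m_sorted[m]) / 2.0)
    best_chi2 = float(chi2[best])
    p_raw = float(sps.chi2.sf(best_chi2, df=1))
    p_adj = miller_siegmund_p(best_chi2, min_group_frac, 1.0 - min_group_frac)
    return CutpointResult(
        cutoff=cutoff,
        chi2=best_chi2,
        p_raw=p_raw,
        p_adjusted=float(max(p_adj, p_raw)),
        group_sizes=(m, n - m),
    )


def optimal_two_cutpoints(
    marker, time, event, min_group_frac: float = 0.10
) -> TwoCutpointResult:
    """Grid search for two ordered cutoffs maximizing the 3-group log-rank.

    Every admissible ordered pair of splits is scored by the overall
    three-group log-rank chi-square (df = 2); the lexicographically
    smallest argmax pair is returned.
    """
    marker, time, event = _validate(marker, time, event)
    n = len(marker)
    if n < 30:
        raise ValueError("two-cutpoint search requires at least 30 patients")
    order, _, d, N, n1, d1 = _prefix_logrank_tables(marker, time, event)
    m_sorted = marker[order]
    change = np.flatnonzero(np.diff(m_sorted)) + 1
    min_n = int(np.ceil(min_group_frac * n))

    safe_N = np.maximum(N - 1.0, 1.0)
    cj = np.where(N > 1, d * (N - d) / safe_N, 0.0)
    cum_d1 = d1.sum(axis=0)  # observed deaths in prefix m (index m-1)
    cum_E = (d[:, None] * n1 / N[:, None]).sum(axis=0)

    best = None  # (chi2, m1, m2)
    for m1 in change[(change >= min_n) & (n - change >= 2 * min_n)]:
        m2_cand = change[(change >= m1 + min_n) & (n - change >= min_n)]
        if m2_cand.size == 0:
            continue
        i1, i2 = m1 - 1, m2_cand - 1
        p1 = n1[:, i1] / N  # k
        p2 = (n1[:, i2] - n1[:, i1][:, None]) / N[:, None]  # k x len(m2)
        U1 = cum_d1[i1] - cum_E[i1]
        U2 = (cum_d1[i2] - cum_d1[i1]) - (cum_E[i2] - cum_E[i1])
        V11 = float((cj * p1 * (1 - p1)).sum())
        V22 = (cj[:, None] * p2 * (1 - p2)).sum(axis=0)
        V12 = -(cj[:, None] * p1[:, None] * p2).sum(axis=0)
        det = V11 * V22 - V12**2
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.where(
                det > 1e-12,
                (V22 * U1**2 - 2 * V12 * U1 * U2 + V11 * U2**2) / np.where(det > 1e-12, det, 1.0),
                0.0,
            )
        j = int(np.argmax(chi2))
        if best is None or chi2[j] > best[0] + 1e-12:
            best = (float(chi2[j]), int(m1), int(m2_cand[j]))
    if best is None:
        raise ValueError("no admissible pair of splits satisfies the group-size floor")
    chi2_best, m1, m2 = best
    c1 = float((m_sorted[m1 - 1] + m_sorted[m1]) / 2.0)
    c2 = float((m_sorted[m2 - 1] + m_sorted[m2]) / 2.0)
    return TwoCutpointResult(
        cutoffs=(c1, c2),
        chi2=chi2_best,
        p_raw=float(sps.chi2.sf(chi2_best, df=2)),
        group_sizes=(m1, m2 - m1, n - m2),
    )
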