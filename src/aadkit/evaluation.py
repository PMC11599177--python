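"""From tracking curves to the study statistics.

- tracking magnitude: mean reconstruction correlation over the analysis
  lag windows (default 120-270 ms, where envelope-following responses are
  strongest);
- decoding accuracy: percentage of trials whose reconstruction correlates
  more with the attended than with the ignored envelope, with a binomial
  chance threshold at a given alpha;
- condition contrasts: Wilcoxon signed-rank Z (normal approximation with
  tie correction and continuity correction);
- robustness: Spearman rank correlations of per-subject tracking between
  conditions, with seeded permutation p-values;
- street segments: per-subject quiet vs busy 2-min tracking pairs from a
  walking recording, delimited by street entry/exit markers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .decoding import TrackingCurve, LagWindowDesign

__all__ = [
    "ContrastResult",
    "RankMatrix",
    "select_analysis_windows",
    "tracking_magnitude",
    "decoding_accuracy",
    "chance_level",
    "wilcoxon_signed_rank",
    "condition_summary",
    "rank_robustness",
    "street_segment_tracking",
]


@dataclass
class ContrastResult:
    """Wilcoxon signed-rank contrast (normal approximation)."""

    z: float
    p: float
    n: int


@dataclass
class RankMatrix:
    """Condition x condition Spearman coefficients with permutation p-values."""

    conditions: list[str]
    r: np.ndarray
    p: np.ndarray


def select_analysis_windows(
    design: LagWindowDesign, lo: float = 120.0, hi: float = 270.0
) -> np.ndarray:
    """Indices of lag windows whose start lies in [lo, hi] ms (inclusive)."""
    sel = np.flatnonzero((design.starts_ms >= lo) & (design.starts_ms <= hi))
    return sel


def tracking_magnitude(
    curve: TrackingCurve, windows: np.ndarray
) -> tuple[float, float | None]:
    """Mean correlation over the selected windows, per stream."""
    windows = np.asarray(windows, dtype=np.intp)
    if windows.size == 0:
        raise ValueError("empty analysis-window set")
    r_att = float(curve.r_att[windows].mean())
    r_ign = None if curve.r_ign is None else float(curve.r_ign[windows].mean())
    return r_att, r_ign


def decoding_accuracy(r_att: np.ndarray, r_ign: np.ndarray) -> float:
    """Percent of trials with stronger attended than ignored correlation.

    Ties count as incorrect (conservative; exact float ties have measure
    zero anyway).
    """
    r_att = np.asarray(r_att, dtype=float)
    r_ign = np.asarray(r_ign, dtype=float)
    if r_att.shape != r_ign.shape or r_att.size == 0:
        raise ValueError("r_att and r_ign must be equal-length, non-empty")
    return 100.0 * np.mean(r_att > r_ign)


def chance_level(n_trials: int, alpha: float = 0.05) -> float:
    """Binomial significance threshold on decoding accuracy, in percent.

    The smallest trial count ``k`` whose Binomial(n, 0.5) CDF reaches
    ``1 - alpha``, expressed as ``100 k / n`` — accuracies above this are
    significantly better than coin flipping at level ``alpha``.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    k = int(sps.binom.ppf(1.0 - alpha, n_trials, 0.5))
    return 100.0 * k / n_trials


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> ContrastResult:
    """Paired Wilcoxon signed-rank test, normal approximation.

    Zero differences are dropped; absolute differences are ranked with
    average ranks on ties; ``Z = (W - mu_W) / sigma_W`` uses the
    tie-corrected variance and a 0.5 continuity correction, with W the sum
    of positive-difference ranks.  The two-sided p comes from the normal
    tail.  The sign of Z follows the sign of the x - y shift.
    """
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return ContrastResult(z=0.0, p=1.0, n=0)
    ranks = sps.rankdata(np.abs(d))
    w_pos = ranks[d > 0].sum()
    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over tie groups
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / 48.0
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if sigma2 <= 0:
        return ContrastResult(z=0.0, p=1.0, n=n)
    dev = w_pos - mu
    cc = 0.5 * np.sign(dev)
    z = (dev - cc) / np.sqrt(sigma2)
    p = 2.0 * sps.norm.sf(abs(z))
    return ContrastResult(z=float(z), p=float(min(p, 1.0)), n=int(n))


def condition_summary(
    curves: list[TrackingCurve], windows: np.ndarray
) -> pd.DataFrame:
    """Per subject x condition mean tracking over the analysis windows.

    Returns a tidy frame with columns subject, block, condition, r_att,
    r_ign (NaN for single-speaker trials), n_trials.
    """
    rows = []
    for c in curves:
        t = c.trial
        r_att, r_ign = tracking_magnitude(c, windows)
        rows.append(
            {
                "subject": t.subject if t else -1,
                "block": t.block if t else "",
                "condition": t.condition if t else "",
                "r_att": r_att,
                "r_ign": np.nan if r_ign is None else r_ign,
            }
        )
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["subject", "block", "condition"], as_index=False)
        .agg(r_att=("r_att", "mean"), r_ign=("r_ign", "mean"), n_trials=("r_att", "size"))
    )
    return out


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra = sps.rankdata(a)
    rb = sps.rankdata(b)
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    den = np.sqrt((ra @ ra) * (rb @ rb))
    if den == 0:
        return 0.0
    return float(ra @ rb / den)


def rank_robustness(
    summary: pd.DataFrame,
    conditions: list[str] | None = None,
    n_perm: int = 10000,
    seed: int = 0,
) -> RankMatrix:
    """Between-condition rank correlations of per-subject tracking.

    Subjects are ranked by attended tracking within each condition
    (average ranks on ties); each condition pair gets the Pearson
    correlation of the rank vectors (Spearman's rho) and a two-sided
    permutation p-value obtained by shuffling one ranking (``n_perm``
    draws, seeded).  Only subjects present in both conditions enter a
    pair.
    """
    if conditions is None:
        conditions = sorted(summary["condition"].unique())
    rng = np.random.default_rng(seed)
    k = len(conditions)
    r = np.eye(k)
    p = np.zeros((k, k))
    by_cond = {
        c: summary[summary["condition"] == c].set_index("subject")["r_att"]
        for c in conditions
    }
    for i in range(k):
        for j in range(i + 1, k):
            a, b = by_cond[conditions[i]], by_cond[conditions[j]]
            common = a.index.intersection(b.index)
            if len(common) < 3:
                raise ValueError(
                    f"fewer than 3 shared subjects between {conditions[i]!r} "
                    f"and {conditions[j]!r}"
                )
            av, bv = a.loc[common].to_numpy(), b.loc[common].to_numpy()
            obs = _spearman(av, bv)
            perm = np.empty(n_perm)
            bperm = bv.copy()
            for t in range(n_perm):
                rng.shuffle(bperm)
                perm[t] = _spearman(av, bperm)
            pv = (1.0 + np.sum(np.abs(perm) >= abs(obs) - 1e-12)) / (n_perm + 1.0)
            r[i, j] = r[j, i] = obs
            p[i, j] = p[j, i] = pv
    return RankMatrix(list(conditions), r, p)


def street_segment_tracking(
    curves: list[TrackingCurve],
    truths: dict[int, "GroundTruth"],  # noqa: F821
    windows: np.ndarray,
    segment_length: float = 120.0,
    min_overlap: float = 30.0,
) -> pd.DataFrame:
    """Per-subject quiet- vs busy-street tracking from a walking recording.

    The quiet segment is the first ``segment_length`` seconds of the
    recording; the busy segment starts at the street-entry marker.  A
    trial contributes to a segment when at least ``min_overlap`` seconds
    of it (half a trial by default) lie inside.  Returns one row per
    subject with mean attended tracking in each segment.
    """
    rows: dict[int, dict[str, list[float]]] = {}
    for c in curves:
        t = c.trial
        subj = t.subject
        if subj not in truths:
            raise ValueError(f"no ground truth markers for subject {subj}")
        truth = truths[subj]
        if truth.street_entry is None or truth.street_exit is None:
            raise ValueError(f"subject {subj}: missing street entry/exit markers")
        quiet = (0.0, segment_length)
        busy = (truth.street_entry, truth.street_entry + segment_length)
        t0, t1 = t.start_time, t.start_time + t.duration
        r_att, _ = tracking_magnitude(c, windows)
        entry = rows.setdefault(subj, {"quiet": [], "busy": []})
        if min(t1, quiet[1]) - max(t0, quiet[0]) >= min_overlap:
            entry["quiet"].append(r_att)
        if min(t1, busy[1]) - max(t0, busy[0]) >= min_overlap:
            entry["busy"].append(r_att)

    out = []
    for subj, d in sorted(rows.items()):
        out.append(
            {
                "subject": subj,
                "quiet_r": float(np.mean(d["quiet"])) if d["quiet"] else np.nan,
                "busy_r": float(np.mean(d["busy"])) if d["busy"] else np.nan,
                "n_quiet": len(d["quiet"]),
                "n_busy": len(d["busy"]),
            }
        )
    return pd.DataFrame(out)
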