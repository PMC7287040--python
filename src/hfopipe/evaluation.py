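"""Scoring of detections against ground truth, and SOZ concordance.

Benchmark scoring uses the confidence-interval (CI) convention: a 100 ms
window centered on every simulated HFO-containing event (spike-only
events define no CI).  A CI holding at least one detection peak is one
true positive, an empty CI one false negative, and every detection peak
outside all CIs one false positive.  Metrics:

    Sens = TP / (TP + FN)
    Prec = TP / (TP + FP)        (1 when TP + FP = 0)
    F1   = 2 TP / (2 TP + FN + FP)  (0 when TP + FP = 0)

SOZ concordance ranks channels by their HFO occurrence rate, calls the
top N "HFO channels", and evaluates

    Sens_SOZ = CH_HFO in SOZ / (CH_HFO in SOZ + CH_Non-HFO in SOZ)
    Spec_SOZ = CH_Non-HFO not in SOZ / (CH_Non-HFO not in SOZ + CH_HFO not in SOZ)

over N = 1..n_channels, tracing an ROC whose area is computed by the
trapezoid rule (anchored at (0,0)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BenchmarkScore",
    "SozResult",
    "score_detections",
    "summarize_benchmark",
    "soz_metrics",
    "soz_roc_auc",
    "wilcoxon_signed_rank",
    "paired_t_test",
]


@dataclass
class BenchmarkScore:
    channel: str
    tp: int
    fp: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0

    @property
    def precision(self) -> float:
        # convention: 1 when nothing was detected at all
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def f1(self) -> float:
        # convention: 0 when nothing was detected at all
        if self.tp + self.fp == 0:
            return 0.0
        return 2 * self.tp / (2 * self.tp + self.fn + self.fp)


def score_detections(detection_peaks: np.ndarray, truth: pd.DataFrame,
                     ci_len: float = 0.100, channel: str = "ch",
                     hfo_type_ids: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
                     ) -> BenchmarkScore:
    """CI-based TP/FP/FN scoring of one channel.

    detection_peaks: peak times (s) of the candidate events.
    truth: ground-truth log with columns center_s and type_id; only
    HFO-containing types define CIs.  A detection "falls in" a CI iff its
    peak lies in the closed window.  Overlapping CIs violate the simulator
    spacing invariant and raise.
    """
    peaks = np.sort(np.asarray(detection_peaks, dtype=float))
    centers = np.sort(
        truth.loc[truth["type_id"].isin(hfo_type_ids), "center_s"].to_numpy())
    half = ci_len / 2
    if len(centers) > 1 and np.min(np.diff(centers)) < ci_len:
        raise ValueError("overlapping confidence intervals in ground truth")
    tp = 0
    in_any_ci = np.zeros(len(peaks), dtype=bool)
    for c in centers:
        inside = (peaks >= c - half) & (peaks <= c + half)
        if inside.any():
            tp += 1  # multiple detections in one CI count once
        in_any_ci |= inside
    fn = len(centers) - tp
    fp = int((~in_any_ci).sum())
    return BenchmarkScore(channel=channel, tp=tp, fp=fp, fn=fn)


def summarize_benchmark(scores: list[BenchmarkScore],
                        snr_of: dict[str, float]) -> pd.DataFrame:
    """Per-SNR median and range of the three metrics (percent)."""
    rows = []
    for s in scores:
        rows.append({"channel": s.channel, "snr_db": snr_of[s.channel],
                     "sensitivity": 100 * s.sensitivity,
                     "precision": 100 * s.precision, "f1": 100 * s.f1})
    df = pd.DataFrame(rows)
    out = []
    for snr, grp in df.groupby("snr_db"):
        row = {"snr_db": snr, "n_channels": len(grp)}
        for metric in ("sensitivity", "precision", "f1"):
            row[f"{metric}_median"] = grp[metric].median()
            row[f"{metric}_min"] = grp[metric].min()
            row[f"{metric}_max"] = grp[metric].max()
        out.append(row)
    return pd.DataFrame(out).sort_values("snr_db").reset_index(drop=True)


# ---------------------------------------------------------------------------
# SOZ concordance
# ---------------------------------------------------------------------------

@dataclass
class SozResult:
    rates: pd.Series           # channel -> rate, input order preserved
    soz: list[str]
    roc: pd.DataFrame          # columns: n_cutoff, sensitivity, one_minus_spec
    auc: float


def _rank_channels(rates: pd.Series) -> list[str]:
    """Channels by descending rate; ties keep the stable input order."""
    order = np.argsort(-rates.to_numpy(), kind="stable")
    return [rates.index[i] for i in order]


def soz_metrics(rates: pd.Series, soz: list[str] | set[str],
                n_cutoff: int) -> tuple[float, float]:
    """Sens_SOZ and Spec_SOZ at one cutoff N (top-N channels = CH_HFO)."""
    soz = set(soz)
    if not soz:
        raise ValueError("no SOZ channels given")
    if not 1 <= n_cutoff <= len(rates):
        raise ValueError("cutoff must be in 1..n_channels")
    ranked = _rank_channels(rates)
    ch_hfo = set(ranked[:n_cutoff])
    ch_non = set(ranked[n_cutoff:])
    sens = len(ch_hfo & soz) / (len(ch_hfo & soz) + len(ch_non & soz))
    non_soz_non_hfo = len(ch_non - soz)
    non_soz_hfo = len(ch_hfo - soz)
    denom = non_soz_non_hfo + non_soz_hfo
    spec = non_soz_non_hfo / denom if denom else 1.0
    return sens, spec


def soz_roc_auc(rates: pd.Series, soz: list[str] | set[str]) -> SozResult:
    """ROC over N = 1..n_channels and its trapezoid AUC.

    The curve is anchored at (0,0); with N = n_channels it ends at (1,1)
    whenever at least one channel lies outside the SOZ.
    """
    soz = set(soz)
    if rates.nunique() == 1:
        warnings.warn("constant rates across channels: degenerate ranking")
    points = [(0.0, 0.0)]
    for n in range(1, len(rates) + 1):
        sens, spec = soz_metrics(rates, soz, n)
        points.append((1.0 - spec, sens))
    roc = pd.DataFrame(points, columns=["one_minus_spec", "sensitivity"])
    roc.insert(0, "n_cutoff", np.arange(len(points)))
    auc = float(np.trapezoid(roc["sensitivity"], roc["one_minus_spec"]))
    return SozResult(rates=rates, soz=sorted(soz), roc=roc, auc=auc)


# ---------------------------------------------------------------------------
# Group comparisons (thin wrappers, for cohort-style summaries)
# ---------------------------------------------------------------------------

def wilcoxon_signed_rank(a, b):
    return stats.wilcoxon(a, b)


def paired_t_test(a, b):
    return stats.ttest_rel(a, b)
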