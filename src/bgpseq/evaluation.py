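"""Uncertainty-evaluation suite for Monte-Carlo predictive distributions.

Covers the full battery used to judge probabilistic risk models here:

* ranking metrics (AUROC, average precision) with patient-level bootstrap CIs;
* accuracy / AUROC as a function of confidence (rejection curves), where the
  predicted label is argmax over the two classes and confidence is the larger
  of the mean predictive probability and its complement;
* calibration curves with 95% epistemic bands: each Monte-Carlo weight draw is
  treated as an independent model, one reliability curve per draw, and the
  band is the 2.5/97.5 percentile envelope across draws;
* the DIV statistic: the KL divergence between Gaussians fitted to the
  predictive-std distributions of incorrect (F = FP or FN) and correct
  (T = TP or TN) predictions, per prediction sign — larger is better;
* embedding-entropy tables ranking tokens by the summed Gaussian entropy of
  their variational embedding rows (lower entropy = more certain association).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .synthetic_ehr import SPECIAL_TOKENS, Vocabulary
from .train_infer import PredictiveSummary
from .variational import gaussian_kl


@dataclass
class UncertaintySplit:
    """Predictive stds partitioned by prediction sign and correctness."""

    tp: np.ndarray
    fp: np.ndarray
    tn: np.ndarray
    fn: np.ndarray
    threshold: float = 0.5

    @classmethod
    def from_summaries(cls, summaries: list[PredictiveSummary],
                       threshold: float = 0.5) -> "UncertaintySplit":
        """Ties at the threshold are predicted negative."""
        mp = np.array([s.mean_probability for s in summaries])
        sp = np.array([s.std_probability for s in summaries])
        y = np.array([s.label for s in summaries])
        pos = mp > threshold
        return cls(
            tp=sp[pos & (y == 1)], fp=sp[pos & (y == 0)],
            tn=sp[~pos & (y == 0)], fn=sp[~pos & (y == 1)],
            threshold=threshold,
        )


@dataclass
class EvaluationReport:
    auroc: float
    auroc_ci: tuple[float, float]
    ap: float
    ap_ci: tuple[float, float]
    confidence_table: pd.DataFrame
    calibration: pd.DataFrame
    div_positive: float | None
    div_negative: float | None
    div_reasons: dict = field(default_factory=dict)
    entropy_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "auroc_ci": list(self.auroc_ci),
            "ap": self.ap,
            "ap_ci": list(self.ap_ci),
            "div_positive": self.div_positive,
            "div_negative": self.div_negative,
            "div_reasons": self.div_reasons,
        }


def ranking_metrics(summaries: list[PredictiveSummary], n_bootstrap: int = 50,
                    seed: int = 0) -> dict:
    """AUROC and AP on mean probabilities, with percentile bootstrap CIs.

    Bootstrap resampling is patient-level with replacement (50 seeded
    resamples by default); degenerate single-class resamples are redrawn.
    """
    y = np.array([s.label for s in summaries])
    p = np.array([s.mean_probability for s in summaries])
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present to rank predictions")
    auroc = float(roc_auc_score(y, p))
    ap = float(average_precision_score(y, p))
    rng = np.random.default_rng(seed)
    boot_auroc, boot_ap = [], []
    n = len(y)
    while len(boot_auroc) < n_bootstrap:
        idx = rng.integers(0, n, size=n)
        if len(np.unique(y[idx])) < 2:
            continue
        boot_auroc.append(roc_auc_score(y[idx], p[idx]))
        boot_ap.append(average_precision_score(y[idx], p[idx]))
    return {
        "auroc": auroc,
        "auroc_ci": (float(np.percentile(boot_auroc, 2.5)),
                     float(np.percentile(boot_auroc, 97.5))),
        "ap": ap,
        "ap_ci": (float(np.percentile(boot_ap, 2.5)),
                  float(np.percentile(boot_ap, 97.5))),
    }


def confidence_curves(summaries: list[PredictiveSummary],
                      thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """Accuracy and AUROC over patients whose confidence exceeds each threshold.

    Confidence is max_k p(y = k | x) = max(p, 1 - p) of the mean predictive
    probability; the predicted label is the argmax (ties at p = 0.5 predicted
    negative).  Rows where no patients survive are marked empty rather than
    raising.
    """
    if thresholds is None:
        thresholds = np.arange(0.5, 1.0, 0.05)
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(thresholds < 0.5) or np.any(thresholds >= 1.0):
        raise ValueError("confidence thresholds must lie in [0.5, 1)")
    mp = np.array([s.mean_probability for s in summaries])
    y = np.array([s.label for s in summaries])
    conf = np.maximum(mp, 1.0 - mp)
    pred = (mp > 0.5).astype(int)
    rows = []
    for tau in thresholds:
        keep = conf >= tau
        n_keep = int(keep.sum())
        row = {"threshold": float(tau), "n_retained": n_keep,
               "accuracy": np.nan, "auroc": np.nan, "no_survivors": n_keep == 0}
        if n_keep:
            row["accuracy"] = float((pred[keep] == y[keep]).mean())
            if len(np.unique(y[keep])) == 2:
                row["auroc"] = float(roc_auc_score(y[keep], mp[keep]))
        rows.append(row)
    return pd.DataFrame(rows)


def calibration_with_bands(summaries: list[PredictiveSummary],
                           n_bins: int = 10) -> pd.DataFrame:
    """Per-bin calibration curve mean and 95% band across Monte-Carlo draws.

    Each MC draw index defines one model: its predicted probabilities are
    binned into `n_bins` equal-width bins on [0, 1] (half-open except the
    last) and the fraction of positives per bin forms one reliability curve.
    The returned table holds, per bin, the across-draw mean and the 2.5th /
    97.5th percentile envelope, plus the mean per-bin count; bins that are
    empty in every draw carry count 0 and NaN curve values.
    """
    if not summaries:
        raise ValueError("no summaries supplied")
    probs = np.stack([s.mc_probabilities for s in summaries])   # n x S
    y = np.array([s.label for s in summaries])
    n_draws = probs.shape[1]
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    curves = np.full((n_draws, n_bins), np.nan)
    counts = np.zeros((n_draws, n_bins))
    for s in range(n_draws):
        binidx = np.clip(np.digitize(probs[:, s], edges[1:-1]), 0, n_bins - 1)
        for b in range(n_bins):
            members = binidx == b
            counts[s, b] = members.sum()
            if members.any():
                curves[s, b] = y[members].mean()
    rows = []
    for b in range(n_bins):
        col = curves[:, b]
        valid = ~np.isnan(col)
        rows.append({
            "bin_low": edges[b], "bin_high": edges[b + 1],
            "mean_count": counts[:, b].mean(),
            "fraction_positive": float(np.mean(col[valid])) if valid.any() else np.nan,
            "band_low": float(np.percentile(col[valid], 2.5)) if valid.any() else np.nan,
            "band_high": float(np.percentile(col[valid], 97.5)) if valid.any() else np.nan,
        })
    return pd.DataFrame(rows)


def div_metric(split: UncertaintySplit) -> tuple[float | None, float | None, dict]:
    """DIV = KL(p(F) || p(T)) per prediction sign, fitting Gaussians to stds.

    F pools the incorrect cell (FP for positive predictions, FN for negative)
    and T the correct one; sample standard deviations use the n-1 denominator.
    A cell with fewer than two members or zero variance makes that sign's DIV
    undefined; the reason is reported instead of a number.
    """
    reasons: dict[str, str] = {}

    def one_sign(f: np.ndarray, t: np.ndarray, sign: str) -> float | None:
        for name, cell in (("incorrect", f), ("correct", t)):
            if len(cell) < 2:
                reasons[sign] = f"{name} cell has fewer than 2 members"
                return None
            if np.std(cell, ddof=1) == 0:
                reasons[sign] = f"{name} cell has zero variance"
                return None
        return gaussian_kl(float(np.mean(f)), float(np.std(f, ddof=1)),
                           float(np.mean(t)), float(np.std(t, ddof=1)))

    div_pos = one_sign(split.fp, split.tp, "positive")
    div_neg = one_sign(split.fn, split.tn, "negative")
    return div_pos, div_neg, reasons


def div_metric_pooled(split: UncertaintySplit) -> float | None:
    """Optional pooled variant: F = FP+FN vs T = TP+TN across both signs."""
    f = np.concatenate([split.fp, split.fn])
    t = np.concatenate([split.tp, split.tn])
    if len(f) < 2 or len(t) < 2:
        return None
    if np.std(f, ddof=1) == 0 or np.std(t, ddof=1) == 0:
        return None
    return gaussian_kl(float(np.mean(f)), float(np.std(f, ddof=1)),
                       float(np.mean(t)), float(np.std(t, ddof=1)))


def gaussian_entropy(sds: np.ndarray) -> float:
    """Sum over dimensions of the Gaussian differential entropy, in nats:
    H = sum_d 1/2 ln(2 pi e sd_d^2)."""
    sds = np.asarray(sds, dtype=float)
    return float(np.sum(0.5 * np.log(2.0 * math.pi * math.e * sds**2)))


def embedding_entropy_table(embedding_block, vocabulary: Vocabulary) -> pd.DataFrame:
    """Rank code tokens by total embedding entropy, most certain first.

    Requires stochastic embeddings; the entropy of token i is the sum across
    embedding dimensions of the Gaussian entropy of its posterior row.
    Special tokens are excluded.  Lower entropy indicates a more certain
    association with the outcome.
    """
    if not getattr(embedding_block, "stochastic", False):
        raise ValueError("embedding entropy is undefined for deterministic embeddings")
    post = embedding_block.tables["code"]
    sds = post.sd
    rows = []
    for tok_id in range(len(SPECIAL_TOKENS), len(vocabulary.tokens)):
        rows.append({
            "token_id": tok_id,
            "token": vocabulary.tokens[tok_id],
            "entropy": gaussian_entropy(sds[tok_id]),
        })
    return pd.DataFrame(rows).sort_values("entropy", ignore_index=True)


def evaluate(summaries: list[PredictiveSummary], n_bootstrap: int = 50,
             n_bins: int = 10, seed: int = 0,
             thresholds: np.ndarray | None = None,
             embedding_block=None, vocabulary: Vocabulary | None = None
             ) -> EvaluationReport:
    """Run the full uncertainty-evaluation suite on one prediction set."""
    rank = ranking_metrics(summaries, n_bootstrap=n_bootstrap, seed=seed)
    split = UncertaintySplit.from_summaries(summaries)
    div_pos, div_neg, reasons = div_metric(split)
    entropy = None
    if embedding_block is not None and vocabulary is not None and \
            getattr(embedding_block, "stochastic", False):
        entropy = embedding_entropy_table(embedding_block, vocabulary)
    return EvaluationReport(
        auroc=rank["auroc"], auroc_ci=rank["auroc_ci"],
        ap=rank["ap"], ap_ci=rank["ap_ci"],
        confidence_table=confidence_curves(summaries, thresholds),
        calibration=calibration_with_bands(summaries, n_bins=n_bins),
        div_positive=div_pos, div_negative=div_neg, div_reasons=reasons,
        entropy_table=entropy,
    )
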