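"""Device-agreement statistics for validating sedentary-time estimates.

Given per-subject pairs (estimate, referent) for one metric, this module
computes the absolute percentage error (APE) and its median/IQR across
subjects (MDAPE), the mean bias with Bland-Altman 95% limits of agreement
and a proportional-bias regression, a TOST equivalence test on the paired
differences, a paired Wilcoxon signed-rank comparison between two methods'
APEs, and the sitting/standing/stepping composition of minutes by predicted
class (the events-file analogue of a confusion matrix).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .ensemble import ActivityLabel, LabeledPrediction
from .io import MatchedSeries


@dataclass
class PairedMetricSample:
    """Per-subject (estimate, referent) pairs for one metric and one method."""

    estimates: np.ndarray
    referents: np.ndarray
    metric: str = ""  # "proportion" | "minutes"

    def __post_init__(self) -> None:
        self.estimates = np.asarray(self.estimates, dtype=float)
        self.referents = np.asarray(self.referents, dtype=float)
        if self.estimates.shape != self.referents.shape:
            raise ValueError("estimates and referents must have equal length")

    def __len__(self) -> int:
        return len(self.estimates)

    @property
    def differences(self) -> np.ndarray:
        return self.estimates - self.referents


@dataclass
class AgreementReport:
    """MDAPE/IQR, bias, limits of agreement, proportional bias and TOST p."""

    n: int
    mdape: float | None = None
    ape_iqr: tuple[float, float] | None = None
    bias_mean: float | None = None
    bias_sd: float | None = None
    loa_low: float | None = None
    loa_high: float | None = None
    prop_bias_slope: float | None = None
    prop_bias_slope_ci: tuple[float, float] | None = None
    prop_bias_p: float | None = None
    tost_p: float | None = None

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        for key in ("ape_iqr", "prop_bias_slope_ci"):
            if d[key] is not None:
                d[key] = list(d[key])
        return d


def ape(estimate: float, referent: float) -> float:
    """Absolute percentage error |estimate - referent| / referent."""
    if referent <= 0:
        raise ValueError("APE requires a positive referent")
    return abs(estimate - referent) / referent


def summarize_mdape(sample: PairedMetricSample) -> tuple[float, tuple[float, float]]:
    """Median and (q1, q3) of the per-subject APEs (linear-interpolated quantiles)."""
    apes = np.array([ape(e, r) for e, r in zip(sample.estimates, sample.referents)])
    q1, med, q3 = np.quantile(apes, [0.25, 0.5, 0.75])
    return float(med), (float(q1), float(q3))


def bland_altman(sample: PairedMetricSample) -> AgreementReport:
    """Mean bias, 95% limits of agreement, and proportional-bias regression.

    Differences d_i = estimate_i - referent_i; limits are bias +/- 1.96 x
    sample SD.  Proportional bias is the OLS slope of d_i on the pairwise
    means (estimate_i + referent_i) / 2, with a 95% CI and two-sided p-value
    for slope = 0 (requires n >= 3).
    """
    d = sample.differences
    n = len(d)
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if n > 1 else 0.0
    report = AgreementReport(
        n=n,
        bias_mean=bias,
        bias_sd=sd,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )
    if n < 3:
        warnings.warn("n < 3: proportional-bias regression not computed", stacklevel=2)
        return report
    means = (sample.estimates + sample.referents) / 2.0
    if np.ptp(means) == 0:
        warnings.warn("constant pairwise means: proportional-bias slope undefined", stacklevel=2)
        return report
    res = stats.linregress(means, d)
    tcrit = stats.t.ppf(0.975, n - 2)
    report.prop_bias_slope = float(res.slope)
    report.prop_bias_slope_ci = (
        float(res.slope - tcrit * res.stderr),
        float(res.slope + tcrit * res.stderr),
    )
    report.prop_bias_p = float(res.pvalue)
    return report


def tost_equivalence(differences: Sequence[float], margin: float) -> float:
    """Two one-sided t-tests of equivalence within +/- margin.

    Returns the larger of the two one-sided p-values; p < alpha declares the
    mean difference equivalent to zero within the margin.
    """
    d = np.asarray(differences, dtype=float)
    n = len(d)
    if n < 2:
        raise ValueError("TOST needs n >= 2")
    if margin <= 0:
        raise ValueError("margin must be positive")
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        return 0.0 if abs(mean) < margin else 1.0
    se = sd / np.sqrt(n)
    t_lower = (mean + margin) / se  # H0: mean <= -margin, reject for large t
    t_upper = (mean - margin) / se  # H0: mean >= +margin, reject for small t
    p_lower = float(stats.t.sf(t_lower, n - 1))
    p_upper = float(stats.t.cdf(t_upper, n - 1))
    return max(p_lower, p_upper)


def wilcoxon_compare_ape(ape_a: Sequence[float], ape_b: Sequence[float]) -> float:
    """Two-sided paired Wilcoxon signed-rank p comparing two methods' APEs.

    Zero differences are dropped; the exact null distribution is used for
    n <= 25 without ties, otherwise the normal approximation with continuity
    correction.
    """
    a = np.asarray(ape_a, dtype=float)
    b = np.asarray(ape_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("samples must be paired (equal length)")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    ties = len(np.unique(np.abs(d))) < len(d)
    method = "exact" if (len(d) <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", correction=True, method=method)
    return float(res.pvalue)


def composition_by_class(
    pairs: Sequence[tuple[MatchedSeries, LabeledPrediction]],
) -> dict:
    """Posture composition of predicted sedentary vs non-sedentary minutes.

    For each subject and predicted class (SEDENTARY vs all others), the mean
    seconds/minute of sitting, standing and stepping recorded by the posture
    referent; then the across-subject mean and standard error.  Returns
    ``{"sedentary": {...}, "non_sedentary": {...}}`` with per-posture
    ``(mean, se)`` entries, or the class absent (with a warning) when no
    subject has minutes of it.
    """
    postures = ("sitting_s", "standing_s", "stepping_s")
    per_subject: dict[str, list[np.ndarray]] = {"sedentary": [], "non_sedentary": []}
    for matched, pred in pairs:
        lab = dict(zip(pred.timestamps, pred.labels))
        labels = np.array([lab[t] for t in matched.timestamps])
        sed = labels == int(ActivityLabel.SEDENTARY)
        for name, mask in (("sedentary", sed), ("non_sedentary", ~sed)):
            if mask.any():
                per_subject[name].append(
                    matched.data.loc[mask, list(postures)].mean(axis=0).to_numpy()
                )
    out: dict = {}
    for name, rows in per_subject.items():
        if not rows:
            warnings.warn(f"no minutes in class {name}", stacklevel=2)
            continue
        m = np.vstack(rows)
        mean = m.mean(axis=0)
        se = m.std(axis=0, ddof=1) / np.sqrt(len(rows)) if len(rows) > 1 else np.full(3, np.nan)
        out[name] = {
            p: {"mean": float(mean[i]), "se": float(se[i])} for i, p in enumerate(postures)
        }
    return out


def evaluate_agreement(
    sample: PairedMetricSample, tost_margin: float
) -> AgreementReport:
    """Full agreement report for one metric and one method."""
    report = bland_altman(sample)
    report.mdape, report.ape_iqr = summarize_mdape(sample)
    if len(sample) >= 2:
        report.tost_p = tost_equivalence(sample.differences, tost_margin)
    else:
        warnings.warn("n < 2: TOST not computed", stacklevel=2)
    return report


def bland_altman_plot(sample: PairedMetricSample, path, title: str = "") -> None:
    """Write a Bland-Altman scatter with bias and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rep = bland_altman(sample)
    means = (sample.estimates + sample.referents) / 2.0
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, sample.differences, s=18, alpha=0.7)
    for y, style in ((rep.bias_mean, "-"), (rep.loa_low, "--"), (rep.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (estimate - referent)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
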