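"""Interaction calling from coculture vs monoculture biomass.

For each strain pair and carbon source the coculture's replicate maximum
OD600 values are compared against each monoculture's by a two-tailed
pooled-variance Student's t-test (normality checked per group with
Shapiro-Wilk).  Raw p-values from the whole experiment are pooled into one
Benjamini-Hochberg family before labeling:

* **positive** — the coculture is significantly denser than *both*
  monocultures (both corrected p < alpha, both directions positive, and the
  larger mean of each compared pair above the instrument noise floor);
* **negative** — the coculture is significantly less dense than *at least
  one* monoculture (same floor rule);
* **neutral** — anything else.

A positive or negative call is further classified by carbon-source
utilization: whether both strains, only one, or neither grows on the carbon
in monoculture (monoculture mean maximum OD above the noise floor).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sstats
from statsmodels.stats.multitest import multipletests

from .growth import GroupStats, GrowthDataset, group_stats, validate_design

logger = logging.getLogger(__name__)

POSITIVE = "positive"
NEGATIVE = "negative"
NEUTRAL = "neutral"

BOTH_USE = "both_use"
SINGLE_USE = "single_use"
NEITHER_USE = "neither_use"
NOT_APPLICABLE = "not_applicable"


@dataclass
class AnalysisConfig:
    """Knobs of the interaction-calling procedure.

    alpha
        Significance level applied to FDR-corrected p-values.
    fdr_method
        Multiple-testing procedure; ``"BH"`` (Benjamini-Hochberg step-up)
        or ``"BY"`` (Benjamini-Yekutieli).
    noise_floor
        OD600 below which a group mean is instrument noise (strict ``>``
        comparisons throughout).
    normality_alpha, normality_policy
        Per-group Shapiro-Wilk gate; ``"warn"`` logs and proceeds with the
        t-test, ``"fallback_nonparametric"`` switches the affected
        comparison to a two-sided Mann-Whitney U test.
    welch
        Use Welch's unequal-variance t-test instead of the pooled form.
    """

    alpha: float = 0.05
    fdr_method: str = "BH"
    noise_floor: float = 0.05
    normality_alpha: float = 0.05
    normality_policy: str = "warn"
    welch: bool = False

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.normality_alpha < 1:
            raise ValueError("normality_alpha must be in (0, 1)")
        if self.normality_policy not in ("warn", "fallback_nonparametric"):
            raise ValueError(f"unknown normality_policy {self.normality_policy!r}")
        if self.fdr_method not in ("BH", "BY"):
            raise ValueError(f"unknown fdr_method {self.fdr_method!r}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


@dataclass
class ComparisonResult:
    """One coculture-vs-monoculture t-test."""

    pair: tuple
    carbon: str
    mono_strain: str
    t_stat: float
    p_raw: float
    q: float
    direction: int  # sign of (co_mean - mono_mean)
    w_stats: dict  # group -> (W, p) Shapiro-Wilk, or None if degenerate
    floor_ok: bool
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        return self.floor_ok and not math.isnan(self.q)


@dataclass
class InteractionCall:
    """Verdict for one (strain pair, carbon source) combination."""

    pair: tuple
    carbon: str
    label: str
    ratio: float  # co_mean / max(mono means); nan when undefined
    case: str = NOT_APPLICABLE
    comparisons: list = field(default_factory=list)


@dataclass
class InteractionSummary:
    n_total: int
    n_positive: int
    n_negative: int
    n_neutral: int
    pct_positive: float
    pct_negative: float
    per_carbon: pd.DataFrame
    per_pair: pd.DataFrame
    case_split: dict  # label -> {case: count}


def shapiro_wilk(values) -> tuple:
    """Shapiro-Wilk normality test ``(W, p)``.

    Requires 3 <= n <= 50 and nonzero variance.  For n=3 the statistic has
    the closed form ``W = (x_(3) - x_(1))^2 / (2 * sum((x - mean)^2))``.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 3:
        raise ValueError(f"Shapiro-Wilk needs n >= 3, got {v.size}")
    if v.size > 50:
        raise ValueError(f"Shapiro-Wilk restricted to n <= 50, got {v.size}")
    if np.ptp(v) == 0:
        raise ValueError("Shapiro-Wilk undefined for a zero-variance sample")
    w, p = sstats.shapiro(v)
    return float(w), float(p)


def student_t_test(x, y, welch: bool = False) -> tuple:
    """Two-sample two-tailed t-test ``(t, p)``.

    Pooled-variance Student's form by default (df = n_x + n_y - 2); Welch's
    approximation with ``welch=True``.  Degenerate contract when both groups
    have zero variance: equal means give ``(0.0, 1.0)``; unequal means give
    ``(+/-inf, 0.0)`` (logged as degenerate).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, 1.0
        logger.warning("degenerate t-test: two zero-variance groups with unequal means")
        return math.copysign(math.inf, x.mean() - y.mean()), 0.0
    t, p = sstats.ttest_ind(x, y, equal_var=not welch)
    return float(t), float(p)


def mann_whitney(x, y) -> tuple:
    """Two-sided Mann-Whitney U test ``(U, p)``; the nonparametric fallback."""
    u, p = sstats.mannwhitneyu(x, y, alternative="two-sided")
    return float(u), float(p)


def fdr_adjust(pvals, method: str = "BH") -> np.ndarray:
    """FDR-corrected p-values (Benjamini-Hochberg step-up by default)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    sm_method = {"BH": "fdr_bh", "BY": "fdr_by"}[method]
    return multipletests(p, method=sm_method)[1]


def call_utilization(dataset: GrowthDataset, strain, carbon, config: AnalysisConfig | None = None) -> bool:
    """Whether a strain *uses* a carbon source: monoculture mean maximum
    OD600 strictly above the noise floor."""
    floor = (config.noise_floor if config is not None else dataset.noise_floor)
    stats = group_stats(dataset, {strain}, carbon)
    return stats.mean > floor


def coculture_ratio(co_mean: float, monoA_mean: float, monoB_mean: float) -> float:
    """``AB_co_average / Max_mono_average``; NaN when both mono means are 0."""
    m = max(monoA_mean, monoB_mean)
    if m <= 0:
        logger.warning("undefined coculture ratio: both monoculture means are 0")
        return math.nan
    return co_mean / m


def _compare(co: GroupStats, mono: GroupStats, config: AnalysisConfig,
             pair=(), carbon="", mono_strain="") -> ComparisonResult:
    """Raw comparison (no FDR yet; q filled by the caller)."""
    w_stats = {}
    non_normal = False
    for name, g in (("co", co), ("mono", mono)):
        try:
            w_stats[name] = shapiro_wilk(g.values)
            if w_stats[name][1] < config.normality_alpha:
                non_normal = True
        except ValueError:
            w_stats[name] = None  # degenerate or tiny group: gate not applicable
    degenerate = co.sd == 0 and mono.sd == 0
    if non_normal and config.normality_policy == "fallback_nonparametric":
        t, p = mann_whitney(co.values, mono.values)
    else:
        if non_normal:
            logger.warning("non-normal group in (%s, %s) vs %s; proceeding with t-test",
                           pair, carbon, mono_strain)
        t, p = student_t_test(co.values, mono.values, welch=config.welch)
    diff = co.mean - mono.mean
    direction = 0 if diff == 0 else (1 if diff > 0 else -1)
    floor_ok = max(co.mean, mono.mean) > config.noise_floor
    return ComparisonResult(pair=tuple(pair), carbon=carbon, mono_strain=mono_strain,
                            t_stat=t, p_raw=p, q=math.nan, direction=direction,
                            w_stats=w_stats, floor_ok=floor_ok, degenerate=degenerate)


def _label(comparisons, alpha: float) -> str:
    sig = [c for c in comparisons if c.floor_ok and c.q < alpha]
    if any(c.direction < 0 for c in sig):
        return NEGATIVE  # "at least one" rule wins on mixed directions
    if len(sig) == len(comparisons) and all(c.direction > 0 for c in sig):
        return POSITIVE
    return NEUTRAL


def classify_interaction(co: GroupStats, monoA: GroupStats, monoB: GroupStats,
                         config: AnalysisConfig | None = None,
                         pair=("A", "B"), carbon="") -> InteractionCall:
    """Label a single (pair, carbon) triad in isolation.

    The FDR family here is just the triad's two comparisons; use
    :func:`classify_all` to pool the family across a whole experiment.
    """
    config = config or AnalysisConfig()
    for name, g in (("coculture", co), ("monoA", monoA), ("monoB", monoB)):
        if g.n < 3:
            raise ValueError(f"{name} group has n={g.n}; need >= 3")
    pair = tuple(sorted(pair))
    comps = [
        _compare(co, monoA, config, pair, carbon, mono_strain=pair[0]),
        _compare(co, monoB, config, pair, carbon, mono_strain=pair[1]),
    ]
    q = fdr_adjust([c.p_raw for c in comps], config.fdr_method)
    for c, qi in zip(comps, q):
        c.q = float(qi)
    return InteractionCall(
        pair=pair, carbon=carbon, label=_label(comps, config.alpha),
        ratio=coculture_ratio(co.mean, monoA.mean, monoB.mean), comparisons=comps,
    )


def classify_case(call: InteractionCall, use_A: bool, use_B: bool) -> str:
    """Utilization case of a non-neutral call: both / single / neither strain
    grows on the carbon in monoculture."""
    if call.label == NEUTRAL:
        return NOT_APPLICABLE
    if use_A and use_B:
        return BOTH_USE
    if use_A or use_B:
        return SINGLE_USE
    return NEITHER_USE


def classify_all(dataset: GrowthDataset, config: AnalysisConfig | None = None) -> list:
    """Classify every complete (pair, carbon) triad in an experiment.

    All raw p-values (two comparisons per triad) are computed first and
    corrected as one pooled FDR family, then labels and utilization cases
    are assigned.  Deterministic given the dataset.
    """
    config = config or AnalysisConfig()
    design = validate_design(dataset)
    complete = design[design["complete"]]
    if complete.empty:
        raise ValueError("no complete (pair, carbon) triad in the dataset")

    calls = []
    comps_flat = []
    for row in complete.itertuples():
        a, b = sorted((row.strain_a, row.strain_b))
        co = group_stats(dataset, {a, b}, row.carbon)
        monoA = group_stats(dataset, {a}, row.carbon)
        monoB = group_stats(dataset, {b}, row.carbon)
        comps = [
            _compare(co, monoA, config, (a, b), row.carbon, mono_strain=a),
            _compare(co, monoB, config, (a, b), row.carbon, mono_strain=b),
        ]
        comps_flat.extend(comps)
        calls.append(InteractionCall(
            pair=(a, b), carbon=row.carbon, label=NEUTRAL,
            ratio=coculture_ratio(co.mean, monoA.mean, monoB.mean),
            comparisons=comps,
        ))

    q = fdr_adjust([c.p_raw for c in comps_flat], config.fdr_method)
    for c, qi in zip(comps_flat, q):
        c.q = float(qi)

    use = {}  # (strain, carbon) -> bool, computed once per monoculture
    for call in calls:
        call.label = _label(call.comparisons, config.alpha)
        for s in call.pair:
            if (s, call.carbon) not in use:
                use[(s, call.carbon)] = call_utilization(dataset, s, call.carbon, config)
        call.case = classify_case(call, use[(call.pair[0], call.carbon)],
                                  use[(call.pair[1], call.carbon)])
    logger.info("classified %d triads: %d positive, %d negative, %d neutral",
                len(calls), *(sum(c.label == l for c in calls)
                              for l in (POSITIVE, NEGATIVE, NEUTRAL)))
    return calls


def summarize(calls) -> InteractionSummary:
    """Count labels, percentages (1 decimal) and utilization-case splits."""
    if not calls:
        raise ValueError("no calls to summarize")
    n = len(calls)
    n_pos = sum(c.label == POSITIVE for c in calls)
    n_neg = sum(c.label == NEGATIVE for c in calls)
    n_neu = n - n_pos - n_neg

    def crosstab(keyfn):
        df = pd.DataFrame([(keyfn(c), c.label) for c in calls], columns=["key", "label"])
        tab = df.groupby(["key", "label"]).size().unstack(fill_value=0)
        return tab.reindex(columns=[POSITIVE, NEGATIVE, NEUTRAL], fill_value=0)

    case_split = {}
    for label in (POSITIVE, NEGATIVE):
        sub = [c.case for c in calls if c.label == label]
        case_split[label] = {case: sub.count(case)
                             for case in (SINGLE_USE, BOTH_USE, NEITHER_USE)}

    return InteractionSummary(
        n_total=n, n_positive=n_pos, n_negative=n_neg, n_neutral=n_neu,
        pct_positive=round(100 * n_pos / n, 1),
        pct_negative=round(100 * n_neg / n, 1),
        per_carbon=crosstab(lambda c: c.carbon),
        per_pair=crosstab(lambda c: "-".join(c.pair)),
        case_split=case_split,
    )


def calls_to_frame(calls) -> pd.DataFrame:
    """Flatten calls to one row per (pair, carbon) for TSV export."""
    rows = []
    for c in calls:
        qa, qb = (c.comparisons[0].q, c.comparisons[1].q) if c.comparisons else (math.nan,) * 2
        rows.append((c.pair[0], c.pair[1], c.carbon, c.label, c.ratio, qa, qb, c.case))
    return pd.DataFrame(rows, columns=["strain_a", "strain_b", "carbon", "label",
                                       "ratio", "q_vs_mono_a", "q_vs_mono_b", "case"])
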