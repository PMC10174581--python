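"""Comparison harness: run all strategies over a set of webs and test
whether the tabu-search strategy disintegrates webs significantly better.

For each (web, method, replicate) the removal curve is built at one
threshold and reduced to SEA and R50.  Per-method web-level means feed a
one-way ANOVA and Dunnett many-to-one contrasts against the tabu-search
control, mirroring the standard "six algorithms, one control" layout.
Deterministic centrality strategies produce identical replicates; only
tabu search is stochastic, with every seed derived from the base seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import ExtinctionCurve
from .strategies import BASELINE_STRATEGIES, STRATEGY_NAMES, sequential_removal
from .tabu import TabuConfig, tabu_removal_curve
from .webio import AugmentedWeb, FoodWeb, augment_with_environment, read_foodweb_json

__all__ = [
    "ExperimentConfig",
    "ComparisonTable",
    "run_comparison",
    "one_way_anova",
    "AnovaResult",
    "dunnett_vs_control",
    "DunnettRow",
]


@dataclass(frozen=True)
class ExperimentConfig:
    webs: tuple[str, ...]                       # paths to canonical JSON files
    methods: tuple[str, ...] = STRATEGY_NAMES
    t: float = 0.5
    reps: int = 10
    tabu: TabuConfig = field(default_factory=TabuConfig)
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if not self.methods:
            raise ValueError("methods must be non-empty")
        unknown = set(self.methods) - set(STRATEGY_NAMES)
        if unknown:
            raise ValueError(f"unknown method(s) {sorted(unknown)}")


@dataclass(frozen=True)
class ComparisonTable:
    """Per-replicate rows plus per-method summary (mean, SD, SEM)."""

    rows: pd.DataFrame      # columns: web, method, rep, SEA, R50
    summary: pd.DataFrame   # per (method, metric): mean, sd, sem

    def method_means(self, metric: str = "SEA") -> pd.Series:
        """Per-method mean over web-level means (each web weighted once)."""
        web_level = self.rows.groupby(["method", "web"])[metric].mean()
        return web_level.groupby("method").mean()

    def web_level(self, metric: str = "SEA") -> pd.DataFrame:
        """Web x method table of replicate-averaged values."""
        return self.rows.pivot_table(
            index="web", columns="method", values=metric, aggfunc="mean"
        )


def _summarize(rows: pd.DataFrame) -> pd.DataFrame:
    records = []
    for metric in ("SEA", "R50"):
        web_level = rows.groupby(["method", "web"])[metric].mean().groupby("method")
        for method, vals in web_level:
            v = vals.to_numpy()
            sd = float(np.std(v, ddof=1)) if v.size > 1 else 0.0
            records.append(
                {
                    "method": method,
                    "metric": metric,
                    "mean": float(v.mean()),
                    "sd": sd,
                    "sem": sd / math.sqrt(v.size) if v.size > 1 else 0.0,
                    "n_webs": int(v.size),
                }
            )
    return pd.DataFrame(records)


def run_comparison(
    cfg: ExperimentConfig,
    *,
    loaded: Mapping[str, AugmentedWeb] | None = None,
) -> ComparisonTable:
    """Run every configured method on every web with replication.

    ``loaded`` bypasses file I/O with pre-augmented webs keyed by name
    (used by the synthetic pipeline and tests); otherwise each entry of
    ``cfg.webs`` is read as canonical JSON.  All results derive from
    ``cfg.base_seed``: replicate seeds are ``base_seed + rep`` and each
    tabu budget folds its own index on top.  Deterministic methods yield
    identical rows across replicates.
    """
    webs: dict[str, AugmentedWeb] = {}
    if loaded is not None:
        webs.update(loaded)
    else:
        for path in cfg.webs:
            p = Path(path)
            if not p.exists():
                raise FileNotFoundError(f"web file not found: {p}")
            web = read_foodweb_json(p)
            webs[web.name] = augment_with_environment(web)

    records = []
    for name, aug in webs.items():
        for method in cfg.methods:
            for rep in range(cfg.reps):
                if method == "TS":
                    rep_cfg = TabuConfig(
                        T_max=cfg.tabu.T_max,
                        n_can=cfg.tabu.n_can,
                        L=cfg.tabu.L,
                        seed=(cfg.base_seed + rep) & 0x7FFFFFFF,
                        retry_cap=cfg.tabu.retry_cap,
                    )
                    result = tabu_removal_curve(aug, cfg.t, rep_cfg)
                else:
                    result = sequential_removal(aug, method, cfg.t)
                curve = ExtinctionCurve.from_sequence(result)
                records.append(
                    {
                        "web": name,
                        "method": method,
                        "rep": rep,
                        "SEA": curve.sea,
                        "R50": curve.r50,
                    }
                )
    rows = pd.DataFrame(records)
    return ComparisonTable(rows=rows, summary=_summarize(rows))


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_between: int
    df_within: int
    p: float
    degenerate: bool = False


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Classical one-way ANOVA across method groups.

    F = MSB/MSW with df = (k-1, sum n_i - k).  When every group is
    internally constant the within-variance is zero and the result is
    flagged degenerate (F infinite or 0/0).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs at least two values")
    df_b = len(arrays) - 1
    df_w = sum(a.size for a in arrays) - len(arrays)
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0.0:
        grand = np.concatenate(arrays).mean()
        ssb = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
        return AnovaResult(
            F=math.inf if ssb > 0 else 0.0,
            df_between=df_b,
            df_within=df_w,
            p=math.nan,
            degenerate=True,
        )
    f_stat, p = stats.f_oneway(*arrays)
    return AnovaResult(F=float(f_stat), df_between=df_b, df_within=df_w, p=float(p))


@dataclass(frozen=True)
class DunnettRow:
    method: str
    mean_difference: float
    p_adjusted: float
    ci_low: float
    ci_high: float
    significance_band: str

    @staticmethod
    def band(p: float) -> str:
        if p < 0.01:
            return "<0.01"
        if p < 0.05:
            return "<0.05"
        return f"{p:.2f}"


def dunnett_vs_control(
    groups: Mapping[str, Sequence[float]], control: str
) -> list[DunnettRow]:
    """Dunnett many-to-one comparisons of every method against a control.

    Mean difference is mean(method) - mean(control); adjusted p-values and
    simultaneous two-sided confidence intervals come from the max-|t|
    reference distribution of the balanced many-to-one design
    (``scipy.stats.dunnett``).  Rows follow the input order, control
    excluded.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} missing from groups")
    others = [k for k in groups if k != control]
    if not others:
        raise ValueError("need at least one non-control group")
    ctrl = np.asarray(groups[control], dtype=float)
    samples = [np.asarray(groups[k], dtype=float) for k in others]
    res = stats.dunnett(*samples, control=ctrl)
    ci = res.confidence_interval()
    rows = []
    for i, name in enumerate(others):
        p = float(res.pvalue[i])
        rows.append(
            DunnettRow(
                method=name,
                mean_difference=float(samples[i].mean() - ctrl.mean()),
                p_adjusted=p,
                ci_low=float(ci.low[i]),
                ci_high=float(ci.high[i]),
                significance_band=DunnettRow.band(p),
            )
        )
    return rows
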