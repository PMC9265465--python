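"""Two-level factorial analysis of composting amendments and field measures.

Experimental groups are coded by binary factor levels (0 = amendment absent,
1 = present) with a binding energy in kJ/mol as response (more negative =
stronger binding = better degradation/inhibition).  The module covers:

* improvement percentages of a treated group over the blank group, computed
  on energy magnitudes: ``100 * (|E_group| - |E_blank|) / |E_blank|``;
* marginal means per factor level;
* Yates-convention effect estimation on complete 2^k designs, where the
  effect of a term T is the contrast ``(1/2^(k-1)) * sum signs * response``
  with 0 -> -1 and 1 -> +1 coding (equal to the high/low marginal-mean
  difference for main effects, and to twice the corresponding least-squares
  coefficient);
* significance screening at p = 0.05 via replicated-design ANOVA t-tests,
  Lenth's pseudo standard error for unreplicated designs, or pooling of the
  highest-order interactions as an error estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from itertools import combinations, product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DesignTable",
    "EffectEstimate",
    "FactorialModel",
    "FactorialResults",
    "binding_improvement",
    "scenario_report",
    "marginal_mean",
    "factorial_effects",
    "significance_screen",
]


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DesignTable:
    """Binary design matrix plus response, one row per experimental run."""

    group_ids: tuple
    factor_names: tuple
    levels: np.ndarray   # (runs, k) of 0/1
    response: np.ndarray  # (runs,) kJ/mol
    blank_id: Optional[str] = None

    def __init__(self, group_ids, factor_names, levels, response, blank_id=None):
        levels = np.asarray(levels, dtype=int)
        response = np.asarray(response, dtype=float)
        if levels.ndim != 2:
            raise ValueError("levels must be 2-D")
        n, k = levels.shape
        if len(group_ids) != n or response.shape != (n,):
            raise ValueError("group_ids, levels and response lengths disagree")
        if len(factor_names) != k:
            raise ValueError("factor_names length must match level columns")
        if len(set(factor_names)) != k:
            raise ValueError("duplicate factor names")
        if not np.isin(levels, (0, 1)).all():
            raise ValueError("levels must be 0 or 1")
        if not np.isfinite(response).all():
            raise ValueError("non-finite response")
        if blank_id is not None:
            if blank_id not in group_ids:
                raise ValueError(f"blank group {blank_id!r} not in design")
            row = list(group_ids).index(blank_id)
            if levels[row].any():
                raise ValueError("blank group must sit at all-zero levels")
        object.__setattr__(self, "group_ids", tuple(group_ids))
        object.__setattr__(self, "factor_names", tuple(factor_names))
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "response", response)
        object.__setattr__(self, "blank_id", blank_id)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response_col: str = "response",
                       group_col: str = "group", blank_id=None) -> "DesignTable":
        factors = [c for c in df.columns if c not in (group_col, response_col)]
        return cls(df[group_col].astype(str).tolist(), factors,
                   df[factors].to_numpy(int), df[response_col].to_numpy(float),
                   blank_id=blank_id)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.levels, columns=list(self.factor_names))
        df.insert(0, "group", list(self.group_ids))
        df["response"] = self.response
        return df


@dataclass(frozen=True)
class EffectEstimate:
    """One factorial effect: factor subset, order and estimate in kJ/mol."""

    term: tuple
    estimate: float
    significant: Optional[bool] = None
    method: Optional[str] = None

    @property
    def order(self) -> int:
        return len(self.term)

    @property
    def label(self) -> str:
        return "&".join(self.term)


def binding_improvement(blank_energy: float, group_energy: float,
                        ndigits: Optional[int] = 2) -> float:
    """Percent gain in binding magnitude over the blank group.

    Positive means the treated group binds more strongly (more negative
    energy) than the blank.  The blank energy must be negative (bound).
    """
    if not blank_energy < 0:
        raise ValueError("blank binding energy must be negative")
    pct = 100.0 * (abs(group_energy) - abs(blank_energy)) / abs(blank_energy)
    return _round_half_up(pct, ndigits) if ndigits is not None else pct


def scenario_report(energies: dict, blank: str = "G0",
                    factor_map: Optional[dict] = None) -> dict:
    """Per-group improvements over the blank and the beneficial-additive set.

    Parameters
    ----------
    energies : mapping group id -> binding energy (kJ/mol)
        Must contain the blank group.
    factor_map : optional mapping group id -> additive name
        Used to translate beneficial groups into additive names.

    Returns a dict with per-group improvements, the groups improved over the
    blank, and the min/max improvement among them.
    """
    if blank not in energies:
        raise ValueError(f"blank group {blank!r} missing from energies")
    blank_e = energies[blank]
    improvements = {
        g: binding_improvement(blank_e, e)
        for g, e in energies.items() if g != blank
    }
    beneficial = sorted(g for g, pct in improvements.items() if pct > 0)
    bene_pcts = [improvements[g] for g in beneficial]
    report = {
        "blank": blank,
        "blank_energy": blank_e,
        "improvements": improvements,
        "beneficial_groups": beneficial,
        "improvement_range": (min(bene_pcts), max(bene_pcts)) if bene_pcts else None,
    }
    if factor_map:
        report["beneficial_additives"] = [factor_map.get(g, g) for g in beneficial]
    return report


def marginal_mean(design: DesignTable, factor: str, level: int,
                  ndigits: Optional[int] = 3) -> float:
    """Mean response over all runs with the factor at the given level."""
    if factor not in design.factor_names:
        raise ValueError(f"unknown factor {factor!r}")
    j = design.factor_names.index(factor)
    mask = design.levels[:, j] == level
    if not mask.any():
        raise ValueError(f"no runs with {factor}={level}")
    mean = float(design.response[mask].mean())
    return _round_half_up(mean, ndigits) if ndigits is not None else mean


def _cell_means(design: DesignTable) -> tuple[np.ndarray, np.ndarray]:
    """Average replicates per level combination; error if the 2^k is incomplete."""
    k = len(design.factor_names)
    cells = {}
    for row, y in zip(design.levels, design.response):
        cells.setdefault(tuple(row), []).append(y)
    full = [tuple(c) for c in product((0, 1), repeat=k)]
    missing = [c for c in full if c not in cells]
    if missing:
        raise ValueError(
            f"incomplete 2^{k} factorial: missing level combinations {missing[:4]}")
    levels = np.array(full, dtype=int)
    means = np.array([np.mean(cells[c]) for c in full])
    return levels, means


def factorial_effects(design: DesignTable, max_order: Optional[int] = None,
                      ndigits: Optional[int] = None) -> list[EffectEstimate]:
    """Yates-convention effect estimates on a complete 2^k design.

    Replicates are averaged per cell first.  ``effect(T) = (1/2^(k-1)) *
    sum over cells of (prod of +-1 signs over factors in T) * cell mean``.
    """
    levels, means = _cell_means(design)
    k = len(design.factor_names)
    if max_order is None:
        max_order = k
    signs = 2 * levels - 1  # 0/1 -> -1/+1
    out = []
    for order in range(1, min(max_order, k) + 1):
        for term_idx in combinations(range(k), order):
            contrast = np.prod(signs[:, term_idx], axis=1)
            est = float(contrast @ means) / 2 ** (k - 1)
            if ndigits is not None:
                est = _round_half_up(est, ndigits)
            out.append(EffectEstimate(
                term=tuple(design.factor_names[i] for i in term_idx),
                estimate=est))
    return out


def _lenth_pse(estimates: np.ndarray) -> float:
    s0 = 1.5 * float(np.median(np.abs(estimates)))
    trimmed = np.abs(estimates)[np.abs(estimates) < 2.5 * s0]
    if trimmed.size == 0:
        trimmed = np.abs(estimates)
    return 1.5 * float(np.median(trimmed))


def significance_screen(effects: Sequence[EffectEstimate], method: str = "lenth",
                        *, design: Optional[DesignTable] = None,
                        alpha: float = 0.05,
                        pool_order: Optional[int] = None) -> list[EffectEstimate]:
    """Attach p = ``alpha`` significance verdicts to effect estimates.

    Methods
    -------
    ``lenth``
        Lenth's pseudo-standard-error for unreplicated 2^k designs; an
        effect is significant when it exceeds the individual margin of
        error ``t(1 - alpha/2, d/3) * PSE`` with d effects.
    ``pool-high-order``
        The highest-order effects present (or those of order >= pool_order)
        are pooled as pure error; remaining effects get t-tests.
    ``replicated-anova``
        Requires the design with >= 2 replicates in every cell; effects are
        tested via ordinary least squares on +-1-coded regressors.
    """
    if method not in ("lenth", "pool-high-order", "replicated-anova"):
        raise ValueError(f"unknown method {method!r}")
    ests = np.array([e.estimate for e in effects])
    if method == "lenth":
        if len(effects) < 3:
            raise ValueError("Lenth screening needs at least 3 effects")
        pse = _lenth_pse(ests)
        d = len(effects)
        tcrit = stats.t.ppf(1 - alpha / 2, d / 3)
        margin = tcrit * pse
        verdicts = np.abs(ests) > margin
        return [EffectEstimate(e.term, e.estimate, bool(v), "lenth")
                for e, v in zip(effects, verdicts)]

    if method == "pool-high-order":
        orders = np.array([e.order for e in effects])
        cut = pool_order if pool_order is not None else orders.max()
        pooled = ests[orders >= cut]
        keep = orders < cut
        if pooled.size == 0 or not keep.any():
            raise ValueError("pooling leaves no error terms or no testable effects")
        # each effect estimate shares one variance; pooled effects estimate it
        var_eff = float((pooled ** 2).mean())
        df = pooled.size
        out = []
        for e in effects:
            if e.order >= cut:
                out.append(EffectEstimate(e.term, e.estimate, None, "pooled-as-error"))
            else:
                tval = e.estimate / np.sqrt(var_eff)
                p = 2 * stats.t.sf(abs(tval), df)
                out.append(EffectEstimate(e.term, e.estimate, bool(p < alpha),
                                          "pool-high-order"))
        return out

    # replicated-anova
    if design is None:
        raise ValueError("replicated-anova needs the design table")
    k = len(design.factor_names)
    counts = pd.Series([tuple(r) for r in design.levels]).value_counts()
    if len(counts) < 2 ** k or counts.min() < 2:
        raise ValueError("replicated-anova needs >= 2 replicates in every cell")
    signs = 2 * design.levels - 1
    cols = []
    for e in effects:
        idx = [design.factor_names.index(f) for f in e.term]
        cols.append(np.prod(signs[:, idx], axis=1))
    Xmat = np.column_stack([np.ones(len(design.response))] + cols)
    import statsmodels.api as sm

    fit = sm.OLS(design.response, Xmat).fit()
    pvals = fit.pvalues[1:]
    return [EffectEstimate(e.term, e.estimate, bool(p < alpha), "replicated-anova")
            for e, p in zip(effects, pvals)]


class FactorialModel:
    """Fixed-effects analysis of a complete two-level factorial design."""

    def __init__(self, design: DesignTable, max_order: Optional[int] = None,
                 method: str = "lenth", alpha: float = 0.05):
        self.design = design
        self.max_order = max_order
        self.method = method
        self.alpha = alpha

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, response_col="response",
                       group_col="group", blank_id=None, **kwargs) -> "FactorialModel":
        return cls(DesignTable.from_dataframe(df, response_col=response_col,
                                              group_col=group_col, blank_id=blank_id),
                   **kwargs)

    def fit(self, screen: bool = True) -> "FactorialResults":
        effects = factorial_effects(self.design, self.max_order)
        if screen:
            try:
                effects = significance_screen(effects, self.method,
                                              design=self.design, alpha=self.alpha)
            except ValueError:
                # screening infeasible for this shape; keep raw estimates
                pass
        return FactorialResults(design=self.design, effects=effects,
                                method=self.method, alpha=self.alpha)


@dataclass(frozen=True)
class FactorialResults:
    design: DesignTable
    effects: list
    method: str
    alpha: float

    def effects_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "term": [e.label for e in self.effects],
            "order": [e.order for e in self.effects],
            "estimate": [e.estimate for e in self.effects],
            "significant": [e.significant for e in self.effects],
            "method": [e.method for e in self.effects],
        })

    def marginal_means(self) -> pd.DataFrame:
        rows = []
        for f in self.design.factor_names:
            for level in (0, 1):
                rows.append({"factor": f, "level": level,
                             "mean_energy": marginal_mean(self.design, f, level)})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Two-level factorial effect analysis",
            "=" * 45,
            f"factors: {', '.join(self.design.factor_names)}   "
            f"runs: {len(self.design.response)}   "
            f"screen: {self.method} (alpha={self.alpha})",
            "",
            "Marginal means (kJ/mol):",
            self.marginal_means().to_string(index=False,
                                            float_format=lambda x: f"{x:.3f}"),
            "",
            "Effect estimates (kJ/mol):",
            self.effects_frame().to_string(index=False,
                                           float_format=lambda x: f"{x:.3f}"),
        ]
        return "\n".join(lines)
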