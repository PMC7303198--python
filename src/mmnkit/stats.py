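"""Within-subject factorial inference with Holm step-down correction.

All factors are two-level and fully within-subject, so every ANOVA effect
has df = (1, n-1) and reduces to a one-sample t test on a per-subject
contrast score: code each cell +/-1 per factor in the effect, multiply the
codes, average the coded cell values within subject, and test the mean
score against zero.  F equals that squared t; sphericity corrections are
moot at df = 1.  Holm's step-down procedure controls the family-wise
error over the a priori hypothesis family.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as spstats


class StatsError(ValueError):
    pass


@dataclass
class EffectResult:
    """One ANOVA or t-test effect."""

    name: str
    statistic: float  # F for ANOVA effects, t for paired tests
    kind: str  # 'F' | 't'
    df: tuple[float, float] | float
    p_raw: float
    p_holm: float | None = None
    direction: str = ""
    mean_contrast: float = 0.0
    degenerate: bool = False
    eta_p2: float | None = None

    def as_dict(self) -> dict:
        d = {
            "effect": self.name,
            "stat": self.statistic,
            "kind": self.kind,
            "df": self.df if isinstance(self.df, (int, float)) else list(self.df),
            "p_raw": self.p_raw,
            "p_holm": self.p_holm,
            "direction": self.direction,
            "mean_contrast": self.mean_contrast,
            "degenerate": self.degenerate,
            "eta_p2": self.eta_p2,
        }
        return d


def _pivot(table: pd.DataFrame, dv: str, subject: str, factors: list[str]) -> tuple[np.ndarray, list[tuple], list]:
    """subjects x cells value matrix plus cell level tuples; validates the
    complete crossing."""
    for col in [dv, subject, *factors]:
        if col not in table.columns:
            raise StatsError(f"column {col!r} missing from cell table")
    levels = {f: sorted(table[f].unique()) for f in factors}
    for f, lv in levels.items():
        if len(lv) != 2:
            raise StatsError(f"factor {f!r} must have exactly 2 levels, got {lv}")
    piv = table.pivot_table(index=subject, columns=factors, values=dv, aggfunc="mean")
    if piv.isna().any().any():
        raise StatsError("missing cells: the subject x cell crossing is incomplete")
    n_cells = int(np.prod([2] * len(factors)))
    if piv.shape[1] != n_cells:
        raise StatsError(
            f"expected {n_cells} cells for factors {factors}, found {piv.shape[1]}"
        )
    if piv.shape[0] < 2:
        raise StatsError("need at least 2 subjects")
    cols = list(piv.columns) if len(factors) > 1 else [(c,) for c in piv.columns]
    return piv.to_numpy(dtype=float), cols, [levels[f] for f in factors]


def rm_anova_2k(
    table: pd.DataFrame,
    dv: str = "value",
    subject: str = "subject",
    factors: list[str] | None = None,
) -> list[EffectResult]:
    """Fully within-subject 2^k repeated-measures ANOVA via contrast scores.

    For each of the 2^k - 1 effects: per-subject score = mean over cells of
    (product of +/-1 codes) x value; F = n * mean(score)^2 / var(score),
    df (1, n-1).  Zero-variance contrasts are reported with a ``degenerate``
    flag (p=0 if the mean score is nonzero, else F=0, p=1) instead of
    raising.  Results are label-driven: cell/column order is irrelevant.
    """
    if not factors:
        raise StatsError("factors must be a non-empty list")
    values, cells, levels = _pivot(table, dv, subject, factors)
    n = values.shape[0]
    results: list[EffectResult] = []
    for k in range(1, len(factors) + 1):
        for combo in combinations(range(len(factors)), k):
            codes = np.ones(len(cells))
            for ci, cell in enumerate(cells):
                for fi in combo:
                    codes[ci] *= 1.0 if cell[fi] == levels[fi][0] else -1.0
            scores = (values * codes).mean(axis=1)
            mean_s = float(scores.mean())
            var_s = float(scores.var(ddof=1))
            name = " x ".join(factors[fi] for fi in combo)
            direction = _describe_direction(factors, levels, combo, mean_s)
            if var_s == 0.0:
                degenerate = True
                if mean_s == 0.0:
                    F, p = 0.0, 1.0
                else:
                    F, p = float("inf"), 0.0
            else:
                degenerate = False
                F = n * mean_s**2 / var_s
                p = float(spstats.f.sf(F, 1, n - 1))
            eta = F / (F + (n - 1)) if np.isfinite(F) else 1.0
            results.append(
                EffectResult(
                    name=name, statistic=float(F), kind="F", df=(1, n - 1),
                    p_raw=p, direction=direction, mean_contrast=mean_s,
                    degenerate=degenerate, eta_p2=float(eta),
                )
            )
    return results


def _describe_direction(factors, levels, combo, mean_s: float) -> str:
    if len(combo) == 1:
        fi = combo[0]
        a, b = levels[fi][0], levels[fi][1]
        sign = ">" if mean_s > 0 else ("<" if mean_s < 0 else "=")
        return f"{a} {sign} {b} (mean difference {2 * mean_s:+.4g})"
    return f"interaction contrast {mean_s:+.4g}"


def rm_anova_2x2_latency(
    table: pd.DataFrame,
    dv: str = "latency_ms",
    subject: str = "subject",
    factors: tuple[str, str] = ("phonprob", "sylstr"),
) -> list[EffectResult]:
    """2 x 2 repeated-measures ANOVA on FCz peak latencies (condition and
    ROI are not factors here: the latency is a single-electrode
    difference-wave measure)."""
    return rm_anova_2k(table, dv=dv, subject=subject, factors=list(factors))


def holm_adjust(pvalues, m: int | None = None) -> np.ndarray:
    """Holm step-down adjusted p-values.

    Sort ascending; adjusted_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)) with
    1-based ranks; restored to input order.  ``m`` defaults to the number
    of p-values but may be larger when the family contains further tests.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise StatsError(f"family size m={m} smaller than number of p-values {p.size}")
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(p.size)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty_like(p)
    out[order] = adj_sorted
    return out


def posthoc_paired_t(
    x, y, name: str = "paired t", n_comparisons: int = 1
) -> EffectResult:
    """Two-sided paired-samples t test with Bonferroni multiplication over
    the comparison family (p capped at 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatsError("paired samples must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise StatsError("paired t test needs n >= 2")
    d = x - y
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean_d == 0.0:
            t, p, degenerate = 0.0, 1.0, False
        else:
            t, p, degenerate = float("inf") * np.sign(mean_d), 0.0, True
    else:
        t = mean_d / (sd / np.sqrt(n))
        p = float(2 * spstats.t.sf(abs(t), n - 1))
        degenerate = False
    return EffectResult(
        name=name, statistic=float(t), kind="t", df=float(n - 1), p_raw=p,
        p_holm=min(1.0, p * n_comparisons),
        direction=f"mean difference {mean_d:+.4g}",
        mean_contrast=mean_d, degenerate=degenerate,
    )


#: A priori hypothesis families, per deviant type.  Effect names refer to
#: the amplitude ANOVA (factors phonprob x sylstr x cond x roi) and the
#: latency ANOVA (phonprob x sylstr).
HYPOTHESIS_FAMILIES = {
    "FD": [
        ("amplitude", "cond", "H1: deviants elicit an MMN (Cond main effect)"),
        ("amplitude", "phonprob x cond", "H2a: MMN amplitude sensitive to phonotactic probability"),
        ("amplitude", "phonprob x sylstr x cond", "H3a: three-way modulation of the MMN"),
        ("latency", "phonprob", "H2b: MMN latency sensitive to phonotactic probability"),
        ("latency", "phonprob x sylstr", "H3b: stress modulates the latency effect"),
    ],
    "TD": [
        ("amplitude", "cond", "H1: deviants elicit an MMN (Cond main effect)"),
        ("amplitude", "sylstr x cond", "H2a: MMN amplitude sensitive to syllable stress"),
        ("amplitude", "phonprob x sylstr x cond", "H3a: three-way modulation of the MMN"),
        ("latency", "sylstr", "H2b: MMN latency sensitive to syllable stress"),
        ("latency", "phonprob x sylstr", "H3b: phonotactic probability modulates the latency effect"),
    ],
}


def hypothesis_report(
    amplitude_effects: dict[str, list[EffectResult]],
    latency_effects: dict[str, list[EffectResult]],
    alpha: float = 0.05,
    families: dict | None = None,
) -> pd.DataFrame:
    """Assemble the a priori effect family per deviant type, Holm-correct
    within each family, and emit a verdict table (one row per hypothesis,
    with family size m printed alongside every adjusted p)."""
    families = families or HYPOTHESIS_FAMILIES
    rows = []
    for devtype, fam in families.items():
        amp = {e.name.lower(): e for e in amplitude_effects.get(devtype, [])}
        lat = {e.name.lower(): e for e in latency_effects.get(devtype, [])}
        effects = []
        for source, ename, label in fam:
            pool = amp if source == "amplitude" else lat
            e = pool.get(ename.lower())
            if e is not None:
                effects.append((source, ename, label, e))
        if not effects:
            continue
        m = len(fam)
        adj = holm_adjust([e.p_raw for *_, e in effects], m=m)
        for (source, ename, label, e), p_holm in zip(effects, adj):
            rows.append(
                {
                    "deviant_type": devtype,
                    "hypothesis": label,
                    "measure": source,
                    "effect": e.name,
                    "stat": e.statistic,
                    "df1": e.df[0] if isinstance(e.df, tuple) else np.nan,
                    "df2": e.df[1] if isinstance(e.df, tuple) else e.df,
                    "p_raw": e.p_raw,
                    "m": m,
                    "p_holm": float(p_holm),
                    "significant": bool(p_holm < alpha),
                    "direction": e.direction,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "deviant_type", "hypothesis", "measure", "effect", "stat", "df1", "df2",
            "p_raw", "m", "p_holm", "significant", "direction",
        ],
    )


def effects_to_frame(effects: list[EffectResult]) -> pd.DataFrame:
    return pd.DataFrame([e.as_dict() for e in effects])
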