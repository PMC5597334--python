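"""Group statistics: Welch's t-test, fold changes, dispersion summaries.

The two-sample comparison used throughout is the unpaired t-test with
Welch's correction for unequal variances:

    t  = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b)
    df = (s2_a/n_a + s2_b/n_b)^2 /
         [ (s2_a/n_a)^2/(n_a - 1) + (s2_b/n_b)^2/(n_b - 1) ]   (Welch-Satterthwaite)

with a two-sided p from the t distribution.  Significance tiers follow the
source convention ``*** p<0.001, ** p<0.01, * p<0.1`` by default (note the
lax single star); a standard 0.05/0.01/0.001 scheme is available via
``scheme="standard"``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._errors import DegenerateDataError, ValidationError

__all__ = ["GroupSample", "TestResult", "welch_t_test", "fold_change",
           "summarize", "significance_tier", "compare_groups"]

_TIER_CUTS = {
    # label scheme: [(p_cut, stars), ...] checked in order
    "paper": [(0.001, "***"), (0.01, "**"), (0.1, "*")],
    "standard": [(0.001, "***"), (0.01, "**"), (0.05, "*")],
}


@dataclass(frozen=True)
class GroupSample:
    """A labelled group of per-specimen measurements."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if not all(np.isfinite(vals)):
            raise ValidationError(f"group {self.label!r} contains non-finite values")
        object.__setattr__(self, "values", vals)

    @classmethod
    def of(cls, label: str, values: Iterable[float]) -> "GroupSample":
        return cls(label, tuple(values))

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    def var(self) -> float:
        return float(np.var(self.values, ddof=1))


@dataclass(frozen=True)
class TestResult:
    """Welch test outcome plus the derived effect summaries."""

    t: float
    df: float
    p: float
    mean_difference: float
    fold_change: float          # mean_a / mean_b; NaN when mean_b <= 0
    tier: str


def significance_tier(p: float, scheme: str = "paper") -> str:
    """Map a p-value to its star tier under the chosen legend."""
    if scheme not in _TIER_CUTS:
        raise ValidationError(f"unknown tier scheme {scheme!r}; allowed: {list(_TIER_CUTS)}")
    for cut, stars in _TIER_CUTS[scheme]:
        if p < cut:
            return stars
    return "ns"


def welch_t_test(a: GroupSample, b: GroupSample, *, scheme: str = "paper") -> TestResult:
    """Unpaired two-sided t-test with Welch's correction.

    Raises
    ------
    DegenerateDataError
        If both groups have zero variance (the statistic is undefined).
    """
    if a.n < 2 or b.n < 2:
        raise ValidationError("Welch test needs n >= 2 in both groups")
    va, vb = a.var(), b.var()
    if va == 0.0 and vb == 0.0:
        if a.mean == b.mean:
            # identical constants: no evidence of difference
            return TestResult(t=0.0, df=float(a.n + b.n - 2), p=1.0,
                              mean_difference=0.0,
                              fold_change=a.mean / b.mean if b.mean > 0 else float("nan"),
                              tier="ns")
        raise DegenerateDataError("both groups have zero variance; t undefined")
    sa, sb = va / a.n, vb / b.n
    se = np.sqrt(sa + sb)
    t = (a.mean - b.mean) / se
    df = (sa + sb) ** 2 / (
        (sa ** 2 / (a.n - 1) if a.n > 1 else 0.0)
        + (sb ** 2 / (b.n - 1) if b.n > 1 else 0.0))
    p = float(2.0 * sps.t.sf(abs(t), df))
    fc = a.mean / b.mean if b.mean > 0 else float("nan")
    return TestResult(t=float(t), df=float(df), p=p,
                      mean_difference=float(a.mean - b.mean),
                      fold_change=fc, tier=significance_tier(p, scheme))


def fold_change(a: GroupSample, b: GroupSample) -> float:
    """``mean_a / mean_b``; *b* is the reference group."""
    if not b.mean > 0:
        raise ValidationError(
            f"fold change undefined: reference group {b.label!r} has mean {b.mean:g} <= 0")
    return a.mean / b.mean


def summarize(groups: Sequence[GroupSample], error_bar: str = "sd") -> pd.DataFrame:
    """Per-group mean, sd, sem and n, CSV-ready.

    ``error_bar`` selects which dispersion column is flagged for plotting
    ("sd" or "sem"); both are always reported.
    """
    if error_bar not in ("sd", "sem"):
        raise ValidationError("error_bar must be 'sd' or 'sem'")
    rows = []
    for g in groups:
        if g.n < 1:
            raise ValidationError(f"group {g.label!r} is empty")
        sd = float(np.std(g.values, ddof=1)) if g.n > 1 else 0.0
        rows.append({"group": g.label, "n": g.n, "mean": g.mean,
                     "sd": sd, "sem": sd / np.sqrt(g.n), "error_bar": error_bar})
    return pd.DataFrame(rows)


def compare_groups(df: pd.DataFrame, group_col: str, value_col: str,
                   control: str | None = None, *, scheme: str = "paper",
                   ) -> pd.DataFrame:
    """Welch-test every group against the control (default: first group).

    Returns one tidy row per comparison with t, df, p, mean difference,
    fold change and the star tier.
    """
    for col in (group_col, value_col):
        if col not in df.columns:
            raise ValidationError(f"column {col!r} not in table ({list(df.columns)})")
    labels = list(dict.fromkeys(df[group_col]))
    if control is None:
        control = labels[0]
    if control not in labels:
        raise ValidationError(f"control group {control!r} not found among {labels}")
    ref = GroupSample.of(str(control), df.loc[df[group_col] == control, value_col])
    rows = []
    for lab in labels:
        if lab == control:
            continue
        test = GroupSample.of(str(lab), df.loc[df[group_col] == lab, value_col])
        res = welch_t_test(test, ref, scheme=scheme)
        rows.append({"group": lab, "control": control, "n": test.n,
                     "n_control": ref.n, "t": res.t, "df": res.df, "p": res.p,
                     "mean_difference": res.mean_difference,
                     "fold_change": res.fold_change, "tier": res.tier})
    return pd.DataFrame(rows)
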