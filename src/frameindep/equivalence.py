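"""One-sided noninferiority t-test for intra- vs inter-case divergence.

The question is whether regions sampled from two frames of the *same* case
diverge as much as regions sampled from two *different* cases — if they do,
the frames can be treated as independent training instances.  With
``M1`` the mean inter-case JS divergence and ``M2`` the mean intra-case JS
divergence, the null hypothesis is that intra divergence is *meaningfully
lower* than inter divergence:

    H0: M1 - M2 >= delta        (frames are dependent)
    H1: M1 - M2 <  delta        (intra divergence within the margin)

with margin ``delta = delta_frac * M1`` (default 5% of the inter mean).
The statistic is the two-sample t with pooled variance,

    t = (M1 - M2 - delta) / SE,
    SE = s_p * sqrt(1/n1 + 1/n2),
    s_p^2 = [(n1-1) s1^2 + (n2-1) s2^2] / (n1 + n2 - 2),

and the one-sided p-value is ``P(T_df <= t)`` with ``df = n1 + n2 - 2``.
Small p rejects H0: the intra-sampled regions do not have significantly
lower divergence than inter-case regions, supporting independence.

Note on the pooled form: the published display of this statistic is
occasionally typeset with a minus sign between the two ``(n-1) s^2`` terms
and a missing "+" between ``1/n1`` and ``1/n2``; the denominator is, as
stated wherever the test is described, simply the standard error of the
mean difference, i.e. the standard pooled form implemented here.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import SampleSizeError

__all__ = [
    "EquivalenceResult",
    "equivalence_t_test",
    "equivalence_from_stats",
    "group_independence_report",
]


@dataclass
class EquivalenceResult:
    """Summary of one intra-vs-inter noninferiority test.

    ``independent`` is True when ``p < alpha``: the intra-case divergence is
    statistically within ``delta`` of the inter-case divergence.
    ``degenerate`` flags a zero pooled variance, where the decision is taken
    from the sign of ``M1 - M2 - delta`` alone (p set to 0, 0.5 or 1).
    """

    m1: float  # mean inter-case JS
    sd1: float
    n1: int
    m2: float  # mean intra-case JS
    sd2: float
    n2: int
    delta_frac: float
    delta: float
    t: float
    df: float
    p: float
    alpha: float
    independent: bool
    welch: bool = False
    degenerate: bool = False

    @property
    def p_lower(self) -> float:
        """Lower-tail p-value ``P(T_df <= t)`` — the test's p."""
        return self.p

    @property
    def p_upper(self) -> float:
        """Upper-tail p-value ``P(T_df >= t)``, exposed for transparency."""
        if self.degenerate:
            return 1.0 - self.p if self.p != 0.5 else 0.5
        return float(stats.t.sf(self.t, self.df))

    def to_dict(self) -> dict:
        return asdict(self)


def equivalence_from_stats(
    m1: float,
    sd1: float,
    n1: int,
    m2: float,
    sd2: float,
    n2: int,
    delta_frac: float = 0.05,
    alpha: float = 0.05,
    welch: bool = False,
) -> EquivalenceResult:
    """Noninferiority test from summary statistics (sample SDs, divisor n-1).

    ``welch=True`` uses the unpooled standard error with Welch-Satterthwaite
    degrees of freedom instead of the pooled default.
    """
    if n1 < 2 or n2 < 2:
        raise SampleSizeError(f"both samples need n >= 2 (got n1={n1}, n2={n2})")
    if delta_frac < 0:
        raise SampleSizeError("delta_frac must be >= 0")
    delta = delta_frac * m1
    num = m1 - m2 - delta
    v1, v2 = sd1**2, sd2**2
    if welch:
        se2 = v1 / n1 + v2 / n2
        df = (
            se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            if se2 > 0
            else float(n1 + n2 - 2)
        )
    else:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        se2 = sp2 * (1.0 / n1 + 1.0 / n2)
        df = float(n1 + n2 - 2)
    degenerate = se2 <= 0.0
    if degenerate:
        # all mass at two points: decide by the sign of the numerator
        t = -np.inf if num < 0 else (np.inf if num > 0 else 0.0)
        p = 0.0 if num < 0 else (1.0 if num > 0 else 0.5)
    else:
        t = num / np.sqrt(se2)
        p = float(stats.t.cdf(t, df))
    return EquivalenceResult(
        m1=float(m1),
        sd1=float(sd1),
        n1=int(n1),
        m2=float(m2),
        sd2=float(sd2),
        n2=int(n2),
        delta_frac=float(delta_frac),
        delta=float(delta),
        t=float(t),
        df=df,
        p=float(p),
        alpha=float(alpha),
        independent=bool(p < alpha),
        welch=welch,
        degenerate=degenerate,
    )


def equivalence_t_test(
    inter: Sequence[float],
    intra: Sequence[float],
    delta_frac: float = 0.05,
    alpha: float = 0.05,
    welch: bool = False,
) -> EquivalenceResult:
    """Noninferiority test from the raw inter and intra JS samples."""
    inter = np.asarray(inter, dtype=float)
    intra = np.asarray(intra, dtype=float)
    if inter.size < 2 or intra.size < 2:
        raise SampleSizeError(
            f"both samples need n >= 2 (got n1={inter.size}, n2={intra.size})"
        )
    return equivalence_from_stats(
        m1=inter.mean(),
        sd1=inter.std(ddof=1),
        n1=inter.size,
        m2=intra.mean(),
        sd2=intra.std(ddof=1),
        n2=intra.size,
        delta_frac=delta_frac,
        alpha=alpha,
        welch=welch,
    )


def group_independence_report(
    groups: Mapping[str, pd.DataFrame],
    delta_frac: float = 0.05,
    alpha: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """One noninferiority test per group from tagged divergence samples.

    ``groups`` maps a group label to a divergence sample table with columns
    ``kind`` ("intra"/"inter") and ``js``.  Returns one row per group with
    the intra/inter mean +- sd summary and the test decision.
    """
    rows = []
    for group, samples in groups.items():
        inter = samples.loc[samples["kind"] == "inter", "js"].to_numpy()
        intra = samples.loc[samples["kind"] == "intra", "js"].to_numpy()
        res = equivalence_t_test(
            inter, intra, delta_frac=delta_frac, alpha=alpha, welch=welch
        )
        rows.append(
            {
                "group": group,
                "n_intra": res.n2,
                "n_inter": res.n1,
                "mean_intra": res.m2,
                "sd_intra": res.sd2,
                "mean_inter": res.m1,
                "sd_inter": res.sd1,
                "delta": res.delta,
                "t": res.t,
                "df": res.df,
                "p": res.p,
                "independent": res.independent,
            }
        )
    return pd.DataFrame(rows)
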