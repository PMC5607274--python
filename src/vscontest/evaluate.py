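"""Statistical comparison of competing screening methods.

Each participating group proposes a ranked compound list; after the
assay cascade every group has ``n_g`` assayed compounds and ``k_g``
hits.  Under the null that every method performs at the pooled rate
``p0 = K / N`` (distinct hits over distinct assayed compounds), a
group's hit count is Binomial(n_g, p0); the one-sided exact tail
``P(X >= k_g)`` is the group's p-value, Bonferroni-multiplied by the
number of groups.  A hit proposed by several groups was assayed once
but is credited to each proposer, so Sum(k_g) may exceed K.

The module also provides enrichment-by-rank curves, a truncation
analysis (re-scoring each group on its top ``m`` assayed compounds) and
the assay-budget design calculation: with true hit rate ``r`` and ``n``
assays the probability of ending with zero hits is ``(1 - r)^n``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import math

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError


def binom_tail(k: int, n: int, p: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p).

    Evaluated through the regularized incomplete beta function, so the
    result is exact to machine precision rather than a normal
    approximation.  Monotone decreasing in ``k``.
    """
    if not (0 <= k <= n):
        raise InputError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0.0 <= p <= 1.0):
        raise InputError(f"p must be a probability, got {p}")
    if k == 0:
        return 1.0
    return float(stats.binom.sf(k - 1, n, p))


@dataclass
class ContestOutcome:
    """Per-group assay results plus pooled totals.

    ``groups`` maps group id to a DataFrame with columns ``rank`` and
    ``compound_id`` (the group's assayed compounds in proposal order);
    ``hits`` is the set of hit compound ids.  ``N``/``K`` count distinct
    compounds across groups; ``p0 = K/N`` is the pooled hit rate.
    """

    groups: dict
    hits: set
    N: int = field(init=False)
    K: int = field(init=False)
    p0: float = field(init=False)

    def __post_init__(self):
        assayed = set()
        for gid, df in self.groups.items():
            if df["rank"].duplicated().any():
                raise InputError(f"group {gid} has duplicate ranks")
            assayed |= set(df["compound_id"])
        missing = self.hits - assayed
        if missing:
            raise InputError(f"hit(s) not in any assayed list: {sorted(missing)}")
        self.N = len(assayed)
        self.K = len(self.hits & assayed)
        self.p0 = self.K / self.N if self.N else 0.0

    def group_counts(self) -> pd.DataFrame:
        rows = [(g, len(df), int(df["compound_id"].isin(self.hits).sum()))
                for g, df in self.groups.items()]
        return pd.DataFrame(rows, columns=["group", "n", "k"])


def evaluate_groups(outcome: ContestOutcome, alpha: float = 0.05,
                    n_tests: int | None = None) -> pd.DataFrame:
    """Exact binomial test of each group against the pooled rate.

    Raw p = P(X >= k_g | n_g, p0), Bonferroni-corrected by the number of
    groups (``n_tests`` overrides), capped at 1.  With zero hits overall
    the null rate is degenerate and every p is 1 (with a warning).
    """
    counts = outcome.group_counts()
    G = n_tests if n_tests is not None else len(outcome.groups)
    if outcome.K == 0:
        warnings.warn("no hits in the contest; null rate degenerate, all p = 1")
        counts["p_raw"] = 1.0
    else:
        counts["p_raw"] = [binom_tail(k, n, outcome.p0)
                           for n, k in zip(counts["n"], counts["k"])]
    counts["p_bonferroni"] = np.minimum(1.0, G * counts["p_raw"])
    counts["significant"] = counts["p_bonferroni"] < alpha
    counts["p0"] = outcome.p0
    return counts


def enrichment_curve(ranked: pd.DataFrame, hits: set,
                     p0: float | None = None) -> pd.DataFrame:
    """Cumulative hits by rank, with the pooled-rate expectation line.

    ``ranked`` has columns ``rank`` and ``compound_id``.  Returns one
    row per rank with ``cum_hits`` and (if ``p0`` given) ``expected =
    rank * p0``.  Also exposes the top-half hit fraction via attrs.
    """
    if ranked["rank"].duplicated().any():
        raise InputError("ranks must be unique within a group")
    df = ranked.sort_values("rank").reset_index(drop=True)
    unknown = set(hits) - set(df["compound_id"])
    if unknown:
        raise InputError(
            f"hit(s) not in the assayed list: {sorted(unknown)}; intersect the "
            "hit set with this group's compounds first"
        )
    is_hit = df["compound_id"].isin(hits).to_numpy()
    out = pd.DataFrame({
        "rank": df["rank"].to_numpy(),
        "cum_hits": np.cumsum(is_hit),
    })
    if p0 is not None:
        out["expected"] = out["rank"] * p0
    total = int(is_hit.sum())
    half = len(df) // 2
    out.attrs["top_half_hit_fraction"] = (
        float(np.cumsum(is_hit)[half - 1] / total) if total and half else np.nan
    )
    return out


def truncation_analysis(outcome: ContestOutcome, m: int,
                        alpha: float = 0.05) -> pd.DataFrame:
    """Re-score each group on its top ``m`` assayed compounds.

    ``p0`` stays fixed at the full-contest pooled rate: the question is
    whether a smaller assay budget would have reached the same verdicts,
    not what the pooled rate would then have been.  Groups with fewer
    than ``m`` assayed compounds are clipped with a warning.
    """
    if m <= 0:
        raise InputError("truncation depth m must be positive")
    truncated = {}
    for g, df in outcome.groups.items():
        if len(df) < m:
            warnings.warn(f"group {g} has only {len(df)} assayed; clipping")
        truncated[g] = df.sort_values("rank").head(m)
    rows = []
    G = len(outcome.groups)
    for g, df in truncated.items():
        k = int(df["compound_id"].isin(outcome.hits).sum())
        n = len(df)
        p_raw = binom_tail(k, n, outcome.p0) if outcome.K else 1.0
        rows.append((g, n, k, p_raw, min(1.0, G * p_raw)))
    out = pd.DataFrame(rows, columns=["group", "n", "k", "p_raw", "p_bonferroni"])
    out["significant"] = out["p_bonferroni"] < alpha
    out["p0"] = outcome.p0
    return out


def design_power(rate: float, n: int) -> tuple[float, float]:
    """Probability of zero hits and of at least one hit in ``n`` assays.

    ``p_zero = (1 - rate)^n``; the complement equals
    ``binom_tail(1, n, rate)`` to machine precision.
    """
    if not (0.0 <= rate <= 1.0):
        raise InputError(f"rate must be a probability, got {rate}")
    if n < 0:
        raise InputError("n must be non-negative")
    p_zero = (1.0 - rate) ** n
    return p_zero, 1.0 - p_zero


def min_assays(rate: float, detect_prob: float) -> int:
    """Smallest n with P(at least one hit) >= detect_prob.

    Closed form ceil(log(1-q)/log(1-r)), nudged for floating-point edge
    cases so ``design_power(rate, n)[1] >= detect_prob`` holds exactly.
    """
    if not (0.0 < rate < 1.0):
        raise InputError("rate must lie strictly between 0 and 1")
    if not (0.0 < detect_prob < 1.0):
        raise InputError("detect_prob must lie strictly between 0 and 1")
    n = max(1, math.ceil(math.log1p(-detect_prob) / math.log1p(-rate)))
    while design_power(rate, n)[1] < detect_prob:
        n += 1
    while n > 1 and design_power(rate, n - 1)[1] >= detect_prob:
        n -= 1
    return n
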