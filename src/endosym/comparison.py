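"""Paired symbiont-vs-relative statistics and the partnership-level sign test.

Per-pair inference is deliberately absent: when whole proteomes are compared
there is no sampling noise to account for, so each pair contributes an effect
size and a direction only.  Inference happens at the partnership level, where
the count of direction agreements is tested against a Binomial(n, 1/2) null
with an exact upper-tail probability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from statistics import fmean

from scipy import stats as _scipy_stats

from .properties import FEATURES
from .seq_io import EmptyProfileError, GenomeProfile

__all__ = [
    "PREDICTED_SIGNS",
    "PairComparison",
    "SignTestResult",
    "CorrelationResult",
    "StratumSummary",
    "DegenerateCorrelationError",
    "compare_pair",
    "binom_upper_tail",
    "sign_test",
    "gene_correlation",
    "stratified_summary",
]

#: A-priori predicted direction of (symbiont mean - relative mean): retained
#: genes are expected to be more hydrophobic and to have lower amino pKa.
#: No prediction exists for carboxyl pKa; it must be supplied explicitly.
PREDICTED_SIGNS: dict[str, int] = {"hydrophobicity": +1, "amino_pka": -1}


class DegenerateCorrelationError(ValueError):
    """A correlation was requested on a feature with zero variance."""


@dataclass(frozen=True)
class PairComparison:
    """One symbiont-vs-relative mean difference for one feature.

    ``agrees`` is True iff the sign of the difference equals the predicted
    sign and the difference is nonzero (an exact tie counts as disagreement,
    conservative for the one-sided alternative).
    """

    symbiont_id: str
    relative_id: str
    feature: str
    symbiont_mean: float
    relative_mean: float
    difference: float
    predicted_sign: int
    agrees: bool

    @property
    def label(self) -> str:
        """Partnership label used for merge-group lookups."""
        return f"{self.symbiont_id}~{self.relative_id}"


@dataclass(frozen=True)
class SignTestResult:
    """k-of-n direction agreements and the exact binomial upper tail."""

    k: int
    n: int
    p_value: float
    grouping: str = "none"


@dataclass(frozen=True)
class CorrelationResult:
    r_squared: float
    n_genes: int
    feature_x: str
    feature_y: str
    method: str = "pearson"


@dataclass(frozen=True)
class StratumSummary:
    """Gene count and feature means for one annotation stratum."""

    stratum: str  # "ribosomal" or "non_ribosomal"
    count: int
    means: dict[str, float] | None  # None flags an empty stratum


def _feature_values(profile: GenomeProfile, feature: str) -> list[float]:
    return [stat.value_for(feature) for stat in profile.stats]


def compare_pair(
    symbiont: GenomeProfile,
    relative: GenomeProfile,
    feature: str,
    predicted_sign: int | None = None,
) -> PairComparison:
    """Compare one partnership on one feature.

    The genome-level summary is the unweighted arithmetic mean over genes
    (each gene counts once regardless of length), matching gene-level
    distribution displays.  ``predicted_sign`` defaults to the theory's
    direction (+1 hydrophobicity, -1 amino pKa) and must be given explicitly
    for carboxyl pKa, for which no prediction exists.
    """
    if feature not in FEATURES:
        raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURES}")
    if len(symbiont) == 0 or len(relative) == 0:
        raise EmptyProfileError("both profiles must contain scored genes")
    if predicted_sign is None:
        if feature not in PREDICTED_SIGNS:
            raise ValueError(
                f"no a-priori predicted sign for {feature!r}; pass predicted_sign"
            )
        predicted_sign = PREDICTED_SIGNS[feature]
    if predicted_sign not in (+1, -1):
        raise ValueError("predicted_sign must be +1 or -1")
    symbiont_mean = fmean(_feature_values(symbiont, feature))
    relative_mean = fmean(_feature_values(relative, feature))
    difference = symbiont_mean - relative_mean
    agrees = difference != 0.0 and math.copysign(1.0, difference) == predicted_sign
    return PairComparison(
        symbiont_id=symbiont.organism_id,
        relative_id=relative.organism_id,
        feature=feature,
        symbiont_mean=symbiont_mean,
        relative_mean=relative_mean,
        difference=difference,
        predicted_sign=predicted_sign,
        agrees=agrees,
    )


def binom_upper_tail(k: int, n: int, p: float = 0.5) -> float:
    """Exact upper tail P(B >= k) for B ~ Binomial(n, p).

    The sum ``sum_{j=k}^{n} C(n, j) p^j (1-p)^(n-j)`` is evaluated in exact
    rational arithmetic (the float ``p`` is taken at its exact binary value),
    then returned as a float.  ``k = 0`` returns 1; ``k = n + 1`` returns 0.
    """
    if not 0 <= k <= n + 1:
        raise ValueError(f"k must satisfy 0 <= k <= n + 1, got k={k}, n={n}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"p must lie in (0, 1), got {p}")
    pf = Fraction(p)
    total = Fraction(0)
    for j in range(k, n + 1):
        total += math.comb(n, j) * pf**j * (1 - pf) ** (n - j)
    return float(total)


def sign_test(
    comparisons: list[PairComparison],
    merge_groups: dict[str, str] | None = None,
) -> SignTestResult:
    """One-sided exact binomial sign test over partnership comparisons.

    Without merging, ``k`` counts comparisons with ``agrees=True`` and ``n``
    is the total.  With ``merge_groups`` (partnership label, see
    :attr:`PairComparison.label`, -> group label), the comparisons of a merged
    group (per feature) contribute a single Bernoulli observation: agreement
    only if the group is unanimous, disagreement otherwise (conservative).
    """
    if not comparisons:
        raise ValueError("sign_test requires at least one comparison")
    merge_groups = merge_groups or {}
    # One observation per (effective group, feature); ungrouped comparisons
    # keep their own partnership label.
    groups: dict[tuple[str, str], list[bool]] = {}
    for comp in comparisons:
        group = merge_groups.get(comp.label, comp.label)
        groups.setdefault((group, comp.feature), []).append(comp.agrees)
    verdicts = [all(flags) for flags in groups.values()]
    k = sum(verdicts)
    n = len(verdicts)
    grouping = (
        "none"
        if not merge_groups
        else "merged: " + ", ".join(sorted(set(merge_groups.values())))
    )
    return SignTestResult(k=k, n=n, p_value=binom_upper_tail(k, n, 0.5), grouping=grouping)


def gene_correlation(
    profiles: list[GenomeProfile],
    feature_x: str = "hydrophobicity",
    feature_y: str = "amino_pka",
) -> CorrelationResult:
    """Pooled gene-by-gene squared Pearson correlation between two features.

    Every gene from every supplied profile contributes one (x, y) point.
    A weak r-squared indicates the two features carry largely independent
    information about each gene.
    """
    xs: list[float] = []
    ys: list[float] = []
    for profile in profiles:
        xs.extend(_feature_values(profile, feature_x))
        ys.extend(_feature_values(profile, feature_y))
    if len(xs) < 3:
        raise ValueError(f"need at least 3 pooled genes, got {len(xs)}")
    if len(set(xs)) == 1 or len(set(ys)) == 1:
        raise DegenerateCorrelationError(
            f"zero variance in {feature_x if len(set(xs)) == 1 else feature_y}"
        )
    r = _scipy_stats.pearsonr(xs, ys).statistic
    return CorrelationResult(
        r_squared=float(r * r),
        n_genes=len(xs),
        feature_x=feature_x,
        feature_y=feature_y,
    )


def stratified_summary(profile: GenomeProfile) -> tuple[StratumSummary, StratumSummary]:
    """Split one genome's genes into ribosomal / non-ribosomal strata.

    Every gene lands in exactly one stratum according to its annotation; an
    empty stratum reports count 0 with means flagged absent (None).
    """
    strata: dict[bool, list] = {True: [], False: []}
    for record, stat in zip(profile.records, profile.stats):
        strata[record.is_ribosomal].append(stat)
    summaries = []
    for is_rib, name in ((True, "ribosomal"), (False, "non_ribosomal")):
        stats = strata[is_rib]
        if not stats:
            summaries.append(StratumSummary(stratum=name, count=0, means=None))
            continue
        means = {
            feature: fmean(stat.value_for(feature) for stat in stats)
            for feature in FEATURES
        }
        summaries.append(StratumSummary(stratum=name, count=len(stats), means=means))
    return summaries[0], summaries[1]
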