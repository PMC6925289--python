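"""Poisson absolute quantification from partition counts.

With k positive of n valid partitions of volume v (µL), the mean copies per
partition is λ̂ = −ln(1 − k/n) and the sample concentration is λ̂/v in
copies/µL (C_p/µL).  Confidence intervals are exact Clopper–Pearson binomial
intervals on p = k/n mapped through the monotone transform −ln(1−p)/v, so
the conservative binomial coverage carries over.  A zero-positive run is
reported as exactly 0 with the nonzero upper bound −ln(α/2)/(n·v) — the
"true zero" used for molecular-remission calls.  A saturated run (k = n) is
unquantifiable and raises rather than returning infinity.

Mutant allele fractions are target:reference concentration ratios in
percent; the ratio CI maps the target's binomial CI through the ratio while
holding the reference at its point estimate (reference counts are orders of
magnitude larger).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy.stats import beta as beta_dist

from .errors import InvalidInputError, SaturationError
from .geometry import round_sig
from .table import PartitionTable


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial CI for the positive fraction p = k/n."""
    if not 0 < level < 1:
        raise InvalidInputError("level must lie in (0, 1)")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Absolute concentration of one channel from one (pooled) run."""

    channel: str
    k_positive: int
    n_valid: int
    partition_volume_ul: float
    lambda_hat: float
    conc: float            # copies/µL
    ci_low: float
    ci_high: float
    level: float = 0.95

    @property
    def is_true_zero(self) -> bool:
        return self.k_positive == 0

    def __str__(self) -> str:
        return (f"{self.channel or 'channel'}: {self.conc:.1f} C_p/uL "
                f"({self.level:.0%} CI {self.ci_low:.1f}-{self.ci_high:.1f}; "
                f"k={self.k_positive}/{self.n_valid})")


@dataclass(frozen=True)
class FractionEstimate:
    """Target:reference concentration ratio in percent, with CI."""

    target: ConcentrationEstimate
    reference: ConcentrationEstimate
    fraction_pct: float
    ci_low_pct: float
    ci_high_pct: float

    def __str__(self) -> str:
        return (f"{self.target.channel}:{self.reference.channel} = "
                f"{round_sig(self.fraction_pct, 2)}% "
                f"(CI {round_sig(self.ci_low_pct, 2)}-{round_sig(self.ci_high_pct, 2)}%)")


def poisson_concentration(k: int, n: int, v: float, *, channel: str = "",
                          level: float = 0.95) -> ConcentrationEstimate:
    """Estimate concentration from k positive of n valid partitions of volume v µL."""
    if n < 1 or not 0 <= k <= n:
        raise InvalidInputError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if v <= 0:
        raise InvalidInputError("partition volume must be > 0")
    if k == n:
        raise SaturationError(
            f"all {n} partitions positive: concentration is unbounded; "
            "dilute the sample and rerun")
    p = k / n
    lam = -math.log1p(-p)
    p_lo, p_hi = clopper_pearson(k, n, level)
    return ConcentrationEstimate(
        channel, k, n, v, lam, lam / v,
        -math.log1p(-p_lo) / v, -math.log1p(-p_hi) / v, level)


def concentration_ci(k: int, n: int, v: float,
                     level: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson CI endpoints mapped to the concentration scale."""
    est = poisson_concentration(k, n, v, level=level)
    return est.ci_low, est.ci_high


def allele_fraction(target: ConcentrationEstimate,
                    reference: ConcentrationEstimate) -> FractionEstimate:
    """Mutant allele fraction: 100 · target.conc / reference.conc.

    The CI maps the target's interval through the ratio with the reference
    held at its point estimate.
    """
    if reference.conc <= 0:
        raise InvalidInputError(
            "reference concentration is zero: fraction undefined")
    scale = 100.0 / reference.conc
    return FractionEstimate(target, reference, target.conc * scale,
                            target.ci_low * scale, target.ci_high * scale)


@dataclass(frozen=True)
class ReplicateSummary:
    pooled: ConcentrationEstimate
    replicates: tuple[ConcentrationEstimate, ...]
    cv: float  # coefficient of variation of the per-replicate concentrations


def merge_replicates(estimates: Sequence[ConcentrationEstimate], *,
                     level: float | None = None) -> ReplicateSummary:
    """Pool k and n across replicates sharing a partition volume, re-estimate."""
    if len(estimates) < 1:
        raise InvalidInputError("need at least one replicate")
    v = estimates[0].partition_volume_ul
    if any(not math.isclose(e.partition_volume_ul, v) for e in estimates):
        raise InvalidInputError("replicates have mixed partition volumes")
    k = sum(e.k_positive for e in estimates)
    n = sum(e.n_valid for e in estimates)
    pooled = poisson_concentration(
        k, n, v, channel=estimates[0].channel,
        level=level if level is not None else estimates[0].level)
    concs = [e.conc for e in estimates]
    mean = sum(concs) / len(concs)
    if len(concs) > 1 and mean > 0:
        var = sum((c - mean) ** 2 for c in concs) / (len(concs) - 1)
        cv = math.sqrt(var) / mean
    else:
        cv = 0.0
    return ReplicateSummary(pooled, tuple(estimates), cv)


@dataclass(frozen=True)
class SerialPoint:
    label: str
    annotation: str
    estimate: ConcentrationEstimate

    @property
    def true_zero(self) -> bool:
        return self.estimate.is_true_zero


@dataclass(frozen=True)
class SerialReport:
    """Longitudinal concentration series, e.g. minimal-residual-disease tracking."""

    points: tuple[SerialPoint, ...]

    def trend(self) -> tuple[str, ...]:
        """Direction of each step: 'up', 'down', 'flat' (beyond CI overlap)."""
        out = []
        for a, b in zip(self.points, self.points[1:]):
            ea, eb = a.estimate, b.estimate
            if eb.ci_low > ea.ci_high:
                out.append("up")
            elif eb.ci_high < ea.ci_low:
                out.append("down")
            else:
                out.append("flat")
        return tuple(out)

    def summary(self) -> str:
        lines = []
        for p in self.points:
            e = p.estimate
            zero = "  TRUE ZERO" if p.true_zero else ""
            note = f" [{p.annotation}]" if p.annotation else ""
            lines.append(f"{p.label}{note}: {e.conc:.1f} C_p/uL "
                         f"(CI {e.ci_low:.3f}-{e.ci_high:.3f}){zero}")
        return "\n".join(lines)


def serial_monitoring_report(
        runs: Sequence[tuple[str, str, PartitionTable]], v: float, *,
        channel: str, level: float = 0.95) -> SerialReport:
    """Per-timepoint concentrations with true-zero flags for an ordered series."""
    points = []
    for label, annotation, tab in runs:
        k, n, _ = tab.counts(channel)
        est = poisson_concentration(k, n, v, channel=channel, level=level)
        points.append(SerialPoint(label, annotation, est))
    return SerialReport(tuple(points))


def estimate_from_table(tab: PartitionTable, channel: str, v: float, *,
                        level: float = 0.95) -> ConcentrationEstimate:
    """Convenience: ConcentrationEstimate straight from a PartitionTable."""
    k, n, _ = tab.counts(channel)
    return poisson_concentration(k, n, v, channel=channel, level=level)
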