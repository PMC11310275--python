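"""Per-arm loss/gain fraction quantification, extent classes, bins, cut-offs.

This is the core statistic: the fraction of a chromosome arm's bases covered
by segments called as loss (log2 ratio below a threshold).  Extent classes
follow the field's convention for 1p in meningioma: "complete" when more
than 95% of the arm is deleted, "segmental" for >5% up to 95%, "none"
otherwise.  The loss cut-off rule is strict: at a 5% cut-off a sample is
called "1p loss" iff its rounded loss percentage is 6 or higher.

Design choices that are not forced by the definitions:

* Call thresholds default to log2 < -0.15 for loss and log2 > +0.15 for
  gain (strict inequalities).  Methylation-array CNV pipelines leave this
  to the analyst; +/-0.15 is a common array heuristic.  The thresholds are
  configurable and recorded in output metadata.
* Fractions are base-pair-weighted ("95% of the chromosomal arm" reads as
  genomic extent); probe weighting is available via ``weight='probes'``.
* Overlapping same-sample segments are resolved per base by the most
  extreme log2 ratio (largest absolute value; ties broken toward loss),
  which is deterministic and order-independent.
* Loss percentages are rounded half-away-from-zero to integer percent
  before binning or cut-off application, because the rules reason in
  integer percent ("6% or higher").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from armloss.genome import GenomeArm, intersect_length
from armloss.segio import MC_LABELS, CnvSegment

__all__ = [
    "CallThresholds",
    "ArmProfile",
    "BinnedDistribution",
    "call_segment_state",
    "arm_fractions",
    "classify_extent",
    "apply_cutoff",
    "bin_distribution",
    "profiles_to_frame",
]

logger = logging.getLogger(__name__)

DEFAULT_LOSS_LOG2 = -0.15
DEFAULT_GAIN_LOG2 = 0.15


@dataclass(frozen=True)
class CallThresholds:
    """Log2 copy-ratio thresholds for calling loss/gain (strict inequalities)."""

    loss_log2: float = DEFAULT_LOSS_LOG2
    gain_log2: float = DEFAULT_GAIN_LOG2

    def __post_init__(self) -> None:
        if not self.loss_log2 < 0 < self.gain_log2:
            raise ValueError(
                f"thresholds must satisfy loss_log2 < 0 < gain_log2, "
                f"got ({self.loss_log2}, {self.gain_log2})"
            )


@dataclass(frozen=True)
class ArmProfile:
    """Per-sample, per-arm loss/gain/neutral fractions and extent category."""

    sample_id: str
    chrom: str
    arm: str
    loss_fraction: float
    gain_fraction: float
    neutral_fraction: float
    loss_percent: int
    extent_category: str

    def __post_init__(self) -> None:
        total = self.loss_fraction + self.gain_fraction + self.neutral_fraction
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.sample_id}: fractions sum to {total}, expected 1")
        if not 0 <= self.loss_percent <= 100:
            raise ValueError(f"loss_percent out of range: {self.loss_percent}")
        if self.extent_category != classify_extent(self.loss_percent):
            raise ValueError(
                f"{self.sample_id}: extent {self.extent_category!r} inconsistent with "
                f"loss_percent {self.loss_percent}"
            )

    @property
    def arm_name(self) -> str:
        return f"{self.chrom}{self.arm}"


def call_segment_state(seg: CnvSegment, thresholds: CallThresholds) -> str:
    """Classify one segment as 'loss', 'neutral' or 'gain' by its log2 ratio."""
    if seg.log2_ratio < thresholds.loss_log2:
        return "loss"
    if seg.log2_ratio > thresholds.gain_log2:
        return "gain"
    return "neutral"


def _round_percent(fraction: float) -> int:
    """Round half away from zero to integer percent (0.455 -> 46 at percent scale)."""
    return int(math.floor(fraction * 100.0 + 0.5))


def classify_extent(loss_percent: int) -> str:
    """'complete' iff >95%, 'segmental' iff >5% and <=95%, else 'none'."""
    if not 0 <= loss_percent <= 100:
        raise ValueError(f"loss_percent must be in [0, 100], got {loss_percent}")
    if loss_percent > 95:
        return "complete"
    if loss_percent > 5:
        return "segmental"
    return "none"


def apply_cutoff(loss_percent: int, cutoff_percent: int) -> bool:
    """Loss called iff loss_percent strictly exceeds the cut-off.

    At the 5% cut-off this counts cases with a loss percentage of 6% or
    higher; at 0% any detectable loss is counted.
    """
    if not 0 <= cutoff_percent <= 100:
        raise ValueError(f"cutoff_percent must be in [0, 100], got {cutoff_percent}")
    return loss_percent > cutoff_percent


def arm_fractions(
    segments: Iterable[CnvSegment],
    arm: GenomeArm,
    thresholds: CallThresholds | None = None,
    weight: str = "bases",
) -> ArmProfile:
    """Compute one sample's loss/gain/neutral fractions on one arm.

    All segments must belong to a single sample; segments on other
    chromosomes are ignored.  Arm bases not covered by any segment count as
    neutral.  Overlaps are resolved per base by the most extreme log2 ratio.
    With ``weight='probes'`` fractions are probe-count-weighted instead of
    base-pair-weighted (every overlapping segment then needs ``n_probes``).
    """
    if thresholds is None:
        thresholds = CallThresholds()
    if weight not in ("bases", "probes"):
        raise ValueError(f"weight must be 'bases' or 'probes', got {weight!r}")
    if not arm.usable or arm.length <= 0:
        raise ValueError(f"arm {arm.name} is unusable (zero length); cannot compute fractions")

    segs = [s for s in segments if s.chrom == arm.chrom]
    sample_ids = {s.sample_id for s in segs}
    if len(sample_ids) > 1:
        raise ValueError(f"segments from multiple samples passed to arm_fractions: {sorted(sample_ids)}")
    sample_id = next(iter(sample_ids)) if sample_ids else ""

    overlapping = [s for s in segs if intersect_length(s.start, s.end, arm) > 0]

    if weight == "probes":
        return _probe_weighted_profile(overlapping, arm, thresholds, sample_id)

    # Sweep over elementary intervals between segment breakpoints, clipped to
    # the arm; within each interval the most extreme log2 wins.
    cuts = sorted(
        {arm.start, arm.end}
        | {max(s.start, arm.start) for s in overlapping}
        | {min(s.end, arm.end) for s in overlapping}
    )
    loss_bases = 0
    gain_bases = 0
    conflict = False
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        covering = [s for s in overlapping if s.start <= lo and s.end >= hi]
        if not covering:
            continue
        if len(covering) > 1:
            states = {call_segment_state(s, thresholds) for s in covering}
            if len(states) > 1:
                conflict = True
        # max |log2|; tie toward the more negative ratio (loss)
        winner = max(covering, key=lambda s: (abs(s.log2_ratio), -s.log2_ratio))
        state = call_segment_state(winner, thresholds)
        if state == "loss":
            loss_bases += hi - lo
        elif state == "gain":
            gain_bases += hi - lo
    if conflict:
        logger.warning(
            "sample %s arm %s: overlapping segments with conflicting states; "
            "resolved per base by most extreme log2 ratio",
            sample_id,
            arm.name,
        )

    loss_fraction = loss_bases / arm.length
    gain_fraction = gain_bases / arm.length
    return _build_profile(sample_id, arm, loss_fraction, gain_fraction)


def _probe_weighted_profile(
    overlapping: Sequence[CnvSegment],
    arm: GenomeArm,
    thresholds: CallThresholds,
    sample_id: str,
) -> ArmProfile:
    if any(s.n_probes is None for s in overlapping):
        raise ValueError("probe weighting requested but some segments lack n_probes")
    total = sum(s.n_probes for s in overlapping)  # type: ignore[misc]
    if total == 0:
        return _build_profile(sample_id, arm, 0.0, 0.0)
    loss = sum(s.n_probes for s in overlapping if call_segment_state(s, thresholds) == "loss")  # type: ignore[misc]
    gain = sum(s.n_probes for s in overlapping if call_segment_state(s, thresholds) == "gain")  # type: ignore[misc]
    return _build_profile(sample_id, arm, loss / total, gain / total)


def _build_profile(
    sample_id: str, arm: GenomeArm, loss_fraction: float, gain_fraction: float
) -> ArmProfile:
    loss_percent = _round_percent(loss_fraction)
    return ArmProfile(
        sample_id=sample_id,
        chrom=arm.chrom,
        arm=arm.arm,
        loss_fraction=loss_fraction,
        gain_fraction=gain_fraction,
        neutral_fraction=1.0 - loss_fraction - gain_fraction,
        loss_percent=loss_percent,
        extent_category=classify_extent(loss_percent),
    )


@dataclass
class BinnedDistribution:
    """Cohort distribution of integer loss percentages over fixed-width bins.

    Bin 0 holds exactly loss_percent == 0; subsequent bins are left-open
    right-closed on integer percent, e.g. width 5 gives 1-5, 6-10, ...,
    96-100.  ``composition`` (optional) is a per-bin fraction table over the
    six methylation classes; rows with any samples sum to 1.
    """

    bin_width: int
    labels: list[str]
    counts: np.ndarray
    composition: pd.DataFrame | None = None

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin": self.labels, "count": self.counts})
        if self.composition is not None:
            df = pd.concat([df, self.composition.reset_index(drop=True)], axis=1)
        return df


def bin_distribution(
    profiles: Iterable[ArmProfile],
    bin_width: int = 5,
    mc_labels: Mapping[str, str] | None = None,
) -> BinnedDistribution:
    """Bin a cohort's loss percentages; optionally attach MC composition.

    ``bin_width`` must divide 100.  With ``mc_labels`` (sample_id -> one of
    the six methylation classes) a per-bin class-fraction table is attached;
    samples absent from the mapping raise an error listing the missing ids.
    """
    if bin_width not in range(1, 101) or 100 % bin_width != 0:
        raise ValueError(f"bin_width must divide 100, got {bin_width}")
    profiles = list(profiles)
    n_bins = 100 // bin_width + 1  # the isolated 0 bin plus 100/width interval bins
    labels = ["0"] + [
        f"{k * bin_width + 1}-{(k + 1) * bin_width}" for k in range(100 // bin_width)
    ]
    counts = np.zeros(n_bins, dtype=int)
    idx_of: list[int] = []
    for p in profiles:
        idx = 0 if p.loss_percent == 0 else math.ceil(p.loss_percent / bin_width)
        counts[idx] += 1
        idx_of.append(idx)

    composition: pd.DataFrame | None = None
    if mc_labels is not None:
        missing = sorted({p.sample_id for p in profiles} - set(mc_labels))
        if missing:
            raise ValueError(f"samples missing from mc_labels: {missing}")
        comp = np.zeros((n_bins, len(MC_LABELS)))
        col_of = {label: j for j, label in enumerate(MC_LABELS)}
        for p, idx in zip(profiles, idx_of):
            label = mc_labels[p.sample_id]
            if label not in col_of:
                raise ValueError(
                    f"{p.sample_id}: unknown methylation class {label!r}; "
                    f"permitted labels: {', '.join(MC_LABELS)}"
                )
            comp[idx, col_of[label]] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(counts[:, None] > 0, comp / np.maximum(counts[:, None], 1), 0.0)
        composition = pd.DataFrame(frac, columns=list(MC_LABELS))

    return BinnedDistribution(
        bin_width=bin_width, labels=labels, counts=counts, composition=composition
    )


def profiles_for_arm(
    segments: Iterable[CnvSegment],
    arm: GenomeArm,
    thresholds: CallThresholds | None = None,
    weight: str = "bases",
) -> list[ArmProfile]:
    """Group a multi-sample segment collection by sample and profile one arm.

    Samples appear in first-occurrence order; samples with no segment on the
    arm's chromosome still get a profile (fully neutral arm).
    """
    import dataclasses

    by_sample: dict[str, list[CnvSegment]] = {}
    for seg in segments:
        by_sample.setdefault(seg.sample_id, []).append(seg)
    out = []
    for sid, segs in by_sample.items():
        profile = arm_fractions(segs, arm, thresholds, weight=weight)
        if profile.sample_id != sid:  # no segment touched the arm's chromosome
            profile = dataclasses.replace(profile, sample_id=sid)
        out.append(profile)
    return out


def profiles_to_frame(profiles: Iterable[ArmProfile]) -> pd.DataFrame:
    """Tabulate ArmProfiles (one row per sample x arm)."""
    rows = list(profiles)
    return pd.DataFrame(
        {
            "sample_id": [p.sample_id for p in rows],
            "chrom_arm": [p.arm_name for p in rows],
            "loss_fraction": [p.loss_fraction for p in rows],
            "gain_fraction": [p.gain_fraction for p in rows],
            "neutral_fraction": [p.neutral_fraction for p in rows],
            "loss_percent": [p.loss_percent for p in rows],
            "extent_category": [p.extent_category for p in rows],
        }
    )
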