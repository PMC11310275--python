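import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from armloss.genome import GenomeArm
from armloss.segio import CnvSegment

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def toy_arm():
    """A 10 kb arm at the origin — small enough for per-base oracles."""
    return GenomeArm(chrom="chr1", arm="p", start=0, end=10_000)


@pytest.fixture
def cytoband_file(tmp_path):
    """Synthetic cytoband file: two metacentric chromosomes plus an
    acrocentric one whose p-arm is satellite-only."""
    lines = [
        ("chr1", 0, 50, "p36", "gneg"),
        ("chr1", 50, 100, "p11", "acen"),
        ("chr1", 100, 150, "q11", "acen"),
        ("chr1", 150, 250, "q44", "gpos50"),
        ("chr2", 0, 40, "p25", "gneg"),
        ("chr2", 40, 90, "q11", "gneg"),
        ("chr22", 0, 30, "p13", "stalk"),
        ("chr22", 30, 80, "q13", "gneg"),
    ]
    path = tmp_path / "cytoBand.txt"
    path.write_text("".join(f"{c}\t{s}\t{e}\t{b}\t{g}\n" for c, s, e, b, g in lines))
    return path


def random_segments(rng: np.random.Generator, arm: GenomeArm, n: int, sample_id="s1"):
    """Random (possibly overlapping, possibly arm-exceeding) segments."""
    segs = []
    for _ in range(n):
        start = int(rng.integers(-arm.length // 10, arm.end))
        length = int(rng.integers(1, arm.length // 2))
        log2 = float(rng.normal(0, 0.4))
        segs.append(CnvSegment(sample_id, arm.chrom, max(start, 0), max(start, 0) + length, log2))
    return segs


def per_base_fractions(segments, arm, thresholds):
    """Independent per-base oracle: label every base of the arm by the most
    extreme covering log2 (ties toward loss), then count states."""
    ratio = np.full(arm.length, np.nan)
    for seg in segments:
        if seg.chrom != arm.chrom:
            continue
        lo = max(seg.start, arm.start) - arm.start
        hi = min(seg.end, arm.end) - arm.start
        if hi <= lo:
            continue
        cur = ratio[lo:hi]
        replace = (
            np.isnan(cur)
            | (abs(seg.log2_ratio) > np.abs(cur))
            | ((abs(seg.log2_ratio) == np.abs(cur)) & (seg.log2_ratio < cur))
        )
        cur[replace] = seg.log2_ratio
    with np.errstate(invalid="ignore"):
        loss = int(np.sum(ratio < thresholds.loss_log2))
        gain = int(np.sum(ratio > thresholds.gain_log2))
    return loss / arm.length, gain / arm.length
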