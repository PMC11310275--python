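"""Chromosome-arm coordinate system derived from UCSC cytoband files.

All coordinates are 0-based half-open throughout the package, so an arm or
segment of length L satisfies ``length == end - start``.  Arm boundaries are
taken as the min/max band coordinates per (chromosome, arm letter); the p-arm
end and q-arm start meet at the centromere with no gap and no overlap because
centromeric ("acen") bands carry their arm letter in the band name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

__all__ = ["GenomeArm", "ArmTable", "load_cytobands", "intersect_length", "normalize_chrom"]

# Giemsa stains that carry no usable euchromatic sequence for fraction
# computation; an arm made only of these is flagged unusable.
_UNUSABLE_STAINS = {"gvar", "stalk", "acen"}


def normalize_chrom(name: str) -> str:
    """Canonicalize a chromosome name: '1' and 'chr1' both become 'chr1'."""
    name = name.strip()
    if not name:
        raise ValueError("empty chromosome name")
    if name.lower().startswith("chr"):
        return "chr" + name[3:]
    return "chr" + name


@dataclass(frozen=True)
class GenomeArm:
    """A named chromosome-arm interval on a reference genome.

    ``usable`` is False for placeholder arms (acrocentric p-arms made only of
    satellite/stalk bands, or absent arms represented as zero-length stubs);
    such arms are excluded from fraction computation rather than producing
    0/0.
    """

    chrom: str
    arm: str
    start: int
    end: int
    usable: bool = True

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be 'p' or 'q', got {self.arm!r}")
        if self.start < 0:
            raise ValueError(f"{self.chrom}{self.arm}: negative start {self.start}")
        if self.usable and not self.start < self.end:
            raise ValueError(
                f"{self.chrom}{self.arm}: usable arm needs start < end "
                f"({self.start} >= {self.end})"
            )
        if self.start > self.end:
            raise ValueError(f"{self.chrom}{self.arm}: start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}{self.arm}"


@dataclass
class ArmTable:
    """Lookup of GenomeArm by (chromosome, arm letter) plus build provenance."""

    arms: dict[tuple[str, str], GenomeArm] = field(default_factory=dict)
    genome_build: str = "unknown"

    def get(self, chrom: str, arm: str) -> GenomeArm:
        key = (normalize_chrom(chrom), arm)
        if key not in self.arms:
            raise KeyError(f"no arm {key[0]}{arm} in ArmTable (build {self.genome_build})")
        return self.arms[key]

    def get_by_name(self, name: str) -> GenomeArm:
        """Look up by a combined name such as 'chr1p' or '22q'."""
        name = name.strip()
        if not name or name[-1] not in ("p", "q"):
            raise ValueError(f"arm name must end in 'p' or 'q': {name!r}")
        return self.get(name[:-1], name[-1])

    def __contains__(self, key: tuple[str, str]) -> bool:
        return (normalize_chrom(key[0]), key[1]) in self.arms

    def __iter__(self) -> Iterator[GenomeArm]:
        return iter(self.arms.values())

    def __len__(self) -> int:
        return len(self.arms)

    def chromosomes(self) -> list[str]:
        return sorted({c for c, _ in self.arms})

    def validate(self) -> None:
        """Check structural invariants: both arms per chromosome, shared
        centromere boundary, no negative-length arms."""
        for chrom in self.chromosomes():
            if (chrom, "p") not in self.arms or (chrom, "q") not in self.arms:
                raise ValueError(f"{chrom}: both p and q arms required")
            p = self.arms[(chrom, "p")]
            q = self.arms[(chrom, "q")]
            if p.end != q.start:
                raise ValueError(
                    f"{chrom}: p-arm end {p.end} != q-arm start {q.start} "
                    "(centromere boundary must be shared)"
                )


def load_cytobands(path: str | Path, genome_build: str = "unknown") -> ArmTable:
    """Parse a UCSC cytoBand.txt file into an ArmTable.

    Expected dialect: five tab-separated columns (chrom, start, end, band
    name, Giemsa stain), no header, band names beginning with 'p' or 'q'.
    Each arm spans the min start to the max end of its bands.  Chromosomes
    with bands on only one arm get a zero-length unusable stub for the
    missing arm at the centromere boundary; arms whose bands are all
    'gvar'/'stalk'/'acen' are kept but flagged unusable.
    """
    path = Path(path)
    # (chrom, arm) -> [min_start, max_end, any_usable_stain]
    spans: dict[tuple[str, str], list] = {}
    n_bands = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, got {len(fields)}"
                )
            chrom_raw, start_s, end_s, band, stain = fields[:5]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or end <= start:
                raise ValueError(f"{path}:{lineno}: invalid band interval [{start}, {end})")
            if not band or band[0] not in ("p", "q"):
                raise ValueError(
                    f"{path}:{lineno}: band name must begin with 'p' or 'q', got {band!r}"
                )
            chrom = normalize_chrom(chrom_raw)
            key = (chrom, band[0])
            usable = stain.strip() not in _UNUSABLE_STAINS
            if key not in spans:
                spans[key] = [start, end, usable]
            else:
                spans[key][0] = min(spans[key][0], start)
                spans[key][1] = max(spans[key][1], end)
                spans[key][2] = spans[key][2] or usable
            n_bands += 1
    if n_bands == 0:
        raise ValueError(f"{path}: no bands parsed")

    arms: dict[tuple[str, str], GenomeArm] = {}
    chroms = {c for c, _ in spans}
    for chrom in chroms:
        p_span = spans.get((chrom, "p"))
        q_span = spans.get((chrom, "q"))
        if p_span is None and q_span is not None:
            # acrocentric-style record: zero-length unusable p stub at the boundary
            p_span = [q_span[0], q_span[0], False]
        if q_span is None and p_span is not None:
            q_span = [p_span[1], p_span[1], False]
        assert p_span is not None and q_span is not None
        arms[(chrom, "p")] = GenomeArm(
            chrom, "p", p_span[0], p_span[1], usable=p_span[2] and p_span[1] > p_span[0]
        )
        arms[(chrom, "q")] = GenomeArm(
            chrom, "q", q_span[0], q_span[1], usable=q_span[2] and q_span[1] > q_span[0]
        )

    table = ArmTable(arms=arms, genome_build=genome_build)
    table.validate()
    return table


def intersect_length(seg_start: int, seg_end: int, arm: GenomeArm) -> int:
    """Length of overlap of half-open [seg_start, seg_end) with the arm; 0 if disjoint."""
    if seg_start >= seg_end:
        raise ValueError(f"degenerate segment [{seg_start}, {seg_end})")
    return max(0, min(seg_end, arm.end) - max(seg_start, arm.start))
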