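"""Copy-number segment calls, genome fractions and cross-sample harmonization.

Segments arrive as CNVkit-style (chrom, start, end, log2) intervals,
0-based half-open internally.  A segment is a *gain* when its log2 copy
ratio exceeds 0.6 and a *loss* below -0.6 (strict inequalities); genome
fractions are computed over the total called length.  Minimum consistency
segmentation re-expresses every sample on the union of all samples'
breakpoints so copy-number state is comparable position by position.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import pandas as pd

from .stats import contingency_2x2, percent

LOG2_GAIN = 0.6
LOG2_LOSS = -0.6


@dataclass(frozen=True)
class CnSegment:
    chrom: str
    start: int
    end: int
    log2_ratio: float
    state: str = "neutral"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty segment {self.chrom}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CnProfile:
    sample_id: str
    segments: list[CnSegment]

    def chromosomes(self) -> set[str]:
        return {s.chrom for s in self.segments}


def call_states(
    segments: list[CnSegment],
    log2_gain: float = LOG2_GAIN,
    log2_loss: float = LOG2_LOSS,
) -> list[CnSegment]:
    """Threshold log2 ratios into gain/neutral/loss states.

    Strict inequalities: log2 must exceed the gain threshold or fall
    below the loss threshold; segments with non-finite log2 are dropped
    with a warning.
    """
    out = []
    for seg in segments:
        if not math.isfinite(seg.log2_ratio):
            warnings.warn(
                f"dropping segment {seg.chrom}:{seg.start}-{seg.end} with non-finite log2"
            )
            continue
        if seg.log2_ratio > log2_gain:
            state = "gain"
        elif seg.log2_ratio < log2_loss:
            state = "loss"
        else:
            state = "neutral"
        out.append(replace(seg, state=state))
    return out


def genome_fractions(profile: CnProfile) -> tuple[float, float]:
    """(fraction_gained, fraction_lost) over the total called length."""
    total = sum(s.length for s in profile.segments)
    if total == 0:
        raise ValueError(f"profile {profile.sample_id} has no called segments")
    gained = sum(s.length for s in profile.segments if s.state == "gain")
    lost = sum(s.length for s in profile.segments if s.state == "loss")
    return gained / total, lost / total


def min_consistency_segmentation(profiles: list[CnProfile]) -> list[CnProfile]:
    """Split every sample's segments at the union of all breakpoints.

    Each sub-segment inherits its parent's log2 and state, so per-sample
    gain/loss fractions are preserved exactly.  Idempotent.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to harmonize")
    common = set.intersection(*(p.chromosomes() for p in profiles))
    if not common:
        raise ValueError("profiles cover disjoint chromosome sets")
    breakpoints: dict[str, set[int]] = {}
    for p in profiles:
        for s in p.segments:
            breakpoints.setdefault(s.chrom, set()).update((s.start, s.end))
    out = []
    for p in profiles:
        new_segs: list[CnSegment] = []
        for s in p.segments:
            cuts = sorted(
                {s.start, s.end}
                | {b for b in breakpoints[s.chrom] if s.start < b < s.end}
            )
            for lo, hi in zip(cuts, cuts[1:]):
                new_segs.append(
                    CnSegment(s.chrom, lo, hi, s.log2_ratio, s.state)
                )
        out.append(CnProfile(sample_id=p.sample_id, segments=new_segs))
    return out


def region_gain_frequency(
    profiles: list[CnProfile],
    region: tuple[str, int, int],
    group_labels: dict[str, str],
) -> dict[str, tuple[int, int, int]]:
    """Per-group gain frequency for a genomic region.

    A sample is gain-positive when any gain-state segment overlaps the
    region by at least 1 bp.  Returns group -> (k_gain, n, percent) with
    the percentage rounded half-up to an integer.
    """
    chrom, start, end = region
    if not any(chrom in p.chromosomes() for p in profiles):
        raise ValueError(f"region chromosome {chrom!r} absent from all profiles")
    counts: dict[str, list[int]] = {}
    for p in profiles:
        group = group_labels.get(p.sample_id)
        if group is None:
            continue
        hit = any(
            s.state == "gain" and s.chrom == chrom and s.start < end and s.end > start
            for s in p.segments
        )
        k, n = counts.get(group, [0, 0])
        counts[group] = [k + int(hit), n + 1]
    return {g: (k, n, percent(k, n)) for g, (k, n) in counts.items()}


def region_gain_fisher(freqs: dict[str, tuple[int, int, int]], group_a: str, group_b: str):
    """Fisher's exact comparison of region-gain frequency between two groups."""
    ka, na, _ = freqs[group_a]
    kb, nb, _ = freqs[group_b]
    return contingency_2x2(ka, na - ka, kb, nb - kb)


# ---------------------------------------------------------------------------
# SEG I/O (CNVkit-style TSV: sample, chrom, start, end, log2; 0-based input)


def read_seg(path, sample_id: str | None = None) -> CnProfile:
    table = pd.read_csv(path, sep="\t")
    required = {"chrom", "start", "end", "log2"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"SEG file {path} missing columns: {sorted(missing)}")
    if sample_id is None:
        sample_id = str(table["sample"].iloc[0]) if "sample" in table.columns else "?"
    segments = [
        CnSegment(str(r.chrom), int(r.start), int(r.end), float(r.log2))
        for r in table.itertuples(index=False)
    ]
    return CnProfile(sample_id=sample_id, segments=segments)


def write_seg(profile: CnProfile, path) -> None:
    rows = [
        {
            "sample": profile.sample_id,
            "chrom": s.chrom,
            "start": s.start,
            "end": s.end,
            "log2": round(s.log2_ratio, 4),
        }
        for s in profile.segments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
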