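"""Descriptive silencing surfaces: size distributions, positional profiles,
hot spots, between-line overlap, homolog (off-target) matching and
transitivity scans.

All positional quantities are keyed by the read start position (1-based) on
the reference sense axis with a sense/antisense strand label. Replicate
averaging is the arithmetic mean of per-replicate CPM, with a sequence
missing from a replicate contributing zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Optional, Sequence

import pandas as pd

from .construct import TargetTranscript
from .mapping import MappedSirna
from .sequences import revcomp


# ---------------------------------------------------------------------------
# size distributions


def size_distribution(
    mapped: Sequence[MappedSirna],
    mode: str = "distinct",
    lengths: Sequence[int] = tuple(range(18, 26)),
) -> pd.DataFrame:
    """Per-(length, strand) size distribution of a mapped (or genome-wide)
    small-RNA set.

    ``distinct`` mode counts unique sequences per cell and normalizes to
    frequencies summing to 1 over all cells; ``total`` mode sums CPM per
    cell (depth-free by construction). Returns columns length, strand,
    value; an empty input yields an all-zero, flagged frame.
    """
    if mode not in {"distinct", "total"}:
        raise ValueError(f"unknown mode {mode!r}")
    cells = {(k, s): 0.0 for k in lengths for s in ("sense", "antisense")}
    if mode == "distinct":
        seen: dict[tuple[int, str], set[str]] = {}
        for m in mapped:
            seen.setdefault((m.length, m.strand), set()).add(m.sequence)
        for key, seqs in seen.items():
            if key in cells:
                cells[key] = float(len(seqs))
        total = sum(cells.values())
        if total > 0:
            cells = {k: v / total for k, v in cells.items()}
    else:
        counted: set[tuple[str, str]] = set()
        for m in mapped:
            if (m.sequence, m.strand) in counted:
                continue  # one CPM contribution per distinct (sequence, strand)
            counted.add((m.sequence, m.strand))
            key = (m.length, m.strand)
            if key in cells:
                cells[key] += m.cpm
    df = pd.DataFrame(
        [(k, s, v) for (k, s), v in sorted(cells.items())],
        columns=["length", "strand", "value"],
    )
    df.attrs["empty_scope"] = len(mapped) == 0
    return df


# ---------------------------------------------------------------------------
# positional profiles and hot spots


def positional_profile(
    replicates: Sequence[Sequence[MappedSirna]] | Sequence[MappedSirna],
    reference_id: Optional[str] = None,
    length_filter: Optional[int] = None,
) -> pd.DataFrame:
    """Per-(start, strand) profile averaged over replicates.

    Accepts a single mapped list or a list of replicate lists. distinct_count
    is the number of distinct sequences observed at a position in any
    replicate; cpm_sum is the mean over replicates of the per-replicate CPM
    sum at that position (missing positions contribute zero).
    """
    if replicates and isinstance(replicates[0], MappedSirna):
        replicates = [replicates]  # type: ignore[list-item]
    refs = {m.reference_id for rep in replicates for m in rep}
    if reference_id is None:
        if len(refs) > 1:
            raise ValueError(f"replicates map to multiple references: {sorted(refs)}")
    elif refs - {reference_id}:
        raise ValueError(
            f"replicates contain references {sorted(refs - {reference_id})} "
            f"other than {reference_id!r}"
        )
    n_rep = max(len(replicates), 1)
    cpm: dict[tuple[int, str], float] = {}
    distinct: dict[tuple[int, str], set[str]] = {}
    for rep in replicates:
        for m in rep:
            if length_filter is not None and m.length != length_filter:
                continue
            key = (m.start, m.strand)
            cpm[key] = cpm.get(key, 0.0) + m.cpm
            distinct.setdefault(key, set()).add(m.sequence)
    rows = [
        (pos, strand, len(distinct[(pos, strand)]), total / n_rep)
        for (pos, strand), total in sorted(cpm.items())
    ]
    return pd.DataFrame(rows, columns=["start", "strand", "distinct_count", "cpm_sum"])


def detect_hotspots(profile: pd.DataFrame, min_fraction: float = 0.05) -> list[tuple[int, str]]:
    """Positions carrying at least ``min_fraction`` of their strand's total
    CPM, sorted by descending CPM. An all-zero profile yields an empty list.

    Hot spots are an operational stand-in for the visually prominent peaks
    of stem-profile plots; the threshold is deliberately configurable.
    """
    if not 0.0 < min_fraction < 1.0:
        raise ValueError("min_fraction must lie in (0,1)")
    out: list[tuple[int, str, float]] = []
    for strand, grp in profile.groupby("strand"):
        total = grp.cpm_sum.sum()
        if total <= 0:
            continue
        hot = grp[grp.cpm_sum >= min_fraction * total]
        out.extend((int(r.start), strand, float(r.cpm_sum)) for r in hot.itertuples())
    out.sort(key=lambda t: -t[2])
    return [(pos, strand) for pos, strand, _ in out]


# ---------------------------------------------------------------------------
# between-line overlap


@dataclass
class OverlapReport:
    """Venn-style decomposition of per-sample sequence sets."""

    sample_ids: tuple[str, ...]
    exclusive_counts: dict[frozenset, int] = field(default_factory=dict)
    shared_fraction: float = float("nan")
    n: int = 0

    @property
    def union_size(self) -> int:
        return sum(self.exclusive_counts.values())


def _venn(sets: Mapping[str, set]) -> dict[frozenset, int]:
    ids = list(sets)
    out: dict[frozenset, int] = {}
    for r in range(1, len(ids) + 1):
        for combo in combinations(ids, r):
            inside = set.intersection(*(sets[i] for i in combo))
            for other in ids:
                if other not in combo:
                    inside -= sets[other]
            out[frozenset(combo)] = len(inside)
    return out


def top_n_overlap(
    libraries: Mapping[str, Mapping[str, float]],
    n: int = 1000,
) -> OverlapReport:
    """Overlap of the top-n sequences by CPM across samples.

    ``libraries`` maps sample -> {sequence: cpm}. Ties at the CPM boundary
    are broken lexicographically by sequence for determinism; if a sample
    holds fewer than n distinct sequences its full set is used (with a
    warning flag implicit in the smaller set). shared_fraction is
    |intersection of all samples' top-n| / n.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    tops: dict[str, set[str]] = {}
    for sample, cpms in libraries.items():
        ranked = sorted(cpms.items(), key=lambda kv: (-kv[1], kv[0]))
        tops[sample] = {seq for seq, _ in ranked[:n]}
    shared = set.intersection(*tops.values()) if tops else set()
    return OverlapReport(
        sample_ids=tuple(libraries),
        exclusive_counts=_venn(tops),
        shared_fraction=len(shared) / n,
        n=n,
    )


# ---------------------------------------------------------------------------
# homolog (off-target) matching


def map_to_homologs(
    ir_sirnas: Sequence[MappedSirna],
    transcripts: Sequence[TargetTranscript],
) -> pd.DataFrame:
    """Re-match IR-derived siRNAs against each homolog's target region.

    Perfect, full-length matching only: a sense siRNA carries over to a
    homolog where its window is substitution-free; an antisense siRNA where
    the window's reverse complement equals it. Transcripts without a target
    region are skipped. Returns one row per (transcript, strand) with
    distinct counts and total CPM, mirroring off-target stem re-mapping.
    """
    rows = []
    for t in transcripts:
        if t.target_region is None:
            continue
        region = t.target_sequence or ""
        carried: dict[str, set[str]] = {"sense": set(), "antisense": set()}
        cpm: dict[str, float] = {"sense": 0.0, "antisense": 0.0}
        for m in ir_sirnas:
            window = region[m.start - 1 : m.end] if m.end <= len(region) else ""
            expected = window if m.strand == "sense" else revcomp(window)
            if window and m.sequence == expected:
                if m.sequence not in carried[m.strand]:
                    carried[m.strand].add(m.sequence)
                    cpm[m.strand] += m.cpm
        for strand in ("sense", "antisense"):
            rows.append((t.id, strand, len(carried[strand]), cpm[strand]))
    return pd.DataFrame(rows, columns=["transcript", "strand", "distinct", "cpm"])


# ---------------------------------------------------------------------------
# transitivity


def transitivity_scan(
    mapped: Sequence[MappedSirna],
    transcript_length: int,
    primary_region: tuple[int, int],
    loop_region: Optional[tuple[int, int]] = None,
    edge_buffer: int = 20,
) -> pd.DataFrame:
    """Partition reads mapped to one reference into {inside, outside, loop}.

    ``inside`` covers reads overlapping the primary target region or lying
    within ``edge_buffer`` nt of its edges (a window straddling or hugging
    the boundary is not evidence of transitivity); ``loop`` covers reads
    inside an optional loop span; everything else is ``outside`` —
    candidate secondary siRNAs, with antisense outside-region reads the
    strongest RdRP signature. Returns per-(category, strand) distinct
    counts and CPM sums plus an ``antisense_outside`` evidence flag in
    ``DataFrame.attrs``.
    """
    r0, r1 = primary_region
    if loop_region is not None:
        l0, l1 = loop_region
        if not (l1 < r0 - edge_buffer or l0 > r1 + edge_buffer):
            raise ValueError("loop region overlaps the buffered primary region")
    cats: dict[tuple[str, str], dict[str, float]] = {}
    seen: dict[tuple[str, str], set[str]] = {}
    for m in mapped:
        if m.end > transcript_length:
            raise ValueError(f"read at {m.start}-{m.end} beyond reference length")
        if loop_region is not None and loop_region[0] <= m.start and m.end <= loop_region[1]:
            cat = "loop"
        elif m.end >= r0 - edge_buffer and m.start <= r1 + edge_buffer:
            cat = "inside"
        else:
            cat = "outside"
        key = (cat, m.strand)
        cats.setdefault(key, {"cpm": 0.0})["cpm"] += m.cpm
        seen.setdefault(key, set()).add(m.sequence)
    rows = [
        (cat, strand, len(seen[(cat, strand)]), vals["cpm"])
        for (cat, strand), vals in sorted(cats.items())
    ]
    df = pd.DataFrame(rows, columns=["category", "strand", "distinct", "cpm"])
    df.attrs["antisense_outside_evidence"] = bool(
        ((df.category == "outside") & (df.strand == "antisense") & (df.distinct > 0)).any()
    )
    return df
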