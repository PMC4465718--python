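"""5'RACE cleavage-site tallies and candidate functional-siRNA selection.

A RACE clone's 5' terminus marks the phosphodiester bond where the
transcript was cut, written as the dinucleotide pair (i, i+1). Per sample,
clone termini are tallied into per-site fractions and classified inside or
outside the target region (outside-region termini indicate natural mRNA
degradation rather than siRNA-directed cleavage). A site observed in every
sample of a designated set is flagged conserved.

Candidate functional siRNAs are the observed 21-nt antisense siRNAs whose
window covers a queried cut site away from the duplex ends: because RISC
cleaves near the center of the guide, windows placing the cut within the
first or last ``terminal_exclusion`` nucleotides are discarded. With k=21
and exclusion 2, one cut site admits 16 windows, and the two sites at
297-298 and 301-302 admit a deduplicated union of 20.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Optional, Sequence

import pandas as pd

from .mapping import MappedSirna, cpm_round as mp_cpm_round
from .sequences import revcomp, to_rna

CutSite = tuple[int, int]


@dataclass
class CleavageTally:
    sample_id: str
    counts: dict[CutSite, int] = field(default_factory=dict)
    inside_region_count: int = 0
    outside_region_count: int = 0
    rejected_rows: int = 0
    conserved_sites: frozenset = frozenset()

    @property
    def total(self) -> int:
        return self.inside_region_count + self.outside_region_count

    @property
    def fractions(self) -> dict[CutSite, float]:
        total = self.total
        return {site: c / total for site, c in self.counts.items()} if total else {}


def tally_cleavage(
    clone_table: pd.DataFrame,
    region: tuple[int, int],
    sample_set: Optional[Sequence[str]] = None,
    transcript_length: Optional[int] = None,
) -> dict[str, CleavageTally]:
    """Tally clone termini into per-sample cut-site fractions.

    ``clone_table`` columns: sample, transcript, cut_i, cut_j. Rows whose
    cut falls outside the transcript (when ``transcript_length`` is given)
    or is not a dinucleotide pair are rejected and counted. A site is
    conserved when present in every sample of ``sample_set`` (default: all
    samples in the table); the conserved set therefore only shrinks as
    samples are added. Inside/outside is judged against ``region`` on the
    same coordinate axis as the cut positions.
    """
    r0, r1 = region
    tallies: dict[str, CleavageTally] = {}
    for row in clone_table.itertuples():
        sample = str(row.sample)
        tally = tallies.setdefault(sample, CleavageTally(sample_id=sample))
        i, j = int(row.cut_i), int(row.cut_j)
        if j != i + 1 or i < 1 or (transcript_length is not None and j > transcript_length):
            tally.rejected_rows += 1
            continue
        site = (i, j)
        tally.counts[site] = tally.counts.get(site, 0) + 1
        if r0 <= i <= r1:
            tally.inside_region_count += 1
        else:
            tally.outside_region_count += 1
    member_samples = list(sample_set) if sample_set is not None else list(tallies)
    if member_samples:
        present = [
            set(tallies[s].counts) for s in member_samples if s in tallies
        ]
        conserved = frozenset(set.intersection(*present)) if len(present) == len(member_samples) and present else frozenset()
    else:
        conserved = frozenset()
    for tally in tallies.values():
        tally.conserved_sites = conserved
    return tallies


def enumerate_candidate_windows(
    cut_sites: Sequence[CutSite],
    k: int = 21,
    terminal_exclusion: int = 2,
) -> list[tuple[int, int]]:
    """All k-nt windows qualified to explain at least one queried cut site.

    A window [s, s+k-1] qualifies for cut (i, i+1) iff it contains both i
    and i+1 and both flanking nucleotides lie outside the terminal
    ``terminal_exclusion`` positions at either window end: with offset
    j = i - s + 1, that is terminal_exclusion + 1 <= j <= k - terminal_exclusion - 1.
    The output is the deduplicated, sorted union over all query sites.
    """
    if not cut_sites:
        raise ValueError("cut_sites is empty")
    if k <= 2 * terminal_exclusion:
        raise ValueError("k must exceed twice the terminal exclusion")
    if terminal_exclusion < 0:
        raise ValueError("terminal_exclusion must be non-negative")
    windows: set[tuple[int, int]] = set()
    for i, j in cut_sites:
        if j != i + 1:
            raise ValueError(f"cut site {(i, j)} is not a dinucleotide pair")
        lo = terminal_exclusion + 1
        hi = k - terminal_exclusion - 1
        for off in range(lo, hi + 1):
            s = i - off + 1
            if s >= 1:
                windows.add((s, s + k - 1))
    return sorted(windows)


def _cut_offsets(window: tuple[int, int], cut_sites: Sequence[CutSite], k: int,
                 terminal_exclusion: int) -> list[tuple[CutSite, int]]:
    s = window[0]
    lo = terminal_exclusion + 1
    hi = k - terminal_exclusion - 1
    out = []
    for i, j in cut_sites:
        off = i - s + 1
        if lo <= off <= hi:
            out.append(((i, j), off))
    return out


def select_candidate_sirnas(
    mapped_by_sample: Mapping[str, Sequence[MappedSirna]],
    cut_sites: Sequence[CutSite],
    reference_sample: str,
    k: int = 21,
    terminal_exclusion: int = 2,
) -> pd.DataFrame:
    """Intersect observed 21-nt antisense siRNAs with the qualified windows
    and rank by CPM in ``reference_sample`` (descending, ties broken
    lexicographically by sequence).

    Returns one row per candidate with columns sequence (RNA alphabet, as
    customarily printed for siRNAs), strand, length, window start/end,
    covered cut sites with offsets, and one CPM column per sample.
    """
    if reference_sample not in mapped_by_sample:
        raise ValueError(f"reference sample {reference_sample!r} absent")
    valid = set(enumerate_candidate_windows(cut_sites, k=k, terminal_exclusion=terminal_exclusion))

    # candidate identity: the antisense sequence; coordinates from any sample
    candidates: dict[str, tuple[int, int]] = {}
    cpm: dict[str, dict[str, float]] = {}
    for sample, mapped in mapped_by_sample.items():
        for m in mapped:
            if m.strand != "antisense" or m.length != k:
                continue
            if (m.start, m.end) not in valid:
                continue
            candidates.setdefault(m.sequence, (m.start, m.end))
            cpm.setdefault(m.sequence, {})[sample] = cpm.get(m.sequence, {}).get(sample, 0.0) + m.cpm

    rows = []
    for seq, window in candidates.items():
        covered = _cut_offsets(window, cut_sites, k, terminal_exclusion)
        row = {
            "sequence": to_rna(seq),
            "strand": "-",
            "length": len(seq),
            "window_start": window[0],
            "window_end": window[1],
            "covered_cut_sites": ";".join(f"{i}-{j}" for (i, j), _ in covered),
            "cut_offsets": ";".join(str(off) for _, off in covered),
        }
        for sample in mapped_by_sample:
            row[f"cpm_{sample}"] = mp_cpm_round(cpm.get(seq, {}).get(sample, 0.0))
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    ref_col = f"cpm_{reference_sample}"
    return df.sort_values([ref_col, "sequence"], ascending=[False, True]).reset_index(drop=True)


def reconstruct_target_from_candidates(
    candidate_sequences: Sequence[str],
) -> tuple[str, dict[str, int]]:
    """Greedily merge the reverse complements of antisense k-mers by exact
    (k-1)-overlap into one contiguous sense segment.

    Succeeds iff the set tiles a single segment; returns the segment and
    each input sequence's 1-based offset within it. Non-overlapping or
    conflicting inputs raise an error naming the offending pair.
    """
    if not candidate_sequences:
        raise ValueError("no candidate sequences")
    sense = {}
    for s in candidate_sequences:
        sense.setdefault(revcomp(s), s)
    frags = sorted(sense)
    k = len(frags[0])
    if any(len(f) != k for f in frags):
        raise ValueError("candidate sequences have unequal lengths")
    if len(frags) == 1:
        return frags[0], {sense[frags[0]]: 1}
    ov = k - 1

    prefix: dict[str, str] = {}
    suffix: dict[str, str] = {}
    for f in frags:
        if f[:ov] in prefix:
            raise ValueError(f"inconsistent overlaps: {prefix[f[:ov]]!r} vs {f!r}")
        if f[-ov:] in suffix:
            raise ValueError(f"inconsistent overlaps: {suffix[f[-ov:]]!r} vs {f!r}")
        prefix[f[:ov]] = f
        suffix[f[-ov:]] = f

    starts = [f for f in frags if f[:ov] not in suffix]
    if len(starts) != 1:
        raise ValueError(
            "candidates do not tile one contiguous segment "
            f"(found {len(starts)} chain starts)"
        )
    segment = starts[0]
    used = {starts[0]}
    cur = starts[0]
    while True:
        nxt = prefix.get(cur[-ov:])
        if nxt is None or nxt in used:
            break
        segment += nxt[-1]
        used.add(nxt)
        cur = nxt
    if used != set(frags):
        missing = sorted(set(frags) - used)
        raise ValueError(
            f"candidates do not tile one contiguous segment; unplaced: {missing}"
        )
    offsets = {sense[f]: segment.find(f) + 1 for f in frags}
    return segment, offsets


def expected_race_product_sizes(
    region_length: int,
    upstream_offset: int,
    downstream_offset: int,
) -> tuple[int, int]:
    """Expected RACE PCR product size range for cleavage anywhere in a region.

    The adapter/primer extents flanking the cleavable span are inputs (they
    depend on the primer design): the minimum product arises from cleavage
    at the region end nearest the reverse primer, min = upstream_offset +
    downstream_offset, and the maximum adds the full region length, so
    max - min == region_length.
    """
    if upstream_offset < 0 or downstream_offset < 0:
        raise ValueError("offsets must be non-negative")
    if region_length < 0:
        raise ValueError("region_length must be non-negative")
    lo = upstream_offset + downstream_offset
    return lo, lo + region_length


# ---------------------------------------------------------------------------
# packaged fixture: the 20 published candidate siRNAs


def load_published_candidates() -> pd.DataFrame:
    """The published 20 candidate functional siRNAs with per-line CPM.

    Sequences are stored DNA-canonical with the RNA rendering in the FASTA
    headers; CPM columns are the printed per-line values (averages of three
    biological replications in the source study design).
    """
    data = resources.files("hpsirna.data")
    tsv = (data / "published_candidates.tsv").read_text()
    from io import StringIO

    return pd.read_csv(StringIO(tsv), sep="\t")


def load_published_candidate_fasta() -> dict[str, str]:
    data = resources.files("hpsirna.data")
    text = (data / "published_candidates.fasta").read_text()
    out: dict[str, str] = {}
    name = None
    for line in text.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name:
            out[name] += line.strip()
    return out
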