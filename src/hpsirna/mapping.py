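"""Read collapsing, exact k-mer mapping and counts-per-million normalization.

Reads are collapsed to distinct sequences with counts, then matched against
reference sequences by exact, full-length lookup (mismatch-containing reads
are discarded, mirroring perfect-match short-read mapping). Strand is
reported relative to the reference sense strand: a read equal to a reference
substring is sense; a read equal to its reverse complement is antisense.

Hairpin double-arm convention: any read from the inverted repeat matches
both arms of the construct (one forward, one as reverse complement). Such
hits are collapsed to a single record in forward-arm (IR) coordinates with
strand defined relative to the target mRNA, so per-position profiles live on
one 1..L axis with a +/- strand, as in standard stem-profile plots.

Library sizes are normalized as CPM over 18-25-nt genome-matching reads:
cpm = raw_count / denominator * 1e6.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

from .construct import HairpinConstruct
from .sequences import normalize, revcomp

MIN_READ_LEN = 18
MAX_READ_LEN = 25


@dataclass
class SmallRNALibrary:
    """Collapsed distinct small-RNA sequences with raw counts."""

    sample_id: str
    entries: dict[str, int] = field(default_factory=dict)
    denominator: Optional[int] = None
    provenance: tuple[str, ...] = ()
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def total_reads(self) -> int:
        return sum(self.entries.values())

    def cpm(self, sequence: str) -> float:
        if not self.denominator:
            raise ValueError("denominator not set; run compute_denominator first")
        return self.entries[sequence] / self.denominator * 1e6


@dataclass(frozen=True)
class MappedSirna:
    sequence: str
    length: int
    reference_id: str
    start: int  # 1-based inclusive, reference sense coordinates
    end: int
    strand: str  # 'sense' | 'antisense' (relative to the reference/mRNA)
    raw_count: int
    cpm: float = float("nan")


def collapse_reads(
    fastq: str | Path | Iterable[tuple[str, str]],
    sample_id: str = "sample",
    min_len: int = MIN_READ_LEN,
    max_len: int = MAX_READ_LEN,
    adapter: Optional[str] = None,
) -> SmallRNALibrary:
    """Collapse a FASTQ (or (id, sequence) iterable) to distinct sequences.

    Reads outside [min_len, max_len] are dropped and tallied in
    ``excluded``. ``adapter`` optionally trims a literal 3' adapter prefix
    found within each read (convenience only; trimming normally happens
    upstream).
    """
    provenance: tuple[str, ...] = ()
    if isinstance(fastq, (str, Path)):
        provenance = (str(fastq),)
        try:
            records = ((r.id, str(r.seq)) for r in SeqIO.parse(str(fastq), "fastq"))
            pairs = list(records)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ {fastq}: {exc}") from exc
    else:
        pairs = list(fastq)

    counts: Counter[str] = Counter()
    excluded = {"too_short": 0, "too_long": 0}
    for _, seq in pairs:
        s = normalize(seq)
        if adapter:
            cut = s.find(normalize(adapter))
            if cut >= 0:
                s = s[:cut]
        if len(s) < min_len:
            excluded["too_short"] += 1
        elif len(s) > max_len:
            excluded["too_long"] += 1
        else:
            counts[s] += 1
    return SmallRNALibrary(
        sample_id=sample_id,
        entries=dict(counts),
        provenance=provenance,
        excluded=excluded,
    )


class ExactIndex:
    """Exact-match index over both strands of a reference set.

    Stores every forward-strand k-mer (k in [min_k, max_k]) of every
    reference with its 1-based start. A query is sense where it equals a
    stored k-mer and antisense where its reverse complement does, so both
    strands are answered from a single forward table.
    """

    def __init__(
        self,
        references: Mapping[str, str],
        min_k: int = MIN_READ_LEN,
        max_k: int = MAX_READ_LEN,
    ) -> None:
        if not references:
            raise ValueError("empty reference set")
        self.references = {rid: normalize(seq) for rid, seq in references.items()}
        self.min_k = min_k
        self.max_k = max_k
        self._table: dict[str, list[tuple[str, int]]] = {}
        for rid, seq in self.references.items():
            n = len(seq)
            for k in range(min_k, max_k + 1):
                for s in range(n - k + 1):
                    self._table.setdefault(seq[s : s + k], []).append((rid, s + 1))

    def hits(self, query: str) -> list[tuple[str, int, int, str]]:
        """All exact hits as (reference_id, start, end, strand)."""
        q = normalize(query)
        if not self.min_k <= len(q) <= self.max_k:
            raise ValueError(
                f"query length {len(q)} outside indexed range "
                f"[{self.min_k}, {self.max_k}]"
            )
        k = len(q)
        out = [(rid, s, s + k - 1, "sense") for rid, s in self._table.get(q, ())]
        if q != revcomp(q):  # palindromes: report sense only
            out += [
                (rid, s, s + k - 1, "antisense")
                for rid, s in self._table.get(revcomp(q), ())
            ]
        return sorted(out)

    def matches(self, query: str) -> bool:
        return bool(self.hits(query))


def build_index(
    references: Mapping[str, str] | str | Path,
    min_k: int = MIN_READ_LEN,
    max_k: int = MAX_READ_LEN,
) -> ExactIndex:
    """Build an ExactIndex from a mapping id->sequence or a FASTA path."""
    if isinstance(references, (str, Path)):
        references = {r.id: str(r.seq) for r in SeqIO.parse(str(references), "fasta")}
    return ExactIndex(references, min_k=min_k, max_k=max_k)


def compute_denominator(library: SmallRNALibrary, genome_index: ExactIndex) -> SmallRNALibrary:
    """Set the CPM denominator: total reads (18-25 nt) with at least one
    exact genome hit. Returns the library with ``denominator`` filled in."""
    denom = sum(
        count for seq, count in library.entries.items() if genome_index.matches(seq)
    )
    library.denominator = denom
    return library


def collapse_hairpin_hits(
    hits: Sequence[tuple[str, int, int, str]],
    construct: HairpinConstruct,
) -> list[tuple[str, int, int, str]]:
    """Collapse double-arm construct hits into forward-arm IR coordinates.

    A hit inside the reverse arm is mirrored into the forward arm with its
    strand flipped (the reverse arm is the forward arm's reverse
    complement); duplicates after mirroring are dropped. Coordinates are
    then reported on the 1..ir_length stem axis.
    """
    fwd = construct.element("ir_forward")
    rev = construct.element("ir_reverse")
    out = set()
    for rid, start, end, strand in hits:
        if rid != construct.id:
            out.add((rid, start, end, strand))
            continue
        if fwd.start <= start and end <= fwd.end:
            out.add(("IR", start - fwd.start + 1, end - fwd.start + 1, strand))
        elif rev.start <= start and end <= rev.end:
            m_start = rev.end - end + 1  # mirror into forward-arm offsets
            m_end = rev.end - start + 1
            flipped = "antisense" if strand == "sense" else "sense"
            out.add(("IR", m_start, m_end, flipped))
        else:
            out.add((rid, start, end, strand))
    return sorted(out)


def map_library(
    library: SmallRNALibrary,
    index: ExactIndex,
    target_id: str,
    hairpin: Optional[HairpinConstruct] = None,
) -> list[MappedSirna]:
    """Map a collapsed library against one reference, perfect matches only.

    Returns one MappedSirna per (sequence, position, strand) hit on
    ``target_id``. With ``hairpin`` given and ``target_id='IR'``, construct
    hits are first collapsed into stem coordinates (see
    ``collapse_hairpin_hits``). CPM is attached when the library has a
    denominator.
    """
    known = set(index.references)
    if hairpin is not None:
        known.add("IR")
    if target_id not in known:
        raise KeyError(f"target {target_id!r} absent from index")
    out: list[MappedSirna] = []
    for seq, count in sorted(library.entries.items()):
        hits = index.hits(seq)
        if hairpin is not None:
            hits = collapse_hairpin_hits(hits, hairpin)
        for rid, start, end, strand in hits:
            if rid != target_id:
                continue
            cpm = (
                count / library.denominator * 1e6 if library.denominator else float("nan")
            )
            out.append(
                MappedSirna(
                    sequence=seq,
                    length=len(seq),
                    reference_id=rid,
                    start=start,
                    end=end,
                    strand=strand,
                    raw_count=count,
                    cpm=cpm,
                )
            )
    return out


def cpm_round(value: float, ndigits: int = 2) -> float:
    """Half-up rounding for rendered CPM values (0.125 prints as 0.13);
    Python's built-in round is half-to-even and would print 0.12."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def cpm_normalize(library: SmallRNALibrary) -> dict[str, float]:
    """CPM per distinct sequence: raw_count / denominator * 1e6."""
    if not library.denominator:
        raise ValueError("denominator is zero or unset")
    return {
        seq: count / library.denominator * 1e6 for seq, count in library.entries.items()
    }


def attach_cpm(mapped: Sequence[MappedSirna], denominator: int) -> list[MappedSirna]:
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return [replace(m, cpm=m.raw_count / denominator * 1e6) for m in mapped]
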