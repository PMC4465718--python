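"""Hairpin-transgene geometry: the annotated construct, the target-transcript
family, and ungapped homology between the inverted repeat and its targets.

A hairpin (hpRNA) construct carries two copies of a target-gene fragment in
opposite orientations (the inverted-repeat arms, here 318 bp in the default
scenario) separated by an intron spacer. The transcript folds back on itself
into a double-stranded stem that Dicer-like enzymes process into siRNAs.
Everything downstream — positional profiles, off-target mapping, candidate
functional siRNAs — consumes the coordinates defined here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

from Bio import SeqIO

from .sequences import VALID_BASES, normalize, revcomp, subseq

ELEMENT_ROLES = frozenset(
    {"promoter", "ir_forward", "loop_intron", "ir_reverse", "terminator", "marker", "other"}
)


class ConstructValidationError(ValueError):
    """A construct or element table violates a structural invariant."""


@dataclass(frozen=True)
class ConstructElement:
    """One annotated feature of the transgene T-DNA (1-based inclusive)."""

    name: str
    role: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.role not in ELEMENT_ROLES:
            raise ConstructValidationError(
                f"element {self.name!r}: unknown role {self.role!r}"
            )
        if self.start < 1 or self.start > self.end:
            raise ConstructValidationError(
                f"element {self.name!r}: invalid span {self.start}-{self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise ConstructValidationError(
                f"element {self.name!r}: invalid strand {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class HairpinConstruct:
    """An annotated hairpin-RNAi transgene.

    Invariants (enforced on construction): exactly one element each of the
    roles ir_forward / loop_intron / ir_reverse; equal arm lengths; the
    reverse arm is the reverse complement of the forward arm; the loop lies
    strictly between the arms; elements are sorted and non-overlapping.
    """

    id: str
    sequence: str
    elements: list[ConstructElement] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence)
        self.elements = sorted(self.elements, key=lambda e: e.start)
        self._validate()

    def _validate(self) -> None:
        n = len(self.sequence)
        prev: Optional[ConstructElement] = None
        for el in self.elements:
            if el.end > n:
                raise ConstructValidationError(
                    f"element {el.name!r} extends past construct end ({el.end} > {n})"
                )
            if prev is not None and el.start <= prev.end:
                raise ConstructValidationError(
                    f"elements {prev.name!r} and {el.name!r} overlap"
                )
            prev = el
        for role in ("ir_forward", "loop_intron", "ir_reverse"):
            found = [e for e in self.elements if e.role == role]
            if len(found) != 1:
                raise ConstructValidationError(
                    f"construct {self.id!r}: expected exactly one {role} element, "
                    f"found {len(found)}"
                )
        fwd, loop, rev = (
            self.element("ir_forward"),
            self.element("loop_intron"),
            self.element("ir_reverse"),
        )
        if fwd.length != rev.length:
            raise ConstructValidationError(
                f"IR arm lengths differ ({fwd.length} vs {rev.length})"
            )
        if not (fwd.end < loop.start and loop.end < rev.start):
            raise ConstructValidationError(
                f"loop intron {loop.name!r} does not lie strictly between the IR arms"
            )
        if self.element_sequence(rev) != revcomp(self.element_sequence(fwd)):
            raise ConstructValidationError("IR arms not reverse-complementary")

    def element(self, role: str) -> ConstructElement:
        for el in self.elements:
            if el.role == role:
                return el
        raise KeyError(role)

    def element_sequence(self, element: ConstructElement) -> str:
        return subseq(self.sequence, element.start, element.end)

    @property
    def ir_length(self) -> int:
        return self.element("ir_forward").length

    @property
    def ir_sequence(self) -> str:
        """Sense-orientation stem sequence (the forward arm)."""
        return self.element_sequence(self.element("ir_forward"))

    # -- serialization -----------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "id": self.id,
                "sequence": self.sequence,
                "elements": [asdict(e) for e in self.elements],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "HairpinConstruct":
        obj = json.loads(text)
        return cls(
            id=obj["id"],
            sequence=obj["sequence"],
            elements=[ConstructElement(**e) for e in obj["elements"]],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "HairpinConstruct":
        return cls.from_json(Path(path).read_text())


@dataclass
class TargetTranscript:
    """A (possibly diverged) member of the target gene family.

    ``target_region`` is the 1-based inclusive span homologous to the IR arm,
    or None for transcripts without a recognized target region.
    """

    id: str
    sequence: str
    target_region: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence)
        if self.target_region is not None:
            s, e = self.target_region
            if s < 1 or e > len(self.sequence) or s > e:
                raise ConstructValidationError(
                    f"transcript {self.id!r}: target region {s}-{e} out of bounds"
                )

    @property
    def target_sequence(self) -> Optional[str]:
        if self.target_region is None:
            return None
        return subseq(self.sequence, *self.target_region)


@dataclass(frozen=True)
class HomologyResult:
    transcript_id: str
    identity_percent: float
    mismatch_positions: tuple[int, ...]


def region_identity(seq_a: str, seq_b: str, transcript_id: str = "") -> HomologyResult:
    """Ungapped per-position identity between two equal-length regions.

    Comparison is case-insensitive with U treated as T. Any position where a
    base falls outside {A,C,G,T} (ambiguity codes such as N) counts as a
    mismatch. identity = 100 * (L - mismatches) / L.
    """
    a, b = normalize(seq_a), normalize(seq_b)
    if len(a) != len(b):
        raise ValueError(f"unequal lengths ({len(a)} vs {len(b)})")
    if not a:
        raise ValueError("empty sequences")
    mismatches = tuple(
        i + 1
        for i, (x, y) in enumerate(zip(a, b))
        if x != y or x not in VALID_BASES or y not in VALID_BASES
    )
    identity = 100.0 * (len(a) - len(mismatches)) / len(a)
    return HomologyResult(transcript_id, identity, mismatches)


def enumerate_sirna_windows(region_length: int, k: int) -> list[tuple[int, int]]:
    """All k-nt windows on one strand of a region, 1-based inclusive.

    A region of length L supports L - k + 1 distinct k-mers per strand
    (e.g. 318 nt and k=21 give 298 possible siRNA positions).
    """
    if k < 1:
        raise ValueError("k must be positive")
    if k > region_length:
        raise ValueError(f"k={k} exceeds region length {region_length}")
    return [(s, s + k - 1) for s in range(1, region_length - k + 2)]


def load_construct(fasta_path: str | Path, elements_table_path: str | Path) -> HairpinConstruct:
    """Build a validated HairpinConstruct from a one-record FASTA and a
    TSV element table with columns name, role, start, end, strand."""
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{fasta_path}: expected exactly one FASTA record, got {len(records)}")
    rec = records[0]

    elements: list[ConstructElement] = []
    with open(elements_table_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {c: i for i, c in enumerate(header)}
        for needed in ("name", "role", "start", "end"):
            if needed not in cols:
                raise ValueError(f"{elements_table_path}: missing column {needed!r}")
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            elements.append(
                ConstructElement(
                    name=fields[cols["name"]],
                    role=fields[cols["role"]],
                    start=int(fields[cols["start"]]),
                    end=int(fields[cols["end"]]),
                    strand=fields[cols["strand"]] if "strand" in cols else "+",
                )
            )
    return HairpinConstruct(id=rec.id, sequence=str(rec.seq), elements=elements)


def save_elements_table(elements: Sequence[ConstructElement], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\trole\tstart\tend\tstrand\n")
        for el in elements:
            fh.write(f"{el.name}\t{el.role}\t{el.start}\t{el.end}\t{el.strand}\n")
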