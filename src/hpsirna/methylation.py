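"""Per-cytosine and per-context methylation calling from bisulfite clones.

Bisulfite treatment converts unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine is protected. Against a gapless reference,
a clone base of C at a reference-cytosine position is therefore a methylated
call and T a converted (unmethylated) call. Plant methylation is classified
by the two bases 3' of the cytosine on the reference: CGN (next base G),
CHG (C-H-G) and CHH (C-H-H), with H = A, T or C and N any base. Context is
always computed on the reference, never on the converted clone, because
conversion destroys the context information itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequences import normalize

CONTEXTS = ("CGN", "CHG", "CHH")
_H = frozenset("ATC")


@dataclass
class CytosineSite:
    position: int  # 1-based on the reference sense strand
    context: str  # CGN | CHG | CHH | edge | ambiguous
    methylated_count: int = 0
    clone_count: int = 0

    @property
    def percent(self) -> float:
        return 100.0 * self.methylated_count / self.clone_count if self.clone_count else 0.0


@dataclass
class MethylationReport:
    region_id: str
    sites: list[CytosineSite] = field(default_factory=list)
    n_clones: int = 0

    def context_percentages(self) -> dict[str, float]:
        """Pooled per-context percentages: 100 * sum(methylated)/sum(calls)
        over non-edge, non-ambiguous cytosines of each context."""
        out = {}
        for ctx in CONTEXTS:
            meth = sum(s.methylated_count for s in self.sites if s.context == ctx)
            total = sum(s.clone_count for s in self.sites if s.context == ctx)
            out[ctx] = 100.0 * meth / total if total else float("nan")
        return out

    def conversion_qc(self) -> float:
        """Fraction of clone calls read as T over all scored cytosine calls —
        a lower bound on conversion efficiency (methylation deflates it)."""
        total = sum(s.clone_count for s in self.sites)
        meth = sum(s.methylated_count for s in self.sites)
        return (total - meth) / total if total else float("nan")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (self.region_id, s.position, s.context, s.methylated_count, s.clone_count, s.percent)
                for s in self.sites
            ],
            columns=["region", "position", "context", "methylated", "total", "percent"],
        )


def classify_contexts(reference: str) -> list[CytosineSite]:
    """Assign a methylation context to every cytosine of the sense strand.

    Cytosines whose context-determining bases run past the 3' end are
    classified from the available bases where the rule is already decided
    (a following G makes CGN regardless of the third base) and flagged
    ``edge`` otherwise; any non-ACGT base at a deciding position flags the
    site ``ambiguous``. Edge and ambiguous sites are excluded from context
    percentages downstream.
    """
    ref = normalize(reference)
    n = len(ref)
    sites: list[CytosineSite] = []
    for i, base in enumerate(ref):
        if base != "C":
            continue
        pos = i + 1
        b1 = ref[i + 1] if i + 1 < n else None
        b2 = ref[i + 2] if i + 2 < n else None
        if b1 is None:
            ctx = "edge"
        elif b1 == "G":
            ctx = "CGN"
        elif b1 in _H:
            if b2 is None:
                ctx = "edge"
            elif b2 == "G":
                ctx = "CHG"
            elif b2 in _H:
                ctx = "CHH"
            else:
                ctx = "ambiguous"
        else:
            ctx = "ambiguous"
        sites.append(CytosineSite(position=pos, context=ctx))
    return sites


def call_methylation(
    clones: Sequence[str] | Mapping[str, str],
    reference: str,
    region_id: str = "region",
    strand: str = "+",
) -> MethylationReport:
    """Score gapless clones against a reference region.

    At each reference cytosine, clone C counts as methylated, clone T as
    converted; any other base is an ambiguous call excluded from that site's
    denominator. Clones must match the reference length exactly (amplicons
    are assumed pre-aligned and indel-free; realignment belongs upstream).
    ``strand='-'`` scores the bottom strand by reverse-complementing the
    reference and every clone before calling.
    """
    if isinstance(clones, Mapping):
        items = list(clones.items())
    else:
        items = [(f"clone_{i + 1}", c) for i, c in enumerate(clones)]
    if strand == "-":
        from .sequences import revcomp

        items = [(name, revcomp(seq)) for name, seq in items]
        reference = revcomp(reference)
    ref = normalize(reference)
    for name, seq in items:
        if len(normalize(seq)) != len(ref):
            raise ValueError(
                f"clone {name!r} length {len(seq)} != reference length {len(ref)}"
            )
    sites = classify_contexts(ref)
    for _, seq in items:
        s = normalize(seq)
        for site in sites:
            call = s[site.position - 1]
            if call == "C":
                site.methylated_count += 1
                site.clone_count += 1
            elif call == "T":
                site.clone_count += 1
            # anything else: ambiguous call, excluded
    return MethylationReport(region_id=region_id, sites=sites, n_clones=len(items))


def compare_regions(
    reports: Iterable[tuple[str, str, MethylationReport]],
) -> pd.DataFrame:
    """Long-format comparison across lines and regions.

    ``reports`` yields (line, region, report); duplicates of a (line, region)
    pair are an error. Output columns: line, region, context, percent.
    """
    rows = []
    seen: set[tuple[str, str]] = set()
    for line, region, report in reports:
        key = (line, region)
        if key in seen:
            raise ValueError(f"duplicate report for line={line!r}, region={region!r}")
        seen.add(key)
        for ctx, pct in report.context_percentages().items():
            rows.append((line, region, ctx, pct))
    return pd.DataFrame(rows, columns=["line", "region", "context", "percent"])
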