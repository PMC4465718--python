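"""Ground-truth simulators for every input the pipeline consumes.

No sequencing data is required to exercise the analysis: this module emits a
hairpin construct with a divergent three-member target family, diced
small-RNA libraries (FASTQ) with a per-read origin label, 5'RACE clone
tables mixing siRNA-directed cleavage with uniform degradation, and
bisulfite clone sets with planted per-context methylation probabilities.
Every generator is a pure function of (parameters, seed): identical inputs
give bit-identical outputs, and each returns the ground truth needed for
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .construct import ConstructElement, HairpinConstruct, TargetTranscript
from .methylation import classify_contexts
from .sequences import revcomp, subseq

BASES = np.array(list("ACGT"))

#: Sense-strand segment (region positions 280-319 of the stem) reconstructed
#: from the published candidate-siRNA table; the only non-synthetic sequence
#: anchor used by the default scenario.
TARGET_SEGMENT_40NT = "TATTACCGTGAGCCAGAAAGATCTGCACCATTACCATTTC"
TARGET_SEGMENT_START = 280

# Default total-abundance size mixture: DCL4/DCL2/DCL3 processing yields a
# dominant 21-nt class, then 22 nt, with a minor 24-nt peak.
DEFAULT_SIZE_WEIGHTS = {
    18: 0.02, 19: 0.02, 20: 0.04, 21: 0.55, 22: 0.18, 23: 0.03, 24: 0.12, 25: 0.04,
}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


@dataclass
class DicingModel:
    """Generative model of hpRNA dicing into a small-RNA library.

    size_weights: probability of each read length 18..25 (must sum to 1).
    antisense_fraction: share of stem reads from the antisense strand
        (guide-strand asymmetry; slightly below 0.5 by default).
    hotspot_positions: window starts on the stem that receive boosted mass.
    hotspot_concentration: a hot window's weight is this multiple of the
        mean background window weight, so hot windows dominate the profile
        by construction at the default of 100.
    per-window abundance is latent log-normal (heavy-tailed), so a few
        prominent siRNAs dominate while most windows carry low mass. The
        latent weights are drawn from ``weights_seed`` (default: ``seed``):
        independent lines sharing a weights_seed share the dicing pattern
        (it is a property of the hairpin substrate, not of the sample)
        while their reads remain independently sampled.
    depth: total reads emitted (stem + loop + transitive + background).
    loop_leakage_rate: fraction of reads from the loop intron (hairpin
        self-targeting producing secondary siRNAs).
    transitivity_rate: fraction of reads from transcript regions outside the
        primary target region (RdRP-amplified secondary siRNAs).
    background_rate: fraction of reads from the synthetic genome background.
    """

    size_weights: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SIZE_WEIGHTS))
    antisense_fraction: float = 0.45
    hotspot_positions: tuple[int, ...] = (80, 145, 275)
    hotspot_concentration: float = 100.0
    abundance_sigma: float = 1.5
    depth: int = 200_000
    loop_leakage_rate: float = 0.005
    transitivity_rate: float = 0.01
    background_rate: float = 0.10
    seed: int = 0
    weights_seed: Optional[int] = None

    def __post_init__(self) -> None:
        total = sum(self.size_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"size_weights sum to {total}, expected 1")
        if not set(self.size_weights) <= set(range(18, 26)):
            raise ValueError("size_weights keys must lie in 18..25")
        if not 0.0 < self.antisense_fraction < 1.0:
            raise ValueError("antisense_fraction must lie in (0,1)")
        for name in ("loop_leakage_rate", "transitivity_rate", "background_rate"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0,1)")
        if self.loop_leakage_rate + self.transitivity_rate + self.background_rate >= 1.0:
            raise ValueError("origin rates leave no mass for stem reads")
        if self.hotspot_concentration <= 0:
            raise ValueError("hotspot_concentration must be positive")


@dataclass
class RaceModel:
    """5'RACE clone-generation model: a mixture of siRNA-directed cleavage at
    weighted dinucleotide sites and uniform degradation over a span."""

    directed_sites: dict[tuple[int, int], float] = field(default_factory=dict)
    degradation_fraction: float = 0.0
    n_clones: int = 25
    span: Optional[tuple[int, int]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.degradation_fraction <= 1.0:
            raise ValueError("degradation_fraction must lie in [0,1]")
        if not self.directed_sites and self.degradation_fraction < 1.0:
            raise ValueError("directed_sites empty but degradation_fraction < 1")
        for (i, j), w in self.directed_sites.items():
            if j != i + 1:
                raise ValueError(f"cut site {(i, j)} is not a dinucleotide position")
            if w <= 0:
                raise ValueError("directed-site weights must be positive")


@dataclass
class BisulfiteModel:
    """Per-context methylation probabilities and bisulfite conversion rate."""

    per_context_methylation: dict[str, float] = field(
        default_factory=lambda: {"CGN": 0.8, "CHG": 0.5, "CHH": 0.2}
    )
    conversion_rate: float = 1.0
    n_clones: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for ctx, p in self.per_context_methylation.items():
            if ctx not in {"CGN", "CHG", "CHH"}:
                raise ValueError(f"unknown context {ctx!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"methylation probability for {ctx} outside [0,1]")
        if not 0.0 < self.conversion_rate <= 1.0:
            raise ValueError("conversion_rate must lie in (0,1]")


# ---------------------------------------------------------------------------
# construct + target family


def simulate_family(
    ir_length: int = 318,
    identities: Sequence[float] = (100.0, 96.5, 84.3),
    seed: int = 0,
    flank: int = 300,
    transcript_ids: Optional[Sequence[str]] = None,
    anchor: Optional[tuple[int, str]] = (TARGET_SEGMENT_START, TARGET_SEGMENT_40NT),
) -> tuple[HairpinConstruct, list[TargetTranscript]]:
    """Generate a hairpin construct and a divergent target family.

    Transcript 1's target region is identical to the IR; transcript i carries
    exactly round(L * (100 - identity_i) / 100) substitutions at uniformly
    drawn positions. ``anchor`` plants a fixed sense segment at a given stem
    start (used by the default scenario to anchor the cleavage-site region);
    pass None for a fully random stem.
    """
    if ir_length < 21:
        raise ValueError("ir_length must be at least 21")
    for ident in identities:
        if not 0.0 < ident <= 100.0:
            raise ValueError(f"identity {ident} outside (0,100]")
        if round(ir_length * (100.0 - ident) / 100.0) >= ir_length:
            raise ValueError(f"identity {ident} implies >= {ir_length} mismatches")

    rng = np.random.default_rng(seed)
    stem = list(_random_seq(rng, ir_length))
    if anchor is not None:
        a_start, a_seq = anchor
        if a_start >= 1 and a_start <= ir_length:
            # truncate to the stem if the segment overhangs its 3' end
            fit = a_seq[: ir_length - a_start + 1]
            stem[a_start - 1 : a_start - 1 + len(fit)] = list(fit)
    stem_seq = "".join(stem)

    # T-DNA layout: promoter | IR-F | loop intron | IR-R | terminator
    promoter = _random_seq(rng, 400)
    loop = _random_seq(rng, 200)
    terminator = _random_seq(rng, 200)
    sequence = promoter + stem_seq + loop + revcomp(stem_seq) + terminator
    p = len(promoter)
    elements = [
        ConstructElement("GlyP", "promoter", 1, p),
        ConstructElement("IR-F", "ir_forward", p + 1, p + ir_length),
        ConstructElement("waxy-a_intron", "loop_intron", p + ir_length + 1, p + ir_length + 200),
        ConstructElement("IR-R", "ir_reverse", p + ir_length + 201, p + 2 * ir_length + 200),
        ConstructElement("Tvsp", "terminator", p + 2 * ir_length + 201, len(sequence)),
    ]
    construct = HairpinConstruct(id="hp_construct", sequence=sequence, elements=elements)

    if transcript_ids is None:
        transcript_ids = [f"target_{i + 1}" for i in range(len(identities))]
    transcripts: list[TargetTranscript] = []
    for tid, ident in zip(transcript_ids, identities):
        n_mm = int(round(ir_length * (100.0 - ident) / 100.0))
        region = list(stem_seq)
        if n_mm > 0:
            positions = rng.choice(ir_length, size=n_mm, replace=False)
            for pos in positions:
                alternatives = [b for b in "ACGT" if b != region[pos]]
                region[pos] = alternatives[rng.integers(0, 3)]
        left = _random_seq(rng, flank)
        right = _random_seq(rng, flank)
        transcripts.append(
            TargetTranscript(
                id=tid,
                sequence=left + "".join(region) + right,
                target_region=(flank + 1, flank + ir_length),
            )
        )
    return construct, transcripts


def simulate_genome(
    construct: HairpinConstruct,
    transcripts: Sequence[TargetTranscript],
    seed: int = 0,
    background_length: int = 10_000,
) -> dict[str, str]:
    """Synthetic genome reference set: a random background contig, the
    endogenous target loci, and the chromosomally integrated transgene."""
    rng = np.random.default_rng(seed)
    genome = {"chr_background": _random_seq(rng, background_length)}
    for t in transcripts:
        genome[t.id] = t.sequence
    genome[construct.id] = construct.sequence
    return genome


# ---------------------------------------------------------------------------
# small-RNA library


@dataclass
class SimulatedLibrary:
    sample_id: str
    reads: list[tuple[str, str]]  # (read_id, sequence)
    truth: pd.DataFrame  # read_id, origin, length, strand, start
    window_weights: dict[int, float]  # latent per-start stem weights

    def true_window_counts(self) -> pd.DataFrame:
        stem = self.truth[self.truth.origin.str.startswith("stem")]
        return (
            stem.groupby(["start", "strand"], as_index=False)
            .size()
            .rename(columns={"size": "true_count"})
        )


def simulate_small_rna_library(
    construct: HairpinConstruct,
    transcripts: Sequence[TargetTranscript],
    dicing: DicingModel,
    genome: Optional[dict[str, str]] = None,
    sample_id: str = "sample",
) -> SimulatedLibrary:
    """Dice the hairpin into a read library with per-read origin labels.

    Origins: stem_sense / stem_antisense (primary siRNAs from the IR),
    loop (hairpin self-targeting), transitive (secondary siRNAs outside the
    target region of a transcript), background (synthetic genome).
    Ground-truth rows sum exactly to ``depth``.
    """
    if dicing.depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(dicing.seed)
    stem = construct.ir_sequence
    L = len(stem)

    lengths_avail = sorted(dicing.size_weights)
    size_p = np.array([dicing.size_weights[k] for k in lengths_avail])

    # Latent heavy-tailed per-start weights, shared across read lengths. Hot
    # windows receive hotspot_concentration times the mean background weight
    # so they dominate the profile by construction, not by lottery.
    weights_rng = np.random.default_rng(
        dicing.seed if dicing.weights_seed is None else dicing.weights_seed
    )
    max_starts = L - min(lengths_avail) + 1
    latent = np.exp(weights_rng.normal(0.0, dicing.abundance_sigma, size=max_starts))
    mean_bg = float(np.exp(dicing.abundance_sigma**2 / 2.0))
    for pos in dicing.hotspot_positions:
        if 1 <= pos <= max_starts:
            latent[pos - 1] = dicing.hotspot_concentration * mean_bg
    window_weights = {s + 1: float(w) for s, w in enumerate(latent)}

    origins = rng.choice(
        np.array(["background", "loop", "transitive", "stem"]),
        size=dicing.depth,
        p=[
            dicing.background_rate,
            dicing.loop_leakage_rate,
            dicing.transitivity_rate,
            1.0 - dicing.background_rate - dicing.loop_leakage_rate - dicing.transitivity_rate,
        ],
    )
    read_lengths = rng.choice(lengths_avail, size=dicing.depth, p=size_p)

    if genome is None:
        genome = simulate_genome(construct, transcripts, seed=dicing.seed)
    bg_id = "chr_background" if "chr_background" in genome else next(iter(genome))
    bg_seq = genome[bg_id]

    loop_el = construct.element("loop_intron")
    loop_seq = construct.element_sequence(loop_el)

    seqs = np.empty(dicing.depth, dtype=object)
    out_origin = np.empty(dicing.depth, dtype=object)
    out_strand = np.empty(dicing.depth, dtype=object)
    out_start = np.zeros(dicing.depth, dtype=int)

    def _fill(idx: np.ndarray, source: str, starts: np.ndarray, k: int,
              anti: np.ndarray, origin_labels: tuple[str, str], offset: int = 0) -> None:
        src = {"stem": stem, "loop": loop_seq, "background": bg_seq}[source]
        for i, s, a in zip(idx, starts, anti):
            frag = src[s - 1 : s - 1 + k]
            seqs[i] = revcomp(frag) if a else frag
            out_strand[i] = "antisense" if a else "sense"
            out_origin[i] = origin_labels[1] if a else origin_labels[0]
            out_start[i] = s + offset

    for k in lengths_avail:
        # primary stem siRNAs: weighted window, guide-strand asymmetry
        sel = np.flatnonzero((origins == "stem") & (read_lengths == k))
        if sel.size:
            w = latent[: L - k + 1]
            starts = rng.choice(L - k + 1, size=sel.size, p=w / w.sum()) + 1
            anti = rng.random(sel.size) < dicing.antisense_fraction
            _fill(sel, "stem", starts, k, anti, ("stem_sense", "stem_antisense"))
        # loop-derived secondary siRNAs, uniform on the intron, both strands
        sel = np.flatnonzero((origins == "loop") & (read_lengths == k))
        if sel.size:
            starts = rng.integers(1, len(loop_seq) - k + 2, size=sel.size)
            anti = rng.random(sel.size) < 0.5
            _fill(sel, "loop", starts, k, anti, ("loop", "loop"), offset=loop_el.start - 1)
        # transitive secondary siRNAs: outside the target region on a
        # uniformly chosen transcript, clear of the region by a margin so
        # the downstream scan is unambiguous
        sel = np.flatnonzero((origins == "transitive") & (read_lengths == k))
        if sel.size:
            which = rng.integers(0, len(transcripts), size=sel.size)
            anti = rng.random(sel.size) < 0.5
            margin = 21
            for i, t_idx, a in zip(sel, which, anti):
                t = transcripts[t_idx]
                r0, r1 = t.target_region
                left = np.arange(1, max(1, r0 - margin - k + 2))
                right = np.arange(
                    min(len(t.sequence) - k + 1, r1 + margin) + 1,
                    len(t.sequence) - k + 2,
                )
                pool = np.concatenate([left, right])
                s = int(rng.choice(pool))
                frag = t.sequence[s - 1 : s - 1 + k]
                seqs[i] = revcomp(frag) if a else frag
                out_strand[i] = "antisense" if a else "sense"
                out_origin[i] = "transitive"
                out_start[i] = s
        # genomic background
        sel = np.flatnonzero((origins == "background") & (read_lengths == k))
        if sel.size:
            starts = rng.integers(1, len(bg_seq) - k + 2, size=sel.size)
            anti = rng.random(sel.size) < 0.5
            _fill(sel, "background", starts, k, anti, ("background", "background"))

    read_ids = [f"{sample_id}_r{i:07d}" for i in range(dicing.depth)]
    reads = list(zip(read_ids, seqs.tolist()))
    truth = pd.DataFrame(
        {
            "read_id": read_ids,
            "origin": out_origin,
            "length": read_lengths,
            "strand": out_strand,
            "start": out_start,
            "sequence": seqs,
        }
    )
    return SimulatedLibrary(sample_id, reads, truth, window_weights)


def write_fastq(reads: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write reads as FASTQ with constant quality (quality is not modeled)."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


# ---------------------------------------------------------------------------
# 5'RACE clones


def simulate_race_clones(
    transcript: TargetTranscript,
    race: RaceModel,
    sample_id: str = "sample",
) -> pd.DataFrame:
    """Clone cut-position table: directed cleavage at weighted sites plus
    uniform degradation over ``race.span`` (default: whole transcript).

    Positions are reported on the transcript axis as dinucleotide cut sites
    (cut_i, cut_j = cut_i + 1). Degradation clones may fall outside the
    target region, emulating natural mRNA turnover seen in wild type.
    """
    if race.n_clones < 0:
        raise ValueError("n_clones must be non-negative")
    rng = np.random.default_rng(race.seed)
    span = race.span or (1, len(transcript.sequence) - 1)
    if span[0] < 1 or span[1] >= len(transcript.sequence):
        raise ValueError("degradation span outside transcript")

    sites = list(race.directed_sites)
    weights = np.array([race.directed_sites[s] for s in sites], dtype=float)
    if weights.size:
        weights = weights / weights.sum()

    rows = []
    for c in range(race.n_clones):
        if rng.random() < race.degradation_fraction:
            i = int(rng.integers(span[0], span[1] + 1))
        else:
            i = sites[int(rng.choice(len(sites), p=weights))][0]
        rows.append((sample_id, transcript.id, i, i + 1))
    return pd.DataFrame(rows, columns=["sample", "transcript", "cut_i", "cut_j"])


# ---------------------------------------------------------------------------
# bisulfite clones


def simulate_bisulfite_clones(
    reference: str,
    model: BisulfiteModel,
) -> list[str]:
    """Bisulfite-converted clone sequences for a reference region.

    Each reference cytosine is methylated with its context probability
    (contexts computed on the reference); an unmethylated cytosine converts
    to T with probability ``conversion_rate`` (incomplete conversion leaves a
    residual C, inflating apparent methylation by (1-p)(1-conversion_rate)).
    """
    rng = np.random.default_rng(model.seed)
    contexts = {site.position: site.context for site in classify_contexts(reference)}
    ref = reference.upper().replace("U", "T")
    clones = []
    for _ in range(model.n_clones):
        clone = list(ref)
        for pos, ctx in contexts.items():
            p_meth = model.per_context_methylation.get(ctx, 0.0)
            if rng.random() < p_meth:
                continue  # methylated: protected from conversion
            if rng.random() < model.conversion_rate:
                clone[pos - 1] = "T"
        clones.append("".join(clone))
    return clones
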