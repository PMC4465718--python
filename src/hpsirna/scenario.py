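"""The default synthetic study: three hairpin-RNAi lines plus wild type.

This module wires the simulators and analysis stages into one reproducible
scenario emulating the study conditions: a 318-nt inverted repeat against a
three-member target family at 100 / 96.5 / 84.3 % identity; three RNAi
lines with one high-expressing line at roughly four-fold the sequencing-
depth-weighted siRNA output of the other two, plus a wild-type control
dominated by genomic background; RACE clone sets mixing directed cleavage
at stem sites 297-298 / 301-302 (plus the shared degradation-prone site
274-275) with uniform degradation; and bisulfite clone sets whose planted
per-context methylation tracks each line's transgene silencing level.

Every quantity is a pure function of the scenario seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml
from Bio import SeqIO

from . import cleavage as cl
from . import mapping as mp
from . import methylation as meth
from . import profiles as pf
from . import simulate as sim
from .construct import HairpinConstruct, TargetTranscript, load_construct, save_elements_table
from .sequences import subseq

RNAI_LINES = ("S-24-4D", "S-24-13", "S-24-15")
ALL_SAMPLES = RNAI_LINES + ("WT",)


@dataclass
class ScenarioConfig:
    seed: int = 0
    ir_length: int = 318
    identities: tuple[float, ...] = (100.0, 96.5, 84.3)
    flank: int = 300
    depths: dict[str, int] = field(
        default_factory=lambda: {
            "S-24-4D": 200_000,
            "S-24-13": 50_000,
            "S-24-15": 50_000,
            "WT": 50_000,
        }
    )
    hotspot_positions: tuple[int, ...] = (80, 145, 275)
    min_fraction: float = 0.05
    top_n: int = 1000
    k: int = 21
    terminal_exclusion: int = 2
    reference_sample: str = "S-24-4D"
    cut_sites: tuple[tuple[int, int], ...] = ((297, 298), (301, 302))
    n_bisulfite_clones: int = 10

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        obj = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key, value in obj.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            default = getattr(cfg, key)
            if isinstance(default, tuple):
                value = tuple(tuple(v) if isinstance(v, list) else v for v in value)
            setattr(cfg, key, value)
        return cfg

    def to_yaml(self) -> str:
        out = {}
        for key, value in self.__dict__.items():
            if isinstance(value, tuple):
                value = [list(v) if isinstance(v, tuple) else v for v in value]
            out[key] = value
        return yaml.safe_dump(out, sort_keys=True)


# Per-line generative settings: the high-expressing line dominates siRNA
# output; transgene methylation is anticorrelated with transgene expression
# (the most transcriptionally silenced line is the most methylated); the
# endogenous promoter picks up ~20% methylation in one line only.
LINE_RACE = {
    "S-24-4D": dict(deg=0.10, sites={(297, 298): 0.35, (301, 302): 0.22, (274, 275): 0.12,
                                     (250, 251): 0.08, (310, 311): 0.05}, n=23),
    "S-24-13": dict(deg=0.20, sites={(297, 298): 0.22, (301, 302): 0.18, (274, 275): 0.15,
                                     (250, 251): 0.07, (230, 231): 0.05}, n=25),
    "S-24-15": dict(deg=0.20, sites={(274, 275): 0.35, (297, 298): 0.10, (301, 302): 0.08,
                                     (250, 251): 0.07}, n=26),
    "WT": dict(deg=1.0, sites={}, n=28),
}

TRANSGENE_METHYLATION = {
    "S-24-4D": {"CGN": 0.10, "CHG": 0.06, "CHH": 0.03},
    "S-24-13": {"CGN": 0.90, "CHG": 0.70, "CHH": 0.40},
    "S-24-15": {"CGN": 0.60, "CHG": 0.40, "CHH": 0.20},
    "WT": {"CGN": 0.0, "CHG": 0.0, "CHH": 0.0},
}
ENDOGENOUS_METHYLATION = {
    "S-24-4D": {"CGN": 0.01, "CHG": 0.01, "CHH": 0.01},
    "S-24-13": {"CGN": 0.02, "CHG": 0.01, "CHH": 0.01},
    "S-24-15": {"CGN": 0.20, "CHG": 0.20, "CHH": 0.20},
    "WT": {"CGN": 0.0, "CHG": 0.0, "CHH": 0.0},
}


@dataclass
class Scenario:
    config: ScenarioConfig
    construct: HairpinConstruct
    transcripts: list[TargetTranscript]
    genome: dict[str, str]
    libraries: dict[str, sim.SimulatedLibrary]
    race_clones: pd.DataFrame
    bisulfite_regions: dict[str, str]  # region id -> reference sequence
    bisulfite_clones: dict[tuple[str, str], list[str]]  # (region, line) -> clones


def _dicing_for(sample: str, cfg: ScenarioConfig, seed: int) -> sim.DicingModel:
    if sample == "WT":
        # no transgene: background dominates, a thin endogenous 21-nt signal
        return sim.DicingModel(
            hotspot_positions=cfg.hotspot_positions,
            depth=cfg.depths[sample],
            loop_leakage_rate=0.0,
            transitivity_rate=0.0,
            background_rate=0.98,
            seed=seed,
            weights_seed=cfg.seed,
        )
    # all lines share the latent dicing pattern (a property of the hairpin
    # substrate) while sampling reads independently
    return sim.DicingModel(
        hotspot_positions=cfg.hotspot_positions,
        depth=cfg.depths[sample],
        seed=seed,
        weights_seed=cfg.seed,
    )


def build_scenario(config: Optional[ScenarioConfig] = None) -> Scenario:
    cfg = config or ScenarioConfig()
    construct, transcripts = sim.simulate_family(
        ir_length=cfg.ir_length,
        identities=cfg.identities,
        seed=cfg.seed,
        flank=cfg.flank,
        transcript_ids=["FAD3A_like", "FAD3B_like", "FAD3C_like"][: len(cfg.identities)],
    )
    genome = sim.simulate_genome(construct, transcripts, seed=cfg.seed + 1)

    libraries = {}
    for i, sample in enumerate(ALL_SAMPLES):
        if sample not in cfg.depths:
            continue
        dicing = _dicing_for(sample, cfg, seed=cfg.seed + 10 + i)
        libraries[sample] = sim.simulate_small_rna_library(
            construct, transcripts, dicing, genome=genome, sample_id=sample
        )

    # RACE clones on the primary target, cut positions on the transcript axis
    fad3a = transcripts[0]
    offset = fad3a.target_region[0] - 1
    frames = []
    for i, (sample, spec_) in enumerate(LINE_RACE.items()):
        model = sim.RaceModel(
            directed_sites={(i0 + offset, j0 + offset): w for (i0, j0), w in spec_["sites"].items()},
            degradation_fraction=spec_["deg"],
            n_clones=spec_["n"],
            seed=cfg.seed + 100 + i,
        )
        frames.append(sim.simulate_race_clones(fad3a, model, sample_id=sample))
    race_clones = pd.concat(frames, ignore_index=True)

    # bisulfite regions: four transgene spans and two endogenous spans
    promoter = construct.element("promoter")
    ir_f = construct.element("ir_forward")
    loop = construct.element("loop_intron")
    term = construct.element("terminator")
    glycinin = genome["chr_background"][:550]  # stand-in endogenous locus
    regions = {
        "I_promoter": subseq(construct.sequence, promoter.end - 299, promoter.end),
        "II_ir_forward": subseq(construct.sequence, ir_f.start, ir_f.end),
        "III_loop": subseq(construct.sequence, loop.start, loop.end),
        "IV_terminator": subseq(construct.sequence, term.start, term.start + 199),
        "V_glycinin_promoter": glycinin[:297],
        "VI_glycinin_coding": glycinin[297:552],
    }
    clones = {}
    for r, (region_id, ref) in enumerate(regions.items()):
        endogenous = region_id.startswith(("V_", "VI_"))
        for s, sample in enumerate(ALL_SAMPLES):
            probs = (ENDOGENOUS_METHYLATION if endogenous else TRANSGENE_METHYLATION)[sample]
            model = sim.BisulfiteModel(
                per_context_methylation=probs,
                conversion_rate=1.0,
                n_clones=cfg.n_bisulfite_clones,
                seed=cfg.seed + 1000 + 10 * r + s,
            )
            clones[(region_id, sample)] = sim.simulate_bisulfite_clones(ref, model)

    return Scenario(
        config=cfg,
        construct=construct,
        transcripts=transcripts,
        genome=genome,
        libraries=libraries,
        race_clones=race_clones,
        bisulfite_regions=regions,
        bisulfite_clones=clones,
    )


# ---------------------------------------------------------------------------
# scenario <-> files


def write_scenario(scenario: Scenario, outdir: str | Path) -> dict[str, str]:
    """Write the scenario as plain-text inputs plus a checksum manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "construct.fasta").write_text(
        f">{scenario.construct.id}\n{scenario.construct.sequence}\n"
    )
    save_elements_table(scenario.construct.elements, out / "elements.tsv")
    scenario.construct.save(out / "construct.json")
    with open(out / "transcripts.fasta", "w") as fh:
        for t in scenario.transcripts:
            r = t.target_region
            tag = f" region={r[0]}-{r[1]}" if r else ""
            fh.write(f">{t.id}{tag}\n{t.sequence}\n")
    with open(out / "genome.fasta", "w") as fh:
        for rid, seq in scenario.genome.items():
            fh.write(f">{rid}\n{seq}\n")
    for sample, lib in scenario.libraries.items():
        sim.write_fastq(lib.reads, out / f"reads_{sample}.fastq")
        lib.truth.to_csv(out / f"truth_{sample}.tsv", sep="\t", index=False)
    scenario.race_clones.to_csv(out / "race_clones.tsv", sep="\t", index=False)
    bis = out / "bisulfite"
    bis.mkdir(exist_ok=True)
    for region_id, ref in scenario.bisulfite_regions.items():
        (bis / f"{region_id}_reference.fasta").write_text(f">{region_id}\n{ref}\n")
    for (region_id, sample), clone_list in scenario.bisulfite_clones.items():
        with open(bis / f"{region_id}_{sample}_clones.fasta", "w") as fh:
            for i, c in enumerate(clone_list, 1):
                fh.write(f">{region_id}_{sample}_clone{i}\n{c}\n")
    (out / "scenario.yaml").write_text(scenario.config.to_yaml())

    manifest = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest[str(path.relative_to(out))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def load_transcripts(path: str | Path) -> list[TargetTranscript]:
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        region = None
        for token in rec.description.split():
            if token.startswith("region="):
                a, b = token[len("region="):].split("-")
                region = (int(a), int(b))
        out.append(TargetTranscript(id=rec.id, sequence=str(rec.seq), target_region=region))
    return out


# ---------------------------------------------------------------------------
# analysis stages over an in-memory scenario


@dataclass
class MappedScenario:
    scenario: Scenario
    libraries: dict[str, mp.SmallRNALibrary]
    ir_mapped: dict[str, list[mp.MappedSirna]]  # stem-axis, double-arm collapsed
    cpm: dict[str, dict[str, float]]
    genome_index: mp.ExactIndex


def map_scenario(scenario: Scenario) -> MappedScenario:
    """Collapse, denominate and map every library to the stem axis."""
    genome_index = mp.build_index(scenario.genome)
    libraries = {}
    ir_mapped = {}
    cpm = {}
    for sample, simlib in scenario.libraries.items():
        lib = mp.collapse_reads(simlib.reads, sample_id=sample)
        mp.compute_denominator(lib, genome_index)
        libraries[sample] = lib
        mapped = mp.map_library(lib, genome_index, "IR", hairpin=scenario.construct)
        ir_mapped[sample] = mapped
        cpm[sample] = mp.cpm_normalize(lib)
    return MappedScenario(scenario, libraries, ir_mapped, cpm, genome_index)


def run_profile(ms: MappedScenario, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Size distributions, stem profiles, hot spots, overlap, homolog and
    transitivity reports, written as TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = ms.scenario.config
    genome_index = ms.genome_index

    results: dict[str, pd.DataFrame] = {}
    size_frames = []
    for sample, mapped in ms.ir_mapped.items():
        for mode in ("distinct", "total"):
            df = pf.size_distribution(mapped, mode=mode)
            df.insert(0, "scope", "IR")
            df.insert(0, "mode", mode)
            df.insert(0, "sample", sample)
            size_frames.append(df)
    results["size_distribution"] = pd.concat(size_frames, ignore_index=True)

    prof_frames = []
    for sample, mapped in ms.ir_mapped.items():
        df = pf.positional_profile(mapped, reference_id="IR")
        df.insert(0, "sample", sample)
        prof_frames.append(df)
    results["profile"] = pd.concat(prof_frames, ignore_index=True)

    hot_rows = []
    for sample, mapped in ms.ir_mapped.items():
        prof = pf.positional_profile(mapped, reference_id="IR")
        for pos, strand in pf.detect_hotspots(prof, min_fraction=cfg.min_fraction):
            hot_rows.append((sample, pos, strand))
    results["hotspots"] = pd.DataFrame(hot_rows, columns=["sample", "start", "strand"])

    ir_cpm = {
        sample: {m.sequence: m.cpm for m in mapped}
        for sample, mapped in ms.ir_mapped.items()
        if sample != "WT"
    }
    overlap = pf.top_n_overlap(ir_cpm, n=cfg.top_n)
    results["overlap"] = pd.DataFrame(
        [
            ("+".join(sorted(k)), v)
            for k, v in sorted(overlap.exclusive_counts.items(), key=lambda kv: sorted(kv[0]))
        ]
        + [("shared_fraction_top_n", overlap.shared_fraction)],
        columns=["subset", "value"],
    )

    homolog_frames = []
    for sample, mapped in ms.ir_mapped.items():
        df = pf.map_to_homologs(mapped, ms.scenario.transcripts)
        df.insert(0, "sample", sample)
        homolog_frames.append(df)
    results["homolog_mapping"] = pd.concat(homolog_frames, ignore_index=True)

    trans_frames = []
    fad3a = ms.scenario.transcripts[0]
    for sample, lib in ms.libraries.items():
        mapped_t = mp.map_library(lib, genome_index, fad3a.id)
        df = pf.transitivity_scan(
            mapped_t, len(fad3a.sequence), fad3a.target_region
        )
        df.insert(0, "sample", sample)
        trans_frames.append(df)
    results["transitivity"] = pd.concat(trans_frames, ignore_index=True)

    for name, df in results.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.6g")
    return results


def run_cleavage(ms: MappedScenario, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """RACE tallies, candidate siRNAs and expected product-size table."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = ms.scenario.config
    fad3a = ms.scenario.transcripts[0]
    region = fad3a.target_region
    offset = region[0] - 1

    tallies = cl.tally_cleavage(
        ms.scenario.race_clones,
        region=region,
        sample_set=list(RNAI_LINES),
        transcript_length=len(fad3a.sequence),
    )
    rows = []
    for sample, tally in tallies.items():
        for site, frac in sorted(tally.fractions.items()):
            rows.append(
                (
                    sample,
                    site[0] - offset,  # report on the 1..L region axis
                    site[1] - offset,
                    tally.counts[site],
                    round(frac, 4),
                    site in tally.conserved_sites,
                    tally.inside_region_count,
                    tally.outside_region_count,
                )
            )
    tally_df = pd.DataFrame(
        rows,
        columns=[
            "sample", "cut_i", "cut_j", "clones", "fraction",
            "conserved", "inside_region", "outside_region",
        ],
    )

    candidates = cl.select_candidate_sirnas(
        {s: m for s, m in ms.ir_mapped.items()},
        cut_sites=list(cfg.cut_sites),
        reference_sample=cfg.reference_sample,
        k=cfg.k,
        terminal_exclusion=cfg.terminal_exclusion,
    )

    sizes = pd.DataFrame(
        [
            ("FAD3A_like", *cl.expected_race_product_sizes(cfg.ir_length, 200, 81)),
            ("FAD3C_like", *cl.expected_race_product_sizes(cfg.ir_length, 100, 43)),
        ],
        columns=["transcript", "min_product", "max_product"],
    )

    tally_df.to_csv(out / "cleavage_tally.tsv", sep="\t", index=False)
    candidates.to_csv(out / "candidate_sirnas.tsv", sep="\t", index=False)
    sizes.to_csv(out / "race_product_sizes.tsv", sep="\t", index=False)
    return {"cleavage_tally": tally_df, "candidate_sirnas": candidates, "race_product_sizes": sizes}


def run_methylation(scenario: Scenario, outdir: str | Path) -> dict[str, pd.DataFrame]:
    """Per-site and per-context methylation reports for every region/line."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    site_frames = []
    reports = []
    for (region_id, sample), clone_list in scenario.bisulfite_clones.items():
        ref = scenario.bisulfite_regions[region_id]
        report = meth.call_methylation(clone_list, ref, region_id=region_id)
        df = report.to_frame()
        df.insert(0, "line", sample)
        site_frames.append(df)
        reports.append((sample, region_id, report))
    sites = pd.concat(site_frames, ignore_index=True)
    contexts = meth.compare_regions(reports)
    sites.to_csv(out / "methylation_sites.tsv", sep="\t", index=False, float_format="%.4g")
    contexts.to_csv(out / "methylation_contexts.tsv", sep="\t", index=False, float_format="%.4g")
    return {"methylation_sites": sites, "methylation_contexts": contexts}


def load_scenario(indir: str | Path) -> Scenario:
    """Rehydrate a scenario from a directory written by write_scenario."""
    ind = Path(indir)
    for required in ("construct.fasta", "elements.tsv", "transcripts.fasta", "genome.fasta"):
        if not (ind / required).exists():
            raise FileNotFoundError(str(ind / required))
    cfg = (
        ScenarioConfig.from_yaml(ind / "scenario.yaml")
        if (ind / "scenario.yaml").exists()
        else ScenarioConfig()
    )
    construct = load_construct(ind / "construct.fasta", ind / "elements.tsv")
    transcripts = load_transcripts(ind / "transcripts.fasta")
    genome = {r.id: str(r.seq) for r in SeqIO.parse(str(ind / "genome.fasta"), "fasta")}
    libraries = {}
    for fq in sorted(ind.glob("reads_*.fastq")):
        sample = fq.stem[len("reads_"):]
        reads = [(r.id, str(r.seq)) for r in SeqIO.parse(str(fq), "fastq")]
        truth_path = ind / f"truth_{sample}.tsv"
        truth = pd.read_csv(truth_path, sep="\t") if truth_path.exists() else pd.DataFrame()
        libraries[sample] = sim.SimulatedLibrary(sample, reads, truth, {})
    race_path = ind / "race_clones.tsv"
    race = pd.read_csv(race_path, sep="\t") if race_path.exists() else pd.DataFrame(
        columns=["sample", "transcript", "cut_i", "cut_j"]
    )
    regions = {}
    clones: dict[tuple[str, str], list[str]] = {}
    bis = ind / "bisulfite"
    if bis.exists():
        for fa in sorted(bis.glob("*_reference.fasta")):
            rec = next(SeqIO.parse(str(fa), "fasta"))
            regions[rec.id] = str(rec.seq)
        for fa in sorted(bis.glob("*_clones.fasta")):
            stem_name = fa.stem[: -len("_clones")]
            for region_id in regions:
                if stem_name.startswith(region_id + "_"):
                    sample = stem_name[len(region_id) + 1 :]
                    clones[(region_id, sample)] = [
                        str(r.seq) for r in SeqIO.parse(str(fa), "fasta")
                    ]
    return Scenario(
        config=cfg,
        construct=construct,
        transcripts=transcripts,
        genome=genome,
        libraries=libraries,
        race_clones=race,
        bisulfite_regions=regions,
        bisulfite_clones=clones,
    )
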