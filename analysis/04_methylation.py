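#!/usr/bin/env python
"""Quantify per-context methylation across transgene and endogenous regions.

Calls methylation from the simulated bisulfite clone sets for six regions
(four on the transgene T-DNA, two on the endogenous stand-in locus) in all
four lines, and writes per-site and per-context tables to
results/methylation/. Prints the per-context percentages next to the
planted probabilities.
"""

from pathlib import Path

from hpsirna.scenario import (
    ENDOGENOUS_METHYLATION,
    TRANSGENE_METHYLATION,
    ScenarioConfig,
    build_scenario,
    run_methylation,
)

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "methylation"


def main() -> None:
    cfg = ScenarioConfig(seed=1)
    scenario = build_scenario(cfg)
    results = run_methylation(scenario, OUT)

    ctx = results["methylation_contexts"]
    print(f"wrote {len(results)} reports to {OUT}")
    for line, grp in ctx[ctx.region == "I_promoter"].groupby("line"):
        planted = TRANSGENE_METHYLATION[line]
        rendered = ", ".join(
            f"{r.context} {r.percent:.1f}% (planted {100*planted[r.context]:.0f}%)"
            for r in grp.itertuples()
        )
        print(f"  transgene promoter, {line}: {rendered}")
    v = ctx[(ctx.region == "V_glycinin_promoter") & (ctx.line == "S-24-15")]
    print(
        "  endogenous promoter, S-24-15: "
        + ", ".join(f"{r.context} {r.percent:.1f}%" for r in v.itertuples())
        + f" (planted {100*ENDOGENOUS_METHYLATION['S-24-15']['CGN']:.0f}% in all contexts)"
    )


if __name__ == "__main__":
    main()
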