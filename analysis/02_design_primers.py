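#!/usr/bin/env python
"""Screen the simulated genomes for mtDNA-unique regions and design primer pairs.

Regions containing the planted NUMTs must be excluded by the screen; the
surviving regions receive ranked 25-30 bp primer pairs with hydrolysis probes,
each checked for nuclear cross-reactivity. Outputs results/design/.
"""
from pathlib import Path

from mitosignal import pipeline

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    sim = ROOT / "simulate"
    if not (sim / "mito.fa").exists():
        raise SystemExit("run analysis/01_simulate_inputs.py first")
    report = pipeline.design(sim / "mito.fa", sim / "nuclear.fa", ROOT / "design")
    print(f"designed {len(report)} primer pairs across {report['region'].nunique()} unique regions")
    if len(report):
        best = report.iloc[0]
        print(f"top pair ({best.region}): {best.forward_seq} / {best.reverse_seq}")
        print(f"  amplicon {best.amplicon_length} bp, Tm {best.tm_forward}/{best.tm_reverse} C, "
              f"penalty {best.penalty}")
        print(f"  best nuclear identity fwd/rev: {best.fwd_best_nuclear_identity}/"
              f"{best.rev_best_nuclear_identity}")
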