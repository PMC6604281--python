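#!/usr/bin/env python
"""Case/control circuit-activity comparison on a planted-shift cohort.

Simulates 20 controls and 20 cases with a -0.3 expression shift planted on
the genes exclusive to the REV3L circuit, estimates circuit activities with
the propagation model, and runs the rank-sum differential report.  The
planted circuit should come out DOWN with the smallest FDR-adjusted p-value.
Writes results/differential_report.tsv.
"""

from pathlib import Path

from circuitdrug import differential as dm
from circuitdrug import knowledge_base as kb
from circuitdrug import mechanistic as mech
from circuitdrug import synthetic as syn

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260929


def main() -> None:
    OUT.mkdir(exist_ok=True)
    graph = kb.load_pathway()
    expr, labels, truth = syn.simulate_case_control(
        n_per_group=20, graph=graph, shifted_circuits=("REV3L",),
        shift=-0.3, seed=SEED,
    )
    cam = mech.circuit_activities(expr, graph)
    report = dm.differential_report(cam, labels, case_level="case")
    print(f"planted: {truth.shifted_circuits} shifted by {truth.shift}")
    print(report.table.to_string(float_format=lambda v: f"{v:.3g}"))
    top = report.table["fdr_adjusted"].idxmin()
    print(f"\nsmallest FDR: {top} "
          f"({'recovered' if top == 'REV3L' else 'NOT the planted circuit'})")
    dm.write_report_tsv(report, OUT / "differential_report.tsv")
    print(f"wrote {OUT / 'differential_report.tsv'}")


if __name__ == "__main__":
    main()
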