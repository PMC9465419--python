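"""Classify samples with the packaged 92-pair lung NE subtyping panel.

Builds three archetype expression profiles over the panel's 184 genes — one
following each branch of the decision tree — classifies them, and prints the
per-step vote trail.  Because only within-sample orderings matter, the
absolute values are arbitrary; only which gene of each pair is higher counts.
"""

import pandas as pd

from nesubtype import ExpressionMatrix, classify_matrix, load_builtin_panel, results_to_frame

panel = load_builtin_panel()

# For a "GT" step, every pair's gene_a is put above its gene_b; for "LE",
# below.  Routing: NE negative -> non-NE; NE+, CARCI+ -> CARCI;
# NE+, CARCI-, SCLC+ -> SCLC.
routes = {"biopsy_A": ["LE"], "biopsy_B": ["GT", "GT"], "biopsy_C": ["GT", "LE", "GT"]}
values = {}
for sample, route in routes.items():
    col = {}
    for i, step in enumerate(panel.steps):
        gt = i < len(route) and route[i] == "GT"
        for pair in step.signature.pairs:
            col[pair.gene_a] = 2.0 if gt else 1.0
            col[pair.gene_b] = 1.5
    values[sample] = col

matrix = ExpressionMatrix(pd.DataFrame(values))
results = classify_matrix(matrix, panel)
print(results_to_frame(results).to_string(index=False))
print()
for r in results:
    steps = " -> ".join(
        f"{s.signature_name} {s.votes_for}/{s.n_evaluable}" for s in r.step_results
    )
    print(f"{r.sample_id}: {steps} => {r.final_label}")
# Each line shows, per evaluated signature, how many of its evaluable gene
# pairs voted for the positive class; a strict majority advances the sample
# down that branch until a terminal subtype label is reached.
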