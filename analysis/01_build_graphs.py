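#!/usr/bin/env python
"""Build and validate the three cancer state graphs (plus the male HPV
companion model) and export them for inspection.

Writes DOT and structured-text (YAML) serializations under results/graphs/.
"""

from pathlib import Path

import yaml

from gcea.states import (
    build_breast_graph,
    build_cervical_graph,
    build_colorectal_graph,
    build_male_hpv_graph,
    validate_graph,
)

OUT = Path("results/graphs")
OUT.mkdir(parents=True, exist_ok=True)

graphs = {
    "cervical_female": build_cervical_graph(),
    "cervical_male": build_male_hpv_graph(),
    "breast": build_breast_graph(),
    "colorectal": build_colorectal_graph(),
}

for name, g in graphs.items():
    violations = validate_graph(g)
    status = "OK" if not violations else f"INVALID: {violations}"
    n_edges = len(g.edges)
    print(f"{name:16s} {len(g.states):3d} states {n_edges:3d} edges  {status}")
    (OUT / f"{name}.dot").write_text(g.to_dot())
    (OUT / f"{name}.yaml").write_text(yaml.safe_dump(g.to_dict(), sort_keys=False))

print(f"\nwrote DOT + YAML for {len(graphs)} graphs to {OUT}/")
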