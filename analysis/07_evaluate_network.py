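"""Evaluate the structure of the assembled ecological network.

Computes alpha (closure), beta (node connection rate), gamma (connectivity)
and the cost ratio for the standard subnetwork pairings, and reproduces the
published desk-scale rows from their printed corridor/node counts as a
cross-check of the evaluator.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import json

import pandas as pd

from econetkit.network_eval import evaluate, round2

from common import RESULTS


def main():
    corridors = pd.read_csv(RESULTS / "corridors.csv")
    nodes = json.loads((RESULTS / "nodes.geojson").read_text())
    node_type = [f["properties"]["node_type"] for f in nodes["features"]]
    n_type = {t: node_type.count(t) for t in ("strategic", "natural", "artificial")}

    lvl1 = corridors[corridors.level == 1]
    lvl23 = corridors[corridors.level.isin([2, 3])]
    rows = [
        ("level-1 corridors + strategic nodes", lvl1, n_type["strategic"]),
        ("level-2,3 corridors + natural nodes", lvl23, n_type["natural"]),
        ("level-2,3 corridors + artificial nodes", lvl23, n_type["artificial"]),
        ("whole network", corridors, len(node_type)),
    ]
    records = []
    for label, sub, v in rows:
        if v < 1 or len(sub) == 0:
            records.append({"subnetwork": label, "L": len(sub), "V": v})
            continue
        m = evaluate(len(sub), v, sub["length_km"].tolist(), label)
        records.append(m.rounded())
    table = pd.DataFrame(records)
    table.to_csv(RESULTS / "network_metrics.csv", index=False)
    print(table.to_string(index=False))

    print("\ncross-check against published subnetwork counts:")
    for label, (L, V) in {"L=10,V=10": (10, 10), "L=48,V=27": (48, 27),
                          "L=48,V=33": (48, 33)}.items():
        m = evaluate(L, V)
        print(f"  {label}: alpha {round2(m.alpha)}, beta {round2(m.beta)}, "
              f"gamma {round2(m.gamma)}")


if __name__ == "__main__":
    main()
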