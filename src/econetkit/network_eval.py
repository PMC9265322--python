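"""Structural indices of the corridor-node network.

For a subnetwork with ``L`` corridors (links), ``V`` nodes and total corridor
length ``C`` (km):

* closure        ``alpha = (L - V + 1) / (2V - 5)``   (defined for V >= 3)
* node connection ``beta = L / V``
* connectivity   ``gamma = L / (3 (V - 2))``          (defined for V >= 3)
* cost ratio     ``1 - L / C``

``C`` is the summed length of the subnetwork's corridors; this total-length
reading is the one consistent with reported cost ratios at network scale.
Reports round half-up to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .corridors import CorridorSet
from .hydronodes import EcoNode

__all__ = ["NetworkMetrics", "evaluate", "subnetworks", "evaluate_network",
           "round2"]


def round2(x: float) -> float:
    """Round half-up to 2 decimals (report convention)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return float("nan")
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class NetworkMetrics:
    """Index values for one (corridor set, node set) pairing."""

    label: str
    n_links: int
    n_nodes: int
    total_length_km: float
    alpha: float
    beta: float
    gamma: float
    cost_ratio: float

    def rounded(self) -> dict:
        return {
            "subnetwork": self.label,
            "L": self.n_links,
            "V": self.n_nodes,
            "total_length": round2(self.total_length_km),
            "alpha": round2(self.alpha),
            "beta": round2(self.beta),
            "gamma": round2(self.gamma),
            "cost_ratio": round2(self.cost_ratio),
        }


def evaluate(n_links: int, n_nodes: int, lengths_km: list[float] | None = None,
             label: str = "") -> NetworkMetrics:
    """Compute alpha/beta/gamma and cost ratio from link/node counts and lengths.

    ``alpha`` and ``gamma`` are NaN for fewer than 3 nodes; the cost ratio is
    NaN without lengths.
    """
    if n_nodes < 1:
        raise ValueError("a network needs at least one node")
    nan = float("nan")
    alpha = (n_links - n_nodes + 1) / (2 * n_nodes - 5) if n_nodes >= 3 else nan
    beta = n_links / n_nodes
    gamma = n_links / (3 * (n_nodes - 2)) if n_nodes >= 3 else nan
    total = float(sum(lengths_km)) if lengths_km else 0.0
    cost_ratio = 1.0 - n_links / total if total > 0 else nan
    return NetworkMetrics(label, n_links, n_nodes, total, alpha, beta, gamma,
                          cost_ratio)


def subnetworks(corridor_set: CorridorSet, nodes: list[EcoNode]
                ) -> list[tuple[str, int, int, list[float]]]:
    """The three standard pairings plus the whole network.

    (level-1 corridors, strategic nodes); (level-2&3 corridors, natural
    nodes); (level-2&3 corridors, artificial nodes); (all corridors, all
    nodes).  Returns (label, L, V, lengths_km) rows.
    """
    by_type = {t: [n for n in nodes if n.node_type == t]
               for t in ("strategic", "natural", "artificial")}
    lvl1 = corridor_set.by_level(1)
    lvl23 = corridor_set.by_level(2, 3)
    rows = [
        ("level-1 corridors + strategic nodes",
         len(lvl1), len(by_type["strategic"]), [c[0].length_km for c in lvl1]),
        ("level-2,3 corridors + natural nodes",
         len(lvl23), len(by_type["natural"]), [c[0].length_km for c in lvl23]),
        ("level-2,3 corridors + artificial nodes",
         len(lvl23), len(by_type["artificial"]), [c[0].length_km for c in lvl23]),
        ("whole network",
         len(corridor_set.corridors), len(nodes),
         [c[0].length_km for c in corridor_set.corridors]),
    ]
    return rows


def evaluate_network(corridor_set: CorridorSet, nodes: list[EcoNode]) -> pd.DataFrame:
    """Metrics table over the standard subnetwork pairings (rounded report)."""
    records = []
    for label, n_links, n_nodes, lengths in subnetworks(corridor_set, nodes):
        if n_nodes == 0:
            records.append({"subnetwork": label, "L": n_links, "V": 0,
                            "total_length": round2(sum(lengths)),
                            "alpha": float("nan"), "beta": float("nan"),
                            "gamma": float("nan"), "cost_ratio": float("nan")})
            continue
        records.append(evaluate(n_links, n_nodes, lengths, label).rounded())
    return pd.DataFrame(records, columns=["subnetwork", "L", "V", "total_length",
                                          "alpha", "beta", "gamma", "cost_ratio"])
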