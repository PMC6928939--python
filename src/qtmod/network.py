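"""Anchor-partner interaction network and degree-based SNP selection.

The kept interaction edges form a bipartite network between a module's
main-effect (anchor) SNPs and the genome-wide partner SNPs. A partner's
degree is the number of distinct anchors it interacts with; the
partners of highest degree are the module's interactive-effect SNPs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["InteractionNetwork", "build_network", "select_interactive"]


@dataclass
class InteractionNetwork:
    """Bipartite anchor/partner edge set with per-partner degrees.

    ``edges`` has columns ``anchor, partner, p``; ``degree`` maps each
    partner to its count of distinct anchors. Degrees never exceed the
    anchor count.
    """

    edges: pd.DataFrame
    degree: pd.Series = field(default_factory=lambda: pd.Series(dtype=int))

    @property
    def anchors(self) -> list[str]:
        return sorted(self.edges["anchor"].unique())

    @property
    def partners(self) -> list[str]:
        return sorted(self.edges["partner"].unique())


def build_network(edges: pd.DataFrame) -> InteractionNetwork:
    """Assemble the network from a kept-edge table.

    ``edges`` needs columns ``anchor, partner, p``; duplicate unordered
    pairs are collapsed to their smallest p. Self-edges are a
    consistency error.
    """
    for col in ("anchor", "partner", "p"):
        if col not in edges.columns:
            raise ValueError(f"edge table missing column {col!r}")
    if (edges["anchor"] == edges["partner"]).any():
        raise ValueError("self-interaction edge (anchor == partner)")
    dedup = (
        edges.groupby(["anchor", "partner"], as_index=False)["p"]
        .min()
        .sort_values(["partner", "anchor"], kind="mergesort")
        .reset_index(drop=True)
    )
    degree = (
        dedup.groupby("partner")["anchor"].nunique().astype(int).sort_index()
    )
    return InteractionNetwork(edges=dedup, degree=degree)


def select_interactive(net: InteractionNetwork, k: int = 3) -> pd.DataFrame:
    """Rank partners by degree and return the top k (interactive-effect SNPs).

    Ties on degree break by the partner's smallest edge p, then by
    lexicographic id — invariant to edge-list input order. Returns
    columns ``partner, degree, min_p, anchors``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(net.edges) == 0:
        warnings.warn("interaction network is empty; nothing to select", stacklevel=2)
        return pd.DataFrame(columns=["partner", "degree", "min_p", "anchors"])
    summary = (
        net.edges.groupby("partner")
        .agg(
            degree=("anchor", "nunique"),
            min_p=("p", "min"),
            anchors=("anchor", lambda s: ",".join(sorted(s))),
        )
        .reset_index()
    )
    summary = summary.sort_values(
        ["degree", "min_p", "partner"],
        ascending=[False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return summary.head(k)
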