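"""Temporal consensus over per-sample directed lineage graphs.

Velocity-style analyses export, per sample, a directed cell-type graph. The
consensus keeps the most prevalent connections across samples and vetoes any
direction that contradicts the order of first appearance along the time
series: a proposed progenitor must be observed earlier than, or
simultaneously with, its derivative. Surviving edges are classed strong or
weak by the fraction of samples supporting them.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .simulate import SampleGraph

__all__ = [
    "SampleGraph",
    "first_appearance",
    "ConsensusEdge",
    "ConsensusGraph",
    "build_consensus",
]


def first_appearance(labels: pd.DataFrame, min_cells: int = 10,
                     type_col: str = "cell_type",
                     time_col: str = "timepoint") -> dict[str, object]:
    """Earliest timepoint at which each type has at least ``min_cells`` cells.

    ``labels`` holds one row per cell with a type and a (totally ordered)
    timepoint column. Types that never reach ``min_cells`` at any single
    timepoint are absent from the table.
    """
    if len(labels) == 0:
        raise ValueError("empty label set")
    if min_cells < 1:
        raise ValueError("min_cells must be >= 1")
    counts = (labels.groupby([type_col, time_col], observed=True)
              .size().rename("n").reset_index())
    present = counts[counts["n"] >= min_cells]
    out: dict[str, object] = {}
    for cell_type, sub in present.groupby(type_col, observed=True):
        out[str(cell_type)] = sub[time_col].min()
    return out


@dataclass(frozen=True)
class ConsensusEdge:
    source: str
    target: str
    prevalence: int
    n_samples: int
    klass: str  # "strong" | "weak"


@dataclass
class ConsensusGraph:
    edges: list[ConsensusEdge]
    n_samples: int
    strong_fraction: float
    min_prevalence: int
    dropped: list[dict] = field(default_factory=list)  # reasoned rejections

    @property
    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.source, e.target) for e in self.edges}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"source": e.source, "target": e.target,
                 "prevalence": e.prevalence, "n_samples": e.n_samples,
                 "class": e.klass}
                for e in self.edges
            ],
            columns=["source", "target", "prevalence", "n_samples", "class"],
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for e in self.edges:
            g.add_edge(e.source, e.target, prevalence=e.prevalence,
                       klass=e.klass)
        return g

    def to_dot(self) -> str:
        """DOT rendering; weak links are dashed (discontinuous) lines."""
        lines = ["digraph consensus {"]
        for e in self.edges:
            style = "solid" if e.klass == "strong" else "dashed"
            lines.append(
                f'  "{e.source}" -> "{e.target}" '
                f'[style={style}, label="{e.prevalence}/{e.n_samples}"];'
            )
        lines.append("}")
        return "\n".join(lines)


def build_consensus(samples: list[SampleGraph], appearance: dict[str, object],
                    strong_fraction: float = 0.5,
                    min_prevalence: int = 2) -> ConsensusGraph:
    """Aggregate per-sample graphs into a temporally sound consensus.

    Rules, applied in order:

    1. edges naming a type without an appearance time are dropped (logged);
    2. prevalence = number of samples containing the directed edge;
    3. a direction whose source first appears *after* its target contradicts
       the time series and is not considered;
    4. edges below ``min_prevalence`` are dropped;
    5. if both directions of a pair survive (possible only when the two
       types appear simultaneously), the more prevalent wins; an exact tie
       drops both, with a logged reason;
    6. surviving edges are strong when ``prevalence / n_samples >=
       strong_fraction``, else weak.

    Simultaneous appearance of source and target is allowed.
    """
    if not samples:
        raise ValueError("at least one sample graph is required")
    if not 0.0 <= strong_fraction <= 1.0:
        raise ValueError("strong_fraction must lie in [0, 1]")
    if min_prevalence < 1:
        raise ValueError("min_prevalence must be >= 1")

    n_samples = len(samples)
    dropped: list[dict] = []
    prevalence: Counter = Counter()
    for sample in samples:
        for src, tgt in set(map(tuple, sample.edges)):  # per-sample presence
            if src == tgt:
                dropped.append({"edge": (src, tgt), "sample": sample.sample_id,
                                "reason": "self_loop"})
                continue
            if src not in appearance or tgt not in appearance:
                dropped.append({"edge": (src, tgt), "sample": sample.sample_id,
                                "reason": "unknown_type"})
                continue
            prevalence[(src, tgt)] += 1

    surviving: dict[tuple[str, str], int] = {}
    for (src, tgt), count in sorted(prevalence.items()):
        if appearance[src] > appearance[tgt]:
            dropped.append({"edge": (src, tgt), "prevalence": count,
                            "reason": "temporal_contradiction"})
            continue
        if count < min_prevalence:
            dropped.append({"edge": (src, tgt), "prevalence": count,
                            "reason": "below_min_prevalence"})
            continue
        surviving[(src, tgt)] = count

    edges: list[ConsensusEdge] = []
    for (src, tgt), count in sorted(surviving.items()):
        rev = surviving.get((tgt, src))
        if rev is not None:
            if rev > count:
                dropped.append({"edge": (src, tgt), "prevalence": count,
                                "reason": "outvoted_by_reverse"})
                continue
            if rev == count:
                if (src, tgt) < (tgt, src):  # report the tie once
                    dropped.append({"edge": (src, tgt), "prevalence": count,
                                    "reason": "direction_tie_both_dropped"})
                continue
        klass = "strong" if count / n_samples >= strong_fraction else "weak"
        edges.append(ConsensusEdge(src, tgt, count, n_samples, klass))

    return ConsensusGraph(edges=edges, n_samples=n_samples,
                          strong_fraction=strong_fraction,
                          min_prevalence=min_prevalence, dropped=dropped)
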