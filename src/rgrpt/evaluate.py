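"""Scoring predictions against simulation truth logs.

A prediction is counted correct when it can be paired one-to-one with a
true event on the same edge, of the same type (fusion and fission are
pooled, as their direction depends on which endpoint is taken as
ancestral), whose created-adjacency sets intersect in canonical form.
The created-set overlap criterion tolerates differences between
equivalent index descriptions of one event while still tying the
prediction to the specific breakpoints of the true event; a ``strict``
variant requires the created sets to be equal.  Pairing is maximum
bipartite matching per edge, so two predictions cannot both claim one
true event and the counted number of correct events is well defined.

Sensitivity is correct / true events, specificity correct / predicted
events; a metric with a zero denominator is reported as absent rather
than zero.

The benchmark drivers reproduce the two simulation studies: the
reversal-only study (leaf counts 3..10, 11 datasets each) and the
mixed-event study (mu in {6, 12, 18, 24}, 10 replicates each), scoring
both the capped predictor (rgrpt) and the uncapped baseline (emrae) on
identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import networkx as nx
import pandas as pd

from .genome import Event
from .inference import Prediction, infer_all
from .simulate import (
    SimDataset,
    TruthLog,
    protocol_all_events,
    protocol_reversal_only,
)

# fusion and fission are indistinguishable without knowing which side is
# ancestral, and the source tables pool them
_CATEGORY = {
    "reversal": "reversal",
    "translocation": "translocation",
    "transposition": "transposition",
    "fusion": "fusion/fission",
    "fission": "fusion/fission",
}
CATEGORIES = ("reversal", "translocation", "transposition", "fusion/fission")


@dataclass(frozen=True)
class EvalResult:
    n_true: int
    n_predicted: int
    n_correct: int
    per_type: dict

    @property
    def sensitivity(self) -> Optional[float]:
        return self.n_correct / self.n_true if self.n_true else None

    @property
    def specificity(self) -> Optional[float]:
        return self.n_correct / self.n_predicted if self.n_predicted else None


def _compatible(pred: Event, true: Event, strict: bool) -> bool:
    if _CATEGORY[pred.etype] != _CATEGORY[true.etype]:
        return False
    if strict:
        return pred.created == true.created
    return bool(pred.created & true.created)


def match_events(
    predicted: dict[int, list[Prediction]],
    truth: TruthLog,
    strict: bool = False,
) -> list[tuple[int, int, int]]:
    """Maximum one-to-one pairing of predictions with true events.

    Returns (edge_id, prediction index, truth index) triples.  Only
    events on the same edge may pair.
    """
    out: list[tuple[int, int, int]] = []
    for edge_id in sorted(set(predicted) | set(truth.events)):
        preds = predicted.get(edge_id, [])
        trues = truth.events.get(edge_id, [])
        if not preds or not trues:
            continue
        g = nx.Graph()
        top = [("p", i) for i in range(len(preds))]
        g.add_nodes_from(top)
        g.add_nodes_from(("t", j) for j in range(len(trues)))
        for i, pr in enumerate(preds):
            for j, tr in enumerate(trues):
                if _compatible(pr.event, tr, strict):
                    g.add_edge(("p", i), ("t", j))
        matching = nx.bipartite.maximum_matching(g, top_nodes=top)
        for i in range(len(preds)):
            partner = matching.get(("p", i))
            if partner is not None:
                out.append((edge_id, i, partner[1]))
    return out


def score(
    predicted: dict[int, list[Prediction]],
    truth: TruthLog,
    strict: bool = False,
) -> EvalResult:
    """Sensitivity/specificity of a prediction set against a truth log."""
    matches = match_events(predicted, truth, strict)
    n_pred = sum(len(v) for v in predicted.values())
    per_type = {
        c: {"true": 0, "predicted": 0, "correct": 0} for c in CATEGORIES
    }
    for ev in truth.all_events():
        per_type[_CATEGORY[ev.etype]]["true"] += 1
    for preds in predicted.values():
        for pr in preds:
            per_type[_CATEGORY[pr.event.etype]]["predicted"] += 1
    for edge_id, i, _ in matches:
        per_type[_CATEGORY[predicted[edge_id][i].event.etype]]["correct"] += 1
    return EvalResult(
        n_true=truth.n_events,
        n_predicted=n_pred,
        n_correct=len(matches),
        per_type=per_type,
    )


def score_dataset(ds: SimDataset, method: str, strict: bool = False) -> EvalResult:
    return score(infer_all(ds.tree, method), ds.truth, strict)


def _mean(values: Iterable[Optional[float]]) -> Optional[float]:
    vals = [v for v in values if v is not None]
    return sum(vals) / len(vals) if vals else None


def benchmark_reversal_only(
    seed: int, leaf_counts: Iterable[int] = range(3, 11)
) -> pd.DataFrame:
    """Reversal-only study: per-leaf-count means over 11 datasets for
    both methods, plus a grand-mean row."""
    rows = []
    for n in leaf_counts:
        datasets = protocol_reversal_only(n, seed=seed + n)
        row = {"leaves": n, "events": _mean([float(d.truth.n_events) for d in datasets])}
        for method in ("emrae", "rgrpt"):
            results = [score_dataset(d, method) for d in datasets]
            row[f"sens_{method}"] = _mean([r.sensitivity for r in results])
            row[f"spec_{method}"] = _mean([r.specificity for r in results])
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = {"leaves": "mean", "events": df["events"].mean()}
    for col in df.columns[2:]:
        mean_row[col] = df[col].mean()
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def benchmark_all_events(
    seed: int, mus: Iterable[int] = (6, 12, 18, 24), n_replicates: int = 10
) -> pd.DataFrame:
    """Mixed-event study: per-mu means over replicates for both
    methods, plus a grand-mean row."""
    rows = []
    for mu in mus:
        datasets = protocol_all_events(mu, seed=seed + mu, n_replicates=n_replicates)
        row = {"mu": mu, "events": _mean([float(d.truth.n_events) for d in datasets])}
        for method in ("emrae", "rgrpt"):
            results = [score_dataset(d, method) for d in datasets]
            row[f"sens_{method}"] = _mean([r.sensitivity for r in results])
            row[f"spec_{method}"] = _mean([r.specificity for r in results])
        rows.append(row)
    df = pd.DataFrame(rows)
    mean_row = {"mu": "mean", "events": df["events"].mean()}
    for col in df.columns[2:]:
        mean_row[col] = df[col].mean()
    return pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)


def prediction_count_table(tree, preds_by_method: dict[str, dict[int, list[Prediction]]]) -> pd.DataFrame:
    """Per-edge, per-category prediction counts (the layout of the
    mammalian result tables), one column block per method."""
    rows = []
    for edge in tree.edges:
        row: dict = {"edge": tree.label(edge.child)}
        for method, preds in preds_by_method.items():
            counts = {c: 0 for c in CATEGORIES}
            for pr in preds.get(edge.id, []):
                counts[_CATEGORY[pr.event.etype]] += 1
            for c in CATEGORIES:
                row[f"{c}_{method}"] = counts[c]
            row[f"total_{method}"] = sum(counts.values())
        rows.append(row)
    df = pd.DataFrame(rows)
    total = {"edge": "total"}
    for col in df.columns[1:]:
        total[col] = df[col].sum()
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True)


def benchmark_mammals(data_dir, resolution: str) -> pd.DataFrame:
    """Run both methods on a locally deposited mammalian synteny-block
    dataset.

    Expects ``<data_dir>/genomes_<resolution>.txt`` (GRIMM block orders
    for the six species) and ``<data_dir>/tree.nwk`` (their phylogeny,
    leaf names matching the genome names).  Returns the per-edge count
    table for both methods.
    """
    from pathlib import Path

    from .grimm import read_genomes
    from .tree import parse_newick

    data_dir = Path(data_dir)
    genome_file = data_dir / f"genomes_{resolution}.txt"
    tree_file = data_dir / "tree.nwk"
    if not genome_file.is_file() or not tree_file.is_file():
        raise FileNotFoundError(
            f"expected {genome_file} (GRIMM block orders) and {tree_file} "
            "(newick phylogeny); the deposited dataset must be converted "
            "to this layout first"
        )
    tree = parse_newick(tree_file.read_text())
    tree.bind_genomes(read_genomes(genome_file))
    preds = {m: infer_all(tree, m) for m in ("emrae", "rgrpt")}
    return prediction_count_table(tree, preds)
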