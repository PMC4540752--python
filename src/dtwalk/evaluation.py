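"""Link-perturbation benchmarking and early-recognition metrics.

The central question is: if a true drug-target link is hidden from the
network, how highly does the walk rank the hidden target among all
candidates for that drug?  Two perturbation protocols generate
:class:`RemovalRecord` collections:

* *single link per drug* — every drug with at least one target loses one
  uniformly chosen link (drugs with a single target are included, testing
  recovery with the drug node as the only seed);
* *fixed count* — a batch of links is removed simultaneously from drugs
  above a degree floor, repeated over resamplings to yield an average
  recovered fraction.

After each removal the shared-neighbor similarities are recomputed from
the perturbed incidence, so the hidden link cannot leak back in through
the topology layers.  Records are pooled and summarized by recovered
fraction at top-N, AUAC, AUC, partial AUC on the top decile, BEDROC and
the enrichment factor, plus two baselines: a degree-preserving
randomized network and a pure sequence-similarity ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .hetnet import HetNet, InteractionTable, rebuild_with_interactions
from .rwr import RankedPrediction, WalkParams, predict_targets
from .similarity import SimilarityLayer

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PerturbationPlan:
    """Configuration of the fixed-count removal protocol."""

    n_remove: int
    repeats: int = 50
    min_degree: int = 3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_remove < 1:
            raise ValueError("n_remove must be >= 1")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.min_degree < 1:
            raise ValueError("min_degree must be >= 1")


@dataclass(frozen=True)
class RemovalRecord:
    """Outcome of one hidden link: the rank its target achieved."""

    drug: str
    target: str
    rank: int
    n_candidates: int

    def __post_init__(self) -> None:
        if not 1 <= self.rank <= self.n_candidates:
            raise ValueError(
                f"rank {self.rank} outside [1, {self.n_candidates}]"
            )


@dataclass(frozen=True)
class MetricsReport:
    """Pooled ranking metrics over a collection of removal records."""

    n_records: int
    recovered: dict[int, float]  # top-N -> fraction
    auac: float
    auc: float
    auc_top: float
    auc_top_fraction: float
    bedroc: float
    bedroc_alpha: float
    ef: float
    ef_fraction: float

    def as_dict(self) -> dict[str, float]:
        out: dict[str, float] = {"n_records": float(self.n_records)}
        for n, frac in sorted(self.recovered.items()):
            out[f"recovered_top{n}"] = frac
        out.update(
            auac=self.auac,
            auc=self.auc,
            auc_top=self.auc_top,
            bedroc=self.bedroc,
            ef=self.ef,
        )
        return out


# ---------------------------------------------------------------------------
# perturbation protocols
# ---------------------------------------------------------------------------


def _record_for_link(
    net: HetNet, drug: str, target: str, params: WalkParams
) -> RemovalRecord:
    """Rank the (absent) link's target among the drug's candidates."""
    pred = predict_targets(net, drug, params)
    return RemovalRecord(
        drug=drug,
        target=target,
        rank=pred.rank_of(target),
        n_candidates=pred.n_candidates,
    )


def single_link_removal(
    net: HetNet, params: WalkParams, rng_seed: int = 0
) -> list[RemovalRecord]:
    """Remove one link per drug and record the hidden target's rank.

    Every drug with at least one target loses one uniformly chosen link
    (seeded RNG).  The network — including the shared-neighbor similarity
    layers — is rebuilt without that link before the walk is re-run for
    the affected drug, then the link is restored for the next test.
    """
    rng = np.random.default_rng(rng_seed)
    records: list[RemovalRecord] = []
    for drug in net.drug_ids:
        targets = net.interactions.targets_of(drug)
        if not targets:
            continue
        hidden = targets[rng.integers(len(targets))]
        perturbed = rebuild_with_interactions(
            net, net.interactions.without_links([(drug, hidden)])
        )
        records.append(_record_for_link(perturbed, drug, hidden, params))
    if not records:
        raise ValueError("no drug has any target; nothing to remove")
    return records


def multi_link_removal(
    net: HetNet, params: WalkParams, plan: PerturbationPlan
) -> list[list[RemovalRecord]]:
    """Remove ``n_remove`` links simultaneously, over ``repeats`` resamples.

    Links are drawn uniformly without replacement from drugs whose degree
    meets ``min_degree``; all links of a repeat are absent at once, and
    every hidden target's rank is recorded against the perturbed network.
    Returns one record list per repeat.
    """
    eligible = sorted(
        (d, t)
        for d, t in net.interactions.links
        if net.interactions.drug_degree(d) >= plan.min_degree
    )
    if plan.n_remove > len(eligible):
        raise ValueError(
            f"n_remove={plan.n_remove} exceeds the {len(eligible)} links on "
            f"drugs with degree >= {plan.min_degree}"
        )
    rng = np.random.default_rng(plan.rng_seed)
    all_records: list[list[RemovalRecord]] = []
    for _ in range(plan.repeats):
        idx = rng.choice(len(eligible), size=plan.n_remove, replace=False)
        removed = [eligible[i] for i in sorted(idx)]
        perturbed = rebuild_with_interactions(
            net, net.interactions.without_links(removed)
        )
        records = [
            _record_for_link(perturbed, d, t, params) for d, t in removed
        ]
        all_records.append(records)
    return all_records


def rank_held_out(
    net: HetNet, links: Iterable[tuple[str, str]], params: WalkParams
) -> list[RemovalRecord]:
    """Rank a set of links that are already absent from the network."""
    records = []
    for drug, target in links:
        if (drug, target) in net.interactions.links:
            raise ValueError(f"link {(drug, target)} is present in the network")
        records.append(_record_for_link(net, drug, target, params))
    return records


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------


def recovered_fraction(records: Sequence[RemovalRecord], n: int) -> float:
    """Fraction of hidden links ranked within the top ``n`` positions."""
    if not records:
        raise ValueError("no removal records")
    return sum(1 for r in records if r.rank <= n) / len(records)


def _nondegenerate(records: Sequence[RemovalRecord]) -> list[RemovalRecord]:
    keep = [r for r in records if r.n_candidates > 1]
    if len(keep) < len(records):
        logger.warning(
            "excluding %d record(s) with a single candidate from "
            "rank-normalized metrics",
            len(records) - len(keep),
        )
    if not keep:
        raise ValueError("all records are degenerate (single candidate)")
    return keep


def auc(records: Sequence[RemovalRecord]) -> float:
    """Pooled ROC area: the Mann-Whitney probability that the hidden
    target outranks a random non-hit candidate.

    Per record the hit at rank ``r`` among ``n`` candidates beats
    ``n - r`` of its ``n - 1`` non-hits; the statistic pools every
    hit/non-hit pair across records.  Single-candidate records are
    excluded with a warning.
    """
    keep = _nondegenerate(records)
    wins = sum(r.n_candidates - r.rank for r in keep)
    pairs = sum(r.n_candidates - 1 for r in keep)
    return wins / pairs


def auac(records: Sequence[RemovalRecord]) -> float:
    """Area under the accumulation curve: ``1 - mean(rank / n_candidates)``.

    The accumulation curve plots the cumulative fraction of hidden links
    recovered against the normalized rank position.
    """
    if not records:
        raise ValueError("no removal records")
    return float(1.0 - np.mean([r.rank / r.n_candidates for r in records]))


def auc_top(records: Sequence[RemovalRecord], fraction: float = 0.1) -> float:
    """Partial ROC area over the top ``fraction`` of each list, rescaled
    to [0, 1].

    For a single hit at rank ``r`` of ``n``, the ROC jumps to 1 at false
    positive rate ``(r - 1)/(n - 1)``; the area below the curve on
    ``[0, fraction]`` divided by ``fraction`` is averaged over records.
    A uniformly random ranking scores ``fraction / 2``, not 0.5.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    keep = _nondegenerate(records)
    vals = []
    for r in keep:
        fpr = (r.rank - 1) / (r.n_candidates - 1)
        vals.append(max(0.0, fraction - fpr) / fraction)
    return float(np.mean(vals))


def bedroc(records: Sequence[RemovalRecord], alpha: float = 20.0) -> float:
    """Exponentially weighted early-recognition score in [0, 1].

    The robust initial enhancement RIE averages ``exp(-alpha * x)`` over
    the hits' relative ranks ``x = (rank - 1)/(n - 1)`` and normalizes by
    the uniform expectation ``(1 - e^-alpha)/alpha``; BEDROC rescales RIE
    between its best case (all hits first, = 1) and worst case (all hits
    last, = 0).  Larger ``alpha`` concentrates the weight on the earliest
    part of the list.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    keep = _nondegenerate(records)
    x = np.array([(r.rank - 1) / (r.n_candidates - 1) for r in keep])
    uniform_mean = (1.0 - np.exp(-alpha)) / alpha
    rie = float(np.mean(np.exp(-alpha * x))) / uniform_mean
    rie_max = 1.0 / uniform_mean  # all hits at x = 0
    rie_min = np.exp(-alpha) / uniform_mean  # all hits at x = 1
    return float((rie - rie_min) / (rie_max - rie_min))


def enrichment_factor(
    records: Sequence[RemovalRecord], top_fraction: float = 0.1
) -> float:
    """Hit rate in the top window relative to random selection.

    The fraction of hidden links found within the top ``top_fraction`` of
    their candidate lists, divided by ``top_fraction``; random ranking
    gives 1 in expectation and the maximum is ``1/top_fraction``.
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError("top_fraction must be in (0, 1]")
    if not records:
        raise ValueError("no removal records")
    hits = sum(
        1 for r in records if r.rank <= top_fraction * r.n_candidates
    )
    return hits / len(records) / top_fraction


DEFAULT_TOP_NS = (10, 25, 50, 100)


def compute_metrics(
    records: Sequence[RemovalRecord],
    top_ns: Sequence[int] = DEFAULT_TOP_NS,
    alpha: float = 20.0,
    ef_fraction: float = 0.1,
    auc_top_fraction: float = 0.1,
) -> MetricsReport:
    """Summarize pooled removal records into a :class:`MetricsReport`."""
    return MetricsReport(
        n_records=len(records),
        recovered={n: recovered_fraction(records, n) for n in top_ns},
        auac=auac(records),
        auc=auc(records),
        auc_top=auc_top(records, auc_top_fraction),
        auc_top_fraction=auc_top_fraction,
        bedroc=bedroc(records, alpha),
        bedroc_alpha=alpha,
        ef=enrichment_factor(records, ef_fraction),
        ef_fraction=ef_fraction,
    )


# ---------------------------------------------------------------------------
# baselines
# ---------------------------------------------------------------------------


def _shuffle_links(
    interactions: InteractionTable, rng: np.random.Generator
) -> InteractionTable:
    """Degree-preserving rewiring of the bipartite incidence.

    Repeated pair swaps (d1,t1),(d2,t2) -> (d1,t2),(d2,t1) preserve every
    drug and target degree exactly.
    """
    links = sorted(interactions.links)
    link_set = set(links)
    n = len(links)
    if n < 2:
        return interactions
    for _ in range(10 * n):
        i, j = rng.integers(n), rng.integers(n)
        (d1, t1), (d2, t2) = links[i], links[j]
        if d1 == d2 or t1 == t2:
            continue
        if (d1, t2) in link_set or (d2, t1) in link_set:
            continue
        link_set -= {(d1, t1), (d2, t2)}
        link_set |= {(d1, t2), (d2, t1)}
        links[i], links[j] = (d1, t2), (d2, t1)
    return InteractionTable(
        drug_ids=interactions.drug_ids,
        target_ids=interactions.target_ids,
        links=frozenset(link_set),
    )


def _shuffle_layer(
    layer: SimilarityLayer, rng: np.random.Generator
) -> SimilarityLayer:
    """Permute the off-diagonal entries of a similarity layer symmetrically."""
    n = len(layer)
    vals = layer.values.copy()
    iu = np.triu_indices(n, k=1)
    upper = vals[iu]
    perm = rng.permutation(len(upper))
    vals[iu] = upper[perm]
    vals.T[iu] = vals[iu]
    return SimilarityLayer(ids=layer.ids, values=vals, source="shuffled")


def shuffle_network(net: HetNet, rng_seed: int) -> HetNet:
    """Null-model network: rewired links and shuffled similarity layers.

    The feature layers and blend weights are dropped — the shuffled
    similarity layers are fixed noise, not recomputed from the rewired
    incidence.
    """
    rng = np.random.default_rng(rng_seed)
    return HetNet(
        drug_layer=_shuffle_layer(net.drug_layer, rng),
        target_layer=_shuffle_layer(net.target_layer, rng),
        interactions=_shuffle_links(net.interactions, rng),
    )


def randomized_baseline(
    net: HetNet,
    params: WalkParams,
    rng_seed: int = 0,
    held_out: Iterable[tuple[str, str]] | None = None,
    top_ns: Sequence[int] = DEFAULT_TOP_NS,
    alpha: float = 20.0,
    ef_fraction: float = 0.1,
    auc_top_fraction: float = 0.1,
) -> MetricsReport:
    """Run the full pipeline on a randomized network for comparison.

    Links are rewired degree-preservingly and the similarity layers
    shuffled; then either the given held-out links are ranked on the
    shuffled network, or the single-link-removal protocol is run on it.
    """
    null = shuffle_network(net, rng_seed)
    if held_out is not None:
        held = [
            (d, t)
            for d, t in held_out
            if (d, t) not in null.interactions.links
        ]
        records = rank_held_out(null, held, params)
    else:
        records = single_link_removal(null, params, rng_seed=rng_seed)
    return compute_metrics(records, top_ns, alpha, ef_fraction, auc_top_fraction)


def sequence_baseline(
    net: HetNet, query_drugs: Iterable[str] | None = None
) -> dict[str, RankedPrediction]:
    """Rank candidates by sequence similarity to the drug's known targets.

    Each candidate target scores the maximum target-layer similarity to
    any known target of the query drug; ties break lexicographically as
    in the walk-based ranking.  The sequence-derived layer is used when
    the network retains one, otherwise the blended target layer.  Drugs
    without known targets have no anchor and are skipped with a warning.
    """
    layer = (
        net.target_feature_layer
        if net.target_feature_layer is not None
        else net.target_layer
    )
    layer = layer.reorder(net.target_ids)
    t_index = {t: i for i, t in enumerate(net.target_ids)}
    queries = tuple(query_drugs) if query_drugs is not None else net.drug_ids
    out: dict[str, RankedPrediction] = {}
    for drug in queries:
        known = net.interactions.targets_of(drug)
        if not known:
            logger.warning(
                "sequence baseline skips drug %r: no known targets", drug
            )
            continue
        known_idx = [t_index[t] for t in known]
        scored = [
            (t, float(layer.values[t_index[t], known_idx].max()))
            for t in net.target_ids
            if t not in set(known)
        ]
        scored.sort(key=lambda ts: (-ts[1], ts[0]))
        out[drug] = RankedPrediction(
            query_drug=drug,
            targets=tuple(t for t, _ in scored),
            scores=tuple(s for _, s in scored),
        )
    return out
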