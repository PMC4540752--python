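"""Heterogeneous network assembly and block transition matrix.

The network has three layers: a drug-drug similarity layer ``S_d``, a
target-target similarity layer ``S_t`` and the bipartite drug-target
incidence ``A``.  Nodes carrying at least one interaction link are
*bridge nodes*: a walker standing on one crosses to the other layer with
jumping probability ``lambda_`` and stays within its own layer with
probability ``1 - lambda_``.  Non-bridge nodes walk within their layer
only.  The resulting row-stochastic transition matrix is ordered targets
first, then drugs, matching the partitioned walk vector ``p = [u; v]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .similarity import BlendWeights, SimilarityLayer

logger = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-10


@dataclass(frozen=True)
class InteractionTable:
    """Binary drug x target interaction incidence (the matrix ``A``).

    ``links`` holds (drug_id, target_id) pairs; every pair must reference
    a registered id and duplicates are forbidden.
    """

    drug_ids: tuple[str, ...]
    target_ids: tuple[str, ...]
    links: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_ids", tuple(str(i) for i in self.drug_ids))
        object.__setattr__(
            self, "target_ids", tuple(str(i) for i in self.target_ids)
        )
        links = frozenset((str(d), str(t)) for d, t in self.links)
        object.__setattr__(self, "links", links)
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug ids")
        if len(set(self.target_ids)) != len(self.target_ids):
            raise ValueError("duplicate target ids")
        dset, tset = set(self.drug_ids), set(self.target_ids)
        for d, t in links:
            if d not in dset:
                raise ValueError(f"link references unregistered drug {d!r}")
            if t not in tset:
                raise ValueError(f"link references unregistered target {t!r}")

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_links(self) -> int:
        return len(self.links)

    def matrix(self) -> np.ndarray:
        """Dense 0/1 incidence, shape (n_drugs, n_targets)."""
        didx = {d: i for i, d in enumerate(self.drug_ids)}
        tidx = {t: j for j, t in enumerate(self.target_ids)}
        A = np.zeros((self.n_drugs, self.n_targets), dtype=np.float64)
        for d, t in self.links:
            A[didx[d], tidx[t]] = 1.0
        return A

    def targets_of(self, drug_id: str) -> tuple[str, ...]:
        return tuple(sorted(t for d, t in self.links if d == drug_id))

    def drugs_of(self, target_id: str) -> tuple[str, ...]:
        return tuple(sorted(d for d, t in self.links if t == target_id))

    def drug_degree(self, drug_id: str) -> int:
        return sum(1 for d, _ in self.links if d == drug_id)

    def without_links(
        self, removed: Iterable[tuple[str, str]]
    ) -> "InteractionTable":
        """Copy of the table with the given links removed."""
        removed = {(str(d), str(t)) for d, t in removed}
        missing = removed - self.links
        if missing:
            raise ValueError(f"cannot remove absent links: {sorted(missing)}")
        return InteractionTable(
            drug_ids=self.drug_ids,
            target_ids=self.target_ids,
            links=self.links - removed,
        )

    def with_links(self, added: Iterable[tuple[str, str]]) -> "InteractionTable":
        return InteractionTable(
            drug_ids=self.drug_ids,
            target_ids=self.target_ids,
            links=self.links | {(str(d), str(t)) for d, t in added},
        )


@dataclass(frozen=True)
class HetNet:
    """Assembled three-layer heterogeneous network.

    ``drug_layer`` (``S_d``) and ``target_layer`` (``S_t``) are the blended
    similarity layers aligned with the interaction registries.  When the
    feature layers (chemical ``C_s``, sequence ``T_s``) and blend weights
    are retained, the blended layers can be rebuilt after links change —
    required by the link-perturbation protocols, where the topology
    similarities must not see a removed link.
    """

    drug_layer: SimilarityLayer
    target_layer: SimilarityLayer
    interactions: InteractionTable
    drug_feature_layer: SimilarityLayer | None = None
    target_feature_layer: SimilarityLayer | None = None
    blend_weights: BlendWeights | None = None

    @property
    def drug_ids(self) -> tuple[str, ...]:
        return self.interactions.drug_ids

    @property
    def target_ids(self) -> tuple[str, ...]:
        return self.interactions.target_ids

    @property
    def n_bridge_drugs(self) -> int:
        return len({d for d, _ in self.interactions.links})

    @property
    def n_bridge_targets(self) -> int:
        return len({t for _, t in self.interactions.links})


@dataclass(frozen=True)
class TransitionModel:
    """Row-stochastic block transition matrix over [targets; drugs].

    Blocks: ``W_TT`` target-to-target, ``W_TD`` target-to-drug, ``W_DT``
    drug-to-target, ``W_DD`` drug-to-drug.  For a bridge node the
    cross-layer block row sums to ``lambda_`` and the within-layer block
    row to ``1 - lambda_``; non-bridge rows stay entirely within their
    layer.
    """

    target_ids: tuple[str, ...]
    drug_ids: tuple[str, ...]
    W: np.ndarray  # full (n_t + n_d) square matrix, targets first
    lambda_: float

    def __post_init__(self) -> None:
        n = len(self.target_ids) + len(self.drug_ids)
        if self.W.shape != (n, n):
            raise ValueError("transition matrix shape mismatch")
        rows = self.W.sum(axis=1)
        if np.max(np.abs(rows - 1.0)) > ROW_SUM_TOL:
            raise ValueError("transition matrix is not row-stochastic")
        W = self.W.copy()
        W.flags.writeable = False
        object.__setattr__(self, "W", W)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_nodes(self) -> int:
        return self.n_targets + self.n_drugs

    @property
    def W_TT(self) -> np.ndarray:
        return self.W[: self.n_targets, : self.n_targets]

    @property
    def W_TD(self) -> np.ndarray:
        return self.W[: self.n_targets, self.n_targets :]

    @property
    def W_DT(self) -> np.ndarray:
        return self.W[self.n_targets :, : self.n_targets]

    @property
    def W_DD(self) -> np.ndarray:
        return self.W[self.n_targets :, self.n_targets :]


def assemble(
    drug_layer: SimilarityLayer,
    target_layer: SimilarityLayer,
    interactions: InteractionTable,
    drug_feature_layer: SimilarityLayer | None = None,
    target_feature_layer: SimilarityLayer | None = None,
    blend_weights: BlendWeights | None = None,
) -> HetNet:
    """Align id registries and build a :class:`HetNet`.

    The similarity layers are reordered to the interaction-table
    registries.  Ids present in the interaction table but absent from a
    layer are an error; layer ids absent from the interaction table are
    trimmed with a log message.
    """
    missing_d = [d for d in interactions.drug_ids if d not in set(drug_layer.ids)]
    if missing_d:
        raise ValueError(f"drugs missing from drug layer: {missing_d}")
    missing_t = [
        t for t in interactions.target_ids if t not in set(target_layer.ids)
    ]
    if missing_t:
        raise ValueError(f"targets missing from target layer: {missing_t}")
    extra_d = set(drug_layer.ids) - set(interactions.drug_ids)
    extra_t = set(target_layer.ids) - set(interactions.target_ids)
    if extra_d or extra_t:
        logger.info(
            "trimming %d drug and %d target layer ids absent from the "
            "interaction registry",
            len(extra_d),
            len(extra_t),
        )
    net = HetNet(
        drug_layer=drug_layer.reorder(interactions.drug_ids),
        target_layer=target_layer.reorder(interactions.target_ids),
        interactions=interactions,
        drug_feature_layer=(
            drug_feature_layer.reorder(interactions.drug_ids)
            if drug_feature_layer is not None
            else None
        ),
        target_feature_layer=(
            target_feature_layer.reorder(interactions.target_ids)
            if target_feature_layer is not None
            else None
        ),
        blend_weights=blend_weights,
    )
    logger.info(
        "assembled network: %d drugs (%d with >=1 target), %d targets "
        "(%d with >=1 drug), %d links",
        interactions.n_drugs,
        net.n_bridge_drugs,
        interactions.n_targets,
        net.n_bridge_targets,
        interactions.n_links,
    )
    return net


def _layer_rows(
    sim: np.ndarray,
    link_mass: np.ndarray,
    cross_rows: np.ndarray,
    lambda_: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Build (within, cross) transition rows for one node type.

    ``sim`` has its diagonal zeroed (no self-loops).  Bridge nodes
    (``link_mass > 0``) split mass lambda_/(1 - lambda_) between the
    cross-layer links and the within-layer similarities; non-bridge nodes
    renormalize their similarity row to 1.  Degenerate rows (no similarity
    mass) route the leftover weight to a self-loop so every row still sums
    to 1.
    """
    n = sim.shape[0]
    within = np.zeros_like(sim)
    cross = np.zeros_like(cross_rows)
    sim_mass = sim.sum(axis=1)
    for i in range(n):
        is_bridge = link_mass[i] > 0
        cross_w = lambda_ if is_bridge else 0.0
        within_w = 1.0 - cross_w
        if cross_w > 0:
            cross[i] = cross_w * cross_rows[i] / link_mass[i]
        if sim_mass[i] > 0:
            within[i] = within_w * sim[i] / sim_mass[i]
        else:
            # isolated within its layer: self-loop absorbs the layer share
            within[i, i] = within_w
    return within, cross


def build_transition(
    net: HetNet, lambda_: float, similarity_cutoff: float = 0.0
) -> TransitionModel:
    """Build the row-stochastic block transition matrix.

    For a bridge drug ``d``: ``W_DT(d, t) = lambda_ * A(d, t) / deg(d)``
    and ``W_DD(d, d') = (1 - lambda_) * S_d(d, d') / sum S_d(d, .)``, with
    the diagonal of ``S_d`` zeroed first; symmetric rules govern targets.
    Non-bridge rows renormalize the within-layer similarities to full
    weight.  An isolated node (no links, no similarity mass) gets a
    self-loop of weight 1.  ``similarity_cutoff`` optionally sparsifies
    the layers: entries strictly below it are dropped before
    normalization (0 keeps the dense layers).
    """
    if not 0.0 <= lambda_ <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lambda_}")
    if not 0.0 <= similarity_cutoff <= 1.0:
        raise ValueError("similarity_cutoff must be in [0, 1]")
    A = net.interactions.matrix()  # drugs x targets
    S_d = net.drug_layer.values.copy()
    S_t = net.target_layer.values.copy()
    np.fill_diagonal(S_d, 0.0)
    np.fill_diagonal(S_t, 0.0)
    if similarity_cutoff > 0.0:
        S_d[S_d < similarity_cutoff] = 0.0
        S_t[S_t < similarity_cutoff] = 0.0

    drug_deg = A.sum(axis=1)
    target_deg = A.sum(axis=0)

    W_DD, W_DT = _layer_rows(S_d, drug_deg, A, lambda_)
    W_TT, W_TD = _layer_rows(S_t, target_deg, A.T, lambda_)

    n_t, n_d = net.interactions.n_targets, net.interactions.n_drugs
    W = np.zeros((n_t + n_d, n_t + n_d), dtype=np.float64)
    W[:n_t, :n_t] = W_TT
    W[:n_t, n_t:] = W_TD
    W[n_t:, :n_t] = W_DT
    W[n_t:, n_t:] = W_DD
    return TransitionModel(
        target_ids=net.target_ids,
        drug_ids=net.drug_ids,
        W=W,
        lambda_=lambda_,
    )


def rebuild_with_interactions(
    net: HetNet, interactions: InteractionTable
) -> HetNet:
    """Rebuild the network around a modified interaction table.

    When the feature layers and blend weights are available the topology
    similarities (shared-target / shared-drug Jaccard) are recomputed from
    the new table and re-blended, so nothing downstream can see a removed
    link through the similarity layers.  Otherwise only the bipartite
    layer changes.
    """
    from .similarity import blend_layers, shared_neighbor_jaccard

    if (
        net.drug_feature_layer is not None
        and net.target_feature_layer is not None
        and net.blend_weights is not None
    ):
        c_n = shared_neighbor_jaccard(interactions, axis="drugs")
        t_n = shared_neighbor_jaccard(interactions, axis="targets")
        s_d = blend_layers(net.drug_feature_layer, c_n, net.blend_weights.w_d)
        s_t = blend_layers(net.target_feature_layer, t_n, net.blend_weights.w_t)
        return HetNet(
            drug_layer=s_d,
            target_layer=s_t,
            interactions=interactions,
            drug_feature_layer=net.drug_feature_layer,
            target_feature_layer=net.target_feature_layer,
            blend_weights=net.blend_weights,
        )
    return HetNet(
        drug_layer=net.drug_layer,
        target_layer=net.target_layer,
        interactions=interactions,
    )
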