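"""Random walk with restart over the heterogeneous network.

The walker iterates ``p_{t+1} = (1 - c) W^T p_t + c p_0`` from a seed
distribution ``p_0`` until the Euclidean change between iterates falls
below ``tol`` (default 1e-10).  The seed distribution splits restart mass
between the two node classes: ``p_0 = [(1 - eta) u_0; eta v_0]`` with
``u_0`` uniform over the query drug's known targets and ``v_0`` the
indicator of the query drug itself.  The steady-state target block
``u_inf`` ranks candidate (non-seed) targets for the query drug.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .hetnet import HetNet, TransitionModel, build_transition

logger = logging.getLogger(__name__)

MASS_TOL = 1e-8


@dataclass(frozen=True)
class WalkParams:
    """Parameters of the restart walk.

    c
        Restart probability in (0, 1]; 0.3 by default (the prediction is
        known to be insensitive to it).
    eta
        Seed-class weight in [0, 1]; the share of restart mass placed on
        the query drug versus its known targets.  Small eta performs best;
        default 0.01.
    lambda_
        Jumping probability at bridge nodes, forwarded to the transition
        matrix; default 0.5.
    tol, max_iter
        Convergence threshold on the L2 change between iterates, and an
        iteration cap.
    """

    c: float = 0.3
    eta: float = 0.01
    lambda_: float = 0.5
    tol: float = 1e-10
    max_iter: int = 1_000_000

    def __post_init__(self) -> None:
        if not 0.0 < self.c <= 1.0:
            raise ValueError(f"c must be in (0, 1], got {self.c}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must be in [0, 1], got {self.eta}")
        if not 0.0 <= self.lambda_ <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {self.lambda_}")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class SeedConfig:
    """Seed nodes for one query: the drug plus its directly linked targets."""

    query_drug: str | None
    seed_targets: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "seed_targets", tuple(str(t) for t in self.seed_targets)
        )
        if self.query_drug is None and not self.seed_targets:
            raise ValueError("seed configuration is empty")

    @classmethod
    def for_drug(cls, net: HetNet, drug_id: str) -> "SeedConfig":
        if drug_id not in set(net.drug_ids):
            raise KeyError(f"unknown drug {drug_id!r}")
        return cls(
            query_drug=drug_id,
            seed_targets=net.interactions.targets_of(drug_id),
        )


@dataclass(frozen=True)
class WalkState:
    """Probability vector over all nodes, partitioned [targets; drugs]."""

    target_ids: tuple[str, ...]
    drug_ids: tuple[str, ...]
    u: np.ndarray
    v: np.ndarray
    iteration: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if u.shape != (len(self.target_ids),):
            raise ValueError("u length does not match target registry")
        if v.shape != (len(self.drug_ids),):
            raise ValueError("v length does not match drug registry")
        if (u < -MASS_TOL).any() or (v < -MASS_TOL).any():
            raise ValueError("negative probability in walk state")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @property
    def p(self) -> np.ndarray:
        return np.concatenate([self.u, self.v])

    @property
    def total_mass(self) -> float:
        return float(self.u.sum() + self.v.sum())


@dataclass(frozen=True)
class RankedPrediction:
    """Candidate targets for a query drug, ordered by steady-state score.

    Candidates are all targets except the seeds; ranks are 1-based and
    ties are broken lexicographically on target id.
    """

    query_drug: str | None
    targets: tuple[str, ...]
    scores: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.targets) != len(self.scores):
            raise ValueError("targets and scores differ in length")
        for a, b in zip(self.scores, self.scores[1:]):
            if b > a + 1e-15:
                raise ValueError("scores must be non-increasing")

    def rank_of(self, target_id: str) -> int:
        """1-based rank position of a candidate target."""
        try:
            return self.targets.index(target_id) + 1
        except ValueError:
            raise KeyError(f"{target_id!r} is not a candidate") from None

    @property
    def n_candidates(self) -> int:
        return len(self.targets)

    def top(self, n: int) -> tuple[str, ...]:
        return self.targets[:n]


def build_p0(
    seeds: SeedConfig,
    eta: float,
    target_ids: Sequence[str],
    drug_ids: Sequence[str],
) -> WalkState:
    """Build the restart distribution ``p_0 = [(1 - eta) u_0; eta v_0]``.

    ``u_0`` is uniform over the seed targets and ``v_0`` puts all drug-side
    mass on the query drug; each class is normalized to unit mass before
    the eta split so that ``p_0`` is a probability vector.  If one class is
    empty (a drug with no known targets, or a target-only query), the full
    restart mass goes to the other class regardless of eta.
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must be in [0, 1], got {eta}")
    t_index = {t: i for i, t in enumerate(target_ids)}
    d_index = {d: i for i, d in enumerate(drug_ids)}
    u0 = np.zeros(len(target_ids))
    v0 = np.zeros(len(drug_ids))
    for t in seeds.seed_targets:
        if t not in t_index:
            raise KeyError(f"seed target {t!r} not registered")
        u0[t_index[t]] = 1.0
    if seeds.query_drug is not None:
        if seeds.query_drug not in d_index:
            raise KeyError(f"query drug {seeds.query_drug!r} not registered")
        v0[d_index[seeds.query_drug]] = 1.0

    u_mass, v_mass = u0.sum(), v0.sum()
    if u_mass == 0 and v_mass == 0:
        raise ValueError("seed configuration places no mass anywhere")
    if u_mass > 0:
        u0 /= u_mass
    if v_mass > 0:
        v0 /= v_mass
    if u_mass == 0:
        w_u, w_v = 0.0, 1.0  # no seed targets: everything on the drug
    elif v_mass == 0:
        w_u, w_v = 1.0, 0.0
    else:
        w_u, w_v = 1.0 - eta, eta
    return WalkState(
        target_ids=tuple(target_ids),
        drug_ids=tuple(drug_ids),
        u=w_u * u0,
        v=w_v * v0,
    )


def iterate_to_steady_state(
    model: TransitionModel, p0: WalkState, params: WalkParams
) -> WalkState:
    """Iterate the restart walk to its fixed point.

    Returns the steady state with ``converged=True`` once the L2 norm of
    the change drops below ``params.tol``; if ``max_iter`` is hit first the
    last state is returned with ``converged=False`` and a warning.
    """
    if p0.target_ids != model.target_ids or p0.drug_ids != model.drug_ids:
        raise ValueError("walk state and transition model registries differ")
    c = params.c
    WT = model.W.T.copy()  # column-stochastic; p_{t+1} = (1-c) WT p_t + c p0
    p_restart = p0.p
    p = p_restart.copy()
    converged = False
    iteration = 0
    for iteration in range(1, params.max_iter + 1):
        p_next = (1.0 - c) * (WT @ p) + c * p_restart
        delta = float(np.linalg.norm(p_next - p))
        p = p_next
        if delta < params.tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "walk did not converge within %d iterations (last delta above tol)",
            params.max_iter,
        )
    n_t = model.n_targets
    return WalkState(
        target_ids=model.target_ids,
        drug_ids=model.drug_ids,
        u=p[:n_t],
        v=p[n_t:],
        iteration=iteration,
        converged=converged,
    )


def solve_steady_state(
    model: TransitionModel, p0: WalkState, params: WalkParams
) -> WalkState:
    """Closed-form fixed point ``c (I - (1-c) W^T)^{-1} p_0``.

    Direct linear solve; useful as an exact cross-check of the iteration
    on small networks.
    """
    n = model.n_nodes
    lhs = np.eye(n) - (1.0 - params.c) * model.W.T
    p = params.c * np.linalg.solve(lhs, p0.p)
    n_t = model.n_targets
    return WalkState(
        target_ids=model.target_ids,
        drug_ids=model.drug_ids,
        u=p[:n_t],
        v=p[n_t:],
        iteration=0,
        converged=True,
    )


def rank_targets(state: WalkState, seeds: SeedConfig) -> RankedPrediction:
    """Rank candidate targets by steady-state probability.

    Candidates are every registered target except the seed targets, sorted
    by ``u_inf`` descending with lexicographic id tie-break.
    """
    seed_set = set(seeds.seed_targets)
    candidates = [
        (t, float(state.u[i]))
        for i, t in enumerate(state.target_ids)
        if t not in seed_set
    ]
    candidates.sort(key=lambda ts: (-ts[1], ts[0]))
    return RankedPrediction(
        query_drug=seeds.query_drug,
        targets=tuple(t for t, _ in candidates),
        scores=tuple(s for _, s in candidates),
    )


def predict_targets(
    net: HetNet,
    drug_id: str,
    params: WalkParams,
    model: TransitionModel | None = None,
) -> RankedPrediction:
    """Run the full walk for one query drug and rank its candidates."""
    model = model if model is not None else build_transition(net, params.lambda_)
    seeds = SeedConfig.for_drug(net, drug_id)
    p0 = build_p0(seeds, params.eta, model.target_ids, model.drug_ids)
    state = iterate_to_steady_state(model, p0, params)
    return rank_targets(state, seeds)


def predict_all(
    net: HetNet,
    params: WalkParams,
    drugs: Iterable[str] | None = None,
) -> dict[str, RankedPrediction]:
    """Ranked candidate targets for each query drug.

    The transition matrix is built once and shared across queries.
    Per-drug failures are logged and skipped rather than aborting the
    batch.
    """
    model = build_transition(net, params.lambda_)
    queries = tuple(drugs) if drugs is not None else net.drug_ids
    out: dict[str, RankedPrediction] = {}
    for drug_id in queries:
        try:
            out[drug_id] = predict_targets(net, drug_id, params, model=model)
        except Exception:
            logger.exception("prediction failed for drug %r", drug_id)
    return out
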