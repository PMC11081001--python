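"""Pathfinder algorithm (PFA) specialized to wrapper feature selection.

The swarm is split into one leader (lowest cost so far within the current
population) and followers. The leader explores with a momentum step plus a
decaying random fluctuation; followers move toward both a random neighbor
and the leader, with a vibration term that vanishes at the final iteration.
Roles can swap each iteration: whoever currently attains the lowest cost is
re-elected leader.

Positions live in [0, 1]^d and are thresholded at 0.5 into feature masks.
The wrapper cost is a weighted sum of the KNN classification error and the
selected-feature fraction:

    cost = phi_alpha * (1 - accuracy) + phi_beta * (n_selected / d)

with the published weighting phi_alpha = 0.94, phi_beta = 0.014, so accuracy
dominates and the size term breaks ties toward compact subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier

from .synthetic import LabeledFeatureMatrix

PHI_ALPHA = 0.94
PHI_BETA = 0.014


@dataclass
class PfaConfig:
    swarm_size: int = 20
    max_iter: int = 30
    phi_alpha: float = PHI_ALPHA
    phi_beta: float = PHI_BETA
    knn_k: int = 5
    eval_scheme: str = "holdout_50_50"  # or "cv5"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.phi_alpha < 0 or self.phi_beta < 0:
            raise ValueError("cost weights must be >= 0")
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.eval_scheme not in ("holdout_50_50", "cv5"):
            raise ValueError(f"unknown eval_scheme {self.eval_scheme!r}")


@dataclass
class SelectionMask:
    selected: np.ndarray

    def __post_init__(self) -> None:
        self.selected = np.asarray(self.selected, dtype=bool)
        if self.selected.ndim != 1 or not self.selected.any():
            raise ValueError("mask must be 1-D with at least one selected feature")

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


@dataclass
class FitnessRecord:
    cost: float
    error: float
    n_selected: int
    accuracy: float


@dataclass
class PfaState:
    """Swarm snapshot: positions, leader bookkeeping, elitist best."""

    positions: np.ndarray  # m x d in [0, 1]
    leader_idx: int
    leader_prev: np.ndarray  # leader position at the previous iteration
    iteration: int
    best_position: np.ndarray
    best_cost: float
    rng: np.random.Generator = field(repr=False, default=None)


def binarize(position: np.ndarray) -> SelectionMask:
    """Threshold a continuous position at 0.5 (strict); argmax fallback.

    If no coordinate exceeds 0.5 the single largest coordinate is selected
    (ties broken toward the lowest index) so the mask is never empty.
    """
    position = np.asarray(position, dtype=float)
    if position.min() < 0 or position.max() > 1:
        raise ValueError("position entries must lie in [0, 1]")
    selected = position > 0.5
    if not selected.any():
        selected = np.zeros_like(selected)
        selected[int(np.argmax(position))] = True
    return SelectionMask(selected)


def fitness(mask: SelectionMask, data: LabeledFeatureMatrix, cfg: PfaConfig) -> FitnessRecord:
    """KNN wrapper cost of a feature subset under the configured split."""
    x = data.values[:, mask.selected]
    y = data.labels
    knn = KNeighborsClassifier(n_neighbors=cfg.knn_k, metric="euclidean")
    if cfg.eval_scheme == "holdout_50_50":
        xtr, xte, ytr, yte = train_test_split(
            x, y, test_size=0.5, stratify=y, random_state=cfg.seed
        )
        acc = float(knn.fit(xtr, ytr).score(xte, yte))
    else:
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=cfg.seed)
        scores = [
            knn.fit(x[tr], y[tr]).score(x[te], y[te]) for tr, te in cv.split(x, y)
        ]
        acc = float(np.mean(scores))
    err = 1.0 - acc
    frac = mask.n_selected / data.n_features
    cost = cfg.phi_alpha * err + cfg.phi_beta * frac
    return FitnessRecord(cost=cost, error=err, n_selected=mask.n_selected, accuracy=acc)


def pathfinder_update(state: PfaState, cfg: PfaConfig) -> np.ndarray:
    """Leader exploration step with momentum and decaying fluctuation.

    new = x_p + 2 r3 * (x_p - x_p_prev) + A,  A = u2 * exp(-2k / k_max),
    r3 ~ U[0,1]^d, u2 ~ U[-1,1]^d; clipped to [0, 1].
    """
    leader = state.positions[state.leader_idx]
    d = leader.size
    r3 = state.rng.uniform(0.0, 1.0, size=d)
    u2 = state.rng.uniform(-1.0, 1.0, size=d)
    fluctuation = u2 * np.exp(-2.0 * state.iteration / cfg.max_iter)
    new = leader + 2.0 * r3 * (leader - state.leader_prev) + fluctuation
    return np.clip(new, 0.0, 1.0)


def follower_update(
    state: PfaState, i: int, cfg: PfaConfig, alpha: float, beta: float
) -> np.ndarray:
    """Follower step toward a random neighbor and the leader, plus vibration.

    new = x_i + alpha r1 * (x_j - x_i) + beta r2 * (x_p - x_i) + eps,
    eps = (1 - k/k_max) * u1 * |x_i - x_j|, u1 ~ U[-1,1]^d; clipped.

    The vibration amplitude is the componentwise member distance, so it is
    bounded by the box width in every coordinate (a scalar Euclidean norm
    would grow like sqrt(d) and drown the attraction terms in high
    dimension), and it vanishes exactly at the last iteration.
    """
    m, d = state.positions.shape
    if not 0 <= i < m:
        raise ValueError("member index out of range")
    if i == state.leader_idx:
        raise ValueError("follower_update does not apply to the leader")
    xi = state.positions[i]
    others = [j for j in range(m) if j != i]
    j = others[int(state.rng.integers(len(others)))]
    xj = state.positions[j]
    leader = state.positions[state.leader_idx]
    r1 = state.rng.uniform(0.0, 1.0, size=d)
    r2 = state.rng.uniform(0.0, 1.0, size=d)
    u1 = state.rng.uniform(-1.0, 1.0, size=d)
    eps = (1.0 - state.iteration / cfg.max_iter) * u1 * np.abs(xi - xj)
    new = xi + alpha * r1 * (xj - xi) + beta * r2 * (leader - xi) + eps
    return np.clip(new, 0.0, 1.0)


def run_pfa(
    data: LabeledFeatureMatrix, cfg: PfaConfig
) -> tuple[SelectionMask, FitnessRecord, list[float]]:
    """Full PFA feature-selection run; elitist, deterministic under seed.

    Returns the best-so-far mask, its fitness record, and the history of
    best cost per iteration (entry 0 is the post-initialization best).
    """
    if data.n_features == 0:
        raise ValueError("data has no features")
    if data.n_classes < 2:
        raise ValueError("need at least two classes")
    rng = np.random.default_rng(cfg.seed)
    m, d = cfg.swarm_size, data.n_features
    positions = rng.uniform(0.0, 1.0, size=(m, d))

    def evaluate(pos: np.ndarray) -> FitnessRecord:
        return fitness(binarize(pos), data, cfg)

    records = [evaluate(p) for p in positions]
    costs = np.array([r.cost for r in records])
    leader_idx = int(np.argmin(costs))
    best_idx = leader_idx
    best_position = positions[best_idx].copy()
    best_record = records[best_idx]
    history = [best_record.cost]

    state = PfaState(
        positions=positions,
        leader_idx=leader_idx,
        leader_prev=positions[leader_idx].copy(),
        iteration=1,
        best_position=best_position,
        best_cost=best_record.cost,
        rng=rng,
    )

    for k in range(1, cfg.max_iter + 1):
        state.iteration = k
        alpha = float(rng.uniform(1.0, 2.0))
        beta = float(rng.uniform(1.0, 2.0))
        old_leader = state.positions[state.leader_idx].copy()
        new_positions = state.positions.copy()
        new_positions[state.leader_idx] = pathfinder_update(state, cfg)
        for i in range(m):
            if i != state.leader_idx:
                new_positions[i] = follower_update(state, i, cfg, alpha, beta)
        state.leader_prev = old_leader

        # greedy acceptance: a member keeps its move only if it improves
        for i in range(m):
            new_record = evaluate(new_positions[i])
            if new_record.cost < records[i].cost:
                state.positions[i] = new_positions[i]
                records[i] = new_record
        costs = np.array([r.cost for r in records])
        state.leader_idx = int(np.argmin(costs))
        if costs[state.leader_idx] < state.best_cost:
            state.best_cost = float(costs[state.leader_idx])
            state.best_position = state.positions[state.leader_idx].copy()
            best_record = records[state.leader_idx]
        history.append(state.best_cost)

    return binarize(state.best_position), best_record, history
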