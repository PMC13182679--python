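"""Masked actor-critic proximal policy optimization.

The agent's action space is the joint choice of (collimator, voxel
position); infeasible positions are removed by adding a large negative
score before the softmax, so masked actions carry exactly zero probability.
Advantages are plain discounted returns minus the critic's value estimate
(no generalized advantage estimation), and the update is the standard
clipped surrogate with an MSE critic loss and an optional entropy bonus:

    L = -E[min(r A, clip(r, 1-eps, 1+eps) A)] + c_v * MSE(V, G) - c_H * H

with r the probability ratio between the updated policy and the behaviour
policy snapshot taken at collection time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .env import PlanningState
from .nets import ActorNet, Adam, CriticNet

__all__ = [
    "PPOConfig",
    "Transition",
    "PPOMemory",
    "masked_log_softmax",
    "actor_forward",
    "sample_action",
    "returns_and_advantages",
    "ppo_loss",
    "actor_batch_gradients",
    "critic_batch_gradients",
    "ppo_update",
    "PPOAgent",
]

_MASK_PENALTY = np.float32(-1e9)


@dataclass(frozen=True)
class PPOConfig:
    """Training hyperparameters of the clipped-surrogate update."""

    learning_rate: float = 0.003
    gamma: float = 0.99
    clip_epsilon: float = 0.2
    epochs_per_update: int = 5
    batch_size: int = 8
    value_loss_coef: float = 0.5
    entropy_coef: float = 0.01
    iterations_per_case: int = 1000
    normalize_advantages: bool = False
    hidden_channels: int = 4

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if self.clip_epsilon <= 0:
            raise ValueError("clip_epsilon must be positive")
        for name in ("epochs_per_update", "batch_size", "iterations_per_case"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")


@dataclass(frozen=True)
class Transition:
    """One interaction: state channels, executable mask, action, bookkeeping."""

    state: np.ndarray  # (4, D, H, W) uint8
    mask: np.ndarray  # flat bool over actions
    action: int
    log_prob: float
    value: float
    reward: float
    done: bool

    def __post_init__(self) -> None:
        if self.log_prob > 1e-6:
            raise ValueError("log_prob must be <= 0")
        if not np.isfinite([self.log_prob, self.value, self.reward]).all():
            raise ValueError("transition fields must be finite")


class PPOMemory:
    """Ordered transition store, cleared after each update cycle."""

    def __init__(self):
        self.transitions: list[Transition] = []

    def __len__(self) -> int:
        return len(self.transitions)

    def store(self, transition: Transition) -> None:
        self.transitions.append(transition)

    def clear(self) -> None:
        self.transitions.clear()

    def batch_indices(self, batch_size: int, rng: np.random.Generator) -> list[np.ndarray]:
        """Shuffled batches of ``batch_size`` partitioning all stored indices."""
        idx = rng.permutation(len(self.transitions))
        return [idx[i : i + batch_size] for i in range(0, len(idx), batch_size)]


def masked_log_softmax(scores: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Log-softmax over the last axis restricted to ``mask``.

    Masked entries get a large negative additive score, so their probability
    underflows to exactly zero while staying finite for safe arithmetic.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any(axis=-1).all():
        raise ValueError("each row needs at least one executable action")
    z = np.where(mask, scores, _MASK_PENALTY).astype(np.float32)
    z = z - z.max(axis=-1, keepdims=True)
    logsum = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    return z - logsum


def actor_forward(policy: ActorNet, state: PlanningState | np.ndarray, executable: np.ndarray) -> np.ndarray:
    """Masked action probabilities for one state.

    ``executable`` is the per-collimator feasibility field, broadcast over
    collimators when given as a single spatial mask. Returns a flat
    probability vector over (collimator, voxel) actions.
    """
    x = state.stack() if isinstance(state, PlanningState) else np.asarray(state, dtype=np.float32)
    scores = policy.forward(x[None])[0]  # (n_coll, D, H, W)
    n_actions = scores.size
    executable = np.asarray(executable, dtype=bool)
    if executable.size == scores[0].size:
        mask = np.broadcast_to(executable.reshape(-1), (scores.shape[0], executable.size)).reshape(-1)
    else:
        mask = executable.reshape(-1)
    if mask.size != n_actions:
        raise ValueError("executable mask does not match the action space")
    logp = masked_log_softmax(scores.reshape(1, -1), mask.reshape(1, -1))[0]
    return np.exp(logp)


def sample_action(probabilities: np.ndarray, rng: np.random.Generator) -> tuple[int, float]:
    """Draw one action index; returns (index, log probability)."""
    p = np.asarray(probabilities, dtype=np.float64)
    if not np.isfinite(p).all() or p.sum() <= 0:
        raise ValueError("degenerate action distribution")
    p = p / p.sum()
    idx = int(rng.choice(p.size, p=p))
    return idx, float(np.log(p[idx]))


def returns_and_advantages(
    memory: PPOMemory, gamma: float
) -> tuple[np.ndarray, np.ndarray]:
    """Discounted returns (reset at episode ends) and return-minus-value advantages."""
    ts = memory.transitions
    if not ts:
        raise ValueError("memory is empty")
    if not ts[-1].done:
        raise ValueError("memory must end with a terminal transition")
    returns = np.zeros(len(ts), dtype=np.float64)
    running = 0.0
    for t in range(len(ts) - 1, -1, -1):
        if ts[t].done:
            running = 0.0
        running = ts[t].reward + gamma * running
        returns[t] = running
    values = np.array([t.value for t in ts], dtype=np.float64)
    return returns, returns - values


def ppo_loss(
    new_log_probs: np.ndarray,
    old_log_probs: np.ndarray,
    advantages: np.ndarray,
    value_predictions: np.ndarray,
    returns: np.ndarray,
    cfg: PPOConfig,
    entropy: float = 0.0,
) -> tuple[float, float, float]:
    """Clipped-surrogate total loss and its actor/critic parts.

    ``total = actor + value_loss_coef * critic - entropy_coef * entropy``.
    """
    arrs = [np.asarray(a, dtype=np.float64) for a in (new_log_probs, old_log_probs, advantages)]
    new_lp, old_lp, adv = arrs
    vpred = np.asarray(value_predictions, dtype=np.float64)
    ret = np.asarray(returns, dtype=np.float64)
    if not (new_lp.shape == old_lp.shape == adv.shape) or vpred.shape != ret.shape:
        raise ValueError("misaligned loss inputs")
    if not all(np.isfinite(a).all() for a in (new_lp, old_lp, adv, vpred, ret)):
        raise ValueError("non-finite loss inputs")
    ratio = np.exp(new_lp - old_lp)
    eps = cfg.clip_epsilon
    surr = np.minimum(ratio * adv, np.clip(ratio, 1 - eps, 1 + eps) * adv)
    actor = -float(surr.mean())
    critic = float(np.mean((vpred - ret) ** 2))
    total = actor + cfg.value_loss_coef * critic - cfg.entropy_coef * float(entropy)
    return total, actor, critic


class PPOAgent:
    """Actor-critic agent with masked action sampling and clipped PPO updates."""

    def __init__(self, n_collimators: int, cfg: PPOConfig | None = None, seed: int = 0):
        self.cfg = cfg or PPOConfig()
        self.policy = ActorNet(n_collimators, self.cfg.hidden_channels, seed=seed)
        self.value = CriticNet(self.cfg.hidden_channels, seed=seed + 1)
        self.opt_policy = Adam(self.policy.parameters(), self.cfg.learning_rate)
        self.opt_value = Adam(self.value.parameters(), self.cfg.learning_rate)
        self.memory = PPOMemory()
        self.n_collimators = n_collimators

    # -- interaction ------------------------------------------------------

    def select_action(
        self, state: PlanningState | np.ndarray, executable: np.ndarray, rng: np.random.Generator
    ) -> tuple[int, float, float]:
        """Sample a flat action index; returns (action, log_prob, value)."""
        x = state.stack() if isinstance(state, PlanningState) else np.asarray(state, np.float32)
        probs = actor_forward(self.policy, x, executable)
        action, logp = sample_action(probs, rng)
        value = float(self.value.forward(x[None])[0])
        return action, logp, value

    def store(self, transition: Transition) -> None:
        self.memory.store(transition)

    def decode_action(self, action: int, spatial_shape: tuple[int, int, int]):
        """Flat action index -> (collimator_index, voxel index triple)."""
        n = int(np.prod(spatial_shape))
        return action // n, tuple(int(i) for i in np.unravel_index(action % n, spatial_shape))

    def update(self, rng: np.random.Generator) -> list[dict[str, float]]:
        return ppo_update(self.policy, self.value, self.memory, self.cfg, rng,
                          opt_policy=self.opt_policy, opt_value=self.opt_value)


def actor_batch_gradients(
    policy: ActorNet,
    states: np.ndarray,
    masks: np.ndarray,
    actions: np.ndarray,
    old_log_probs: np.ndarray,
    advantages: np.ndarray,
    cfg: PPOConfig,
) -> tuple[float, float, list[np.ndarray]]:
    """Forward + analytic backward of the clipped surrogate (with entropy bonus).

    Returns ``(actor_loss, entropy, parameter_gradients)`` for the policy's
    contribution ``actor_loss - entropy_coef * entropy`` on one batch.
    """
    B = states.shape[0]
    scores = policy.forward(states)  # (B, n_coll, D, H, W)
    logp_all = masked_log_softmax(scores.reshape(B, -1), masks.reshape(B, -1))
    p_all = np.exp(logp_all)
    new_lp = logp_all[np.arange(B), actions]
    ratio = np.exp(new_lp - old_log_probs)
    eps = cfg.clip_epsilon
    surr1 = ratio * advantages
    surr2 = np.clip(ratio, 1 - eps, 1 + eps) * advantages
    actor_loss = -float(np.minimum(surr1, surr2).mean())
    # entropy over executable actions (masked entries have p exactly 0)
    plogp = np.where(p_all > 0, p_all * logp_all, 0.0)
    ent_per = -plogp.sum(axis=1)
    entropy = float(ent_per.mean())

    # d/d scores: the clipped branch has zero slope outside the clip window
    active = (surr1 <= surr2) | ((ratio > 1 - eps) & (ratio < 1 + eps))
    dlogp_chosen = -(np.where(active, ratio * advantages, 0.0)) / B
    onehot_minus_p = -p_all
    onehot_minus_p[np.arange(B), actions] += 1.0
    dscores = dlogp_chosen[:, None] * onehot_minus_p
    if cfg.entropy_coef:
        safe_logp = np.where(p_all > 0, logp_all, 0.0)
        dscores += (cfg.entropy_coef / B) * p_all * (safe_logp + ent_per[:, None])
    grads = policy.backward(dscores.reshape(scores.shape).astype(np.float32))
    return actor_loss, entropy, grads


def critic_batch_gradients(
    value: CriticNet, states: np.ndarray, returns: np.ndarray, cfg: PPOConfig
) -> tuple[float, list[np.ndarray]]:
    """MSE critic loss and gradients of ``value_loss_coef * MSE`` on one batch."""
    B = states.shape[0]
    vpred = value.forward(states)
    critic_loss = float(np.mean((vpred - returns) ** 2))
    dv = (cfg.value_loss_coef * 2.0 / B) * (vpred - returns)
    grads = value.backward(dv.astype(np.float32))
    return critic_loss, grads


def ppo_update(
    policy: ActorNet,
    value: CriticNet,
    memory: PPOMemory,
    cfg: PPOConfig,
    rng: np.random.Generator | int,
    opt_policy: Adam | None = None,
    opt_value: Adam | None = None,
) -> list[dict[str, float]]:
    """Run ``epochs_per_update`` passes of clipped-surrogate updates.

    Batches of ``batch_size`` are drawn from a fresh shuffle each epoch and
    optimized with Adam; the memory is cleared afterwards. Returns the loss
    trace (one row per batch). Deterministic given the generator state.
    """
    if len(memory) == 0:
        raise ValueError("cannot update from empty memory")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    opt_policy = opt_policy or Adam(policy.parameters(), cfg.learning_rate)
    opt_value = opt_value or Adam(value.parameters(), cfg.learning_rate)

    returns, advantages = returns_and_advantages(memory, cfg.gamma)
    if cfg.normalize_advantages and len(memory) > 1:
        advantages = (advantages - advantages.mean()) / (advantages.std() + 1e-8)
    ts = memory.transitions
    trace: list[dict[str, float]] = []

    for epoch in range(cfg.epochs_per_update):
        for batch in memory.batch_indices(cfg.batch_size, rng):
            states = np.stack([ts[i].state for i in batch]).astype(np.float32)
            masks = np.stack([ts[i].mask for i in batch])
            actions = np.array([ts[i].action for i in batch])
            old_lp = np.array([ts[i].log_prob for i in batch])
            adv = advantages[batch].astype(np.float32)
            ret = returns[batch].astype(np.float32)

            actor_loss, entropy, grads = actor_batch_gradients(
                policy, states, masks, actions, old_lp, adv, cfg
            )
            opt_policy.step(grads)
            critic_loss, vgrads = critic_batch_gradients(value, states, ret, cfg)
            opt_value.step(vgrads)

            trace.append(
                {
                    "epoch": float(epoch),
                    "actor_loss": actor_loss,
                    "critic_loss": critic_loss,
                    "entropy": entropy,
                    "total": actor_loss + cfg.value_loss_coef * critic_loss
                    - cfg.entropy_coef * entropy,
                }
            )
    memory.clear()
    return trace
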