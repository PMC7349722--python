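"""Deep-Q-network patient scheduler.

One shared fully connected network scores every waiting patient: the input
is the global ED state concatenated with the candidate's feature vector,
and the output a scalar Q-value, so the action set may grow and shrink
freely. Hidden layers of 64, 32 and 2 units use leaky ReLU; the head is
linear. The network, its gradients and the Adam optimiser are implemented
directly in numpy — the model is small enough that this is both simple and
fast.

Training follows the classic DQN recipe: an epsilon-greedy behaviour
policy, a bounded FIFO replay memory sampled uniformly, a target network
synced to the online network once per episode, and one minibatch gradient
step on the squared Bellman error every 60 simulated minutes once the
memory is at least half full.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import mdp
from .domain import DomainTables, generate_patients, load_tables
from .simulator import EDSimulator, Scheduler, SimulationResult

__all__ = [
    "Hyperparameters",
    "MLP",
    "Adam",
    "Transition",
    "ReplayMemory",
    "DQNScheduler",
    "select_greedy",
    "train",
    "TrainingResult",
]

_LEAKY_SLOPE = 0.01


@dataclass
class Hyperparameters:
    """Training hyperparameters with their default values.

    Defaults: Adam at learning rate 1e-7, epsilon from 1 decaying by 0.999
    per episode down to 1e-8, discount 0.9999, replay memory of 2000
    transitions, 1000 training episodes, minibatch size 100.
    """

    learning_rate: float = 1e-7
    epsilon: float = 1.0
    epsilon_decay: float = 0.999
    epsilon_min: float = 1e-8
    gamma: float = 0.9999
    memory_size: int = 2000
    episodes: int = 1000
    batch_size: int = 100
    hidden_layers: tuple[int, ...] = (64, 32, 2)
    #: "episode" decays epsilon once per episode; "step" once per decision
    epsilon_decay_scope: str = "episode"
    #: "global" feeds the full 29-entry state; "group" zero-masks every
    #: block except the deciding group's
    state_scope: str = "global"

    def epsilon_at(self, k: int) -> float:
        """Deterministic epsilon after ``k`` decay events (never below min)."""
        return max(self.epsilon * self.epsilon_decay**k, self.epsilon_min)


class MLP:
    """Small fully connected net: leaky-ReLU hidden layers, linear scalar head."""

    def __init__(self, input_dim: int, hidden: tuple[int, ...], rng: np.random.Generator):
        dims = [input_dim, *hidden, 1]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    def forward(self, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
        """Return Q-values (n,) and per-layer activations for backprop."""
        acts = [X]
        h = X
        last = len(self.weights) - 1
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = h @ W + b
            h = z if i == last else np.where(z > 0, z, _LEAKY_SLOPE * z)
            acts.append(h)
        return h[:, 0], acts

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.forward(np.atleast_2d(X))[0]

    def gradients(self, acts: list[np.ndarray], dout: np.ndarray):
        """Backprop a gradient w.r.t. the scalar outputs through the net."""
        grads_W, grads_b = [], []
        delta = dout[:, None]
        for i in range(len(self.weights) - 1, -1, -1):
            grads_W.append(acts[i].T @ delta)
            grads_b.append(delta.sum(axis=0))
            if i > 0:
                delta = delta @ self.weights[i].T
                delta = delta * np.where(acts[i] > 0, 1.0, _LEAKY_SLOPE)
        return grads_W[::-1], grads_b[::-1]

    def get_params(self) -> list[np.ndarray]:
        return [a.copy() for a in (*self.weights, *self.biases)]

    def set_params(self, params: list[np.ndarray]) -> None:
        n = len(self.weights)
        self.weights = [p.copy() for p in params[:n]]
        self.biases = [p.copy() for p in params[n:]]

    def copy_from(self, other: "MLP") -> None:
        self.set_params(other.get_params())

    def save(self, path) -> None:
        arrays = {f"W{i}": W for i, W in enumerate(self.weights)}
        arrays.update({f"b{i}": b for i, b in enumerate(self.biases)})
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "MLP":
        data = np.load(path)
        n = len(data.files) // 2
        net = cls.__new__(cls)
        net.weights = [data[f"W{i}"] for i in range(n)]
        net.biases = [data[f"b{i}"] for i in range(n)]
        return net


class Adam:
    """Adam optimiser over a flat list of parameter arrays."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p) for p in params]
            self.v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class Transition:
    """One (state, action features, reward, next state) record.

    ``next_inputs`` caches the Q-network input rows of the *next*
    decision's candidates (next state concatenated with each candidate's
    features); ``None`` marks the episode's last decision, whose target is
    the reward alone.
    """

    state: np.ndarray
    action_features: np.ndarray
    reward: float
    next_state: np.ndarray | None = None
    next_inputs: np.ndarray | None = None

    @property
    def input(self) -> np.ndarray:
        return np.concatenate([self.state, self.action_features])


class ReplayMemory:
    """Bounded FIFO of transitions with uniform sampling."""

    def __init__(self, capacity: int):
        self.capacity = capacity
        self._buf: deque[Transition] = deque(maxlen=capacity)

    def push(self, tr: Transition) -> None:
        self._buf.append(tr)

    def sample(self, rng: np.random.Generator, k: int) -> list[Transition]:
        idx = rng.choice(len(self._buf), size=k, replace=False)
        return [self._buf[i] for i in idx]

    def __len__(self) -> int:
        return len(self._buf)

    def __iter__(self):
        return iter(self._buf)


def select_greedy(q: np.ndarray, candidates: list) -> object:
    """Max-Q candidate; ties break toward the lowest patient id."""
    best = 0
    for i in range(1, len(candidates)):
        if q[i] > q[best] or (q[i] == q[best] and candidates[i].id < candidates[best].id):
            best = i
    return candidates[best]


class DQNScheduler(Scheduler):
    """Scheduler that scores each waiting patient with the shared Q-network.

    In training mode it also runs the behaviour policy (epsilon-greedy),
    records transitions into the replay memory, and performs one gradient
    step per hourly tick once the memory is half full. Outside training it
    is a deterministic greedy policy (epsilon = 0).
    """

    def __init__(
        self,
        hparams: Hyperparameters | None = None,
        tables: DomainTables | None = None,
        seed: int = 0,
        training: bool = False,
        network: MLP | None = None,
    ):
        self.hp = hparams or Hyperparameters()
        self.tables = tables or load_tables()
        self.rng = np.random.default_rng(seed)
        self.training = training
        self.requires_train_ticks = training
        self.input_dim = mdp.state_dim(self.tables) + mdp.feature_dim()
        self.net = network or MLP(self.input_dim, self.hp.hidden_layers, self.rng)
        self.target_net = MLP(self.input_dim, self.hp.hidden_layers, self.rng)
        self.target_net.copy_from(self.net)
        self.optimizer = Adam(self.hp.learning_rate)
        self.memory = ReplayMemory(self.hp.memory_size)
        self.epsilon = self.hp.epsilon if training else 0.0
        self.losses: list[float] = []
        self._pending: Transition | None = None
        # precompute the state-vector slice of each group for "group" scope
        self._group_slices: dict[str, slice] = {}
        offset = 0
        n_acuity = len(self.tables.acuity_levels)
        for g in ("doctor", "nurse", "xray", "ct"):
            width = n_acuity + len(self.tables.group_treatments[g])
            self._group_slices[g] = slice(offset, offset + width)
            offset += width

    # -- scoring ------------------------------------------------------------
    def _state_vector(self, sim: EDSimulator, group: str) -> np.ndarray:
        state = mdp.compute_state(sim.waiting, self.tables)
        if self.hp.state_scope == "group":
            masked = np.zeros_like(state)
            sl = self._group_slices[group]
            masked[sl] = state[sl]
            return masked
        return state

    def _candidate_inputs(self, state: np.ndarray, candidates, t: float) -> np.ndarray:
        feats = np.stack([mdp.features(p, t) for p in candidates])
        return np.hstack([np.broadcast_to(state, (len(candidates), state.size)), feats])

    def q_values(self, state: np.ndarray, candidates, t: float, target: bool = False) -> np.ndarray:
        """One Q-value per candidate from a single batched forward pass."""
        if not candidates:
            raise ValueError("candidate set is empty")
        net = self.target_net if target else self.net
        return net.predict(self._candidate_inputs(state, candidates, t))

    def select_action(self, state: np.ndarray, candidates, t: float, epsilon: float | None = None):
        """Epsilon-greedy pick: random with probability epsilon, else max-Q."""
        eps = self.epsilon if epsilon is None else epsilon
        if eps > 0 and self.rng.random() <= eps:
            return candidates[int(self.rng.integers(len(candidates)))]
        return select_greedy(self.q_values(state, candidates, t), candidates)

    # -- simulator hooks ----------------------------------------------------
    def select_patient(self, group, candidates, t, sim):
        state = self._state_vector(sim, group)
        chosen = self.select_action(state, candidates, t)
        if self.training:
            inputs = self._candidate_inputs(state, candidates, t)
            if self._pending is not None:
                self._pending.next_state = state
                self._pending.next_inputs = inputs
                self.memory.push(self._pending)
            self._pending = Transition(
                state=state,
                action_features=mdp.features(chosen, t),
                reward=mdp.compute_reward(chosen, t),
            )
            if self.hp.epsilon_decay_scope == "step":
                self.epsilon = max(self.epsilon * self.hp.epsilon_decay, self.hp.epsilon_min)
        return chosen

    def on_train_tick(self, t, sim):
        loss = self.train_step()
        if loss is not None:
            self.losses.append(loss)

    def end_episode(self, sim):
        if self.training and self._pending is not None:
            self.memory.push(self._pending)  # terminal-ish: target is reward alone
            self._pending = None

    def finish_episode(self) -> None:
        """Per-episode bookkeeping: sync the target net, decay epsilon."""
        self.target_net.copy_from(self.net)
        if self.hp.epsilon_decay_scope == "episode":
            self.epsilon = max(self.epsilon * self.hp.epsilon_decay, self.hp.epsilon_min)

    # -- learning -----------------------------------------------------------
    def train_step(self) -> float | None:
        """One uniform minibatch step on the squared Bellman error.

        A no-op (returns None) until the memory holds at least half its
        capacity.
        """
        if len(self.memory) < self.hp.memory_size // 2:
            return None
        batch = self.memory.sample(self.rng, min(self.hp.batch_size, len(self.memory)))
        X = np.stack([tr.input for tr in batch])
        targets = np.empty(len(batch))
        for i, tr in enumerate(batch):
            y = tr.reward
            if tr.next_inputs is not None and len(tr.next_inputs):
                y += self.hp.gamma * float(self.target_net.predict(tr.next_inputs).max())
            targets[i] = y
        q, acts = self.net.forward(X)
        err = q - targets
        loss = float(np.mean(err**2))
        if not np.isfinite(loss):
            raise RuntimeError(
                f"divergent loss at optimiser step {self.optimizer.t}: loss={loss}, "
                f"|q|max={np.abs(q).max():.3g}, |y|max={np.abs(targets).max():.3g}"
            )
        dout = 2.0 * err / len(batch)
        gW, gb = self.net.gradients(acts, dout)
        self.optimizer.step([*self.net.weights, *self.net.biases], [*gW, *gb])
        return loss

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        self.net.save(path)

    @classmethod
    def from_checkpoint(cls, path, hparams: Hyperparameters | None = None, tables=None, seed: int = 0):
        net = MLP.load(path)
        sched = cls(hparams=hparams, tables=tables, seed=seed, training=False)
        sched.net = net
        sched.target_net.copy_from(net)
        return sched


@dataclass
class TrainingResult:
    scheduler: DQNScheduler
    curves: pd.DataFrame = field(repr=False)


def train(
    hparams: Hyperparameters | None = None,
    rate_per_hour: float = 7.0,
    horizon_minutes: float = 14 * 1440.0,
    warmup_minutes: float = 1440.0,
    episodes: int | None = None,
    seed: int = 0,
    tables: DomainTables | None = None,
    capacities: dict[str, int] | None = None,
    pattern_weights=None,
    checkpoint_path=None,
    verbose: bool = False,
) -> TrainingResult:
    """Train a DQN scheduler against the simulated ED.

    Each episode is a fresh simulated instance at ``rate_per_hour``; the
    behaviour policy is epsilon-greedy, transitions accumulate in the
    replay memory, one gradient step runs per hourly tick once the memory
    is half full, and the target network syncs at each episode end. Returns
    the trained scheduler and a per-episode curve table (mean loss, mean
    weighted waiting time of post-warm-up discharges, epsilon).
    """
    hp = hparams or Hyperparameters()
    if episodes is not None:
        hp = replace(hp, episodes=episodes)
    tables = tables or load_tables()
    agent = DQNScheduler(hparams=hp, tables=tables, seed=seed, training=True)
    rows = []
    for ep in range(hp.episodes):
        ep_rng = np.random.default_rng(np.random.SeedSequence([seed, ep]))
        patients = generate_patients(
            ep_rng, rate_per_hour, horizon_minutes, tables=tables, pattern_weights=pattern_weights
        )
        sim = EDSimulator(
            patients, agent, horizon=horizon_minutes, tables=tables,
            capacities=capacities, keep_events=False,
        )
        agent.losses = []
        result: SimulationResult = sim.run()
        discharged = result.discharged(arrived_after=warmup_minutes)
        objective = (
            float(np.mean([p.acuity.waiting_weight * p.total_wait() for p in discharged]))
            if discharged
            else np.nan
        )
        rows.append(
            {
                "episode": ep,
                "mean_loss": float(np.mean(agent.losses)) if agent.losses else np.nan,
                "train_steps": len(agent.losses),
                "objective": objective,
                "epsilon": agent.epsilon,
            }
        )
        agent.finish_episode()
        if verbose:
            print(f"episode {ep}: objective={objective:.1f} eps={agent.epsilon:.4f}")
    agent.training = False
    agent.requires_train_ticks = False
    agent.epsilon = 0.0
    if checkpoint_path is not None:
        agent.save(checkpoint_path)
    return TrainingResult(scheduler=agent, curves=pd.DataFrame(rows))
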