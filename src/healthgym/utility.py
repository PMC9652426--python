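"""Utility verification through offline reinforcement learning.

A synthetic cohort is useful if an agent trained on it behaves like an
agent trained on the real cohort.  The pipeline:

1. split variables into observations ``D_O`` and actions ``D_A``;
2. reduce the encoded observation rows to a small latent score matrix by
   cross decomposition (a partial-least-squares fit paired against the
   one-hot action matrix), default 5 components;
3. K-means cluster the scores (default 100 clusters) to a discrete state
   space; centroids fitted on the real cohort assign out-of-sample states
   to synthetic rows so both agents share one state space;
4. index actions on the mixed-radix grid of the action variables' classes
   (4 x 4 = 16 actions for the ICU cohorts, 6 x 4 = 24 for HIV);
5. train tabular batch-constrained Q-learning: full sweeps of
   ``Q(s,a) += step * (r + gamma * max_{a' eligible} Q(s',a') - Q(s,a))``
   with the greedy policy restricted to actions actually observed in each
   state (at a configurable minimum empirical frequency);
6. compare the real- and synthetic-trained policies through their
   action-frequency heatmaps (tile percentages summing to 100) and the
   total-variation distance between them.

Reward functions are pluggable; the bundled defaults are simple clinical
stand-ins (e.g. reward when mean arterial pressure is restored above
65 mmHg), clearly labelled as such and configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .preprocessing import ChannelMap, TransformSpec, encode, fit_transforms
from .schema import NUMERIC, CohortSchema, LongitudinalDataset, SchemaError


# ---------------------------------------------------------------------------
# problem specification
# ---------------------------------------------------------------------------

@dataclass
class RLProblemSpec:
    """Observation/action split plus discretisation and training knobs."""

    observation_variables: Sequence[str]
    action_variables: Sequence[str]
    n_state_components: int = 5
    n_clusters: int = 100
    reward: str = "zero"
    reward_params: dict = field(default_factory=dict)
    discount: float = 0.99
    bcq_threshold: float = 0.0
    n_iterations: int = 100
    step_size: float = 0.01
    action_bins: int = 4  # quantile bins for numeric action variables

    def validate(self, schema: CohortSchema) -> None:
        obs, act = set(self.observation_variables), set(self.action_variables)
        if obs & act:
            raise SchemaError("observation and action variables overlap")
        known = set(schema.variable_names)
        unknown = (obs | act) - known
        if unknown:
            raise SchemaError(f"unknown variables: {sorted(unknown)}")
        if not 0.0 <= self.discount < 1.0:
            raise SchemaError("discount must lie in [0, 1)")
        if not 0.0 <= self.bcq_threshold <= 1.0:
            raise SchemaError("bcq_threshold must lie in [0, 1]")


def default_problem(schema: CohortSchema) -> RLProblemSpec:
    """The published observation/action splits for the bundled cohorts."""
    presets = {
        "hypotension": (("Fluid Boluses", "Vasopressors"), "hypotension"),
        "sepsis": (("Input 4H", "Max Vaso"), "sepsis"),
        "hiv": (("Base Drug Combo", "Comp. NNRTI"), "hiv"),
    }
    if schema.name not in presets:
        raise SchemaError(f"no default RL problem for schema {schema.name!r}")
    actions, reward = presets[schema.name]
    obs = [n for n in schema.variable_names if n not in actions]
    return RLProblemSpec(obs, list(actions), reward=reward)


# ---------------------------------------------------------------------------
# observation reduction and state clustering
# ---------------------------------------------------------------------------

class ObservationReducer:
    """Cross-decomposition reducer fitted on real data, applicable to both."""

    def __init__(self, spec: RLProblemSpec, schema: CohortSchema,
                 transform_spec: Optional[TransformSpec] = None):
        self.spec = spec
        self.schema = schema
        self.transform_spec = transform_spec
        self._pls = None
        self._obs_channels: Optional[np.ndarray] = None

    def _obs_matrix(self, dataset: LongitudinalDataset) -> np.ndarray:
        spec = self.transform_spec
        if spec is None:
            spec = fit_transforms(dataset)
            self.transform_spec = spec
        batch = encode(dataset, spec)
        if self._obs_channels is None:
            cols = []
            for ch in batch.channel_map.channels:
                if ch.name in self.spec.observation_variables:
                    cols.extend(range(ch.start, ch.stop))
            self._obs_channels = np.array(cols, dtype=int)
        return batch.pooled()[:, self._obs_channels]

    def fit(self, real: LongitudinalDataset, actions: np.ndarray) -> np.ndarray:
        """Fit against the one-hot action matrix; returns latent scores."""
        from sklearn.cross_decomposition import PLSRegression

        X = self._obs_matrix(real)
        n_actions = int(actions.max()) + 1 if len(actions) else 1
        Y = np.zeros((len(actions), n_actions))
        Y[np.arange(len(actions)), actions] = 1.0
        rank = np.linalg.matrix_rank(X - X.mean(axis=0))
        k = self.spec.n_state_components
        if rank < k:
            warnings.warn(
                f"observation matrix has effective rank {rank} < "
                f"{k} requested components", stacklevel=2,
            )
            k = max(1, rank)
        self._pls = PLSRegression(n_components=k, scale=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self._pls.fit(X, Y)
        return self._pls.transform(X)

    def transform(self, dataset: LongitudinalDataset) -> np.ndarray:
        if self._pls is None:
            raise SchemaError("reducer not fitted")
        return self._pls.transform(self._obs_matrix(dataset))

    @property
    def loadings(self) -> np.ndarray:
        """Observation-side weights (channels x components)."""
        if self._pls is None:
            raise SchemaError("reducer not fitted")
        return self._pls.x_weights_


@dataclass
class StateSpace:
    labels: np.ndarray
    centroids: np.ndarray
    inertia: float

    def assign(self, scores: np.ndarray) -> np.ndarray:
        """Nearest-centroid assignment for out-of-sample rows."""
        from scipy.spatial.distance import cdist

        return cdist(scores, self.centroids).argmin(axis=1)


def cluster_states(scores: np.ndarray, n_clusters: int, seed: int = 0,
                   n_init: int = 10) -> StateSpace:
    """K-means state construction with stored centroids."""
    from sklearn.cluster import KMeans

    n_distinct = len(np.unique(scores, axis=0))
    if n_clusters > n_distinct:
        raise SchemaError(
            f"{n_clusters} clusters requested but only {n_distinct} distinct "
            "points available"
        )
    km = KMeans(n_clusters=n_clusters, n_init=n_init, random_state=seed)
    labels = km.fit_predict(scores)
    return StateSpace(labels, km.cluster_centers_, float(km.inertia_))


# ---------------------------------------------------------------------------
# action discretisation
# ---------------------------------------------------------------------------

def action_class_lists(
    dataset: LongitudinalDataset, spec: RLProblemSpec,
    bin_edges: Optional[dict] = None,
) -> Tuple[List[tuple], dict]:
    """Class labels per action variable; numeric actions are quantile-binned.

    Returns (class lists in spec order, bin edges used for numeric actions).
    """
    lists, edges = [], dict(bin_edges or {})
    for name in spec.action_variables:
        v = dataset.schema[name]
        if v.kind == NUMERIC:
            if name not in edges:
                qs = np.linspace(0, 100, spec.action_bins + 1)[1:-1]
                edges[name] = np.unique(np.percentile(dataset.column(name).astype(float), qs))
            lists.append(tuple(f"bin{k}" for k in range(len(edges[name]) + 1)))
        else:
            lists.append(v.classes)
    return lists, edges


def discretize_actions(
    dataset: LongitudinalDataset, spec: RLProblemSpec,
    bin_edges: Optional[dict] = None,
) -> Tuple[np.ndarray, List[tuple], dict]:
    """Mixed-radix action index per record, row-major in spec order.

    The index is bijective with the class tuple:
    ``index = c_0 * (K_1 * K_2 * ...) + c_1 * (K_2 * ...) + ...``.
    """
    lists, edges = action_class_lists(dataset, spec, bin_edges)
    radices = [len(c) for c in lists]
    idx = np.zeros(len(dataset), dtype=int)
    for name, classes in zip(spec.action_variables, lists):
        v = dataset.schema[name]
        if v.kind == NUMERIC:
            codes = np.searchsorted(edges[name], dataset.column(name).astype(float),
                                    side="right")
        else:
            codes = dataset.coded_column(name).astype(int)
        idx = idx * len(classes) + codes
    return idx, lists, edges


def n_actions_of(class_lists: List[tuple]) -> int:
    out = 1
    for c in class_lists:
        out *= len(c)
    return out


# ---------------------------------------------------------------------------
# rewards (pluggable; bundled defaults are labelled stand-ins)
# ---------------------------------------------------------------------------

def reward_zero(obs_now: dict, obs_next: dict, params: dict) -> float:
    return 0.0


def reward_hypotension(obs_now: dict, obs_next: dict, params: dict) -> float:
    """Stand-in: +1 when next-step MAP is at or above target (default
    65 mmHg), otherwise a penalty scaled by the shortfall."""
    target = params.get("map_target", 65.0)
    scale = params.get("penalty_scale", 0.1)
    m = float(obs_next.get("MAP", obs_now.get("MAP", target)))
    return 1.0 if m >= target else -scale * (target - m)

def reward_sepsis(obs_now: dict, obs_next: dict, params: dict) -> float:
    """Stand-in: negative change of an acuity proxy (default: Lactate);
    improvement (falling lactate) is rewarded."""
    var = params.get("acuity_variable", "Lactate")
    scale = params.get("scale", 1.0)
    return -scale * (float(obs_next[var]) - float(obs_now[var]))


def reward_hiv(obs_now: dict, obs_next: dict, params: dict) -> float:
    """Stand-in: +1 when next-step viral load is below the suppression
    threshold (default 1000 copies/mL), else a fixed penalty."""
    thr = params.get("vl_threshold", 1000.0)
    penalty = params.get("penalty", 0.7)
    return 1.0 if float(obs_next["VL"]) < thr else -penalty


REWARD_REGISTRY: Dict[str, Callable] = {
    "zero": reward_zero,
    "hypotension": reward_hypotension,
    "sepsis": reward_sepsis,
    "hiv": reward_hiv,
}


# ---------------------------------------------------------------------------
# transitions and batch-constrained Q-learning
# ---------------------------------------------------------------------------

@dataclass
class TransitionBatch:
    state: np.ndarray
    action: np.ndarray
    reward: np.ndarray
    next_state: np.ndarray
    terminal: np.ndarray
    n_states: int
    n_actions: int

    def __len__(self) -> int:
        return len(self.state)


def build_transitions(
    dataset: LongitudinalDataset,
    spec: RLProblemSpec,
    states: np.ndarray,
    actions: np.ndarray,
    n_states: int,
    n_actions: int,
    reward_fn: Optional[Callable] = None,
) -> TransitionBatch:
    """Consecutive-timestep (s, a, r, s') tuples within each patient.

    The final timestep of each patient is terminal; rewards are evaluated
    on the observation rows bracketing each transition.
    """
    T = dataset.schema.timesteps_per_patient
    n = dataset.n_patients
    if n == 0:
        z = np.zeros(0, dtype=int)
        return TransitionBatch(z, z, z.astype(float), z, z.astype(bool),
                               n_states, n_actions)
    reward_fn = reward_fn or REWARD_REGISTRY[spec.reward]
    obs_names = list(spec.observation_variables)
    cols = {m: dataset.column(m) for m in obs_names}
    s = states.reshape(n, T)
    a = actions.reshape(n, T)
    rows = []
    for m in obs_names:
        rows.append(cols[m].reshape(n, T))

    st, at, rt, nt, done = [], [], [], [], []
    for p in range(n):
        for t in range(T - 1):
            o_now = {m: rows[i][p, t] for i, m in enumerate(obs_names)}
            o_next = {m: rows[i][p, t + 1] for i, m in enumerate(obs_names)}
            st.append(s[p, t])
            at.append(a[p, t])
            rt.append(reward_fn(o_now, o_next, spec.reward_params))
            nt.append(s[p, t + 1])
            done.append(t + 1 == T - 1)
    return TransitionBatch(
        np.array(st), np.array(at), np.array(rt, dtype=float), np.array(nt),
        np.array(done, dtype=bool), n_states, n_actions,
    )


@dataclass
class TabularPolicy:
    Q: np.ndarray
    eligible: np.ndarray  # boolean (n_states, n_actions)
    greedy: np.ndarray    # action per state; -1 where undefined
    n_undefined: int

    def action(self, state: int) -> int:
        a = int(self.greedy[state])
        if a < 0:
            raise SchemaError(f"policy undefined in state {state}")
        return a


def bcq_train(batch: TransitionBatch, spec: RLProblemSpec) -> TabularPolicy:
    """Tabular batch-constrained Q-learning.

    ``spec.n_iterations`` full sweeps over the batch in fixed order with
    learning rate ``spec.step_size``; the bootstrap maximum and the greedy
    policy range only over actions whose empirical frequency in a state
    reaches ``bcq_threshold`` (and that were observed at least once).
    States never visited have no eligible actions; the policy is undefined
    there and such states are excluded from heatmaps (count reported).
    Ties break to the lowest action index.
    """
    nS, nA = batch.n_states, batch.n_actions
    counts = np.zeros((nS, nA))
    np.add.at(counts, (batch.state, batch.action), 1.0)
    visits = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(visits > 0, counts / visits, 0.0)
    eligible = (counts > 0) & (freq >= spec.bcq_threshold)
    # a visited state always keeps at least its majority action
    visited = visits[:, 0] > 0
    none_left = visited & ~eligible.any(axis=1)
    if none_left.any():
        top = counts[none_left].argmax(axis=1)
        eligible[np.flatnonzero(none_left), top] = True

    Q = np.zeros((nS, nA))
    gamma, lr = spec.discount, spec.step_size
    neg = np.where(eligible, 0.0, -np.inf)
    for _ in range(spec.n_iterations):
        # sequential updates in fixed batch order; each bootstrap target
        # uses the current Q restricted to the eligible actions of s'
        for s, a, r, ns, term in zip(
            batch.state, batch.action, batch.reward,
            batch.next_state, batch.terminal,
        ):
            if term:
                tgt = r
            else:
                m = np.max(Q[ns] + neg[ns])
                tgt = r + gamma * (m if np.isfinite(m) else 0.0)
            Q[s, a] += lr * (tgt - Q[s, a])

    masked = np.where(eligible, Q, -np.inf)
    greedy = np.where(eligible.any(axis=1), masked.argmax(axis=1), -1)
    return TabularPolicy(Q, eligible, greedy, int((greedy < 0).sum()))


def plain_q_train(batch: TransitionBatch, spec: RLProblemSpec) -> np.ndarray:
    """Unconstrained tabular Q-learning (the bcq_threshold = 0, all-actions
    -observed special case); used as an independent cross-check."""
    nS, nA = batch.n_states, batch.n_actions
    Q = np.zeros((nS, nA))
    gamma, lr = spec.discount, spec.step_size
    for _ in range(spec.n_iterations):
        for s, a, r, ns, term in zip(
            batch.state, batch.action, batch.reward,
            batch.next_state, batch.terminal,
        ):
            tgt = r if term else r + gamma * Q[ns].max()
            Q[s, a] += lr * (tgt - Q[s, a])
    return Q


# ---------------------------------------------------------------------------
# heatmaps
# ---------------------------------------------------------------------------

@dataclass
class PolicyHeatmap:
    """Relative action frequencies (%) on the action-variable grid."""

    grid: np.ndarray
    class_lists: List[tuple]
    action_variables: List[str]
    n_undefined_states: int = 0

    def __post_init__(self):
        if len(self.grid.shape) != len(self.class_lists):
            raise SchemaError("heatmap grid rank does not match action variables")
        total = float(self.grid.sum())
        if self.grid.size and abs(total - 100.0) > 0.01:
            raise SchemaError(f"heatmap tiles sum to {total}, expected 100")

    @property
    def flat(self) -> np.ndarray:
        return self.grid.reshape(-1)


def action_heatmap(
    policy: TabularPolicy,
    states: np.ndarray,
    class_lists: List[tuple],
    action_variables: List[str],
) -> PolicyHeatmap:
    """Evaluate the greedy policy on every dataset row and tabulate the
    chosen actions as percentages on the action grid."""
    acts = policy.greedy[states]
    defined = acts >= 0
    n_undef = int((~defined).sum())
    acts = acts[defined]
    nA = n_actions_of(class_lists)
    counts = np.bincount(acts, minlength=nA).astype(float)
    if counts.sum() == 0:
        raise SchemaError("no defined policy actions to tabulate")
    shares = 100.0 * counts / counts.sum()
    grid = shares.reshape([len(c) for c in class_lists])
    return PolicyHeatmap(grid, class_lists, list(action_variables), n_undef)


@dataclass
class HeatmapComparison:
    tile_abs_diff: np.ndarray
    total_variation: float
    largest_gaps: list  # [(action labels tuple, real %, syn %), ...]

    def summary(self) -> str:
        lines = [f"Policy heatmap comparison: TV distance = "
                 f"{self.total_variation:.4f}"]
        for labels, r, s in self.largest_gaps[:5]:
            lines.append(f"  {labels}: real {r:.2f}% vs synthetic {s:.2f}%")
        return "\n".join(lines)


def compare_heatmaps(h_real: PolicyHeatmap, h_syn: PolicyHeatmap) -> HeatmapComparison:
    """Per-tile absolute gaps, total-variation distance, ranked mismatches."""
    if h_real.grid.shape != h_syn.grid.shape:
        raise SchemaError("heatmap shapes differ")
    diff = np.abs(h_real.grid - h_syn.grid)
    tv = float(diff.sum() / 2.0 / 100.0)
    order = np.argsort(diff.reshape(-1))[::-1]
    gaps = []
    for k in order:
        idx = np.unravel_index(k, diff.shape)
        labels = tuple(h_real.class_lists[d][i] for d, i in enumerate(idx))
        gaps.append((labels, float(h_real.grid[idx]), float(h_syn.grid[idx])))
    return HeatmapComparison(diff, tv, gaps)


# ---------------------------------------------------------------------------
# end-to-end convenience
# ---------------------------------------------------------------------------

@dataclass
class UtilityReport:
    heatmap_real: PolicyHeatmap
    heatmap_syn: PolicyHeatmap
    comparison: HeatmapComparison

    def summary(self) -> str:
        return self.comparison.summary()


def verify_utility(
    real: LongitudinalDataset,
    syn: LongitudinalDataset,
    spec: Optional[RLProblemSpec] = None,
    seed: int = 0,
) -> UtilityReport:
    """Train real- and synthetic-data agents over a shared state space and
    compare their action-frequency heatmaps.

    The observation reducer, K-means centroids and numeric-action bin edges
    are fitted on the real cohort and reused for the synthetic one, so both
    agents act over identical discrete spaces.
    """
    spec = spec or default_problem(real.schema)
    spec.validate(real.schema)
    a_real, class_lists, edges = discretize_actions(real, spec)
    nA = n_actions_of(class_lists)

    reducer = ObservationReducer(spec, real.schema)
    scores_real = reducer.fit(real, a_real)
    space = cluster_states(scores_real, spec.n_clusters, seed=seed)
    s_real = space.labels

    scores_syn = reducer.transform(syn)
    s_syn = space.assign(scores_syn)
    a_syn, _, _ = discretize_actions(syn, spec, bin_edges=edges)

    nS = spec.n_clusters
    batch_real = build_transitions(real, spec, s_real, a_real, nS, nA)
    batch_syn = build_transitions(syn, spec, s_syn, a_syn, nS, nA)
    pol_real = bcq_train(batch_real, spec)
    pol_syn = bcq_train(batch_syn, spec)

    h_real = action_heatmap(pol_real, s_real, class_lists, spec.action_variables)
    h_syn = action_heatmap(pol_syn, s_real, class_lists, spec.action_variables)
    return UtilityReport(h_real, h_syn, compare_heatmaps(h_real, h_syn))
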