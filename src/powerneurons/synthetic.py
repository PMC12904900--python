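"""Synthetic labeled connectomes with ground truth.

The generator emulates the statistical structure the analysis relies on in
real insect connectomes: two mirrored hemispheres with homolog pairs, a
handful of neuronal groups wired by a directed block model, heavy-tailed
degrees from log-normal per-node propensities, a planted set of boosted,
densely interwired hub neurons (the backbone the power-neuron detector
should recover), and optionally planted motif instances. Every random
choice flows from one integer seed.

The left hemisphere is sampled first and mirrored onto the right by graph
copy and relabeling, so homolog semantics are exact ground truth; a
``mirror_noise`` fraction of right-hemisphere arcs is then rewired to decay
the symmetry, and cross-hemisphere arcs are added preferentially between
nodes of the same group (which includes every homolog partner pair).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import Connectome, NodeRecord, ValidationError
from .motifs import ConnectomeMotif

DEFAULT_GROUPS: list[tuple[str, float]] = [
    ("sensory", 0.22),
    ("ascending", 0.08),
    ("innate", 0.15),
    ("learning/memory", 0.15),
    ("deep brain", 0.20),
    ("pre-output", 0.12),
    ("brain outputs", 0.08),
]


def default_block_matrix(n_groups: int, within: float = 0.05, forward: float = 0.02, background: float = 0.008) -> np.ndarray:
    """Feedforward-flavored block probabilities.

    Within-group wiring is densest, one-step-forward wiring (sensory toward
    outputs in the default group ordering) intermediate, everything else a
    low background rate.
    """
    block = np.full((n_groups, n_groups), background)
    for i in range(n_groups):
        block[i, i] = within
        if i + 1 < n_groups:
            block[i, i + 1] = forward
    return block


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults define the reference study conditions."""

    n_per_hemisphere: int = 500
    groups: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_GROUPS)
    )
    base_block_prob: np.ndarray | None = None  # group x group, row=source
    degree_propensity: tuple[float, float] = (0.0, 1.0)  # lognormal (mu, sigma)
    hub_fraction: float = 0.05
    hub_boost: float = 6.0
    hub_hub_prob: float = 0.3
    mirror_noise: float = 0.05
    cross_hemisphere_prob: float = 0.01
    cross_group_damping: float = 0.2  # cross-hemisphere factor for unlike groups
    unlabeled_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_block_prob is None:
            self.base_block_prob = default_block_matrix(len(self.groups))
        self.base_block_prob = np.asarray(self.base_block_prob, dtype=float)
        self.validate()

    def validate(self) -> None:
        proportions = [p for _, p in self.groups]
        if abs(sum(proportions) - 1.0) > 1e-9:
            raise ValidationError("group proportions must sum to 1")
        if self.n_per_hemisphere < len(self.groups):
            raise ValidationError("need at least one node per group")
        if self.base_block_prob.shape != (len(self.groups), len(self.groups)):
            raise ValidationError("base_block_prob must be group x group")
        for name, value in (
            ("base_block_prob", self.base_block_prob),
            ("hub_hub_prob", self.hub_hub_prob),
            ("mirror_noise", self.mirror_noise),
            ("cross_hemisphere_prob", self.cross_hemisphere_prob),
        ):
            arr = np.asarray(value)
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValidationError(f"{name} must lie in [0, 1]")
        if not 0 <= self.hub_fraction < 1:
            raise ValidationError("hub_fraction must lie in [0, 1)")
        if self.hub_boost < 1:
            raise ValidationError("hub_boost must be >= 1")
        if not 0 <= self.unlabeled_fraction < 1:
            raise ValidationError("unlabeled_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    planted_hub_ids: set[str]
    homolog_pairs: list[tuple[str, str]]
    planted_motifs: list[tuple[str, ConnectomeMotif]] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "planted_hub_ids": sorted(self.planted_hub_ids),
            "homolog_pairs": self.homolog_pairs,
            "planted_motifs": [
                {
                    "core_id": core,
                    "core_group": m.core_group,
                    "in_groups": sorted(m.in_groups),
                    "out_groups": sorted(m.out_groups),
                }
                for core, m in self.planted_motifs
            ],
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def _group_assignment(config: SyntheticConfig) -> np.ndarray:
    """Deterministic per-node group indices honoring the proportions."""
    n = config.n_per_hemisphere
    raw = np.array([p * n for _, p in config.groups])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    by_frac = np.argsort(-(raw - counts))
    for i in range(remainder):
        counts[by_frac[i % len(counts)]] += 1
    return np.repeat(np.arange(len(config.groups)), counts)


def generate_connectome(config: SyntheticConfig) -> tuple[Connectome, GroundTruth]:
    """Sample one labeled connectome plus its ground truth.

    Arc probability for an ordered intra-hemisphere pair (i, j) is
    ``min(1, block[g_i, g_j] * out_prop_i * in_prop_j * boost_i * boost_j)``
    with log-normal propensities and a ``hub_boost`` multiplier on planted
    hubs; hub pairs additionally wire directly with ``hub_hub_prob``. The
    clipping at 1 slightly biases the extreme upper tail.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_per_hemisphere
    group_idx = _group_assignment(config)
    group_names = [name for name, _ in config.groups]

    mu, sigma = config.degree_propensity
    out_prop = rng.lognormal(mu, sigma, n)
    in_prop = rng.lognormal(mu, sigma, n)
    # lognormal median is exp(mu); rescale so the median propensity is 1 and
    # base_block_prob keeps its meaning as the typical-pair arc probability
    out_prop /= np.exp(mu)
    in_prop /= np.exp(mu)

    n_hubs = int(config.hub_fraction * n)
    hubs = np.sort(rng.choice(n, size=n_hubs, replace=False))
    boost = np.ones(n)
    boost[hubs] = config.hub_boost

    prob = (
        config.base_block_prob[group_idx[:, None], group_idx[None, :]]
        * (out_prop * boost)[:, None]
        * (in_prop * boost)[None, :]
    )
    np.fill_diagonal(prob, 0.0)
    if prob.sum() > n * (n - 1):
        raise ValidationError(
            "infeasible config: expected arc count exceeds n(n-1)"
        )
    adj_left = rng.random((n, n)) < np.minimum(prob, 1.0)
    np.fill_diagonal(adj_left, False)
    if n_hubs > 1 and config.hub_hub_prob > 0:
        hub_extra = rng.random((n_hubs, n_hubs)) < config.hub_hub_prob
        np.fill_diagonal(hub_extra, False)
        adj_left[np.ix_(hubs, hubs)] |= hub_extra

    # mirror, then decay the symmetry
    adj_right = adj_left.copy()
    if config.mirror_noise > 0:
        sources, targets = np.nonzero(adj_right)
        rewire = rng.random(sources.size) < config.mirror_noise
        n_rewired = int(rewire.sum())
        adj_right[sources[rewire], targets[rewire]] = False
        added = 0
        while added < n_rewired:
            u = int(rng.integers(n))
            v = int(rng.integers(n))
            if u != v and not adj_right[u, v]:
                adj_right[u, v] = True
                added += 1

    same_group = group_idx[:, None] == group_idx[None, :]
    cross_prob = config.cross_hemisphere_prob * np.where(
        same_group, 1.0, config.cross_group_damping
    )
    adj_lr = rng.random((n, n)) < cross_prob  # left -> right
    adj_rl = rng.random((n, n)) < cross_prob  # right -> left

    n_unlabeled = int(config.unlabeled_fraction * n)
    unlabeled = set(rng.choice(n, size=n_unlabeled, replace=False).tolist())

    left_ids = [f"L{i:04d}" for i in range(n)]
    right_ids = [f"R{i:04d}" for i in range(n)]
    connectome = Connectome(stage_label="synthetic")
    for ids, side in ((left_ids, "left"), (right_ids, "right")):
        for i, node_id in enumerate(ids):
            partner = (right_ids if side == "left" else left_ids)[i]
            connectome.add_node(
                NodeRecord(
                    id=node_id,
                    group=None if i in unlabeled else group_names[group_idx[i]],
                    side=side,
                    homolog_id=partner,
                    extra={"cell_type": f"{group_names[group_idx[i]]}#{i:04d}"},
                )
            )
    for u, v in zip(*np.nonzero(adj_left)):
        connectome.add_arc(left_ids[u], left_ids[v])
    for u, v in zip(*np.nonzero(adj_right)):
        connectome.add_arc(right_ids[u], right_ids[v])
    for u, v in zip(*np.nonzero(adj_lr)):
        connectome.add_arc(left_ids[u], right_ids[v])
    for u, v in zip(*np.nonzero(adj_rl)):
        connectome.add_arc(right_ids[u], left_ids[v])

    truth = GroundTruth(
        planted_hub_ids={left_ids[i] for i in hubs} | {right_ids[i] for i in hubs},
        homolog_pairs=[(left_ids[i], right_ids[i]) for i in range(n)],
    )
    return connectome, truth


def exchangeable_null_connectome(seed: int) -> tuple[Connectome, set[str]]:
    """A connectome whose group labels carry no information, for calibration.

    Generates a dense, homogeneous two-hemisphere graph (three equal
    groups, uniform block probability 0.10, mild propensity spread, no
    hubs) and then overwrites every group label with a uniform random
    draw, so labels are exchangeable by construction. Wiring this dense
    keeps motif signatures coarse — every high-degree core sees all three
    groups on both sides — so the QAP null distribution of each observed
    key is non-degenerate. Returns the connectome and the core set
    (top 20% of nodes by total degree) on which motif calibration runs.
    """
    groups3 = [("alpha", 0.34), ("beta", 0.33), ("gamma", 0.33)]
    config = SyntheticConfig(
        n_per_hemisphere=150,
        groups=groups3,
        base_block_prob=np.full((3, 3), 0.10),
        degree_propensity=(0.0, 0.3),
        hub_fraction=0.0,
        hub_hub_prob=0.0,
        mirror_noise=0.05,
        cross_hemisphere_prob=0.02,
        unlabeled_fraction=0.0,
        seed=seed,
    )
    connectome, _ = generate_connectome(config)
    rng = np.random.default_rng(seed)
    names = [g for g, _ in groups3]
    for rec in connectome.records():
        rec.group = names[rng.integers(len(names))]
    degree = dict(connectome.graph.degree())
    cores = set(sorted(degree, key=lambda v: (-degree[v], v))[:60])
    return connectome, cores


def plant_motifs(
    connectome: Connectome,
    core_group: str,
    in_groups: set[str],
    out_groups: set[str],
    count: int,
    seed: int = 0,
) -> tuple[Connectome, list[str]]:
    """Force ``count`` core neurons to carry exactly the requested motif.

    For each selected core of ``core_group``: arcs to and from labeled
    neighbors outside the requested group sets are removed, and one arc per
    missing input (output) group is added from (to) a random member of that
    group. Unlabeled neighbors are untouched — they are invisible to the
    motif signature. Returns a modified copy and the chosen core ids.
    """
    groups = connectome.groups()
    for g in {core_group} | set(in_groups) | set(out_groups):
        if g not in groups:
            raise ValidationError(f"group {g!r} not present in the connectome")
    eligible = sorted(
        rec.id for rec in connectome.records() if rec.group == core_group
    )
    if count > len(eligible):
        raise ValidationError(
            f"cannot plant {count} motifs: only {len(eligible)} nodes in "
            f"group {core_group!r}"
        )
    if count == 0:
        return connectome.copy(), []
    rng = np.random.default_rng(seed)
    cores = sorted(rng.choice(eligible, size=count, replace=False).tolist())
    by_group: dict[str, list[str]] = {}
    for rec in connectome.records():
        if rec.group is not None:
            by_group.setdefault(rec.group, []).append(rec.id)

    result = connectome.copy()
    graph = result.graph
    for core in cores:
        for nbr in list(graph.predecessors(core)):
            g = result.record(nbr).group
            if g is not None and g not in in_groups:
                graph.remove_edge(nbr, core)
        for nbr in list(graph.successors(core)):
            g = result.record(nbr).group
            if g is not None and g not in out_groups:
                graph.remove_edge(core, nbr)
        for g in sorted(in_groups):
            present = any(
                result.record(p).group == g for p in graph.predecessors(core)
            )
            if not present:
                candidates = [v for v in by_group[g] if v != core]
                if not candidates:
                    raise ValidationError(f"no candidate in-neighbor in group {g!r}")
                graph.add_edge(candidates[int(rng.integers(len(candidates)))], core)
        for g in sorted(out_groups):
            present = any(
                result.record(s).group == g for s in graph.successors(core)
            )
            if not present:
                candidates = [v for v in by_group[g] if v != core]
                if not candidates:
                    raise ValidationError(f"no candidate out-neighbor in group {g!r}")
                graph.add_edge(core, candidates[int(rng.integers(len(candidates)))])
    return result, cores
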