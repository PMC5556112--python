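"""Seeded synthetic drug-target datasets with known ground truth.

Real PU screening corpora are large and external; this module emulates
their structure at desk scale so every pipeline stage is testable: rare
true interactions, an unlabeled pool hiding most of them, and mixed
binary/continuous high-dimensional features of which only a subset is
class-discriminative.

The affinity model draws latent vectors for drugs and targets, scores
every pair with a logistic function of the latent dot product, and marks
the top ``positive_rate`` fraction of pairs as truly interacting — a
simple, fully controllable class geometry. Only ``label_rate`` of the
true interactions are revealed as known positives; the rest hide inside
the unlabeled pool, exactly the situation reliable-negative extraction
has to cope with.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import FeatureTable, PairTable
from .weighting import PrototypeSet


@dataclass
class SyntheticSpec:
    """Generator settings; defaults are the package's study conditions."""

    n_drugs: int = 200
    n_targets: int = 50
    n_features: int = 50
    n_informative: int = 15
    positive_rate: float = 0.03
    label_rate: float = 0.3
    effect_size: float = 1.0
    noise_sd: float = 1.0
    binary_fraction: float = 0.4
    latent_dim: int = 4
    seed: int = 11

    def __post_init__(self) -> None:
        if not 0 < self.positive_rate < 1:
            raise ValueError("positive_rate must be in (0, 1)")
        if not 0 < self.label_rate <= 1:
            raise ValueError("label_rate must be in (0, 1]")
        if self.n_informative > self.n_features:
            raise ValueError("n_informative cannot exceed n_features")
        if not 0 <= self.binary_fraction <= 1:
            raise ValueError("binary_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SyntheticDataset:
    """Generated pairs, features and the generator's own bookkeeping."""

    pairs: PairTable
    features: FeatureTable
    truth: np.ndarray  # 1 = truly interacting, 0 = truly not
    spec: SyntheticSpec

    @property
    def known_mask(self) -> np.ndarray:
        return self.pairs.labels == 1

    @property
    def hidden_positive_mask(self) -> np.ndarray:
        return (self.truth == 1) & (self.pairs.labels == 0)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw a synthetic PU dataset; identical spec+seed gives identical data."""
    rng = np.random.default_rng(spec.seed)
    n_pairs = spec.n_drugs * spec.n_targets

    # latent affinity -> top positive_rate fraction truly interacts
    du = rng.normal(size=(spec.n_drugs, spec.latent_dim))
    tv = rng.normal(size=(spec.n_targets, spec.latent_dim))
    affinity = 1.0 / (
        1.0 + np.exp(-(du @ tv.T) / np.sqrt(spec.latent_dim))
    ).ravel()
    n_true = max(1, int(round(spec.positive_rate * n_pairs)))
    truth = np.zeros(n_pairs, dtype=int)
    truth[np.argsort(affinity)[::-1][:n_true]] = 1

    # per-entity base features: drug block then target block
    n_drug_feat = spec.n_features // 2
    n_target_feat = spec.n_features - n_drug_feat
    n_binary = int(round(spec.binary_fraction * spec.n_features))
    binary_cols = rng.choice(spec.n_features, size=n_binary, replace=False)
    is_binary = np.zeros(spec.n_features, dtype=bool)
    is_binary[binary_cols] = True

    def base_block(n_entities: int, n_feat: int, offset: int) -> np.ndarray:
        block = rng.normal(size=(n_entities, n_feat))
        bin_here = is_binary[offset:offset + n_feat]
        block[:, bin_here] = rng.random((n_entities, bin_here.sum())) < 0.3
        return block

    drug_feat = base_block(spec.n_drugs, n_drug_feat, 0)
    target_feat = base_block(spec.n_targets, n_target_feat, n_drug_feat)

    d_idx, t_idx = np.divmod(np.arange(n_pairs), spec.n_targets)
    X = np.hstack([drug_feat[d_idx], target_feat[t_idx]])

    # pair-level noise: gaussian on continuous coords, rare flips on binary
    cont = ~is_binary
    X[:, cont] += spec.noise_sd * rng.normal(size=(n_pairs, cont.sum()))
    flips = rng.random((n_pairs, is_binary.sum())) < 0.02
    X[:, is_binary] = np.abs(X[:, is_binary] - flips)

    # class signal on a deterministic informative subset (both kinds)
    informative = np.linspace(
        0, spec.n_features - 1, spec.n_informative, dtype=int
    )
    pos = truth == 1
    for j in informative:
        if is_binary[j]:
            p_pos = min(0.3 + 0.25 * spec.effect_size, 0.95)
            X[pos, j] = (rng.random(pos.sum()) < p_pos).astype(float)
        else:
            X[pos, j] += spec.effect_size

    # reveal only label_rate of the true interactions
    true_idx = np.flatnonzero(truth)
    n_hidden = int(np.floor((1.0 - spec.label_rate) * n_true))
    hidden = rng.choice(true_idx, size=n_hidden, replace=False)
    labels = truth.copy()
    labels[hidden] = 0

    drug_ids = [f"D{i:04d}" for i in d_idx]
    target_ids = [f"T{i:04d}" for i in t_idx]
    pairs = PairTable(drug_ids, target_ids, labels)
    features = FeatureTable(pairs.pair_ids, X)
    return SyntheticDataset(pairs=pairs, features=features, truth=truth,
                            spec=spec)


# ---------------------------------------------------------------------------
# Worked local-weight fixture: four ambiguous clusters around the diagonal
# ---------------------------------------------------------------------------


@dataclass
class LocalWeightFixture:
    """2-D ambiguous-sample configuration with known local weights.

    Four well-separated point clusters (M1..M4) straddle the diagonal
    decision boundary between a positive prototype along (1, 0) and a
    negative prototype along (0, 1): M1 lies entirely on the positive
    side, M2 splits 5 positive-tagged / 7 negative, M3 splits 7 / 3, and
    M4 is entirely negative, so the expected cluster-shared local weight
    pairs are (1, 0), (5/12, 7/12), (7/10, 3/10) and (0, 1).
    """

    points: np.ndarray
    cluster_of: np.ndarray  # 0..3 for M1..M4
    prototypes: PrototypeSet
    expected: dict[int, tuple[float, float]] = field(default_factory=dict)
    rn_size: int = 247  # with t=30 and 38 ambiguous points -> 4 clusters
    t: int = 30


_M1 = [(-0.2, -0.15), (-0.2, 0.15), (0.2, -0.15), (0.2, 0.15),
       (0.0, 0.2), (0.0, -0.2), (0.25, 0.0), (-0.25, 0.0)]
_M2_POS = [(0.4, -0.2), (0.3, -0.3), (0.5, 0.1), (0.2, -0.1), (0.35, 0.05)]
_M2_NEG = [(-0.2, 0.4), (-0.3, 0.3), (0.1, 0.5), (-0.1, 0.2), (0.05, 0.35),
           (-0.25, 0.15), (-0.05, 0.45)]
_M3_POS = [(0.3, -0.2), (0.2, -0.3), (0.4, 0.0), (0.1, -0.15), (0.25, -0.05),
           (0.35, -0.25), (0.15, -0.35)]
_M3_NEG = [(-0.2, 0.3), (-0.3, 0.2), (-0.05, 0.25)]
_M4 = [(-0.15, -0.2), (0.15, -0.2), (-0.15, 0.2), (0.15, 0.2),
       (0.2, 0.0), (-0.2, 0.0), (0.0, 0.25), (0.0, -0.25)]


def fig11_fixture(seed: int = 0) -> LocalWeightFixture:
    """Build the packaged worked example for local similarity weights.

    The configuration is deterministic; ``seed`` only feeds the k-means
    stream of any downstream clustering call.
    """
    centers = {
        0: (5.0, 0.9),   # M1: all positive-tagged
        1: (6.0, 6.0),   # M2: 5 of 12 positive
        2: (1.5, 1.5),   # M3: 7 of 10 positive
        3: (0.9, 5.0),   # M4: all negative
    }
    offsets = {
        0: _M1,
        1: _M2_POS + _M2_NEG,
        2: _M3_POS + _M3_NEG,
        3: _M4,
    }
    points, cluster_of = [], []
    for cid, offs in offsets.items():
        cx, cy = centers[cid]
        for ox, oy in offs:
            points.append((cx + ox, cy + oy))
            cluster_of.append(cid)
    prototypes = PrototypeSet(
        positives=np.array([[1.0, 0.0]]), negatives=np.array([[0.0, 1.0]])
    )
    expected = {
        0: (1.0, 0.0),
        1: (5 / 12, 7 / 12),
        2: (7 / 10, 3 / 10),
        3: (0.0, 1.0),
    }
    return LocalWeightFixture(
        points=np.array(points),
        cluster_of=np.array(cluster_of),
        prototypes=prototypes,
        expected=expected,
    )
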