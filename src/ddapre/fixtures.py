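"""Self-contained toy inputs with the statistical structure the pipeline assumes.

Three generators: parseable toy SMILES from a fragment grammar, toy MeSH
TreeNumber codes drawn from a random rooted tree (so siblings share
ancestor prefixes), and a planted-signal pair dataset in which a known
subset of feature dimensions carries a class mean shift. The planted
mean-shift Gaussian model makes one-way ANOVA F-values analytically
predictable and gives classifiers a recoverable signal.

The default scale mirrors the benchmark inventory at one tenth of its
size (27 drugs x 60 diseases) with the same positive share (11.4%, a
roughly 1:7.7 positive:negative imbalance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from ddapre.io_formats import (
    AssociationTable,
    DiseaseRecord,
    DrugRecord,
)

PAPER_SCALE = (269, 598)
DEFAULT_SCALE = (27, 60)
DEFAULT_POSITIVE_FRACTION = 0.114


@dataclass
class FeatureMatrix:
    """Per-pair feature rows plus the label vector and pair identity."""

    X: np.ndarray
    y: np.ndarray
    drug_ids: list[str] = field(default_factory=list)
    disease_ids: list[str] = field(default_factory=list)
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.X.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class FixtureSpec:
    """Parameters of the planted-signal pair dataset."""

    n_drugs: int = DEFAULT_SCALE[0]
    n_diseases: int = DEFAULT_SCALE[1]
    positive_fraction: float = DEFAULT_POSITIVE_FRACTION
    n_features: int = 64
    planted_informative_dims: tuple[int, ...] = (0, 1, 2, 3, 4)
    effect_size: float = 3.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must lie in (0, 1)")
        if any(d < 0 or d >= self.n_features for d in self.planted_informative_dims):
            raise ValueError("planted dims out of feature index range")


# fragment grammar: backbone x functional tail, all guaranteed-parseable
_BACKBONES = ["C", "CC", "CCC", "CCCC", "CCCCC", "c1ccccc1", "C1CCCCC1"]
_TAILS = ["", "O", "N", "C(=O)O", "C(C)C", "OC", "NC", "C=C", "Cl", "Br"]


def make_toy_smiles(n: int, seed: int = 0) -> list[DrugRecord]:
    """``n`` valid toy molecules assembled from alkane / alcohol / amine /
    aromatic fragments; deterministic under seed."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        while True:
            smiles = _BACKBONES[rng.integers(len(_BACKBONES))] + _TAILS[
                rng.integers(len(_TAILS))
            ]
            if Chem.MolFromSmiles(smiles) is not None:
                break
        records.append(DrugRecord(f"DR{i:04d}", smiles))
    return records


def make_toy_mesh(
    n_diseases: int, depth: int = 3, branching: int = 3, seed: int = 0
) -> list[DiseaseRecord]:
    """Toy MeSH TreeNumbers drawn from a random rooted tree.

    The tree has ``depth`` levels below a small set of roots and up to
    ``branching`` children per node; every generated code's truncation
    parent is itself a generated internal code, and leaves under the same
    parent share their length-(depth-1) prefix. Roughly one disease in
    eight receives a second code from another branch, exercising the
    multi-code path.
    """
    if depth < 2:
        raise ValueError("depth must be >= 2")
    rng = np.random.default_rng(seed)
    # grow the code tree breadth-first until it can host n_diseases leaves
    n_roots = max(2, int(np.ceil(n_diseases ** (1.0 / depth))))
    level = [f"C{r + 1:02d}" for r in range(n_roots)]
    for _ in range(depth - 1):
        nxt = []
        for code in level:
            n_children = int(rng.integers(1, branching + 1))
            for c in range(n_children):
                nxt.append(f"{code}.{100 + c * 10 + int(rng.integers(10))}")
        level = nxt
        if len(level) >= n_diseases * 2:
            break
    while len(level) < n_diseases:
        extra = []
        for code in level:
            for c in range(branching):
                extra.append(f"{code}.{100 + c * 10 + int(rng.integers(10))}")
        level = extra
    leaves = sorted(set(level))
    chosen = sorted(rng.choice(len(leaves), size=n_diseases, replace=False))
    spare = [leaves[i] for i in range(len(leaves)) if i not in set(chosen)]
    rng.shuffle(spare)
    records = []
    for i, leaf_idx in enumerate(chosen):
        codes = [leaves[leaf_idx]]
        if spare and rng.random() < 0.125:
            codes.append(spare.pop())  # second branch, never shared
        records.append(DiseaseRecord(f"DS{i:04d}", tuple(codes)))
    return records


def make_planted_dataset(spec: FixtureSpec) -> tuple[FeatureMatrix, AssociationTable]:
    """Planted-signal pair dataset over the full drug x disease space.

    Labels are iid Bernoulli(``positive_fraction``). Features are iid
    Normal(0, ``noise_sd``^2) except on the planted dimensions, which are
    shifted by +``effect_size`` for positive pairs and -``effect_size``
    for negative pairs (class mean gap 2 x effect_size). With
    ``effect_size`` 0 the planted dimensions are indistinguishable from
    noise and downstream discrimination collapses to chance.
    """
    rng = np.random.default_rng(spec.seed)
    drug_ids = [f"DR{i:04d}" for i in range(spec.n_drugs)]
    disease_ids = [f"DS{i:04d}" for i in range(spec.n_diseases)]
    n = spec.n_drugs * spec.n_diseases
    y = (rng.random(n) < spec.positive_fraction).astype(np.int64)
    X = rng.normal(0.0, spec.noise_sd, size=(n, spec.n_features))
    shift = np.where(y == 1, spec.effect_size, -spec.effect_size)
    for dim in spec.planted_informative_dims:
        X[:, dim] += shift
    pair_drugs = [dr for dr in drug_ids for _ in disease_ids]
    pair_diseases = [di for _ in drug_ids for di in disease_ids]
    matrix = FeatureMatrix(X, y, pair_drugs, pair_diseases)
    table = AssociationTable(pair_drugs, pair_diseases, y, provenance="enumerated")
    return matrix, table
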