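"""Mol2vec-style drug embedding.

A molecule becomes a "sentence" of Morgan substructure identifiers (one
token per heavy atom per radius 0..r, in canonical atom order), the
sentences train a skip-gram model, and a molecule vector is the mean of
its substructure vectors. An optional externally supplied embedding
table (e.g. transformer-derived molecular fingerprints) can be
concatenated per drug.
"""

from __future__ import annotations

import warnings

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from ddapre.io_formats import DrugRecord, EmbeddingTable
from ddapre.skipgram import SkipGramModel, train_skipgram

DEFAULT_DIMENSION = 300
DEFAULT_WINDOW = 10
DEFAULT_RADIUS = 1


class FeaturizationError(ValueError):
    pass


def molecule_to_sentence(smiles: str, radius: int = DEFAULT_RADIUS) -> list[str]:
    """Substructure sentence: per heavy atom, the Morgan environment
    identifier at each radius 0..``radius``, in atom order.

    Identifiers are RDKit's canonical invariant hashes, so different
    SMILES spellings of the same molecule yield the same token multiset.
    Atoms whose environment at some radius is unresolvable contribute the
    sentinel token ``"UNK"`` at that radius, keeping the sentence-length
    law |tokens| = heavy_atoms * (radius + 1) intact.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(f"unparseable SMILES: {smiles!r}")
    info: dict[int, tuple[tuple[int, int], ...]] = {}
    AllChem.GetMorganFingerprint(mol, radius, bitInfo=info)
    per_atom: dict[tuple[int, int], int] = {}
    for identifier, hits in info.items():
        for atom_idx, rad in hits:
            per_atom[(atom_idx, rad)] = identifier
    sentence = []
    for atom_idx in range(mol.GetNumAtoms()):
        for rad in range(radius + 1):
            ident = per_atom.get((atom_idx, rad))
            sentence.append(str(ident) if ident is not None else "UNK")
    return sentence


def train_mol2vec(
    sentences: list[list[str]],
    dimension: int = DEFAULT_DIMENSION,
    window: int = DEFAULT_WINDOW,
    epochs: int = 5,
    min_count: int = 1,
    seed: int = 0,
) -> SkipGramModel:
    """Train substructure vectors by skip-gram on molecular sentences."""
    if not sentences:
        raise FeaturizationError("empty sentence corpus")
    return train_skipgram(
        sentences,
        dimension=dimension,
        window=window,
        epochs=epochs,
        min_count=min_count,
        seed=seed,
    )


def embed_molecule(model: SkipGramModel, sentence: list[str]) -> np.ndarray:
    """Molecule vector = arithmetic mean of in-vocabulary token vectors.

    Out-of-vocabulary tokens are skipped; an all-OOV sentence maps to the
    zero vector (with a warning) so downstream matrix shapes stay total.
    """
    if not sentence:
        raise FeaturizationError("empty sentence")
    known = [model[t] for t in sentence if t in model]
    if not known:
        warnings.warn("all tokens out of vocabulary; returning zero vector")
        return np.zeros(model.dimension)
    return np.mean(known, axis=0)


def embed_drugs(
    drugs: list[DrugRecord],
    dimension: int = DEFAULT_DIMENSION,
    window: int = DEFAULT_WINDOW,
    radius: int = DEFAULT_RADIUS,
    epochs: int = 5,
    seed: int = 0,
    model: SkipGramModel | None = None,
) -> EmbeddingTable:
    """Sentence-ize, train (unless a pre-trained model is given), embed."""
    sentences = {d.drug_id: molecule_to_sentence(d.smiles, radius) for d in drugs}
    if model is None:
        model = train_mol2vec(
            list(sentences.values()),
            dimension=dimension,
            window=window,
            epochs=epochs,
            seed=seed,
        )
    return EmbeddingTable(
        {did: embed_molecule(model, sent) for did, sent in sentences.items()},
        dimension=model.dimension,
    )


def fuse_drug_features(
    mol2vec: EmbeddingTable, external: EmbeddingTable | None = None
) -> EmbeddingTable:
    """Concatenate [substructure embedding || external embedding] per drug.

    With no external table this is the identity. Both tables must cover
    the same id set; the symmetric difference is reported otherwise.
    """
    if external is None:
        return mol2vec
    a, b = set(mol2vec.ids()), set(external.ids())
    if a != b:
        raise ValueError(
            f"id mismatch between embedding tables; symmetric difference: "
            f"{sorted(a ^ b)}"
        )
    fused = {
        did: np.concatenate([mol2vec[did], external[did]]) for did in mol2vec.ids()
    }
    return EmbeddingTable(fused, dimension=mol2vec.dimension + external.dimension)
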