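"""Similarity layers for the heterogeneous drug-target network.

Four sources of pairwise similarity feed the network:

* chemical similarity between drugs — Tanimoto (Jaccard) coefficient on
  binary fingerprints (``C_s``);
* sequence similarity between protein targets — Smith-Waterman local
  alignment scores normalized to a unit-diagonal kernel (``T_s``);
* topological similarity — Jaccard coefficient of shared interaction
  partners, for drugs (shared targets, ``C_s^n``) and for targets
  (shared drugs, ``T_s^n``);
* a blended layer per node type: ``S_d = w_d*C_s + (1-w_d)*C_s^n`` and
  ``S_t = w_t*T_s + (1-w_t)*T_s^n``.

All layers are square, symmetric, valued in [0, 1] with an exactly unit
diagonal; :class:`SimilarityLayer` enforces those invariants on
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .hetnet import InteractionTable

logger = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-12

#: residues accepted in protein sequences (20 standard amino acids + X).
VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY" + "X")


class RegistryMismatchError(ValueError):
    """Two objects that must share an id registry do not."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FingerprintTable:
    """Binary chemical fingerprints for an ordered set of drugs.

    Parameters
    ----------
    ids
        Unique drug identifiers, one per row of ``bits``.
    bits
        Boolean array of shape ``(n_drugs, width)``; ``bits[i, k]`` marks
        feature ``k`` present in drug ``i``.
    family
        Fingerprint family label: ``MACCS``, ``ECFP6``, ``PHFP4`` or
        ``EXTERNAL`` for precomputed tables.
    """

    ids: tuple[str, ...]
    bits: np.ndarray
    family: str = "EXTERNAL"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        bits = np.asarray(self.bits, dtype=bool)
        if bits.ndim != 2:
            raise ValueError("bits must be a 2-D array")
        if len(self.ids) != bits.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but {bits.shape[0]} fingerprint rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate drug ids in fingerprint table")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def width(self) -> int:
        return int(self.bits.shape[1])


@dataclass(frozen=True)
class SequenceTable:
    """Amino-acid sequences for an ordered set of targets."""

    ids: tuple[str, ...]
    residues: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        object.__setattr__(
            self, "residues", tuple(str(s).upper() for s in self.residues)
        )
        if len(self.ids) != len(self.residues):
            raise ValueError("ids and residues differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate target ids in sequence table")
        for tid, seq in zip(self.ids, self.residues):
            if not seq:
                raise ValueError(f"empty sequence for target {tid!r}")
            validate_residues(seq, label=tid)

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class SimilarityLayer:
    """Square symmetric similarity among nodes of one type.

    ``values`` is symmetric within 1e-12, entries lie in [0, 1] and the
    diagonal is exactly 1; row/column order follows ``ids``.
    """

    ids: tuple[str, ...]
    values: np.ndarray
    source: str = "external"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(str(i) for i in self.ids))
        vals = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValueError(f"values shape {vals.shape} does not match {n} ids")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate ids in similarity layer")
        if n and np.max(np.abs(vals - vals.T)) > SYMMETRY_TOL:
            raise ValueError("similarity matrix is not symmetric within 1e-12")
        if n and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ValueError("similarity values outside [0, 1]")
        if n and not np.all(np.diag(vals) == 1.0):
            raise ValueError("similarity diagonal must be exactly 1")
        vals = vals.copy()
        vals.flags.writeable = False
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.ids)

    def index_of(self, node_id: str) -> int:
        try:
            return self.ids.index(node_id)
        except ValueError:
            raise KeyError(f"unknown id {node_id!r}") from None

    def reorder(self, ids: Sequence[str]) -> "SimilarityLayer":
        """Return the layer restricted/permuted to ``ids``."""
        idx = [self.index_of(i) for i in ids]
        return SimilarityLayer(
            ids=tuple(ids),
            values=self.values[np.ix_(idx, idx)],
            source=self.source,
        )


@dataclass(frozen=True)
class BlendWeights:
    """Linear-combination weights for the blended layers.

    ``w_d`` weighs chemical against shared-target similarity for drugs and
    ``w_t`` weighs sequence against shared-drug similarity for targets; the
    benchmark optimum sits at 0.5 for both, which is the default.
    """

    w_d: float = 0.5
    w_t: float = 0.5

    def __post_init__(self) -> None:
        for name, w in (("w_d", self.w_d), ("w_t", self.w_t)):
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {w}")


@dataclass(frozen=True)
class AlignmentScoring:
    """Scoring scheme for Smith-Waterman local alignment.

    Either a named substitution matrix (default BLOSUM62) or explicit
    ``match``/``mismatch`` scores; gap penalties are affine and given as
    positive costs (open 10, extend 0.5 by default).
    """

    matrix: str | None = "BLOSUM62"
    match: float | None = None
    mismatch: float | None = None
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.matrix is None and (self.match is None or self.mismatch is None):
            raise ValueError("provide a matrix name or match/mismatch scores")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are positive costs")

    def make_aligner(self):
        from Bio import Align
        from Bio.Align import substitution_matrices

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        if self.match is not None and self.mismatch is not None:
            aligner.match_score = float(self.match)
            aligner.mismatch_score = float(self.mismatch)
        else:
            aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -float(self.gap_open)
        aligner.extend_gap_score = -float(self.gap_extend)
        return aligner


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def validate_residues(seq: str, label: str = "sequence") -> None:
    """Reject residue characters outside the 20-letter alphabet plus X."""
    bad = [(pos, ch) for pos, ch in enumerate(seq) if ch not in VALID_RESIDUES]
    if bad:
        where = ", ".join(f"{ch!r} at position {pos}" for pos, ch in bad[:5])
        raise ValueError(f"invalid residues in {label}: {where}")


def tanimoto_similarity(fp: FingerprintTable) -> SimilarityLayer:
    """Tanimoto (Jaccard) similarity between all fingerprint pairs.

    Entry (i, j) is ``C / (A + B - C)`` with ``A``, ``B`` the set-bit counts
    of the two fingerprints and ``C`` the count of shared bits.  A drug with
    no set bits makes the coefficient undefined; such rows get similarity 0
    off-diagonal (and 1 on the diagonal) with a logged warning, so the node
    stays in the network but contributes no chemical signal.
    """
    if len(fp) == 0:
        raise ValueError("empty fingerprint table")
    bits = fp.bits.astype(np.float64)
    counts = bits.sum(axis=1)  # A_i
    inter = bits @ bits.T  # C_ij
    union = counts[:, None] + counts[None, :] - inter
    empty = counts == 0
    if empty.any():
        bad = [fp.ids[i] for i in np.flatnonzero(empty)]
        logger.warning(
            "Tanimoto undefined for %d drug(s) with zero set bits: %s; "
            "assigning 0 off-diagonal",
            len(bad),
            ", ".join(bad),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(sim, 1.0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    return SimilarityLayer(ids=fp.ids, values=sim, source="chemical")


def smith_waterman_score(
    a: str, b: str, scoring: AlignmentScoring | None = None
) -> float:
    """Optimal local-alignment score of two sequences.

    Dynamic programming with affine gaps via Biopython's pairwise aligner;
    the score is symmetric in its arguments.  Sequences must be non-empty
    and use the standard amino-acid alphabet (plus X).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a, b = a.upper(), b.upper()
    validate_residues(a, "first sequence")
    validate_residues(b, "second sequence")
    scoring = scoring or AlignmentScoring()
    aligner = scoring.make_aligner()
    return float(aligner.score(a, b))


def normalized_sw_layer(
    seqs: SequenceTable, scoring: AlignmentScoring | None = None
) -> SimilarityLayer:
    """All-pairs normalized Smith-Waterman similarity kernel.

    ``T_s(g, g') = SW(g, g') / (sqrt(SW(g, g)) * sqrt(SW(g', g')))``, the
    normalization of Bleakley & Yamanishi, giving a unit diagonal.  Values
    are clamped to [0, 1] against floating-point overshoot.  A sequence
    whose self-score is not positive cannot be normalized and is rejected.
    """
    scoring = scoring or AlignmentScoring()
    aligner = scoring.make_aligner()
    n = len(seqs)
    self_scores = np.array(
        [float(aligner.score(s, s)) for s in seqs.residues], dtype=float
    )
    bad = np.flatnonzero(self_scores <= 0)
    if bad.size:
        raise ValueError(
            "non-positive self-alignment score for: "
            + ", ".join(seqs.ids[i] for i in bad)
        )
    raw = np.zeros((n, n), dtype=float)
    for i in range(n):
        raw[i, i] = self_scores[i]
        for j in range(i + 1, n):
            raw[i, j] = raw[j, i] = float(
                aligner.score(seqs.residues[i], seqs.residues[j])
            )
    norm = np.sqrt(self_scores)
    sim = raw / np.outer(norm, norm)
    sim = np.clip(sim, 0.0, 1.0)
    np.fill_diagonal(sim, 1.0)
    sim = (sim + sim.T) / 2.0
    return SimilarityLayer(ids=seqs.ids, values=sim, source="sequence")


def shared_neighbor_jaccard(
    interactions: "InteractionTable", axis: str
) -> SimilarityLayer:
    """Topology similarity from shared interaction partners.

    With ``A`` the binary drug x target incidence matrix and
    ``M = A A^T`` (drugs) or ``A^T A`` (targets), entry (i, j) is
    ``M(i,j) / (M(i,i) + M(j,j) - M(i,j))`` — the Jaccard coefficient of
    the two neighbor sets.  Nodes with no neighbors get 0 off-diagonal.
    """
    if axis not in ("drugs", "targets"):
        raise ValueError("axis must be 'drugs' or 'targets'")
    A = interactions.matrix().astype(np.float64)
    if axis == "drugs":
        M = A @ A.T
        ids = interactions.drug_ids
        source = "topology-drugs"
    else:
        M = A.T @ A
        ids = interactions.target_ids
        source = "topology-targets"
    diag = np.diag(M)
    union = diag[:, None] + diag[None, :] - M
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, M / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(sim, 1.0)
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    return SimilarityLayer(ids=ids, values=sim, source=source)


def blend_layers(
    feature_layer: SimilarityLayer,
    topology_layer: SimilarityLayer,
    weight: float,
) -> SimilarityLayer:
    """Convex combination ``weight*feature + (1-weight)*topology``.

    Both layers must share the same id registry (same ids, same order after
    reordering); symmetry, range and unit diagonal are preserved by
    convexity.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError(f"blend weight must be in [0, 1], got {weight}")
    if set(feature_layer.ids) != set(topology_layer.ids):
        only_a = sorted(set(feature_layer.ids) - set(topology_layer.ids))
        only_b = sorted(set(topology_layer.ids) - set(feature_layer.ids))
        raise RegistryMismatchError(
            f"id registries differ; only in feature layer: {only_a}; "
            f"only in topology layer: {only_b}"
        )
    topo = topology_layer.reorder(feature_layer.ids)
    vals = weight * feature_layer.values + (1.0 - weight) * topo.values
    np.fill_diagonal(vals, 1.0)
    return SimilarityLayer(ids=feature_layer.ids, values=vals, source="blended")


# ---------------------------------------------------------------------------
# optional fingerprint adapter (requires rdkit)
# ---------------------------------------------------------------------------


def fingerprints_from_smiles(
    smiles: Sequence[str],
    ids: Sequence[str],
    family: str = "MACCS",
    n_bits: int = 2048,
) -> FingerprintTable:
    """Compute binary fingerprints from SMILES strings (requires rdkit).

    ``family`` is ``MACCS`` (166-key), ``ECFP6`` (Morgan radius 3, hashed to
    ``n_bits``) or ``PHFP4`` (hashed topological-distance pharmacophore
    pairs/triplets, hashed to ``n_bits``).  The core pipeline never requires
    this adapter: a precomputed :class:`FingerprintTable` or an external
    similarity layer works equally.
    """
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys, rdFingerprintGenerator
    from rdkit.Chem.Pharm2D import Generate, Gobbi_Pharm2D

    rows = []
    for smi, did in zip(smiles, ids):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for {did!r}: {smi!r}")
        if family == "MACCS":
            fp = MACCSkeys.GenMACCSKeys(mol)
            row = np.array([fp.GetBit(i) for i in range(fp.GetNumBits())], bool)
        elif family == "ECFP6":
            gen = rdFingerprintGenerator.GetMorganGenerator(
                radius=3, fpSize=n_bits
            )
            row = np.array(gen.GetFingerprint(mol).ToList(), bool)
        elif family == "PHFP4":
            fp = Generate.Gen2DFingerprint(mol, Gobbi_Pharm2D.factory)
            row = np.zeros(n_bits, bool)
            for bit in fp.GetOnBits():
                row[bit % n_bits] = True
        else:
            raise ValueError(f"unknown fingerprint family {family!r}")
        rows.append(row)
    return FingerprintTable(ids=tuple(ids), bits=np.array(rows), family=family)
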