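"""Per-type similarity matrices used as initial vertex features.

Three entity types, three similarity notions:

* metabolites — Tanimoto coefficient |A∩B| / |A∪B| over hashed circular
  substructure fingerprints (radius 2, 2048 bits by default);
* proteins — pairwise sequence alignment (BLOSUM62, affine gaps, open 11 /
  extend 1), normalized either by aligned-identity fraction or by min-max
  rescaling of raw scores;
* GO terms — ancestor-set Jaccard over the is_a / part_of DAG.

Every matrix is symmetric with unit diagonal and values in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence
import warnings

import numpy as np

from .godag import GoDag

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class Fingerprint:
    """Sparse bitset representation of a molecular fingerprint."""

    bits: frozenset[int]
    n_bits: int = 2048

    def __post_init__(self) -> None:
        if self.n_bits <= 0:
            raise ValueError("n_bits must be positive")
        if any(b < 0 or b >= self.n_bits for b in self.bits):
            raise ValueError("fingerprint bit position out of range")

    @classmethod
    def from_bits(cls, bits, n_bits: int = 2048) -> "Fingerprint":
        return cls(frozenset(int(b) for b in bits), n_bits)


@dataclass
class SimilarityMatrix:
    """Square symmetric matrix in [0, 1] with unit diagonal over labeled entities."""

    labels: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("similarity matrix shape does not match labels")
        self.values = v

    def validate(self, atol: float = 1e-9) -> None:
        v = self.values
        if not np.all(np.isfinite(v)):
            raise ValueError("similarity matrix contains non-finite values")
        if np.abs(v - v.T).max(initial=0.0) > atol:
            raise ValueError("similarity matrix is not symmetric")
        if np.abs(np.diag(v) - 1.0).max(initial=0.0) > atol:
            raise ValueError("similarity matrix diagonal is not 1")
        if v.min(initial=1.0) < -atol or v.max(initial=0.0) > 1 + atol:
            raise ValueError("similarity values outside [0, 1]")


@dataclass
class AlignmentParams:
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    mode: str = "local"

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.mode not in ("local", "global"):
            raise ValueError("mode must be 'local' or 'global'")


# ---------------------------------------------------------------------------
# Metabolite fingerprints


def smiles_to_fingerprint(smiles: str, n_bits: int = 2048, radius: int = 2) -> Fingerprint:
    """Hashed circular-substructure (Morgan) fingerprint of a SMILES string.

    Canonicalization is handled by the chemistry toolkit, so different
    SMILES spellings of the same molecule give identical fingerprints.
    The rdkit backend is imported lazily (install extra ``chem``).
    """
    try:
        from rdkit import Chem, RDLogger
        from rdkit.Chem import rdFingerprintGenerator
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise ImportError("smiles_to_fingerprint requires rdkit (extra 'chem')") from exc
    RDLogger.DisableLog("rdApp.*")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fp = gen.GetFingerprint(mol)
    return Fingerprint.from_bits(fp.GetOnBits(), n_bits)


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tc(A, B) = |A∩B| / |A∪B|; two empty fingerprints share no features -> 0."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint sizes differ: {a.n_bits} vs {b.n_bits}")
    union = len(a.bits | b.bits)
    if union == 0:
        return 0.0
    return len(a.bits & b.bits) / union


def tanimoto_matrix(fps: Sequence[Fingerprint], labels: Sequence[str]) -> SimilarityMatrix:
    """All-pairs Tanimoto matrix; diagonal forced to 1 (an empty fingerprint
    is trivially identical to itself even though tanimoto() returns 0)."""
    if len(fps) == 0:
        raise ValueError("need at least one fingerprint")
    if len(fps) != len(labels):
        raise ValueError("labels do not match fingerprints")
    n = len(fps)
    v = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = tanimoto(fps[i], fps[j])
    m = SimilarityMatrix(list(labels), v, meta={"kind": "tanimoto"})
    m.validate()
    return m


# ---------------------------------------------------------------------------
# Protein sequence alignment


def _make_aligner(params: AlignmentParams):
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    aligner.open_gap_score = -float(params.gap_open)
    aligner.extend_gap_score = -float(params.gap_extend)
    aligner.mode = params.mode
    return aligner


def _check_sequence(seq: str, which: str) -> None:
    if not seq:
        raise ValueError(f"{which} sequence is empty")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"{which} sequence contains illegal characters {sorted(bad)}")


def align_score(
    seq_a: str, seq_b: str, params: AlignmentParams | None = None
) -> tuple[float, float]:
    """Affine-gap pairwise alignment score and percent identity.

    Local (blastp-like) by default.  Identity is 100 x matches / alignment
    columns of the best alignment.
    """
    params = params or AlignmentParams()
    _check_sequence(seq_a, "first")
    _check_sequence(seq_b, "second")
    aligner = _make_aligner(params)
    aln = aligner.align(seq_a, seq_b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    identity = 100.0 * counts.identities / columns if columns else 0.0
    return float(aln.score), identity


def align_score_only(seq_a: str, seq_b: str, params: AlignmentParams | None = None) -> float:
    """Raw alignment score without traceback (much faster for all-vs-all)."""
    params = params or AlignmentParams()
    _check_sequence(seq_a, "first")
    _check_sequence(seq_b, "second")
    return float(_make_aligner(params).score(seq_a, seq_b))


def protein_similarity_matrix(
    labels: Sequence[str],
    pairwise: dict[tuple[str, str], float],
    mode: str = "identity_fraction",
) -> SimilarityMatrix:
    """Assemble the protein similarity matrix from pairwise results.

    ``pairwise`` maps unordered label pairs to either raw alignment scores
    (mode ``minmax``: off-diagonal min-max rescaled to [0,1]) or percent
    identities (mode ``identity_fraction``: divided by 100).  The diagonal
    is forced to 1 and the result symmetrized as (M + M.T) / 2.
    """
    if mode not in ("minmax", "identity_fraction"):
        raise ValueError(f"unknown normalization mode {mode!r}")
    n = len(labels)
    if n == 0:
        raise ValueError("empty label set")
    raw = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i == j:
                continue
            key = (a, b) if (a, b) in pairwise else (b, a)
            if key not in pairwise:
                raise ValueError(f"missing pairwise result for ({a!r}, {b!r})")
            raw[i, j] = pairwise[key]

    off = ~np.eye(n, dtype=bool)
    v = np.zeros((n, n))
    if n > 1:
        if mode == "minmax":
            lo, hi = raw[off].min(), raw[off].max()
            if hi == lo:
                warnings.warn("degenerate min-max normalization: all raw scores equal; "
                              "setting off-diagonal similarities to 1.0")
                v[off] = 1.0
            else:
                v[off] = (raw[off] - lo) / (hi - lo)
        else:
            v[off] = raw[off] / 100.0
    v = (v + v.T) / 2.0
    np.fill_diagonal(v, 1.0)
    m = SimilarityMatrix(list(labels), v, meta={"kind": "protein", "normalization": mode})
    m.validate()
    return m


def protein_similarity_from_sequences(
    sequences: dict[str, str],
    params: AlignmentParams | None = None,
    mode: str = "identity_fraction",
) -> SimilarityMatrix:
    """Exhaustive all-vs-all alignment, then normalization.

    Intended for synthetic-scale protein sets; precomputed score tables can
    be fed to :func:`protein_similarity_matrix` directly for larger data.
    """
    labels = list(sequences)
    pairwise: dict[tuple[str, str], float] = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            if mode == "minmax":
                pairwise[(a, b)] = align_score_only(sequences[a], sequences[b], params)
            else:
                _, ident = align_score(sequences[a], sequences[b], params)
                pairwise[(a, b)] = ident
    return protein_similarity_matrix(labels, pairwise, mode=mode)


# ---------------------------------------------------------------------------
# GO semantic similarity


def go_similarity(dag: GoDag, t1: str, t2: str) -> float:
    """Ancestor-set Jaccard: |A(t1) ∩ A(t2)| / |A(t1) ∪ A(t2)|,
    with A(t) = {t} plus all is_a/part_of ancestors."""
    a1, a2 = dag.ancestor_set(t1), dag.ancestor_set(t2)
    return len(a1 & a2) / len(a1 | a2)


def go_similarity_matrix(dag: GoDag, terms: Sequence[str]) -> SimilarityMatrix:
    if len(terms) == 0:
        raise ValueError("empty term list")
    ancestors = [dag.ancestor_set(t) for t in terms]
    n = len(terms)
    v = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            inter = len(ancestors[i] & ancestors[j])
            v[i, j] = v[j, i] = inter / len(ancestors[i] | ancestors[j])
    m = SimilarityMatrix(list(terms), v, meta={"kind": "go_jaccard"})
    m.validate()
    return m


# Pluggable fingerprint function type used by pipelines.
FingerprintFn = Callable[[str], Fingerprint]
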