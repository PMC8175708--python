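"""Compound and protein similarity kernels.

Compound kernels are Tanimoto or Dice similarities over hashed bit
fingerprints (circular/Morgan or path-based, RDKit backends).  Protein
kernels are normalized Smith–Waterman local-alignment scores,
``K(i, j) = sw(i, j) / sqrt(sw(i, i) * sw(j, j))``, which guarantees a
unit diagonal and entries in [0, 1].  Normalized alignment matrices are
not guaranteed positive semidefinite, so :func:`ensure_psd` repairs them
by a diagonal shift (preserving the off-diagonal similarity ordering)
followed by re-normalization to unit diagonal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io import AMINO_ACID_ALPHABET, CompoundRecord, ProteinRecord

__all__ = [
    "FingerprintSpec",
    "Fingerprint",
    "AlignmentScoring",
    "KernelMatrix",
    "fingerprint",
    "similarity_kernel",
    "compound_kernel",
    "tanimoto_matrix",
    "sw_score",
    "protein_kernel",
    "ensure_psd",
    "qed_fingerprint_specs",
    "read_kernel_tsv",
    "write_kernel_tsv",
    "read_fingerprints_tsv",
    "write_fingerprints_tsv",
]

_SYMMETRY_TOL = 1e-10


@dataclass(frozen=True)
class FingerprintSpec:
    """Hashed fingerprint parameters.

    ``kind='circular'`` is a Morgan/ECFP-style fingerprint with the given
    radius; ``kind='path'`` a linear-path fingerprint with the given
    maximum path depth.  ``n_bits`` must be a positive power of two
    (hashed folding length, default 1024).
    """

    kind: str = "circular"
    radius_or_depth: int = 2
    n_bits: int = 1024
    use_chirality: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("circular", "path"):
            raise ValueError(f"kind must be 'circular' or 'path', got {self.kind!r}")
        if self.radius_or_depth < 1:
            raise ValueError("radius_or_depth must be >= 1")
        if self.n_bits < 1 or (self.n_bits & (self.n_bits - 1)) != 0:
            raise ValueError(f"n_bits must be a positive power of two, got {self.n_bits}")


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length 0/1 bit vector."""

    bits: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.bits, dtype=np.uint8)
        if arr.ndim != 1:
            raise ValueError("fingerprint bits must be a 1-D vector")
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("fingerprint bits must be 0/1")
        object.__setattr__(self, "bits", arr)

    def __len__(self) -> int:
        return len(self.bits)


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap local alignment scoring.

    A gap of length L costs ``gap_open + L * gap_extend``.  Defaults are
    the ubiquitous protein choices: BLOSUM62, open 11, extend 1.
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be non-negative")


@dataclass(frozen=True)
class KernelMatrix:
    """Symmetric similarity matrix with entity identifiers.

    Houses both the compound kernel K_c and the protein kernel K_p fed to
    the KronRLS regressors.  Construction enforces symmetry (within
    1e-10); similarity kernels additionally carry a unit diagonal and
    entries in [0, 1].
    """

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        if len(set(ids)) != len(ids):
            raise ValueError("kernel entity ids must be unique")
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (len(ids), len(ids)):
            raise ValueError(
                f"kernel shape {vals.shape} does not match {len(ids)} ids"
            )
        if vals.size and np.max(np.abs(vals - vals.T)) > _SYMMETRY_TOL:
            raise ValueError("kernel matrix is not symmetric within 1e-10")
        vals = (vals + vals.T) / 2.0
        object.__setattr__(self, "ids", ids)
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index(self) -> dict[str, int]:
        return {i: k for k, i in enumerate(self.ids)}

    def loc(self, a: str, b: str) -> float:
        idx = self.index()
        return float(self.values[idx[a], idx[b]])

    def submatrix(self, ids: Sequence[str]) -> "KernelMatrix":
        idx = self.index()
        sel = [idx[i] for i in ids]
        return KernelMatrix(tuple(ids), self.values[np.ix_(sel, sel)])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0]) if self.n else 0.0


# ---------------------------------------------------------------------------
# fingerprints
# ---------------------------------------------------------------------------

def fingerprint(compound: CompoundRecord, spec: FingerprintSpec) -> Fingerprint:
    """Compute (or pass through) a compound's bit fingerprint.

    A precomputed fingerprint on the record is returned as-is if its
    length matches ``spec.n_bits``; otherwise the SMILES is parsed and
    hashed with the RDKit generator for ``spec.kind``.  Deterministic:
    identical structures give identical fingerprints.
    """
    if compound.fingerprint is not None:
        fp = Fingerprint(np.asarray(compound.fingerprint))
        if len(fp) != spec.n_bits:
            raise ValueError(
                f"compound {compound.compound_id}: precomputed fingerprint "
                f"length {len(fp)} does not match spec n_bits {spec.n_bits}"
            )
        return fp
    if compound.smiles is None:
        raise ValueError(
            f"compound {compound.compound_id} has neither SMILES nor "
            "a precomputed fingerprint"
        )
    from rdkit import Chem
    from rdkit.Chem import rdFingerprintGenerator

    mol = Chem.MolFromSmiles(compound.smiles)
    if mol is None:
        raise ValueError(
            f"compound {compound.compound_id}: unparsable SMILES "
            f"{compound.smiles!r}"
        )
    if spec.kind == "circular":
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=spec.radius_or_depth,
            fpSize=spec.n_bits,
            includeChirality=spec.use_chirality,
        )
    else:
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(
            maxPath=spec.radius_or_depth, fpSize=spec.n_bits
        )
    bv = gen.GetFingerprint(mol)
    arr = np.zeros(spec.n_bits, dtype=np.uint8)
    arr[list(bv.GetOnBits())] = 1
    return Fingerprint(arr)


def qed_fingerprint_specs() -> list[tuple[FingerprintSpec, str]]:
    """The eight (fingerprint spec, metric) combinations of the Q.E.D grid.

    {radius 2, 3} x {chirality on, off} x {tanimoto, dice} on 1024-bit
    circular fingerprints; lexicographic order (radius, chirality, metric).
    """
    out = []
    for radius in (2, 3):
        for chirality in (False, True):
            for metric in ("tanimoto", "dice"):
                out.append(
                    (
                        FingerprintSpec(
                            kind="circular",
                            radius_or_depth=radius,
                            n_bits=1024,
                            use_chirality=chirality,
                        ),
                        metric,
                    )
                )
    return out


def tanimoto_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto similarity between two 0/1 fingerprint stacks."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 0.0)
    return sim


def similarity_kernel(
    fps: Sequence[Fingerprint],
    metric: str = "tanimoto",
    ids: Sequence[str] | None = None,
) -> KernelMatrix:
    """Tanimoto or Dice similarity kernel over a fingerprint collection.

    tanimoto(a, b) = |a & b| / |a | b|;  dice(a, b) = 2|a & b| / (|a| + |b|).
    For a pair of all-zero fingerprints both ratios are 0/0; the kernel is
    defined as 1 on the diagonal and 0 off-diagonal in that case.
    """
    if metric not in ("tanimoto", "dice"):
        raise ValueError(f"metric must be 'tanimoto' or 'dice', got {metric!r}")
    lengths = {len(fp) for fp in fps}
    if len(lengths) > 1:
        raise ValueError(f"mixed fingerprint lengths {sorted(lengths)}")
    mat = np.vstack([fp.bits for fp in fps]).astype(float)
    inter = mat @ mat.T
    counts = mat.sum(axis=1)
    if metric == "tanimoto":
        denom = counts[:, None] + counts[None, :] - inter
    else:
        denom = counts[:, None] + counts[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        factor = 2.0 if metric == "dice" else 1.0
        sim = np.where(denom > 0, factor * inter / np.maximum(denom, 1e-300), 0.0)
    np.fill_diagonal(sim, 1.0)
    if ids is None:
        ids = [f"fp{i}" for i in range(len(fps))]
    return KernelMatrix(tuple(ids), sim)


def compound_kernel(
    compounds: Sequence[CompoundRecord],
    spec: FingerprintSpec,
    metric: str = "tanimoto",
) -> KernelMatrix:
    """Convenience: fingerprint a compound collection and build its kernel."""
    fps = [fingerprint(c, spec) for c in compounds]
    return similarity_kernel(fps, metric, ids=[c.compound_id for c in compounds])


# ---------------------------------------------------------------------------
# Smith–Waterman protein kernel
# ---------------------------------------------------------------------------

def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(
        scoring.substitution_matrix
    )
    # first gapped position costs open+extend, each further one extend
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _check_sequence(seq: str, label: str) -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq):
        if ch not in AMINO_ACID_ALPHABET:
            raise ValueError(
                f"{label}: illegal residue {ch!r} at position {pos}"
            )
    return seq


def sw_score(
    a: str, b: str, scoring: AlignmentScoring = AlignmentScoring()
) -> float:
    """Optimal Smith–Waterman local-alignment score under affine gaps.

    Symmetric in its arguments and always >= 0 (the empty local alignment
    scores zero).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    a = _check_sequence(a, "sequence a")
    b = _check_sequence(b, "sequence b")
    return float(_aligner(scoring).score(a, b))


def protein_kernel(
    proteins: Sequence[ProteinRecord],
    scoring: AlignmentScoring = AlignmentScoring(),
) -> KernelMatrix:
    """Normalized Smith–Waterman kernel over a protein collection.

    Entry (i, j) = sw(i, j) / sqrt(sw(i, i) * sw(j, j)); the diagonal is
    exactly 1 and all entries lie in [0, 1] (a local alignment of i with
    j never outscores the self-alignments it is normalized by for
    positive-diagonal substitution matrices).
    """
    aligner = _aligner(scoring)
    seqs = [_check_sequence(p.sequence, p.protein_id) for p in proteins]
    n = len(seqs)
    self_scores = np.array([aligner.score(s, s) for s in seqs], dtype=float)
    for p, s in zip(proteins, self_scores):
        if s <= 0:
            raise ValueError(
                f"{p.protein_id}: degenerate sequence with zero self-alignment score"
            )
    raw = np.zeros((n, n))
    np.fill_diagonal(raw, self_scores)
    for i in range(n):
        for j in range(i + 1, n):
            if seqs[i] == seqs[j]:
                raw[i, j] = raw[j, i] = self_scores[i]
            else:
                raw[i, j] = raw[j, i] = aligner.score(seqs[i], seqs[j])
    norm = np.sqrt(self_scores)
    values = np.minimum(raw / np.outer(norm, norm), 1.0)
    np.fill_diagonal(values, 1.0)
    return KernelMatrix(tuple(p.protein_id for p in proteins), values)


def ensure_psd(kernel: KernelMatrix, eps: float = 1e-8) -> KernelMatrix:
    """Repair an indefinite kernel by a diagonal shift.

    If the smallest eigenvalue lambda_min is negative, adds
    ``|lambda_min| + eps`` to the diagonal and rescales back to unit
    diagonal (dividing by ``1 + shift`` when the input diagonal is 1).
    The diagonal shift preserves the off-diagonal similarity ordering,
    unlike eigenvalue clipping.  Already-PSD input is returned unchanged.
    """
    if eps < 0:
        raise ValueError("eps must be >= 0")
    lam_min = kernel.min_eigenvalue()
    if lam_min >= 0:
        return kernel
    shift = abs(lam_min) + eps
    shifted = kernel.values + shift * np.eye(kernel.n)
    d = np.sqrt(np.diag(shifted))
    rescaled = shifted / np.outer(d, d)
    np.fill_diagonal(rescaled, 1.0)
    return KernelMatrix(kernel.ids, rescaled)


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_kernel_tsv(kernel: KernelMatrix, path: str | Path) -> None:
    """TSV with a leading id column and id header row; 12 significant digits."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(kernel.ids) + "\n")
        for i, row_id in enumerate(kernel.ids):
            row = "\t".join(f"{v:.12g}" for v in kernel.values[i])
            fh.write(f"{row_id}\t{row}\n")


def read_kernel_tsv(path: str | Path) -> KernelMatrix:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "id":
            raise ValueError(f"{path}: first header field must be 'id'")
        ids = tuple(header[1:])
        rows = []
        row_ids = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            row_ids.append(parts[0])
            rows.append([float(x) for x in parts[1:]])
    if tuple(row_ids) != ids:
        raise ValueError(f"{path}: row ids do not match column ids")
    return KernelMatrix(ids, np.array(rows))


def write_fingerprints_tsv(
    fps: Sequence[Fingerprint], ids: Sequence[str], path: str | Path
) -> None:
    """TSV of id + hex-encoded bitstring (big-endian bit packing)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tfingerprint_hex\n")
        for fp, fid in zip(fps, ids):
            packed = np.packbits(fp.bits)
            fh.write(f"{fid}\t{packed.tobytes().hex()}\n")


def read_fingerprints_tsv(path: str | Path, n_bits: int) -> tuple[list[Fingerprint], list[str]]:
    fps: list[Fingerprint] = []
    ids: list[str] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["id", "fingerprint_hex"]:
            raise ValueError(f"{path}: bad fingerprint TSV header {header}")
        for line in fh:
            fid, hexstr = line.rstrip("\n").split("\t")
            bits = np.unpackbits(np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8))
            if len(bits) < n_bits:
                raise ValueError(f"{path}: fingerprint for {fid} shorter than {n_bits}")
            fps.append(Fingerprint(bits[:n_bits]))
            ids.append(fid)
    return fps, ids
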