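"""Domain types and file I/O for compound–kinase bioactivity data.

The central container is the :class:`InteractionTable`: deduplicated
``(compound_id, protein_id, pKd)`` triplets on the pKd scale,
``pKd = -log10(Kd in molar)``.  A pKd of 5 conventionally encodes
"inactive at the 10 µM dose-response assay ceiling".

Readers/writers cover the plain-text formats used throughout:

* bioactivity CSV: ``compound_id,protein_id,assay_type,value,unit``
* prediction CSV:  ``compound_id,protein_id,pkd_pred``
* measured CSV:    ``compound_id,protein_id,pkd``
* FASTA protein sequences (id = first whitespace-delimited header token)
* SMILES ``.smi``: one ``SMILES<TAB>compound_id`` per line
* annotation TSV:  ``protein_id,group,family``

All CSV dialects are comma-separated UTF-8 with a required header row;
column names are matched case-insensitively.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "AssayType",
    "Unit",
    "CompoundRecord",
    "ProteinRecord",
    "BioactivityRecord",
    "InteractionTable",
    "PredictionSet",
    "KinaseAnnotation",
    "ValidationReport",
    "AMINO_ACID_ALPHABET",
    "to_pkd",
    "merge_replicates",
    "validate_prediction_file",
    "filter_by_similarity",
    "filter_by_pkd_range",
    "random_dropout",
    "challenge_summary",
    "read_bioactivity_csv",
    "write_bioactivity_csv",
    "read_fasta",
    "write_fasta",
    "read_smi",
    "write_smi",
    "read_annotations",
    "write_annotations",
]

AMINO_ACID_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")


class AssayType(enum.Enum):
    """Bioactivity assay readout types accepted in input tables."""

    KD = "KD"
    KI = "KI"
    IC50 = "IC50"
    EC50 = "EC50"
    INHIBITION_PCT = "INHIBITION_PCT"
    ACTIVITY_PCT = "ACTIVITY_PCT"

    @classmethod
    def parse(cls, text: str) -> "AssayType":
        return cls(text.strip().upper().replace("%", "_PCT"))


#: assay types whose values live on a molar concentration scale
CONCENTRATION_TYPES = frozenset(
    {AssayType.KD, AssayType.KI, AssayType.IC50, AssayType.EC50}
)


class Unit(enum.Enum):
    M = "M"
    MM = "mM"
    UM = "uM"
    NM = "nM"
    PCT = "PCT"

    @classmethod
    def parse(cls, text: str) -> "Unit":
        t = text.strip().replace("µ", "u")
        for u in cls:
            if u.value.lower() == t.lower():
                return u
        raise ValueError(f"unknown unit {text!r}")


# decimal exponent such that value * 10**-exp is the molar quantity
_UNIT_EXPONENT = {Unit.M: 0, Unit.MM: 3, Unit.UM: 6, Unit.NM: 9}


@dataclass(frozen=True)
class CompoundRecord:
    """A small molecule identified by an opaque key.

    At least one of ``smiles`` / ``fingerprint`` must be present when the
    compound participates in a similarity kernel.  ``fingerprint`` is a
    0/1 ``numpy`` vector (see :mod:`kronbind.kernels`).
    """

    compound_id: str
    smiles: str | None = None
    fingerprint: "np.ndarray | None" = None

    def __post_init__(self) -> None:
        if not self.compound_id:
            raise ValueError("compound_id must be non-empty")


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identified by accession/gene symbol with its sequence."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValueError("protein_id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"{self.protein_id}: sequence must be non-empty")
        bad = set(self.sequence.upper()) - AMINO_ACID_ALPHABET
        if bad:
            raise ValueError(
                f"{self.protein_id}: illegal residues {sorted(bad)} "
                "(20-letter amino-acid alphabet plus X)"
            )


@dataclass(frozen=True)
class BioactivityRecord:
    """One raw assay measurement for a compound–protein pair."""

    compound_id: str
    protein_id: str
    assay_type: AssayType
    value: float
    unit: Unit

    def __post_init__(self) -> None:
        if not math.isfinite(self.value) or self.value < 0:
            raise ValueError(
                f"({self.compound_id}, {self.protein_id}): value must be "
                f"finite and >= 0, got {self.value}"
            )
        if self.assay_type in CONCENTRATION_TYPES:
            if self.unit is Unit.PCT:
                raise ValueError(
                    f"concentration assay {self.assay_type.value} cannot "
                    "carry a percentage unit"
                )
        elif self.unit is not Unit.PCT:
            raise ValueError(
                f"percentage assay {self.assay_type.value} must carry "
                "unit PCT"
            )


_IT_COLUMNS = ["compound_id", "protein_id", "pkd"]


@dataclass(frozen=True)
class InteractionTable:
    """Deduplicated (compound, protein, pKd) triplets.

    Backed by a pandas DataFrame with columns
    ``compound_id, protein_id, pkd``; at most one row per pair, pKd
    finite and non-negative.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in _IT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"InteractionTable frame missing columns {missing}")
        df = df[_IT_COLUMNS].reset_index(drop=True)
        if df.duplicated(["compound_id", "protein_id"]).any():
            dups = df[df.duplicated(["compound_id", "protein_id"], keep=False)]
            raise ValueError(
                "duplicate pairs in InteractionTable: "
                f"{sorted(set(map(tuple, dups[['compound_id', 'protein_id']].values)))[:5]}"
            )
        vals = df["pkd"].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("pkd values must be finite and >= 0")
        object.__setattr__(self, "frame", df)

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_rows(
        cls, rows: Iterable[tuple[str, str, float]]
    ) -> "InteractionTable":
        return cls(pd.DataFrame(list(rows), columns=_IT_COLUMNS))

    @classmethod
    def read_csv(cls, path: str | Path) -> "InteractionTable":
        df = _read_table(path, _IT_COLUMNS, sep=",")
        df["pkd"] = df["pkd"].astype(float)
        return cls(df)

    # -- accessors ------------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def pairs(self) -> list[tuple[str, str]]:
        return list(
            map(tuple, self.frame[["compound_id", "protein_id"]].itertuples(index=False))
        )

    def pkd_map(self) -> dict[tuple[str, str], float]:
        return {
            (c, p): v
            for c, p, v in self.frame.itertuples(index=False)
        }

    def compounds(self) -> list[str]:
        return sorted(self.frame["compound_id"].unique())

    def proteins(self) -> list[str]:
        return sorted(self.frame["protein_id"].unique())

    def write_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def equals(self, other: "InteractionTable") -> bool:
        a = self.frame.sort_values(_IT_COLUMNS[:2]).reset_index(drop=True)
        b = other.frame.sort_values(_IT_COLUMNS[:2]).reset_index(drop=True)
        return a.equals(b)


@dataclass
class PredictionSet:
    """One model's predicted pKd per compound–kinase pair."""

    model_id: str
    entries: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for pair, v in self.entries.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite prediction for pair {pair}")

    def pairs(self) -> set[tuple[str, str]]:
        return set(self.entries)

    def values_for(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        return np.array([self.entries[p] for p in pairs], dtype=float)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["compound_id", "protein_id", "pkd_pred"])
            for (c, p), v in sorted(self.entries.items()):
                w.writerow([c, p, repr(float(v))])

    @classmethod
    def read_csv(cls, path: str | Path, model_id: str | None = None) -> "PredictionSet":
        df = _read_table(path, ["compound_id", "protein_id", "pkd_pred"], sep=",")
        entries = {
            (str(c), str(p)): float(v)
            for c, p, v in df[["compound_id", "protein_id", "pkd_pred"]].itertuples(
                index=False
            )
        }
        if len(entries) != len(df):
            raise ValueError(f"{path}: duplicate pairs in prediction file")
        return cls(model_id or Path(path).stem, entries)


@dataclass(frozen=True)
class KinaseAnnotation:
    """Kinase group/family annotation (e.g. group CMGC, family CDK)."""

    protein_id: str
    group: str
    family: str


@dataclass
class ValidationReport:
    """Outcome of prediction-file validation; ``ok`` iff no violations."""

    path: str
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


# ---------------------------------------------------------------------------
# unit conversion and replicate merging
# ---------------------------------------------------------------------------

def to_pkd(record: BioactivityRecord) -> float:
    """Convert a concentration-type measurement to the pKd scale.

    ``pKd = -log10(value in molar)``.  Exact for powers of ten: the molar
    exponent of the unit is applied as an integer offset, so e.g.
    ``(KD, 10, nM)`` gives exactly ``8.0``.

    Raises
    ------
    ValueError
        For percentage assay types (no molar interpretation) or a zero
        value (log undefined).
    """
    if record.assay_type not in CONCENTRATION_TYPES:
        raise ValueError(
            f"cannot convert percentage assay type "
            f"{record.assay_type.value} to pKd"
        )
    if record.value == 0:
        raise ValueError("cannot take pKd of a zero concentration")
    return _UNIT_EXPONENT[record.unit] - math.log10(record.value)


def merge_replicates(
    records: Sequence[BioactivityRecord],
    assay_filter: Iterable[AssayType] = (AssayType.KD,),
) -> InteractionTable:
    """Collapse replicate measurements to one pKd per pair.

    Records outside ``assay_filter`` are dropped; the rest are converted
    with :func:`to_pkd` and the median per (compound, protein) pair is
    taken (median of an even count = mean of the central two).  Merging
    on the pKd scale rather than raw Kd keeps the operation idempotent
    on already-merged tables.
    """
    keep = frozenset(assay_filter)
    rows = [
        (r.compound_id, r.protein_id, to_pkd(r))
        for r in records
        if r.assay_type in keep
    ]
    if not rows:
        return InteractionTable.from_rows([])
    df = pd.DataFrame(rows, columns=_IT_COLUMNS)
    merged = (
        df.groupby(["compound_id", "protein_id"], as_index=False)["pkd"]
        .median()
    )
    return InteractionTable(merged)


# ---------------------------------------------------------------------------
# prediction-file validation
# ---------------------------------------------------------------------------

def validate_prediction_file(
    path: str | Path,
    template: Iterable[tuple[str, str]],
    model_id: str | None = None,
) -> PredictionSet | ValidationReport:
    """Validate a submitted prediction file against a pair template.

    The file must be a CSV with header ``compound_id,protein_id,pkd_pred``
    (case-insensitive), cover exactly the template pair set, contain no
    duplicates, and have a numeric prediction for every pair.  On success
    a :class:`PredictionSet` keyed exactly by the template is returned;
    otherwise a :class:`ValidationReport` listing every violation.

    Structural CSV problems (missing columns, short rows) raise
    ``ValueError`` with the offending line number.
    """
    template = set(map(tuple, template))
    report = ValidationReport(str(path))
    entries: dict[tuple[str, str], float] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file (line 1)") from None
        cols = [h.strip().lower() for h in header]
        try:
            ic = cols.index("compound_id")
            ip = cols.index("protein_id")
            iv = cols.index("pkd_pred")
        except ValueError:
            raise ValueError(
                f"{path}: line 1: header must contain compound_id, "
                f"protein_id, pkd_pred (got {header})"
            ) from None
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) <= max(ic, ip, iv):
                raise ValueError(f"{path}: line {lineno}: too few fields")
            pair = (row[ic].strip(), row[ip].strip())
            if pair in entries:
                report.violations.append(f"duplicate pair {pair}")
                continue
            try:
                val = float(row[iv])
                if not math.isfinite(val):
                    raise ValueError
            except ValueError:
                report.violations.append(
                    f"non-numeric prediction {row[iv]!r} for pair {pair}"
                )
                entries[pair] = math.nan
                continue
            entries[pair] = val
    for pair in sorted(template - set(entries)):
        report.violations.append(f"missing pair {pair}")
    for pair in sorted(set(entries) - template):
        report.violations.append(f"extra pair {pair}")
    if not report.ok:
        return report
    return PredictionSet(model_id or Path(path).stem, entries)


# ---------------------------------------------------------------------------
# training-data drop-out filters
# ---------------------------------------------------------------------------

def filter_by_similarity(
    train: InteractionTable,
    train_compounds: Sequence[CompoundRecord],
    test_compounds: Sequence[CompoundRecord],
    fp_spec,
    threshold: float,
) -> InteractionTable:
    """Remove training rows for compounds too similar to any test compound.

    A training compound is removed when its maximum Tanimoto similarity
    (fingerprints per ``fp_spec``) to any test compound is >= ``threshold``
    (closed bound: ties at the threshold are removed).  The filter is
    monotone in the threshold: lowering it never retains more rows.
    """
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    from . import kernels  # local import to avoid a cycle

    train_fps = np.vstack(
        [kernels.fingerprint(c, fp_spec).bits for c in train_compounds]
    )
    test_fps = np.vstack(
        [kernels.fingerprint(c, fp_spec).bits for c in test_compounds]
    )
    sim = kernels.tanimoto_matrix(train_fps, test_fps)
    max_sim = sim.max(axis=1)
    removed = {
        c.compound_id
        for c, s in zip(train_compounds, max_sim)
        if s >= threshold
    }
    keep = ~train.frame["compound_id"].isin(removed)
    return InteractionTable(train.frame[keep])


def filter_by_pkd_range(
    train: InteractionTable, lo: float, hi: float
) -> InteractionTable:
    """Keep rows with ``lo <= pkd <= hi`` (both bounds inclusive)."""
    if lo > hi:
        raise ValueError(f"lo must be <= hi, got ({lo}, {hi})")
    mask = (train.frame["pkd"] >= lo) & (train.frame["pkd"] <= hi)
    return InteractionTable(train.frame[mask])


def random_dropout(
    train: InteractionTable, n_remove: int, seed: int
) -> InteractionTable:
    """Remove exactly ``n_remove`` uniformly sampled rows, reproducibly."""
    n = len(train)
    if not (0 <= n_remove <= n):
        raise ValueError(f"n_remove must be in [0, {n}], got {n_remove}")
    rng = np.random.default_rng(seed)
    drop = rng.choice(n, size=n_remove, replace=False)
    mask = np.ones(n, dtype=bool)
    mask[drop] = False
    return InteractionTable(train.frame[mask])


def challenge_summary(
    rounds: Mapping[str, InteractionTable]
) -> dict[str, dict[str, int]]:
    """Count pairs / compounds / kinases per round and over their union.

    Mirrors the bookkeeping used when loading blinded challenge test sets
    (e.g. pair counts per round, the compound and kinase universes, and
    the pooled totals).
    """
    out: dict[str, dict[str, int]] = {}
    all_pairs: set[tuple[str, str]] = set()
    all_c: set[str] = set()
    all_p: set[str] = set()
    for name, table in rounds.items():
        out[name] = {
            "n_pairs": len(table),
            "n_compounds": len(set(table.frame["compound_id"])),
            "n_kinases": len(set(table.frame["protein_id"])),
        }
        all_pairs.update(table.pairs())
        all_c.update(table.frame["compound_id"])
        all_p.update(table.frame["protein_id"])
    out["union"] = {
        "n_pairs": len(all_pairs),
        "n_compounds": len(all_c),
        "n_kinases": len(all_p),
    }
    return out


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, required: Sequence[str], sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_bioactivity_csv(path: str | Path) -> list[BioactivityRecord]:
    df = _read_table(
        path, ["compound_id", "protein_id", "assay_type", "value", "unit"], sep=","
    )
    return [
        BioactivityRecord(
            compound_id=str(r.compound_id),
            protein_id=str(r.protein_id),
            assay_type=AssayType.parse(r.assay_type),
            value=float(r.value),
            unit=Unit.parse(r.unit),
        )
        for r in df.itertuples(index=False)
    ]


def write_bioactivity_csv(
    records: Sequence[BioactivityRecord], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["compound_id", "protein_id", "assay_type", "value", "unit"])
        for r in records:
            w.writerow(
                [r.compound_id, r.protein_id, r.assay_type.value, repr(float(r.value)), r.unit.value]
            )


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    return [
        ProteinRecord(protein_id=rec.id, sequence=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(proteins: Sequence[ProteinRecord], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
        for p in proteins
    ]
    SeqIO.write(records, str(path), "fasta")


def read_smi(path: str | Path) -> list[CompoundRecord]:
    """Read ``SMILES<TAB>compound_id`` lines."""
    out = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 'SMILES<TAB>compound_id'"
                )
            out.append(CompoundRecord(compound_id=parts[1].strip(), smiles=parts[0].strip()))
    return out


def write_smi(compounds: Sequence[CompoundRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in compounds:
            if c.smiles is None:
                raise ValueError(f"compound {c.compound_id} has no SMILES")
            fh.write(f"{c.smiles}\t{c.compound_id}\n")


def read_annotations(path: str | Path) -> dict[str, KinaseAnnotation]:
    df = _read_table(path, ["protein_id", "group", "family"], sep="\t")
    out: dict[str, KinaseAnnotation] = {}
    for r in df.itertuples(index=False):
        pid = str(r.protein_id)
        if pid in out:
            raise ValueError(f"{path}: duplicate annotation for {pid}")
        out[pid] = KinaseAnnotation(pid, str(r.group), str(r.family))
    return out


def write_annotations(
    annotations: Iterable[KinaseAnnotation], path: str | Path
) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["protein_id", "group", "family"])
        for a in annotations:
            w.writerow([a.protein_id, a.group, a.family])
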