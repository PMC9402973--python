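"""Domain types and I/O for annotated protein chains.

The canonical input is a tab-separated annotation file joining, per residue,
the amino acid with its predicted structural tracks and the binding label:

    chain_id  position  aa  ss  rsa  phi  psi  disorder  label

``position`` is 1-based in files; all in-memory indexing is 0-based.  Rows
for a chain must be contiguous and position-ordered.  Sequences may also be
read from FASTA, but annotation tracks must then be joined separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VACANCY_SYMBOL = "-"
NONSTANDARD = set("XBZUJO")

COLUMNS = ["chain_id", "position", "aa", "ss", "rsa", "phi", "psi", "disorder", "label"]

#: default fragment window length per metal-ion ligand
LIGAND_WINDOWS = {
    "Zn2+": 13,
    "Cu2+": 15,
    "Fe2+": 9,
    "Fe3+": 11,
    "Co2+": 11,
    "Mn2+": 11,
    "Ca2+": 9,
    "Mg2+": 15,
}


class FormatError(ValueError):
    """Malformed input file (missing columns, bad FASTA, ...)."""


class ValidationError(ValueError):
    """Well-formed file whose values violate the domain invariants."""


@dataclass(frozen=True)
class LigandProfile:
    """A metal-ion ligand together with its fragment window length L."""

    ligand_name: str
    window_length: int

    def __post_init__(self) -> None:
        if self.window_length < 1 or self.window_length % 2 == 0:
            raise ValueError(
                f"window length must be an odd positive integer, got {self.window_length}"
            )

    @classmethod
    def for_ligand(cls, name: str) -> "LigandProfile":
        try:
            return cls(name, LIGAND_WINDOWS[name])
        except KeyError:
            raise ValueError(
                f"unknown ligand {name!r}; known: {sorted(LIGAND_WINDOWS)}"
            ) from None


@dataclass
class AnnotatedChain:
    """One protein chain with sequence, six per-residue tracks and labels."""

    chain_id: str
    sequence: str
    ss: str
    rsa: np.ndarray
    phi: np.ndarray
    psi: np.ndarray
    disorder: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.rsa = np.asarray(self.rsa, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.psi = np.asarray(self.psi, dtype=float)
        self.disorder = np.asarray(self.disorder, dtype=float)
        self.labels = np.asarray(self.labels, dtype=np.uint8)

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self, allow_vacancy: bool = True) -> None:
        n = len(self.sequence)
        for name in ("ss", "rsa", "phi", "psi", "disorder", "labels"):
            if len(getattr(self, name)) != n:
                raise ValidationError(
                    f"chain {self.chain_id}: track {name} has length "
                    f"{len(getattr(self, name))}, expected {n}"
                )
        allowed = set(AMINO_ACIDS) | ({VACANCY_SYMBOL} if allow_vacancy else set())
        for i, aa in enumerate(self.sequence):
            if aa not in allowed:
                raise ValidationError(
                    f"chain {self.chain_id} position {i + 1}: "
                    f"non-canonical residue {aa!r}"
                )
        for i, s in enumerate(self.ss):
            if s not in "HEC":
                raise ValidationError(
                    f"chain {self.chain_id} position {i + 1}: "
                    f"secondary-structure code {s!r} not in H/E/C"
                )
        for name, arr, lo, hi in (
            ("rsa", self.rsa, 0.0, 1.0),
            ("disorder", self.disorder, 0.0, 1.0),
            ("phi", self.phi, -180.0, 180.0),
            ("psi", self.psi, -180.0, 180.0),
        ):
            bad = np.nonzero(~((arr >= lo) & (arr <= hi)))[0]
            if bad.size:
                raise ValidationError(
                    f"chain {self.chain_id} position {bad[0] + 1}: "
                    f"{name} value {arr[bad[0]]} outside [{lo}, {hi}]"
                )
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError(f"chain {self.chain_id}: labels must be 0/1")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedChain):
            return NotImplemented
        return (
            self.chain_id == other.chain_id
            and self.sequence == other.sequence
            and self.ss == other.ss
            and np.allclose(self.rsa, other.rsa, atol=1e-9)
            and np.allclose(self.phi, other.phi, atol=5e-4)
            and np.allclose(self.psi, other.psi, atol=5e-4)
            and np.allclose(self.disorder, other.disorder, atol=1e-9)
            and np.array_equal(self.labels, other.labels)
        )


def read_annotation_file(path, remap_nonstandard: bool = False) -> list[AnnotatedChain]:
    """Read the per-residue annotation TSV into a list of chains.

    Non-canonical residues (X, B, Z, U, J, O) are rejected unless
    ``remap_nonstandard``, in which case they map to the vacancy symbol.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chain_id": str, "aa": str, "ss": str})
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"annotation file {path}: missing column(s) {missing}")

    chains: list[AnnotatedChain] = []
    seen: set[str] = set()
    # contiguous blocks, file order preserved
    block_ids = df["chain_id"].ne(df["chain_id"].shift()).cumsum()
    for _, block in df.groupby(block_ids, sort=False):
        cid = block["chain_id"].iloc[0]
        if cid in seen:
            raise FormatError(
                f"annotation file {path}: rows for chain {cid} are not contiguous"
            )
        seen.add(cid)
        pos = block["position"].to_numpy()
        if not np.array_equal(pos, np.arange(1, len(block) + 1)):
            raise ValidationError(
                f"chain {cid}: positions must run 1..{len(block)} in order"
            )
        seq = []
        for i, aa in enumerate(block["aa"]):
            aa = str(aa).upper()
            if aa in NONSTANDARD:
                if remap_nonstandard:
                    aa = VACANCY_SYMBOL
                else:
                    raise ValidationError(
                        f"chain {cid} position {i + 1}: non-canonical residue {aa!r} "
                        "(use remap_nonstandard to map to vacancy)"
                    )
            seq.append(aa)
        chain = AnnotatedChain(
            chain_id=cid,
            sequence="".join(seq),
            ss="".join(block["ss"]),
            rsa=block["rsa"].to_numpy(dtype=float),
            phi=block["phi"].to_numpy(dtype=float),
            psi=block["psi"].to_numpy(dtype=float),
            disorder=block["disorder"].to_numpy(dtype=float),
            labels=block["label"].to_numpy(),
        )
        chain.validate()
        chains.append(chain)
    return chains


def write_annotation_file(chains: Sequence[AnnotatedChain], path) -> None:
    """Write chains as the annotation TSV (reals at 6 significant digits)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for ch in chains:
            for i in range(len(ch)):
                fh.write(
                    f"{ch.chain_id}\t{i + 1}\t{ch.sequence[i]}\t{ch.ss[i]}\t"
                    f"{ch.rsa[i]:.6g}\t{ch.phi[i]:.6g}\t{ch.psi[i]:.6g}\t"
                    f"{ch.disorder[i]:.6g}\t{int(ch.labels[i])}\n"
                )


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, upper-cased sequence) pairs."""
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(path, "fasta")]
    if not records:
        raise FormatError(f"FASTA file {path}: no records found")
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise FormatError(f"FASTA file {path}: duplicate ids {dupes}")
    return records


def write_fasta(chains: Sequence[AnnotatedChain], path, width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for ch in chains:
            fh.write(f">{ch.chain_id}\n")
            for i in range(0, len(ch.sequence), width):
                fh.write(ch.sequence[i : i + width] + "\n")


def filter_min_length(
    chains: Iterable[AnnotatedChain], min_len: int = 50
) -> list[AnnotatedChain]:
    """Drop chains shorter than ``min_len`` residues (order preserved)."""
    return [c for c in chains if len(c.sequence) >= min_len]
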