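"""Dataset input/output, allele normalization, and dataset accounting.

All tabular formats are TSV with a header row.  Positions are 0-based and
windows are half-open ``[start, start + length)`` throughout.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_VALID_RESIDUES = frozenset(AMINO_ACIDS + "X")

_ALLELE_RE = re.compile(r"^([A-Z]+[0-9]*)\*([0-9]{4})$")


class ValidationError(ValueError):
    """Raised when an input file or record violates its contract."""


def normalize_allele(name: str) -> str:
    """Normalize an HLA allele name to ``LOCUS*NNNN`` form (e.g. DRB1*0401).

    An optional ``HLA-`` prefix is stripped and the name is uppercased.
    Idempotent: normalizing an already-normalized name is a no-op.
    """
    cleaned = name.strip().upper()
    if cleaned.startswith("HLA-"):
        cleaned = cleaned[4:]
    if not _ALLELE_RE.match(cleaned):
        raise ValidationError(
            f"allele {name!r} does not match the locus*4-digit form (e.g. DRB1*0401)"
        )
    return cleaned


@dataclass(frozen=True)
class ProteinRecord:
    """A source antigen sequence with identifier."""

    protein_id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.protein_id:
            raise ValidationError("protein_id must be non-empty")
        if not self.sequence:
            raise ValidationError(f"protein {self.protein_id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_RESIDUES
        if bad:
            raise ValidationError(
                f"protein {self.protein_id!r}: illegal residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class LigandRecord:
    """An MHC-II ligand peptide with its allele and source protein.

    ``start`` is the 0-based offset of the leftmost occurrence of the
    peptide in the source protein.
    """

    ligand_id: str
    peptide: str
    allele: str
    protein_id: str
    set_label: str
    start: int = -1

    def __post_init__(self) -> None:
        if len(self.peptide) < 9:
            raise ValidationError(
                f"ligand {self.ligand_id!r}: peptide shorter than 9 residues"
            )
        if self.set_label not in ("train", "test"):
            raise ValidationError(
                f"ligand {self.ligand_id!r}: set_label must be 'train' or 'test', "
                f"got {self.set_label!r}"
            )

    @property
    def length(self) -> int:
        return len(self.peptide)

    @property
    def span(self) -> tuple[int, int]:
        """Half-open residue span ``(start, start + length)``."""
        return (self.start, self.start + len(self.peptide))


@dataclass
class ResidueFeatureTrack:
    """Per-residue structure/exposure predictions and glycosylation calls."""

    protein_id: str
    rsa: np.ndarray
    p_helix: np.ndarray
    p_strand: np.ndarray
    p_coil: np.ndarray
    nglyc: np.ndarray
    oglyc: np.ndarray

    def __post_init__(self) -> None:
        arrays = [self.rsa, self.p_helix, self.p_strand, self.p_coil, self.nglyc, self.oglyc]
        lengths = {len(a) for a in arrays}
        if len(lengths) != 1:
            raise ValidationError(
                f"track {self.protein_id!r}: per-feature arrays have unequal lengths"
            )
        if np.any(self.rsa < 0):
            raise ValidationError(f"track {self.protein_id!r}: negative RSA value")
        for name, arr in (("p_helix", self.p_helix), ("p_strand", self.p_strand),
                          ("p_coil", self.p_coil)):
            if np.any((arr < 0) | (arr > 1)):
                raise ValidationError(
                    f"track {self.protein_id!r}: {name} outside [0, 1]"
                )

    def __len__(self) -> int:
        return len(self.rsa)


@dataclass(frozen=True)
class AlleleCountSummary:
    """Per-allele ligand counts with totals."""

    counts: dict[str, int]
    total: int
    n_alleles: int

    @classmethod
    def from_counts(cls, counts: dict[str, int]) -> "AlleleCountSummary":
        nonzero = {a: c for a, c in counts.items() if c > 0}
        return cls(counts=dict(counts), total=sum(counts.values()),
                   n_alleles=len(nonzero))


class BindingTable:
    """Per-window binding scores in 1-log50k units, keyed on
    ``(protein_id, start, length, allele)``."""

    def __init__(self, scores: dict[tuple[str, int, int, str], float]):
        self._scores = dict(scores)

    def __len__(self) -> int:
        return len(self._scores)

    def __contains__(self, key: tuple[str, int, int, str]) -> bool:
        return key in self._scores

    def get(self, protein_id: str, start: int, length: int, allele: str) -> float:
        key = (protein_id, start, length, allele)
        try:
            return self._scores[key]
        except KeyError:
            raise ValidationError(
                f"binding table has no score for window {key}"
            ) from None

    def items(self):
        return self._scores.items()


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def _header_line_numbers(path: Path) -> dict[int, int]:
    """Map FASTA record index to the 1-based line number of its header."""
    out = {}
    idx = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                out[idx] = lineno
                idx += 1
    return out


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read source proteins from a FASTA file.

    The header token before the first whitespace is the protein id and
    sequences are uppercased.  Duplicate ids and illegal residues are
    reported with the line number of the offending record.
    """
    path = Path(path)
    lines = _header_line_numbers(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        lineno = lines.get(i, -1)
        pid = rec.id
        if pid in seen:
            raise ValidationError(
                f"{path}:{lineno}: duplicate protein id {pid!r} "
                f"(first seen at line {seen[pid]})"
            )
        seen[pid] = lineno
        try:
            records.append(ProteinRecord(pid, str(rec.seq).upper()))
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from None
    if not records:
        raise ValidationError(f"{path}: no FASTA records found")
    return records


def write_fasta(proteins: list[ProteinRecord], path: str | Path) -> None:
    records = [SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
               for p in proteins]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Ligand table
# ---------------------------------------------------------------------------

_LIGAND_COLUMNS = ["ligand_id", "peptide", "allele", "protein_id", "set_label"]


def read_ligand_table(path: str | Path,
                      proteins: list[ProteinRecord]) -> list[LigandRecord]:
    """Read and validate a TSV ligand table against its source proteins.

    Every peptide must occur as a substring of its referenced protein; the
    leftmost occurrence defines the ligand span (a warning is logged when
    the peptide occurs more than once).  Alleles are normalized to DRB form.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _LIGAND_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    by_id = {p.protein_id: p for p in proteins}
    ligands = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        lig_id = row.ligand_id
        if row.protein_id not in by_id:
            raise ValidationError(
                f"{path}: row {row_no}: ligand {lig_id!r} references unknown "
                f"protein {row.protein_id!r}"
            )
        protein = by_id[row.protein_id]
        peptide = row.peptide.upper()
        start = protein.sequence.find(peptide)
        if start < 0:
            raise ValidationError(
                f"{path}: row {row_no}: ligand {lig_id!r} peptide is not a "
                f"substring of protein {row.protein_id!r}"
            )
        if protein.sequence.find(peptide, start + 1) >= 0:
            logger.warning(
                "ligand %s occurs more than once in protein %s; "
                "using leftmost occurrence at %d", lig_id, row.protein_id, start
            )
        try:
            ligands.append(LigandRecord(
                ligand_id=lig_id,
                peptide=peptide,
                allele=normalize_allele(row.allele),
                protein_id=row.protein_id,
                set_label=row.set_label,
                start=start,
            ))
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {row_no}: {exc}") from None
    return ligands


def write_ligand_table(ligands: list[LigandRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(l.ligand_id, l.peptide, l.allele, l.protein_id, l.set_label)
         for l in ligands],
        columns=_LIGAND_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Residue feature tracks
# ---------------------------------------------------------------------------

_TRACK_COLUMNS = ["protein_id", "pos", "aa", "rsa", "p_helix", "p_strand",
                  "p_coil", "nglyc", "oglyc"]


def read_residue_tracks(path: str | Path) -> dict[str, ResidueFeatureTrack]:
    """Read per-residue feature tracks keyed by protein id.

    Positions must form a contiguous 0-based range for every protein.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    tracks = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        if not np.array_equal(pos, np.arange(len(pos))):
            raise ValidationError(
                f"{path}: track {pid!r}: positions are not a contiguous "
                f"0-based range"
            )
        tracks[str(pid)] = ResidueFeatureTrack(
            protein_id=str(pid),
            rsa=grp["rsa"].to_numpy(dtype=float),
            p_helix=grp["p_helix"].to_numpy(dtype=float),
            p_strand=grp["p_strand"].to_numpy(dtype=float),
            p_coil=grp["p_coil"].to_numpy(dtype=float),
            nglyc=grp["nglyc"].to_numpy(dtype=int).astype(bool),
            oglyc=grp["oglyc"].to_numpy(dtype=int).astype(bool),
        )
    return tracks


def write_residue_tracks(tracks: dict[str, ResidueFeatureTrack],
                         proteins: list[ProteinRecord],
                         path: str | Path) -> None:
    by_id = {p.protein_id: p for p in proteins}
    frames = []
    for pid, t in tracks.items():
        seq = by_id[pid].sequence if pid in by_id else "X" * len(t)
        if pid in by_id and len(t) != len(seq):
            raise ValidationError(
                f"track {pid!r} length {len(t)} != protein length {len(seq)}"
            )
        frames.append(pd.DataFrame({
            "protein_id": pid,
            "pos": np.arange(len(t)),
            "aa": list(seq),
            "rsa": t.rsa,
            "p_helix": t.p_helix,
            "p_strand": t.p_strand,
            "p_coil": t.p_coil,
            "nglyc": t.nglyc.astype(int),
            "oglyc": t.oglyc.astype(int),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Window binding-score table and background scores
# ---------------------------------------------------------------------------

_SCORE_COLUMNS = ["protein_id", "start", "length", "allele", "score_1log50k"]


def read_window_scores(path: str | Path) -> BindingTable:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    scores = {
        (str(r.protein_id), int(r.start), int(r.length),
         normalize_allele(str(r.allele))): float(r.score_1log50k)
        for r in df.itertuples(index=False)
    }
    if len(scores) != len(df):
        raise ValidationError(f"{path}: duplicate window keys")
    return BindingTable(scores)


def write_window_scores(table: BindingTable, path: str | Path) -> None:
    rows = [(pid, start, length, allele, score)
            for (pid, start, length, allele), score in table.items()]
    pd.DataFrame(rows, columns=_SCORE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_background_scores(path: str | Path) -> dict[str, np.ndarray]:
    """Read per-allele random-peptide background scores (columns: allele, score)."""
    df = pd.read_csv(path, sep="\t")
    for col in ("allele", "score"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    return {
        normalize_allele(str(allele)): grp["score"].to_numpy(dtype=float)
        for allele, grp in df.groupby("allele", sort=False)
    }


def write_background_scores(backgrounds: dict[str, np.ndarray],
                            path: str | Path) -> None:
    frames = [pd.DataFrame({"allele": allele, "score": scores})
              for allele, scores in backgrounds.items()]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Accounting
# ---------------------------------------------------------------------------

def summarize_alleles(ligands: list[LigandRecord],
                      set_label: str | None = None) -> AlleleCountSummary:
    """Count ligands per allele, optionally restricted to one set label."""
    counter = Counter(
        l.allele for l in ligands
        if set_label is None or l.set_label == set_label
    )
    return AlleleCountSummary.from_counts(dict(counter))


def balance_by_allele(ligands: list[LigandRecord], cap: int,
                      seed: int) -> list[LigandRecord]:
    """Cap the number of ligands per allele by seeded uniform subsampling.

    Alleles at or under the cap keep all their ligands.  Output preserves
    the input order of the retained ligands and is deterministic given the
    seed; the output size is ``sum(min(count_a, cap))`` over alleles.
    """
    if cap < 0:
        raise ValueError("cap must be >= 0")
    rng = np.random.default_rng(seed)
    by_allele: dict[str, list[int]] = {}
    for i, lig in enumerate(ligands):
        by_allele.setdefault(lig.allele, []).append(i)
    keep: set[int] = set()
    for allele in sorted(by_allele):
        idx = by_allele[allele]
        if len(idx) <= cap:
            keep.update(idx)
        elif cap > 0:
            keep.update(rng.choice(idx, size=cap, replace=False).tolist())
    return [lig for i, lig in enumerate(ligands) if i in keep]
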