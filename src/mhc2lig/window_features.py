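"""Tiling proteins into ligand-length windows and per-window feature means.

Every source protein is cut into overlapping windows of the length of its
ligand (stride 1).  Each window carries the predicted binding score, the
arithmetic means of the residue-level structural features over the window,
and glycosylation-site counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from mhc2lig.data_io import (
    BindingTable,
    LigandRecord,
    ProteinRecord,
    ResidueFeatureTrack,
    ValidationError,
)

FEATURE_NAMES = ("rsa", "helix", "strand", "coil")

_TRACK_ATTR = {"rsa": "rsa", "helix": "p_helix", "strand": "p_strand",
               "coil": "p_coil"}


@dataclass
class PeptideWindow:
    """One ligand-length window of a source protein.

    Feature fields are NaN / unset until :func:`annotate_windows` fills them.
    ``start`` is 0-based; the window spans ``[start, start + length)``.
    """

    protein_id: str
    start: int
    length: int
    sequence: str
    allele: str | None = None
    score_1log50k: float = float("nan")
    rescaled: float = float("nan")
    mean_rsa: float = float("nan")
    mean_helix: float = float("nan")
    mean_strand: float = float("nan")
    mean_coil: float = float("nan")
    glyc_n: int = 0
    glyc_o: int = 0
    is_ligand: bool = False

    @property
    def glyc_count(self) -> int:
        return self.glyc_n + self.glyc_o

    @property
    def is_glycosylated(self) -> bool:
        return self.glyc_count >= 1

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.start + self.length)

    def overlaps(self, other: "PeptideWindow") -> bool:
        """True if the two windows share any residue position (same protein)."""
        if self.protein_id != other.protein_id:
            return False
        return self.start < other.start + other.length and \
            other.start < self.start + self.length


@dataclass
class GlycCount:
    n: int
    o: int

    @property
    def total(self) -> int:
        return self.n + self.o

    @property
    def is_glycosylated(self) -> bool:
        return self.total >= 1


@dataclass
class PairWindows:
    """All windows of one protein-ligand pair, tiled at the ligand's length.

    Exactly one window (the annotated ligand) carries ``is_ligand=True``.
    """

    protein_id: str
    ligand_id: str
    allele: str
    windows: list[PeptideWindow] = field(default_factory=list)

    @property
    def ligand_window(self) -> PeptideWindow:
        for w in self.windows:
            if w.is_ligand:
                return w
        raise ValidationError(
            f"pair {self.ligand_id!r}: no window is flagged as the ligand"
        )

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def tile_protein(protein: ProteinRecord, length: int) -> list[PeptideWindow]:
    """Cut a protein into all overlapping windows of the given length.

    Returns ``L - length + 1`` windows at stride 1, features unset.
    """
    if length < 1:
        raise ValueError("window length must be >= 1")
    if length > len(protein):
        raise ValidationError(
            f"window length {length} exceeds protein {protein.protein_id!r} "
            f"length {len(protein)}"
        )
    return [
        PeptideWindow(
            protein_id=protein.protein_id,
            start=start,
            length=length,
            sequence=protein.sequence[start:start + length],
        )
        for start in range(len(protein) - length + 1)
    ]


def _check_bounds(track: ResidueFeatureTrack, start: int, length: int) -> None:
    if start < 0 or length < 1 or start + length > len(track):
        raise ValidationError(
            f"window [{start}, {start + length}) out of bounds for track "
            f"{track.protein_id!r} of length {len(track)}"
        )


def window_mean(track: ResidueFeatureTrack, start: int, length: int,
                feature: str) -> float:
    """Arithmetic mean of a residue feature over ``[start, start + length)``."""
    if feature not in _TRACK_ATTR:
        raise ValueError(f"unknown feature {feature!r}; expected one of {FEATURE_NAMES}")
    _check_bounds(track, start, length)
    values = getattr(track, _TRACK_ATTR[feature])
    return float(np.mean(values[start:start + length]))


def count_glyc_sites(track: ResidueFeatureTrack, start: int,
                     length: int) -> GlycCount:
    """Count predicted N- and O-glycosylation sites inside a window.

    The window is half-open, so a site exactly at ``start + length`` is
    not counted.  A window is "predicted glycosylated" iff the total is >= 1.
    """
    _check_bounds(track, start, length)
    sl = slice(start, start + length)
    return GlycCount(n=int(np.sum(track.nglyc[sl])),
                     o=int(np.sum(track.oglyc[sl])))


def annotate_windows(windows: list[PeptideWindow],
                     allele: str,
                     tracks: dict[str, ResidueFeatureTrack],
                     binding: BindingTable,
                     ligand_spans: set[tuple[str, int, int]] = frozenset(),
                     ) -> list[PeptideWindow]:
    """Populate windows with binding scores, feature means and glyc counts.

    ``ligand_spans`` identifies the annotated ligand window(s) as
    ``(protein_id, start, length)`` tuples; only those are flagged
    ``is_ligand``.  A missing track or binding score is an error naming
    the offending window.
    """
    out = []
    for w in windows:
        if w.protein_id not in tracks:
            raise ValidationError(f"no residue feature track for protein "
                                  f"{w.protein_id!r}")
        track = tracks[w.protein_id]
        glyc = count_glyc_sites(track, w.start, w.length)
        out.append(replace(
            w,
            allele=allele,
            score_1log50k=binding.get(w.protein_id, w.start, w.length, allele),
            mean_rsa=window_mean(track, w.start, w.length, "rsa"),
            mean_helix=window_mean(track, w.start, w.length, "helix"),
            mean_strand=window_mean(track, w.start, w.length, "strand"),
            mean_coil=window_mean(track, w.start, w.length, "coil"),
            glyc_n=glyc.n,
            glyc_o=glyc.o,
            is_ligand=(w.protein_id, w.start, w.length) in ligand_spans,
        ))
    return out


def build_pair_windows(proteins: list[ProteinRecord],
                       ligands: list[LigandRecord],
                       tracks: dict[str, ResidueFeatureTrack],
                       binding: BindingTable,
                       strict_negatives: bool = False,
                       ) -> list[PairWindows]:
    """Assemble one fully annotated :class:`PairWindows` per ligand.

    Each ligand defines its own protein-ligand pair; its source protein is
    tiled at the ligand's length and all windows except the ligand window
    are negatives.  By default other known ligand windows of the same
    protein are removed from the negatives; ``strict_negatives=True`` keeps
    every non-annotated window as a negative.
    """
    by_id = {p.protein_id: p for p in proteins}
    spans_by_protein: dict[str, set[tuple[int, int]]] = {}
    for lig in ligands:
        spans_by_protein.setdefault(lig.protein_id, set()).add(
            (lig.start, lig.length))
    pairs = []
    for lig in ligands:
        if lig.protein_id not in by_id:
            raise ValidationError(
                f"ligand {lig.ligand_id!r} references unknown protein "
                f"{lig.protein_id!r}"
            )
        protein = by_id[lig.protein_id]
        windows = tile_protein(protein, lig.length)
        annotated = annotate_windows(
            windows, lig.allele, tracks, binding,
            ligand_spans={(lig.protein_id, lig.start, lig.length)},
        )
        if not strict_negatives:
            other = spans_by_protein[lig.protein_id] - {(lig.start, lig.length)}
            annotated = [
                w for w in annotated
                if w.is_ligand or (w.start, w.length) not in other
            ]
        pairs.append(PairWindows(
            protein_id=lig.protein_id,
            ligand_id=lig.ligand_id,
            allele=lig.allele,
            windows=annotated,
        ))
    return pairs
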