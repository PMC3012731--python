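"""Synthetic antigen datasets with configurable planted structure.

Generates complete inputs for the full pipeline — source proteins, one
planted ligand per protein, smoothed per-residue exposure/secondary-
structure tracks, per-window binding scores, sparse glycosylation sites
and per-allele random-peptide backgrounds — with known effect sizes:
ligand windows can be made more exposed (``delta_rsa``), more coil
(``delta_coil``), stronger binders (``ligand_binding_boost``) and less
glycosylated (``glyc_rate_ligand`` below ``glyc_rate_background``).
Setting all deltas to zero produces an exact null dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mhc2lig.data_io import (
    BindingTable,
    LigandRecord,
    ProteinRecord,
    ResidueFeatureTrack,
    write_background_scores,
    write_fasta,
    write_ligand_table,
    write_residue_tracks,
    write_window_scores,
)
from mhc2lig.scaling_model import NATURAL_AA_FREQUENCIES

_AA = np.array(list(NATURAL_AA_FREQUENCIES))
_AA_P = np.array(list(NATURAL_AA_FREQUENCIES.values()))

DEFAULT_ALLELES = {
    "DRB1*0101": (0.45, 0.15),
    "DRB1*0301": (0.25, 0.12),
    "DRB1*0401": (0.35, 0.15),
}


@dataclass
class SyntheticConfig:
    """Knobs of the generator; the seed fully determines the output."""

    n_proteins: int = 100
    protein_length: tuple[int, int] = (120, 200)  # inclusive range
    ligand_length: int = 15
    #: allele -> (location, scale) of its window binding-score distribution
    alleles: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ALLELES))
    delta_rsa: float = 0.0
    delta_coil: float = 0.0
    ligand_binding_boost: float = 0.0
    glyc_rate_background: float = 0.02
    glyc_rate_ligand: float = 0.02
    track_smoothing: int = 9
    background_size: int = 20_000
    seed: int = 0

    def validate(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        lo, hi = self.protein_length
        if lo > hi or lo < 1:
            raise ValueError("invalid protein_length range")
        if self.ligand_length > lo:
            raise ValueError(
                f"ligand_length {self.ligand_length} exceeds minimum protein "
                f"length {lo}"
            )
        for rate in (self.glyc_rate_background, self.glyc_rate_ligand):
            if not 0 <= rate <= 1:
                raise ValueError("glycosylation rates must be in [0, 1]")
        if not self.alleles:
            raise ValueError("at least one allele is required")
        if self.track_smoothing < 1:
            raise ValueError("track_smoothing must be >= 1")


@dataclass
class SyntheticDataset:
    proteins: list[ProteinRecord]
    ligands: list[LigandRecord]
    tracks: dict[str, ResidueFeatureTrack]
    binding: BindingTable
    backgrounds: dict[str, np.ndarray]
    #: realized (post-clip) effect sizes and per-ligand spans
    truth: dict = field(default_factory=dict)


def generate_background_peptides(n: int, length: int,
                                 rng: np.random.Generator | int,
                                 ) -> list[str]:
    """``n`` random peptides drawn i.i.d. from natural residue frequencies."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    letters = rng.choice(_AA, size=(n, length), p=_AA_P)
    return ["".join(row) for row in letters]


def background_scores(n: int, loc: float, scale: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Binding scores of a random-peptide background, clipped to (0, 1]."""
    return np.clip(rng.normal(loc, scale, size=n), 1e-6, 1.0)


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average giving residue tracks realistic autocorrelation."""
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    padded = np.pad(values, window // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[:len(values)]


def _smooth_field(length: int, window: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Standardized smooth noise: zero mean, unit SD, correlation length
    ~``window``.  Standardizing after the moving average keeps the
    between-region variance that plain smoothing would average away."""
    z = _smooth(rng.normal(0.0, 1.0, size=length), window)
    sd = z.std()
    if sd < 1e-12:
        return np.zeros(length)
    return (z - z.mean()) / sd


def _random_sequence(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_AA, size=length, p=_AA_P))


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic dataset with one planted ligand per protein.

    Per protein: RSA is a smoothed Beta-like process; (helix, strand, coil)
    come from a smoothed softmax composition; window binding scores are
    drawn from the protein's allele distribution.  Within the planted
    ligand window, RSA is shifted by ``delta_rsa`` (clipped), coil by
    ``delta_coil`` (helix/strand renormalized), the binding score by
    ``ligand_binding_boost`` (clipped to 1), and glycosylation sites use
    the ligand rate.  Realized post-clip effects are recorded as truth.
    """
    config.validate()
    root = np.random.SeedSequence(config.seed)
    ss = root.spawn(4)
    rng_seq = np.random.default_rng(ss[0])
    rng_track = np.random.default_rng(ss[1])
    rng_score = np.random.default_rng(ss[2])
    rng_bg = np.random.default_rng(ss[3])

    allele_names = sorted(config.alleles)
    lo, hi = config.protein_length
    L_lig = config.ligand_length

    proteins: list[ProteinRecord] = []
    ligands: list[LigandRecord] = []
    tracks: dict[str, ResidueFeatureTrack] = {}
    scores: dict[tuple[str, int, int, str], float] = {}
    realized_rsa, realized_coil, realized_boost = [], [], []

    for i in range(config.n_proteins):
        pid = f"P{i:05d}"
        allele = allele_names[i % len(allele_names)]
        loc, scale = config.alleles[allele]
        length = int(rng_seq.integers(lo, hi + 1))
        lig_start = int(rng_seq.integers(0, length - L_lig + 1))

        # sequence: redraw in the (vanishingly rare) case the planted
        # peptide also occurs upstream of its span
        for _ in range(100):
            sequence = _random_sequence(length, rng_seq)
            peptide = sequence[lig_start:lig_start + L_lig]
            if sequence.find(peptide) == lig_start:
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place a unique ligand peptide")

        # residue tracks: smooth fields with preserved between-region variance
        rsa = np.clip(0.40 + 0.18 * _smooth_field(length, config.track_smoothing,
                                                  rng_track), 0.0, 1.0)
        logits = np.vstack([
            _smooth_field(length, config.track_smoothing, rng_track)
            for _ in range(3)
        ])
        expl = np.exp(logits * 1.5)  # sharpen so states are distinct
        comp = expl / expl.sum(axis=0)
        p_helix, p_strand, p_coil = comp

        sl = slice(lig_start, lig_start + L_lig)
        rsa_before = rsa[sl].mean()
        coil_before = p_coil[sl].mean()
        if config.delta_rsa != 0.0:
            rsa[sl] = np.clip(rsa[sl] + config.delta_rsa, 0.0, 1.0)
        if config.delta_coil != 0.0:
            new_coil = np.clip(p_coil[sl] + config.delta_coil, 0.0, 0.999)
            rest = p_helix[sl] + p_strand[sl]
            factor = np.where(rest > 0, (1.0 - new_coil) / np.where(rest > 0, rest, 1.0), 0.0)
            p_helix[sl] *= factor
            p_strand[sl] *= factor
            p_coil[sl] = new_coil
        realized_rsa.append(rsa[sl].mean() - rsa_before)
        realized_coil.append(p_coil[sl].mean() - coil_before)

        glyc_rate = np.full(length, config.glyc_rate_background)
        glyc_rate[sl] = config.glyc_rate_ligand
        nglyc = rng_track.random(length) < glyc_rate / 2.0
        oglyc = rng_track.random(length) < glyc_rate / 2.0

        tracks[pid] = ResidueFeatureTrack(
            protein_id=pid, rsa=rsa, p_helix=p_helix, p_strand=p_strand,
            p_coil=p_coil, nglyc=nglyc, oglyc=oglyc,
        )

        # per-window binding scores
        n_windows = length - L_lig + 1
        w_scores = np.clip(rng_score.normal(loc, scale, size=n_windows),
                           1e-6, 1.0)
        lig_before = w_scores[lig_start]
        w_scores[lig_start] = min(1.0, lig_before + config.ligand_binding_boost)
        realized_boost.append(w_scores[lig_start] - lig_before)
        for start in range(n_windows):
            scores[(pid, start, L_lig, allele)] = float(w_scores[start])

        proteins.append(ProteinRecord(pid, sequence))
        ligands.append(LigandRecord(
            ligand_id=f"L{i:05d}", peptide=peptide, allele=allele,
            protein_id=pid, set_label="train", start=lig_start,
        ))

    backgrounds = {
        allele: background_scores(config.background_size, *config.alleles[allele],
                                  rng=rng_bg)
        for allele in allele_names
    }

    truth = {
        "realized_delta_rsa": float(np.mean(realized_rsa)),
        "realized_delta_coil": float(np.mean(realized_coil)),
        "realized_binding_boost": float(np.mean(realized_boost)),
        "ligand_spans": {l.ligand_id: l.span for l in ligands},
    }
    return SyntheticDataset(
        proteins=proteins, ligands=ligands, tracks=tracks,
        binding=BindingTable(scores), backgrounds=backgrounds, truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset in the package's standard file formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": outdir / "proteins.fasta",
        "ligands": outdir / "ligands.tsv",
        "tracks": outdir / "tracks.tsv",
        "binding": outdir / "binding.tsv",
        "backgrounds": outdir / "backgrounds.tsv",
    }
    write_fasta(dataset.proteins, paths["proteins"])
    write_ligand_table(dataset.ligands, paths["ligands"])
    write_residue_tracks(dataset.tracks, dataset.proteins, paths["tracks"])
    write_window_scores(dataset.binding, paths["binding"])
    write_background_scores(dataset.backgrounds, paths["backgrounds"])
    return paths


def parse_config_file(path: str | Path) -> SyntheticConfig:
    """Parse a flat ``key = value`` config file into a SyntheticConfig.

    ``protein_length`` is given as ``lo-hi``; alleles as a comma-separated
    ``NAME:loc:scale`` list.
    """
    kwargs = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key == "protein_length":
                lo, _, hi = value.partition("-")
                kwargs[key] = (int(lo), int(hi))
            elif key == "alleles":
                alleles = {}
                for item in value.split(","):
                    name, loc, scale = item.strip().split(":")
                    alleles[name] = (float(loc), float(scale))
                kwargs[key] = alleles
            elif key in ("n_proteins", "ligand_length", "track_smoothing",
                         "background_size", "seed"):
                kwargs[key] = int(value)
            else:
                kwargs[key] = float(value)
    return SyntheticConfig(**kwargs)
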