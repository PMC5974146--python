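"""Feature construction for mitochondrial targeting prediction.

Four blocks, concatenated in fixed order:

* ``AAFreq.NT`` — amino-acid frequencies over the first L residues (20),
* ``PSSM.NT``   — scaled profile rows for the first L residues (20*L, 440 at
  the default L = 22),
* ``PSSM``      — scaled profile rows averaged per residue type over the
  whole sequence, a length-invariant "generalized composition" (400),
* ``Coexpr``    — five co-expression KNN scores.

Profiles come either from PSI-BLAST ASCII PSSM files or from a
substitution-matrix fallback (one BLOSUM62 row per residue) that enables
database-free operation; the fallback is flagged in the profile source so a
prediction can report that no evolutionary profile was used.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .seqdata import AMBIGUOUS_AA, STANDARD_AA, ProteinRecord

ALPHABET = STANDARD_AA  # ACDEFGHIKLMNPQRSTVWY, fixed column order everywhere
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

BLOCK_ORDER = ("AAFreq.NT", "PSSM.NT", "PSSM", "Coexpr")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class ProfileError(ValueError):
    """Profile file inconsistent with the sequence it claims to describe."""


class FeatureError(ValueError):
    """A feature block cannot be computed from the available inputs."""


@dataclass
class ProfileMatrix:
    """Per-position 20-column sequence profile.

    ``rows`` has one row per sequence position (1..L top to bottom) and 20
    columns in the fixed alphabet order.  ``scaled`` records whether the
    per-protein linear rescaling to [-1, 1] has been applied.
    """

    protein_id: str
    rows: np.ndarray
    scaled: bool = False
    source: str = "psiblast_ascii"  # or "substitution_fallback"

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        if self.rows.ndim != 2 or self.rows.shape[1] != 20:
            raise ProfileError(f"{self.protein_id}: profile must be L x 20")
        if self.scaled and (np.abs(self.rows) > 1 + 1e-9).any():
            raise ProfileError(f"{self.protein_id}: scaled entries outside [-1, 1]")


@dataclass(frozen=True)
class FeatureConfig:
    """Which blocks to compute and the N-terminal window length L (residues)."""

    nterm_window: int = 22
    blocks_enabled: tuple[str, ...] = BLOCK_ORDER

    def __post_init__(self) -> None:
        if not (5 <= self.nterm_window <= 50):
            raise FeatureError("nterm_window must be in [5, 50]")
        unknown = set(self.blocks_enabled) - set(BLOCK_ORDER)
        if unknown:
            raise FeatureError(f"unknown feature blocks: {sorted(unknown)}")

    def block_lengths(self) -> dict[str, int]:
        L = self.nterm_window
        return {"AAFreq.NT": 20, "PSSM.NT": 20 * L, "PSSM": 400, "Coexpr": 5}

    def layout(self) -> list[tuple[str, int, int]]:
        lengths = self.block_lengths()
        out, offset = [], 0
        for name in BLOCK_ORDER:
            if name in self.blocks_enabled:
                out.append((name, offset, lengths[name]))
                offset += lengths[name]
        return out

    def total_length(self) -> int:
        return sum(n for _, _, n in self.layout())


@dataclass
class FeatureVector:
    protein_id: str
    values: np.ndarray
    layout: list[tuple[str, int, int]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != sum(n for _, _, n in self.layout):
            raise FeatureError(
                f"{self.protein_id}: vector length {len(self.values)} != layout sum"
            )

    def block(self, name: str) -> np.ndarray:
        for bname, off, n in self.layout:
            if bname == name:
                return self.values[off : off + n]
        raise KeyError(name)


def aa_frequency(sequence: str, window: int | None = 22) -> np.ndarray:
    """Amino-acid frequencies over the first ``window`` residues.

    ``window=None`` uses the whole sequence; a window longer than the
    sequence falls back to the whole sequence.  Ambiguity codes are excluded
    from both numerator and denominator, so the 20 entries sum to one.
    """
    seg = sequence if window is None else sequence[:window]
    counts = np.zeros(20)
    for aa in seg:
        idx = _AA_INDEX.get(aa)
        if idx is not None:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise FeatureError("window contains no standard residues")
    return counts / total


# --- PSI-BLAST ASCII PSSM ---------------------------------------------------

def parse_profile(path: str | Path, sequence: str) -> ProfileMatrix:
    """Parse a PSI-BLAST ASCII PSSM file for ``sequence``.

    The file's own column alphabet (usually ARNDCQEGHILKMFPSTWYV) is read from
    the header line and remapped to the fixed alphabet order.  The residue
    column is cross-checked against the sequence position by position.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    col_alpha: list[str] | None = None
    rows: list[np.ndarray] = []
    residues: list[str] = []
    for line in lines:
        tokens = line.split()
        if col_alpha is None:
            if len(tokens) >= 20 and all(len(t) == 1 and t.isalpha() for t in tokens[:20]):
                col_alpha = tokens[:20]
            continue
        if len(tokens) >= 22 and tokens[0].isdigit():
            pos = int(tokens[0])
            if pos != len(rows) + 1:
                raise ProfileError(f"{path}: rows out of order at position {pos}")
            residues.append(tokens[1])
            try:
                scores = np.array([float(t) for t in tokens[2:22]])
            except ValueError as exc:
                raise ProfileError(f"{path}: bad score at position {pos}") from exc
            rows.append(scores)
    if col_alpha is None or not rows:
        raise ProfileError(f"{path}: no PSSM table found")
    if len(rows) != len(sequence):
        raise ProfileError(
            f"{path}: {len(rows)} profile rows but sequence has {len(sequence)} residues"
        )
    for i, (res, aa) in enumerate(zip(residues, sequence), start=1):
        if res.upper() != aa.upper():
            raise ProfileError(
                f"{path}: residue mismatch at position {i}: file {res!r} vs sequence {aa!r}"
            )
    perm = []
    for aa in ALPHABET:
        try:
            perm.append(col_alpha.index(aa))
        except ValueError as exc:
            raise ProfileError(f"{path}: column alphabet lacks {aa!r}") from exc
    mat = np.vstack(rows)[:, perm]
    return ProfileMatrix(protein_id=path.stem, rows=mat, scaled=False)


def write_profile(path: str | Path, sequence: str, rows: np.ndarray) -> None:
    """Write an unscaled integer profile in the PSI-BLAST ASCII PSSM layout."""
    rows = np.asarray(rows)
    if rows.shape != (len(sequence), 20):
        raise ProfileError("rows must be len(sequence) x 20")
    buf = io.StringIO()
    buf.write("\n")
    buf.write("Last position-specific scoring matrix computed\n")
    buf.write("            " + "  ".join(ALPHABET) + "\n")
    for i, (aa, row) in enumerate(zip(sequence, rows), start=1):
        cells = " ".join(f"{int(round(v)):3d}" for v in row)
        buf.write(f"{i:5d} {aa} {cells}\n")
    Path(path).write_text(buf.getvalue())


def scale_profile(profile: ProfileMatrix) -> ProfileMatrix:
    """Rescale a raw profile linearly to [-1, 1] using its own min and max.

    A constant matrix (degenerate range) maps to all zeros.
    """
    if profile.scaled:
        raise ProfileError(f"{profile.protein_id}: profile already scaled")
    lo, hi = profile.rows.min(), profile.rows.max()
    if hi == lo:
        scaled = np.zeros_like(profile.rows)
    else:
        scaled = 2.0 * (profile.rows - lo) / (hi - lo) - 1.0
    return ProfileMatrix(profile.protein_id, scaled, scaled=True, source=profile.source)


def substitution_fallback_profile(sequence: str, protein_id: str = "") -> ProfileMatrix:
    """Profile whose row at each position is the BLOSUM62 row of that residue.

    Ambiguity codes get zero rows.  Used when no PSI-BLAST profile is
    available; the source flag propagates into prediction metadata.
    """
    rows = np.zeros((len(sequence), 20))
    for i, aa in enumerate(sequence):
        if aa in _AA_INDEX:
            rows[i] = [_BLOSUM62[aa][b] for b in ALPHABET]
    return ProfileMatrix(protein_id or "fallback", rows, scaled=False,
                         source="substitution_fallback")


def nterm_profile_feature(profile: ProfileMatrix, L: int = 22) -> np.ndarray:
    """Flatten the first ``L`` scaled profile rows, zero-padding short chains.

    Position-major order: flat index of (position p, alphabet index a) is
    (p-1)*20 + a.
    """
    if not profile.scaled:
        raise ProfileError("nterm_profile_feature requires a scaled profile")
    if not (5 <= L <= 50):
        raise FeatureError("L must be in [5, 50]")
    out = np.zeros(20 * L)
    n = min(L, profile.rows.shape[0])
    out[: 20 * n] = profile.rows[:n].ravel()
    return out


def global_profile_feature(profile: ProfileMatrix, sequence: str) -> np.ndarray:
    """Average scaled profile rows per residue type; 20 x 20 flattened.

    For each of the 20 types, the mean of all rows whose sequence residue is
    that type (zeros for absent types), concatenated in alphabet order.
    Discards position information but is length-invariant, acting as a
    profile-weighted generalization of whole-sequence composition.
    """
    if not profile.scaled:
        raise ProfileError("global_profile_feature requires a scaled profile")
    if profile.rows.shape[0] != len(sequence):
        raise ProfileError("profile row count != sequence length")
    out = np.zeros((20, 20))
    for aa, idx in _AA_INDEX.items():
        mask = np.fromiter((s == aa for s in sequence), bool, len(sequence))
        if mask.any():
            out[idx] = profile.rows[mask].mean(axis=0)
    return out.ravel()


def assemble_features(
    record: ProteinRecord,
    profile: ProfileMatrix | None,
    knn: np.ndarray | None,
    config: FeatureConfig,
) -> FeatureVector:
    """Concatenate the enabled blocks in fixed order into one vector.

    A missing co-expression score vector becomes five zeros (the unmapped
    convention); a missing profile with a profile block enabled is an error.
    """
    L = config.nterm_window
    needs_profile = {"PSSM.NT", "PSSM"} & set(config.blocks_enabled)
    if needs_profile and profile is None:
        raise FeatureError(f"{record.id}: profile required for {sorted(needs_profile)}")
    if profile is not None and not profile.scaled:
        profile = scale_profile(profile)
    parts: list[np.ndarray] = []
    for name, _, _ in config.layout():
        if name == "AAFreq.NT":
            parts.append(aa_frequency(record.sequence, L))
        elif name == "PSSM.NT":
            parts.append(nterm_profile_feature(profile, L))
        elif name == "PSSM":
            parts.append(global_profile_feature(profile, record.sequence))
        elif name == "Coexpr":
            if knn is None:
                parts.append(np.zeros(5))
            else:
                knn = np.asarray(knn, dtype=float)
                if knn.shape != (5,):
                    raise FeatureError(f"{record.id}: co-expression block must have 5 scores")
                parts.append(knn)
    return FeatureVector(record.id, np.concatenate(parts), config.layout())


def layout_fingerprint(layout: Sequence[tuple[str, int, int]]) -> str:
    return "|".join(f"{n}:{o}:{ln}" for n, o, ln in layout)


# --- feature table IO -------------------------------------------------------

def write_feature_table(path: str | Path, vectors: Sequence[FeatureVector]) -> None:
    """Write feature vectors as delimited text with a block:offset header."""
    if not vectors:
        raise FeatureError("no vectors to write")
    layout = vectors[0].layout
    header = ["protein_id"]
    for name, off, n in layout:
        header += [f"{name}:{off + j}" for j in range(n)]
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for v in vectors:
            if v.layout != layout:
                raise FeatureError("mixed layouts in one feature table")
            fh.write(v.protein_id + "\t" + "\t".join(repr(float(x)) for x in v.values) + "\n")


def read_feature_table(path: str | Path) -> list[FeatureVector]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise FeatureError(f"{path}: empty feature table")
    header = lines[0].split("\t")[1:]
    layout: list[tuple[str, int, int]] = []
    for col in header:
        name, _, off = col.rpartition(":")
        off = int(off)
        if layout and layout[-1][0] == name:
            bname, boff, n = layout[-1]
            layout[-1] = (bname, boff, n + 1)
        else:
            layout.append((name, off, 1))
    out = []
    for line in lines[1:]:
        cells = line.split("\t")
        out.append(FeatureVector(cells[0], np.array([float(c) for c in cells[1:]]), list(layout)))
    return out
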