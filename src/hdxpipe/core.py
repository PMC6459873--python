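"""Domain types shared by every stage of the pipeline.

The types here encode the peptide-level bookkeeping of an HDX-MS experiment:
the protein construct under study, the identified peptic peptides, their
deuterium-uptake measurements over a labeling time course, and the
maximally-labeled control used to quantify back-exchange.

Residue numbering is 1-based and inclusive throughout (a peptide spanning
"residues 99-109" contains 11 residues), matching the convention used in
HDX literature and structure viewers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

from pyteomics import mass as _pyteomics_mass

from .constants import CANONICAL_AA


class HdxError(Exception):
    """Base class for errors raised by this package."""


class ValidationError(HdxError):
    """A value violates a domain invariant."""


class FormatError(HdxError):
    """An input file does not conform to the expected dialect."""


def get_logger(name: str = "hdxpipe") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


# ---------------------------------------------------------------------------
# exchangeable-amide counting


def compute_n_amides(sequence: str, convention: str = "skip_first") -> int:
    """Number of exchangeable backbone amide hydrogens of a peptide.

    Prolines have no amide hydrogen and never count. Two conventions are
    offered because HDX software packages disagree on how many N-terminal
    residues back-exchange too fast to carry signal:

    ``"skip_first"`` (default)
        The first residue is excluded; prolines at positions 2..len are
        subtracted: ``len - 1 - n_prolines(2..len)``.
    ``"skip_first_two"``
        The first two residues are excluded; prolines at positions 3..len
        are subtracted: ``len - 2 - n_prolines(3..len)``.
    """
    if len(sequence) < 2:
        raise ValidationError(
            f"peptide sequence must have at least 2 residues, got {sequence!r}"
        )
    if convention == "skip_first":
        skip = 1
    elif convention == "skip_first_two":
        skip = 2
    else:
        raise ValidationError(f"unknown amide-counting convention {convention!r}")
    body = sequence[skip:]
    return len(body) - body.count("P")


def peptide_monoisotopic_mass(sequence: str) -> float:
    """Undeuterated monoisotopic mass (Da) of a peptide, via pyteomics."""
    return float(_pyteomics_mass.fast_mass(sequence))


# ---------------------------------------------------------------------------
# protein / peptide containers


@dataclass(frozen=True)
class ProteinContext:
    """The protein construct whose peptides are being analyzed.

    Parameters
    ----------
    sequence
        One-letter amino-acid string of the construct (tags included if they
        are part of the expressed protein).
    residue_offset
        Residue number of the first sequence position (1-based). Allows
        analyzing a construct whose numbering starts above 1.
    name
        Free-text label used in logs and output headers.
    """

    sequence: str
    residue_offset: int = 1
    name: str = "protein"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValidationError("protein sequence must be non-empty")
        bad = set(self.sequence) - CANONICAL_AA
        if bad:
            raise ValidationError(
                f"protein sequence contains non-canonical letters: {sorted(bad)}"
            )
        if self.residue_offset < 1:
            raise ValidationError("residue_offset must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def first_residue(self) -> int:
        return self.residue_offset

    @property
    def last_residue(self) -> int:
        return self.residue_offset + len(self.sequence) - 1

    def subsequence(self, start: int, end: int) -> str:
        """Residues ``start``..``end`` (1-based, inclusive, construct numbering)."""
        if start > end:
            raise ValidationError(f"start {start} > end {end}")
        if start < self.first_residue or end > self.last_residue:
            raise ValidationError(
                f"residues {start}-{end} outside construct range "
                f"{self.first_residue}-{self.last_residue}"
            )
        i = start - self.residue_offset
        return self.sequence[i : i + (end - start + 1)]


@dataclass(frozen=True)
class PeptideRecord:
    """An identified peptide: bounds, sequence, amide count, undeuterated mass."""

    start: int
    end: int
    sequence: str
    n_amides: int
    m0: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"peptide start {self.start} > end {self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ValidationError(
                f"peptide {self.start}-{self.end}: sequence length "
                f"{len(self.sequence)} does not match bounds"
            )
        if not (1 <= self.n_amides <= len(self.sequence) - 1):
            raise ValidationError(
                f"peptide {self.start}-{self.end}: n_amides {self.n_amides} outside "
                f"[1, {len(self.sequence) - 1}]"
            )

    @property
    def key(self) -> tuple[int, int, str]:
        """Deduplication/sort key: (start, end, sequence)."""
        return (self.start, self.end, self.sequence)

    @property
    def label(self) -> str:
        return f"{self.start}-{self.end}"

    @classmethod
    def from_bounds(
        cls,
        protein: ProteinContext,
        start: int,
        end: int,
        convention: str = "skip_first",
        m0: float | None = None,
    ) -> "PeptideRecord":
        """Build a record from residue bounds, deriving sequence, amide count
        and (if not supplied) the undeuterated monoisotopic mass."""
        seq = protein.subsequence(start, end)
        return cls(
            start=start,
            end=end,
            sequence=seq,
            n_amides=compute_n_amides(seq, convention),
            m0=peptide_monoisotopic_mass(seq) if m0 is None else float(m0),
        )

    def validate_against(self, protein: ProteinContext) -> None:
        expected = protein.subsequence(self.start, self.end)
        if expected != self.sequence:
            raise ValidationError(
                f"peptide {self.start}-{self.end}: sequence {self.sequence!r} does "
                f"not match protein ({expected!r}) at that range"
            )


@dataclass(frozen=True)
class LabelingDesign:
    """Labeling conditions: deuterium fraction, exposure grid, temperature.

    Defaults reproduce a standard continuous-labeling design: 85% deuterium
    in the exchange buffer and a five-point time grid from 15 s to 8 h at
    25 degrees C.
    """

    d_frac: float = 0.85
    time_grid_min: tuple[float, ...] = (0.25, 1.0, 10.0, 60.0, 480.0)
    temperature_C: float = 25.0

    def __post_init__(self) -> None:
        if not (0.0 < self.d_frac <= 1.0):
            raise ValidationError(f"d_frac must be in (0, 1], got {self.d_frac}")
        grid = tuple(float(t) for t in self.time_grid_min)
        if any(b <= a for a, b in zip(grid, grid[1:])) or not grid:
            raise ValidationError("time grid must be non-empty and strictly increasing")
        if any(t <= 0 for t in grid):
            raise ValidationError("exposure times must be positive")
        object.__setattr__(self, "time_grid_min", grid)


@dataclass(frozen=True)
class UptakeMeasurement:
    """One replicate uptake observation for a peptide in one state at one time."""

    peptide: PeptideRecord
    state: str
    exposure_min: float
    replicate: int
    uptake_D: float
    source_row: int | None = None  # provenance: row index in the input table

    def __post_init__(self) -> None:
        if self.exposure_min <= 0:
            raise ValidationError(
                f"exposure must be positive, got {self.exposure_min} "
                f"(peptide {self.peptide.label}, state {self.state})"
            )
        if self.uptake_D < 0:
            raise ValidationError(
                f"uptake must be >= 0, got {self.uptake_D} "
                f"(peptide {self.peptide.label}, state {self.state})"
            )

    def check_plausible(self, d_frac: float, noise_sd: float = 0.1) -> None:
        """Soft sanity check: warn if uptake exceeds the theoretical maximum
        N*d_frac by more than 3 noise SDs. Never raises."""
        ceiling = self.peptide.n_amides * d_frac + 3.0 * noise_sd
        if self.uptake_D > ceiling:
            warnings.warn(
                f"peptide {self.peptide.label} {self.state} t={self.exposure_min}: "
                f"uptake {self.uptake_D:.2f} D exceeds N*d_frac + 3 sigma "
                f"({ceiling:.2f} D)",
                stacklevel=2,
            )


@dataclass(frozen=True)
class MaxLabelControl:
    """Maximally labeled control for one peptide.

    ``m_max`` is the centroid neutral mass of the control; the control's
    uptake ``m_max - m0`` is the experimentally realized maximum deuterium
    content, used both for back-exchange (QC) and for normalizing uptake.
    """

    peptide: PeptideRecord
    m_max: float

    def __post_init__(self) -> None:
        if self.m_max < self.peptide.m0:
            raise ValidationError(
                f"peptide {self.peptide.label}: max-label mass {self.m_max} below "
                f"undeuterated mass {self.peptide.m0}"
            )

    @property
    def uptake_max_D(self) -> float:
        return self.m_max - self.peptide.m0

    def check_ceiling(self, d_frac: float, tol_D: float = 0.2) -> None:
        """Warn if the control exceeds the theoretical maximum N*d_frac."""
        ceiling = self.peptide.n_amides * d_frac + tol_D
        if self.uptake_max_D > ceiling:
            warnings.warn(
                f"peptide {self.peptide.label}: max-label uptake "
                f"{self.uptake_max_D:.2f} D above N*d_frac ({ceiling:.2f} D)",
                stacklevel=2,
            )
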