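"""Readers and writers for the plain-text formats the pipeline speaks.

Formats
-------
Uptake table
    Comma-separated, UTF-8, one header row, ``#`` comment lines permitted.
    Two dialects: *uptake* (column ``uptake_D`` in daltons) and *centroid*
    (columns ``center_mz`` + ``charge``; uptake is computed against the
    peptide's undeuterated mass). Common commercial state-data column names
    (Start, End, Sequence, State, Exposure, Center, Uptake, z) are accepted
    via an alias map. Unknown columns are preserved, never dropped.
Max-label table
    Columns ``start, end, sequence`` plus either ``m_max`` (neutral mass)
    or ``uptake_max_D``.
Isotope envelope
    Two-column ``mz,intensity`` text with ``# key: value`` metadata header
    lines (peptide bounds/sequence, charge, state, exposure, seed).
Protein sequence
    FASTA (via Biopython) or bare one-letter text.
Config
    TOML, read with the standard library.
"""

from __future__ import annotations

import tomllib
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from Bio import SeqIO

from .constants import MASS_PROTON
from .core import (
    FormatError,
    LabelingDesign,
    MaxLabelControl,
    PeptideRecord,
    ProteinContext,
    ValidationError,
    compute_n_amides,
    get_logger,
    peptide_monoisotopic_mass,
)

log = get_logger(__name__)

#: Commercial state-data export column names -> canonical names.
COLUMN_ALIASES: dict[str, str] = {
    "start": "start",
    "end": "end",
    "sequence": "sequence",
    "state": "state",
    "exposure": "exposure_min",
    "exposure_min": "exposure_min",
    "replicate": "replicate",
    "file": "replicate",
    "uptake": "uptake_D",
    "uptake_d": "uptake_D",
    "center": "center_mz",
    "center_mz": "center_mz",
    "z": "charge",
    "charge": "charge",
    "m0": "m0",
    "maxuptake": "max_uptake",
}


def _canonicalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    renames = {}
    for col in df.columns:
        key = col.strip().lower().replace(" ", "_")
        if key in COLUMN_ALIASES:
            renames[col] = COLUMN_ALIASES[key]
    return df.rename(columns=renames)


def read_protein(path: str | Path, name: str | None = None) -> ProteinContext:
    """Read a protein sequence from FASTA or bare one-letter text."""
    path = Path(path)
    text = path.read_text().strip()
    if text.startswith(">"):
        record = next(SeqIO.parse(str(path), "fasta"))
        return ProteinContext(str(record.seq).upper(), name=name or record.id)
    seq = "".join(text.split()).upper()
    return ProteinContext(seq, name=name or path.stem)


def read_config(path: str | Path) -> dict[str, Any]:
    with open(path, "rb") as fh:
        return tomllib.load(fh)


# ---------------------------------------------------------------------------
# uptake tables


def read_uptake_table(
    path: str | Path,
    protein: ProteinContext,
    design: LabelingDesign | None = None,
    convention: str = "skip_first",
):
    """Read a peptide-level uptake table.

    Returns ``(measurements_df, peptides)`` where ``measurements_df`` is a
    tidy DataFrame with canonical columns ``start, end, sequence, state,
    exposure_min, replicate, uptake_D, source_row`` (extra input columns
    passed through) and ``peptides`` is a dict mapping ``(start, end,
    sequence)`` to :class:`PeptideRecord`, deduplicated across rows.

    Raises :class:`FormatError` naming any missing required column and
    :class:`ValidationError` when a row's sequence does not match the
    protein at its residue range.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, comment="#")
    df = _canonicalize_columns(df)

    required = ["start", "end", "sequence", "state", "exposure_min"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"uptake table {path.name}: missing column(s) {missing}")
    has_uptake = "uptake_D" in df.columns
    has_centroid = "center_mz" in df.columns and "charge" in df.columns
    if not (has_uptake or has_centroid):
        raise FormatError(
            f"uptake table {path.name}: need either column 'uptake_D' or columns "
            "'center_mz' + 'charge'"
        )
    if "replicate" not in df.columns:
        df["replicate"] = 1

    df = df.copy()
    df["source_row"] = np.arange(len(df))
    if (df["exposure_min"] <= 0).any():
        bad = df.loc[df["exposure_min"] <= 0, "source_row"].tolist()
        raise ValidationError(f"non-positive exposure time in rows {bad}")

    # build the deduplicated peptide set, validating sequences as we go
    peptides: dict[tuple[int, int, str], PeptideRecord] = {}
    for start, end, seq in (
        df[["start", "end", "sequence"]].drop_duplicates().itertuples(index=False)
    ):
        start, end, seq = int(start), int(end), str(seq)
        expected = protein.subsequence(start, end)
        if expected != seq:
            raise ValidationError(
                f"row sequence {seq!r} does not match protein at residues "
                f"{start}-{end} ({expected!r})"
            )
        m0 = None
        if "m0" in df.columns:
            sub = df[(df["start"] == start) & (df["end"] == end)]
            m0 = float(sub["m0"].iloc[0])
        peptides[(start, end, seq)] = PeptideRecord(
            start=start,
            end=end,
            sequence=seq,
            n_amides=compute_n_amides(seq, convention),
            m0=peptide_monoisotopic_mass(seq) if m0 is None else m0,
        )

    if not has_uptake:
        m0_col = df.apply(
            lambda r: peptides[(int(r["start"]), int(r["end"]), str(r["sequence"]))].m0,
            axis=1,
        )
        df["uptake_D"] = df["charge"] * (df["center_mz"] - MASS_PROTON) - m0_col

    if (df["uptake_D"] < -1e-9).any():
        n_neg = int((df["uptake_D"] < -1e-9).sum())
        log.warning("%s: %d rows with slightly negative uptake clipped to 0", path.name, n_neg)
    df["uptake_D"] = df["uptake_D"].clip(lower=0.0)

    if design is not None:
        # soft plausibility screen, warn-only
        n_am = df.apply(
            lambda r: peptides[
                (int(r["start"]), int(r["end"]), str(r["sequence"]))
            ].n_amides,
            axis=1,
        )
        over = df["uptake_D"] > n_am * design.d_frac + 0.3
        if over.any():
            log.warning(
                "%s: %d measurements exceed N*d_frac ceiling", path.name, int(over.sum())
            )

    log.info("read %s: %d measurements, %d peptides", path.name, len(df), len(peptides))
    return df, peptides


def read_max_label_table(
    path: str | Path,
    peptides: dict[tuple[int, int, str], PeptideRecord],
) -> dict[tuple[int, int, str], MaxLabelControl]:
    """Read maximally-labeled controls keyed to an existing peptide set."""
    df = pd.read_csv(path, comment="#")
    df = _canonicalize_columns(df)
    for col in ("start", "end", "sequence"):
        if col not in df.columns:
            raise FormatError(f"max-label table: missing column '{col}'")
    controls: dict[tuple[int, int, str], MaxLabelControl] = {}
    for row in df.itertuples(index=False):
        key = (int(row.start), int(row.end), str(row.sequence))
        if key not in peptides:
            log.warning("max-label control for unknown peptide %s-%s skipped", row.start, row.end)
            continue
        pep = peptides[key]
        if hasattr(row, "m_max") and not pd.isna(row.m_max):
            m_max = float(row.m_max)
        elif hasattr(row, "uptake_max_D"):
            m_max = pep.m0 + float(row.uptake_max_D)
        else:
            raise FormatError("max-label table: need column 'm_max' or 'uptake_max_D'")
        controls[key] = MaxLabelControl(peptide=pep, m_max=m_max)
    return controls


def write_measurements(df: pd.DataFrame, path: str | Path, header_lines: list[str] | None = None) -> None:
    """Write a tidy measurement table with optional ``#`` metadata lines."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# isotope envelopes


def write_envelope(env, path: str | Path, extra_meta: dict[str, Any] | None = None) -> None:
    """Write an isotope envelope as m/z,intensity text with metadata header."""
    path = Path(path)
    meta = {
        "peptide_start": env.peptide.start,
        "peptide_end": env.peptide.end,
        "peptide_sequence": env.peptide.sequence,
        "m0": repr(env.peptide.m0),
        "n_amides": env.peptide.n_amides,
        "charge": env.charge,
        "state": env.state,
        "exposure_min": env.exposure_min,
    }
    meta.update(extra_meta or {})
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}: {value}\n")
        fh.write("mz,intensity\n")
        for mz, inten in zip(env.mz, env.intensity):
            fh.write(f"{float(mz)!r},{float(inten)!r}\n")


def read_envelope(path: str | Path):
    """Read an envelope written by :func:`write_envelope`."""
    from .ex1 import IsotopeEnvelope  # local import to avoid a cycle

    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            elif line.lower().startswith("mz"):
                continue
            else:
                a, b = line.split(",")
                rows.append((float(a), float(b)))
    try:
        pep = PeptideRecord(
            start=int(meta["peptide_start"]),
            end=int(meta["peptide_end"]),
            sequence=meta["peptide_sequence"],
            n_amides=int(meta["n_amides"]),
            m0=float(meta["m0"]),
        )
        charge = int(meta["charge"])
    except KeyError as exc:
        raise FormatError(f"envelope {path.name}: missing metadata key {exc}") from exc
    mz = np.array([r[0] for r in rows])
    intensity = np.array([r[1] for r in rows])
    return IsotopeEnvelope(
        mz=mz,
        intensity=intensity,
        charge=charge,
        peptide=pep,
        state=meta.get("state", ""),
        exposure_min=float(meta.get("exposure_min", "nan")),
    )


# ---------------------------------------------------------------------------
# summary table

SUMMARY_PREAMBLE = (
    "column order: peptide bounds/sequence/n_amides, back-exchange, then per "
    "state x time: mean uptake (D), SD (D), n; then per comparison: CI "
    "threshold (D), verdict, rule"
)


def write_summary_table(summary: pd.DataFrame, path: str | Path, meta: dict[str, Any] | None = None) -> None:
    """Write the per-peptide summary table produced by the pipeline.

    The column order is fixed by construction in
    :func:`hdxpipe.pipeline.build_summary`; a header comment documents it.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {SUMMARY_PREAMBLE}\n")
        for key, value in (meta or {}).items():
            fh.write(f"# {key}: {value}\n")
        summary.to_csv(fh, index=False)


def read_summary_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
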