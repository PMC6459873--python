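"""Per-peptide uptake statistics, back-exchange and butterfly comparisons.

The quantities here are the descriptive layer of a peptide-level HDX-MS
analysis: replicate means and standard deviations of deuterium uptake per
(peptide, state, time) cell, the back-exchange of each peptide computed
from its maximally-labeled control,

    BE% = (1 - (m_max - m0) / (N * d_frac)) * 100,

uptake normalized to the max-label control (a plain ratio, flagged but not
clamped when it exceeds 1), and the mirrored ("butterfly") arrangement of
two states' normalized uptake used for visual state comparison.

Reported uptake is never back-exchange corrected by default; BE serves as a
QC quantity. An explicitly labeled corrected view is available via
:func:`correct_for_back_exchange`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    MaxLabelControl,
    PeptideRecord,
    ValidationError,
    get_logger,
)

log = get_logger(__name__)

PeptideKey = tuple[int, int, str]


@dataclass
class UptakeSeries:
    """Mean uptake time course of one peptide in one state.

    ``sd_D`` is the sample standard deviation (n - 1 denominator), NaN
    where fewer than two replicates exist; means are computed only over
    available replicates, never imputed.
    """

    peptide: PeptideRecord
    state: str
    times: np.ndarray
    mean_D: np.ndarray
    sd_D: np.ndarray
    n: np.ndarray
    control: MaxLabelControl | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.mean_D = np.asarray(self.mean_D, float)
        self.sd_D = np.asarray(self.sd_D, float)
        self.n = np.asarray(self.n, int)
        order = np.argsort(self.times)
        self.times = self.times[order]
        self.mean_D = self.mean_D[order]
        self.sd_D = self.sd_D[order]
        self.n = self.n[order]

    def at(self, t: float) -> float:
        idx = np.flatnonzero(np.isclose(self.times, t))
        if idx.size == 0:
            raise ValidationError(
                f"peptide {self.peptide.label} {self.state}: no measurement at t={t}"
            )
        return float(self.mean_D[idx[0]])


def summarize_uptake(
    measurements: pd.DataFrame,
    peptides: dict[PeptideKey, PeptideRecord],
    controls: dict[PeptideKey, MaxLabelControl] | None = None,
) -> dict[tuple[PeptideKey, str], UptakeSeries]:
    """Aggregate replicate measurements into per-(peptide, state) series.

    ``measurements`` is the tidy table produced by the reader or the
    simulator (columns ``start, end, sequence, state, exposure_min,
    uptake_D``). Cells absent from the input are absent from the series.
    Replicate order does not affect the result.
    """
    if measurements.empty:
        return {}
    grouped = (
        measurements.groupby(["start", "end", "sequence", "state", "exposure_min"])[
            "uptake_D"
        ]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    out: dict[tuple[PeptideKey, str], UptakeSeries] = {}
    for (start, end, seq, state), sub in grouped.groupby(
        ["start", "end", "sequence", "state"]
    ):
        key = (int(start), int(end), str(seq))
        if key not in peptides:
            raise ValidationError(f"measurement references unknown peptide {key}")
        out[(key, state)] = UptakeSeries(
            peptide=peptides[key],
            state=str(state),
            times=sub["exposure_min"].to_numpy(),
            mean_D=sub["mean"].to_numpy(),
            sd_D=sub["std"].to_numpy(),  # NaN where count == 1
            n=sub["count"].to_numpy(),
            control=(controls or {}).get(key),
        )
    return out


def summary_frame(series: dict[tuple[PeptideKey, str], UptakeSeries]) -> pd.DataFrame:
    """Flatten a series mapping back into a tidy DataFrame."""
    rows = []
    for (key, state), s in series.items():
        for t, m, sd, n in zip(s.times, s.mean_D, s.sd_D, s.n):
            rows.append(
                {
                    "start": key[0],
                    "end": key[1],
                    "sequence": key[2],
                    "state": state,
                    "exposure_min": t,
                    "mean_D": m,
                    "sd_D": sd,
                    "n": int(n),
                }
            )
    return pd.DataFrame(rows).sort_values(
        ["start", "end", "state", "exposure_min"], ignore_index=True
    )


# ---------------------------------------------------------------------------
# back-exchange


@dataclass(frozen=True)
class BackExchangeResult:
    """Back-exchange of one peptide; flagged when outside [0, 100]%."""

    peptide: PeptideRecord
    be_percent: float

    @property
    def flagged(self) -> bool:
        return not (0.0 <= self.be_percent <= 100.0)

    @property
    def be_fraction(self) -> float:
        return self.be_percent / 100.0


def back_exchange(m_max: float, m0: float, n_amides: int, d_frac: float) -> float:
    """Back-exchange percentage from a maximally-labeled control.

    ``BE% = (1 - (m_max - m0) / (N * d_frac)) * 100``. Values outside
    [0, 100] are returned as-is with a warning - a negative BE diagnoses an
    inconsistent control or undeuterated mass rather than a physical loss.
    """
    if n_amides < 1:
        raise ValidationError("n_amides must be >= 1")
    if not (0.0 < d_frac <= 1.0):
        raise ValidationError(f"d_frac must be in (0, 1], got {d_frac}")
    be = (1.0 - (m_max - m0) / (n_amides * d_frac)) * 100.0
    if not (0.0 <= be <= 100.0):
        warnings.warn(
            f"back-exchange {be:.1f}% outside [0, 100]%: control or m0 inconsistent",
            stacklevel=2,
        )
    return be


def back_exchange_from_control(control: MaxLabelControl, d_frac: float) -> BackExchangeResult:
    be = back_exchange(control.m_max, control.peptide.m0, control.peptide.n_amides, d_frac)
    return BackExchangeResult(peptide=control.peptide, be_percent=be)


def correct_for_back_exchange(uptake_D: float, be_percent: float) -> float:
    """Explicitly labeled BE-corrected uptake: ``uptake / (1 - BE)``.

    Not applied anywhere by default; plotted and tabulated uptake is raw.
    """
    frac = be_percent / 100.0
    if frac >= 1.0:
        raise ValidationError("cannot correct for 100% back-exchange")
    return uptake_D / (1.0 - frac)


# ---------------------------------------------------------------------------
# normalized uptake and butterfly comparison


def normalized_uptake(uptake_D: float, uptake_max_D: float) -> float:
    """Uptake as a fraction of the max-label control's uptake.

    Plain ratio; values above 1 are flagged with a warning, never clamped.
    Raises when the control uptake is non-positive (the peptide is then
    marked not-computable by callers).
    """
    if not uptake_max_D > 0:
        raise ValidationError(
            f"max-label uptake must be positive to normalize, got {uptake_max_D}"
        )
    ratio = uptake_D / uptake_max_D
    if ratio > 1.0:
        warnings.warn(f"normalized uptake {ratio:.3f} exceeds 1", stacklevel=2)
    return ratio


def butterfly_series(
    series_a: dict[tuple[PeptideKey, str], UptakeSeries] | dict[PeptideKey, UptakeSeries],
    series_b: dict,
    timepoint: float,
    state_a: str | None = None,
    state_b: str | None = None,
) -> pd.DataFrame:
    """Mirrored normalized-uptake comparison of two states at one time point.

    Accepts either ``{(key, state): series}`` mappings (with the state
    selected by ``state_a``/``state_b``) or plain ``{key: series}``
    mappings. Rows are ordered by peptide position N- to C-terminal
    ((start, end) lexicographic); state A is positive, state B negated.
    Peptides present in only one state are dropped with a log message;
    disjoint peptide sets are an error.
    """

    def _select(mapping: dict, state: str | None) -> dict[PeptideKey, UptakeSeries]:
        first = next(iter(mapping))
        if isinstance(first, tuple) and len(first) == 2 and isinstance(first[1], str):
            return {k: s for (k, st), s in mapping.items() if state is None or st == state}
        return dict(mapping)

    a = _select(series_a, state_a)
    b = _select(series_b, state_b)
    shared = sorted(set(a) & set(b))
    if not shared:
        raise ValidationError("butterfly comparison: peptide sets are disjoint")
    dropped = (set(a) | set(b)) - set(shared)
    if dropped:
        log.info("butterfly: dropped %d peptides present in only one state", len(dropped))

    rows = []
    for idx, key in enumerate(shared, start=1):
        sa, sb = a[key], b[key]
        if sa.control is None or sb.control is None:
            log.info("butterfly: peptide %s-%s has no max-label control, skipped", key[0], key[1])
            continue
        try:
            na = normalized_uptake(sa.at(timepoint), sa.control.uptake_max_D)
            nb = normalized_uptake(sb.at(timepoint), sb.control.uptake_max_D)
        except ValidationError:
            continue
        rows.append(
            {
                "peptide_index": idx,
                "start": key[0],
                "end": key[1],
                "sequence": key[2],
                "exposure_min": timepoint,
                "normalized_a": na,
                "normalized_b_mirrored": -nb,
            }
        )
    return pd.DataFrame(rows)
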