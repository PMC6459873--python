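"""Forward simulation of HDX-MS datasets with known ground truth.

The generator emulates the statistical structure of a peptide-level HDX-MS
study of a polytopic membrane transporter: 62 peptic peptides over a
648-residue construct covering ~69% of the sequence, a five-point labeling
time grid (0.25-480 min) at 85% deuterium, triplicate measurements at the
0.25/10/60 min time points, per-peptide back-exchange, additive replicate
noise, EX2 kinetics everywhere except one designated EX1 segment (residues
99-109) whose two populations are separated by ~6 deuterons, and a
triplicate 1-48 nM saturation binding assay.

Exchange kinetics follow the Linderstrom-Lang model: each amide exchanges
with observed rate ``k_obs = k_int / pf`` where ``pf >= 1`` is its
protection factor. Under EX2 the per-amide deuteration probability at time
``t`` is ``d_frac * (1 - exp(-k_obs t))``. Under EX1 a peptide is a
two-population mixture whose open fraction grows as ``1 - exp(-k_open t)``
and whose open population has a block of correlated amides fully exchanged.

Every stochastic draw flows from a single top-level seed; the same seed
produces byte-identical output files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import MASS_DH, MASS_PROTON
from .core import (
    LabelingDesign,
    PeptideRecord,
    ProteinContext,
    ValidationError,
    get_logger,
)
from .ex1 import IsotopeEnvelope

log = get_logger(__name__)

PeptideKey = tuple[int, int, str]

DEFAULT_K_INT_PER_MIN = 100.0  # fast relative to the 0.25-min first time point
DEFAULT_NOISE_SD_D = 0.079
DEFAULT_BACK_EXCHANGE = 0.25
DEFAULT_REPLICATE_PLAN = {0.25: 3, 1.0: 1, 10.0: 3, 60.0: 3, 480.0: 1}


# ---------------------------------------------------------------------------
# kinetics primitives


@dataclass(frozen=True)
class AmideKinetics:
    """Per-amide intrinsic rates and protection factors of one peptide."""

    k_int: np.ndarray  # min^-1
    pf: np.ndarray  # dimensionless, >= 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_int", np.atleast_1d(np.asarray(self.k_int, float)))
        object.__setattr__(self, "pf", np.atleast_1d(np.asarray(self.pf, float)))
        k_int, pf = self.k_int, self.pf
        if k_int.size == 1 and pf.size > 1:
            object.__setattr__(self, "k_int", np.full(pf.size, float(k_int[0])))
        if self.k_int.shape != self.pf.shape:
            raise ValidationError("k_int and pf must have matching shapes")
        if np.any(self.k_int <= 0):
            raise ValidationError("intrinsic rates must be positive")
        if np.any(self.pf < 1):
            raise ValidationError("protection factors must be >= 1")

    @property
    def k_obs(self) -> np.ndarray:
        return self.k_int / self.pf

    @classmethod
    def from_protection(cls, pf, k_int: float = DEFAULT_K_INT_PER_MIN) -> "AmideKinetics":
        pf = np.atleast_1d(np.asarray(pf, float))
        return cls(k_int=np.full(pf.size, k_int), pf=pf)


def ex2_probabilities(kinetics: AmideKinetics, t_min: float, d_frac: float) -> np.ndarray:
    """Per-amide deuteration probability under EX2 at time ``t_min``."""
    if t_min < 0:
        raise ValidationError(f"labeling time must be >= 0, got {t_min}")
    return d_frac * -np.expm1(-kinetics.k_obs * t_min)


def simulate_ex2_uptake(kinetics: AmideKinetics, t_min, d_frac: float):
    """Expected peptide uptake (deuterons) under EX2 kinetics.

    ``uptake(t) = d_frac * sum_i (1 - exp(-k_obs,i t))``; monotone
    non-decreasing in ``t`` and bounded by ``d_frac * N``. ``t_min`` may be
    a scalar or an array of times.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValidationError("labeling time must be >= 0")
    uptake = d_frac * np.sum(-np.expm1(-np.outer(np.atleast_1d(t), kinetics.k_obs)), axis=-1)
    return float(uptake[0]) if t.ndim == 0 else uptake


@dataclass(frozen=True)
class Ex1Spec:
    """Two-population (EX1) kinetics for one peptide.

    The closed population exchanges per-amide with rates ``k_closed`` (EX2
    within the population). The open population additionally has the amides
    flagged in ``correlated`` fully exchanged - these are the amides whose
    hydrogen bonds break together in the slow opening event, and their
    count sets the inter-population separation. The open fraction at time
    ``t`` is ``1 - exp(-k_open t)``.
    """

    k_open_per_min: float
    k_closed: np.ndarray  # min^-1, per amide
    correlated: np.ndarray  # bool mask, per amide

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_closed", np.asarray(self.k_closed, float))
        object.__setattr__(self, "correlated", np.asarray(self.correlated, bool))
        if self.k_open_per_min <= 0:
            raise ValidationError("k_open must be positive")
        if self.k_closed.shape != self.correlated.shape:
            raise ValidationError("k_closed and correlated must have matching shapes")
        if np.any(self.k_closed < 0):
            raise ValidationError("closed-population rates must be >= 0")

    def population_probabilities(
        self, t_min: float, d_frac: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """(closed, open) per-amide deuteration probabilities at ``t_min``."""
        if t_min < 0:
            raise ValidationError("labeling time must be >= 0")
        closed = d_frac * -np.expm1(-self.k_closed * t_min)
        open_ = closed.copy()
        open_[self.correlated] = d_frac
        return closed, open_

    def expected_separation_D(self, d_frac: float, t_min: float = 0.0) -> float:
        closed, open_ = self.population_probabilities(t_min, d_frac)
        return float(np.sum(open_ - closed))


def simulate_ex1_mixture(
    spec: Ex1Spec, t_min: float, d_frac: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Open-population fraction and both population probability vectors.

    Returns ``(fraction_open, closed_probs, open_probs)``. The mixture's
    expected centroid uptake is
    ``(1 - f) * sum(closed) + f * sum(open)``.
    """
    if t_min < 0:
        raise ValidationError("labeling time must be >= 0")
    fraction_open = float(-np.expm1(-spec.k_open_per_min * t_min))
    closed, open_ = spec.population_probabilities(t_min, d_frac)
    return fraction_open, closed, open_


# ---------------------------------------------------------------------------
# isotope envelopes


def deuteron_distribution(per_amide_probs: np.ndarray) -> np.ndarray:
    """Exact Poisson-binomial distribution of the deuteron count.

    Computed by iterative convolution of the per-amide Bernoulli
    distributions; returns probabilities for 0..N deuterons.
    """
    probs = np.asarray(per_amide_probs, dtype=float)
    if np.any((probs < 0) | (probs > 1)):
        raise ValidationError("per-amide probabilities must be in [0, 1]")
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf


def thin_probabilities(per_amide_probs: np.ndarray, be_fraction: float) -> np.ndarray:
    """Apply back-exchange to per-amide probabilities (independent thinning)."""
    if not (0.0 <= be_fraction < 1.0):
        raise ValidationError(f"back-exchange fraction must be in [0, 1), got {be_fraction}")
    return np.asarray(per_amide_probs, float) * (1.0 - be_fraction)


def apply_back_exchange(uptake_D, be_fraction: float):
    """Observed uptake after fractional back-exchange loss."""
    if not (0.0 <= be_fraction < 1.0):
        raise ValidationError(f"back-exchange fraction must be in [0, 1), got {be_fraction}")
    return np.asarray(uptake_D, float) * (1.0 - be_fraction) if np.ndim(uptake_D) else float(
        uptake_D * (1.0 - be_fraction)
    )


def envelope_from_uptake(
    peptide: PeptideRecord,
    per_amide_probs: np.ndarray,
    charge: int = 2,
    mixing: tuple[np.ndarray, float] | None = None,
    natural_isotopes: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    state: str = "",
    exposure_min: float = float("nan"),
) -> IsotopeEnvelope:
    """Build a stick-spectrum isotope envelope from per-amide probabilities.

    The deuteron-count distribution is the exact Poisson binomial; when
    ``mixing=(open_probs, weight_open)`` is given the distribution is the
    weighted two-population mixture. Peaks sit at
    ``(m0 + d * 1.00628 + z * 1.00728) / z``. An optional natural-isotope
    distribution is convolved in; optional additive Gaussian intensity
    noise (SD as a fraction of the base peak) is applied before the final
    max-1 normalization.
    """
    pmf = deuteron_distribution(per_amide_probs)
    if mixing is not None:
        other_probs, weight = mixing
        if not (0.0 <= weight <= 1.0):
            raise ValidationError("mixture weight must be in [0, 1]")
        other = deuteron_distribution(other_probs)
        n = max(pmf.size, other.size)
        pmf = (1.0 - weight) * np.pad(pmf, (0, n - pmf.size)) + weight * np.pad(
            other, (0, n - other.size)
        )
    if natural_isotopes is not None:
        pmf = np.convolve(pmf, np.asarray(natural_isotopes, float))
    if pmf.size < 5:  # envelope container requires >= 5 points
        pmf = np.pad(pmf, (0, 5 - pmf.size))
    d = np.arange(pmf.size)
    mz = (peptide.m0 + d * MASS_DH + charge * MASS_PROTON) / charge
    intensity = pmf.copy()
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        intensity = intensity + rng.normal(0.0, noise_sd * intensity.max(), intensity.size)
        intensity = np.clip(intensity, 0.0, None)
    return IsotopeEnvelope(
        mz=mz,
        intensity=intensity,
        charge=charge,
        peptide=peptide,
        state=state,
        exposure_min=exposure_min,
    )


# ---------------------------------------------------------------------------
# study-level ground truth


@dataclass(frozen=True)
class DesignedRegion:
    """A residue region with a designed uptake change in the test state.

    ``delta_D > 0`` means increased deuterium uptake (destabilization) in
    the test state relative to the reference state.
    """

    start: int
    end: int
    delta_D: float

    def overlaps(self, peptide: PeptideRecord) -> bool:
        return not (peptide.end < self.start or peptide.start > self.end)


@dataclass
class StudyTruth:
    """Complete ground truth for one simulated two-state HDX study."""

    protein: ProteinContext
    peptides: list[PeptideRecord]
    pf: dict[PeptideKey, np.ndarray]
    states: tuple[str, str] = ("Na", "K")
    reference_state: str = "Na"
    designed_regions: tuple[DesignedRegion, ...] = ()
    ex1: dict[tuple[PeptideKey, str], Ex1Spec] = field(default_factory=dict)
    k_int_per_min: float = DEFAULT_K_INT_PER_MIN
    noise_sd: float = DEFAULT_NOISE_SD_D
    back_exchange: dict[PeptideKey, float] = field(default_factory=dict)
    replicate_plan: dict[float, int] = field(default_factory=lambda: dict(DEFAULT_REPLICATE_PLAN))
    seed: int = 0

    def __post_init__(self) -> None:
        keys = {p.key for p in self.peptides}
        for region in self.designed_regions:
            if not any(region.overlaps(p) for p in self.peptides):
                raise ValidationError(
                    f"designed region {region.start}-{region.end} maps onto no peptide"
                )
        for (key, state), _ in self.ex1.items():
            if key not in keys:
                raise ValidationError(f"EX1 designation references unknown peptide {key}")
            if state not in self.states:
                raise ValidationError(f"EX1 designation references unknown state {state!r}")

    @property
    def test_state(self) -> str:
        return next(s for s in self.states if s != self.reference_state)

    def be_of(self, key: PeptideKey) -> float:
        return self.back_exchange.get(key, DEFAULT_BACK_EXCHANGE)

    def region_delta(self, peptide: PeptideRecord) -> float:
        return sum(r.delta_D for r in self.designed_regions if r.overlaps(peptide))

    def to_jsonable(self) -> dict:
        return {
            "seed": self.seed,
            "protein_name": self.protein.name,
            "protein_length": len(self.protein),
            "states": list(self.states),
            "reference_state": self.reference_state,
            "noise_sd": self.noise_sd,
            "k_int_per_min": self.k_int_per_min,
            "replicate_plan": {str(t): n for t, n in self.replicate_plan.items()},
            "designed_regions": [
                {"start": r.start, "end": r.end, "delta_D": r.delta_D}
                for r in self.designed_regions
            ],
            "ex1_peptides": [
                {
                    "start": key[0],
                    "end": key[1],
                    "state": state,
                    "k_open_per_min": spec.k_open_per_min,
                    "n_correlated": int(spec.correlated.sum()),
                }
                for (key, state), spec in self.ex1.items()
            ],
            "peptides": [
                {
                    "start": p.start,
                    "end": p.end,
                    "sequence": p.sequence,
                    "n_amides": p.n_amides,
                    "back_exchange": self.be_of(p.key),
                    "log10_pf": [float(v) for v in np.log10(self.pf[p.key])],
                }
                for p in self.peptides
            ],
        }


# -- default study layout ----------------------------------------------------

_PROTEIN_LENGTH = 648  # 630-residue transporter + C-terminal protease site and His tag
_MAP_RNG_SEED = 617  # fixed: the peptide map is part of the study design, not noise


def _default_protein() -> ProteinContext:
    """Deterministic pseudo-random 648-residue construct sequence.

    Prolines are kept rare (~2%) and excluded from the EX1 segment
    (residues 99-109) so that segment retains its full complement of ten
    exchangeable amides.
    """
    rng = np.random.default_rng(_MAP_RNG_SEED)
    alphabet = np.array(list("ACDEFGHIKLMNQRSTVWY"))  # no P
    seq = rng.choice(alphabet, size=_PROTEIN_LENGTH)
    pro_sites = rng.choice(_PROTEIN_LENGTH, size=13, replace=False)
    for i in pro_sites:
        if not (98 <= i <= 108):  # 0-based residues 99..109
            seq[i] = "P"
    return ProteinContext("".join(seq), name="synthetic-transporter")


def default_peptide_intervals() -> list[tuple[int, int]]:
    """The 62 default peptide intervals (1-based, inclusive).

    Coverage starts at residue 70 (the N-terminal tail is unrecovered), has
    a gap at residues 96-98 flanking the 99-109 EX1 segment, and leaves the
    C-terminal tag uncovered; the union covers 448 of 648 residues (69.1%).
    """
    intervals: list[tuple[int, int]] = [(70, 77), (78, 86), (87, 94), (99, 109)]
    lengths = [9] * 4 + [8] * 47
    start = 110
    for i, length in enumerate(lengths):
        intervals.append((start, start + length - 1))
        start += length
        if (i + 1) % 6 == 0 and i < len(lengths) - 1:
            start += 14  # inter-run coverage gap
    # seven overlapping peptides spanning adjacent covered blocks
    overlaps = [(70, 86)]
    for j in range(6):
        a = intervals[4 + 6 * j]
        b = intervals[5 + 6 * j]
        overlaps.append((a[0], b[1]))
    intervals.extend(overlaps)
    intervals.sort()
    return intervals


def default_study_truth(
    seed: int = 0,
    designed_regions: tuple[DesignedRegion, ...] = (),
    include_ex1: bool = True,
    noise_sd: float = DEFAULT_NOISE_SD_D,
    back_exchange: float = DEFAULT_BACK_EXCHANGE,
    states: tuple[str, str] = ("Na", "K"),
    convention: str = "skip_first",
) -> StudyTruth:
    """Build the default 62-peptide two-state study truth.

    Per-amide protection factors are drawn log-uniformly over 10..1e6
    (observed exchange timescales spanning the 0.25-480 min grid and
    beyond); peptides overlapping a designed region draw from the slower
    3..6 decades so the designed uptake offset is not clipped by the
    ``N * d_frac`` saturation bound. When ``include_ex1`` is true, the
    99-109 segment gets EX1 kinetics in the test state: seven correlated
    amides (expected population separation 7 * d_frac = 5.95 D at 85%
    deuterium) opening at 0.03 / min.
    """
    protein = _default_protein()
    peptides = [
        PeptideRecord.from_bounds(protein, a, b, convention=convention)
        for a, b in default_peptide_intervals()
    ]
    rng = np.random.default_rng([seed, 0])
    pf: dict[PeptideKey, np.ndarray] = {}
    for pep in peptides:
        in_region = any(r.overlaps(pep) for r in designed_regions)
        lo, hi = (3.0, 6.0) if in_region else (1.0, 6.0)
        pf[pep.key] = 10.0 ** rng.uniform(lo, hi, size=pep.n_amides)

    ex1: dict[tuple[PeptideKey, str], Ex1Spec] = {}
    if include_ex1:
        tm1b = next(p for p in peptides if (p.start, p.end) == (99, 109))
        n = tm1b.n_amides
        correlated = np.zeros(n, dtype=bool)
        correlated[:7] = True
        k_closed = np.full(n, 1e-9)
        k_closed[~correlated] = 3.0  # fast amides, exchanged within a minute
        test_state = next(s for s in states if s != states[0])
        ex1[(tm1b.key, test_state)] = Ex1Spec(
            k_open_per_min=0.03, k_closed=k_closed, correlated=correlated
        )
        # in the reference state the same segment is simply well protected
        pf[tm1b.key] = np.where(correlated, 1e9, DEFAULT_K_INT_PER_MIN / 3.0)

    return StudyTruth(
        protein=protein,
        peptides=peptides,
        pf=pf,
        states=states,
        reference_state=states[0],
        designed_regions=tuple(designed_regions),
        ex1=ex1,
        noise_sd=noise_sd,
        back_exchange={p.key: back_exchange for p in peptides},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# study generation


@dataclass
class StudyData:
    """In-memory output of :func:`generate_study`."""

    truth: StudyTruth
    design: LabelingDesign
    measurements: pd.DataFrame
    max_label: pd.DataFrame
    envelopes: list[IsotopeEnvelope]

    def peptide_records(self) -> dict[PeptideKey, PeptideRecord]:
        return {p.key: p for p in self.truth.peptides}


def expected_observed_uptake(
    truth: StudyTruth, pep: PeptideRecord, state: str, t: float, d_frac: float
) -> float:
    """Noiseless observed (post-back-exchange) mean uptake of one cell.

    Designed region offsets are specified on the observed-uptake scale and
    applied after back-exchange, so a designed +1.5 D difference appears as
    a 1.5 D difference in the measured tables.
    """
    be = truth.be_of(pep.key)
    spec = truth.ex1.get((pep.key, state))
    if spec is not None:
        f, closed, open_ = simulate_ex1_mixture(spec, t, d_frac)
        return float((1 - f) * closed.sum() + f * open_.sum()) * (1.0 - be)
    kin = AmideKinetics.from_protection(truth.pf[pep.key], truth.k_int_per_min)
    uptake = simulate_ex2_uptake(kin, t, d_frac) * (1.0 - be)
    if state == truth.test_state:
        ceiling = pep.n_amides * d_frac * (1.0 - be)
        uptake = float(np.clip(uptake + truth.region_delta(pep), 0.0, ceiling))
    return uptake


def generate_study(
    truth: StudyTruth,
    design: LabelingDesign | None = None,
    out_dir: str | Path | None = None,
    envelope_charge: int = 2,
    envelope_noise_sd: float = 0.01,
) -> StudyData:
    """Simulate the full study and optionally write reader-compatible files.

    Emits the uptake table (uptake dialect), max-label control table,
    isotope envelopes for EX1-designated peptides (in both states, across
    the whole time grid) and a JSON ground-truth file. Replicate noise is
    additive Gaussian with ``truth.noise_sd``; the max-label control is
    ``N * d_frac * (1 - BE)`` plus the same noise. Deterministic given
    ``truth.seed``.
    """
    design = design or LabelingDesign()
    rng = np.random.default_rng([truth.seed, 1])
    d_frac = design.d_frac

    rows = []
    for pep in truth.peptides:
        for state in truth.states:
            for t in design.time_grid_min:
                n_rep = truth.replicate_plan.get(t, 1)
                true_up = expected_observed_uptake(truth, pep, state, t, d_frac)
                noise = rng.normal(0.0, truth.noise_sd, n_rep)
                for rep in range(1, n_rep + 1):
                    rows.append(
                        {
                            "start": pep.start,
                            "end": pep.end,
                            "sequence": pep.sequence,
                            "state": state,
                            "exposure_min": t,
                            "replicate": rep,
                            "uptake_D": max(0.0, true_up + noise[rep - 1]),
                        }
                    )
    measurements = pd.DataFrame(rows)

    ml_rows = []
    for pep in truth.peptides:
        be = truth.be_of(pep.key)
        uptake_max = max(
            0.0, pep.n_amides * d_frac * (1.0 - be) + rng.normal(0.0, truth.noise_sd)
        )
        ml_rows.append(
            {
                "start": pep.start,
                "end": pep.end,
                "sequence": pep.sequence,
                "m_max": pep.m0 + uptake_max,
                "uptake_max_D": uptake_max,
            }
        )
    max_label = pd.DataFrame(ml_rows)

    peptide_by_key = {p.key: p for p in truth.peptides}
    envelopes: list[IsotopeEnvelope] = []
    for (key, ex1_state), spec in truth.ex1.items():
        pep = peptide_by_key[key]
        be = truth.be_of(key)
        for state in truth.states:
            for t in design.time_grid_min:
                if state == ex1_state:
                    f, closed, open_ = simulate_ex1_mixture(spec, t, d_frac)
                    env = envelope_from_uptake(
                        pep,
                        thin_probabilities(closed, be),
                        charge=envelope_charge,
                        mixing=(thin_probabilities(open_, be), f),
                        noise_sd=envelope_noise_sd,
                        rng=rng,
                        state=state,
                        exposure_min=t,
                    )
                else:
                    kin = AmideKinetics.from_protection(truth.pf[key], truth.k_int_per_min)
                    probs = ex2_probabilities(kin, t, d_frac)
                    env = envelope_from_uptake(
                        pep,
                        thin_probabilities(probs, be),
                        charge=envelope_charge,
                        noise_sd=envelope_noise_sd,
                        rng=rng,
                        state=state,
                        exposure_min=t,
                    )
                envelopes.append(env)

    data = StudyData(
        truth=truth,
        design=design,
        measurements=measurements,
        max_label=max_label,
        envelopes=envelopes,
    )
    if out_dir is not None:
        _write_study(data, Path(out_dir))
    return data


def _write_study(data: StudyData, out_dir: Path) -> None:
    from .io import write_envelope, write_measurements

    out_dir.mkdir(parents=True, exist_ok=True)
    header = [f"seed: {data.truth.seed}", f"d_frac: {data.design.d_frac}"]
    write_measurements(data.measurements, out_dir / "uptake.csv", header)
    write_measurements(data.max_label, out_dir / "max_label.csv", header)
    env_dir = out_dir / "envelopes"
    env_dir.mkdir(exist_ok=True)
    for env in data.envelopes:
        name = f"env_{env.peptide.start}_{env.peptide.end}_{env.state}_{env.exposure_min:g}min.csv"
        write_envelope(env, env_dir / name, extra_meta={"seed": data.truth.seed})
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(data.truth.to_jsonable(), fh, indent=1, sort_keys=True)
    log.info(
        "wrote study to %s: %d measurements, %d peptides, %d envelopes",
        out_dir,
        len(data.measurements),
        len(data.truth.peptides),
        len(data.envelopes),
    )


# ---------------------------------------------------------------------------
# saturation binding assay


def simulate_binding_assay(
    kd_nM: float = 7.5,
    bmax: float = 100.0,
    ns_slope: float = 0.5,
    conc_grid_nM: tuple[float, ...] = (1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 48.0),
    n_rep: int = 3,
    noise_cv: float = 0.05,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate a saturation binding assay with a paired nonspecific series.

    Total signal is ``bmax * L / (kd + L) + ns_slope * L`` and the paired
    nonspecific signal ``ns_slope * L``, each multiplied by unit-mean
    lognormal noise with coefficient of variation ``noise_cv``. Returns a
    tidy DataFrame with columns ``concentration_nM, replicate, total,
    nonspecific``.
    """
    if kd_nM <= 0:
        raise ValidationError("kd must be positive")
    conc = np.asarray(conc_grid_nM, dtype=float)
    if np.any(conc <= 0):
        raise ValidationError("concentrations must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)

    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv**2)))

        def factor(size):
            return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)

    else:

        def factor(size):
            return np.ones(size)

    rows = []
    for rep in range(1, n_rep + 1):
        total = (bmax * conc / (kd_nM + conc) + ns_slope * conc) * factor(conc.size)
        nonspecific = ns_slope * conc * factor(conc.size)
        for L, tot, ns in zip(conc, total, nonspecific):
            rows.append(
                {
                    "concentration_nM": L,
                    "replicate": rep,
                    "total": tot,
                    "nonspecific": ns,
                }
            )
    return pd.DataFrame(rows)
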