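"""State-vs-state differential HDX analysis with the pooled-SD CI framework.

The significance machinery works at the level of a whole comparison (one
reference state vs one test state):

1. Per peptide, the difference profile dD(t) = mean uptake(reference) -
   mean uptake(test) at every shared time point. Positive dD means
   *decreased* HDX (stabilization) in the test state.
2. A single comparison-wide confidence threshold from pooled replicate
   standard deviations: the per-peptide, per-time sample SDs of both
   states are averaged into sigma_bar, the accumulated SD is
   sigma_ave = sqrt(n) * sigma_bar, and the zero-centered two-tailed
   threshold is CI = t_crit * sigma_ave / sqrt(n) = t_crit * sigma_bar,
   with t_crit from the Student t distribution with n - 1 degrees of
   freedom (4.303 for 95% and n = 3).
3. A hybrid decision rule per peptide: significant iff |dD| exceeds the CI
   at two consecutive time points, OR a per-time two-sample Student t-test
   rejects (p < alpha) at two consecutive time points where both states
   have replicates, OR the last time point alone shows |dD| at least twice
   the CI (an expanding difference not fully sampled by the time course).
4. Consolidation of peptide verdicts onto residues, with explicit
   mixed/no-coverage labels and a coverage percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import PeptideRecord, ProteinContext, ValidationError, get_logger
from .uptake import UptakeSeries

log = get_logger(__name__)

PeptideKey = tuple[int, int, str]

VERDICTS = ("increase", "decrease", "none")
RULES = ("consecutive_CI", "t_test", "last_point_2xCI", "none")


@dataclass
class DifferenceProfile:
    """Per-peptide uptake difference between two states over shared times.

    Sign convention: ``delta_D = mean(reference) - mean(test)``; positive
    values indicate decreased HDX (stabilization) in the test state.
    """

    peptide: PeptideRecord
    state_ref: str
    state_test: str
    times: np.ndarray
    delta_D: np.ndarray
    n_ref: np.ndarray
    n_test: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        self.delta_D = np.asarray(self.delta_D, float)
        self.n_ref = np.asarray(self.n_ref, int)
        self.n_test = np.asarray(self.n_test, int)


def difference_profile(series_ref: UptakeSeries, series_test: UptakeSeries) -> DifferenceProfile:
    """Difference profile over the time points shared by both states.

    Times present in only one state are omitted (and logged); having no
    shared time point at all is an error for that peptide.
    """
    if series_ref.peptide.key != series_test.peptide.key:
        raise ValidationError("difference profile requires the same peptide in both states")
    shared, ia, ib = np.intersect1d(series_ref.times, series_test.times, return_indices=True)
    if shared.size == 0:
        raise ValidationError(
            f"peptide {series_ref.peptide.label}: no shared time points between "
            f"{series_ref.state} and {series_test.state}"
        )
    dropped = set(series_ref.times) ^ set(series_test.times)
    if dropped:
        log.info(
            "peptide %s: %d time points present in only one state omitted",
            series_ref.peptide.label,
            len(dropped),
        )
    return DifferenceProfile(
        peptide=series_ref.peptide,
        state_ref=series_ref.state,
        state_test=series_test.state,
        times=shared,
        delta_D=series_ref.mean_D[ia] - series_test.mean_D[ib],
        n_ref=series_ref.n[ia],
        n_test=series_test.n[ib],
    )


# ---------------------------------------------------------------------------
# pooled-SD confidence threshold


@dataclass(frozen=True)
class CiThreshold:
    """Comparison-wide significance threshold from pooled replicate SDs.

    ``ci = t_crit * sigma_ave / sqrt(n) = t_crit * sigma_bar`` - the
    accumulated-SD formulation and the direct product are algebraically
    identical; both are carried for transparency.
    """

    sigma_bar: float
    n: int
    t_crit: float
    sigma_ave: float
    ci: float
    confidence: float = 0.95

    def __str__(self) -> str:
        return (
            f"CI threshold {self.ci:.3f} D "
            f"(sigma_bar={self.sigma_bar:.4f}, n={self.n}, t={self.t_crit:.3f}, "
            f"{self.confidence:.0%} two-tailed)"
        )


def ci_threshold(
    sds_ref,
    sds_test,
    n: int = 3,
    confidence: float = 0.95,
) -> CiThreshold:
    """Pooled-SD confidence threshold for one state-vs-state comparison.

    ``sds_ref``/``sds_test`` are the per-peptide, per-time replicate sample
    SDs of the two states (NaNs from single-replicate cells are ignored).
    ``sigma_bar`` is their plain arithmetic mean across both states,
    ``t_crit`` the two-tailed Student critical value with ``n - 1`` degrees
    of freedom.
    """
    if n < 2:
        raise ValidationError("replicate count n must be >= 2 for a CI threshold")
    pooled = np.concatenate([np.asarray(sds_ref, float).ravel(), np.asarray(sds_test, float).ravel()])
    pooled = pooled[~np.isnan(pooled)]
    if pooled.size == 0:
        raise ValidationError(
            "no replicate SDs available: at least one time point needs >= 2 "
            "replicates in some state to form the threshold"
        )
    sigma_bar = float(pooled.mean())
    t_crit = float(stats.t.ppf(0.5 + confidence / 2.0, df=n - 1))
    sigma_ave = float(np.sqrt(n) * sigma_bar)
    ci = t_crit * sigma_ave / np.sqrt(n)  # == t_crit * sigma_bar
    return CiThreshold(
        sigma_bar=sigma_bar,
        n=n,
        t_crit=t_crit,
        sigma_ave=sigma_ave,
        ci=float(ci),
        confidence=confidence,
    )


# ---------------------------------------------------------------------------
# hybrid significance rule


@dataclass
class SignificanceCall:
    """Verdict for one peptide in one comparison.

    ``verdict`` is "increase"/"decrease"/"none" (direction of HDX in the
    test state relative to the reference); ``rule_fired`` records which
    branch of the hybrid rule triggered, in fixed priority order.
    ``direction_unstable`` flags calls whose triggering time points
    disagreed in sign (the larger |dD| then sets the direction).
    """

    peptide: PeptideRecord
    verdict: str
    rule_fired: str
    supporting_times: list[float] = field(default_factory=list)
    direction_unstable: bool = False
    max_abs_delta_D: float = 0.0

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise ValidationError(f"unknown verdict {self.verdict!r}")
        if self.rule_fired not in RULES:
            raise ValidationError(f"unknown rule {self.rule_fired!r}")
        if (self.verdict == "none") != (self.rule_fired == "none"):
            raise ValidationError("verdict and rule_fired must be none together")


def _consecutive_run(mask: np.ndarray, min_run: int) -> np.ndarray | None:
    """Indices of the first run of True of length >= min_run, else None."""
    run: list[int] = []
    for i, ok in enumerate(mask):
        if ok:
            run.append(i)
            if len(run) >= min_run:
                return np.asarray(run)
        else:
            run = []
    return None


def _direction(deltas: np.ndarray) -> tuple[str, bool]:
    """Verdict direction from the triggering dD values.

    Positive dD = decreased HDX in test state -> "decrease"; mixed signs are
    resolved by the larger |dD| and flagged.
    """
    signs = np.sign(deltas)
    unstable = bool(len(set(signs[signs != 0])) > 1)
    lead = deltas[np.argmax(np.abs(deltas))]
    return ("decrease" if lead > 0 else "increase"), unstable


def classify_significance(
    profile: DifferenceProfile,
    ci: CiThreshold,
    replicate_data: dict[float, tuple[np.ndarray, np.ndarray]] | None = None,
    alpha: float = 0.01,
    min_consecutive: int = 2,
) -> SignificanceCall:
    """Apply the hybrid significance rule to one peptide's profile.

    Branches, evaluated in priority order:

    (a) ``consecutive_CI``: |dD| > CI at ``min_consecutive`` consecutive
        time points;
    (b) ``t_test``: a two-tailed two-sample pooled-variance Student t-test
        on the replicate uptake values rejects at ``alpha`` at
        ``min_consecutive`` consecutive time points where both states have
        >= 2 replicates (``replicate_data`` maps time -> (ref values, test
        values); without it this branch is disabled);
    (c) ``last_point_2xCI``: |dD| at the last time point >= 2 * CI.

    Missing replicates disable branch (b) only; peptides measured n = 1
    everywhere still participate via (a) and (c).
    """
    if profile.times.size < 2:
        raise ValidationError(
            f"peptide {profile.peptide.label}: need >= 2 time points to classify"
        )
    abs_d = np.abs(profile.delta_D)
    max_abs = float(abs_d.max())

    # (a) consecutive exceedance of the CI band
    run = _consecutive_run(abs_d > ci.ci, min_consecutive)
    if run is not None:
        verdict, unstable = _direction(profile.delta_D[run])
        return SignificanceCall(
            peptide=profile.peptide,
            verdict=verdict,
            rule_fired="consecutive_CI",
            supporting_times=[float(t) for t in profile.times[run]],
            direction_unstable=unstable,
            max_abs_delta_D=max_abs,
        )

    # (b) per-time Student t-test, same consecutiveness requirement
    if replicate_data:
        reject = np.zeros(profile.times.size, dtype=bool)
        for i, t in enumerate(profile.times):
            pair = replicate_data.get(float(t))
            if pair is None:
                continue
            ref_vals, test_vals = (np.asarray(v, float) for v in pair)
            if ref_vals.size < 2 or test_vals.size < 2:
                continue
            p = stats.ttest_ind(ref_vals, test_vals, equal_var=True).pvalue
            reject[i] = bool(p < alpha)
        run = _consecutive_run(reject, min_consecutive)
        if run is not None:
            verdict, unstable = _direction(profile.delta_D[run])
            return SignificanceCall(
                peptide=profile.peptide,
                verdict=verdict,
                rule_fired="t_test",
                supporting_times=[float(t) for t in profile.times[run]],
                direction_unstable=unstable,
                max_abs_delta_D=max_abs,
            )

    # (c) expanding difference at the final time point
    if abs_d[-1] >= 2.0 * ci.ci and ci.ci > 0:
        verdict, _ = _direction(profile.delta_D[-1:])
        return SignificanceCall(
            peptide=profile.peptide,
            verdict=verdict,
            rule_fired="last_point_2xCI",
            supporting_times=[float(profile.times[-1])],
            max_abs_delta_D=max_abs,
        )

    return SignificanceCall(
        peptide=profile.peptide,
        verdict="none",
        rule_fired="none",
        max_abs_delta_D=max_abs,
    )


# ---------------------------------------------------------------------------
# whole-comparison driver


@dataclass
class ComparisonResult:
    """All per-peptide outputs of one reference-vs-test comparison."""

    state_ref: str
    state_test: str
    ci: CiThreshold
    profiles: dict[PeptideKey, DifferenceProfile]
    calls: dict[PeptideKey, SignificanceCall]

    def table(self) -> pd.DataFrame:
        """One row per peptide x time: dD, CI, verdict, rule."""
        rows = []
        for key in sorted(self.profiles):
            prof, call = self.profiles[key], self.calls[key]
            for t, d in zip(prof.times, prof.delta_D):
                rows.append(
                    {
                        "start": key[0],
                        "end": key[1],
                        "sequence": key[2],
                        "state_ref": self.state_ref,
                        "state_test": self.state_test,
                        "exposure_min": t,
                        "delta_D": d,
                        "ci_D": self.ci.ci,
                        "verdict": call.verdict,
                        "rule_fired": call.rule_fired,
                        "direction_unstable": call.direction_unstable,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "start",
                "end",
                "sequence",
                "state_ref",
                "state_test",
                "exposure_min",
                "delta_D",
                "ci_D",
                "verdict",
                "rule_fired",
                "direction_unstable",
            ],
        )


def compare_states(
    measurements: pd.DataFrame,
    series: dict[tuple[PeptideKey, str], "UptakeSeries"],
    state_ref: str,
    state_test: str,
    n: int = 3,
    confidence: float = 0.95,
    alpha: float = 0.01,
    min_consecutive: int = 2,
) -> ComparisonResult:
    """Run the full differential analysis for one pair of states.

    Pools SDs across both states into a single threshold, builds every
    peptide's difference profile, gathers replicate values for the t-test
    branch, and classifies each peptide.
    """
    ref_series = {k: s for (k, st), s in series.items() if st == state_ref}
    test_series = {k: s for (k, st), s in series.items() if st == state_test}
    shared = sorted(set(ref_series) & set(test_series))
    if not shared:
        raise ValidationError(
            f"no peptides shared between states {state_ref!r} and {state_test!r}"
        )

    ci = ci_threshold(
        np.concatenate([ref_series[k].sd_D for k in shared]),
        np.concatenate([test_series[k].sd_D for k in shared]),
        n=n,
        confidence=confidence,
    )

    sub = measurements[measurements["state"].isin([state_ref, state_test])]
    rep_values: dict[tuple[PeptideKey, str, float], np.ndarray] = {
        (
            (int(start), int(end), str(seq)),
            str(state),
            float(t),
        ): g["uptake_D"].to_numpy()
        for (start, end, seq, state, t), g in sub.groupby(
            ["start", "end", "sequence", "state", "exposure_min"]
        )
    }

    profiles: dict[PeptideKey, DifferenceProfile] = {}
    calls: dict[PeptideKey, SignificanceCall] = {}
    for key in shared:
        prof = difference_profile(ref_series[key], test_series[key])
        replicate_data = {}
        for t in prof.times:
            ref_vals = rep_values.get((key, state_ref, float(t)))
            test_vals = rep_values.get((key, state_test, float(t)))
            if ref_vals is not None and test_vals is not None:
                replicate_data[float(t)] = (ref_vals, test_vals)
        profiles[key] = prof
        calls[key] = classify_significance(
            prof, ci, replicate_data, alpha=alpha, min_consecutive=min_consecutive
        )
    return ComparisonResult(
        state_ref=state_ref, state_test=state_test, ci=ci, profiles=profiles, calls=calls
    )


# ---------------------------------------------------------------------------
# residue-level consolidation


RESIDUE_LABELS = ("increase", "decrease", "none", "mixed", "no_coverage")


@dataclass
class ResidueClassificationMap:
    """Per-residue verdict labels over the whole construct sequence."""

    residues: np.ndarray
    labels: list[str]
    max_abs_delta_D: np.ndarray
    coverage_percent: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "residue": self.residues,
                "label": self.labels,
                "delta_D_max": self.max_abs_delta_D,
            }
        )

    def write_attributes(self, path) -> None:
        """Flat per-residue attribute file for painting onto a structure."""
        self.to_frame().to_csv(path, index=False)


def consolidate_residues(
    calls: dict[PeptideKey, SignificanceCall],
    peptides: dict[PeptideKey, PeptideRecord],
    protein: ProteinContext,
    coverage_denominator: int | None = None,
) -> ResidueClassificationMap:
    """Project peptide verdicts onto residues.

    A residue covered by significant peptides takes their verdict when they
    agree, "mixed" when they disagree; residues covered only by
    non-significant peptides are "none"; uncovered residues are
    "no_coverage". Significant verdicts take precedence over "none" from
    overlapping peptides. Coverage is the union of all peptide intervals
    over the construct length (or an explicit denominator).
    """
    first, last = protein.first_residue, protein.last_residue
    n_res = last - first + 1
    verdict_sets: list[set[str]] = [set() for _ in range(n_res)]
    covered = np.zeros(n_res, dtype=bool)
    max_abs = np.zeros(n_res, dtype=float)

    for key, call in calls.items():
        pep = peptides[key]
        lo, hi = pep.start - first, pep.end - first
        covered[lo : hi + 1] = True
        max_abs[lo : hi + 1] = np.maximum(max_abs[lo : hi + 1], call.max_abs_delta_D)
        if call.verdict != "none":
            for i in range(lo, hi + 1):
                verdict_sets[i].add(call.verdict)

    labels: list[str] = []
    for i in range(n_res):
        if not covered[i]:
            labels.append("no_coverage")
        elif not verdict_sets[i]:
            labels.append("none")
        elif len(verdict_sets[i]) == 1:
            labels.append(next(iter(verdict_sets[i])))
        else:
            labels.append("mixed")

    denom = coverage_denominator or n_res
    coverage = float(covered.sum()) / denom * 100.0
    return ResidueClassificationMap(
        residues=np.arange(first, last + 1),
        labels=labels,
        max_abs_delta_D=max_abs,
        coverage_percent=coverage,
    )


def coverage_percent(
    peptides: dict[PeptideKey, PeptideRecord] | list[PeptideRecord],
    protein: ProteinContext,
    denominator: int | None = None,
) -> float:
    """Percent of residues covered by the union of peptide intervals."""
    peps = peptides.values() if isinstance(peptides, dict) else peptides
    first = protein.first_residue
    covered = np.zeros(len(protein), dtype=bool)
    for p in peps:
        covered[p.start - first : p.end - first + 1] = True
    return float(covered.sum()) / (denominator or len(protein)) * 100.0
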