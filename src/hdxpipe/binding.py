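"""Equilibrium receptor-ligand occupancy and one-site saturation binding.

Occupancy with depletion
------------------------
HDX labeling of a receptor at micromolar concentration violates the usual
"ligand in vast excess" assumption: a non-trivial fraction of the ligand is
consumed by binding. The bound-receptor concentration then solves the
mass-action quadratic

    B^2 - (L + R + Kd) B + L R = 0,
    B = [(L + R + Kd) - sqrt((L + R + Kd)^2 - 4 L R)] / 2,

where L and R are *total* ligand and receptor. The physical root always
satisfies 0 <= B <= min(L, R). Occupancy is B / R. A no-depletion mode
(L / (L + Kd)) is available for comparison; it overestimates occupancy
whenever depletion matters. Occupancy functions work in uM by convention.

Saturation binding fit
----------------------
The activity assay measures total and nonspecific signal over a nanomolar
concentration series; after nonspecific subtraction the specific signal is
fit to the one-site model ``specific = Bmax * L / (Kd + L)`` by nonlinear
least squares (:class:`OneSiteBindingModel`, statsmodels-style: ``fit()``
returns a results object with estimates, asymptotic standard errors and a
``summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import ValidationError

NM_PER_UM = 1000.0


def um_to_nm(x: float) -> float:
    return x * NM_PER_UM


def nm_to_um(x: float) -> float:
    return x / NM_PER_UM


@dataclass(frozen=True)
class LigandSpec:
    """A ligand's binding parameters and the labeling totals, in uM."""

    name: str
    kd_uM: float
    l_total_uM: float
    r_total_uM: float = 0.31

    def __post_init__(self) -> None:
        if self.kd_uM <= 0 or self.l_total_uM < 0 or self.r_total_uM <= 0:
            raise ValidationError(f"ligand {self.name}: parameters must be positive")

    def occupancy(self, depletion: bool = True) -> float:
        return occupancy(self.l_total_uM, self.r_total_uM, self.kd_uM, depletion=depletion)


def bound_receptor(l_total: float, r_total: float, kd: float) -> float:
    """Bound-receptor concentration from the depletion quadratic (same units in/out)."""
    if kd < 0 or l_total < 0 or r_total <= 0:
        raise ValidationError("l_total, kd must be >= 0 and r_total > 0")
    s = l_total + r_total + kd
    disc = s * s - 4.0 * l_total * r_total
    # conjugate form of the smaller quadratic root: avoids catastrophic
    # cancellation when the bound fraction is small
    denom = s + np.sqrt(max(disc, 0.0))
    b = 2.0 * l_total * r_total / denom if denom > 0 else 0.0
    return float(np.clip(b, 0.0, min(l_total, r_total)))


def occupancy(l_total: float, r_total: float, kd: float, depletion: bool = True) -> float:
    """Fraction of receptor bound at equilibrium.

    ``depletion=True`` (default) solves the two-component quadratic with
    total concentrations; ``depletion=False`` uses the free-ligand
    approximation ``L / (L + Kd)``.
    """
    if not depletion:
        if l_total + kd <= 0:
            return 0.0
        return l_total / (l_total + kd)
    return bound_receptor(l_total, r_total, kd) / r_total


def required_ligand(target_occ: float, r_total: float, kd: float) -> float:
    """Total ligand needed to reach a target occupancy, exactly inverting
    the depletion quadratic: ``L = occ * R + Kd * occ / (1 - occ)``."""
    if not (0.0 < target_occ < 1.0):
        raise ValidationError(f"target occupancy must be in (0, 1), got {target_occ}")
    if r_total <= 0 or kd < 0:
        raise ValidationError("r_total must be > 0 and kd >= 0")
    return target_occ * r_total + kd * target_occ / (1.0 - target_occ)


# ---------------------------------------------------------------------------
# one-site saturation fit


def one_site(conc, bmax: float, kd: float):
    """Specific binding of the one-site model: ``Bmax * L / (Kd + L)``."""
    conc = np.asarray(conc, float)
    return bmax * conc / (kd + conc)


@dataclass
class BindingFitResults:
    """One-site fit results: estimates, asymptotic SEs, diagnostics."""

    kd_nM: float
    bmax: float
    kd_se: float
    bmax_se: float
    converged: bool
    concentrations_nM: np.ndarray
    specific: np.ndarray
    residuals: np.ndarray
    message: str = ""

    @property
    def ssr(self) -> float:
        return float(self.residuals @ self.residuals)

    def predict(self, conc_nM) -> np.ndarray:
        return one_site(conc_nM, self.bmax, self.kd_nM)

    def summary(self) -> str:
        lines = [
            "One-site saturation binding fit",
            "-" * 40,
            f"Kd     {self.kd_nM:10.3f} +/- {self.kd_se:.3f} nM",
            f"Bmax   {self.bmax:10.3f} +/- {self.bmax_se:.3f}",
            f"n obs  {self.concentrations_nM.size:10d}",
            f"SSR    {self.ssr:10.4g}",
            f"converged  {self.converged}",
        ]
        if self.message:
            lines.append(f"note: {self.message}")
        return "\n".join(lines)


@dataclass
class BindingCurve:
    """A measured concentration series with its fitted one-site parameters."""

    concentrations_nM: np.ndarray
    total: np.ndarray
    nonspecific: np.ndarray
    fit: BindingFitResults | None = None

    @property
    def specific(self) -> np.ndarray:
        return self.total - self.nonspecific


class OneSiteBindingModel:
    """Nonlinear least-squares model for one-site saturation binding.

    Built from specific-binding observations (nM concentration axis).
    Initialization: Kd0 is the concentration whose specific signal is
    nearest half of the maximum; Bmax0 is 1.2x the maximum signal.
    """

    def __init__(self, concentrations_nM, specific):
        conc = np.asarray(concentrations_nM, float)
        spec = np.asarray(specific, float)
        if conc.shape != spec.shape:
            raise ValidationError("concentration and signal arrays must match")
        if np.unique(conc).size < 4:
            raise ValidationError("one-site fit needs >= 4 distinct concentrations")
        if np.any(conc <= 0):
            raise ValidationError("concentrations must be positive")
        order = np.argsort(conc)
        self.conc = conc[order]
        self.specific = spec[order]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "OneSiteBindingModel":
        """Build from a tidy table with ``concentration_nM``, ``total`` and
        ``nonspecific`` columns, subtracting the paired nonspecific series
        (interpolated linearly in concentration when the grids differ)."""
        required = {"concentration_nM", "total"}
        missing = required - set(table.columns)
        if missing:
            raise ValidationError(f"binding table missing column(s) {sorted(missing)}")
        conc = table["concentration_nM"].to_numpy(float)
        total = table["total"].to_numpy(float)
        if "nonspecific" in table.columns and not table["nonspecific"].isna().all():
            ns_tab = (
                table.dropna(subset=["nonspecific"])
                .groupby("concentration_nM")["nonspecific"]
                .mean()
            )
            ns = np.interp(conc, ns_tab.index.to_numpy(), ns_tab.to_numpy())
        else:
            ns = np.zeros_like(total)
        return cls(conc, total - ns)

    def fit(self, max_nfev: int = 10000) -> BindingFitResults:
        conc, spec = self.conc, self.specific
        top = float(spec.max())
        half_idx = int(np.argmin(np.abs(spec - 0.5 * top)))
        kd0 = float(conc[half_idx])
        bmax0 = 1.2 * top
        try:
            popt, pcov = curve_fit(
                one_site,
                conc,
                spec,
                p0=[bmax0, kd0],
                bounds=([0.0, 1e-9], [np.inf, np.inf]),
                max_nfev=max_nfev,
            )
            bmax, kd = (float(v) for v in popt)
            se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
            return BindingFitResults(
                kd_nM=kd,
                bmax=bmax,
                kd_se=float(se[1]),
                bmax_se=float(se[0]),
                converged=True,
                concentrations_nM=conc,
                specific=spec,
                residuals=spec - one_site(conc, bmax, kd),
            )
        except RuntimeError as exc:  # non-convergence: flagged, never raised
            return BindingFitResults(
                kd_nM=float("nan"),
                bmax=float("nan"),
                kd_se=float("nan"),
                bmax_se=float("nan"),
                converged=False,
                concentrations_nM=conc,
                specific=spec,
                residuals=np.full_like(spec, np.nan),
                message=str(exc),
            )


def fit_one_site(concentrations_nM, specific) -> BindingFitResults:
    """Convenience: fit the one-site model to a specific-binding series."""
    return OneSiteBindingModel(concentrations_nM, specific).fit()


def fit_binding_table(table: pd.DataFrame) -> BindingCurve:
    """Nonspecific-subtract and fit a tidy total/nonspecific binding table."""
    model = OneSiteBindingModel.from_table(table)
    grouped = table.groupby("concentration_nM").mean(numeric_only=True)
    curve = BindingCurve(
        concentrations_nM=grouped.index.to_numpy(float),
        total=grouped["total"].to_numpy(float),
        nonspecific=grouped["nonspecific"].to_numpy(float)
        if "nonspecific" in grouped
        else np.zeros(len(grouped)),
        fit=model.fit(),
    )
    return curve
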