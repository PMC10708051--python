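"""Physical-chemistry analysis of donor/pi-acceptor charge-transfer complexes.

Implements the classic spectrophotometric toolbox for a 1:1 charge-transfer
complex (CTC) between an electron donor D and a pi-acceptor A observed
through its visible CT band:

* Benesi-Hildebrand linearization ``[A0]/A = 1/(eps*l) + 1/(K*eps*l*[D0])``
  giving the association constant K (L/mol) and molar absorptivity eps
  (L/mol/cm) from a donor titration at fixed acceptor concentration.
* Tauc analysis of a direct allowed transition, ``(alpha*h*nu)^2`` linear in
  photon energy above the absorption edge, whose x-intercept estimates the
  band-gap (HOMO-LUMO) energy Eg.
* Job's method of continuous variation for the complex stoichiometry.
* Empirical electronic constants: donor ionization potential from the CT
  band wavenumber, standard free energy of association from K, oscillator
  strength, transition dipole moment and resonance energy.
* Ranking of candidate electron-donating sites from a table of computed
  atomic partial charges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TitrationSeries",
    "BHResult",
    "JobSeries",
    "TaucResult",
    "ElectronicConstants",
    "ChargeTable",
    "BHModelError",
    "TaucFitError",
    "benesi_hildebrand",
    "tauc_band_gap",
    "ct_transition_energy",
    "ionization_potential",
    "standard_free_energy",
    "oscillator_strength",
    "transition_dipole",
    "resonance_energy",
    "jobs_ratio",
    "donor_site_ranking",
    "load_charge_table",
    "ug_per_ml_to_molar",
    "molar_to_ug_per_ml",
    "read_titration_csv",
    "write_titration_csv",
    "read_job_csv",
    "write_job_csv",
    "read_edge_csv",
    "write_edge_csv",
]

# photon-energy conversion: E(eV) = EV_NM / lambda(nm)
EV_NM = 1239.84
# gas constant, J/(mol K)
R_GAS = 8.314
#: molar mass (g/mol) of the bundled donor fixture, C17H18N6
DEFAULT_MOLAR_MASS = 306.37


class BHModelError(ValueError):
    """Benesi-Hildebrand model inapplicable to the supplied data."""


class TaucFitError(ValueError):
    """No acceptable linear region found in a Tauc plot."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class TitrationSeries:
    """Donor titration at fixed acceptor concentration.

    ``donor_concs`` (mol/L) and ``absorbances`` (AU, at the CT band) must
    have equal length >= 5; ``acceptor_conc`` is the fixed total acceptor
    concentration (mol/L) and ``path`` the optical path (cm).
    """

    donor_concs: np.ndarray
    acceptor_conc: float
    absorbances: np.ndarray
    path: float = 1.0

    def __post_init__(self) -> None:
        self.donor_concs = np.asarray(self.donor_concs, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.donor_concs.size != self.absorbances.size:
            raise ValueError("donor_concs and absorbances must have equal length")
        if self.donor_concs.size < 5:
            raise ValueError("a titration needs at least 5 points")
        if np.any(self.donor_concs <= 0) or self.acceptor_conc <= 0:
            raise ValueError("concentrations must be positive")
        if self.path <= 0:
            raise ValueError("optical path must be positive")


@dataclass
class BHResult:
    """Benesi-Hildebrand fit: K (L/mol), epsilon (L/mol/cm), regression
    slope/intercept of [A0]/A vs 1/[D0], and the fit R^2."""

    K: float
    epsilon: float
    r_squared: float
    slope: float
    intercept: float


@dataclass
class JobSeries:
    """Continuous-variation series at fixed total molarity.

    ``mole_fractions`` are the donor mole fractions in [0, 1], sorted
    ascending; ``absorbances`` the CT-band readings; ``total_conc`` the
    fixed combined molarity (mol/L).
    """

    mole_fractions: np.ndarray
    absorbances: np.ndarray
    total_conc: float

    def __post_init__(self) -> None:
        self.mole_fractions = np.asarray(self.mole_fractions, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.mole_fractions.size != self.absorbances.size:
            raise ValueError("mole_fractions and absorbances must have equal length")
        if self.mole_fractions.size < 5:
            raise ValueError("a Job series needs at least 5 points")
        if np.any(self.mole_fractions < 0) or np.any(self.mole_fractions > 1):
            raise ValueError("mole fractions must lie in [0, 1]")
        if np.any(np.diff(self.mole_fractions) <= 0):
            raise ValueError("mole fractions must be sorted strictly ascending")
        if self.total_conc <= 0:
            raise ValueError("total concentration must be positive")


@dataclass
class TaucResult:
    """Band gap Eg (eV) with diagnostics of the selected linear window."""

    eg: float
    slope: float
    intercept: float
    r_squared: float
    window: tuple[float, float]
    n_points: int


@dataclass
class ElectronicConstants:
    """Bundle of CT electronic constants (all optional fields may be None
    when their auxiliary inputs are unavailable)."""

    ip: float
    ct_energy: float
    band_gap: float | None
    delta_g0: float
    resonance_energy: float | None = None
    oscillator_strength: float | None = None
    dipole_moment: float | None = None


@dataclass
class ChargeTable:
    """Computed atomic partial charges (elementary charge units).

    Wraps a table with columns ``atom_number`` (unique positive int),
    ``atom_type`` (text) and ``partial_charge`` (e).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"atom_number", "atom_type", "partial_charge"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"charge table missing columns: {sorted(missing)}")
        nums = self.table["atom_number"]
        if nums.duplicated().any():
            raise ValueError("atom numbers must be unique")
        if (nums <= 0).any():
            raise ValueError("atom numbers must be positive")

    def charge(self, atom_number: int) -> float:
        sel = self.table.loc[self.table["atom_number"] == atom_number, "partial_charge"]
        if sel.empty:
            raise KeyError(f"atom number {atom_number} not in charge table")
        return float(sel.iloc[0])


def load_charge_table(path: str | Path) -> ChargeTable:
    """Load a partial-charge CSV (``atom_number,atom_type,partial_charge``)."""
    return ChargeTable(pd.read_csv(path, comment="#"))


# --------------------------------------------------------------------------
# unit helpers
# --------------------------------------------------------------------------

def ug_per_ml_to_molar(conc_ug_ml, molar_mass: float = DEFAULT_MOLAR_MASS):
    """Convert ug/mL to mol/L for the given molar mass (g/mol)."""
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    return np.asarray(conc_ug_ml, dtype=float) * 1e-3 / molar_mass


def molar_to_ug_per_ml(conc_molar, molar_mass: float = DEFAULT_MOLAR_MASS):
    """Convert mol/L to ug/mL for the given molar mass (g/mol)."""
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    return np.asarray(conc_molar, dtype=float) * 1e3 * molar_mass


# --------------------------------------------------------------------------
# Benesi-Hildebrand
# --------------------------------------------------------------------------

def benesi_hildebrand(t: TitrationSeries) -> BHResult:
    """Fit the Benesi-Hildebrand line and extract K and epsilon.

    Ordinary least squares of ``y = [A0]/A`` on ``x = 1/[D0]``; then
    ``epsilon = 1/(intercept * path)`` and ``K = intercept/slope``.  The
    linearization assumes 1:1 binding with the varied species far from
    saturating the acceptor; data violating it (non-positive slope or
    intercept) raise :class:`BHModelError` rather than returning a
    meaningless K.
    """
    if np.any(t.absorbances <= 0):
        raise BHModelError("absorbances must be positive for a B-H fit")
    x = 1.0 / t.donor_concs
    y = t.acceptor_conc / t.absorbances
    fit = stats.linregress(x, y)
    if fit.intercept <= 0 or fit.slope <= 0:
        raise BHModelError(
            "B-H model inapplicable: non-positive slope or intercept "
            f"(slope={fit.slope:.3g}, intercept={fit.intercept:.3g})"
        )
    return BHResult(
        K=fit.intercept / fit.slope,
        epsilon=1.0 / (fit.intercept * t.path),
        r_squared=fit.rvalue**2,
        slope=fit.slope,
        intercept=fit.intercept,
    )


# --------------------------------------------------------------------------
# Tauc band gap
# --------------------------------------------------------------------------

def _window_stats(cum: dict[str, np.ndarray], i: np.ndarray, j: np.ndarray):
    """OLS slope/intercept/R^2/slope-SE for windows [i, j] via prefix sums."""
    n = (j - i + 1).astype(float)
    sx = cum["x"][j + 1] - cum["x"][i]
    sy = cum["y"][j + 1] - cum["y"][i]
    sxx = cum["xx"][j + 1] - cum["xx"][i]
    sxy = cum["xy"][j + 1] - cum["xy"][i]
    syy = cum["yy"][j + 1] - cum["yy"][i]
    cxx = sxx - sx * sx / n
    cyy = syy - sy * sy / n
    cxy = sxy - sx * sy / n
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = cxy / cxx
        intercept = (sy - slope * sx) / n
        r2 = np.where(cyy > 0, cxy * cxy / (cxx * cyy), 0.0)
        resid = np.clip(cyy - slope * cxy, 0.0, None)
        se = np.where(n > 2, np.sqrt(resid / np.maximum(n - 2, 1) / cxx), 0.0)
    return slope, intercept, r2, se


def tauc_band_gap(
    energies_ev,
    alpha,
    window_min_points: int = 5,
    r2_min: float = 0.99,
) -> TaucResult:
    """Estimate a direct-transition band gap from a Tauc plot.

    Transforms the absorption coefficient to ``y = (alpha*h*nu)^2``, scans
    every contiguous window of at least ``window_min_points`` points and
    keeps windows that pass a two-part linearity gate: a positive slope
    with R^2 >= ``r2_min``, and agreement between the slopes fitted to the
    window's two halves (within 4 sigma of the cleaner half's slope
    standard error, or within relative 1e-6 for exact data).  The R^2 gate
    alone cannot reject a long window that drags in the flat below-edge
    foot, and short windows pass it by chance under noise; the equal-slope
    test catches both.  Among qualifying windows the longest wins, with
    ties broken by the larger slope and then the lower-energy start, so an
    exactly linear edge yields the full above-edge region.  Returns the
    x-intercept ``-intercept/slope`` as Eg.

    Raises :class:`TaucFitError` when no window qualifies; the error message
    carries the best R^2 seen, to aid diagnosing noisy or curved edges.
    """
    e = np.asarray(energies_ev, dtype=float)
    a = np.asarray(alpha, dtype=float)
    if e.size != a.size:
        raise ValueError("energies and alpha must have equal length")
    if window_min_points < 3:
        raise ValueError("window_min_points must be at least 3")
    if e.size < window_min_points:
        raise TaucFitError(
            f"need at least {window_min_points} points, got {e.size}"
        )
    if np.any(np.diff(e) <= 0):
        order = np.argsort(e)
        e, a = e[order], a[order]
    y = (a * e) ** 2
    cum = {
        "x": np.concatenate([[0.0], np.cumsum(e)]),
        "y": np.concatenate([[0.0], np.cumsum(y)]),
        "xx": np.concatenate([[0.0], np.cumsum(e * e)]),
        "xy": np.concatenate([[0.0], np.cumsum(e * y)]),
        "yy": np.concatenate([[0.0], np.cumsum(y * y)]),
    }
    n = e.size
    best = None  # (key, slope, intercept, r2, i, j)
    best_r2 = -np.inf
    # longest windows first: the first length with a qualifying window wins
    for length in range(n, window_min_points - 1, -1):
        i = np.arange(0, n - length + 1)
        j = i + length - 1
        slope, intercept, r2, _ = _window_stats(cum, i, j)
        mid = i + length // 2
        s1, _, _, se1 = _window_stats(cum, i, mid - 1)
        s2, _, _, se2 = _window_stats(cum, mid, j)
        # equal-slope-of-halves gate; the *cleaner* half sets the scale so a
        # curved half cannot widen its own tolerance
        tol = np.maximum(
            1e-6 * np.abs(slope), 4.0 * np.sqrt(2.0) * np.minimum(se1, se2)
        )
        ok = (slope > 0) & (r2 >= r2_min) & (np.abs(s1 - s2) <= tol)
        finite = np.isfinite(r2)
        if np.any(finite) and np.max(r2[finite]) > best_r2:
            best_r2 = float(np.max(r2[finite]))
        if np.any(ok):
            for idx in np.flatnonzero(ok):
                key = (float(slope[idx]), -int(i[idx]))
                if best is None or key > best[0]:
                    best = (
                        key,
                        float(slope[idx]),
                        float(intercept[idx]),
                        float(r2[idx]),
                        int(i[idx]),
                        int(j[idx]),
                    )
            break
    if best is None:
        raise TaucFitError(
            f"no linear region with R^2 >= {r2_min} "
            f"(best window R^2 = {best_r2:.4f})"
        )
    _, s, b, r2v, lo, hi = best
    return TaucResult(
        eg=-b / s,
        slope=s,
        intercept=b,
        r_squared=r2v,
        window=(float(e[lo]), float(e[hi])),
        n_points=hi - lo + 1,
    )


# --------------------------------------------------------------------------
# electronic constants
# --------------------------------------------------------------------------

def ct_transition_energy(lambda_max_nm: float) -> float:
    """Photon energy (eV) of the CT band maximum: E = 1239.84 / lambda."""
    if lambda_max_nm <= 0:
        raise ValueError("wavelength must be positive")
    return EV_NM / lambda_max_nm


def wavenumber(lambda_nm: float) -> float:
    """Wavenumber (cm^-1) of a wavelength in nm: nu = 1e7 / lambda."""
    if lambda_nm <= 0:
        raise ValueError("wavelength must be positive")
    return 1.0e7 / lambda_nm


def ionization_potential(lambda_max_nm: float) -> float:
    """Donor ionization potential (eV) from the CT band maximum.

    Uses the empirical linear relation for CT complexes,
    ``Ip = 5.76 + 1.53e-4 * nu`` with nu the band wavenumber in cm^-1.
    """
    return 5.76 + 1.53e-4 * wavenumber(lambda_max_nm)


def standard_free_energy(K: float, T: float = 298.0) -> float:
    """Standard free energy of association, ``-R T ln K``, in kJ/mol.

    T defaults to 298 K (ambient).  K <= 0 raises ``ValueError``.
    """
    if K <= 0:
        raise ValueError("association constant must be positive")
    if T <= 0:
        raise ValueError("temperature must be positive")
    return -R_GAS * T * np.log(K) / 1000.0


def oscillator_strength(epsilon_max: float, half_bandwidth: float) -> float:
    """Oscillator strength ``f = 4.32e-9 * eps_max * dnu_half``.

    ``half_bandwidth`` is the CT band full width at half maximum in cm^-1;
    it must be measured from the spectrum and supplied explicitly.
    """
    if epsilon_max is None or half_bandwidth is None:
        raise ValueError("insufficient data: epsilon_max and half_bandwidth required")
    if epsilon_max < 0 or half_bandwidth < 0:
        raise ValueError("epsilon_max and half_bandwidth must be non-negative")
    return 4.32e-9 * epsilon_max * half_bandwidth


def transition_dipole(
    epsilon_max: float, half_bandwidth: float, nu_max: float
) -> float:
    """Transition dipole moment (Debye),
    ``mu = 0.0958 * sqrt(eps_max * dnu_half / nu_max)``."""
    if any(v is None for v in (epsilon_max, half_bandwidth, nu_max)):
        raise ValueError(
            "insufficient data: epsilon_max, half_bandwidth and nu_max required"
        )
    if epsilon_max < 0 or half_bandwidth < 0:
        raise ValueError("epsilon_max and half_bandwidth must be non-negative")
    if nu_max <= 0:
        raise ValueError("nu_max must be positive")
    return 0.0958 * float(np.sqrt(epsilon_max * half_bandwidth / nu_max))


def resonance_energy(
    ip: float, electron_affinity: float, coulomb_term: float, ct_energy: float
) -> float:
    """Resonance (stabilization) energy of the CT transition, eV.

    From the energy balance ``h*nu_CT = Ip - EA - W + R_N``:
    ``R_N = h*nu_CT - Ip + EA + W``.  The acceptor electron affinity EA and
    the Coulomb term W must be supplied by the caller; there is no default.
    """
    if any(v is None for v in (ip, electron_affinity, coulomb_term, ct_energy)):
        raise ValueError(
            "insufficient data: ip, electron_affinity, coulomb_term and "
            "ct_energy are all required"
        )
    return ct_energy - ip + electron_affinity + coulomb_term


# --------------------------------------------------------------------------
# Job's method
# --------------------------------------------------------------------------

def jobs_ratio(
    j: JobSeries, snap_tolerance: float = 0.1
) -> tuple[float, float, str | None]:
    """Estimate complex stoichiometry by continuous variation.

    Fits a parabola to the 5 points centred on the empirical absorbance
    maximum (window clamped to the grid); the vertex ``x*`` is the donor
    mole fraction of maximum complexation and the donor:acceptor ratio is
    ``x*/(1-x*)``.  Returns ``(x_star, ratio, label)`` where ``label`` is
    the nearest small-integer ratio among 1:2, 1:1, 2:1 when ``x*`` is
    within ``snap_tolerance`` of 1/3, 1/2 or 2/3, else None.

    A maximum at a boundary mole fraction raises ``ValueError`` ("no
    interior maximum"); ties in the empirical maximum break toward lower x.
    """
    x, y = j.mole_fractions, j.absorbances
    imax = int(np.argmax(y))  # argmax takes the first, i.e. lowest x, on ties
    if imax == 0 or imax == x.size - 1:
        raise ValueError("no interior maximum in the Job series")
    lo = max(0, min(imax - 2, x.size - 5))
    xs, ys = x[lo : lo + 5], y[lo : lo + 5]
    a, b, _ = np.polyfit(xs, ys, 2)
    if a >= 0:
        raise ValueError("no interior maximum: Job curve not concave at peak")
    x_star = float(-b / (2.0 * a))
    if not (0.0 < x_star < 1.0):
        raise ValueError("no interior maximum: vertex outside (0, 1)")
    ratio = x_star / (1.0 - x_star)
    label = None
    for cand_x, cand_label in ((1.0 / 3.0, "1:2"), (0.5, "1:1"), (2.0 / 3.0, "2:1")):
        if abs(x_star - cand_x) <= snap_tolerance:
            if label is None or abs(x_star - cand_x) < abs(x_star - label[0]):
                label = (cand_x, cand_label)
    return x_star, ratio, None if label is None else label[1]


# --------------------------------------------------------------------------
# donor-site ranking
# --------------------------------------------------------------------------

# --------------------------------------------------------------------------
# CSV I/O for titration, Job and absorption-edge tables
# --------------------------------------------------------------------------

def write_titration_csv(t: TitrationSeries, path: str | Path) -> None:
    """Write ``donor_conc_molar,acceptor_conc_molar,absorbance,path_cm``."""
    pd.DataFrame(
        {
            "donor_conc_molar": t.donor_concs,
            "acceptor_conc_molar": t.acceptor_conc,
            "absorbance": t.absorbances,
            "path_cm": t.path,
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_titration_csv(path: str | Path) -> TitrationSeries:
    df = pd.read_csv(path, comment="#")
    required = {"donor_conc_molar", "acceptor_conc_molar", "absorbance"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    acceptor = df["acceptor_conc_molar"].unique()
    if acceptor.size != 1:
        raise ValueError(f"{path}: acceptor concentration must be fixed")
    path_cm = float(df["path_cm"].iloc[0]) if "path_cm" in df.columns else 1.0
    return TitrationSeries(
        donor_concs=df["donor_conc_molar"].to_numpy(dtype=float),
        acceptor_conc=float(acceptor[0]),
        absorbances=df["absorbance"].to_numpy(dtype=float),
        path=path_cm,
    )


def write_job_csv(j: JobSeries, path: str | Path) -> None:
    """Write ``mole_fraction,absorbance,total_conc_molar``."""
    pd.DataFrame(
        {
            "mole_fraction": j.mole_fractions,
            "absorbance": j.absorbances,
            "total_conc_molar": j.total_conc,
        }
    ).to_csv(path, index=False, float_format="%.10g")


def read_job_csv(path: str | Path) -> JobSeries:
    df = pd.read_csv(path, comment="#")
    required = {"mole_fraction", "absorbance", "total_conc_molar"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return JobSeries(
        mole_fractions=df["mole_fraction"].to_numpy(dtype=float),
        absorbances=df["absorbance"].to_numpy(dtype=float),
        total_conc=float(df["total_conc_molar"].iloc[0]),
    )


def write_edge_csv(energies_ev, alpha, path: str | Path) -> None:
    """Write an absorption edge as ``energy_ev,alpha``."""
    pd.DataFrame({"energy_ev": np.asarray(energies_ev), "alpha": np.asarray(alpha)}).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_edge_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, comment="#")
    required = {"energy_ev", "alpha"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df["energy_ev"].to_numpy(dtype=float), df["alpha"].to_numpy(dtype=float)


def donor_site_ranking(
    charges: ChargeTable, sites: Mapping[str, Iterable[int]]
) -> list[tuple[str, float]]:
    """Rank candidate electron-donating sites by partial-charge density.

    ``score(site) = |sum of signed partial charges over its atoms|``; sites
    are returned sorted by descending score (name as tie-break).  An atom
    number absent from the table raises ``KeyError`` naming it.
    """
    scored = []
    for name, atoms in sites.items():
        total = sum(charges.charge(int(n)) for n in atoms)
        scored.append((name, abs(total)))
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored
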