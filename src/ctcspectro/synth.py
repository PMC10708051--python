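"""Synthetic spectrophotometric data with known ground truth.

Every input the analysis chain consumes can be generated here: Gaussian-band
absorption spectra (Beer-Lambert mixtures), donor titrations under an exact
1:1 complexation equilibrium, Job continuous-variation series, direct-
transition absorption edges with a known band gap, and 96-well calibration
plates with heteroscedastic noise.  All generators are pure functions of
their parameters and a seed, so downstream estimators can be tested as
parameter-recovery problems.

Noise model: readings are perturbed multiplicatively (relative sd) and
additively (absolute sd, AU), both Gaussian.  The defaults (0.002 AU and
0.5 % relative) keep replicate RSDs in the low-percent range typical of a
plate reader.  Any stochastic call requires an explicit seed; there is no
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .characterization import JobSeries, TitrationSeries
from .spectra import Spectrum
from .validation import PlateLayout

__all__ = [
    "BandSpec",
    "EquilibriumSystem",
    "NoiseModel",
    "NOISELESS",
    "solve_1to1_equilibrium",
    "make_spectrum",
    "make_titration",
    "make_job_series",
    "make_tauc_edge",
    "make_calibration_plate",
    "PLATE_ROWS",
    "PLATE_COLS",
]

PLATE_ROWS = tuple("ABCDEFGH")
PLATE_COLS = tuple(range(1, 13))

#: default noise scales: 0.002 AU additive, 0.5 % relative
DEFAULT_SD_ABSOLUTE = 0.002
DEFAULT_SD_RELATIVE = 0.005


@dataclass(frozen=True)
class BandSpec:
    """A Gaussian absorption band in the wavelength domain.

    ``center`` (nm) > 0, ``width`` (Gaussian sigma, nm) > 0,
    ``height`` (peak absorbance, AU) >= 0.
    """

    center: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if self.center <= 0:
            raise ValueError("band center must be positive")
        if self.width <= 0:
            raise ValueError("band width must be positive")
        if self.height < 0:
            raise ValueError("band height must be non-negative")

    def evaluate(self, wavelengths: np.ndarray) -> np.ndarray:
        z = (np.asarray(wavelengths, dtype=float) - self.center) / self.width
        return self.height * np.exp(-0.5 * z * z)


@dataclass(frozen=True)
class EquilibriumSystem:
    """Parameters of a 1:1 donor-acceptor complexation equilibrium.

    ``K`` association constant (L/mol), ``epsilon`` molar absorptivity of
    the complex (L/mol/cm), ``path`` optical path (cm), plus the total
    (analytical) donor and acceptor concentrations (mol/L).
    """

    K: float
    epsilon: float
    path: float = 1.0
    donor_total: float = 0.0
    acceptor_total: float = 0.0

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("association constant must be non-negative")
        if self.epsilon < 0:
            raise ValueError("molar absorptivity must be non-negative")
        if self.path <= 0:
            raise ValueError("optical path must be positive")
        if self.donor_total < 0 or self.acceptor_total < 0:
            raise ValueError("total concentrations must be non-negative")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: ``x -> x*(1 + N(0, sd_relative)) + N(0, sd_absolute)``.

    A seed is mandatory whenever either sd is non-zero; the same seed always
    reproduces the same draw.
    """

    sd_absolute: float = 0.0
    sd_relative: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sd_absolute < 0 or self.sd_relative < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if (self.sd_absolute > 0 or self.sd_relative > 0) and self.seed is None:
            raise ValueError("a seed is required for non-zero noise")

    @property
    def is_noiseless(self) -> bool:
        return self.sd_absolute == 0 and self.sd_relative == 0

    def apply(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.is_noiseless:
            return values.copy()
        rng = np.random.default_rng(self.seed)
        rel = rng.normal(0.0, self.sd_relative, size=values.shape)
        add = rng.normal(0.0, self.sd_absolute, size=values.shape)
        return values * (1.0 + rel) + add


#: convenience noiseless model
NOISELESS = NoiseModel()


# --------------------------------------------------------------------------
# equilibrium solver
# --------------------------------------------------------------------------

def solve_1to1_equilibrium(system: EquilibriumSystem) -> float:
    """Exact complex concentration [DA] (mol/L) for 1:1 binding.

    Solves the mass-action relation ``K = c / ((D0-c)(A0-c))`` for the
    complex concentration c, taking the physical root of the quadratic
    ``c^2 - (D0+A0+1/K) c + D0*A0 = 0`` in the numerically stable form
    ``c = 2*D0*A0 / (b + sqrt(b^2 - 4*D0*A0))`` with ``b = D0+A0+1/K``,
    which avoids the catastrophic cancellation of the textbook
    ``(b - sqrt(...))/2`` expression at weak binding.  ``K = 0`` returns 0.
    """
    d0, a0, k = system.donor_total, system.acceptor_total, system.K
    if k == 0 or d0 == 0 or a0 == 0:
        return 0.0
    b = d0 + a0 + 1.0 / k
    disc = b * b - 4.0 * d0 * a0
    # disc >= (D0-A0)^2 + positive terms, so never negative analytically;
    # clamp to guard against rounding
    disc = max(disc, 0.0)
    return 2.0 * d0 * a0 / (b + float(np.sqrt(disc)))


# --------------------------------------------------------------------------
# generators
# --------------------------------------------------------------------------

def make_spectrum(
    bands: Sequence[BandSpec],
    grid: np.ndarray,
    noise: NoiseModel = NOISELESS,
    metadata: dict | None = None,
) -> Spectrum:
    """Beer-Lambert mixture of Gaussian bands on a wavelength grid (nm).

    The grid must be non-empty and strictly ascending.  An empty band list
    yields a flat zero trace.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2:
        raise ValueError("wavelength grid needs at least 2 points")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("wavelength grid must be strictly ascending")
    trace = np.zeros_like(grid)
    for band in bands:
        trace += band.evaluate(grid)
    return Spectrum(grid, noise.apply(trace), dict(metadata or {}))


def make_titration(
    system: EquilibriumSystem,
    donor_concs: Sequence[float],
    noise: NoiseModel = NOISELESS,
    mode: str = "equilibrium",
) -> TitrationSeries:
    """Donor titration at the template's fixed acceptor concentration.

    ``mode='equilibrium'`` computes each absorbance from the exact 1:1
    equilibrium: ``A_i = eps * path * [DA](D_i)``.

    ``mode='bh_exact'`` instead places the points exactly on the
    Benesi-Hildebrand line ``[A0]/A = 1/(eps*l) + 1/(K*eps*l*[D0])``.  The
    two modes differ because the B-H linearization is only approximate for
    exact-equilibrium data unless the varied species is in large excess;
    'bh_exact' exists so the downstream fit can be verified to float
    tolerance for any (K, eps).
    """
    donor_concs = np.asarray(donor_concs, dtype=float)
    if donor_concs.size < 2:
        raise ValueError("a titration needs at least 2 donor concentrations")
    if np.any(donor_concs <= 0):
        raise ValueError("donor concentrations must be positive")
    a0 = system.acceptor_total
    if a0 <= 0:
        raise ValueError("acceptor_total must be positive for a titration")
    el = system.epsilon * system.path
    if mode == "equilibrium":
        absorb = np.array(
            [
                el
                * solve_1to1_equilibrium(
                    EquilibriumSystem(
                        K=system.K,
                        epsilon=system.epsilon,
                        path=system.path,
                        donor_total=float(d),
                        acceptor_total=a0,
                    )
                )
                for d in donor_concs
            ]
        )
    elif mode == "bh_exact":
        if system.K <= 0 or el <= 0:
            raise ValueError("bh_exact mode requires positive K and epsilon")
        y = 1.0 / el + 1.0 / (system.K * el * donor_concs)
        absorb = a0 / y
    else:
        raise ValueError(f"unknown titration mode: {mode!r}")
    return TitrationSeries(
        donor_concs=donor_concs,
        acceptor_conc=a0,
        absorbances=noise.apply(absorb),
        path=system.path,
    )


def make_job_series(
    total_conc: float,
    K: float,
    epsilon: float,
    fractions: Sequence[float],
    noise: NoiseModel = NOISELESS,
    path: float = 1.0,
) -> JobSeries:
    """Continuous-variation series at fixed total molarity.

    At donor mole fraction x the totals are ``D0 = x*C`` and
    ``A0 = (1-x)*C``; the absorbance follows from the exact equilibrium.
    Fractions must lie in [0, 1] and ascend.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any(fractions < 0) or np.any(fractions > 1):
        raise ValueError("mole fractions must lie in [0, 1]")
    if total_conc <= 0:
        raise ValueError("total concentration must be positive")
    absorb = np.array(
        [
            epsilon
            * path
            * solve_1to1_equilibrium(
                EquilibriumSystem(
                    K=K,
                    epsilon=epsilon,
                    path=path,
                    donor_total=float(x) * total_conc,
                    acceptor_total=(1.0 - float(x)) * total_conc,
                )
            )
            for x in fractions
        ]
    )
    return JobSeries(
        mole_fractions=fractions,
        absorbances=noise.apply(absorb),
        total_conc=total_conc,
    )


def make_tauc_edge(
    eg_ev: float,
    edge_coefficient: float,
    grid_ev: Sequence[float],
    noise: NoiseModel = NOISELESS,
) -> tuple[np.ndarray, np.ndarray]:
    """Direct-transition absorption edge with a known band gap.

    Above the edge the absorption coefficient obeys
    ``alpha = sqrt(B*(h*nu - Eg)) / (h*nu)`` so that ``(alpha*h*nu)^2`` is
    exactly linear in photon energy with x-intercept Eg; below the edge
    alpha is zero.  Noise is applied to alpha.  Returns
    ``(energies_ev, alpha)``.
    """
    if eg_ev <= 0:
        raise ValueError("band gap must be positive")
    if edge_coefficient <= 0:
        raise ValueError("edge coefficient must be positive")
    e = np.asarray(grid_ev, dtype=float)
    if e.size < 2 or np.any(np.diff(e) <= 0):
        raise ValueError("photon-energy grid must be ascending with >= 2 points")
    alpha = np.where(
        e > eg_ev, np.sqrt(np.clip(edge_coefficient * (e - eg_ev), 0, None)) / e, 0.0
    )
    return e, noise.apply(alpha)


def make_calibration_plate(
    slope: float,
    intercept: float,
    conc_levels: Sequence[float],
    replicates: int,
    noise: NoiseModel = NOISELESS,
    blanks: int = 0,
) -> tuple[pd.DataFrame, PlateLayout]:
    """Simulated 96-well calibration plate.

    Standards at ``conc_levels`` (ug/mL) x ``replicates`` are laid out
    row-major from A1, followed by ``blanks`` blank wells; each well reads
    ``intercept + slope*C`` plus noise (blanks read the intercept, i.e. the
    reagent background).  Returns ``(plate, layout)``: the plate is an
    8x12 DataFrame (rows A-H, columns 1-12, NaN for unused wells), the
    layout maps ``well -> (sample_id, nominal_ug_ml, role)``.

    Requesting more than 96 wells raises ``ValueError``.
    """
    conc_levels = np.asarray(conc_levels, dtype=float)
    if replicates < 1:
        raise ValueError("replicates must be at least 1")
    n_wells = conc_levels.size * replicates + blanks
    if n_wells > 96:
        raise ValueError(f"{n_wells} wells requested, plate holds 96")
    concs = np.repeat(conc_levels, replicates)
    values = intercept + slope * concs
    values = np.concatenate([values, np.full(blanks, intercept)])
    values = noise.apply(values)
    plate = pd.DataFrame(
        np.full((8, 12), np.nan), index=list(PLATE_ROWS), columns=list(PLATE_COLS)
    )
    rows = []
    for idx in range(n_wells):
        r, c = divmod(idx, 12)
        well = f"{PLATE_ROWS[r]}{PLATE_COLS[c]}"
        plate.iloc[r, c] = values[idx]
        if idx < concs.size:
            level = idx // replicates
            rows.append(
                {
                    "well": well,
                    "sample_id": f"std_{conc_levels[level]:g}",
                    "nominal_ug_ml": concs[idx],
                    "role": "standard",
                }
            )
        else:
            rows.append(
                {"well": well, "sample_id": "blank", "nominal_ug_ml": 0.0, "role": "blank"}
            )
    layout = PlateLayout(
        pd.DataFrame(rows, columns=["well", "sample_id", "nominal_ug_ml", "role"])
    )
    return plate, layout
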