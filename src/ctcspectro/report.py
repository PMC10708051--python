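"""Scenario simulation and end-to-end report assembly.

A *scenario* bundles the ground-truth parameters of one donor/acceptor
charge-transfer system (band maximum, K, epsilon, band gap, titration and
Job conditions, calibration line).  ``simulate_scenario`` writes every file
the analysis workflows consume; ``characterize_report``, ``validate_report``
and ``greenness_report`` assemble JSON-serializable reports that embed the
configuration used, so identical inputs and seed give byte-identical output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import characterization as chz
from . import greenness as green
from . import synth
from . import validation as val
from .config import RunConfig
from .spectra import (
    Spectrum,
    ct_band_shift_check,
    find_band_maxima,
    read_spectrum_csv,
    write_spectrum_csv,
)

__all__ = [
    "Scenario",
    "load_scenario",
    "simulate_scenario",
    "characterize_report",
    "validate_report",
    "greenness_report",
    "dump_report",
]


@dataclass
class Scenario:
    """Ground-truth parameters of one charge-transfer system."""

    name: str
    lambda_max_nm: float
    association_constant: float
    molar_absorptivity: float
    band_gap_ev: float
    acceptor_total_molar: float
    donor_concs_molar: list[float]
    jobs_total_molar: float
    donor_band_centers_nm: list[float]
    donor_band_widths_nm: list[float]
    donor_band_heights_au: list[float]
    acceptor_band_centers_nm: list[float]
    acceptor_band_widths_nm: list[float]
    acceptor_band_heights_au: list[float]
    ct_band_width_nm: float
    ct_band_height_au: float
    calibration: dict


def load_scenario(source: str | Path) -> Scenario:
    """Load a scenario YAML; bare names resolve to bundled fixtures."""
    path = Path(source)
    if not path.exists():
        from . import data_path

        candidate = data_path(f"scenario_{source}.yaml")
        if not candidate.is_file():
            raise FileNotFoundError(f"no scenario file or bundled scenario {source!r}")
        raw = yaml.safe_load(candidate.read_text())
    else:
        raw = yaml.safe_load(path.read_text())
    return Scenario(**raw)


def _bands(centers, widths, heights) -> list[synth.BandSpec]:
    return [
        synth.BandSpec(c, w, h) for c, w, h in zip(centers, widths, heights)
    ]


def simulate_scenario(
    scenario: Scenario,
    outdir: str | Path,
    config: RunConfig,
    noise: synth.NoiseModel | None = None,
) -> dict[str, str]:
    """Generate every input file for one scenario.

    Writes donor/acceptor/reaction spectra, a Benesi-Hildebrand titration,
    a Job series, a Tauc absorption edge, a calibration plate with layout,
    and a ``truth.json`` sidecar echoing the generating parameters.  With
    ``noise=None`` the default plate-reader noise model (0.002 AU absolute,
    0.5 % relative) is used, seeded from the config.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if noise is None:
        noise = synth.NoiseModel(
            synth.DEFAULT_SD_ABSOLUTE, synth.DEFAULT_SD_RELATIVE, seed=config.seed
        )

    def subnoise(offset: int) -> synth.NoiseModel:
        if noise.is_noiseless:
            return noise
        return synth.NoiseModel(
            noise.sd_absolute, noise.sd_relative, seed=noise.seed + offset
        )

    files: dict[str, str] = {}
    grid = np.arange(200.0, 700.0, 0.5)
    donor_bands = _bands(
        scenario.donor_band_centers_nm,
        scenario.donor_band_widths_nm,
        scenario.donor_band_heights_au,
    )
    acceptor_bands = _bands(
        scenario.acceptor_band_centers_nm,
        scenario.acceptor_band_widths_nm,
        scenario.acceptor_band_heights_au,
    )
    ct_band = synth.BandSpec(
        scenario.lambda_max_nm, scenario.ct_band_width_nm, scenario.ct_band_height_au
    )
    for label, bands, off in (
        ("donor", donor_bands, 1),
        ("acceptor", acceptor_bands, 2),
        ("reaction", donor_bands + acceptor_bands + [ct_band], 3),
    ):
        spec = synth.make_spectrum(bands, grid, subnoise(off), {"scenario": scenario.name})
        dest = outdir / f"{label}_spectrum.csv"
        write_spectrum_csv(spec, dest)
        files[f"{label}_spectrum"] = str(dest)

    system = synth.EquilibriumSystem(
        K=scenario.association_constant,
        epsilon=scenario.molar_absorptivity,
        path=config.path_cm,
        acceptor_total=scenario.acceptor_total_molar,
    )
    titration = synth.make_titration(
        system, scenario.donor_concs_molar, subnoise(4), mode="bh_exact"
    )
    dest = outdir / "titration.csv"
    chz.write_titration_csv(titration, dest)
    files["titration"] = str(dest)

    job = synth.make_job_series(
        scenario.jobs_total_molar,
        scenario.association_constant,
        scenario.molar_absorptivity,
        np.linspace(0.1, 0.9, 9),
        subnoise(5),
        path=config.path_cm,
    )
    dest = outdir / "job.csv"
    chz.write_job_csv(job, dest)
    files["job"] = str(dest)

    energies, alpha = synth.make_tauc_edge(
        scenario.band_gap_ev, 1.0, np.arange(1.5, 3.5 + 1e-9, 0.01), subnoise(6)
    )
    dest = outdir / "tauc_edge.csv"
    chz.write_edge_csv(energies, alpha, dest)
    files["tauc_edge"] = str(dest)

    cal = scenario.calibration
    plate, layout = synth.make_calibration_plate(
        cal["slope"],
        cal["intercept"],
        cal["levels_ug_ml"],
        cal["replicates"],
        subnoise(7),
        blanks=cal.get("blanks", 0),
    )
    dest = outdir / "plate.csv"
    val.write_plate_csv(plate, dest)
    files["plate"] = str(dest)
    dest = outdir / "layout.csv"
    layout.table.to_csv(dest, index=False)
    files["layout"] = str(dest)

    truth = {
        "scenario": scenario.__dict__,
        "config": config.to_dict(),
        "noise": {
            "sd_absolute": noise.sd_absolute,
            "sd_relative": noise.sd_relative,
            "seed": noise.seed,
        },
    }
    dest = outdir / "truth.json"
    dest.write_text(json.dumps(truth, indent=2, sort_keys=True))
    files["truth"] = str(dest)
    return files


def characterize_report(
    config: RunConfig,
    titration_csv: str | Path | None = None,
    job_csv: str | Path | None = None,
    edge_csv: str | Path | None = None,
    reaction_spectrum_csv: str | Path | None = None,
    donor_spectrum_csv: str | Path | None = None,
    acceptor_spectrum_csv: str | Path | None = None,
    lambda_max_nm: float | None = None,
) -> dict:
    """Assemble a characterization report from whichever inputs exist.

    The CT band maximum comes from the new-band check when all three spectra
    are given, else from ``lambda_max_nm``.  Fields not computable from the
    supplied inputs are null in the report.
    """
    report: dict = {"config": config.to_dict()}

    lam = lambda_max_nm
    if reaction_spectrum_csv and donor_spectrum_csv and acceptor_spectrum_csv:
        reaction = read_spectrum_csv(reaction_spectrum_csv)
        donor = read_spectrum_csv(donor_spectrum_csv)
        acceptor = read_spectrum_csv(acceptor_spectrum_csv)
        new_bands = ct_band_shift_check(
            reaction, donor, acceptor, config.min_shift_nm, config.prominence_frac
        )
        report["new_bands_nm"] = [round(w, 3) for w, _ in new_bands]
        if new_bands and lam is None:
            # the CT band is the strongest new band
            lam = max(new_bands, key=lambda t: t[1])[0]

    report["lambda_max_nm"] = lam
    if lam is not None:
        report["ct_transition_energy_ev"] = chz.ct_transition_energy(lam)
        report["ionization_potential_ev"] = chz.ionization_potential(lam)
    else:
        report["ct_transition_energy_ev"] = None
        report["ionization_potential_ev"] = None

    if titration_csv:
        bh = chz.benesi_hildebrand(chz.read_titration_csv(titration_csv))
        report["association_constant_L_mol"] = bh.K
        report["molar_absorptivity_L_mol_cm"] = bh.epsilon
        report["bh_r_squared"] = bh.r_squared
        report["standard_free_energy_kJ_mol"] = chz.standard_free_energy(
            bh.K, config.temperature_k
        )
    else:
        report["association_constant_L_mol"] = None
        report["molar_absorptivity_L_mol_cm"] = None
        report["bh_r_squared"] = None
        report["standard_free_energy_kJ_mol"] = None

    if edge_csv:
        energies, alpha = chz.read_edge_csv(edge_csv)
        tauc = chz.tauc_band_gap(
            energies, alpha, config.tauc_window_min_points, config.tauc_r2_min
        )
        report["band_gap_ev"] = tauc.eg
        report["tauc_window_ev"] = list(tauc.window)
        report["tauc_r_squared"] = tauc.r_squared
    else:
        report["band_gap_ev"] = None

    if job_csv:
        x_star, ratio, label = chz.jobs_ratio(
            chz.read_job_csv(job_csv), config.job_snap_tolerance
        )
        report["jobs_x_star"] = x_star
        report["jobs_ratio"] = ratio
        report["jobs_ratio_label"] = label
    else:
        report["jobs_x_star"] = None
        report["jobs_ratio"] = None
        report["jobs_ratio_label"] = None
    return report


def validate_report(
    config: RunConfig, plate_csv: str | Path, layout_csv: str | Path
) -> dict:
    """Calibration + LOD/LOQ + unknown quantitation report for one plate."""
    plate = val.read_plate_csv(plate_csv)
    layout = val.read_layout_csv(layout_csv)
    corrected = val.blank_correct(plate, layout)
    fit = val.fit_calibration_from_plate(corrected, layout, blanked=False)
    lod, loq = val.lod_loq(fit)
    unknowns = val.quantify_unknowns(fit, corrected, layout)
    per_sample = []
    for sample_id, group in unknowns[unknowns["role"] == "unknown"].groupby("sample_id"):
        entry = {
            "sample_id": sample_id,
            "n": int(len(group)),
            "mean_conc_ug_ml": float(group["conc_ug_ml"].mean()),
            "in_range": bool(group["in_range"].all()),
        }
        layout_rows = layout.table[layout.table["sample_id"] == sample_id]
        nominal = float(layout_rows["nominal_ug_ml"].iloc[0])
        if nominal > 0 and len(group) >= 2:
            entry.update(val.precision_accuracy(group["conc_ug_ml"], nominal))
            entry["nominal_ug_ml"] = nominal
            entry["label_claim_pct"] = val.label_claim(
                entry["mean_conc_ug_ml"], nominal
            )
        per_sample.append(entry)
    return {
        "config": config.to_dict(),
        "calibration": {
            "slope": fit.slope,
            "intercept": fit.intercept,
            "r_squared": fit.r_squared,
            "intercept_se": fit.intercept_se,
            "n": fit.n,
            "linear_range_ug_ml": list(fit.conc_range),
        },
        "lod_ug_ml": lod,
        "loq_ug_ml": loq,
        "samples": per_sample,
    }


def greenness_report(ledger_path: str | Path) -> dict:
    """Eco-Scale report: itemized ledger, subtotals, score, text table."""
    ledger = green.load_ledger(ledger_path)
    result = green.aes_score(ledger)
    return {
        "method": ledger.method,
        "items": [
            {"category": i.category, "description": i.description, "pp": i.pp}
            for i in ledger.items
        ],
        "subtotals": {c: ledger.subtotal(c) for c in green.CATEGORIES},
        **result,
        "table": green.format_ledger_table(ledger),
    }


def dump_report(report: dict, path: str | Path | None) -> str:
    """Serialize a report deterministically (sorted keys, fixed format)."""
    text = json.dumps(report, indent=2, sort_keys=True, allow_nan=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text
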