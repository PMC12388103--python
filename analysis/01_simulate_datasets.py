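"""Generate the full synthetic data bundle emulating the study design.

Two ligand scenarios — a weak binder (Kb = 13.64e3 L/mol, the Sotorasib-like
case) and a strong binder (Kb = 63.67e3, Adagrasib-like) — titrated into
2 uM albumin over 0-33 uM in 3 uM steps, plus UV spectra, emission spectra,
EEMs at 2.5:1 and 5:1 drug:protein ratios, and a 1:1 Job series at constant
total 2 uM. All outputs land under results/data/ as CSV.
"""

from pathlib import Path

import numpy as np

from hsabind import io as hio
from hsabind.datamodel import GroundTruth
from hsabind.synthetic import (
    EEMPeak,
    simulate_eem,
    simulate_emission_spectrum,
    simulate_job_series,
    simulate_titration,
    simulate_uv_spectrum,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20250919

# Stern-Volmer constants of the two reference ligands (L/mol); the SV-mode
# simulator reproduces the published linear quenching law exactly.
SCENARIOS = {
    "weak_binder": {"ksv": 2.64e3, "kb": 13.64e3, "uv_shift": 7.0, "em_shift": -0.4,
                    "eem": {2.5: (3435, 1617), 5.0: (3159, 1573)}},
    "strong_binder": {"ksv": 60.73e3, "kb": 63.67e3, "uv_shift": 8.0, "em_shift": 5.4,
                      "eem": {2.5: (3156, 1573), 5.0: (2915, 1518)}},
}
EEM_REFERENCE = (3462.0, 1680.0)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    uv_grid = np.arange(200.0, 400.5, 0.5)
    em_grid = np.arange(300.0, 400.1, 0.2)

    ref_uv = simulate_uv_spectrum(
        [(211.0, 6.0, 1.0), (280.0, 12.0, 0.12)], uv_grid, label="protein_only"
    )
    hio.write_spectrum_csv(ref_uv, OUT / "uv_reference.csv")
    ref_em = simulate_emission_spectrum(338.0, 18.0, 1000.0, em_grid,
                                        label="protein_only")
    hio.write_spectrum_csv(ref_em, OUT / "emission_reference.csv")
    ref_eem = simulate_eem(
        [EEMPeak(220, 345, EEM_REFERENCE[0]), EEMPeak(275, 350, EEM_REFERENCE[1])],
        label="protein_only",
    )
    hio.write_eem_csv(ref_eem, OUT / "eem_reference.csv")

    for name, sc in SCENARIOS.items():
        truth = GroundTruth(kb=sc["ksv"], mode="stern_volmer",
                            noise_sd_fraction=0.005, seed=SEED)
        series = simulate_titration(truth, label=name)
        hio.write_titration_csv(series, OUT / f"titration_{name}.csv")

        uv = simulate_uv_spectrum(
            [(211.0 + sc["uv_shift"], 6.0, 1.05), (280.0, 12.0, 0.13)],
            uv_grid, label=name,
        )
        hio.write_spectrum_csv(uv, OUT / f"uv_{name}.csv")
        em = simulate_emission_spectrum(338.0 + sc["em_shift"], 18.0, 700.0,
                                        em_grid, label=name)
        hio.write_spectrum_csv(em, OUT / f"emission_{name}.csv")

        for ratio, (p1, p2) in sc["eem"].items():
            eem = simulate_eem(
                [EEMPeak(220, 345, p1), EEMPeak(275, 350, p2)],
                label=f"{name}_{ratio:g}to1",
            )
            hio.write_eem_csv(eem, OUT / f"eem_{name}_{ratio:g}to1.csv")

    job = simulate_job_series(
        GroundTruth(kb=63.67e3, n_stoich=1, noise_sd_fraction=0.005, seed=SEED),
        total_conc=2.0e-6,
        mole_fractions=np.arange(0.0, 1.0001, 0.05),
        label="strong_binder",
    )
    hio.write_job_csv(job, OUT / "job_strong_binder.csv")

    n_files = len(list(OUT.glob("*.csv")))
    print(f"wrote {n_files} CSV files to {OUT}")


if __name__ == "__main__":
    main()
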