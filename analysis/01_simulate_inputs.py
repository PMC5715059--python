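"""Generate the synthetic study inputs used by the downstream analyses.

Emulates the data modalities of a rat-vs-kangaroo collagen matrix
comparison with two synthetic "preparations" that share identical ground
truth (the study's null scenario: the alternative collagen source should be
indistinguishable).  Images land in scratch/ (binary), tables in results/.
"""

from pathlib import Path

import pandas as pd
import tifffile
import numpy as np

from orgmatrix import simulate as sim

ROOT = Path(__file__).resolve().parents[1]
SCRATCH = ROOT / "scratch" / "inputs"
RESULTS = ROOT / "results"

PREPARATIONS = {"rat": 0, "kangaroo": 100}  # label -> seed offset


def main() -> None:
    SCRATCH.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(parents=True, exist_ok=True)

    for prep, offset in PREPARATIONS.items():
        # SEM-like fibre micrographs (moderate alignment, shared kappa)
        fibre = sim.generate_fibre_image(sim.FibreFieldSpec(
            512, 512, 600, orientation_mean_deg=40.0, orientation_kappa=5.0,
            seed=offset + 1))
        tifffile.imwrite(SCRATCH / f"{prep}_fibres.tif",
                         (fibre.image * 65535).astype(np.uint16))

        # SHG-like textures with the same correlation length for both preps
        texture = sim.generate_correlated_texture(
            sim.TextureFieldSpec(512, 512, 8.0, seed=offset + 2))
        tifffile.imwrite(SCRATCH / f"{prep}_texture.tif",
                         (texture * 65535).astype(np.uint16))

        # AFM force-curve grid: 3 areas x 9 points, soft-matrix modulus
        for area in range(3):
            for point in range(9):
                curve = sim.generate_force_curve(sim.ForceCurveSpec(
                    5000.0, contact_z_um=2.0, force_noise_sd_nN=0.12,
                    seed=offset + 10 + 9 * area + point))
                pd.DataFrame({"z_um": curve.z_um,
                              "force_nN": curve.force_nN}).to_csv(
                    SCRATCH / f"{prep}_afm_a{area}_p{point}.csv", index=False)

        # polarized-light birefringence scene
        scene = sim.generate_histology_scene(sim.HistologySceneSpec(
            {"red_orange": 0.30, "yellow": 0.20, "green": 0.35,
             "background": 0.15}, 512, 512, seed=offset + 50))
        tifffile.imwrite(SCRATCH / f"{prep}_hsb.tif", scene.hsb)

    # drug-screen invasion counts (shared across preparations)
    vehicle = (0.05, 0.03, 0.02, 0.0)
    spec = sim.InvasionTableSpec(
        ("DMSO", "Y-27632", "Gefitinib"), "DMSO",
        {"DMSO": vehicle,
         "Y-27632": tuple(0.4 * f for f in vehicle),
         "Gefitinib": tuple(0.6 * f for f in vehicle)},
        replicates_per_condition=4, rois_per_replicate=9, seed=7)
    sim.generate_invasion_counts(spec).to_csv(
        RESULTS / "invasion_counts.csv", index=False)

    # fibroblast-marker Ct table, rat as reference group
    ct = sim.generate_ct_table(sim.CtTableSpec(
        ("ACTA2", "THY1", "TGFB1"), ("rat", "kangaroo"),
        {"ACTA2": 1.3, "THY1": 0.9, "TGFB1": 1.1},
        ct_noise_sd=0.25, replicates=4, seed=8))
    ct.to_csv(RESULTS / "ct_table.csv", index=False)

    print(f"inputs written to {SCRATCH} and {RESULTS}")


if __name__ == "__main__":
    main()
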