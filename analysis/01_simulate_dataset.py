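#!/usr/bin/env python
"""Generate the full synthetic input set for the treatment grid.

Writes reflectance spectra, rapid light curves and excitation spectra for
every treatment cell (4 intensities x mesophotic/shallow plus shallow+red
at 350 umol photons m^-2 s^-1; 2 replicates each), one example
time-resolved fluorescence surface, and the ground-truth record, all under
scratch/synthetic/.  Downstream scripts regenerate what they need, so this
step exists to inspect the raw inputs.
"""

import numpy as np

from phycoflux import io
from phycoflux.experiments import default_grids
from phycoflux.synthetic_data import GroundTruth, simulate_surface
from phycoflux.workflow import generate_synthetic_manifest

OUT = "scratch/synthetic"


def main() -> None:
    truth = GroundTruth(seed=1)
    config = generate_synthetic_manifest(truth, OUT, replicates=2)
    print(f"wrote {len(config.samples)} samples ({len(config.samples) * 3} files) to {OUT}/")

    time_grid, wavelength_grid = default_grids()
    noisy, _ = simulate_surface(truth, time_grid, wavelength_grid)
    io.write_surface(f"{OUT}/example_surface.csv", noisy)
    print(
        f"example surface: {noisy.time.size} x {noisy.wavelength.size} grid, "
        f"peak intensity {noisy.intensity.max():.3f} (truth: 50/50 ps transfer, 220 ps terminal)"
    )
    print(f"ground truth recorded in {OUT}/truth.yaml")


if __name__ == "__main__":
    main()
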