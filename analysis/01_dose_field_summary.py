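#!/usr/bin/env python
"""Dosimetric summary of the microbeam field model.

Builds the study collimator (30 µm slits, 300 µm pitch, PVDR 45.77,
2 x 2 cm field), verifies that the modeled field reproduces the measured
peak/valley dose-rate bookkeeping and the configured PVDR at 0° and 45°,
and exports a small dose-map patch as CSV.
"""

import argparse
from pathlib import Path

import pandas as pd

from mrtfrac.dose_field import (
    IntegrationDomain,
    MicrobeamGeometry,
    fraction_dose_map,
    pvdr_of_map,
    save_dose_map,
    valley_from_peak,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    geometry = MicrobeamGeometry()
    domain = IntegrationDomain(extent_mm=3.0, resolution_um=5.0)

    valley_rate = valley_from_peak(4.31, geometry.pvdr)
    rows = [{"quantity": "valley_dose_rate_gy_per_min", "value": valley_rate}]
    print(f"peak dose rate 4.31 Gy/min at PVDR {geometry.pvdr} -> "
          f"valley {valley_rate:.4f} Gy/min (prints as {valley_rate:.2f})")

    for angle in (0.0, 45.0):
        m = fraction_dose_map(geometry, 1.0, angle, domain)
        pvdr = pvdr_of_map(m, geometry)
        rows.append({"quantity": f"pvdr_recovered_angle_{angle:g}", "value": pvdr})
        print(f"PVDR recovered from the {angle:g} deg map: {pvdr:.6f}")

    patch = IntegrationDomain(extent_mm=0.9, resolution_um=5.0)
    save_dose_map(fraction_dose_map(geometry, 1.0, 45.0, patch),
                  args.out / "dose_map_45deg_patch.csv")
    pd.DataFrame(rows).to_csv(args.out / "dose_field_summary.csv", index=False)
    print(f"wrote {args.out}/dose_field_summary.csv and a 0.9 mm map patch")


if __name__ == "__main__":
    main()
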