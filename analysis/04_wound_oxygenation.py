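#!/usr/bin/env python
"""Ratiometric wound-bed oxygenation: inversion accuracy and group contrast.

Verifies the Stern-Volmer round trip on a graded oxygen phantom, then runs a
two-group (treated vs control) wound study in which treatment doubles tissue
oxygen, reporting mean gray values relative to a day-0 reference.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mpam import oxymap, synthetic as syn

RESULTS = Path("results")


def inversion_check(ksv=1.3):
    po2 = np.linspace(0.05, 3.0, 400).reshape(20, 20)
    pair = syn.simulate_ratiometric_images(po2, ksv=ksv, backgrounds=(0.2, 0.4))
    blue, red = oxymap.subtract_background(pair)
    image = oxymap.ratio_map(blue, red, red_floor=1e-9)
    recovered = oxymap.invert_stern_volmer(image, ksv=ksv, ratio0=1.0)
    return float(np.nanmax(np.abs(recovered - po2) / po2))


def group_study(seed=1, reps=4, days=(0, 3, 6, 10), ksv=1.0):
    rows = []
    s = seed
    roi = np.ones((32, 32), dtype=bool)
    for day in days:
        for group, level in (("treated", 2.0), ("control", 1.0)):
            for rep in range(reps):
                field = np.full((32, 32), level * (1 + 0.05 * day))
                pair = syn.simulate_ratiometric_images(field, ksv=ksv, noise_sd=0.01, seed=s)
                s += 1
                blue, red = oxymap.subtract_background(pair)
                image = oxymap.ratio_map(blue, red, red_floor=1e-6, gray_bounds=(0, 6))
                rows.append({"day": day, "group": group, "replicate": rep,
                             "mean_gray": oxymap.mean_gray(image, roi)})
    df = pd.DataFrame(rows)
    reference = df[(df["day"] == 0) & (df["group"] == "control")]["mean_gray"].mean()
    return oxymap.relative_oxygenation(df, reference=reference)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    max_err = inversion_check()
    print(f"Stern-Volmer inversion on a noiseless graded phantom: "
          f"max relative pO2 error = {max_err:.2e}")

    out = group_study()
    out.to_csv(RESULTS / "wound_oxygenation.csv", index=False)
    print("relative wound-bed oxygenation (% of control day 0, mean +/- SEM):")
    print(out.round(1).to_string(index=False))
    wide = out.pivot(index="day", columns="group", values="mean")
    assert (wide["treated"] > wide["control"]).all()
    print("treated > control at every day, as programmed")


if __name__ == "__main__":
    main()
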